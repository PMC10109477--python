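"""Welch-from-summaries, Tukey HSD, pooled CIs, percent reduction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ihtsim import (
    GroupSummary,
    anova_tukey,
    group_ci,
    load_waiting_time_summaries,
    percent_reduction,
    pooled_mse,
    welch_from_summary,
)


def _exact_sample(rng, n, mean, sd):
    """A sample with exactly the requested mean and (n-1)-denominator SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestWelch:
    def test_night_validation_row(self):
        # 13 observed days vs 30 simulated days of nightly request counts.
        res = welch_from_summary(13, 2.31, 0.82, 30, 2.07, 0.27)
        assert res.diff == pytest.approx(0.24)
        assert round(res.ci_high, 3) == 2.092
        assert res.p == pytest.approx(0.78, abs=0.01)
        assert res.df == 14  # truncated Welch–Satterthwaite value

    def test_morning_validation_row(self):
        res = welch_from_summary(13, 49.54, 2.5, 30, 46.63, 0.94)
        assert res.diff == pytest.approx(2.91)
        assert res.p > 0.05

    def test_identical_summaries_give_zero_diff_unit_p(self):
        res = welch_from_summary(10, 5.0, 0.5, 10, 5.0, 0.5)
        assert res.diff == 0.0 and res.p == pytest.approx(1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            welch_from_summary(10, 5.0, 0.0, 10, 5.0, 0.5)

    def test_ci_contains_diff(self):
        res = welch_from_summary(5, 1.0, 0.2, 8, 3.0, 0.4)
        assert res.ci_low <= res.diff <= res.ci_high

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n1=st.integers(5, 40),
        n2=st.integers(5, 40),
        shift=st.floats(-3, 3, allow_nan=False),
    )
    def test_matches_raw_welch_test(self, seed, n1, n2, shift):
        """Summaries computed from raw samples reproduce scipy's raw-data
        Welch test exactly when fractional df is kept."""
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, n1), rng.normal(shift, 2, n2)
        res = welch_from_summary(
            n1, x.mean(), x.std(ddof=1) / math.sqrt(n1),
            n2, y.mean(), y.std(ddof=1) / math.sqrt(n2),
            integer_df=False,
        )
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


@pytest.fixture(scope="module")
def table8():
    return load_waiting_time_summaries()


@pytest.fixture(scope="module")
def tukey(table8):
    return {frozenset(r.pair): r for r in anova_tukey(table8)}


class TestTukey:
    def test_published_headline_pair(self, tukey):
        r = tukey[frozenset(("Mabc:1:8", "M0:2:6"))]
        d = r.diff if r.pair[0] == "Mabc:1:8" else -r.diff
        assert d == pytest.approx(-0.756, abs=5e-4)
        assert r.se_diff == pytest.approx(0.113, abs=1e-3)
        assert abs(r.t) == pytest.approx(6.72, abs=0.01)
        lo, hi = (r.ci_low, r.ci_high) if r.pair[0] == "Mabc:1:8" else (-r.ci_high, -r.ci_low)
        assert lo == pytest.approx(-1.154, abs=2e-3)
        assert hi == pytest.approx(-0.357, abs=2e-3)
        assert r.p_adj < 0.001

    def test_published_contrast_diffs(self, tukey):
        r1 = tukey[frozenset(("Mab:2:6", "M0:2:6"))]
        assert abs(r1.diff) == pytest.approx(0.6841, abs=1e-4)
        r2 = tukey[frozenset(("Mabc:1:8", "M0:1:8"))]
        assert abs(r2.diff) == pytest.approx(0.2558, abs=1e-4)
        assert r2.p_adj == pytest.approx(0.753, abs=0.01)

    def test_se_diff_constant_across_pairs(self, table8):
        ses = {r.se_diff for r in anova_tukey(table8)}
        assert len(ses) == 1
        assert round(ses.pop(), 3) == 0.113

    def test_two_identical_groups(self):
        g = [GroupSummary("a", 30, 1.0, 0.5), GroupSummary("b", 30, 1.0, 0.5)]
        (r,) = anova_tukey(g)
        assert r.diff == 0.0 and r.p_adj == pytest.approx(1.0, abs=1e-9)

    def test_k2_reduces_to_pooled_t_test(self):
        g = [GroupSummary("a", 25, 1.0, 0.8), GroupSummary("b", 25, 1.6, 1.1)]
        (r,) = anova_tukey(g)
        mse, dfe = pooled_mse(g)
        t = (1.6 - 1.0) / math.sqrt(2 * mse / 25)
        p_pooled = 2 * sps.t.sf(abs(t), dfe)
        assert r.p_adj == pytest.approx(p_pooled, abs=1e-5)

    def test_pair_reversal_symmetry(self):
        g = [GroupSummary("a", 30, 1.0, 0.5), GroupSummary("b", 30, 2.0, 0.6)]
        (fwd,) = anova_tukey(g)
        (rev,) = anova_tukey(list(reversed(g)))
        assert rev.diff == pytest.approx(-fwd.diff)
        assert rev.t == pytest.approx(-fwd.t)
        assert (rev.ci_low, rev.ci_high) == pytest.approx((-fwd.ci_high, -fwd.ci_low))
        assert rev.p_adj == pytest.approx(fwd.p_adj, abs=1e-9)

    def test_p_adj_decreasing_in_t(self, table8):
        rows = sorted(anova_tukey(table8), key=lambda r: abs(r.t))
        ps = [r.p_adj for r in rows]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_unequal_n_rejected(self):
        g = [GroupSummary("a", 30, 1.0, 0.5), GroupSummary("b", 29, 2.0, 0.6)]
        with pytest.raises(ValueError, match="unequal|balanced"):
            anova_tukey(g)

    def test_cross_check_against_statsmodels_raw_tukey(self):
        """Summary-based Tukey agrees with statsmodels' raw-data pairwise
        Tukey HSD on samples constructed to have exactly those summaries."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(4)
        summaries = [
            GroupSummary("g1", 30, 1.0, 0.9),
            GroupSummary("g2", 30, 1.7, 1.1),
            GroupSummary("g3", 30, 0.6, 0.7),
        ]
        data, labels = [], []
        for g in summaries:
            data.extend(_exact_sample(rng, g.n, g.mean, g.sd))
            labels.extend([g.label] * g.n)
        ref = pairwise_tukeyhsd(np.array(data), np.array(labels))
        ours = anova_tukey(summaries)  # labels already in sorted order
        assert np.allclose([r.diff for r in ours], ref.meandiffs, atol=1e-9)
        assert np.allclose(
            [(r.ci_low, r.ci_high) for r in ours], ref.confint, atol=1e-6
        )
        assert np.allclose([r.p_adj for r in ours], ref.pvalues, atol=1e-4)


class TestGroupCI:
    def test_published_baseline_interval(self, table8):
        mse, dfe = pooled_mse(table8)
        baseline = next(g for g in table8 if g.label == "M0:1:8")
        lo, hi = group_ci(baseline, mse, dfe)
        assert lo == pytest.approx(1.0192, abs=1e-3)
        assert hi == pytest.approx(1.3311, abs=1e-3)

    def test_zero_mse_collapses_to_mean(self):
        g = GroupSummary("a", 10, 2.5, 1.0)
        lo, hi = group_ci(g, 0.0, 18)
        assert lo == hi == 2.5

    def test_width_scales_inverse_sqrt_n(self):
        w = lambda n: np.subtract(*group_ci(GroupSummary("a", n, 0.0, 1.0), 4.0, 10_000)[::-1])
        assert w(400) == pytest.approx(w(100) / 2, rel=1e-3)


class TestPercentReduction:
    def test_headline_reduction(self):
        pr = percent_reduction(1.1751, 0.9193)
        assert pr == pytest.approx(21.78, abs=0.02)

    @pytest.mark.parametrize("base,new,expect", [(2.0, 1.0, 50.0), (1.3, 1.3, 0.0)])
    def test_simple_values(self, base, new, expect):
        assert percent_reduction(base, new) == pytest.approx(expect)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)
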