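"""Distribution fitting for observed service durations ("input analysis").

Given a column of observed durations, the fitter shifts the data onto a
candidate family's native support, estimates parameters by maximum
likelihood (method of moments as a fallback), and scores the fit with two
goodness-of-fit measures: the Kolmogorov–Smirnov statistic and the summed
squared error between the histogram's relative frequencies and the fitted
bin probabilities.  Families are then ranked, squared error first — the
ranking criterion classical input-analysis tools use.

Support convention: empirical offsets are ``min - 0.5`` and spans
``(max - min) + 1`` — the half-unit padding that stopwatch data recorded in
whole or half minutes produces (visible in the fitted tables' offsets of
2.5, 1.5, 0.5, 5.5, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .arena_expr import DistributionSpec, render

__all__ = [
    "FitResult",
    "DegenerateSamplesError",
    "UnsupportedSampleError",
    "estimate_support",
    "fit_family",
    "select_best",
    "fit_report",
    "CONTINUOUS_FAMILIES",
]

#: Families the fitter knows how to estimate (DISC is handled by the
#: degenerate/categorical path, not by continuous fitting).
CONTINUOUS_FAMILIES: tuple[str, ...] = (
    "BETA", "LOGN", "GAMM", "ERLA", "WEIB", "NORM", "UNIF", "TRIA", "POIS",
)

#: Families fitted on the unit interval after the (offset, scale) transform.
_UNIT_SUPPORT = ("BETA", "TRIA")
#: Families fitted on the positive axis after subtracting the offset.
_POSITIVE_SUPPORT = ("LOGN", "GAMM", "ERLA", "WEIB")


class DegenerateSamplesError(ValueError):
    """Fewer than two distinct sample values: fit a constant instead."""


class UnsupportedSampleError(ValueError):
    """Samples violate the candidate family's support; family is skipped."""


@dataclass(frozen=True)
class FitResult:
    spec: DistributionSpec
    gof_ks: float
    gof_sqerr: float
    n: int


def estimate_support(samples: Sequence[float]) -> tuple[float, float]:
    """Empirical (offset, scale) with half-unit padding.

    ``offset = min - 0.5``; ``scale = (max - min) + 1``.
    """
    x = np.asarray(samples, dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateSamplesError("need at least two distinct sample values")
    lo, hi = float(x.min()), float(x.max())
    return lo - 0.5, (hi - lo) + 1.0


def _gof(z: np.ndarray, frozen) -> tuple[float, float]:
    """KS statistic and histogram squared error against a frozen scipy dist."""
    ks = float(sps.kstest(z, frozen.cdf).statistic)
    bins = max(2, int(math.ceil(math.log2(len(z))) + 1))  # Sturges
    counts, edges = np.histogram(z, bins=bins)
    p_obs = counts / len(z)
    p_fit = np.diff(frozen.cdf(edges))
    return ks, float(np.sum((p_obs - p_fit) ** 2))


def _mom_gamma(z: np.ndarray) -> tuple[float, float]:
    m, v = float(z.mean()), float(z.var(ddof=1))
    shape = m * m / v
    return shape, v / m  # (shape, scale)


def fit_family(
    samples: Sequence[float], family: str, offset: float, scale: float
) -> FitResult:
    """Fit one candidate family to the samples shifted by (offset, scale).

    Parameters are maximum-likelihood estimates; a method-of-moments
    fallback covers MLE non-convergence.  Raises
    :class:`UnsupportedSampleError` when the shifted data violate the
    family's support.
    """
    x = np.asarray(samples, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    fam = family.upper()
    if fam not in CONTINUOUS_FAMILIES:
        raise ValueError(f"unknown fit family {family!r}")

    eps = 1e-9
    if fam in _UNIT_SUPPORT:
        z = (x - offset) / scale
        if z.min() < -eps or z.max() > 1 + eps:
            raise UnsupportedSampleError(
                f"{fam}: samples fall outside [offset, offset+scale]"
            )
        z = np.clip(z, eps, 1 - eps)
    elif fam in _POSITIVE_SUPPORT:
        z = x - offset
        if z.min() <= 0:
            raise UnsupportedSampleError(f"{fam}: nonpositive values after shift")
    else:
        z = x

    if fam == "BETA":
        try:
            a, b, *_ = sps.beta.fit(z, floc=0, fscale=1)
        except (sps.FitError, ValueError):
            m, v = z.mean(), z.var(ddof=1)
            c = m * (1 - m) / v - 1
            a, b = m * c, (1 - m) * c
        spec = DistributionSpec("BETA", (a, b), offset, scale)
        frozen = sps.beta(a, b)
    elif fam == "LOGN":
        try:
            s, _, sc = sps.lognorm.fit(z, floc=0)
            mu, sigma = math.log(sc), s
        except (sps.FitError, ValueError):
            lz = np.log(z)
            mu, sigma = float(lz.mean()), float(lz.std(ddof=1))
        m_arith = math.exp(mu + sigma**2 / 2)
        s_arith = m_arith * math.sqrt(math.expm1(sigma**2))
        spec = DistributionSpec("LOGN", (m_arith, s_arith), offset, scale)
        frozen = sps.lognorm(sigma, scale=math.exp(mu))
    elif fam in ("GAMM", "ERLA"):
        try:
            shape, _, sc = sps.gamma.fit(z, floc=0)
        except (sps.FitError, ValueError):
            shape, sc = _mom_gamma(z)
        if fam == "ERLA":
            k = max(1, int(round(shape)))
            sc = float(z.mean()) / k  # re-estimate scale at integral shape
            spec = DistributionSpec("ERLA", (sc, float(k)), offset, scale)
            frozen = sps.gamma(k, scale=sc)
        else:
            spec = DistributionSpec("GAMM", (sc, shape), offset, scale)
            frozen = sps.gamma(shape, scale=sc)
    elif fam == "WEIB":
        try:
            c, _, sc = sps.weibull_min.fit(z, floc=0)
        except (sps.FitError, ValueError):
            raise UnsupportedSampleError("WEIB: fit failed")
        spec = DistributionSpec("WEIB", (sc, c), offset, scale)
        frozen = sps.weibull_min(c, scale=sc)
    elif fam == "NORM":
        mu, sd = sps.norm.fit(z)
        if sd <= 0:
            raise UnsupportedSampleError("NORM: zero variance")
        spec = DistributionSpec("NORM", (mu, sd), offset, scale)
        frozen = sps.norm(mu, sd)
    elif fam == "UNIF":
        lo, hi = offset, offset + scale
        spec = DistributionSpec("UNIF", (lo, hi))
        frozen = sps.uniform(lo, hi - lo)
        z = x  # scored on the original scale against the padded support
    elif fam == "TRIA":
        try:
            c, *_ = sps.triang.fit(z, floc=0, fscale=1)
        except (sps.FitError, ValueError):
            c = float(np.clip(3 * z.mean() - 1.0, eps, 1 - eps))  # mode = 3m - min - max
        spec = DistributionSpec("TRIA", (offset, offset + c * scale, offset + scale))
        frozen = sps.triang(c)
    elif fam == "POIS":
        z = x
        if (z < 0).any() or not np.allclose(z, np.round(z)):
            raise UnsupportedSampleError("POIS: samples are not nonnegative counts")
        lam = float(z.mean())
        if lam <= 0:
            raise UnsupportedSampleError("POIS: zero rate")
        spec = DistributionSpec("POIS", (lam,))
        frozen = sps.poisson(lam)
    else:  # pragma: no cover
        raise ValueError(fam)

    ks, sqerr = _gof(z, frozen)
    return FitResult(spec, ks, sqerr, len(x))


def select_best(
    samples: Sequence[float],
    families: Iterable[str] = CONTINUOUS_FAMILIES,
) -> list[FitResult]:
    """Fit every candidate family and rank ascending by (sqerr, KS).

    Single-valued data short-circuit to a CONST spec.  Families whose
    support the data violate are skipped; if nothing fits, raises
    :class:`UnsupportedSampleError`.
    """
    x = np.asarray(samples, dtype=float)
    try:
        offset, scale = estimate_support(x)
    except DegenerateSamplesError:
        spec = DistributionSpec("CONST", (float(x[0]),))
        return [FitResult(spec, 0.0, 0.0, len(x))]

    results: list[FitResult] = []
    for fam in families:
        fam = fam.upper()
        if fam in _POSITIVE_SUPPORT:
            off, sc = offset, 1.0
        elif fam in _UNIT_SUPPORT or fam == "UNIF":
            off, sc = offset, scale
        else:
            off, sc = 0.0, 1.0
        try:
            results.append(fit_family(x, fam, off, sc))
        except UnsupportedSampleError:
            continue
    if not results:
        raise UnsupportedSampleError("no candidate family fits the samples")
    results.sort(key=lambda r: (r.gof_sqerr, r.gof_ks, r.spec.family))
    return results


def fit_report(
    samples_by_station: Mapping[int, Sequence[float]],
    families: Iterable[str] = CONTINUOUS_FAMILIES,
) -> pd.DataFrame:
    """Best-fit expression per station as a tidy report table.

    Columns: station, family, expression, gof_ks, gof_sqerr, n — ready to be
    written to CSV or pasted into a model-configuration fragment.
    """
    rows = []
    for sid in sorted(samples_by_station):
        best = select_best(samples_by_station[sid], families)[0]
        rows.append(
            {
                "station": sid,
                "family": best.spec.family,
                "expression": render(best.spec),
                "gof_ks": best.gof_ks,
                "gof_sqerr": best.gof_sqerr,
                "n": best.n,
            }
        )
    return pd.DataFrame(rows)
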