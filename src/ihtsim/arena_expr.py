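"""Distribution-expression dialect: parsing, sampling, analytic moments.

Hospital input-modelling tools express fitted distributions as strings of the
form ``offset + scale * FAMILY(p1, p2, ...)`` — e.g. ``2.5 + 16 *
BETA(0.571, 1.73)`` or ``DISC(0.804,1,1,2)``.  This module parses that dialect
into :class:`DistributionSpec` objects that can be sampled reproducibly and
whose mean and variance are available in closed form.

Parameter conventions follow the originating simulation dialect:

* ``GAMM(beta, alpha)`` — (scale, shape); mean ``alpha * beta``.
* ``ERLA(beta, k)`` — sum of ``k`` exponentials of mean ``beta``
  (gamma with integer shape ``k`` and scale ``beta``).
* ``WEIB(beta, alpha)`` — (scale, shape).
* ``LOGN(M, S)`` — the ARITHMETIC mean and SD of the lognormal; internally
  ``sigma^2 = ln(1 + (S/M)^2)``, ``mu = ln M - sigma^2 / 2``.
* ``TRIA(min, mode, max)``; ``UNIF(a, b)``; ``NORM(mu, sd)``; ``POIS(rate)``.
* ``DISC(c1, v1, ..., ck, vk)`` — CUMULATIVE probability / value pairs,
  with ``ck == 1`` exactly.
* ``CONST(v)`` — degenerate point mass (not part of the printed tables but
  needed for constant observed columns).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Family",
    "DistributionSpec",
    "ExpressionError",
    "parse_expression",
    "render",
    "sample",
    "sample_nonnegative",
    "analytic_mean",
    "analytic_var",
]

#: Families understood by the parser, with their required parameter counts
#: (``None`` means variable length, validated separately).
_FAMILIES: dict[str, int | None] = {
    "BETA": 2,
    "LOGN": 2,
    "GAMM": 2,
    "ERLA": 2,
    "WEIB": 2,
    "NORM": 2,
    "UNIF": 2,
    "TRIA": 3,
    "POIS": 1,
    "DISC": None,
    "CONST": 1,
}

Family = str  # one of the _FAMILIES keys


class ExpressionError(ValueError):
    """Raised when a distribution expression cannot be parsed or validated."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parsed distribution expression.

    ``offset`` shifts and ``scale`` multiplies the family's native variate:
    the realized value is ``offset + scale * X``.
    """

    family: Family
    params: tuple[float, ...]
    offset: float = 0.0
    scale: float = 1.0
    source_text: str = ""

    def __post_init__(self) -> None:
        _validate(self)

    @property
    def disc_pairs(self) -> tuple[tuple[float, float], ...]:
        """(cumulative probability, value) pairs for a DISC spec."""
        if self.family != "DISC":
            raise ExpressionError("disc_pairs is only defined for DISC specs")
        p = self.params
        return tuple((p[i], p[i + 1]) for i in range(0, len(p), 2))


def _validate(spec: DistributionSpec) -> None:
    fam, p = spec.family, spec.params
    if fam not in _FAMILIES:
        raise ExpressionError(f"unknown family {fam!r}")
    want = _FAMILIES[fam]
    if want is not None and len(p) != want:
        raise ExpressionError(
            f"{fam} expects {want} parameters, got {len(p)}"
        )
    if not spec.scale > 0:
        raise ExpressionError(f"scale must be positive, got {spec.scale}")
    if fam in ("BETA", "GAMM", "WEIB", "LOGN"):
        if not all(v > 0 for v in p):
            raise ExpressionError(f"{fam} parameters must be positive: {p}")
    elif fam == "ERLA":
        beta, k = p
        if not beta > 0:
            raise ExpressionError(f"ERLA mean must be positive, got {beta}")
        if not (k > 0 and float(k).is_integer()):
            raise ExpressionError(f"ERLA stage count must be a positive integer, got {k}")
    elif fam == "NORM":
        if not p[1] > 0:
            raise ExpressionError(f"NORM sd must be positive, got {p[1]}")
    elif fam == "UNIF":
        if not p[0] <= p[1]:
            raise ExpressionError(f"UNIF requires a <= b, got {p}")
    elif fam == "TRIA":
        lo, mode, hi = p
        if not (lo <= mode <= hi and lo < hi):
            raise ExpressionError(f"TRIA requires min <= mode <= max, got {p}")
    elif fam == "POIS":
        if not p[0] > 0:
            raise ExpressionError(f"POIS rate must be positive, got {p[0]}")
    elif fam == "DISC":
        if len(p) < 2 or len(p) % 2:
            raise ExpressionError("DISC expects an even, nonzero parameter count")
        cum = p[0::2]
        if any(b < a for a, b in zip(cum, cum[1:])):
            raise ExpressionError(f"DISC cumulative probabilities must be nondecreasing: {cum}")
        if not (0 <= cum[0] <= 1) or cum[-1] != 1.0:
            raise ExpressionError(
                f"DISC cumulative probabilities must end exactly at 1, got {cum[-1]}"
            )


# ---------------------------------------------------------------------------
# Parsing / rendering
# ---------------------------------------------------------------------------

_EXPR_RE = re.compile(
    r"""^\s*
    (?:(?P<offset>[-+]?[\d.eE+-]+)\s*\+\s*)?     # optional additive offset
    (?:(?P<scale>[-+]?[\d.eE+-]+)\s*\*\s*)?      # optional multiplier
    (?P<family>[A-Za-z]+)\s*
    \(\s*(?P<args>[^)]*)\)\s*$""",
    re.VERBOSE,
)


def parse_expression(text: str) -> DistributionSpec:
    """Parse ``[offset +] [scale *] FAMILY(p1, p2, ...)`` into a spec.

    >>> parse_expression("2.5 + 16 * BETA(0.571, 1.73)")
    DistributionSpec(family='BETA', params=(0.571, 1.73), offset=2.5, scale=16.0, ...)
    """
    m = _EXPR_RE.match(text)
    if m is None:
        raise ExpressionError(f"malformed distribution expression: {text!r}")
    fam = m.group("family").upper()
    if fam not in _FAMILIES:
        raise ExpressionError(f"unknown family {m.group('family')!r} in {text!r}")
    raw_args = [a.strip() for a in m.group("args").split(",") if a.strip()]
    try:
        params = tuple(float(a) for a in raw_args)
    except ValueError as exc:
        raise ExpressionError(f"non-numeric parameter in {text!r}: {exc}") from None
    offset = float(m.group("offset")) if m.group("offset") else 0.0
    scale = float(m.group("scale")) if m.group("scale") else 1.0
    return DistributionSpec(fam, params, offset, scale, source_text=text.strip())


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() and abs(x) < 1e15 else repr(float(x))


def render(spec: DistributionSpec) -> str:
    """Render a spec back to expression text (numerically round-trippable)."""
    body = f"{spec.family}({', '.join(_fmt(v) for v in spec.params)})"
    if spec.scale != 1.0:
        body = f"{_fmt(spec.scale)} * {body}"
    if spec.offset != 0.0:
        body = f"{_fmt(spec.offset)} + {body}"
    return body


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _sample_family(spec: DistributionSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    fam, p = spec.family, spec.params
    if fam == "BETA":
        return rng.beta(p[0], p[1], size=n)
    if fam == "LOGN":
        m_, s_ = p
        sigma2 = math.log1p((s_ / m_) ** 2)
        mu = math.log(m_) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    if fam == "GAMM":
        beta, alpha = p
        return rng.gamma(shape=alpha, scale=beta, size=n)
    if fam == "ERLA":
        beta, k = p
        return rng.gamma(shape=int(k), scale=beta, size=n)
    if fam == "WEIB":
        beta, alpha = p
        return beta * rng.weibull(alpha, size=n)
    if fam == "NORM":
        return rng.normal(p[0], p[1], size=n)
    if fam == "UNIF":
        return rng.uniform(p[0], p[1], size=n)
    if fam == "TRIA":
        lo, mode, hi = p
        return rng.triangular(lo, mode, hi, size=n)
    if fam == "POIS":
        return rng.poisson(p[0], size=n).astype(float)
    if fam == "DISC":
        pairs = spec.disc_pairs
        cum = np.array([c for c, _ in pairs])
        vals = np.array([v for _, v in pairs])
        u = rng.random(n)
        return vals[np.searchsorted(cum, u, side="left")]
    if fam == "CONST":
        return np.full(n, p[0])
    raise ExpressionError(f"unsampleable family {fam!r}")  # pragma: no cover


def sample(spec: DistributionSpec, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Draw ``n`` values of ``offset + scale * X`` from the spec's family."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return spec.offset + spec.scale * _sample_family(spec, rng, n)


def sample_nonnegative(spec: DistributionSpec, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Like :func:`sample` but resamples negative draws (NORM durations).

    Rejection preserves the distribution's shape on the nonnegative axis
    better than clamping at zero; the induced truncation bias is negligible
    for the printed expressions (e.g. NORM(11.5, 4.11) is negative with
    probability ~0.003).
    """
    out = sample(spec, rng, n)
    while True:
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = sample(spec, rng, int(bad.sum()))


# ---------------------------------------------------------------------------
# Analytic moments
# ---------------------------------------------------------------------------


def _family_mean_var(spec: DistributionSpec) -> tuple[float, float]:
    fam, p = spec.family, spec.params
    if fam == "BETA":
        a, b = p
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1))
    elif fam == "LOGN":
        m, v = p[0], p[1] ** 2
    elif fam == "GAMM":
        beta, alpha = p
        m, v = alpha * beta, alpha * beta**2
    elif fam == "ERLA":
        beta, k = p
        m, v = k * beta, k * beta**2
    elif fam == "WEIB":
        beta, alpha = p
        g1 = math.gamma(1 + 1 / alpha)
        g2 = math.gamma(1 + 2 / alpha)
        m, v = beta * g1, beta**2 * (g2 - g1**2)
    elif fam == "NORM":
        m, v = p[0], p[1] ** 2
    elif fam == "UNIF":
        a, b = p
        m, v = (a + b) / 2, (b - a) ** 2 / 12
    elif fam == "TRIA":
        lo, mo, hi = p
        m = (lo + mo + hi) / 3
        v = (lo**2 + mo**2 + hi**2 - lo * mo - lo * hi - mo * hi) / 18
    elif fam == "POIS":
        m = v = p[0]
    elif fam == "DISC":
        pairs = spec.disc_pairs
        prev = 0.0
        m = m2 = 0.0
        for c, val in pairs:
            w = c - prev
            m += w * val
            m2 += w * val**2
            prev = c
        v = m2 - m**2
    elif fam == "CONST":
        m, v = p[0], 0.0
    else:  # pragma: no cover
        raise ExpressionError(f"no analytic moments for {fam!r}")
    return m, v


def analytic_mean(spec: DistributionSpec) -> float:
    """Exact mean of ``offset + scale * X``."""
    return spec.offset + spec.scale * _family_mean_var(spec)[0]


def analytic_var(spec: DistributionSpec) -> float:
    """Exact variance of ``offset + scale * X``."""
    return spec.scale**2 * _family_mean_var(spec)[1]
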