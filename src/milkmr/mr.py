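"""Two-sample Wald/IV-ratio causal estimation.

The causal effect of milk intake on an outcome is estimated as the ratio
of the instrument-outcome association beta_GY to the instrument-exposure
association beta_GX (g/day of milk per effect allele), rescaled to a
50 g/day increment of milk intake:

    b_IV = (beta_GY / beta_GX) * scale_grams

Uncertainty comes from the delta method. The first-order standard error
propagates only the outcome uncertainty, se = (se_GY/|beta_GX|)*scale; the
second-order form (default) adds the exposure-uncertainty term
beta_GY^2 * se_GX^2 / beta_GX^4 under the square root. For binary outcomes
the ratio is computed on the log-odds scale and exponentiated to an odds
ratio per 50 g/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .associations import AssociationEstimate
from .exceptions import ValidationError

__all__ = [
    "ExposureEstimate",
    "WaldResult",
    "DEFAULT_EXPOSURE",
    "wald_ratio",
    "wald_ratio_binary",
    "iv_proportionality_check",
]


@dataclass(frozen=True)
class ExposureEstimate:
    """Instrument-exposure association: g/day of milk per effect allele."""

    beta_gx: float
    se_gx: float = 0.0
    source: str = "configured"
    n: int | None = None

    def __post_init__(self) -> None:
        if self.beta_gx == 0 or not np.isfinite(self.beta_gx):
            raise ValidationError("exposure beta must be nonzero and finite (weak/undefined instrument)")
        if self.se_gx < 0 or not np.isfinite(self.se_gx):
            raise ValidationError("exposure se must be a non-negative finite value")


#: Default instrument-exposure effect. The per-allele milk-intake shift and
#: its uncertainty are configuration, back-derived from the ratio of printed
#: genetic and IV estimates; override with study-specific values when known.
DEFAULT_EXPOSURE = ExposureEstimate(beta_gx=17.5, se_gx=4.0, source="default-configured")


@dataclass(frozen=True)
class WaldResult:
    """Causal effect per ``scale_grams`` g/day of milk intake.

    ``estimate`` is on the outcome scale (log-OR for binary outcomes);
    ``odds_ratio``/``or_ci95`` are populated only by the binary estimator.
    """

    trait: str
    estimate: float
    se: float
    ci95: tuple[float, float]
    p: float
    scale_grams: float = 50.0
    method: str = "second_order"
    odds_ratio: float | None = None
    or_ci95: tuple[float, float] | None = None


def _delta_se(gy_beta: float, gy_se: float, gx: ExposureEstimate,
              scale_grams: float, method: str) -> float:
    first = (gy_se / abs(gx.beta_gx)) ** 2
    if method == "first_order":
        var = first
    elif method == "second_order":
        var = first + gy_beta**2 * gx.se_gx**2 / gx.beta_gx**4
    else:
        raise ValidationError(f"unknown delta method {method!r}")
    return scale_grams * math.sqrt(var)


def wald_ratio(
    gy: AssociationEstimate,
    gx: ExposureEstimate = DEFAULT_EXPOSURE,
    scale_grams: float = 50.0,
    method: str = "second_order",
) -> WaldResult:
    """Wald/IV-ratio causal estimate for a continuous outcome.

    Parameters
    ----------
    gy
        Instrument-outcome association (typically a pooled meta-analysis
        estimate; its standard error is used unchanged).
    gx
        Instrument-exposure association in g/day per effect allele.
    scale_grams
        Report the effect per this many g/day of milk (default 50).
    method
        ``"second_order"`` (default) propagates exposure uncertainty;
        ``"first_order"`` ignores it.
    """
    if gy.se <= 0:
        raise ValidationError("outcome se must be positive")
    estimate = gy.beta / gx.beta_gx * scale_grams
    se = _delta_se(gy.beta, gy.se, gx, scale_grams, method)
    p = float(2 * stats.norm.sf(abs(estimate) / se)) if se > 0 else float("nan")
    return WaldResult(
        trait=gy.trait, estimate=float(estimate), se=float(se),
        ci95=(float(estimate - 1.96 * se), float(estimate + 1.96 * se)),
        p=p, scale_grams=float(scale_grams), method=method,
    )


def wald_ratio_binary(
    gy_logor: AssociationEstimate,
    gx: ExposureEstimate = DEFAULT_EXPOSURE,
    scale_grams: float = 50.0,
    method: str = "second_order",
) -> WaldResult:
    """Wald ratio for a binary outcome, reported as an odds ratio.

    The ratio is taken on the log-odds scale and exponentiated, so the
    95% CI is symmetric on the log scale.
    """
    base = wald_ratio(gy_logor, gx, scale_grams, method)
    lo, hi = base.ci95
    return WaldResult(
        trait=base.trait, estimate=base.estimate, se=base.se, ci95=base.ci95,
        p=base.p, scale_grams=base.scale_grams, method=base.method,
        odds_ratio=float(math.exp(base.estimate)),
        or_ci95=(float(math.exp(lo)), float(math.exp(hi))),
    )


@dataclass(frozen=True)
class ProportionalityReport:
    """Implied exposure denominators across outcome rows sharing one instrument."""

    implied_beta_gx: tuple[float, ...]
    intervals: tuple[tuple[float, float], ...]
    spread: float
    consistent: bool
    common_interval: tuple[float, float] | None


def iv_proportionality_check(
    pairs,  # sequence of (genetic_beta, iv_estimate)
    scale_grams: float = 50.0,
    decimals: int = 3,
) -> ProportionalityReport:
    """Check that several (genetic beta, IV estimate) pairs imply one denominator.

    Each pair implies beta_GX = scale_grams * beta_genetic / beta_IV. When
    the inputs are rounded to ``decimals`` decimal places, each implied
    value is only known up to an interval; the rows are mutually consistent
    iff those intervals share a common point.
    """
    pairs = [(float(g), float(iv)) for g, iv in pairs]
    if not pairs:
        raise ValidationError("at least one (genetic beta, IV estimate) pair required")
    half = 0.5 * 10.0 ** (-decimals)
    implied, intervals = [], []
    degenerate = False
    for g, iv in pairs:
        if iv == 0:
            degenerate = True
            implied.append(float("inf"))
            intervals.append((float("inf"), float("inf")))
            continue
        implied.append(scale_grams * g / iv)
        corners = [
            scale_grams * (g + s1 * half) / (iv + s2 * half)
            for s1 in (-1, 1) for s2 in (-1, 1)
            if iv + s2 * half != 0
        ]
        intervals.append((min(corners), max(corners)))
    lo = max(a for a, _ in intervals)
    hi = min(b for _, b in intervals)
    finite = [v for v in implied if np.isfinite(v)]
    spread = float(max(finite) - min(finite)) if len(finite) > 1 else 0.0
    consistent = (not degenerate) and lo <= hi
    return ProportionalityReport(
        implied_beta_gx=tuple(implied),
        intervals=tuple(intervals),
        spread=spread,
        consistent=consistent,
        common_interval=(float(lo), float(hi)) if consistent else None,
    )
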