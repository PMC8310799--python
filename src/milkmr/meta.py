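"""DerSimonian-Laird random-effects meta-analysis.

Pools per-study association estimates with inverse-variance weights, a
method-of-moments between-study variance tau^2, Cochran's Q, the
heterogeneity p-value and I^2, and per-study weight percentages.

The random-effects weights are w_i* = 1/(se_i^2 + tau^2) with
tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) computed from the
fixed-effects weights w_i = 1/se_i^2. When Q <= df the estimator truncates
tau^2 at zero and the pooled result coincides exactly with fixed-effects
pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .associations import AssociationEstimate
from .exceptions import ValidationError

__all__ = ["MetaInput", "MetaResult", "fixed_effects_meta", "cochran_q", "dersimonian_laird"]


@dataclass(frozen=True)
class MetaInput:
    """Estimates entering one pooled analysis, after overlap exclusions.

    All estimates must share trait, kind and coding; at least two are
    required (single-study traits are reported, not pooled).
    """

    estimates: tuple[AssociationEstimate, ...]
    exclusions: tuple[tuple[str, str], ...] = ()  # (study, reason) pairs

    def __init__(self, estimates: Sequence[AssociationEstimate], exclusions=()):
        object.__setattr__(self, "estimates", tuple(estimates))
        object.__setattr__(self, "exclusions", tuple(tuple(e) for e in exclusions))
        if len(self.estimates) < 2:
            raise ValidationError("meta-analysis requires at least two studies")
        traits = {e.trait for e in self.estimates}
        kinds = {e.kind for e in self.estimates}
        if len(traits) > 1 or len(kinds) > 1:
            raise ValidationError(
                f"estimates must share trait and kind; got traits={traits}, kinds={kinds}"
            )
        for e in self.estimates:
            if e.se <= 0:
                raise ValidationError(f"non-positive se for study {e.study!r}")

    @property
    def trait(self) -> str:
        return self.estimates[0].trait

    @property
    def kind(self) -> str:
        return self.estimates[0].kind


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity statistics and study weights."""

    trait: str
    kind: str
    beta: float
    se: float
    p: float
    q: float
    df: int
    het_p: float
    i2: float  # percent in [0, 100]
    tau2: float
    weights_pct: dict[str, float] = field(default_factory=dict)
    method: str = "dersimonian_laird"

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


def _arrays(inputs: MetaInput) -> tuple[np.ndarray, np.ndarray, list[str]]:
    betas = np.array([e.beta for e in inputs.estimates], dtype=float)
    ses = np.array([e.se for e in inputs.estimates], dtype=float)
    studies = [e.study for e in inputs.estimates]
    return betas, ses, studies


def fixed_effects_meta(inputs: MetaInput) -> MetaResult:
    """Inverse-variance fixed-effects pooling (tau^2 forced to zero)."""
    betas, ses, studies = _arrays(inputs)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q, df, het_p, i2 = cochran_q(inputs)
    weights = {s: float(100 * wi / np.sum(w)) for s, wi in zip(studies, w)}
    return MetaResult(
        trait=inputs.trait, kind=inputs.kind, beta=beta, se=se,
        p=float(2 * stats.norm.sf(abs(beta) / se)),
        q=q, df=df, het_p=het_p, i2=i2, tau2=0.0,
        weights_pct=weights, method="fixed_effects",
    )


def cochran_q(inputs: MetaInput) -> tuple[float, int, float, float]:
    """Cochran's Q, its degrees of freedom, heterogeneity p-value and I^2.

    Q = sum w_i (beta_i - beta_FE)^2 with fixed-effects weights; I^2 is
    the percentage max(0, (Q - df)/Q) * 100.
    """
    betas, ses, _ = _arrays(inputs)
    w = 1.0 / ses**2
    beta_fe = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - beta_fe) ** 2))
    df = len(betas) - 1
    het_p = float(stats.chi2.sf(q, df)) if q > 0 else 1.0
    i2 = float(max(0.0, (q - df) / q) * 100) if q > 0 else 0.0
    return q, df, het_p, i2


def dersimonian_laird(inputs: MetaInput) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    Returns the pooled beta, its standard error, a two-sided normal
    p-value, heterogeneity statistics and per-study random-effects weight
    percentages (summing to 100).
    """
    betas, ses, studies = _arrays(inputs)
    w = 1.0 / ses**2
    q, df, het_p, i2 = cochran_q(inputs)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (ses**2 + tau2)
    beta = float(np.sum(w_re * betas) / np.sum(w_re))
    se = float(np.sum(w_re) ** -0.5)
    weights = {s: float(100 * wi / np.sum(w_re)) for s, wi in zip(studies, w_re)}
    return MetaResult(
        trait=inputs.trait, kind=inputs.kind, beta=beta, se=se,
        p=float(2 * stats.norm.sf(abs(beta) / se)),
        q=q, df=df, het_p=het_p, i2=i2, tau2=float(tau2),
        weights_pct=weights,
    )
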