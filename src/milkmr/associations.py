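"""Per-cohort estimation stage.

Trait preprocessing (medication corrections, rank-based inverse-normal
transform), genotype coding, covariate-adjusted linear/logistic association,
Hardy-Weinberg testing and contingency summaries of milk consumption by
genotype.

Medication corrections follow the epidemiological convention of recovering
an approximate untreated value: +15/+10 mmHg for systolic/diastolic blood
pressure under antihypertensive treatment, and division by a
biomarker-specific factor for lipid-lowering treatment (0.68 LDL-C,
1.05 HDL-C, 0.75 total cholesterol, 0.87 triglycerides, 1.21 CRP,
1.04 HbA1c).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    ConvergenceError,
    DegenerateFitError,
    ValidationError,
)

__all__ = [
    "BP_MEDICATION_OFFSETS",
    "MEDICATION_FACTORS",
    "TraitConfig",
    "GeneticCoding",
    "AssociationEstimate",
    "HWEResult",
    "ContingencyTable",
    "code_genotypes",
    "adjust_blood_pressure",
    "adjust_biomarker",
    "pulse_pressure",
    "inverse_normal_transform",
    "linear_association",
    "logistic_association",
    "hwe_test",
    "contingency_summary",
]

# mmHg added back for individuals on blood-pressure-lowering medication
BP_MEDICATION_OFFSETS: Mapping[str, float] = {"sbp": 15.0, "dbp": 10.0}

# division factors for individuals on lipid-lowering medication
MEDICATION_FACTORS: Mapping[str, float] = {
    "ldl_c": 0.68,
    "hdl_c": 1.05,
    "total_cholesterol": 0.75,
    "triglycerides": 0.87,
    "crp": 1.21,
    "hba1c": 1.04,
}

_BP_TRAITS = frozenset({"sbp", "dbp", "pulse_pressure"})


@dataclass(frozen=True)
class TraitConfig:
    """Configuration of one outcome trait.

    Parameters
    ----------
    name
        Trait label (e.g. ``"ldl_c"``).
    scale
        One of ``{"sd_transformed", "mmHg", "percent", "binary"}``.
        Blood pressures stay in mmHg and HbA1c in percent; every other
        continuous trait is analysed on the SD scale after inverse-normal
        transformation, making effect sizes comparable across studies.
    medication_rule
        ``"none"``, ``"add_constant"`` (blood pressure) or
        ``"divide_by_factor"`` (lipid-lowering correction).
    factor
        Division factor when ``medication_rule == "divide_by_factor"``.
    transform
        Whether the trait is inverse-normal transformed before regression.
    """

    name: str
    scale: str = "sd_transformed"
    medication_rule: str = "none"
    factor: float | None = None
    transform: bool | None = None

    def __post_init__(self) -> None:
        if self.scale not in {"sd_transformed", "mmHg", "percent", "binary"}:
            raise ValidationError(f"unknown scale {self.scale!r} for trait {self.name!r}")
        if self.medication_rule not in {"none", "add_constant", "divide_by_factor"}:
            raise ValidationError(
                f"unknown medication rule {self.medication_rule!r} for trait {self.name!r}"
            )
        if self.medication_rule == "add_constant" and self.name not in _BP_TRAITS:
            raise ValidationError("add_constant medication rule is reserved for blood pressure")
        if self.medication_rule == "divide_by_factor":
            f = self.factor if self.factor is not None else MEDICATION_FACTORS.get(self.name)
            if f is None:
                raise ValidationError(f"no correction factor known for trait {self.name!r}")
            if f <= 0:
                raise ValidationError("correction factor must be positive")
            object.__setattr__(self, "factor", float(f))
        if self.transform is None:
            object.__setattr__(self, "transform", self.scale == "sd_transformed")
        if self.scale == "sd_transformed" and not self.transform:
            raise ValidationError("sd_transformed traits must set transform=True")
        if self.scale in {"mmHg", "percent"} and self.transform:
            raise ValidationError(f"{self.name}: mmHg/percent traits are analysed untransformed")


class GeneticCoding(str, enum.Enum):
    """Genotype coding for the lactase-persistence variant.

    ``additive`` counts effect ('T') alleles 0/1/2; ``recessive_carrier``
    contrasts CT+TT carriers against CC homozygotes (the reference).
    """

    ADDITIVE = "additive"
    RECESSIVE_CARRIER = "recessive_carrier"


def code_genotypes(dosages: Sequence[float], coding: GeneticCoding) -> np.ndarray:
    """Map allele-count dosages in {0,1,2} to the requested coding."""
    d = np.asarray(dosages, dtype=float)
    if not np.all(np.isin(d[np.isfinite(d)], [0.0, 1.0, 2.0])):
        raise ValidationError("genotype dosages must be 0, 1 or 2")
    coding = GeneticCoding(coding)
    if coding is GeneticCoding.ADDITIVE:
        return d
    return (d > 0).astype(float)


@dataclass(frozen=True)
class AssociationEstimate:
    """One (beta, SE, N, p) estimate for a study x trait x analysis kind."""

    study: str
    trait: str
    kind: str  # "genetic" or "phenotypic"
    beta: float
    se: float
    n: int | None = None
    p: float | None = None
    coding: GeneticCoding | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"genetic", "phenotypic"}:
            raise ValidationError(f"kind must be 'genetic' or 'phenotypic', got {self.kind!r}")
        if not np.isfinite(self.beta):
            raise ValidationError("beta must be finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"se must be positive, got {self.se}")
        if self.p is None:
            object.__setattr__(self, "p", _two_sided_normal_p(self.beta, self.se))

    @property
    def variance(self) -> float:
        return self.se**2


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df)."""

    n_cc: int
    n_ct: int
    n_tt: int
    t_allele_freq: float
    chi_square: float
    p: float


@dataclass(frozen=True)
class ContingencyTable:
    """Genotype x consumption-category counts with row percentages."""

    counts: pd.DataFrame
    row_percentages: pd.DataFrame
    chi_square: float
    df: int
    p: float

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def _two_sided_normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


# ---------------------------------------------------------------------------
# trait preprocessing


def adjust_blood_pressure(sbp, dbp, on_bp_medication):
    """Correct measured blood pressure for antihypertensive use.

    Adds 15 mmHg to systolic and 10 mmHg to diastolic pressure for treated
    individuals; untreated values pass through unchanged. Accepts scalars
    or arrays.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    flag = np.asarray(on_bp_medication, dtype=bool)
    if np.any(sbp <= 0) or np.any(dbp <= 0):
        raise ValidationError("blood pressures must be positive")
    if np.any(sbp <= dbp):
        raise ValidationError("systolic pressure must exceed diastolic pressure")
    sbp_adj = np.where(flag, sbp + BP_MEDICATION_OFFSETS["sbp"], sbp)
    dbp_adj = np.where(flag, dbp + BP_MEDICATION_OFFSETS["dbp"], dbp)
    if sbp_adj.ndim == 0:
        return float(sbp_adj), float(dbp_adj)
    return sbp_adj, dbp_adj


def adjust_biomarker(value, trait: TraitConfig | str, on_lipid_medication):
    """Correct a biomarker for lipid-lowering medication.

    Treated values are divided by the trait-specific factor; untreated
    values pass through. ``trait`` may be a :class:`TraitConfig` or a trait
    name with a known factor.
    """
    if isinstance(trait, str):
        if trait not in MEDICATION_FACTORS:
            raise ValidationError(f"no medication correction factor for trait {trait!r}")
        factor = MEDICATION_FACTORS[trait]
    else:
        if trait.medication_rule != "divide_by_factor":
            raise ValidationError(f"trait {trait.name!r} has no divide_by_factor rule")
        factor = trait.factor
    value = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(value)):
        raise ValidationError("biomarker values must be finite")
    flag = np.asarray(on_lipid_medication, dtype=bool)
    out = np.where(flag, value / factor, value)
    return float(out) if out.ndim == 0 else out


def pulse_pressure(sbp, dbp):
    """Pulse pressure = systolic minus diastolic pressure (mmHg)."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp <= dbp):
        raise ValidationError("systolic pressure must exceed diastolic pressure")
    pp = sbp - dbp
    return float(pp) if pp.ndim == 0 else pp


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    Maps values to standard-normal quantiles ``Phi^-1((r - 3/8)/(n + 1/4))``
    where r is the (average, tie-aware) rank. The result is strictly
    rank-preserving with sample mean ~0 and variance slightly below 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-d array of values")
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must be finite")
    if np.unique(x).size < 2:
        raise ValidationError("inverse-normal transform undefined for constant input")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 0.25))


# ---------------------------------------------------------------------------
# regression


def _design_matrix(predictor, covariates, index=None):
    pred = pd.Series(np.asarray(predictor, dtype=float), name="predictor")
    cols = [pred]
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov.columns = [str(c) for c in cov.columns]
        cols.append(cov.astype(float))
    X = pd.concat(cols, axis=1)
    X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = np.empty((arr.shape[0], 0))
        for j, name in enumerate(X.columns):
            cand = np.column_stack([kept, arr[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise DegenerateFitError(f"design matrix is rank deficient; collinear columns: {bad}")


def _complete_cases(*arrays):
    stacked = np.column_stack([np.asarray(a, dtype=float) for a in arrays])
    mask = np.all(np.isfinite(stacked), axis=1)
    return mask


def linear_association(
    outcome,
    predictor,
    covariates=None,
    coding: GeneticCoding | None = None,
    *,
    study: str = "synthetic",
    trait: str = "outcome",
    kind: str = "genetic",
) -> AssociationEstimate:
    """Covariate-adjusted OLS association of an outcome with a predictor.

    The predictor is a genotype (optionally recoded via ``coding``) for
    genetic associations or milk intake for phenotypic ones. Returns the
    slope on the predictor with its classical standard error and a
    two-sided normal p-value, computed on complete cases.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if coding is not None:
        x = code_genotypes(x, coding)
    X = _design_matrix(x, covariates)
    mask = _complete_cases(y, *[X[c] for c in X.columns])
    y, X = y[mask], X.loc[mask].reset_index(drop=True)
    if len(y) < X.shape[1] + 2:
        raise ValidationError(
            f"too few complete cases ({len(y)}) for {X.shape[1]} parameters"
        )
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    if fit.ssr <= 1e-12 * max(1.0, float(np.sum(y**2))):
        raise DegenerateFitError("perfect fit: residual variance is zero")
    beta = float(fit.params["predictor"])
    se = float(fit.bse["predictor"])
    return AssociationEstimate(
        study=study, trait=trait, kind=kind, beta=beta, se=se,
        n=int(len(y)), p=_two_sided_normal_p(beta, se), coding=coding,
    )


def logistic_association(
    outcome,
    predictor,
    covariates=None,
    coding: GeneticCoding | None = None,
    *,
    study: str = "synthetic",
    trait: str = "outcome",
    kind: str = "genetic",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> AssociationEstimate:
    """Maximum-likelihood logistic association; beta is the log odds ratio.

    With no covariates on a 2x2 layout this reproduces the closed-form
    cross-product odds ratio. Separation or non-convergence after
    ``maxiter`` Newton iterations raises an explicit error.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if coding is not None:
        x = code_genotypes(x, coding)
    X = _design_matrix(x, covariates)
    mask = _complete_cases(y, *[X[c] for c in X.columns])
    y, X = y[mask], X.loc[mask].reset_index(drop=True)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValidationError("binary outcome must be coded 0/1")
    if classes.size < 2:
        raise DegenerateFitError("outcome has a single class (complete separation)")
    _check_rank(X)
    import warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
    except PerfectSeparationWarning as exc:
        raise DegenerateFitError("perfect separation in logistic fit") from exc
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        if "separation" in str(exc).lower() or "Singular" in str(exc):
            raise DegenerateFitError(f"logistic fit degenerate: {exc}") from exc
        raise
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit did not converge in {maxiter} iterations")
    beta = float(fit.params["predictor"])
    se = float(fit.bse["predictor"])
    if not np.isfinite(se) or se > 1e3:
        raise DegenerateFitError("separation suspected: unbounded log-OR standard error")
    return AssociationEstimate(
        study=study, trait=trait, kind=kind, beta=beta, se=se,
        n=int(len(y)), p=_two_sided_normal_p(beta, se), coding=coding,
    )


# ---------------------------------------------------------------------------
# genotype summaries


def hwe_test(n_cc: int, n_ct: int, n_tt: int) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg equilibrium.

    The allele frequency is estimated from the sample; expected genotype
    counts are ``(q^2, 2pq, p^2) * N`` with p the T-allele frequency.
    Monomorphic samples are in exact equilibrium by construction.
    """
    counts = np.array([n_cc, n_ct, n_tt], dtype=float)
    if np.any(counts < 0):
        raise ValidationError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValidationError("at least one individual required")
    p = (2 * n_tt + n_ct) / (2 * n)  # T-allele frequency
    q = 1.0 - p
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    if p in (0.0, 1.0):
        return HWEResult(int(n_cc), int(n_ct), int(n_tt), p, 0.0, 1.0)
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return HWEResult(int(n_cc), int(n_ct), int(n_tt), float(p), chi2, float(stats.chi2.sf(chi2, 1)))


def contingency_summary(counts, row_labels=None, col_labels=None) -> ContingencyTable:
    """Row-percentage summary of a genotype x consumption table.

    Percentages are 100*count/row-total (reported to 2 decimals); a Pearson
    chi-square of independence is attached when the table has at least two
    rows and two columns.
    """
    if isinstance(counts, pd.DataFrame):
        table = counts.astype(float)
    else:
        table = pd.DataFrame(np.asarray(counts, dtype=float))
        if row_labels is not None:
            table.index = list(row_labels)
        if col_labels is not None:
            table.columns = list(col_labels)
    if table.size == 0:
        raise ValidationError("empty contingency table")
    if np.any(table.to_numpy() < 0):
        raise ValidationError("counts must be non-negative")
    row_totals = table.sum(axis=1)
    if np.any(row_totals.to_numpy() == 0):
        raise ValidationError("every row must have a positive total")
    pct = (table.div(row_totals, axis=0) * 100).round(2)
    if table.shape[0] >= 2 and table.shape[1] >= 2:
        chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    else:
        chi2, p, df = float("nan"), float("nan"), 0
    return ContingencyTable(counts=table, row_percentages=pct,
                            chi_square=float(chi2), df=int(df), p=float(p))
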