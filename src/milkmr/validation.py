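"""Instrument validation: confounder scan with Bonferroni correction.

A valid instrument must be unrelated to potential confounders of the
exposure-outcome relation. This module regresses each candidate covariate
(age, sex, income, education, health status, smoking, alcohol, coffee, ...)
on the genotype and flags any association below the Bonferroni threshold
alpha/m, where m is the number of covariates actually tested
(0.05/8 = 0.00625 for the default eight factors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .associations import (
    AssociationEstimate,
    GeneticCoding,
    linear_association,
    logistic_association,
)
from .exceptions import DegenerateFitError, ValidationError

__all__ = ["ValidationReport", "confounder_scan", "DEFAULT_COVARIATES"]

#: The eight candidate confounders scanned by default.
DEFAULT_COVARIATES = (
    "age", "sex", "income", "education", "health_status",
    "smoking", "alcohol", "coffee",
)


@dataclass(frozen=True)
class ValidationReport:
    """Per-covariate genotype associations against a Bonferroni threshold."""

    estimates: dict[str, AssociationEstimate]
    alpha: float
    n_tests: int
    threshold: float
    flags: dict[str, str] = field(default_factory=dict)  # covariate -> pass/fail
    skipped: tuple[str, ...] = ()

    @property
    def any_fail(self) -> bool:
        return any(v == "fail" for v in self.flags.values())


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[np.isfinite(values)])
    return u.size == 2 and set(u).issubset({0.0, 1.0})


def confounder_scan(
    cohort,
    covariates=DEFAULT_COVARIATES,
    coding: GeneticCoding = GeneticCoding.ADDITIVE,
    alpha: float = 0.05,
) -> ValidationReport:
    """Scan candidate confounders for association with the instrument.

    Continuous covariates are tested by linear regression on the coded
    genotype, binary ones by logistic regression; ordered categorical
    covariates should be supplied as ordinal scores. A covariate is
    flagged ``fail`` when its p-value falls below ``alpha / m`` with m the
    number of covariates tested. Constant covariates are skipped with a
    warning, never silently.
    """
    data = cohort.data if hasattr(cohort, "data") else cohort
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValidationError(f"covariates not present in cohort: {missing}")
    genotype = np.asarray(data["genotype"], dtype=float)

    testable, skipped = [], []
    for cov in covariates:
        vals = np.asarray(data[cov], dtype=float)
        if np.unique(vals[np.isfinite(vals)]).size < 2:
            warnings.warn(f"covariate {cov!r} is constant; skipped from the scan")
            skipped.append(cov)
        else:
            testable.append(cov)
    if not testable:
        raise ValidationError("no testable covariates (all constant)")

    m = len(testable)
    threshold = alpha / m
    estimates: dict[str, AssociationEstimate] = {}
    flags: dict[str, str] = {}
    for cov in testable:
        vals = np.asarray(data[cov], dtype=float)
        fit = logistic_association if _is_binary(vals) else linear_association
        est = fit(vals, genotype, coding=coding, trait=cov, kind="genetic")
        estimates[cov] = est
        flags[cov] = "fail" if est.p < threshold else "pass"
    return ValidationReport(
        estimates=estimates, alpha=alpha, n_tests=m,
        threshold=threshold, flags=flags, skipped=tuple(skipped),
    )
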