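"""Seeded individual-level cohort simulator.

Generates cohorts with the causal structure a single-instrument Mendelian
randomization analysis assumes: a biallelic variant in Hardy-Weinberg
equilibrium (UK-Biobank-like T-allele frequency 0.759), milk intake in
g/day shifted per effect allele, continuous and binary outcomes driven by
milk intake, an unobserved confounder U acting on both milk and outcome,
optional direct (pleiotropic) genetic effects that violate the exclusion
restriction, and medication-use indicators generated by treatment-by-
indication so the downstream correction rules change results measurably.

Every generated quantity draws from its own named RNG substream derived
from the scenario seed, so adding a new outcome never perturbs existing
draws and identical scenario+seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .exceptions import ValidationError

__all__ = [
    "MedicationModel",
    "SimulationScenario",
    "CohortFrame",
    "sample_genotypes",
    "simulate_milk_intake",
    "simulate_outcomes",
    "simulate_cohort",
    "make_two_sample_setting",
]

_CONTINUOUS_TRAITS = ("outcome", "sbp", "dbp", "ldl_c", "hba1c")
_BINARY_TRAITS = ("disease",)
_COVARIATES = ("sex", "age", "pc1")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream: stable under addition of other streams."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class MedicationModel:
    """Treatment-by-indication: P(treated) rises with the untreated outcome.

    ``p = max_prob * expit(slope * (value - midpoint))`` — a logistic
    probability centred at ``midpoint`` (outcome units).
    """

    midpoint: float
    slope: float = 0.1
    max_prob: float = 0.9

    def probability(self, value) -> np.ndarray:
        if self.slope < 0 or not (0 <= self.max_prob <= 1):
            raise ValidationError("medication model needs slope >= 0 and max_prob in [0,1]")
        return self.max_prob * expit(self.slope * (np.asarray(value, dtype=float) - self.midpoint))


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of one simulated study population.

    Defaults describe a lactase-persistence-like setting: T-allele
    frequency 0.759, a 17.5 g/day per-allele shift in milk intake around a
    150 g/day baseline, and a generic SD-scale outcome. ``causal_effect_per_gram``
    is the structural effect of milk on the outcome (per gram per day;
    interpreted on the log-odds scale for the binary outcome);
    ``direct_genetic_effect`` injects horizontal pleiotropy (0 = exclusion
    restriction holds); the latent standard-normal confounder U acts on
    milk and outcome with the two ``confounder_effect_*`` loadings.
    """

    n_individuals: int = 10_000
    t_allele_freq: float = 0.759
    per_allele_milk_effect: float = 17.5  # g/day per effect allele
    milk_baseline: float = 150.0  # g/day
    milk_sd: float = 100.0  # g/day residual spread
    causal_effect_per_gram: float = 0.001  # outcome units per g/day
    direct_genetic_effect: float = 0.0  # outcome units per allele (pleiotropy)
    confounder_effect_on_milk: float = 0.0  # g/day per SD of U
    confounder_effect_on_outcome: float = 0.0  # outcome units per SD of U
    outcome_noise_sd: float = 1.0
    binary_baseline_prevalence: float = 0.05
    bp_medication_model: MedicationModel = field(
        default_factory=lambda: MedicationModel(midpoint=150.0, slope=0.08, max_prob=0.9)
    )
    lipid_medication_model: MedicationModel = field(
        default_factory=lambda: MedicationModel(midpoint=4.5, slope=1.2, max_prob=0.9)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if not (0.0 < self.t_allele_freq <= 1.0):
            raise ValidationError("t_allele_freq must lie in (0, 1]")
        if self.milk_sd <= 0 or self.outcome_noise_sd <= 0:
            raise ValidationError("standard deviations must be strictly positive")
        if not (0.0 < self.binary_baseline_prevalence < 1.0):
            raise ValidationError("binary_baseline_prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class CohortFrame:
    """Individual-level records of one simulated cohort.

    ``data`` holds one row per individual: ``genotype`` (T-allele dosage
    0/1/2), ``milk`` (g/day, truncated at 0), continuous outcomes
    (``outcome`` SD units, ``sbp``/``dbp`` mmHg, ``ldl_c`` mmol/L,
    ``hba1c`` %), the binary ``disease`` flag, covariates (``sex``,
    ``age``, ``pc1``) and medication flags (``bp_medication``,
    ``lipid_medication``). Stored blood pressures and LDL-C reflect
    on-treatment values so the correction operations are exercised.
    """

    data: pd.DataFrame
    continuous_traits: tuple[str, ...] = _CONTINUOUS_TRAITS
    binary_traits: tuple[str, ...] = _BINARY_TRAITS
    covariates: tuple[str, ...] = _COVARIATES

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, key: str) -> pd.Series:
        return self.data[key]

    def outcome(self, trait: str) -> pd.Series:
        if trait not in self.continuous_traits and trait not in self.binary_traits:
            raise ValidationError(f"unknown trait {trait!r}")
        return self.data[trait]


def sample_genotypes(n: int, t_allele_freq: float, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw allele-count dosages from Hardy-Weinberg proportions.

    Genotype frequencies are (q^2, 2pq, p^2) for CC/CT/TT with p the
    T-allele frequency; a frequency of exactly 1 is treated as the
    1 - epsilon limit (all TT).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (0.0 < t_allele_freq <= 1.0):
        raise ValidationError("t_allele_freq must lie in (0, 1]")
    p = min(float(t_allele_freq), 1.0 - 1e-12)
    if rng is None:
        rng = _substream(0 if seed is None else int(seed), "genotypes")
    return rng.binomial(2, p, size=int(n)).astype(np.int64)


def _confounder(scenario: SimulationScenario, prefix: str = "") -> np.ndarray:
    rng = _substream(scenario.seed, prefix + "confounder")
    return rng.standard_normal(scenario.n_individuals)


def simulate_milk_intake(
    genotypes: Sequence[int],
    scenario: SimulationScenario,
    confounder: np.ndarray | None = None,
    _prefix: str = "",
) -> np.ndarray:
    """Milk intake (g/day): baseline + per-allele shift + confounding + noise.

    Intakes are truncated at 0 g/day. With the confounder loading zero and
    large n, regressing intake on dosage recovers ``per_allele_milk_effect``.
    """
    g = np.asarray(genotypes, dtype=float)
    if confounder is None:
        confounder = np.zeros_like(g) if scenario.confounder_effect_on_milk == 0 \
            else _confounder(scenario, _prefix)
    if len(confounder) != len(g):
        raise ValidationError("genotypes and confounder must have equal length")
    rng = _substream(scenario.seed, _prefix + "milk_noise")
    intake = (
        scenario.milk_baseline
        + scenario.per_allele_milk_effect * g
        + scenario.confounder_effect_on_milk * np.asarray(confounder, dtype=float)
        + rng.normal(0.0, scenario.milk_sd, size=len(g))
    )
    return np.maximum(intake, 0.0)


def _solve_logistic_intercept(linear: np.ndarray, prevalence: float) -> float:
    lo, hi = -40.0, 40.0
    f = lambda b0: float(np.mean(expit(b0 + linear))) - prevalence
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def simulate_outcomes(
    genotypes: Sequence[int],
    milk: Sequence[float],
    scenario: SimulationScenario,
    confounder: np.ndarray | None = None,
    _prefix: str = "",
) -> CohortFrame:
    """Generate outcomes, covariates and medication flags for one cohort.

    The generic continuous outcome follows the structural model
    ``y = causal*milk + pleiotropy*dosage + confounding*U + noise``; the
    binary outcome uses the same linear predictor on the log-odds scale
    with the intercept solved so the marginal prevalence matches
    ``binary_baseline_prevalence``. Blood pressures and LDL-C are stored
    on-treatment (treated SBP/DBP lowered by 15/10 mmHg; treated LDL-C
    multiplied by 0.68), so the medication corrections are exercised.
    """
    g = np.asarray(genotypes, dtype=float)
    milk = np.asarray(milk, dtype=float)
    if len(g) != len(milk):
        raise ValidationError("genotypes and milk must have equal length")
    n = len(g)
    if confounder is None:
        confounder = _confounder(scenario, _prefix) \
            if (scenario.confounder_effect_on_milk or scenario.confounder_effect_on_outcome) \
            else np.zeros(n)
    u = np.asarray(confounder, dtype=float)

    structural = (
        scenario.causal_effect_per_gram * milk
        + scenario.direct_genetic_effect * g
        + scenario.confounder_effect_on_outcome * u
    )
    noise = _substream(scenario.seed, _prefix + "outcome_noise").standard_normal(n)
    y = structural + scenario.outcome_noise_sd * noise

    # covariates, independent of genotype (the instrument is valid by design)
    sex = _substream(scenario.seed, _prefix + "sex").integers(0, 2, size=n)
    age = _substream(scenario.seed, _prefix + "age").uniform(40.0, 70.0, size=n)
    pc1 = _substream(scenario.seed, _prefix + "pc1").standard_normal(n)

    # blood pressure (mmHg): diastolic plus a positive pulse pressure
    rng_bp = _substream(scenario.seed, _prefix + "bp")
    dbp_untx = 78.0 + 9.0 * rng_bp.standard_normal(n)
    pp = np.maximum(40.0 + 10.0 * rng_bp.standard_normal(n), 10.0)
    sbp_untx = dbp_untx + pp
    p_bp = scenario.bp_medication_model.probability(sbp_untx)
    bp_med = _substream(scenario.seed, _prefix + "bp_medication").random(n) < p_bp
    sbp = np.where(bp_med, sbp_untx - 15.0, sbp_untx)
    dbp = np.where(bp_med, dbp_untx - 10.0, dbp_untx)

    # LDL cholesterol (mmol/L), lowered by treatment (stored / factor recovers)
    rng_ldl = _substream(scenario.seed, _prefix + "ldl")
    ldl_untx = 3.6 + 0.8 * rng_ldl.standard_normal(n)
    p_ldl = scenario.lipid_medication_model.probability(ldl_untx)
    lipid_med = _substream(scenario.seed, _prefix + "lipid_medication").random(n) < p_ldl
    ldl = np.where(lipid_med, ldl_untx * 0.68, ldl_untx)

    hba1c = 5.4 + 0.4 * _substream(scenario.seed, _prefix + "hba1c").standard_normal(n)

    b0 = _solve_logistic_intercept(structural, scenario.binary_baseline_prevalence)
    p_disease = expit(b0 + structural)
    disease = (_substream(scenario.seed, _prefix + "disease").random(n) < p_disease).astype(np.int64)

    data = pd.DataFrame(
        {
            "genotype": g.astype(np.int64),
            "milk": milk,
            "outcome": y,
            "sbp": sbp,
            "dbp": dbp,
            "ldl_c": ldl,
            "hba1c": hba1c,
            "disease": disease,
            "sex": sex,
            "age": age,
            "pc1": pc1,
            "bp_medication": bp_med.astype(np.int64),
            "lipid_medication": lipid_med.astype(np.int64),
        }
    )
    return CohortFrame(data=data)


def simulate_cohort(scenario: SimulationScenario, _prefix: str = "") -> CohortFrame:
    """Full cohort draw: genotypes, confounder, milk intake and outcomes."""
    g = sample_genotypes(
        scenario.n_individuals, scenario.t_allele_freq,
        rng=_substream(scenario.seed, _prefix + "genotypes"),
    )
    u = _confounder(scenario, _prefix)
    milk = simulate_milk_intake(g, scenario, confounder=u, _prefix=_prefix)
    return simulate_outcomes(g, milk, scenario, confounder=u, _prefix=_prefix)


def make_two_sample_setting(scenario: SimulationScenario) -> tuple[CohortFrame, CohortFrame]:
    """Two independent cohorts from one scenario, on disjoint RNG streams.

    The first (exposure) cohort supplies the instrument-milk association;
    the second (outcome) cohort supplies the instrument-outcome
    association, emulating non-overlapping two-sample designs.
    """
    exposure = simulate_cohort(scenario, _prefix="exposure/")
    outcome = simulate_cohort(scenario, _prefix="outcome/")
    return exposure, outcome
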