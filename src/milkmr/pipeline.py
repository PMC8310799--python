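"""Orchestration, tabular I/O, printed-table fixtures and reproduction report.

Two modes of operation:

* **fixture mode** — the per-study estimates and contingency counts printed
  in the source tables ship with the package (``milkmr/fixtures``); the
  pipeline re-pools them, recomputes row percentages and checks IV-ratio
  proportionality, producing a per-cell comparison report against the
  printed meta columns.

* **synthetic mode** — an in-repo scenario generates one exposure cohort
  and two or more independent outcome cohorts; per-cohort associations are
  estimated, pooled by DerSimonian-Laird, and fed into the Wald/IV-ratio
  estimator, with an instrument-validation scan alongside.

Comparisons against printed values use round-to-printed-digits equality
with one-ulp slack in the last printed digit. Cells whose recomputed value
is ambiguous given that the inputs themselves are rounded (e.g. weight
splits between studies with equal rounded standard errors) are classified
``not_assertable`` by propagating half-ulp input perturbations through the
pooling.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    AssociationEstimate,
    GeneticCoding,
    contingency_summary,
    inverse_normal_transform,
    linear_association,
    logistic_association,
)
from .exceptions import SchemaError, ValidationError
from .meta import MetaInput, MetaResult, dersimonian_laird
from .mr import (
    DEFAULT_EXPOSURE,
    ExposureEstimate,
    iv_proportionality_check,
    wald_ratio,
    wald_ratio_binary,
)
from .synthetic import SimulationScenario, make_two_sample_setting, simulate_cohort
from .validation import confounder_scan

logger = logging.getLogger("milkmr")

__all__ = [
    "PipelineConfig",
    "fixture_path",
    "load_summary_table",
    "load_exclusions",
    "build_meta_inputs",
    "run_full_pipeline",
    "reproduce_printed_tables",
]

STUDIES = ("uk_biobank", "1958bc", "hrs", "consortia")


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture file."""
    return Path(resources.files("milkmr") / "fixtures" / name)


# ---------------------------------------------------------------------------
# summary-table I/O


def load_summary_table(path) -> list[AssociationEstimate]:
    """Load a delimited per-study summary-statistics table.

    Required columns: study, trait, kind, beta, se; optional: n.
    Malformed rows are reported with their line numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    required = ["study", "trait", "kind", "beta", "se"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    estimates, bad = [], []
    for i, row in df.iterrows():
        line = i + 2  # header on line 1
        try:
            beta, se = float(row["beta"]), float(row["se"])
            if not np.isfinite(beta) or not np.isfinite(se) or se <= 0:
                raise ValueError(f"beta={row['beta']!r}, se={row['se']!r}")
            n = int(row["n"]) if "n" in df.columns and pd.notna(row.get("n")) else None
            estimates.append(
                AssociationEstimate(
                    study=str(row["study"]), trait=str(row["trait"]),
                    kind=str(row["kind"]), beta=beta, se=se, n=n,
                )
            )
        except (ValueError, ValidationError) as exc:
            bad.append(f"line {line}: {exc}")
    if bad:
        raise SchemaError(f"{path}: malformed row(s): " + "; ".join(bad))
    return estimates


def load_exclusions(path=None) -> dict:
    """Exclusion map {kind: {trait: {study: reason}}} (defaults to packaged fixture)."""
    path = Path(path) if path is not None else fixture_path("table2_exclusions.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {kind: {t: dict(v or {}) for t, v in (m or {}).items()} for kind, m in raw.items()}


def build_meta_inputs(estimates, exclusions=None) -> dict[tuple[str, str], MetaInput]:
    """Group estimates by (trait, kind) and apply overlap exclusions.

    Groups with fewer than two included studies are dropped (pooling
    requires at least two studies); a log record notes each drop.
    """
    exclusions = exclusions or {}
    groups: dict[tuple[str, str], list[AssociationEstimate]] = {}
    for e in estimates:
        groups.setdefault((e.trait, e.kind), []).append(e)
    out = {}
    for (trait, kind), ests in groups.items():
        excl = exclusions.get(kind, {}).get(trait, {})
        included = [e for e in ests if e.study not in excl]
        if len(included) < 2:
            logger.info("skipping %s/%s: %d study(ies) after exclusions", trait, kind, len(included))
            continue
        out[(trait, kind)] = MetaInput(included, exclusions=tuple(excl.items()))
    return out


# ---------------------------------------------------------------------------
# synthetic full pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a synthetic end-to-end run."""

    scenario: SimulationScenario = field(default_factory=SimulationScenario)
    n_outcome_cohorts: int = 2
    coding: GeneticCoding = GeneticCoding.ADDITIVE
    exposure: ExposureEstimate | None = None  # None -> estimate from the exposure cohort
    scale_grams: float = 50.0
    delta_method: str = "second_order"
    out_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        scenario = SimulationScenario(**raw.pop("scenario", {}))
        exposure = raw.pop("exposure", None)
        if exposure is not None:
            exposure = ExposureEstimate(**exposure)
        coding = GeneticCoding(raw.pop("coding", "additive"))
        out_dir = raw.pop("out_dir", None)
        return cls(scenario=scenario, exposure=exposure, coding=coding,
                   out_dir=Path(out_dir) if out_dir else None, **raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _estimate_rows(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study": e.study, "trait": e.trait, "kind": e.kind,
                "coding": e.coding.value if e.coding else "NA",
                "beta": e.beta, "se": e.se, "n": e.n, "p": e.p,
            }
            for e in estimates
        ]
    )


def _meta_rows(results: dict[tuple[str, str], MetaResult]) -> pd.DataFrame:
    rows = []
    for (trait, kind), r in results.items():
        weights = ";".join(f"{s}={w:.2f}" for s, w in r.weights_pct.items())
        rows.append(
            {
                "trait": trait, "kind": kind, "beta": r.beta, "se": r.se, "p": r.p,
                "Q": r.q, "df": r.df, "het_p": r.het_p, "I2": r.i2, "tau2": r.tau2,
                "weights": weights,
            }
        )
    return pd.DataFrame(rows)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Synthetic end-to-end run: simulate, associate, pool, estimate, validate.

    Returns a result bundle with the per-stage DataFrames; when
    ``config.out_dir`` is set the stage outputs are written as TSV with a
    JSON sidecar recording seed, config hash and package version.
    """
    scenario = config.scenario
    logger.info("pipeline start: seed=%d config=%s", scenario.seed, _config_hash(config))

    exposure_cohort = simulate_cohort(scenario, _prefix="exposure/")
    outcome_cohorts = [
        simulate_cohort(replace(scenario), _prefix=f"outcome{k}/")
        for k in range(config.n_outcome_cohorts)
    ]

    # instrument-exposure association from the exposure sample
    gx_est = linear_association(
        exposure_cohort["milk"], exposure_cohort["genotype"],
        covariates=exposure_cohort.data[["sex", "age", "pc1"]],
        coding=config.coding, study="exposure", trait="milk", kind="genetic",
    )
    exposure = config.exposure or ExposureEstimate(
        beta_gx=gx_est.beta, se_gx=gx_est.se, source="exposure_cohort", n=gx_est.n
    )

    # per-cohort associations
    continuous = ["outcome", "sbp", "dbp", "ldl_c", "hba1c"]
    estimates: list[AssociationEstimate] = [gx_est]
    for k, cohort in enumerate(outcome_cohorts):
        study = f"outcome_cohort_{k}"
        df = cohort.data
        covs = df[["sex", "age", "pc1"]]
        for trait in continuous:
            y = _preprocess_trait(df, trait)
            estimates.append(
                linear_association(y, df["genotype"], covariates=covs,
                                   coding=config.coding, study=study,
                                   trait=trait, kind="genetic")
            )
        estimates.append(
            logistic_association(df["disease"], df["genotype"], covariates=covs,
                                 coding=config.coding, study=study,
                                 trait="disease", kind="genetic")
        )
    # phenotypic (observational) association in the exposure sample
    for trait in continuous:
        y = _preprocess_trait(exposure_cohort.data, trait)
        estimates.append(
            linear_association(y, exposure_cohort["milk"],
                               covariates=exposure_cohort.data[["sex", "age", "pc1"]],
                               study="exposure", trait=trait, kind="phenotypic")
        )

    # pool genetic outcome associations across outcome cohorts
    pooled = {
        key: dersimonian_laird(mi)
        for key, mi in build_meta_inputs(
            [e for e in estimates if e.kind == "genetic" and e.study.startswith("outcome_cohort")]
        ).items()
    }

    # Wald/IV ratios from the pooled numerators
    mr_rows = []
    for (trait, _), res in pooled.items():
        gy = AssociationEstimate(study="meta", trait=trait, kind="genetic",
                                 beta=res.beta, se=res.se)
        if trait == "disease":
            w = wald_ratio_binary(gy, exposure, config.scale_grams, config.delta_method)
            mr_rows.append({"trait": trait, "estimate": w.estimate, "se": w.se,
                            "ci_low": w.ci95[0], "ci_high": w.ci95[1], "p": w.p,
                            "or": w.odds_ratio, "or_ci_low": w.or_ci95[0],
                            "or_ci_high": w.or_ci95[1]})
        else:
            w = wald_ratio(gy, exposure, config.scale_grams, config.delta_method)
            mr_rows.append({"trait": trait, "estimate": w.estimate, "se": w.se,
                            "ci_low": w.ci95[0], "ci_high": w.ci95[1], "p": w.p,
                            "or": np.nan, "or_ci_low": np.nan, "or_ci_high": np.nan})

    report = confounder_scan(exposure_cohort, covariates=("age", "sex", "pc1"),
                             coding=config.coding)
    validation_rows = pd.DataFrame(
        [
            {"covariate": c, "beta": e.beta, "se": e.se, "p": e.p,
             "flag": report.flags[c], "threshold": report.threshold}
            for c, e in report.estimates.items()
        ]
    )

    bundle = {
        "estimates": _estimate_rows(estimates),
        "meta": _meta_rows(pooled),
        "mr": pd.DataFrame(mr_rows),
        "validation": validation_rows,
        "exposure": exposure,
        "metadata": {
            "seed": scenario.seed,
            "config_hash": _config_hash(config),
            "version": __version__,
        },
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("estimates", "meta", "mr", "validation"):
            bundle[name].to_csv(out / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
        (out / "run_metadata.json").write_text(json.dumps(bundle["metadata"], indent=2))
        logger.info("wrote stage outputs to %s", out)
    return bundle


def _preprocess_trait(df: pd.DataFrame, trait: str) -> np.ndarray:
    """Apply medication corrections and the inverse-normal transform.

    Blood pressures are corrected (+15/+10 mmHg for treated individuals)
    and analysed in mmHg; LDL-C is medication-corrected then inverse-normal
    transformed; HbA1c stays in percent; the generic SD-scale outcome is
    inverse-normal transformed.
    """
    from .associations import adjust_biomarker, adjust_blood_pressure

    if trait in {"sbp", "dbp"}:
        sbp, dbp = adjust_blood_pressure(df["sbp"], df["dbp"], df["bp_medication"])
        return sbp if trait == "sbp" else dbp
    if trait == "ldl_c":
        corrected = adjust_biomarker(df["ldl_c"], "ldl_c", df["lipid_medication"])
        return inverse_normal_transform(corrected)
    if trait == "hba1c":
        return np.asarray(df["hba1c"], dtype=float)
    if trait == "outcome":
        return inverse_normal_transform(np.asarray(df["outcome"], dtype=float))
    raise ValidationError(f"unknown trait {trait!r}")


# ---------------------------------------------------------------------------
# reproduction of the printed tables


def _printed_decimals(text: str) -> int:
    text = str(text)
    if "e" in text.lower():
        mantissa = text.lower().split("e")[0]
        return len(mantissa.split(".")[1]) if "." in mantissa else 0
    return len(text.split(".")[1]) if "." in text else 0


def _match_one_ulp(computed: float, printed: float, decimals: int) -> bool:
    ulp = 10.0 ** (-decimals)
    return abs(round(computed, decimals) - printed) <= ulp * (1 + 1e-9)


def _dl_cells(estimates) -> dict[str, float]:
    res = dersimonian_laird(MetaInput(estimates))
    cells = {"beta": res.beta, "se": res.se, "i2": res.i2}
    for s, w in res.weights_pct.items():
        cells[f"w_{s}"] = w
    return cells


def _cell_ranges(estimates, precisions) -> dict[str, tuple[float, float]]:
    """Range of each pooled cell under half-ulp rounding of every input.

    ``precisions`` maps study -> (beta_decimals, se_decimals) as printed.
    """
    perturbed = []
    for e in estimates:
        beta_dec, se_dec = precisions[e.study]
        db = 0.5 * 10.0 ** (-beta_dec)
        ds = 0.5 * 10.0 ** (-se_dec)
        perturbed.append([(e.beta + sb * db, e.se + ss * ds)
                          for sb in (-1, 0, 1) for ss in (-1, 0, 1) if e.se + ss * ds > 0])
    ranges: dict[str, list[float]] = {}
    for combo in itertools.product(*perturbed):
        ests = [
            AssociationEstimate(study=e.study, trait=e.trait, kind=e.kind, beta=b, se=s)
            for e, (b, s) in zip(estimates, combo)
        ]
        for cell, val in _dl_cells(ests).items():
            ranges.setdefault(cell, []).append(val)
    return {c: (min(v), max(v)) for c, v in ranges.items()}


def reproduce_printed_tables(estimates_path=None, meta_path=None,
                             contingency_path=None, bodyfat_path=None,
                             exclusions_path=None) -> dict:
    """Recompute the printed tables from their own inputs and compare.

    Returns a report dict with per-cell statuses
    (``match``/``mismatch``/``not_assertable``) for the meta-analysis
    columns, exact 2-decimal checks of the contingency row percentages,
    and the IV-ratio proportionality verdict. ``ok`` is True when no
    assertable cell mismatches.
    """
    est_df_path = estimates_path or fixture_path("table2_estimates.csv")
    meta_df = pd.read_csv(meta_path or fixture_path("table2_meta.csv"),
                          dtype=str, keep_default_na=False)
    cont_df = pd.read_csv(contingency_path or fixture_path("table1_contingency.csv"))
    fat_df = pd.read_csv(bodyfat_path or fixture_path("table3_bodyfat.csv"))
    exclusions = load_exclusions(exclusions_path)

    estimates = load_summary_table(est_df_path)
    inputs = build_meta_inputs(estimates, exclusions)
    raw = pd.read_csv(est_df_path, dtype=str)
    precisions = {
        (r["trait"], r["kind"], r["study"]): (_printed_decimals(r["beta"]),
                                              _printed_decimals(r["se"]))
        for _, r in raw.iterrows()
    }

    cells = []
    for _, row in meta_df.iterrows():
        key = (row["trait"], row["kind"])
        if key not in inputs:
            continue
        ests = inputs[key].estimates
        computed = _dl_cells(list(ests))
        ranges = _cell_ranges(
            list(ests),
            {e.study: precisions[(key[0], key[1], e.study)] for e in ests},
        )
        printed_cells = {"beta": row["beta"], "se": row["se"], "i2": row["i2"]}
        for s in STUDIES:
            col = f"w_{s}"
            if col in row and row[col] not in ("", "NA"):
                printed_cells[col] = row[col]
        for cell, printed_str in printed_cells.items():
            if printed_str in ("", "NA") or cell not in computed:
                continue
            printed = float(printed_str)
            decimals = _printed_decimals(printed_str)
            comp = computed[cell]
            if _match_one_ulp(comp, printed, decimals):
                status = "match"
            else:
                lo, hi = ranges.get(cell, (comp, comp))
                half = 0.5 * 10.0 ** (-decimals)
                status = "not_assertable" if (lo - half) <= printed <= (hi + half) else "mismatch"
            cells.append({"table": "table2", "trait": key[0], "kind": key[1],
                          "cell": cell, "printed": printed, "computed": comp,
                          "status": status})

    # Table 1: exact row-percentage checks
    for _, row in cont_df.iterrows():
        table = contingency_summary(
            [[row["n_never"], row["n_drinker"]]],
            row_labels=[row["row"]], col_labels=["never", "drinker"],
        )
        pct = table.row_percentages.iloc[0]
        for col, printed in (("never", row["pct_never"]), ("drinker", row["pct_drinker"])):
            status = "match" if abs(pct[col] - printed) < 0.005 + 1e-9 else "mismatch"
            cells.append({"table": "table1", "trait": f"{row['cohort']}/{row['panel']}",
                          "kind": row["row"], "cell": f"pct_{col}",
                          "printed": printed, "computed": float(pct[col]),
                          "status": status})

    # Table 3: proportionality of the shared IV denominator
    gen = fat_df[fat_df["kind"] == "genetic"].set_index("trait")["beta"]
    iv = fat_df[fat_df["kind"] == "iv_ratio"].set_index("trait")["beta"]
    pairs = [(gen[t], iv[t]) for t in gen.index]
    prop = iv_proportionality_check(pairs, scale_grams=50.0, decimals=3)
    cells.append({"table": "table3", "trait": "body_fat", "kind": "iv_ratio",
                  "cell": "denominator_consistency", "printed": float("nan"),
                  "computed": prop.spread,
                  "status": "match" if prop.consistent else "mismatch"})

    statuses = [c["status"] for c in cells]
    report = {
        "cells": cells,
        "n_match": statuses.count("match"),
        "n_not_assertable": statuses.count("not_assertable"),
        "n_mismatch": statuses.count("mismatch"),
        "proportionality": prop,
        "ok": statuses.count("mismatch") == 0,
    }
    for c in cells:
        if c["status"] != "match":
            logger.warning("%s %s/%s %s: %s (printed=%s computed=%.6g)",
                           c["table"], c["trait"], c["kind"], c["cell"],
                           c["status"], c["printed"], c["computed"])
    return report
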