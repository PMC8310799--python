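# Methods

## Causal model and estimator

The analysis treats the lactase-persistence variant rs4988235 (T allele)
as an instrumental variable for habitual milk intake. Writing G for the
allele count (0/1/2), X for milk intake in g/day, Y for an outcome and U
for unobserved confounding, the assumed structural model is

    X = α₀ + α₁·G + γ_X·U + ε_X          (relevance: α₁ ≠ 0)
    Y = θ·X + δ·G + γ_Y·U + ε_Y          (exclusion restriction: δ = 0)

with G ⫫ U (instrument unconfoundedness). Under these assumptions the
ratio β_GY / β_GX of the reduced-form coefficients identifies θ, and the
package reports it per 50 g/day of milk: b_IV = 50·β̂_GY/β̂_GX.

Uncertainty uses the delta method. The default is the second-order form,

    Var(b_IV) = 50²·( se_GY²/β_GX² + β_GY²·se_GX²/β_GX⁴ ),

which propagates the exposure-association uncertainty; the published IV
SEs for the body-fat outcomes (0.007–0.01) exceed the first-order
prediction from the genetic SEs alone (≈0.0056), so exposure uncertainty
was evidently propagated there, and the second-order form is the default.
The first-order form (drop the second term) is available by flag. A zero
exposure beta is rejected as an undefined/weak instrument; no other
weak-instrument correction is attempted (single-variant design, no
MR-Egger/median estimators — deliberately out of scope).

For binary outcomes the ratio is computed on the log-odds scale and
exponentiated; CIs are symmetric on the log scale.

When the numerator comes from a meta-analysis, its pooled SE is used
unchanged — the two-step flow (pool, then ratio) adds no extra
between-study term.

## Meta-analysis

Pooling is DerSimonian–Laird (method of moments): fixed-effects weights
w_i = 1/se_i², Q = Σw_i(β_i − β_FE)², τ² = max(0, (Q − df)/(Σw − Σw²/Σw)),
random-effects weights w*_i = 1/(se_i² + τ²). I² = max(0, (Q − df)/Q)·100.
The pooled p-value is a two-sided normal (Wald) test without
Knapp–Hartung adjustment. These choices were pinned down empirically: DL
with normal p-values reproduces the published random-effects weight split
for the BMI phenotypic row (51.55/48.45) and every published pooled
beta/SE from the printed per-study inputs, which REML or Paule–Mandel do
not guarantee. When Q ≤ df, τ² truncates to zero and the result coincides
exactly with fixed-effects pooling — a property the test suite asserts and
cross-checks against `statsmodels.stats.meta_analysis.combine_effects`
(used only as an independent oracle).

Per-trait exclusions before pooling (to avoid overlap between cohorts and
the consortium GWAS samples) are data, not code: they are loaded from
`fixtures/table2_exclusions.yaml` and can be replaced.

### Comparing recomputed to printed values

Printed tables carry 2–4 decimals, and the pooled quantities are computed
from inputs that are themselves rounded. A recomputed cell is declared a
**match** when it equals the printed value after rounding to the printed
number of decimals, with one-ulp slack in the last digit. Cells that fail
that test are classified **not-assertable** (rather than mismatch) when
the printed value lies inside the range the pooled quantity can take as
each input beta/SE varies by ±half an ulp of its printed precision; the
range is evaluated by propagating the 3^(2k) sign-perturbation corners
through the pooling. The canonical example is the weight split between two
studies whose SEs both print as 0.003: the printed 61.6/38.4 cannot be
recovered from the rounded inputs (any split between ~34% and ~66% is
compatible), so only the pooled beta is asserted for that row.

## Per-cohort estimation

- **Medication corrections** operate on the measurement scale, before any
  transform: +15/+10 mmHg to systolic/diastolic pressure for treated
  individuals; division by trait-specific factors (0.68 LDL-C, 1.05
  HDL-C, 0.75 total cholesterol, 0.87 triglycerides, 1.21 CRP, 1.04
  HbA1c) for lipid-lowering treatment. The pipeline applies each
  correction exactly once (the flag is consumed at preprocessing; raw and
  corrected columns are never mixed).
- **Inverse-normal transform**: Blom scores Φ⁻¹((r − 3/8)/(n + 1/4)) with
  average ranks for ties — the GWAS-consortium convention; the source
  specifies only "inverse-normal-transformed". Output has mean ~0 and
  variance slightly below 1 (e.g. 0.97 at n = 500). Blood pressures stay
  in mmHg and HbA1c in percent; other continuous traits are transformed.
- **Genotype coding**: additive (0/1/2 T alleles) or recessive-carrier
  (CT+TT = 1 vs CC = 0, CC the reference). The "recessive" label follows
  the field's usage for this contrast even though it is formally a
  dominance coding for the T allele; the coding is recorded in every
  estimate's metadata.
- **Regression**: OLS with classical SEs for continuous outcomes, Newton
  maximum likelihood (tolerance 1e-8, max 100 iterations) for binary
  ones, both on complete cases per model, with covariates supplied as
  configuration (the real cohorts used different adjustment sets).
  Rank-deficient designs are rejected naming the collinear columns;
  perfect fits and separation raise explicit errors. p-values are
  two-sided normal.
- **HWE**: Pearson chi-square (1 df) against expected counts from the
  sample allele frequency; monomorphic samples are reported as exact
  equilibrium (χ² = 0) rather than an error.

## Instrument validation

Each candidate confounder is regressed on the coded genotype (linear for
continuous/ordinal covariates, logistic for binary) and flagged at the
Bonferroni threshold α/m, with m the number of covariates actually tested
— 0.00625 for the default eight (age, sex, income, education, health
status, smoking, alcohol, coffee). Constant covariates are skipped with a
warning and removed from m. Categorical covariates are expected as
ordinal scores. With per-test threshold α/m the family-wise error under
the null is ≤ α (≈0.049 for m = 8); the acceptance suite verifies this
over 1000 simulated scans.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| `t_allele_freq` | 0.759 | derived from the published UK-Biobank genotype counts, (2·225,250 + 142,271)/(2·390,431) |
| `per_allele_milk_effect` | 17.5 g/day | back-derived: the published genetic/IV-ratio pairs imply a denominator of 16.7–18.0 g/day per allele |
| `milk_baseline` / `milk_sd` | 150 / 100 g/day | matches published g/day medians (146–188) with a realistic spread |
| `causal_effect_per_gram` | 0.001 SD per g/day | 0.05 SD per 50 g, the magnitude of the published body-fat IV ratios |
| `outcome_noise_sd` | 1 | outcomes on the SD scale |
| `binary_baseline_prevalence` | 0.05 | T2D-like prevalence |
| confounder loadings | 0 | a valid instrument by default; set both nonzero to plant confounding |

Milk intake is normal with truncation at 0 g/day (not log-normal): this
keeps OLS recovery of the per-allele effect exact in expectation at the
stated effect sizes while matching the published medians. The confounder
U is a single standard-normal latent variable — the minimal structure
that demonstrates observational bias alongside MR robustness. Medication
flags follow treatment by indication (a logistic probability increasing
in the untreated outcome), and the *stored* values are on-treatment
(SBP/DBP lowered by 15/10; LDL-C multiplied by 0.68), so the correction
operations visibly change downstream estimates. The binary outcome's
intercept is solved by root-finding so the marginal prevalence matches
the target.

Every quantity draws from a named RNG substream
(`SeedSequence(seed, spawn_key=(crc32(name),))`), so identical
scenario+seed is bit-reproducible and adding an outcome never perturbs
existing draws. `make_two_sample_setting` produces exposure and outcome
cohorts on disjoint stream prefixes, emulating non-overlapping samples.
The synthetic full pipeline draws one exposure cohort plus two (or more)
outcome cohorts and pools the outcome-cohort genetic associations by DL
before the ratio step, mirroring the two-step published flow.

What the generator does **not** model: LD structure or multi-SNP
instruments, genotyping error, relatedness/population stratification
(the PC covariate is pure noise), non-normal outcome tails, selection
effects, and reverse causation. Passing tests therefore demonstrate the
statistical machinery under the assumed structural model, not robustness
of the scientific conclusion to violations the real studies may face.

## Problem sizes and numerical choices

Parameter-recovery checks run at n = 200,000 individuals (where a 0.001
SD/g effect is resolved at ~4 SEs); CI-coverage uses 200 replicates of
two 20,000-person cohorts; calibration checks (regression type-I error,
family-wise error of the scan) use 1000 replicates at n = 2,000–10,000.
Logistic fits declare separation when an SE exceeds 10³ or statsmodels
flags perfect prediction. Exposure-frequency 1 is treated as the 1 − ε
limit (all TT). Tolerances on simulation-based assertions are 3 SEs of
the quantity under test (4 binomial SDs for raw proportions).

## Known limitations

- Single-instrument ratio estimation only; no pleiotropy-robust
  estimators, no Steiger filtering, no F-statistic screening.
- Classical (homoskedastic) OLS standard errors; no clustering.
- The published Table 4 odds ratios and the exact EPIC-InterAct
  instrument–milk estimate are not reproducible from printed inputs; the
  former ship as display-only fixtures, the latter is configuration with
  a back-derived default (17.5 ± 4.0 g/day per allele).
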