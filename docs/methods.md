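# Methods

This note documents the models and numerical choices behind each pipeline
stage, the parameters that matter, and what the synthetic data generator
does and does not emulate.

## Chromatographic descriptors

Retention enters as `(percent_organic, t_R, t0, replicate)` points per
compound and column system; dead times are always taken from the input
table (baseline disturbance for RP18, citric acid for IAM), never
hard-coded.

- **Capacity factor** `k' = (t_R − t0)/t0`; `t_R < t0` and `t0 ≤ 0` are
  hard errors. `k' = 0` (unretained analyte) is representable but any
  downstream logarithm raises.
- **BRlogD** = `3.31·log₁₀ k'₆₀ + 2.79`, with replicate injections
  averaged on the log k' scale.
- **log kw_IAM**: replicates at each organic fraction are averaged on the
  log k' scale first, then an OLS line of mean log k' versus %ACN is
  fitted and read at 0% organic. The functional form is linear in the
  volume fraction — the standard isocratic-extrapolation practice; the
  fit R² is carried on every profile so curvature in a real series is
  visible rather than silently absorbed. At least three distinct organic
  levels are required.
- **Δlog kw_IAM** = `log kw_IAM − (0.92·BRlogD − 1.03)`. Both identities
  (`clog kw_IAM` and the difference) are computed from the stored fields
  with no intermediate rounding, so they hold bit-for-bit on every
  profile.
- **EPSA** is pass-through data. No retention→EPSA transform is computed;
  a user-supplied calibration line `EPSA = a·retention + b` can be
  applied explicitly. SFC gradient settings are stored as run metadata
  only.

## Solubility quantification

Calibration lines are OLS on (concentration mg/mL, AUC); five or more
points are expected (fewer fit with a warning, matching 5–10-point
experimental practice). Quantification inverts the line with dilution
correction; a non-positive interpolated concentration is treated as
below-LOQ and censored rather than reported negative. The numeric LOQ is
never assumed — censoring is an input state.

Unit chain: mg/mL numerically equals g/L, so `log S = log₁₀(conc/MW)`;
µM = 10^(log S)·10⁶. Replicate summaries use the sample SD (n−1
denominator) and RSD% relative to the mean.

GSK classes: low < 30 µM, high > 200 µM, and the **closed** interval
[30, 200] µM maps to intermediate — the published class bounds are
strict inequalities on the outer classes, which leaves both boundary
values in the middle class. Censored measurements classify low and are
excluded from every quantitative analysis (`filter_quantitative`, which
is idempotent).

Molecular weights are recorded as given; a stated MW more than
0.5 g/mol from the structure-derived average-mass value raises a
validation finding (possible salt/solvate) but is never auto-corrected.

## 2D descriptors

- **TPSA** is an in-repo Ertl fragment-contribution implementation over
  N/O atom environments (charge, aromaticity, H count, bond-order
  pattern, three-ring membership), with Ertl's linear fallback for
  unmatched environments and an opt-in flag adding S/P contributions.
  The N,O-only flavour is the default because it is the common default
  of descriptor packages; thresholds learned from user data should be
  refit if the flavour changes. RDKit's aromaticity model is used for
  perception, which makes results invariant to input kekulisation; RDKit's
  own `CalcTPSA` serves as an independent cross-check in the test suite
  (agreement within 0.01 Å² on a 20-molecule drug panel), never as the
  implementation.
- **Kier Φ** = `¹κα·²κα/A` with `¹κα = (A+α)(A+α−1)²/(¹P+α)²`,
  `²κα = (A+α−1)(A+α−2)²/(²P+α)²`; A = heavy atoms, ¹P = bonds,
  ²P = two-bond paths, α = Σ covalent-radius corrections relative to sp³
  carbon (Hall–Kier table; aromatic atoms count as sp²; unknown
  environments fall back to α = 0 with a warning). Φ is undefined
  (error, not 0) for A < 3 or ²P = 0. For unbranched alkanes Φ = A − 1
  exactly, which the tests exploit as a closed form.

## Conformer-ensemble 3D-PSA

Polar surface = exposed van-der-Waals area (probe radius 0) of N, O and
hydrogens within 1.30 Å of an N/O (sulfur excluded by default,
switchable). Radii are Bondi values with r(H) = 1.20 Å. Each polar
atom's sphere is sampled with a deterministic golden-spiral point set
(default 960 points/atom; the count is a config knob recorded in CLI
output); a point survives if it lies outside every other atom's sphere,
and the exposed fraction scales 4πr². Determinism follows from the fixed
point set; accuracy is ~0.5% at 960 points on occluded systems (tested
against a dense latitude–longitude grid oracle and the two-sphere closed
form) and exact for isolated atoms. Rotation invariance holds to the
sampling tolerance.

Ensemble summaries use linear-interpolation quantiles (the plotting
convention of the original software is unknown; this rule is documented
and tested) and Tukey adjacent limits: the extreme data values inside
the inner fences Q1 − 1.5·IQR and Q3 + 1.5·IQR, degrading to the
quartiles themselves if a fence excludes all data. Conformer generation
(force fields, MD) is out of scope: ensembles are ingested from
multi-record SDF or multi-model PDB files, or from the toy generator for
testing.

## Classification

The fixed rule (TPSA ≥ 289.31 Å² → high; else BRlogD ≥ 2.58 → low; else
intermediate) is also materialised as a two-split tree object; both
thresholds are inclusive. The third leaf is labelled intermediate: the
published rule assigns only the high and low leaves explicitly, and the
remaining region of the (TPSA, BRlogD) plane is the middle class by
elimination.

The refittable learner is plain CART: exhaustive search over midpoint
thresholds of consecutive distinct feature values, minimising weighted
Gini impurity, deterministic tie-breaks (lowest impurity, then feature
index, then threshold), optional seeded per-node feature subsampling to
approximate "random tree" behaviour. Cross-validation uses stratified
folds when every class has ≥ k members, otherwise plain shuffled k-fold
with a warning; predictions are pooled into one confusion matrix, and
accuracy is pooled-correct/n. Model-fitting entry points accept
exclusion lists so outlier removal is configuration, not code.

## Building-block pair logic

log S values are interval-aware: a value may be censored above (only a
lower bound known, e.g. a block more soluble than the assay ceiling) or
below (sub-LOQ). Two values are ordered only when their intervals are
disjoint; concordance compares the degrader ordering with the varied
block's ordering and is indeterminate whenever either ordering is open
or tied. This is what lets a censored-above block value still support a
determinate, concordant comparison when the bound already exceeds the
other block's value.

## Synthetic data generator

Defaults encode the study conditions: n = 21 compounds; TPSA ~ U(166,
335) Å², nC ~ U{34..58}, Φ ~ U(9, 27), BRlogD ~ U(0.5, 5.5); MW ~
U(700, 1100) g/mol (sampled, since synthetic compounds carry no
structures); `log kw_IAM = 0.92·BRlogD − 1.03 + Δ` with Δ ~ N(0, 0.4)
so the polarity identity is exercised; `log S = −0.75·BRlogD − 3.29 +
N(0, σ)` with σ defaulting to the calibration
`σ² = var(slope·x)·(1 − R²)/R²` at target R² = 0.67 (σ ≈ 0.76);
censoring below log S = −6.5, chosen so the expected ND fraction
(~24%) matches a 5-of-21 panel. Descriptors are sampled independently:
independence suffices to test every pipeline stage, and the real data's
moderate lipophilicity cross-correlations are deliberately not emulated.
Retention tables are generated by inverting the descriptor transforms
(optionally with replicate jitter on the log k' scale), so the
chromatography module recovers the generating descriptors exactly at
zero jitter — a strong end-to-end correctness check.

Calibration experiments (the R² check and the slope-recovery sweep) run
with censoring disabled, because they characterise the generative line
itself; with the default LOQ active, truncating the least-soluble tail
biases an OLS refit toward shallower slopes (≈ −0.56 at large n), which
is a real property of censored panels, not an implementation artefact.

Sampling error matters at these scales: with σ calibrated for R² = 0.67,
the SE of a refit slope is `|slope|·√((1−R²)/R²)/√n` ≈ 0.037 at n = 200,
so individual refits scatter a few hundredths around −0.75, and small
panels (n ≈ 16) scatter much more. The acceptance script reports the
measured recovery rate rather than asserting a point value.

What passing tests do **not** show about real data: structure–descriptor
consistency (synthetic descriptors are drawn, not computed), pH-dependent
ionisation effects, salt/solvate mass corrections, chromatographic
curvature, or conformer ensembles of real degraders.

## Problem sizes

The test suite and acceptance script use n = 21 panels for structure
checks, n = 200 for cross-validation and per-seed recovery, n = 2000 for
asymptotic calibration, 100-seed sweeps for rates, 10⁴ random points for
rule/tree agreement, and 960–15 360 sphere points for surface accuracy;
the full suite runs in well under a minute.

## Known limitations

- The exact polar-atom set and quantile rule of the original 3D-PSA and
  plotting tools are unpublished; sulfur handling and the quantile
  convention are explicit knobs/documented choices here.
- Whether the original IAM extrapolation was linear in volume fraction is
  not stated; the fit R² is reported so deviations are visible.
- The TPSA flavour (N,O vs total) and Φ parameterisation of the original
  descriptor software are unstated; learned thresholds are
  flavour-dependent.
- The "random tree" software used originally is approximated, not
  re-implemented; its fold seeding is unknown, so cross-validated
  accuracies on small panels should be read with seed-sweep uncertainty.
- Daily QC compounds (caffeine, carbamazepine, ketoprofen, theobromine,
  toluene) have no published acceptance ranges; QC is reporting, not a
  gate.
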