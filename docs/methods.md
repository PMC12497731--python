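# Methods

## Study design and data model

The package models a pot trial on *Glycyrrhiza uralensis* seedlings with
six treatments — unstressed control (CK), 160 mM NaCl stress (S), and NaCl
plus lanthanum nitrate at 0.25, 0.5, 0.75 and 1.0 mM (S+La0.25 … S+La1.0) —
five replicate pots per treatment, and 29 physiological indicators grouped
into four systems: growth (9 indicators: biomass, allocation and root
architecture), photosynthesis (6: SLA, SPAD chlorophyll, Pn, Gs, Ci, Tr),
antioxidant (8: leaf/root SOD, POD, CAT activities plus leaf/root MDA) and
pharmacological (6 secondary metabolites). All indicators are
positive-polarity ("more is better") except the two MDA columns, which mark
membrane lipid peroxidation damage.

Replicate-level raw indicator data for this design were never published;
what is available — and shipped as packaged fixtures transcribed exactly as
printed — are the treatment means ± SD of the photosynthetic and metabolite
panels (`table1`, `table2`), the per-treatment CRITIC weights in percent
(`table3`), the 30-row replicate-level composite-score table (`table4`),
and the six linear calibration curves (`standard_curves`). Replicate ids
1–5 within each treatment of `table4` follow the printed top-to-bottom
order; the source gives no ids, so a fixed convention is required for
deterministic seeding and splits.

## Measurement calculators

- MDA content: `6.45·(A532 − A600) − 0.56·A450` per gram fresh weight. The
  difference term removes turbidity background, the A450 term corrects for
  soluble-sugar interference. Absorbances may be slightly negative after
  blank correction; only non-finite inputs are rejected.
- Standard-curve inversion: `X = (Y − intercept)/slope`; concentrations
  outside the validated calibration range warn rather than error, since
  extrapolated values are routinely inspected rather than discarded.
- Percent change is reported in the integer style of agronomy papers:
  round half away from zero. `decrease` and `increase` are sign conventions
  on the same quantity.
- Pearson correlations use sample (n−1) covariance (the SPSS convention the
  indicator heat-maps in this literature are produced with). Constant
  columns yield undefined (NaN) coefficients and are flagged, not dropped.

## CRITIC weighting and composite scores

Standardization is min–max per indicator within each scope group
(`per-treatment` by default, `global` optional): positive polarity
`(x − min)/(max − min)`, negative polarity reflected. Min–max rather than
z-scoring is essential: after z-scoring every contrast would equal 1 and
CRITIC would reduce to a pure conflict weighting. Constant columns map to 0
and are flagged.

For each (scope group, system) block, indicator j receives contrast
`C_j = sd(x̃_j)` (sample SD, ddof 1), conflict `R_j = Σ_k (1 − r_jk)` over
the block, score `S_j = C_j·R_j` and weight `w_j = S_j/Σ S`. Undefined
correlations from constant columns enter as r = 0 with a flag; an all-zero
block falls back to uniform weights and is marked degenerate.

Two genuinely open design points were resolved as follows:

- **Scope = per-treatment.** The published weight table reports distinct
  weights per treatment column, and each system block sums to 100% within
  each treatment (verified arithmetically on the fixture, e.g. the CK
  photosynthesis block 4.1+8.3+3.4+24.7+58.5+1.0 = 100.0). Per-treatment
  weighting with the five replicates as the sample is therefore the default;
  `global` is available.
- **Composite value basis = raw.** The published composite scores run in
  the hundreds to thousands, incompatible with weighted sums of
  standardized values in [0, 1]; raw-basis aggregation reproduces that
  scale regime. The composite operation is validated on synthetic data —
  the published composite table cannot be recomputed without the
  unpublished replicate panel, which is exactly why it ships as a fixture.

## Adaptive-bandwidth density estimation and sample weights

Pilot bandwidth per dimension is Silverman's rule
`h = 0.9·min(SD, IQR/1.34)·n^(−1/5)`; a zero-spread dimension falls back to
`|mean|·10⁻³ + 10⁻⁶` with a flag. A fixed-bandwidth Gaussian product-kernel
pilot estimate f̃ at the sample points sets Abramson local factors
`λ_i = (f̃(x_i)/g)^(−α)` with g the geometric mean of the pilot densities
(so the λ_i have geometric mean 1), and the final estimate uses per-sample
bandwidths h_d·λ_i. α = 0.5 is the canonical Abramson sensitivity and the
default; α = 0 recovers the fixed-bandwidth KDE exactly.

The density values at the training inputs become per-sample LSSVM weights.
The direction of the weighting is not determined by the coupled-model
description, so both are exposed: `proportional` (`ω_i = f̂(x_i)/mean f̂`,
default — replicates in dense regions are treated as more trustworthy) and
`inverse` (reciprocal, clipped to [0.1, 10] before renormalization so a
single isolated sample cannot dominate the conditioning of the dual
system). Weights are renormalized to mean 1, so ω ≡ 1 recovers the
unweighted LSSVM.

## Weighted LSSVM

Training solves the (n+1)×(n+1) saddle system
`[[0, 1ᵀ], [1, K + diag(1/(γ ω_i))]]·[b; α] = [0; y]` by one exact dense
solve (n ≤ a few hundred here; determinism beats iterative solvers at this
scale), with one +10⁻¹²·I jitter retry on singularity. The RBF kernel uses
the `exp(−‖x−z‖²/(2σ²))` convention — stated explicitly so the search
bounds on σ are unambiguous. Inputs are min–max normalized to [0, 1] and
targets z-scored inside the model, fitted on training rows only, making the
hyperparameter bounds scale-free. Solver round-off on the zero-sum KKT row
is projected out of α after the solve. Models serialize to JSON with
hex-encoded floats for bit-exact round trips.

## Hyperparameter search

Four strategies behind one seeded, bounds-clipping, strictly-improving
interface. The default `nrbo` follows the hybrid description of the
coupled model: a velocity/position update
`v ← ω_v·v + c₁γ₁(pbest − x) + c₂γ₂(gbest − x)` (inertia ω_v = 0.7,
c₁ = c₂ = 1.5, per-dimension uniform randoms γ₁, γ₂ — renamed here to avoid
collision with the LSSVM's γ and the density weight ω), plus a
Newton-Raphson search rule moving each particle along the direction implied
by the population's best and worst members with step modulated by
δ_t = (1 − 2t/MaxIt)⁵ (magnitude decaying, sign randomized), plus a
trap-avoidance operator that, with probability DF = 0.6, resamples a
particle as a random convex mixture of gbest and a random member plus
δ-scaled bounded noise. `canonical_nrbo=True` switches to the canonical
NRBO operator formulas (vector NRSR with ρ drift, X1/X2/X3 mixing, TAO).
NGO and CPO are implemented in their canonical forms as comparison
baselines. Ties in pbest/gbest updates keep the incumbent; a single seeded
generator drives all draws, so results are bit-reproducible.

Default search space: γ ∈ [10⁻², 10⁴], σ ∈ [10⁻², 10²], both searched in
log10 space (multiplicative hyperparameters), population 30, 200
iterations.

Two fitness modes tune (γ, σ):

- `paper_faithful` (default): the MSE on the held-out test rows of a model
  trained on the training rows. This is the protocol of the original
  analysis; it lets model selection see the test targets and is therefore
  leaky — the tuner logs this. Reported held-out metrics under this mode
  are optimistically biased.
- `cv`: mean 5-fold cross-validation MSE on the training rows only
  (deterministic round-robin folds). Test rows are untouched until final
  evaluation; this is the mode to use for honest generalization estimates.

## Coupled pipeline and evaluation

The composite dataset is split 25/5 by default: one test replicate drawn
from each of five distinct treatments, matching the five-sample-point
evaluation of the original analysis (whether those five points were one per
treatment is not stated; the stratified default is the inference, and a
uniform split is available). Each target system (growth; pharmacological)
is fit by its own single-output model. Metrics are Pearson R, RMSE, MAE and
residual standard deviation (the quantity labelled "RSD" in this
literature, which is never formally defined there), reported both on the
test rows and on all rows, since the published fit degree plots mix train
and test points. Reports serialize to versioned JSON byte-identically given
(dataset, config, seed).

## Synthetic data generator

The generator emulates the study design — 6 treatments × n replicates
(default 5) × 29 indicators — as correlated Gaussians per treatment.
Means/SDs default to the published tables where printed; enzyme, MDA and
growth-morphology defaults are **placeholders**, chosen so that CK
baselines are physiologically plausible for licorice seedlings and the S
and S+La0.75 treatment means reproduce the quoted percent changes
(intermediate doses interpolate linearly at 1/3 and 2/3 toward the 0.75 mM
optimum; 1.0 mM regresses to 20% of the way, reflecting the reported
supra-optimal decline). Placeholder SDs are 6% of the mean. The correlation
structure is system-block-exchangeable (ρ_within = 0.6) with the MDA
columns at ρ_mda = −0.5 against their system's enzyme columns, repaired to
the nearest PSD matrix by eigenvalue clipping if needed; negative draws for
strictly-positive indicators are truncated at zero with a logged count
(simple and deterministic, at the cost of a slight mean bias when an SD is
large relative to its mean — negligible at the defaults).

Composite-shaped datasets for predictor testing draw antioxidant and
photosynthesis scores per treatment from the packaged composite table's
means/SDs and compute growth/pharmacological outputs through a named link
(`constant`, `linear`, or `smooth-nonlinear` = linear plus sine terms) plus
Gaussian noise (default 5% of each clean output's range).

What passing tests on synthetic data do and do not show: they verify the
estimators and the pipeline recover known structure (the smooth-nonlinear
recovery reaches held-out R ≥ 0.95 as a 10-seed median), but the generator
is not a calibrated model of licorice physiology — real replicate data have
non-Gaussian tails, treatment-dependent variances and cross-system
correlations the generator deliberately omits.

## Numerical choices

- Panel CSVs are written with 12 significant digits; one write/read pass
  quantizes, after which round trips are exactly idempotent.
- Degenerate rules: constant standardized columns → 0 with flag; all-zero
  CRITIC block → uniform weights with flag; zero densities floored at
  10⁻³⁰⁰ with warning; constant evaluation vectors → undefined R (NaN) with
  warning; n = 1 LSSVM → α = 0, constant prediction.
- Non-finite optimizer fitness values are treated as +∞; all candidate
  positions are clipped to bounds before evaluation.
- Every random path (generator, splits, optimizers) derives from one
  explicit integer seed through `numpy.random.default_rng`.

## Reproduction protocol and problem sizes

The headline quantities are recomputed by `scripts/acceptance.py` as the
best over ten run seeds of the held-out RMSE (per target) under the
`paper_faithful` protocol on the packaged 30-row composite table, plus the
all-rows R of the best growth run. Best-of-ten is the package's protocol
for reproducing single-run numbers whose originating seed is unknown. The
NRBO budget is population 30 × 200 iterations per run — past the point
where the search reproducibly reaches the global optimum of this 2-D
fitness (verified against an exhaustive grid plus multistart local
refinement during development).

## Known limitations

- Under a genuine 25/5 held-out protocol on the published composite table,
  the best achievable held-out RMSE (global optimum over (γ, σ), any of the
  ten splits) is ≈ 3.7 growth-score units and ≈ 31 pharmacological-score
  units, and the corresponding all-rows R ≈ 0.77–0.9: a two-hyperparameter
  kernel model cannot fit five held-out replicates closer than their
  within-treatment noise (SD ≈ 30 and ≈ 70 score units). Originally
  reported accuracies of order 1 score unit and R ≈ 0.99998 are reachable
  only if the evaluated points effectively participate in training. The
  package reports what the stated protocol actually yields.
- The `paper_faithful` fitness is leaky by construction; use `cv` for
  honest generalization estimates.
- ANOVA/post-hoc significance labelling, HPLC peak integration and figure
  digitization are out of scope.
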