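# Methods

This note documents the models implemented in `synovclass`, the defaults
of the synthetic-cohort generator, and the numerical choices made where
the procedure left room for interpretation.

## Data model

A cohort is a genes × samples expression matrix (log2-like scale), a
per-sample table of binary clinical attributes with a diagnosis label and
optional DAS28-like activity score, and — for the low-density array
pathway — a long table of raw spots: (sample, probe, role, replicate,
foreground, background), with probe roles `diagnostic`, `housekeeping`,
`internal_standard` and `hybridization_control`, spotted in triplicate.

## Array preprocessing

1. **Background subtraction.** `intensity = foreground − background` per
   spot. Negative values are kept: the glog transform is defined for them,
   and clipping would bias the additive-noise floor upward.
2. **Generalized log.** `g(x) = ln((x − α) + sqrt((x − α)² + λ))`,
   linear for |x − α| ≪ √λ and logarithmic above, so that two-component
   spot noise (additive background + multiplicative hybridization) has
   approximately constant variance after transformation. (λ, α) are fitted
   by maximizing the transform-both-sides normal likelihood over replicate
   groups — per-group means and a pooled variance profiled out, with the
   Jacobian term Σ ln g′(x) making likelihoods comparable across
   parameters. The λ search runs on a log grid (1e−2 … 1e10) followed by a
   Nelder–Mead polish in log λ. α is held at 0 by default
   (`optimize_alpha=True` to free it): background subtraction already
   removes the additive offset α models, and on replicate data (λ, α) are
   poorly identified jointly — freeing α lets it drift and absorb
   several-fold errors in λ. For negative arguments g uses the
   algebraically equivalent form λ/(√(u²+λ) − u) to avoid catastrophic
   cancellation.
3. **Control-probe normalization.** The additive model
   `z_ijk = μ + a_i + b_j + ε` is fitted by OLS to the glog-transformed
   housekeeping + internal-standard spots (hybridization controls are
   excluded — they report on the labeling mix, not the sample), with
   `a_1 = b_1 = 0` for identifiability. Outlier rejection is iterative and
   **one replicate at a time**: compute residuals, flag candidates with
   |residual| > 3 × 1.4826 × MAD of the retained residuals, remove only the
   worst offender, refit, repeat until no candidate remains. Removing one
   spot per iteration keeps the leverage of a gross outlier from dragging
   sound replicates over the threshold (simultaneous flagging demonstrably
   over-flags in the near-noiseless regime). A floor of 1e−8 × the data
   scale on the threshold prevents flagging numerically-zero residuals.
   The fitted `a_i` is subtracted from every value of sample i; probe
   effects `b_j` are left in place (they cancel in gene-wise contrasts),
   so within-sample gene contrasts are preserved exactly. A consequence of
   one-at-a-time rejection is that a sample can never lose all its
   replicates — its remaining spots are always absorbable by `a_i` — so
   the "sample fully flagged" error path is a defensive guard only.
   Single-sample input is an error (a_i unidentifiable), not a no-op.
4. **Summarization.** Median of surviving replicates per (gene, sample);
   an even count yields the midpoint mean; zero survivors yield a missing
   value with a warning.

qPCR tables are normalized as ΔCt: `expression = −(Ct_gene − Ct_hk)`
(log2-like units under ~2× per-cycle efficiency). Assays with no signal in
any sample are dropped with a warning; a missing housekeeping Ct is an
error.

## Signature selection

Quantile variability filter (drop the 75% of genes with the smallest
p95 − p5 spread; linear-interpolation percentiles; ceiling on the kept
count), then per-gene one-way ANOVA at unadjusted p ≤ 0.05, then per-class
one-vs-rest two-sample t statistics. Welch's unequal-variance t is the
default — the one-vs-rest splits are heavily unbalanced — with the
pooled-variance variant available (`equal_var=True`). Genes are ranked by
|t| (discrimination in either direction); ties in any ranking or in the
spread cutoff are broken lexicographically by gene id so results are
exactly reproducible. The signature takes the top ⌊k/C⌋ genes per class
(floor when C ∤ k); a gene selected by several classes counts once.

## Classification

`dist(x₁,x₂) = ρ·dist_E(φ(x₁),φ(x₂)) + (1−ρ)·dist_P(ω(x₁),ω(x₂))` with
the components combined raw and unscaled — the scale mismatch between a
Euclidean distance on 3 binary attributes (0…√3) and a Pearson distance
(0…2) is a property of the method, not corrected away. The neighbor set of
a k-NN query is the k closest references plus every reference exactly tied
with the k-th distance (binary clinical vectors make such ties common;
they are the mechanism by which the expression term acts as tie-breaker
for ρ just below 1). The majority class among the neighbor set wins; vote
ties are resolved by the smallest mean distance among the tied classes,
then lexicographic class name. References with missing expression are
excluded (with a warning) whenever the expression component is active; no
imputation is attempted. The ρ = 0 and ρ = 1 endpoints skip the unused
component entirely, which makes them bit-identical to the pure
single-component computations.

## Evaluation

200 random splits into 90% training references / 10% test queries
(⌈0.10·n⌉ test size, drawn without replacement). Splits are **stratified
by class** by default: with 4 SA samples, unstratified 10% splits
routinely orphan the class from training; a `stratify=False` mode draws
pure random splits and redraws (logged) when a class vanishes. When a
patient id column is present, all biopsies of a patient stay on one side
of every split (repeat UA biopsies would otherwise leak). Per split we
record the 3-class BCR, the 2-class BCR obtained by collapsing the
3-class predictions to RA vs not-RA post hoc (no binary retraining), and
per-class sensitivity/PPV; PPV is missing — not zero — for a class never
predicted, and aggregation over splits is NaN-aware. Reported means ± SD
are the sample mean and SD of the retained per-split values. The rho
sweep uses 21 evenly spaced values in [0, 1] by default and re-runs the
full resampling per grid point with the same seed, so its endpoints
reproduce the standalone clinical/transcriptomic runs bit for bit. The
signature-size sweep re-selects the signature on each training set
(filters + ranking) before predicting. In probe-against-pool mode every
query is predicted on each split against a stratified 90% subsample of
the pool, never seeing itself or another biopsy of its patient. The
criteria-flag comparator scores the binary flag directly as the
prediction (balanced accuracy).

## Synthetic cohorts

The generator emulates the structure of the study data, with known ground
truth:

- **Expression.** Baseline 8.0 log2 units, i.i.d. Gaussian noise
  (`noise_sd` = 1.0 within-class SD — a typical log2 between-sample SD for
  synovial tissue profiles). Each class has a block of marker genes whose
  mean is shifted by `effect_size` (default 2.0 SD) × `compression` in its
  class. `compression` ∈ (0,1] multiplies all planted effects and emulates
  low-density fold-change compression; noise draws precede and are
  independent of the effect parameters, so cohorts at different
  compression levels from one seed share their noise realization and
  differ only in the planted shifts (making compression exactly
  multiplicative, and monotonicity comparisons noise-free).
- **Activity.** A DAS28-like score, Uniform(2, 7) per sample.
  `activity_coupling` w replaces a marker's fixed shift by
  `effect × ((1−w) + w·activity/4.5)`: at w = 1 the within-class shift is
  proportional to activity while the class-mean shift is unchanged.
- **Clinical attributes.** Independent class-conditional Bernoulli draws.
  Defaults follow the observed baseline tables: the definite-diagnosis
  prevalences (e.g. psoriasis 100% in SA and 0 elsewhere, hand arthritis
  100% RA / 4% OA, rheumatoid factor 90% RA / 12% OA) and a UA variant
  keyed by later diagnosis, built from the progressor / non-progressor
  columns (future-RA takes the progressor values; psoriasis among
  non-progressors is placed on the future-SA class at 3/9). Note the UA
  variant leaves SA and OA nearly indistinguishable clinically — as in
  the undifferentiated situation it models — so mixing clinical data in
  at ρ = 0.5 only helps when the definite-diagnosis prevalences are used;
  the ordering checks therefore use those.
- **Raw arrays.** Layout: 13 housekeeping + 6 internal-standard + 49
  hybridization-control probes beside the diagnostic genes, triplicate
  spots. On the glog scale, control spots follow μ + a_i + b_j + ε with
  a_i ~ N(0, 0.3), b_j ~ N(0, 0.5) (between-array scale shifts dominate
  probe-to-probe spotting differences) and replicate noise
  ε ~ N(0, 0.05) — within-array triplicate spots of a colorimetric array
  are tight relative to between-array variation. Signals are
  back-transformed through the inverse glog (λ = 1000, α = 0) and given
  an additive local background (~N(100, 10), clipped at 0). A fraction
  `outlier_rate` of control replicates is displaced by +6 noise-SD — far
  enough to be unambiguous for testing the iterative rejection — and
  recorded.
- **qPCR.** Ct = 30 − expression + N(0, 0.1); a designated assay can be
  made all-missing to emulate a failed assay, and a constant housekeeping
  row can be appended (`with_housekeeping`).

What the generator does **not** emulate: gene–gene correlation (markers
are conditionally independent given class), spatial/print-tip array
artifacts, probe-specific affinity differences on diagnostic genes,
correlated clinical attributes (real hand-arthritis and rheumatoid-factor
status co-occur within RA), and disease heterogeneity beyond the activity
coupling. Passing tests therefore demonstrate the correctness and the
qualitative behavior of the pipeline under its assumed noise model — not
clinical performance on real biopsies.

## Problem sizes and numerical choices

The test suite and acceptance script run cohorts of 39–60 samples with
100–2000 genes and 200 resampling splits (15–60 splits in unit tests),
matching the study-scale cohort sizes while keeping runs fast. The glog
λ-recovery check uses the median over five independent 50-probe ×
3-replicate datasets: the single-dataset MLE of λ has a log-scale spread
for which a factor of 2 is only ~1.5σ, so any single draw is
uninformative about estimator correctness. Distance ties are detected by
exact float equality — Euclidean distances on {0,1} vectors and Pearson
distances of identical vectors reproduce bit-identically, and the
deliberate tie-inclusion semantics depend on exact ties, not
almost-ties. Percentages are printed to one decimal.

## Known limitations

- The additive control model assumes control probes are
  expression-invariant; a systematically regulated "housekeeping" gene
  would bias a_i.
- OLS-based outlier rejection tolerates sparse gross outliers (a few
  percent of spots); a fully corrupted sample is beyond its breakdown
  point and will distort the fit before rejection can isolate it.
- The hybrid distance's unscaled mixing means the useful ρ range depends
  on the number of clinical attributes.
- With ≤ 4 samples in a class, per-class metrics on 10% test sets are
  quantized (0/1 per split); their across-split SDs are accordingly
  large.
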