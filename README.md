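# synovclass

Diagnosis of arthritis from synovial-biopsy gene expression, for
rheumatology researchers working with low-density transcriptomic
platforms. Early discrimination of rheumatoid arthritis (RA) from
psoriatic spondyloarthropathy (SA) and osteoarthritis (OA) — especially in
patients presenting with undifferentiated arthritis (UA) — is limited when
expression data are used alone, because fold changes are compressed on
low-density platforms and molecular signatures overlap between conditions.
`synovclass` implements a pipeline in which a small set of binary clinical
attributes is mixed directly into the distance function of a
nearest-neighbor classifier, so that clinical data resolve the ties that
expression data alone cannot, and vice versa.

## The method

**Preprocessing (spotted cDNA arrays).** Raw triplicate spot intensities
pass through four steps: (1) local background subtraction; (2) a
generalized-log variance-stabilizing transform
`g(x) = ln((x − α) + sqrt((x − α)² + λ))` with (λ, α) tuned by maximizing a
transform-both-sides replicate likelihood; (3) a per-sample scale
normalization from the additive control-probe model

```
z_ijk = μ + a_i + b_j + ε_ijk ,   a_1 = b_1 = 0
```

fitted by least squares to the housekeeping and internal-standard spots
with iterative outlier rejection, after which each sample's coefficient
`a_i` is subtracted from its data; (4) summarization of the triplicates
into a single median value per diagnostic gene. qPCR data are normalized
as ΔCt against a housekeeping assay (expression = −(Ct_gene − Ct_hk)).

**Signature selection.** A quantile filter drops the 75% of genes with the
smallest 5th-to-95th-percentile spread, a per-gene one-way ANOVA filter
keeps genes with p ≤ 0.05 (unadjusted), and genes are then ranked per
diagnosis by the absolute one-vs-rest t statistic; the top ⌊k/C⌋ genes per
class form a signature of size ≤ k.

**Classification.** The distance between samples x₁, x₂ is

```
dist(x₁, x₂) = ρ · dist_E(φ(x₁), φ(x₂)) + (1 − ρ) · dist_P(ω(x₁), ω(x₂))
```

where `dist_E` is the Euclidean distance on the binary clinical attribute
vector φ(·), `dist_P` the Pearson correlation distance (1 − r) on the
signature-gene expression vector ω(·), and ρ ∈ [0, 1] mixes them (ρ = 1:
clinical only; ρ = 0: expression only). A k-nearest-neighbor vote (k = 1,
3 or 5) predicts the diagnosis; every reference tied with the k-th
distance joins the neighbor set, which is how a small ρ < 1 lets
expression break the ties that binary clinical vectors produce.

**Evaluation.** Cohorts are split 200 times into 90% training references
and 10% test queries; the balanced classification rate (BCR — the mean of
the within-class accuracies) is reported as mean ± SD across splits, both
over the three diagnoses and collapsed to RA versus not-RA, along with
per-class sensitivity and positive predictive value. A classification-
criteria flag can be scored as a comparator, and UA samples can be probed
against a resampled pool of all samples.

A seeded synthetic-cohort generator (`synovclass.synthetic`) produces
expression matrices with class-specific over-expressed gene blocks, a
DAS28-like activity score, class-conditional clinical attributes, raw
triplicate array spots obeying the additive control model, and qPCR Ct
tables — with the planted ground truth returned alongside, so every stage
is testable without external data.

## Worked example

```python
from synovclass import synthetic as syn
from synovclass.containers import ClinicalTable, Dataset
from synovclass.evaluate import resample_evaluate
from synovclass.io import format_percent

# definite-diagnosis-like cohort: RA/SA/OA = 10/4/25, compressed fold changes
spec = syn.known_cohort_spec(compression=0.4)
expr, labels, activity, _ = syn.generate_expression_cohort(spec, seed=3)
clin = syn.generate_clinical(labels, spec, seed=4, activity=activity)
model = ClinicalTable(
    clin.attributes[["arthritis_hands", "rheumatoid_factor", "psoriasis"]],
    clin.diagnosis,
)
ds = Dataset(expr, model)
for tag in ("clinical", "transcriptomic", "combined"):
    r = resample_evaluate(ds, model=tag, rho=0.5, n_neighbors=5,
                          n_splits=200, seed=1)
    print(f"{tag:>14}: 3-class BCR {format_percent(r.bcr3_mean)} ± "
          f"{format_percent(r.bcr3_sd)} %   2-class BCR "
          f"{format_percent(r.bcr2_mean)} ± {format_percent(r.bcr2_sd)} %")
```

prints

```
      clinical: 3-class BCR 63.7 ± 9.6 %   2-class BCR 95.5 ± 14.3 %
transcriptomic: 3-class BCR 42.1 ± 20.2 %   2-class BCR 59.3 ± 23.1 %
      combined: 3-class BCR 96.1 ± 9.9 %   2-class BCR 94.5 ± 14.6 %
```

With compressed fold changes the expression-only model confuses RA and SA;
three binary clinical attributes alone do better but leave large tied
neighborhoods; mixing both at ρ = 0.5 resolves the ties and lifts the
3-class BCR above either single-source model.

The same stages are available from the shell:

```sh
synovclass simulate --spec spec.yaml --seed 7 --out sim/
synovclass preprocess-array --raw sim/raw_array.tsv --out sim/normalized.tsv
synovclass select --expr sim/expression.tsv --clinical sim/clinical.csv \
    --k 100 --out sim/signature.tsv
synovclass evaluate --expr sim/expression.tsv --clinical sim/clinical.csv \
    --model combined --rho 0.5 --splits 200 --seed 1 --out sim/report.csv
```

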