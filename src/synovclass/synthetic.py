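"""Seeded synthetic cohorts with known ground truth.

Generates everything the downstream stages consume: a log2 expression
matrix with class-specific over-expressed gene blocks, a continuous
DAS28-like disease-activity score optionally coupled to one block's
shift, class-conditional binary clinical attributes, raw spotted-array
replicate intensities obeying the additive control-probe model
z_ijk = mu + a_i + b_j + eps with injected outliers, and qPCR Ct values
with one housekeeping assay.

All generators are pure functions of (spec, seed): the same inputs give
bit-identical output. Random draws that do not depend on the effect /
compression parameters are made first, so cohorts generated from the same
seed at different compression levels share their noise realization and
differ only in the planted shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix
from .preprocess import GlogParams, glog_inverse

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "ArrayLayout",
    "KNOWN_DIAGNOSIS_PREVALENCES",
    "UA_PREVALENCES",
    "known_cohort_spec",
    "ua_cohort_spec",
    "generate_expression_cohort",
    "generate_clinical",
    "generate_raw_array",
    "generate_qpcr",
    "with_housekeeping",
    "two_component_intensities",
    "constant_glog_variance_intensities",
]

#: Disease-activity score range (DAS28-like), Uniform(2, 7) per sample.
ACTIVITY_RANGE = (2.0, 7.0)
_ACTIVITY_MEAN = sum(ACTIVITY_RANGE) / 2.0

#: Class-conditional prevalences of binary clinical attributes in the
#: definite-diagnosis cohort (rheumatoid arthritis / psoriatic
#: spondyloarthropathy / osteoarthritis).
KNOWN_DIAGNOSIS_PREVALENCES: dict[str, dict[str, float]] = {
    "acr_eular_2010": {"RA": 1.0, "SA": 0.0, "OA": 0.0},
    "morning_stiffness": {"RA": 0.90, "SA": 0.25, "OA": 0.08},
    "arthritis_hands": {"RA": 1.0, "SA": 0.0, "OA": 0.04},
    "symmetric_arthritis": {"RA": 1.0, "SA": 0.50, "OA": 0.36},
    "psoriasis": {"RA": 0.0, "SA": 1.0, "OA": 0.0},
    "acpa": {"RA": 0.80, "SA": 0.0, "OA": 0.0},
    "rheumatoid_factor": {"RA": 0.90, "SA": 0.0, "OA": 0.12},
    "xray_erosions": {"RA": 0.60, "SA": 0.0, "OA": 0.0},
    "crp_elevated": {"RA": 1.0, "SA": 0.25, "OA": 0.04},
}

#: Attribute prevalences in the undifferentiated-arthritis cohort, keyed by
#: eventual outcome (progression to RA or not). Psoriasis among
#: non-progressors concentrates in future SA patients.
UA_PREVALENCES: dict[str, dict[str, float]] = {
    "morning_stiffness": {"progressor": 0.461, "non_progressor": 0.214},
    "arthritis_hands": {"progressor": 0.731, "non_progressor": 0.143},
    "symmetric_arthritis": {"progressor": 0.308, "non_progressor": 0.429},
    "psoriasis": {"progressor": 0.0, "non_progressor": 0.107},
    "acpa": {"progressor": 0.769, "non_progressor": 0.0},
    "rheumatoid_factor": {"progressor": 0.731, "non_progressor": 0.071},
    "acr_eular_2010": {"progressor": 0.423, "non_progressor": 0.036},
    "xray_erosions": {"progressor": 0.115, "non_progressor": 0.0},
    "crp_elevated": {"progressor": 0.50, "non_progressor": 0.179},
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``block_assignment`` maps each gene id to the class whose samples
    over-express it, or ``"null"`` for background genes. ``effect_size`` is
    the log2 mean shift of a block in its class; ``compression`` multiplies
    all effect sizes (emulating the fold-change compression of low-density
    platforms); ``activity_coupling`` is the fraction of a block's shift
    that scales with the sample's activity score (the remainder is a fixed
    shift), normalized so the class-mean shift is unchanged.
    """

    classes: tuple[str, ...]
    n_per_class: dict[str, int]
    n_genes: int
    block_assignment: dict[str, str]
    clinical_prevalence: dict[str, dict[str, float]]
    effect_size: float = 2.0
    compression: float = 1.0
    activity_coupling: float = 0.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("n_per_class entries must be >= 1")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")
        if not 0 <= self.activity_coupling <= 1:
            raise ValueError("activity_coupling must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        bad = {
            c for c in self.block_assignment.values()
            if c != "null" and c not in self.classes
        }
        if bad:
            raise ValueError(f"block assigned to unknown class(es): {sorted(bad)}")
        for attr, by_class in self.clinical_prevalence.items():
            for cls, p in by_class.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"prevalence of {attr!r} in {cls!r} not in [0,1]")


@dataclass
class GroundTruth:
    """What was planted: marker genes per class, the true per-sample and
    per-probe biases used in raw-array generation (first sample / probe
    pinned at 0), and the (sample, probe, replicate) spots displaced as
    outliers."""

    planted_genes: dict[str, set] = field(default_factory=dict)
    true_sample_bias: dict[str, float] = field(default_factory=dict)
    true_probe_bias: dict[str, float] = field(default_factory=dict)
    outlier_spots: set = field(default_factory=set)


@dataclass
class ArrayLayout:
    """Probe roles and replicate count of the low-density array: 13
    housekeeping probes, 6 internal standards and 49 hybridization controls
    around the diagnostic genes, everything spotted in triplicate."""

    n_housekeeping: int = 13
    n_internal_standard: int = 6
    n_hybridization_control: int = 49
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")

    @property
    def control_probes(self) -> list[str]:
        """Probes entering the normalization model (housekeeping + internal
        standards)."""
        return [f"HK{i+1:02d}" for i in range(self.n_housekeeping)] + [
            f"IS{i+1:02d}" for i in range(self.n_internal_standard)
        ]

    @property
    def hybridization_probes(self) -> list[str]:
        return [f"HC{i+1:02d}" for i in range(self.n_hybridization_control)]


def _default_blocks(
    classes: tuple[str, ...], n_genes: int, markers_per_class: int
) -> dict[str, str]:
    if n_genes < markers_per_class * len(classes) or n_genes <= 0:
        raise ValueError(
            f"n_genes={n_genes} cannot hold {markers_per_class} markers "
            f"for each of {len(classes)} classes"
        )
    genes = [f"G{i+1:04d}" for i in range(n_genes)]
    assign: dict[str, str] = {}
    pos = 0
    for cls in classes:
        for _ in range(markers_per_class):
            assign[genes[pos]] = cls
            pos += 1
    for g in genes[pos:]:
        assign[g] = "null"
    return assign


def known_cohort_spec(
    n_genes: int = 100,
    markers_per_class: int = 10,
    compression: float = 1.0,
    **overrides,
) -> CohortSpec:
    """Spec emulating the definite-diagnosis cohort: RA/SA/OA = 10/4/25,
    a 100-gene diagnostic panel with class-specific marker blocks, and the
    observed clinical-attribute prevalences."""
    classes = ("RA", "SA", "OA")
    kw = dict(
        classes=classes,
        n_per_class={"RA": 10, "SA": 4, "OA": 25},
        n_genes=n_genes,
        block_assignment=_default_blocks(classes, n_genes, markers_per_class),
        clinical_prevalence=KNOWN_DIAGNOSIS_PREVALENCES,
        compression=compression,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def ua_cohort_spec(
    n_genes: int = 100,
    markers_per_class: int = 10,
    compression: float = 0.5,
    **overrides,
) -> CohortSpec:
    """Spec emulating the undifferentiated-arthritis cohort: later diagnoses
    RA/SA/OA = 26/9/19, compressed fold changes, activity-coupled RA block,
    and attribute prevalences taken from the UA baseline table (progressors
    for the future-RA class, non-progressors otherwise; psoriasis placed on
    the future-SA class)."""
    classes = ("RA", "SA", "OA")
    prev: dict[str, dict[str, float]] = {}
    for attr, by_out in UA_PREVALENCES.items():
        prev[attr] = {
            "RA": by_out["progressor"],
            "SA": by_out["non_progressor"],
            "OA": by_out["non_progressor"],
        }
    # the 3/28 psoriasis-positive non-progressors are the future-SA patients
    prev["psoriasis"] = {"RA": 0.0, "SA": 0.333, "OA": 0.0}
    kw = dict(
        classes=classes,
        n_per_class={"RA": 26, "SA": 9, "OA": 19},
        n_genes=n_genes,
        block_assignment=_default_blocks(classes, n_genes, markers_per_class),
        clinical_prevalence=prev,
        compression=compression,
        activity_coupling=0.5,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def generate_expression_cohort(
    spec: CohortSpec, seed: int
) -> tuple[ExpressionMatrix, pd.Series, pd.Series, GroundTruth]:
    """Generate a log2 expression matrix with planted class blocks.

    Returns (expression, labels, activity, ground truth). A gene in the
    block of class c has its mean shifted by effect_size * compression in
    samples of class c; with ``activity_coupling`` w, the per-sample shift
    is effect * ((1 - w) + w * activity / mean_activity), so coupling
    redistributes the shift with activity without changing the class mean.
    """
    rng = np.random.default_rng(seed)
    labels_list: list[str] = []
    for cls in spec.classes:
        labels_list += [cls] * spec.n_per_class[cls]
    n = len(labels_list)
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    labels = pd.Series(labels_list, index=sample_ids, name="diagnosis")

    genes = list(spec.block_assignment.keys())
    if len(genes) != spec.n_genes:
        raise ValueError(
            f"block_assignment covers {len(genes)} genes, spec declares {spec.n_genes}"
        )

    # parameter-independent draws first (shared across compression levels)
    activity = pd.Series(
        rng.uniform(*ACTIVITY_RANGE, size=n), index=sample_ids, name="activity"
    )
    values = spec.baseline_mean + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))

    effect = spec.effect_size * spec.compression
    w = spec.activity_coupling
    act_scale = (1.0 - w) + w * activity.to_numpy() / _ACTIVITY_MEAN
    lab_arr = np.asarray(labels_list)
    planted: dict[str, set] = {cls: set() for cls in spec.classes}
    for gi, g in enumerate(genes):
        cls = spec.block_assignment[g]
        if cls == "null":
            continue
        planted[cls].add(g)
        in_cls = lab_arr == cls
        values[gi, in_cls] += effect * act_scale[in_cls]

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids), "log2"
    )
    truth = GroundTruth(planted_genes=planted)
    return expr, labels, activity, truth


def generate_clinical(
    labels: pd.Series,
    spec: CohortSpec,
    seed: int,
    activity: pd.Series | None = None,
) -> ClinicalTable:
    """Sample class-conditional Bernoulli clinical attributes per sample.

    Every (attribute, class) pair present in the labels must have a declared
    prevalence. When an ``acr_eular_2010`` attribute is present it is also
    exposed as the table's classification-criteria flag.
    """
    rng = np.random.default_rng(seed)
    classes_present = pd.unique(labels)
    cols = {}
    for attr in spec.clinical_prevalence:
        by_class = spec.clinical_prevalence[attr]
        missing = [c for c in classes_present if c not in by_class]
        if missing:
            raise KeyError(f"no prevalence for attribute {attr!r} in class(es) {missing}")
        p = labels.map(by_class).to_numpy(dtype=float)
        cols[attr] = (rng.random(len(labels)) < p).astype(int)
    attrs = pd.DataFrame(cols, index=labels.index)
    flag = None
    if "acr_eular_2010" in attrs.columns:
        flag = attrs["acr_eular_2010"].astype(bool)
    return ClinicalTable(attrs, labels.copy(), activity=activity, criteria_flag=flag)


def generate_raw_array(
    expr: ExpressionMatrix,
    layout: ArrayLayout | None = None,
    bias_sd: float = 0.3,
    outlier_rate: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.05,
    probe_bias_sd: float = 0.5,
    glog_lambda: float = 1000.0,
    glog_alpha: float = 0.0,
    control_level: float = 8.0,
    hyb_control_level: float = 9.0,
    background_level: float = 100.0,
    outlier_shift_sd: float = 6.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate raw spotted-array replicate intensities from an expression
    matrix.

    On the glog scale, control spots follow mu + a_i + b_j + N(0, noise_sd)
    with a_1 = b_1 = 0; diagnostic spots follow the sample's expression
    value plus a_i and noise. A fraction ``outlier_rate`` of control
    replicates is displaced by +``outlier_shift_sd`` x noise_sd (an
    unambiguous displacement for testing iterative rejection) and recorded
    in the ground truth. Signals are back-transformed through the inverse
    glog and given an additive local background, so foreground =
    glog_inverse(z) + background.
    """
    layout = layout or ArrayLayout()
    rng = np.random.default_rng(seed)
    samples = list(expr.samples)
    a = rng.normal(0.0, bias_sd, size=len(samples))
    a[0] = 0.0
    controls = layout.control_probes
    b = rng.normal(0.0, probe_bias_sd, size=len(controls))
    b[0] = 0.0
    hyb = layout.hybridization_probes
    b_hyb = rng.normal(0.0, probe_bias_sd, size=len(hyb))

    gp = GlogParams(glog_lambda, glog_alpha)
    R = layout.n_replicates
    recs: list[tuple] = []
    truth = GroundTruth(
        true_sample_bias=dict(zip(samples, a)),
        true_probe_bias=dict(zip(controls, b)),
    )

    def emit(sample, probe, role, z_base):
        z = z_base + rng.normal(0.0, noise_sd, size=R)
        if role in ("housekeeping", "internal_standard") and outlier_rate > 0:
            out = rng.random(R) < outlier_rate
            z[out] += outlier_shift_sd * noise_sd
            for k in np.nonzero(out)[0]:
                truth.outlier_spots.add((sample, probe, int(k) + 1))
        bg = np.clip(
            rng.normal(background_level, 0.1 * background_level, size=R), 0.0, None
        )
        fg = glog_inverse(z, gp) + bg
        for k in range(R):
            recs.append((sample, probe, role, k + 1, fg[k], bg[k]))

    role_of_control = ["housekeeping"] * layout.n_housekeeping + [
        "internal_standard"
    ] * layout.n_internal_standard
    for si, s in enumerate(samples):
        for g in expr.genes:
            emit(s, g, "diagnostic", float(expr.data.at[g, s]) + a[si])
        for j, probe in enumerate(controls):
            emit(s, probe, role_of_control[j], control_level + a[si] + b[j])
        for j, probe in enumerate(hyb):
            emit(s, probe, "hybridization_control", hyb_control_level + a[si] + b_hyb[j])

    batch = pd.DataFrame(
        recs,
        columns=["sample", "probe", "role", "replicate", "foreground", "background"],
    )
    return batch, truth


def with_housekeeping(
    expr: ExpressionMatrix, hk_gene: str = "RN18S", level: float = 12.0
) -> ExpressionMatrix:
    """Append a constant, highly expressed housekeeping gene row."""
    if hk_gene in expr.genes:
        raise ValueError(f"{hk_gene!r} already present")
    row = pd.DataFrame(
        [[level] * len(expr.samples)], index=[hk_gene], columns=expr.samples
    )
    return ExpressionMatrix(pd.concat([expr.data, row]), expr.scale)


def generate_qpcr(
    expr: ExpressionMatrix,
    hk_gene: str,
    ct_scale: float = 0.1,
    seed: int = 0,
    ct_offset: float = 30.0,
    failed_assays: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Generate qPCR Ct values: Ct = offset - expression + N(0, ct_scale).

    The housekeeping gene must be a (near-constant) row of ``expr``. Assays
    in ``failed_assays`` produce no signal (all-missing rows), emulating a
    failed Taqman assay.
    """
    if hk_gene not in expr.genes:
        raise KeyError(f"housekeeping gene {hk_gene!r} not in expression matrix")
    rng = np.random.default_rng(seed)
    ct = ct_offset - expr.data + rng.normal(0.0, ct_scale, size=expr.shape)
    for g in failed_assays:
        if g not in ct.index:
            raise KeyError(f"failed assay {g!r} not in expression matrix")
        ct.loc[g] = np.nan
    return ct


def two_component_intensities(
    means: np.ndarray, n_replicates: int, mult_sd: float, add_sd: float, seed: int
) -> np.ndarray:
    """Replicate intensities with multiplicative + additive noise:
    x = mean * exp(N(0, mult_sd)) + N(0, add_sd). Raw-scale replicate SD
    grows with the mean; a glog transform with lambda ~ (add_sd/mult_sd)^2
    approximately stabilizes it."""
    rng = np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)[:, None]
    shape = (len(means), n_replicates)
    return means * np.exp(rng.normal(0.0, mult_sd, shape)) + rng.normal(
        0.0, add_sd, shape
    )


def constant_glog_variance_intensities(
    centers: np.ndarray,
    n_replicates: int,
    sd: float,
    lam: float,
    alpha: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Replicate intensities whose variance is exactly constant on the glog
    scale at the stated (lambda, alpha): z ~ N(center, sd) back-transformed
    through the inverse glog."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)[:, None]
    z = centers + rng.normal(0.0, sd, size=(len(centers), n_replicates))
    return glog_inverse(z, GlogParams(lam, alpha))
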