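"""Resampling evaluation of the nearest-neighbor diagnostic models.

The protocol: split the cohort 200 times into 90% training references and
10% test queries, predict every test sample with the tie-inclusive
nearest-neighbor classifier at the model's rho (clinical-only rho = 1,
transcriptomic-only rho = 0, combined in between), and report the mean and
SD across splits of the balanced classification rate (BCR) — the
arithmetic average of the within-class accuracies — both over the three
diagnoses and collapsed to RA versus not-RA. Per-class sensitivity and
positive predictive value are aggregated the same way. A separate
probe-against-pool mode scores undifferentiated-arthritis queries against
a resampled pool of all samples, and a comparator mode scores a binary
classification-criteria flag as the prediction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import hybrid_distance_matrix, vote_from_distances
from .containers import Dataset
from .signatures import anova_filter, build_signature, variability_filter

__all__ = [
    "EvaluationResult",
    "SweepResult",
    "MODEL_RHO",
    "bcr",
    "class_metrics",
    "comparator_flag_bcr",
    "resample_evaluate",
    "sweep",
    "probe_pool_evaluate",
]

logger = logging.getLogger(__name__)

#: rho implied by each model tag (combined uses the caller's rho)
MODEL_RHO = {"clinical": 1.0, "transcriptomic": 0.0}

DEFAULT_RHO_GRID = np.linspace(0.0, 1.0, 21)


def bcr(y_true, y_pred, class_set=None) -> float:
    """Balanced classification rate: the arithmetic average of the
    within-class accuracies. Classes absent from the truth are excluded."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    present = np.unique(y_true)
    if class_set is not None:
        unknown = set(present) - set(class_set)
        if unknown:
            raise ValueError(f"true labels outside the class set: {sorted(unknown)}")
    accs = [np.mean(y_pred[y_true == c] == c) for c in present]
    return float(np.mean(accs))


def class_metrics(y_true, y_pred, class_set=None) -> pd.DataFrame:
    """Per-class sensitivity (within-class accuracy) and positive predictive
    value (fraction of predicted-as-class that truly are). PPV is missing
    (NaN), not zero, for a class never predicted; sensitivity is missing for
    a class absent from the truth."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    classes = sorted(class_set) if class_set is not None else sorted(
        set(y_true) | set(y_pred)
    )
    rows = {}
    for c in classes:
        t = y_true == c
        p = y_pred == c
        sens = float(np.mean(y_pred[t] == c)) if t.any() else np.nan
        ppv = float(np.mean(y_true[p] == c)) if p.any() else np.nan
        rows[c] = {"sensitivity": sens, "ppv": ppv}
    return pd.DataFrame(rows).T


def comparator_flag_bcr(flags, outcomes) -> float:
    """2-class BCR of a binary criteria flag used directly as the
    prediction of the positive outcome (balanced accuracy)."""
    flags = np.asarray(flags)
    outcomes = np.asarray(outcomes)
    if flags.size == 0 or flags.size != outcomes.size:
        raise ValueError("flags and outcomes must be non-empty and aligned")
    if pd.isna(flags).any():
        raise ValueError("missing criteria flags")
    return bcr(
        np.where(outcomes.astype(bool), "pos", "neg"),
        np.where(flags.astype(bool), "pos", "neg"),
    )


@dataclass
class EvaluationResult:
    """Aggregated resampling metrics for one model configuration.

    Means are fractions in [0, 1] (formatted as percentages on output);
    SDs are across-split sample SDs. ``sensitivity`` / ``ppv`` are
    class x (mean, sd) DataFrames; ``per_split`` retains the split-level
    metrics for audit.
    """

    model: str
    rho: float
    n_neighbors: int
    n_splits: int
    seed: int
    classes: list[str]
    bcr3_mean: float
    bcr3_sd: float
    bcr2_mean: float
    bcr2_sd: float
    sensitivity: pd.DataFrame
    ppv: pd.DataFrame
    per_split: dict = field(repr=False, default_factory=dict)
    n_redrawn_splits: int = 0


@dataclass
class SweepResult:
    """Grid of evaluation results along one axis (rho or signature size)."""

    axis: str
    grid: list
    results: list[EvaluationResult]


def _effective_rho(model: str, rho: float) -> float:
    if model in MODEL_RHO:
        return MODEL_RHO[model]
    if model == "combined":
        return float(rho)
    raise ValueError(f"unknown model tag {model!r}")


def _draw_split(
    labels: np.ndarray,
    groups: np.ndarray,
    test_frac: float,
    stratify: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (train sample indices, test sample indices, redraw count).

    Splitting operates on unique groups (patients) so repeat biopsies stay
    on one side. Stratified mode draws ceil(test_frac * n_c) test groups per
    class, keeping every class represented in training; non-stratified mode
    draws ceil(test_frac * n) groups at random and redraws (logged) if a
    class vanishes from training.
    """
    uniq, first = np.unique(groups, return_index=True)
    grp_label = labels[first]
    n_grp = len(uniq)
    redraws = 0
    if stratify:
        test_groups = []
        for c in np.unique(grp_label):
            members = uniq[grp_label == c]
            n_test = math.ceil(test_frac * len(members))
            if len(members) - n_test < 1:
                n_test = max(len(members) - 1, 0)
            perm = rng.permutation(len(members))
            test_groups.extend(members[perm[:n_test]])
        test_groups = set(test_groups)
    else:
        n_test = math.ceil(test_frac * n_grp)
        for _ in range(1000):
            perm = rng.permutation(n_grp)
            test_groups = set(uniq[perm[:n_test]])
            train_lab = grp_label[~np.isin(uniq, list(test_groups))]
            if set(np.unique(grp_label)) <= set(np.unique(train_lab)):
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a split keeping every class in training")
        if redraws:
            logger.info("redrew split %d time(s) to keep all classes in training", redraws)
    is_test = np.isin(groups, list(test_groups))
    return np.nonzero(~is_test)[0], np.nonzero(is_test)[0], redraws


def _split_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    classes: list[str],
    positive_class: str,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    b3 = bcr(y_true, y_pred)
    t2 = np.where(y_true == positive_class, positive_class, "not_" + positive_class)
    p2 = np.where(y_pred == positive_class, positive_class, "not_" + positive_class)
    b2 = bcr(t2, p2)
    cm = class_metrics(y_true, y_pred, class_set=classes)
    return b3, b2, cm["sensitivity"].to_numpy(), cm["ppv"].to_numpy()


def _aggregate(
    model: str,
    rho: float,
    n_neighbors: int,
    seed: int,
    classes: list[str],
    b3: np.ndarray,
    b2: np.ndarray,
    sens: np.ndarray,
    ppv: np.ndarray,
    redraws: int,
) -> EvaluationResult:
    def msd(x):  # nan-aware mean +/- across-split sample SD
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(x)), float(np.nanstd(x, ddof=1))

    sens_df = pd.DataFrame(
        {"mean": _nanmean_cols(sens), "sd": _nanstd_cols(sens)}, index=classes
    )
    ppv_df = pd.DataFrame(
        {"mean": _nanmean_cols(ppv), "sd": _nanstd_cols(ppv)}, index=classes
    )
    b3m, b3s = msd(b3)
    b2m, b2s = msd(b2)
    return EvaluationResult(
        model=model,
        rho=rho,
        n_neighbors=n_neighbors,
        n_splits=len(b3),
        seed=seed,
        classes=classes,
        bcr3_mean=b3m,
        bcr3_sd=b3s,
        bcr2_mean=b2m,
        bcr2_sd=b2s,
        sensitivity=sens_df,
        ppv=ppv_df,
        per_split={"bcr3": b3, "bcr2": b2, "sensitivity": sens, "ppv": ppv},
        n_redrawn_splits=redraws,
    )


def _nanmean_cols(x: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(x, axis=0)


def _nanstd_cols(x: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(x, axis=0, ddof=1)


def _signature_genes_for_split(
    dataset: Dataset,
    train_idx: np.ndarray,
    signature_size: int,
    signature_params: dict,
) -> list[int]:
    X = dataset.expression.subset_samples(dataset.samples[train_idx])
    labels = dataset.labels.iloc[train_idx]
    kept = variability_filter(X, signature_params.get("drop_frac", 0.75))
    X = X.subset_genes(kept)
    kept = anova_filter(X, labels, signature_params.get("alpha", 0.05))
    if len(kept) >= len(pd.unique(labels)):
        X = X.subset_genes(kept)
    sig = build_signature(X, labels, signature_size)
    gene_pos = pd.Index(dataset.expression.genes)
    return [int(gene_pos.get_loc(g)) for g in sig.signature]


def resample_evaluate(
    dataset: Dataset,
    model: str = "combined",
    n_splits: int = 200,
    test_frac: float = 0.10,
    n_neighbors: int = 5,
    rho: float = 0.5,
    seed: int = 0,
    stratify: bool = True,
    positive_class: str = "RA",
    signature_size: int | None = None,
    signature_params: dict | None = None,
) -> EvaluationResult:
    """Repeated random-subsampling evaluation of one model.

    ``model`` fixes the distance mix: ``clinical`` (rho = 1),
    ``transcriptomic`` (rho = 0) or ``combined`` (the given rho) — the
    endpoints of a rho sweep are bit-identical to the standalone clinical /
    transcriptomic runs under the same seed, because the split sequence
    does not depend on rho. With ``signature_size`` set, the gene panel is
    re-selected on each training set (variability filter, ANOVA filter,
    one-vs-rest t ranking) before prediction.
    """
    rho_eff = _effective_rho(model, rho)
    rng = np.random.default_rng(seed)
    labels = dataset.labels.to_numpy(dtype=object)
    classes = sorted(pd.unique(dataset.labels))
    groups = (
        dataset.patient_id.to_numpy(dtype=object)
        if dataset.patient_id is not None
        else dataset.samples.to_numpy(dtype=object)
    )
    X = dataset.expression.data.to_numpy(dtype=float).T  # samples x genes
    C = dataset.clinical.attributes.to_numpy(dtype=float)
    ids = dataset.samples.to_numpy(dtype=object)
    sig_params = signature_params or {}

    b3 = np.empty(n_splits)
    b2 = np.empty(n_splits)
    sens = np.empty((n_splits, len(classes)))
    ppv = np.empty((n_splits, len(classes)))
    total_redraws = 0
    for s in range(n_splits):
        train, test, redraws = _draw_split(labels, groups, test_frac, stratify, rng)
        total_redraws += redraws
        if signature_size is not None and rho_eff < 1.0:
            cols = _signature_genes_for_split(dataset, train, signature_size, sig_params)
            Xte, Xtr = X[test][:, cols], X[train][:, cols]
        else:
            Xte, Xtr = X[test], X[train]
        D = hybrid_distance_matrix(Xte, C[test], Xtr, C[train], rho_eff)
        preds = np.array(
            [
                vote_from_distances(D[i], labels[train], ids[train], n_neighbors)[0]
                for i in range(len(test))
            ],
            dtype=object,
        )
        b3[s], b2[s], sens[s], ppv[s] = _split_metrics(
            labels[test], preds, classes, positive_class
        )
    return _aggregate(
        model, rho_eff, n_neighbors, seed, classes, b3, b2, sens, ppv, total_redraws
    )


def sweep(
    dataset: Dataset,
    axis: str,
    grid=None,
    **fixed,
) -> SweepResult:
    """Sweep rho (default grid: 21 evenly spaced points in [0, 1]) or the
    signature size, re-running the full resampling at each grid value with
    the same seed."""
    if axis == "rho":
        grid = DEFAULT_RHO_GRID if grid is None else np.asarray(grid, dtype=float)
        if ((grid < 0) | (grid > 1)).any():
            raise ValueError("rho grid values must lie in [0, 1]")
        results = [
            resample_evaluate(dataset, model="combined", rho=float(v), **fixed)
            for v in grid
        ]
        return SweepResult(axis="rho", grid=[float(v) for v in grid], results=results)
    if axis == "signature_size":
        if grid is None or len(grid) == 0:
            raise ValueError("signature-size sweep needs an explicit grid")
        if any(int(k) < 1 for k in grid):
            raise ValueError("signature sizes must be >= 1")
        results = [
            resample_evaluate(dataset, signature_size=int(k), **fixed) for k in grid
        ]
        return SweepResult(
            axis="signature_size", grid=[int(k) for k in grid], results=results
        )
    raise ValueError(f"unknown sweep axis {axis!r}")


def probe_pool_evaluate(
    queries: Dataset,
    pool: Dataset,
    n_neighbors: int = 5,
    rho: float = 0.5,
    n_splits: int = 200,
    seed: int = 0,
    pool_frac: float = 0.90,
    model: str = "combined",
    positive_class: str = "RA",
) -> EvaluationResult:
    """Probe each query against a resampled reference pool.

    Every query is predicted on each split against a random ``pool_frac``
    stratified subset of the pool; a query (or another biopsy from the same
    patient) never serves as its own neighbor. Accuracy compares the
    prediction to the query's (later) clinical diagnosis.
    """
    rho_eff = _effective_rho(model, rho)
    rng = np.random.default_rng(seed)
    q_labels = queries.labels.to_numpy(dtype=object)
    classes = sorted(pd.unique(queries.labels))
    p_labels = pool.labels.to_numpy(dtype=object)
    p_groups = (
        pool.patient_id.to_numpy(dtype=object)
        if pool.patient_id is not None
        else pool.samples.to_numpy(dtype=object)
    )
    q_groups = (
        queries.patient_id.to_numpy(dtype=object)
        if queries.patient_id is not None
        else queries.samples.to_numpy(dtype=object)
    )
    genes = list(queries.expression.genes)
    Xq = queries.expression.data.to_numpy(dtype=float).T
    Xp = pool.expression.subset_genes(genes).data.to_numpy(dtype=float).T
    attrs = list(queries.clinical.attributes.columns)
    Cq = queries.clinical.attributes.to_numpy(dtype=float)
    Cp = pool.clinical.attributes[attrs].to_numpy(dtype=float)
    q_ids = queries.samples.to_numpy(dtype=object)
    p_ids = pool.samples.to_numpy(dtype=object)

    D_full = hybrid_distance_matrix(Xq, Cq, Xp, Cp, rho_eff)
    # self (and same-patient) exclusion mask
    self_mask = (q_ids[:, None] == p_ids[None, :]) | (
        q_groups[:, None] == p_groups[None, :]
    )

    b3 = np.empty(n_splits)
    b2 = np.empty(n_splits)
    sens = np.empty((n_splits, len(classes)))
    ppv = np.empty((n_splits, len(classes)))
    for s in range(n_splits):
        keep_idx, _, _ = _draw_split(
            p_labels, p_groups, 1.0 - pool_frac, True, rng
        )
        preds = []
        for i in range(len(q_ids)):
            usable = keep_idx[~self_mask[i, keep_idx]]
            if len(usable) == 0:
                raise ValueError(f"no usable pool references for query {q_ids[i]!r}")
            preds.append(
                vote_from_distances(
                    D_full[i, usable], p_labels[usable], p_ids[usable], n_neighbors
                )[0]
            )
        b3[s], b2[s], sens[s], ppv[s] = _split_metrics(
            q_labels, np.array(preds, dtype=object), classes, positive_class
        )
    return _aggregate(
        model, rho_eff, n_neighbors, seed, classes, b3, b2, sens, ppv, 0
    )
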