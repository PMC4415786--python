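"""Gene filtering, diagnostic-signature construction and descriptive
expression analytics (activity correlation, cross-platform concordance).

The selection chain mirrors the resampling protocol used on the
high-density data: a quantile variability filter dropping the 75% least
variable genes (variability = distance between the 5th and 95th
percentile), a per-gene one-way ANOVA filter at an unadjusted 5% level,
then per-class one-vs-rest t-statistics from which the top k/C genes per
class are pooled into a signature of size <= k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "SignatureSpec",
    "ConcordanceResult",
    "variability_filter",
    "anova_filter",
    "build_signature",
    "covariate_correlation",
    "cross_platform_concordance",
]


@dataclass
class SignatureSpec:
    """A diagnostic gene signature: requested size ``k``, per-class quota
    floor(k / C), the per-class rankings (gene, t-statistic) and the pooled
    signature gene list (duplicates counted once, order deterministic)."""

    k: int
    per_class_quota: int
    ranked_lists: dict[str, pd.DataFrame]
    signature: list[str]


@dataclass
class ConcordanceResult:
    """Cross-platform agreement of group-mean expression differences.

    ``diff_a`` / ``diff_b`` are per-gene differences of group means on each
    platform; ``slope`` is the least-squares through-origin slope of B on A
    (slope < 1 means platform B compresses fold changes relative to A).
    ``norm_*`` variants are computed after dividing each group mean by its
    within-group SD."""

    diff_a: pd.Series
    diff_b: pd.Series
    pearson_r: float
    slope: float
    norm_diff_a: pd.Series
    norm_diff_b: pd.Series
    norm_pearson_r: float
    norm_slope: float


def _check_labels(X: ExpressionMatrix, labels: pd.Series) -> pd.Series:
    labels = labels.reindex(X.samples)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    return labels


def variability_filter(X: ExpressionMatrix, drop_frac: float = 0.75) -> list[str]:
    """Keep the ceil((1 - drop_frac) * G) genes with the largest spread
    between the 5th and 95th percentile across samples (linear-interpolation
    percentiles). Ties broken lexicographically by gene id."""
    if X.data.empty:
        raise ValueError("empty expression matrix")
    if X.shape[1] < 2:
        raise ValueError("variability filter needs >= 2 samples")
    vals = X.data.to_numpy(dtype=float)
    p5, p95 = np.percentile(vals, [5, 95], axis=1)
    spread = pd.Series(p95 - p5, index=X.genes)
    n_keep = int(np.ceil((1.0 - drop_frac) * len(spread)))
    order = sorted(spread.index, key=lambda g: (-spread[g], g))
    return order[:n_keep]


def anova_filter(
    X: ExpressionMatrix, labels: pd.Series, alpha: float = 0.05
) -> list[str]:
    """Keep genes whose one-way ANOVA p-value across classes is <= alpha
    (unadjusted). Genes with an undefined F (no within- or between-class
    variation) are removed."""
    labels = _check_labels(X, labels)
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("ANOVA filter needs >= 2 classes")
    groups = []
    for cls in classes:
        cols = labels.index[labels == cls]
        if len(cols) < 2:
            raise ValueError(f"class {cls!r} has < 2 samples")
        groups.append(X.data[cols].to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*groups, axis=1)
    keep = pd.Series(p, index=X.genes) <= alpha  # NaN compares False
    return list(X.genes[keep.to_numpy()])


def _one_vs_rest_t(
    X: ExpressionMatrix, labels: pd.Series, cls: str, equal_var: bool
) -> pd.Series:
    in_cls = X.data.loc[:, (labels == cls).to_numpy()].to_numpy(dtype=float)
    rest = X.data.loc[:, (labels != cls).to_numpy()].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = stats.ttest_ind(in_cls, rest, axis=1, equal_var=equal_var)
    return pd.Series(t, index=X.genes)


def build_signature(
    X: ExpressionMatrix,
    labels: pd.Series,
    k: int,
    equal_var: bool = False,
) -> SignatureSpec:
    """Build a size-<=k signature from per-class one-vs-rest t-statistics.

    For each class, every gene gets a two-sample t-statistic (class vs all
    other samples; Welch by default, Student's pooled-variance with
    ``equal_var=True``), genes are ranked by |t| (ties broken by gene id),
    and the top floor(k / C) genes per class are pooled; a gene selected for
    several classes counts once.
    """
    labels = _check_labels(X, labels)
    classes = sorted(pd.unique(labels))
    if k < len(classes):
        raise ValueError(f"k={k} smaller than the number of classes ({len(classes)})")
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has < 2 samples")
    quota = k // len(classes)
    ranked: dict[str, pd.DataFrame] = {}
    signature: list[str] = []
    seen = set()
    for cls in classes:
        t = _one_vs_rest_t(X, labels, cls, equal_var=equal_var)
        order = sorted(t.index, key=lambda g: (-abs(t[g]) if np.isfinite(t[g]) else 0.0, g))
        ranked[cls] = pd.DataFrame({"gene": order, "t": t[order].to_numpy()})
        for g in order[:quota]:
            if g not in seen:
                seen.add(g)
                signature.append(g)
    return SignatureSpec(k=k, per_class_quota=quota, ranked_lists=ranked, signature=signature)


def covariate_correlation(X: ExpressionMatrix, covariate: pd.Series) -> pd.Series:
    """Pearson correlation of each (mean-centered) gene with a continuous
    per-sample covariate such as a disease-activity score.

    Constant genes (or a constant covariate) have undefined correlation and
    are returned as missing, with a warning.
    """
    cov = covariate.reindex(X.samples).to_numpy(dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate must be finite for every sample")
    if len(cov) < 3:
        raise ValueError("need >= 3 samples for a correlation")
    vals = X.data.to_numpy(dtype=float)
    vals = vals - vals.mean(axis=1, keepdims=True)
    covc = cov - cov.mean()
    denom_g = np.sqrt((vals**2).sum(axis=1))
    denom_c = float(np.sqrt((covc**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vals @ covc) / (denom_g * denom_c)
    undef = (denom_g == 0) | (denom_c == 0)
    if undef.any() or denom_c == 0:
        r = np.where(undef | (denom_c == 0), np.nan, r)
        warnings.warn(
            "correlation undefined for constant gene(s) or covariate; set to missing",
            stacklevel=2,
        )
    return pd.Series(r, index=X.genes, name="pearson_r")


def _group_stats(
    X: ExpressionMatrix, labels: pd.Series, group: list[str]
) -> tuple[pd.Series, pd.Series]:
    mask = labels.isin(group).to_numpy()
    if not mask.any():
        raise ValueError(f"contrast group {group} empty")
    sub = X.data.loc[:, mask]
    return sub.mean(axis=1), sub.std(axis=1, ddof=1)


def cross_platform_concordance(
    XA: ExpressionMatrix,
    labelsA: pd.Series,
    XB: ExpressionMatrix,
    labelsB: pd.Series,
    contrast: tuple[list[str], list[str]],
) -> ConcordanceResult:
    """Compare per-gene group-mean differences between two platforms.

    ``contrast`` names the two label groups, e.g. (["OA"], ["RA", "SA"]).
    For each platform, the per-gene difference of group means is computed
    on the shared gene set; the Pearson correlation across genes measures
    agreement and the through-origin slope of platform B on platform A
    measures fold-change compression. Normalized variants divide each group
    mean by its within-group SD first.
    """
    labelsA = _check_labels(XA, labelsA)
    labelsB = _check_labels(XB, labelsB)
    shared = [g for g in XA.genes if g in set(XB.genes)]
    if not shared:
        raise ValueError("no shared genes between platforms")
    XA = XA.subset_genes(shared)
    XB = XB.subset_genes(shared)
    g1, g2 = [list(g) for g in contrast]

    def diffs(X, labels):
        m1, s1 = _group_stats(X, labels, g1)
        m2, s2 = _group_stats(X, labels, g2)
        return m1 - m2, m1 / s1 - m2 / s2

    dA, ndA = diffs(XA, labelsA)
    dB, ndB = diffs(XB, labelsB)

    def r_slope(a: pd.Series, b: pd.Series) -> tuple[float, float]:
        av, bv = a.to_numpy(), b.to_numpy()
        r = float(np.corrcoef(av, bv)[0, 1])
        slope = float((av @ bv) / (av @ av))
        return r, slope

    r, slope = r_slope(dA, dB)
    nr, nslope = r_slope(ndA, ndB)
    return ConcordanceResult(
        diff_a=dA,
        diff_b=dB,
        pearson_r=r,
        slope=slope,
        norm_diff_a=ndA,
        norm_diff_b=ndB,
        norm_pearson_r=nr,
        norm_slope=nslope,
    )
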