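"""Low-density spotted-array preprocessing and qPCR delta-Ct normalization.

The array chain has four steps: (1) local background subtraction,
(2) a generalized-log (glog) variance-stabilizing transform whose
parameters are tuned by maximum likelihood on replicate spot groups,
(3) a per-sample scale normalization obtained from a two-way additive
model fitted to the control probes (housekeeping genes and internal
standards) with iterative outlier rejection, and (4) summarization of
replicate spots into a single median value per gene and sample.

The glog transform is g(x) = ln((x - alpha) + sqrt((x - alpha)^2 + lambda)).
It behaves linearly near the additive-noise floor and logarithmically at
high intensity, so that two-component (additive + multiplicative) spot
noise has approximately constant variance after transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import (
    CONTROL_ROLES,
    ExpressionMatrix,
    validate_raw_batch,
)

__all__ = [
    "GlogParams",
    "ControlModelFit",
    "subtract_background",
    "glog_transform",
    "glog_inverse",
    "fit_glog",
    "fit_control_model",
    "apply_normalization",
    "summarize_replicates",
    "preprocess_array",
    "qpcr_delta_ct",
]


@dataclass
class GlogParams:
    """Fitted glog parameters: curvature ``lam`` (lambda), offset ``alpha``,
    and the attained profile log-likelihood."""

    lam: float
    alpha: float = 0.0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class ControlModelFit:
    """Result of the additive control-probe model z_ijk = mu + a_i + b_j + eps.

    ``sample_bias`` maps sample -> a_i and ``probe_bias`` probe -> b_j, with
    the first sample and first probe pinned to zero for identifiability.
    ``outlier_mask`` is True for replicates rejected during iterative
    refitting; ``residuals`` are with respect to the final fit.
    """

    mu: float
    sample_bias: pd.Series
    probe_bias: pd.Series
    residuals: pd.Series
    outlier_mask: pd.Series
    n_iterations: int


def subtract_background(batch: pd.DataFrame) -> pd.DataFrame:
    """Subtract each spot's local background from its foreground intensity.

    Adds an ``intensity`` column; negative values are retained (the glog
    transform is defined for them).
    """
    validate_raw_batch(batch)
    if batch["background"].isna().any():
        bad = batch.loc[batch["background"].isna(), ["sample", "probe"]]
        raise ValueError(
            f"missing background for spots: {bad.head().to_dict('records')}"
        )
    out = batch.copy()
    out["intensity"] = out["foreground"] - out["background"]
    return out


def glog_transform(x, params: GlogParams):
    """g(x) = ln((x - alpha) + sqrt((x - alpha)^2 + lambda)).

    Strictly increasing for lambda > 0; for lambda = 0 it reduces to
    ln(2 (x - alpha)) on x > alpha.
    """
    x = np.asarray(x, dtype=float)
    u = x - params.alpha
    root = np.sqrt(u * u + params.lam)
    with np.errstate(invalid="ignore", divide="ignore"):
        # for u < 0, u + root cancels catastrophically; the algebraically
        # equivalent lam / (root - u) is stable there
        arg = np.where(u >= 0, u + root, params.lam / (root - u))
        return np.log(arg)


def glog_inverse(z, params: GlogParams):
    """Inverse of :func:`glog_transform`: x = alpha + (e^z - lambda e^-z)/2."""
    z = np.asarray(z, dtype=float)
    return params.alpha + 0.5 * (np.exp(z) - params.lam * np.exp(-z))


def _glog_profile_loglik(groups: list[np.ndarray], lam: float, alpha: float) -> float:
    """Transform-both-sides normal profile log-likelihood.

    Model: g(x_pk) ~ N(m_p, sigma^2) with group means m_p and the common
    variance profiled out; the Jacobian term sum ln g'(x) makes likelihoods
    comparable across (lambda, alpha).
    """
    if lam < 0:
        return -np.inf
    p = GlogParams(lam, alpha)
    rss = 0.0
    n = 0
    jac = 0.0
    for x in groups:
        z = glog_transform(x, p)
        if not np.all(np.isfinite(z)):
            return -np.inf
        rss += float(np.sum((z - z.mean()) ** 2))
        n += len(z)
        u = x - alpha
        jac += float(-0.5 * np.sum(np.log(u * u + lam)))
    if rss <= 0:
        # degenerate (noiseless) data: likelihood unbounded; rank by Jacobian
        return jac
    sigma2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + jac


def _as_groups(data) -> list[np.ndarray]:
    if isinstance(data, pd.DataFrame):
        groups = [np.asarray(r, dtype=float) for _, r in data.iterrows()]
    elif isinstance(data, np.ndarray) and data.ndim == 2:
        groups = [np.asarray(r, dtype=float) for r in data]
    else:
        groups = [np.asarray(g, dtype=float) for g in data]
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 replicate groups with >= 2 replicates each")
    return groups


def fit_glog(
    replicate_groups,
    init: GlogParams | None = None,
    lambda_grid=None,
    alpha_grid=(0.0,),
    refine: bool = True,
    optimize_alpha: bool = False,
) -> GlogParams:
    """Fit glog parameters by maximizing the replicate-group likelihood.

    Parameters
    ----------
    replicate_groups:
        2-D array, DataFrame (rows = groups) or iterable of 1-D arrays of
        replicate intensities measuring the same quantity.
    init:
        Optional starting point; when given, the grid stage is skipped.
    lambda_grid, alpha_grid:
        Coarse candidate grids searched before local refinement. Defaults:
        log-spaced lambda over 1e-2..1e10 and alpha = 0.
    refine:
        When True, polish the best grid point with a local simplex search;
        when False, return the best grid point with its exact likelihood.
    optimize_alpha:
        When True, alpha is refined jointly with lambda. Off by default:
        local background subtraction precedes the transform in the
        preprocessing chain, which removes the additive offset the alpha
        parameter models, and (lambda, alpha) are poorly identified
        jointly on replicate data.
    """
    groups = _as_groups(replicate_groups)

    if init is not None:
        best = (init.lam, init.alpha)
    else:
        if lambda_grid is None:
            lambda_grid = np.logspace(-2, 10, 25)
        cands = [(lam, a) for lam in lambda_grid for a in alpha_grid]
        lls = [_glog_profile_loglik(groups, lam, a) for lam, a in cands]
        best = cands[int(np.argmax(lls))]
        if not refine:
            return GlogParams(best[0], best[1], max(lls))

    if optimize_alpha:
        def nll(theta):
            return -_glog_profile_loglik(groups, np.exp(theta[0]), theta[1])

        x0 = np.array([np.log(max(best[0], 1e-8)), best[1]])
    else:
        alpha0 = best[1]

        def nll(theta):
            return -_glog_profile_loglik(groups, np.exp(theta[0]), alpha0)

        x0 = np.array([np.log(max(best[0], 1e-8))])
    res = optimize.minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(
            f"glog likelihood optimization failed: {res.message} "
            f"(x0={x0}, nfev={res.nfev})"
        )
    lam = float(np.exp(res.x[0]))
    alpha = float(res.x[1]) if optimize_alpha else float(best[1])
    return GlogParams(lam, alpha, float(-res.fun))


def fit_control_model(
    glog_controls: pd.DataFrame,
    outlier_sd: float = 3.0,
    value_col: str = "value",
    max_iterations: int = 2000,
) -> ControlModelFit:
    """Fit z_ijk = mu + a_i + b_j + eps to control-probe replicates by OLS,
    iteratively rejecting outlier replicates until none remain.

    ``glog_controls`` is a long DataFrame with columns ``sample``, ``probe``
    and ``value`` (glog scale), one row per replicate spot. Identifiability:
    a_1 = b_1 = 0 for the first-seen sample and probe. A replicate is an
    outlier when its absolute residual exceeds ``outlier_sd`` times the
    robust residual SD (1.4826 x MAD) of the currently retained replicates;
    rejection proceeds one replicate at a time (the worst offender first,
    refitting after each removal) so that the leverage of a gross outlier
    on the fit never drags sound replicates over the threshold.
    """
    df = glog_controls
    samples = pd.unique(df["sample"])
    probes = pd.unique(df["probe"])
    if len(samples) < 2:
        raise ValueError(
            f"control model needs >= 2 samples (got {len(samples)}): "
            "the sample effects a_i are unidentifiable"
        )
    if len(probes) < 2:
        raise ValueError(f"control model needs >= 2 control probes (got {len(probes)})")

    s_idx = pd.Index(samples).get_indexer(df["sample"])
    p_idx = pd.Index(probes).get_indexer(df["probe"])
    y = df[value_col].to_numpy(dtype=float)
    n = len(y)
    S, P = len(samples), len(probes)

    # design: intercept + treatment-coded sample and probe dummies
    X = np.zeros((n, 1 + (S - 1) + (P - 1)))
    X[:, 0] = 1.0
    rows = np.arange(n)
    nz = s_idx > 0
    X[rows[nz], s_idx[nz]] = 1.0
    nz = p_idx > 0
    X[rows[nz], S - 1 + p_idx[nz]] = 1.0

    scale_floor = 1e-8 * max(1.0, float(np.median(np.abs(y))) or 1.0)
    keep = np.ones(n, dtype=bool)
    n_iter = 0
    while True:
        n_iter += 1
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        resid = y - X @ beta
        kept_resid = resid[keep]
        mad = float(np.median(np.abs(kept_resid - np.median(kept_resid))))
        threshold = max(outlier_sd * 1.4826 * mad, scale_floor)
        candidates = keep & (np.abs(resid) > threshold)
        if not candidates.any() or n_iter >= max_iterations:
            break
        worst = int(np.argmax(np.where(candidates, np.abs(resid), -np.inf)))
        keep[worst] = False
        i = s_idx[worst]
        if not keep[s_idx == i].any():
            raise ValueError(
                f"all replicates of sample {samples[i]!r} flagged as outliers"
            )

    mu = float(beta[0])
    a = pd.Series(np.concatenate([[0.0], beta[1:S]]), index=samples, name="a_i")
    b = pd.Series(np.concatenate([[0.0], beta[S : S + P - 1]]), index=probes, name="b_j")
    return ControlModelFit(
        mu=mu,
        sample_bias=a,
        probe_bias=b,
        residuals=pd.Series(resid, index=df.index, name="residual"),
        outlier_mask=pd.Series(~keep, index=df.index, name="outlier"),
        n_iterations=n_iter,
    )


def apply_normalization(matrix: ExpressionMatrix, fit: ControlModelFit) -> ExpressionMatrix:
    """Subtract the fitted sample coefficient a_i from each sample's column.

    Probe coefficients b_j are not subtracted: the normalization corrects
    per-sample scale only, so within-sample gene contrasts are untouched.
    """
    missing = [s for s in matrix.samples if s not in fit.sample_bias.index]
    if missing:
        raise KeyError(f"samples missing from control-model fit: {missing}")
    out = matrix.data.sub(fit.sample_bias[matrix.samples], axis=1)
    return ExpressionMatrix(out, matrix.scale)


def summarize_replicates(
    batch: pd.DataFrame,
    value_col: str = "value",
    outlier_mask: pd.Series | None = None,
) -> ExpressionMatrix:
    """Summarize replicate spots into one median value per (gene, sample).

    Outlier-masked replicates are excluded first. An even replicate count
    yields the mean of the two central values (ordinary median convention).
    A (gene, sample) cell with no surviving replicate becomes missing, with
    a warning.
    """
    df = batch
    if outlier_mask is not None:
        df = df.loc[~outlier_mask.reindex(df.index, fill_value=False)]
    if df.empty:
        raise ValueError("no replicates left to summarize")
    wide = df.pivot_table(
        index="probe", columns="sample", values=value_col, aggfunc="median"
    )
    # pivot_table drops all-NaN cells silently; re-introduce full grid
    all_probes = pd.unique(batch["probe"])
    all_samples = pd.unique(batch["sample"])
    wide = wide.reindex(index=all_probes, columns=all_samples)
    if wide.isna().any().any():
        n_missing = int(wide.isna().sum().sum())
        warnings.warn(
            f"{n_missing} (gene, sample) cells have no surviving replicate; "
            "set to missing",
            stacklevel=2,
        )
    return ExpressionMatrix(wide, "glog")


def preprocess_array(
    batch: pd.DataFrame,
    outlier_sd: float = 3.0,
    glog_params: GlogParams | None = None,
) -> tuple[ExpressionMatrix, GlogParams, ControlModelFit]:
    """Run the full four-step chain on a raw array batch.

    Returns the median-summarized, sample-normalized diagnostic-gene matrix
    (glog scale) together with the fitted glog parameters and control model.
    The glog fit uses all replicate spot groups; the additive model uses
    housekeeping and internal-standard spots only (hybridization controls
    are excluded).
    """
    bg = subtract_background(batch)
    if glog_params is None:
        groups = bg.pivot_table(
            index=["sample", "probe"], columns="replicate", values="intensity"
        ).to_numpy()
        glog_params = fit_glog(groups)
    bg = bg.assign(value=glog_transform(bg["intensity"].to_numpy(), glog_params))

    controls = bg[bg["role"].isin(CONTROL_ROLES)]
    fit = fit_control_model(controls, outlier_sd=outlier_sd)

    diag = bg[bg["role"] == "diagnostic"]
    summarized = summarize_replicates(diag)
    return apply_normalization(summarized, fit), glog_params, fit


def qpcr_delta_ct(ct: pd.DataFrame, hk_gene: str) -> ExpressionMatrix:
    """Delta-Ct normalization: expression = -(Ct_gene - Ct_housekeeping).

    Higher values mean higher expression (log2-like units since qPCR
    efficiency ~ 2 per cycle). Assays missing in every sample are dropped
    with a warning naming them; a housekeeping Ct missing in any sample is
    an error.
    """
    if hk_gene not in ct.index:
        raise KeyError(f"housekeeping gene {hk_gene!r} not in Ct table")
    hk = ct.loc[hk_gene]
    if hk.isna().any():
        bad = list(ct.columns[hk.isna()])
        raise ValueError(f"housekeeping Ct missing in samples: {bad}")
    all_missing = ct.index[ct.isna().all(axis=1)]
    if len(all_missing):
        warnings.warn(
            f"dropping assays with no signal in any sample: {list(all_missing)}",
            stacklevel=2,
        )
        ct = ct.drop(index=all_missing)
    expr = -(ct.drop(index=hk_gene).sub(hk, axis=1))
    return ExpressionMatrix(expr, "delta_ct")
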