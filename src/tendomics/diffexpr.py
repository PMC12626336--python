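"""Normalization and nested negative-binomial time-course testing.

The model for feature *i*, sample *j* is a negative-binomial GLM with log
link and log-size-factor offsets:

    full:     log mu_ij = b_i0 + b_iRIN * RIN_j + b_iTP[tp_j]
    reduced:  log mu_ij = b_i0 + b_iRIN * RIN_j

Time-point coefficients are reference-coded against the earliest time
point.  A likelihood-ratio test between the two fits isolates the time
effect while blocking on RIN (the per-sample RNA-integrity covariate).
Dispersion is the per-feature MLE profiled under the full model and shared
by both fits so the models stay strictly nested; this deliberately forgoes
DESeq2-style empirical-Bayes shrinkage (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "NBFit", "DEResult", "size_factors", "cpm", "adjust_bh",
    "build_design", "fit_nb_glm", "estimate_dispersion",
    "estimate_dispersions", "lrt",
    "run_lrt", "wald_pairwise", "independent_filter",
]

#: dispersion search bounds on log(alpha)
_LOG_ALPHA_BOUNDS = (-11.5, 3.0)
_MIN_ALPHA = 1e-5


@dataclass
class NBFit:
    """A fitted NB GLM for one feature."""

    coef: np.ndarray
    alpha: float
    llf: float
    cov: np.ndarray | None = None
    converged: bool = True
    colnames: list = field(default_factory=list)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over features (restricted to
    features with a strictly positive geometric mean across samples) of
    count / geometric-mean.
    """
    mat = np.asarray(counts, dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError(
            "size factors undefined: no feature has nonzero counts in every sample"
        )
    ratios = mat[usable] / np.exp(log_geo[usable])[:, None]
    sf = np.median(ratios, axis=0)
    if (sf <= 0).any():
        raise ValueError("non-positive size factor estimated")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def cpm(counts: pd.DataFrame, sf: pd.Series | None = None, log2: bool = False) -> pd.DataFrame:
    """Counts per million on size-factor-normalized counts.

    Each sample's normalized column is rescaled to sum to 1e6; with
    ``log2=True`` returns log2(CPM + 1).
    """
    if sf is None:
        sf = size_factors(counts)
    norm = counts / np.asarray(sf, dtype=float)
    totals = norm.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total normalized count")
    out = norm / totals * 1e6
    if log2:
        out = np.log2(out + 1.0)
    return out


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values propagate as NaN and do not count toward the number of
    tests.  Output is clipped to [0, 1] and monotone in sorted-p order.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = pm.size
    if n == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def build_design(samples: pd.DataFrame, timepoint: bool = True,
                 rin: bool = True) -> pd.DataFrame:
    """Reference-coded design matrix from a sample sheet.

    The earliest timepoint (first category of an ordered categorical, else
    sorted order of appearance) is the baseline.
    """
    cols = {"Intercept": np.ones(len(samples))}
    if rin:
        if "RIN" not in samples.columns:
            raise ValueError("sample sheet lacks a RIN column")
        cols["RIN"] = samples["RIN"].astype(float).to_numpy()
    if timepoint:
        tp = samples["timepoint"]
        levels = (list(tp.cat.categories) if isinstance(tp.dtype, pd.CategoricalDtype)
                  else sorted(tp.unique(), key=_tp_key))
        for level in levels[1:]:
            cols[f"tp_{level}"] = (tp == level).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=samples.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def _tp_key(label):
    """Sort P0, P7, ... numerically when labels look like P<number>."""
    s = str(label)
    if s.startswith("P") and s[1:].isdigit():
        return (0, int(s[1:]))
    return (1, s)


def _nb_llf(y, mu, alpha):
    """NB2 log-likelihood (size r = 1/alpha, mean mu)."""
    r = 1.0 / alpha
    return float(np.sum(
        scipy.stats.nbinom.logpmf(y, r, r / (r + mu))
    ))


def fit_nb_glm(y, X, offset=None, alpha: float | None = None) -> NBFit:
    """Fit one NB GLM row by IRLS (statsmodels), MLE dispersion if not given.

    ``offset`` is log size factors.  Returns capped coefficients with
    ``converged=False`` instead of raising on separation/divergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    colnames = list(X.columns) if isinstance(X, pd.DataFrame) else []
    Xa = np.asarray(X, dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    if not y.any():
        raise ValueError("all-zero count row cannot be fitted")
    if offset is None:
        offset = np.zeros_like(y)
    offset = np.asarray(offset, dtype=float)

    if alpha is None:
        alpha = estimate_dispersion(y, Xa, offset)

    fam = sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, Xa, family=fam, offset=offset).fit(maxiter=100)
            converged = bool(res.converged)
            coef = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            mu = np.asarray(res.mu)
        except Exception:  # perfect separation and friends
            converged = False
            coef = np.zeros(Xa.shape[1])
            coef[0] = np.log(max(y.mean(), 1e-8))
            cov = np.full((Xa.shape[1],) * 2, np.nan)
            mu = np.exp(Xa @ coef + offset)
    cap = 30.0
    if np.abs(coef).max() > cap:
        coef = np.clip(coef, -cap, cap)
        mu = np.exp(np.clip(Xa @ coef + offset, -cap, cap))
        converged = False
    llf = _nb_llf(y, np.maximum(mu, 1e-12), alpha)
    return NBFit(coef=coef, alpha=alpha, llf=llf, cov=cov,
                 converged=converged, colnames=colnames)


def estimate_dispersion(y, X, offset) -> float:
    """Per-feature dispersion alpha by Cox-Reid adjusted profile likelihood.

    Maximizes ll(alpha) - 0.5 log det(X' W X) over log(alpha) under the
    given design, where W = diag(mu / (1 + alpha mu)) at the IRLS optimum.
    The Cox-Reid term corrects the downward bias of the plain profile MLE
    caused by estimating the mean-model coefficients (without it the
    likelihood-ratio test is visibly anti-conservative at these sample
    sizes).  No shrinkage across features is applied.
    """
    from scipy.optimize import minimize_scalar

    def neg_apl(log_alpha):
        a = float(np.exp(log_alpha))
        fam = sm.families.NegativeBinomial(alpha=a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=50)
            except Exception:
                return np.inf
        mu = np.maximum(np.asarray(res.mu), 1e-12)
        w = mu / (1.0 + a * mu)
        sign, logdet = np.linalg.slogdet(X.T @ (w[:, None] * X))
        if sign <= 0:
            return np.inf
        return -(_nb_llf(y, mu, a) - 0.5 * logdet)

    opt = minimize_scalar(neg_apl, bounds=_LOG_ALPHA_BOUNDS, method="bounded",
                          options={"xatol": 1e-2, "maxiter": 40})
    return max(float(np.exp(opt.x)), _MIN_ALPHA)


#: shared log-dispersion grid for profile-likelihood pooling
_ALPHA_GRID = np.linspace(_LOG_ALPHA_BOUNDS[0], _LOG_ALPHA_BOUNDS[1], 25)


def _cr_apl_curve(y, X, offset, grid=_ALPHA_GRID) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood evaluated on a log-alpha grid."""
    out = np.full(grid.size, -np.inf)
    for gi, la in enumerate(grid):
        a = float(np.exp(la))
        fam = sm.families.NegativeBinomial(alpha=a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=50)
            except Exception:
                continue
        mu = np.maximum(np.asarray(res.mu), 1e-12)
        w = mu / (1.0 + a * mu)
        sign, logdet = np.linalg.slogdet(X.T @ (w[:, None] * X))
        if sign <= 0:
            continue
        out[gi] = _nb_llf(y, mu, a) - 0.5 * logdet
    return out


def estimate_dispersions(counts, X, offset, base_mean):
    """Trend-moderated per-feature dispersions from pooled CR profiles.

    Three stages, all operating on per-feature Cox-Reid adjusted profile
    log-likelihood curves evaluated on a shared log(alpha) grid:

    1. per-feature point estimate = curve argmax;
    2. parametric trend alpha(m) = a0 + a1/m fitted by maximizing the SUM
       of the interpolated curves (pooling across features makes the trend
       nearly unbiased even at 2 replicates per group, where individual
       estimates are biased low);
    3. per-feature posterior mode under a log-normal prior centered on the
       trend, with prior variance = excess spread of the point estimates
       around the trend beyond the trigamma sampling variance.

    Returns (alpha array aligned with counts' rows, info dict).
    """
    import scipy.special

    counts_arr = np.asarray(counts, dtype=float)
    bm = np.maximum(np.asarray(base_mean, dtype=float), 1e-8)
    n_feat = counts_arr.shape[0]
    curves = np.vstack([
        _cr_apl_curve(counts_arr[i], X, offset) for i in range(n_feat)
    ])
    # parabolic refinement of the per-feature grid argmax
    argmax_idx = np.argmax(curves, axis=1)
    raw_log = _ALPHA_GRID[argmax_idx].copy()
    step = _ALPHA_GRID[1] - _ALPHA_GRID[0]
    for i in range(n_feat):
        j = argmax_idx[i]
        if 0 < j < _ALPHA_GRID.size - 1 and np.all(np.isfinite(curves[i, j - 1:j + 2])):
            lo, mid, hi = curves[i, j - 1:j + 2]
            denom = lo - 2 * mid + hi
            if denom < 0:
                raw_log[i] += 0.5 * step * (lo - hi) / denom
    raw = np.exp(raw_log)

    fine = np.linspace(_LOG_ALPHA_BOUNDS[0], _LOG_ALPHA_BOUNDS[1], 200)
    finite = np.where(np.isfinite(curves), curves, -1e30)
    interp = np.vstack([np.interp(fine, _ALPHA_GRID, finite[i])
                        for i in range(n_feat)])

    from scipy.optimize import minimize

    def neg_pooled(params):
        a0, a1 = np.exp(params)
        la = np.log(a0 + a1 / bm)
        la = np.clip(la, _LOG_ALPHA_BOUNDS[0], _LOG_ALPHA_BOUNDS[1])
        total = 0.0
        for i in range(n_feat):
            total += np.interp(la[i], fine, interp[i])
        return -total

    opt = minimize(neg_pooled, x0=np.log([0.1, 1.0]), method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 200})
    a0, a1 = np.exp(opt.x)
    trend = np.clip(a0 + a1 / bm, _MIN_ALPHA, None)

    m, p = X.shape
    resid_df = max(m - p, 3)
    samp_var = float(scipy.special.polygamma(1, resid_df / 2.0))
    # robust spread around the trend; grid-boundary estimates are degenerate
    interior = (argmax_idx > 0) & (argmax_idx < _ALPHA_GRID.size - 1)
    log_resid = (np.log(np.maximum(raw, _MIN_ALPHA)) - np.log(trend))[interior]
    if log_resid.size >= 10:
        spread = 1.4826 * float(np.median(np.abs(log_resid - np.median(log_resid))))
    else:
        spread = float(np.std(log_resid)) if log_resid.size else 0.0
    prior_var = max(spread**2 - samp_var, 0.05)

    # posterior mode on the log scale = precision-weighted combination of
    # the point estimate and the trend (log-normal prior x approx normal
    # likelihood in log alpha); boundary features fall back to the trend
    w = (1.0 / samp_var) / (1.0 / samp_var + 1.0 / prior_var)
    alpha_map = np.where(
        interior,
        np.exp(w * np.log(np.maximum(raw, _MIN_ALPHA)) + (1 - w) * np.log(trend)),
        trend)
    post_var = 1.0 / (1.0 / samp_var + 1.0 / prior_var)
    info = {"trend": (float(a0), float(a1)), "prior_var": prior_var,
            "sampling_var": samp_var, "posterior_var": post_var,
            "raw": raw, "weight": w}
    return np.maximum(alpha_map, _MIN_ALPHA), info


def lrt(full: NBFit, reduced: NBFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested NB fits.

    Statistic 2*(ll_full - ll_reduced) clipped at zero; chi-square p with
    df = difference in parameter count.  Requires the reduced design's
    columns to be a strict subset of the full design's.
    """
    if full.colnames and reduced.colnames:
        if not set(reduced.colnames) < set(full.colnames):
            raise ValueError("reduced model is not nested in the full model")
    df = len(full.coef) - len(reduced.coef)
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(scipy.stats.chi2.sf(stat, df))
    return stat, df, p


def run_lrt(counts: pd.DataFrame, samples: pd.DataFrame, *, rin: bool = True,
            alpha_level: float = 0.05, filter_quantiles=None) -> pd.DataFrame:
    """Time-course LRT over all features of a count matrix.

    Per feature: Cox-Reid dispersion estimation under the full model,
    empirical-Bayes moderation toward the dispersion-mean trend, then full
    and reduced fits sharing the moderated dispersion (keeping the models
    nested), LRT, independent filtering on mean normalized counts, and BH
    adjustment among retained features.

    Returns a frame indexed by feature with columns stat, df, p, padj,
    base_mean, filtered, converged, alpha (dispersion).
    """
    samples = samples.loc[counts.columns]
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    X_full = build_design(samples, timepoint=True, rin=rin)
    X_red = build_design(samples, timepoint=False, rin=rin)
    Xfa = X_full.to_numpy()
    base_mean = (counts / sf).mean(axis=1)

    nonzero = [fid for fid, y in counts.iterrows() if y.to_numpy().any()]
    post_var = 0.0
    if len(nonzero) >= 10:
        alphas, disp_info = estimate_dispersions(
            counts.loc[nonzero], Xfa, offset, base_mean.loc[nonzero].to_numpy())
        alpha_by_feature = dict(zip(nonzero, alphas))
        post_var = disp_info["posterior_var"]
    else:
        alpha_by_feature = {
            fid: estimate_dispersion(counts.loc[fid].to_numpy(dtype=float),
                                     Xfa, offset)
            for fid in nonzero
        }

    # p-value averaged over the dispersion posterior (3-point Gauss-Hermite
    # in log alpha): plugging in a point estimate ignores dispersion
    # uncertainty and leaves the test anti-conservative
    if post_var > 0:
        nodes = np.sqrt(3.0 * post_var) * np.array([-1.0, 0.0, 1.0])
        node_w = np.array([1.0, 4.0, 1.0]) / 6.0
    else:
        nodes, node_w = np.array([0.0]), np.array([1.0])

    rows = []
    for fid, y in counts.iterrows():
        yv = y.to_numpy(dtype=float)
        if not yv.any():
            rows.append((fid, np.nan, np.nan, np.nan, True, np.nan))
            continue
        a = float(alpha_by_feature[fid])
        p_nodes, stat0, df0, conv = [], np.nan, np.nan, True
        for node, _w in zip(nodes, node_w):
            an = float(a * np.exp(node))
            fit_full = fit_nb_glm(yv, X_full, offset, alpha=an)
            fit_red = fit_nb_glm(yv, X_red, offset, alpha=an)
            stat, df, p_node = lrt(fit_full, fit_red)
            p_nodes.append(p_node)
            if node == 0.0:
                stat0, df0 = stat, df
                conv = fit_full.converged and fit_red.converged
        p = float(np.dot(node_w, p_nodes))
        rows.append((fid, stat0, df0, p, conv, a))
    res = pd.DataFrame(rows, columns=["feature", "stat", "df", "p",
                                      "converged", "alpha"]).set_index("feature")
    res["base_mean"] = base_mean
    res = independent_filter(res, base_mean, alpha_level=alpha_level,
                             quantiles=filter_quantiles)
    return res


def independent_filter(results: pd.DataFrame, base_mean: pd.Series, *,
                       alpha_level: float = 0.05, quantiles=None,
                       smooth_window: int = 5) -> pd.DataFrame:
    """Automatic independent filtering on mean normalized count.

    Scans mean-count quantile thresholds (default 0 to 0.95 in steps of
    0.01), BH-adjusts only features above each threshold, and keeps the
    threshold whose (moving-average smoothed) rejection count at
    ``alpha_level`` is maximal (ties -> lowest threshold).  Features below
    the chosen threshold get NaN adjusted p and ``filtered=True``.
    """
    if quantiles is None:
        quantiles = np.arange(0.0, 0.951, 0.01)
    res = results.copy()
    bm = base_mean.loc[res.index].to_numpy(dtype=float)
    p = res["p"].to_numpy(dtype=float)

    n_rej = []
    cutoffs = np.quantile(bm, quantiles)
    for cut in cutoffs:
        keep = bm >= cut
        padj = adjust_bh(np.where(keep, p, np.nan))
        n_rej.append(int(np.nansum(padj < alpha_level)))
    n_rej = np.asarray(n_rej, dtype=float)
    if smooth_window > 1 and len(n_rej) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.concatenate([np.repeat(n_rej[0], pad), n_rej,
                                 np.repeat(n_rej[-1], pad)])
        smoothed = np.convolve(padded, kernel, mode="valid")
    else:
        smoothed = n_rej
    best = int(np.argmax(smoothed))
    cut = cutoffs[best]
    keep = bm >= cut
    res["filtered"] = ~keep
    res["padj"] = adjust_bh(np.where(keep, p, np.nan))
    res.attrs["filter_threshold"] = float(cut)
    res.attrs["filter_quantile"] = float(quantiles[best])
    return res


def wald_pairwise(counts: pd.DataFrame, samples: pd.DataFrame, tp_a, tp_b, *,
                  rin: bool = True) -> pd.DataFrame:
    """Per-feature Wald test of the contrast between two timepoints.

    Uses the full-model fit; statistic = contrast estimate / SE, two-sided
    normal p, BH adjustment within the contrast.
    """
    if tp_a == tp_b:
        raise ValueError("invalid contrast: identical timepoints")
    tps = samples["timepoint"].astype(str)
    for tp in (tp_a, tp_b):
        n = int((tps == str(tp)).sum())
        if n == 0:
            raise ValueError(f"timepoint {tp} absent from sample sheet")
        if n < 2:
            raise ValueError(
                f"timepoint {tp} has a single sample; variance not estimable")
    samples = samples.loc[counts.columns]
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    X = build_design(samples, timepoint=True, rin=rin)

    contrast = np.zeros(X.shape[1])
    for sign, tp in ((1.0, tp_b), (-1.0, tp_a)):
        col = f"tp_{tp}"
        if col in X.columns:  # baseline level has no column
            contrast[X.columns.get_loc(col)] = sign

    rows = []
    for fid, y in counts.iterrows():
        yv = y.to_numpy(dtype=float)
        if not yv.any():
            rows.append((fid, np.nan, np.nan, np.nan))
            continue
        fit = fit_nb_glm(yv, X, offset)
        est = float(contrast @ fit.coef)
        var = float(contrast @ fit.cov @ contrast)
        if not np.isfinite(var) or var <= 0:
            rows.append((fid, est, np.nan, np.nan))
            continue
        z = est / np.sqrt(var)
        rows.append((fid, est, z, 2.0 * float(scipy.stats.norm.sf(abs(z)))))
    out = pd.DataFrame(rows, columns=["feature", "lfc", "stat", "p"]).set_index("feature")
    out["padj"] = adjust_bh(out["p"].to_numpy())
    return out
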