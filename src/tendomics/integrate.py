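"""Peak-gene linkage, cross-assay correlation, and pair co-clustering.

A DA peak annotated to a nearest gene (within +/- 50 kb of its summit)
forms a peak-gene pair.  Accessibility and expression profiles are
averaged over replicates per time point on the shared time points of the
two assays (the RNA series may include a time point the ATAC series lacks)
and correlated with Pearson r.  Pairs with r > 0.5 are classed positive
(candidate enhancers), r < -0.5 negative; the rest stay unclassified.
Positive pairs are re-clustered with PAM on the concatenated z-scored
profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cluster import pam_cluster

__all__ = [
    "timepoint_means", "pair_peaks_genes", "pair_correlation",
    "classify_pairs", "cocluster_pairs", "subset_by_motif_family",
]


def timepoint_means(mat: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns per time point (columns ordered by time)."""
    tps = samples.loc[mat.columns, "timepoint"]
    levels = (list(tps.cat.categories) if isinstance(tps.dtype, pd.CategoricalDtype)
              else list(dict.fromkeys(tps)))
    cols = {}
    for tp in levels:
        sel = (tps == tp).to_numpy()
        if sel.any():
            cols[str(tp)] = mat.loc[:, sel].mean(axis=1)
    return pd.DataFrame(cols)


def pair_peaks_genes(annotations: pd.DataFrame, peak_profiles: pd.DataFrame,
                     gene_profiles: pd.DataFrame) -> pd.DataFrame:
    """Build unclassified peak-gene pairs on shared time points.

    ``annotations`` must carry a ``nearest_gene`` column (peaks without an
    assigned gene emit no pair); ``peak_profiles`` / ``gene_profiles`` are
    per-timepoint mean normalized profiles from :func:`timepoint_means`.
    Genes absent from the expression matrix (not detected throughout the
    series) are dropped.  A gene with several assigned peaks contributes
    one pair per peak.
    """
    shared = [tp for tp in peak_profiles.columns if tp in set(gene_profiles.columns)]
    if not shared:
        raise ValueError("no timepoints shared between assays")
    rows = []
    for peak_id, ann in annotations.iterrows():
        gene = ann.get("nearest_gene")
        if gene is None or (isinstance(gene, float) and np.isnan(gene)) or gene == "":
            continue
        if peak_id not in peak_profiles.index or gene not in gene_profiles.index:
            continue
        rows.append((peak_id, gene, float(ann.get("tss_distance", np.nan))))
    pairs = pd.DataFrame(rows, columns=["peak_id", "gene_id", "tss_distance"])
    pairs.attrs["shared_timepoints"] = shared
    pairs.attrs["alignment"] = "replicate means on shared timepoints"
    return pairs


def pair_correlation(pairs: pd.DataFrame, peak_profiles: pd.DataFrame,
                     gene_profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between accessibility and expression per pair.

    Needs >= 3 shared time points; zero-variance profiles leave r as NaN
    (the pair stays unclassified) with a warning.
    """
    shared = pairs.attrs.get("shared_timepoints") or [
        tp for tp in peak_profiles.columns if tp in set(gene_profiles.columns)]
    out = pairs.copy()
    if len(shared) < 3:
        warnings.warn("fewer than 3 shared timepoints; all pairs unclassified")
        out["r"] = np.nan
        out.attrs["unclassified_reason"] = "<3 shared timepoints"
        return out
    acc = peak_profiles.loc[out["peak_id"], shared].to_numpy(dtype=float)
    expr = gene_profiles.loc[out["gene_id"], shared].to_numpy(dtype=float)
    a = acc - acc.mean(axis=1, keepdims=True)
    e = expr - expr.mean(axis=1, keepdims=True)
    sa = np.sqrt((a * a).sum(axis=1))
    se = np.sqrt((e * e).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * e).sum(axis=1) / (sa * se)
    n_flat = int((~np.isfinite(r)).sum())
    if n_flat:
        warnings.warn(f"{n_flat} pairs with a zero-variance profile; r undefined")
    out["r"] = np.where(np.isfinite(r), r, np.nan)
    out.attrs["shared_timepoints"] = shared
    return out


def classify_pairs(pairs: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Strict-threshold classification: positive iff r > t, negative iff r < -t."""
    out = pairs.copy()
    r = out["r"].to_numpy(dtype=float)
    cls = np.where(np.isnan(r), "unclassified",
                   np.where(r > threshold, "positive",
                            np.where(r < -threshold, "negative", "unclassified")))
    out["class"] = cls
    return out


def _pair_feature_matrix(pairs: pd.DataFrame, peak_profiles: pd.DataFrame,
                         gene_profiles: pd.DataFrame, shared) -> pd.DataFrame:
    def _z(block):
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (block - mu) / sd

    acc = _z(peak_profiles.loc[pairs["peak_id"], shared].to_numpy(dtype=float))
    expr = _z(gene_profiles.loc[pairs["gene_id"], shared].to_numpy(dtype=float))
    feat = np.hstack([acc, expr])
    idx = pairs["peak_id"] + "|" + pairs["gene_id"]
    cols = [f"acc_{t}" for t in shared] + [f"expr_{t}" for t in shared]
    return pd.DataFrame(feat, index=idx, columns=cols)


def cocluster_pairs(pairs: pd.DataFrame, peak_profiles: pd.DataFrame,
                    gene_profiles: pd.DataFrame, k: int = 5,
                    seed: int | None = None) -> pd.DataFrame:
    """PAM co-clustering of positive pairs on joint accessibility+expression.

    Feature vector = z-scored accessibility profile concatenated with the
    z-scored expression profile; degenerate inputs (all pairs identical)
    collapse to one effective module with a warning.
    """
    pos = pairs[pairs["class"] == "positive"] if "class" in pairs.columns else pairs
    if len(pos) < k:
        raise ValueError(f"need >= k={k} positive pairs, have {len(pos)}")
    shared = pairs.attrs.get("shared_timepoints") or [
        tp for tp in peak_profiles.columns if tp in set(gene_profiles.columns)]
    feat = _pair_feature_matrix(pos, peak_profiles, gene_profiles, shared)
    modules = pam_cluster(feat, k=k, seed=seed)
    occupied = modules["module"].nunique()
    if occupied < k:
        warnings.warn(f"only {occupied} of {k} modules occupied (degenerate input)")
    out = pos.reset_index(drop=True).copy()
    out["module"] = modules["module"].to_numpy()
    out.attrs.update(pairs.attrs)
    out.attrs["module_inertia"] = modules.attrs["inertia"]
    return out


def subset_by_motif_family(pairs: pd.DataFrame, hits: pd.DataFrame,
                           family_map: dict, family: str,
                           peak_profiles: pd.DataFrame,
                           gene_profiles: pd.DataFrame,
                           k: int = 2, seed: int | None = None) -> pd.DataFrame:
    """Re-cluster the positive pairs whose peak carries a family motif hit.

    ``family_map`` maps motif id -> family label; a peak qualifies if it
    has >= 1 hit from any member motif.  Raises on an empty subset.
    """
    members = {m for m, f in family_map.items() if f == family}
    fam_hits = hits[hits["motif_id"].isin(members)]
    with_hit = set(fam_hits["seq_id"])
    pos = pairs[pairs["class"] == "positive"] if "class" in pairs.columns else pairs
    sub = pos[pos["peak_id"].isin(with_hit)].copy()
    if sub.empty:
        raise ValueError(f"no positive pair's peak carries a {family} motif hit")
    sub.attrs.update(pairs.attrs)
    return cocluster_pairs(sub, peak_profiles, gene_profiles,
                           k=min(k, len(sub)), seed=seed)
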