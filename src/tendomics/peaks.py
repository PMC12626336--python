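"""Consensus ATAC peak construction, counting, DA testing, and annotation.

All interval arithmetic is 0-based half-open; overlap means >= 1 shared
base.  A consensus peak must be present (overlapping calls) in both
replicates of at least one time point, and is emitted at a fixed 500 bp
width centered on the merged region's representative summit (the summit of
the highest-scoring supporting call; ties broken leftmost).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import diffexpr

__all__ = [
    "filter_spurious", "build_consensus", "count_in_peaks",
    "differential_accessibility", "annotate_peaks",
    "DEFAULT_PROMOTER", "DEFAULT_MAX_TSS_DIST", "TSS_BIN_EDGES_KB",
]

DEFAULT_PROMOTER = (-3000, 3000)       # around the TSS, strand-aware
DEFAULT_MAX_TSS_DIST = 50_000
TSS_BIN_EDGES_KB = (0, 1, 3, 5, 10, 100)

#: annotation category precedence, highest first
CATEGORY_ORDER = ["promoter", "5'UTR", "3'UTR", "exon", "intron",
                  "downstream", "distal intergenic"]


def _trees(intervals: pd.DataFrame) -> dict:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]))
    return trees


def filter_spurious(peaks: pd.DataFrame, blacklist: pd.DataFrame,
                    control_peaks: pd.DataFrame) -> pd.DataFrame:
    """Drop peak calls overlapping blacklist or naked-DNA control intervals.

    Overlap is >= 1 bp under half-open arithmetic, so a peak exactly
    abutting a blacklist interval is retained.  Order-preserving.
    """
    bad = pd.concat([blacklist[["chrom", "start", "end"]],
                     control_peaks[["chrom", "start", "end"]]],
                    ignore_index=True)
    if bad.empty:
        return peaks.copy()
    peak_chroms, bad_chroms = set(peaks["chrom"]), set(bad["chrom"])
    if peak_chroms and bad_chroms and not (peak_chroms & bad_chroms):
        per_chrom = bad["chrom"].value_counts().to_dict()
        warnings.warn(
            "no chromosome shared between peak calls and filter sets; "
            f"filter intervals per chromosome: {per_chrom}")
    trees = _trees(bad)
    keep = [
        not (row.chrom in trees and trees[row.chrom].overlap(row.start, row.end))
        for row in peaks.itertuples()
    ]
    return peaks.loc[keep].copy()


def build_consensus(peak_calls: pd.DataFrame, width: int = 500,
                    min_replicates: int = 2) -> pd.DataFrame:
    """Build the reproducibility-filtered fixed-width consensus peak set.

    ``peak_calls`` needs columns chrom, start, end, summit, score,
    timepoint, replicate.  Calls from all replicates are pooled and merged
    into candidate regions by transitive overlap; a region is kept iff some
    time point contributes overlapping calls from at least
    ``min_replicates`` distinct replicates.  Time points with fewer than
    ``min_replicates`` replicates overall are excluded with a warning
    (irreproducibility cannot be assessed there).

    Returns a BED-like frame: chrom, start, end (width bp), summit,
    support ("tp:rep" pairs, semicolon-joined), peak_id.
    """
    calls = peak_calls.copy()
    reps_per_tp = calls.groupby("timepoint", observed=True)["replicate"].nunique()
    bad_tps = reps_per_tp[reps_per_tp < min_replicates].index.tolist()
    if bad_tps:
        warnings.warn(f"excluding timepoints with a single replicate: {bad_tps}")
        calls = calls[~calls["timepoint"].isin(bad_tps)]
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "summit",
                                     "support", "peak_id"])

    out_rows = []
    for chrom, sub in calls.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # sweep merge of transitively overlapping calls
        region_id = np.zeros(len(sub), dtype=int)
        cur, cur_end = 0, ends[0]
        for i in range(1, len(sub)):
            if starts[i] < cur_end:           # half-open overlap
                cur_end = max(cur_end, ends[i])
            else:
                cur += 1
                cur_end = ends[i]
            region_id[i] = cur
        sub = sub.assign(_region=region_id)
        for _, region in sub.groupby("_region"):
            support_tps = region.groupby("timepoint", observed=True)["replicate"].nunique()
            if not (support_tps >= min_replicates).any():
                continue
            best = region.sort_values(["score", "summit"],
                                      ascending=[False, True]).iloc[0]
            summit = int(best["summit"])
            support = sorted(set(zip(region["timepoint"].astype(str),
                                     region["replicate"].astype(str))))
            out_rows.append((chrom, summit - width // 2, summit - width // 2 + width,
                             summit, ";".join(f"{t}:{r}" for t, r in support)))
    out = pd.DataFrame(out_rows, columns=["chrom", "start", "end", "summit",
                                          "support"])
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    out["peak_id"] = [f"consensus_{i:05d}" for i in range(len(out))]
    return out


def count_in_peaks(fragments: dict, peaks: pd.DataFrame) -> pd.DataFrame:
    """Count fragments per consensus peak by midpoint containment.

    ``fragments`` maps replicate id -> frame (chrom, start, end) of 0-based
    half-open fragment intervals.  A fragment is counted for a peak iff its
    midpoint (start+end)/2 satisfies peak.start <= midpoint < peak.end.
    Returns a peaks x replicates count matrix indexed by peak_id.
    """
    index = peaks["peak_id"] if "peak_id" in peaks.columns else peaks.index
    mat = pd.DataFrame(0, index=index, columns=list(fragments), dtype=np.int64)
    for rep, frags in fragments.items():
        if len(frags) == 0:
            continue
        mids = frags.assign(_mid=(frags["start"] + frags["end"]) / 2.0)
        for chrom, sub in mids.groupby("chrom"):
            mid_sorted = np.sort(sub["_mid"].to_numpy())
            sel = peaks["chrom"] == chrom
            if not sel.any():
                continue
            lo = np.searchsorted(mid_sorted, peaks.loc[sel, "start"].to_numpy(), "left")
            hi = np.searchsorted(mid_sorted, peaks.loc[sel, "end"].to_numpy(), "left")
            mat.loc[np.asarray(index)[np.asarray(sel)], rep] += hi - lo
    return mat


def differential_accessibility(counts: pd.DataFrame, samples: pd.DataFrame,
                               alpha_level: float = 0.05) -> pd.DataFrame:
    """Time-course DA testing: NB GLM LRT with timepoint-only full model.

    RIN is not measured for ATAC samples, so the full model is
    intercept + timepoint and the reduced model is intercept-only.
    """
    tps = samples.loc[counts.columns, "timepoint"]
    if tps.astype(str).nunique() < 2:
        raise ValueError("differential accessibility needs >= 2 timepoints")
    vc = tps.astype(str).value_counts()
    if (vc < 2).any():
        raise ValueError(
            f"timepoints with < 2 replicates: {vc[vc < 2].index.tolist()}")
    return diffexpr.run_lrt(counts, samples, rin=False, alpha_level=alpha_level)


def _gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    g = genes[genes["feature"] == "gene"].copy()
    g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
    return g.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                   promoter_window: tuple = DEFAULT_PROMOTER,
                   max_tss_dist: int = DEFAULT_MAX_TSS_DIST) -> pd.DataFrame:
    """Annotate consensus peaks to genomic features and nearest genes.

    Feature category follows the precedence promoter > 5'UTR > 3'UTR >
    exon > intron > downstream > distal intergenic, evaluated at the peak
    summit.  The signed TSS distance is strand-aware (positive = downstream
    of the TSS in the gene's orientation).  The nearest gene is the one
    whose TSS minimizes |summit - TSS| (ties -> lexicographically smaller
    gene id), assigned only when the distance is <= ``max_tss_dist``.
    """
    if genes[genes["feature"] == "gene"].empty:
        raise ValueError("empty gene set")
    gt = _gene_table(genes)
    up, down = promoter_window
    exons = genes[genes["feature"] == "exon"]
    utr5 = genes[genes["feature"].isin(["five_prime_utr", "5UTR"])]
    utr3 = genes[genes["feature"].isin(["three_prime_utr", "3UTR"])]
    exon_trees = _trees(exons) if len(exons) else {}
    utr5_trees = _trees(utr5) if len(utr5) else {}
    utr3_trees = _trees(utr3) if len(utr3) else {}
    body_trees = _trees(gt)
    downstream_trees = {}
    ds = gt.copy()
    ds_start = np.where(ds["strand"] == "+", ds["end"], ds["start"] - 3000)
    ds_end = np.where(ds["strand"] == "+", ds["end"] + 3000, ds["start"])
    downstream_trees = _trees(pd.DataFrame({
        "chrom": ds["chrom"], "start": ds_start, "end": ds_end}))

    rows = []
    for row in peaks.itertuples():
        summit = int(row.summit)
        chrom = row.chrom
        sub = gt[gt["chrom"] == chrom]
        gene_id, signed, absdist = None, np.nan, np.inf
        if len(sub):
            tss = sub["tss"].to_numpy()
            d = np.abs(summit - tss)
            best = np.lexsort((sub["gene_id"].to_numpy(), d))[0]
            absdist = int(d[best])
            strand = sub["strand"].to_numpy()[best]
            raw = summit - int(tss[best])
            signed = raw if strand == "+" else -raw
            gene_id = sub["gene_id"].to_numpy()[best] if absdist <= max_tss_dist else None

        # promoter test against *any* gene's promoter window (strand-aware)
        in_promoter = False
        if len(sub):
            tss = sub["tss"].to_numpy()
            strands = sub["strand"].to_numpy()
            rel = np.where(strands == "+", summit - tss, tss - summit)
            in_promoter = bool(((rel >= up) & (rel <= down)).any())

        if in_promoter:
            cat = "promoter"
        elif chrom in utr5_trees and utr5_trees[chrom].overlap(summit, summit + 1):
            cat = "5'UTR"
        elif chrom in utr3_trees and utr3_trees[chrom].overlap(summit, summit + 1):
            cat = "3'UTR"
        elif chrom in exon_trees and exon_trees[chrom].overlap(summit, summit + 1):
            cat = "exon"
        elif chrom in body_trees and body_trees[chrom].overlap(summit, summit + 1):
            cat = "intron"
        elif chrom in downstream_trees and downstream_trees[chrom].overlap(summit, summit + 1):
            cat = "downstream"
        else:
            cat = "distal intergenic"

        rows.append((getattr(row, "peak_id", row.Index), chrom, summit, cat,
                     signed, gene_id, _tss_bin(signed)))
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "summit", "category",
                                       "tss_distance", "nearest_gene",
                                       "tss_bin"]).set_index("peak_id")


def _tss_bin(signed_dist, edges_kb=TSS_BIN_EDGES_KB) -> str:
    if not np.isfinite(signed_dist):
        return "NA"
    kb = abs(signed_dist) / 1000.0
    sign = "-" if signed_dist < 0 else "+"
    for lo, hi in zip(edges_kb[:-1], edges_kb[1:]):
        if lo <= kb < hi or (kb == hi == edges_kb[-1]):
            return f"{sign}{lo}-{hi}kb"
    return f"{sign}>{edges_kb[-1]}kb"
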