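"""End-to-end orchestration of the synthetic study analysis.

simulate -> differential expression -> consensus/DA peaks -> module
clustering -> peak-gene integration -> motif enrichment -> gene-set ORA,
with a reproducibility report (stage counts, thresholds, seed, checksums).
A single run seed governs every stochastic stage through a stage-name
derivation scheme, so stages are reproducible independently.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster, diffexpr, integrate, motifs, peaks, simulate
from .enrich import ora

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "write_report"]


@dataclass
class RunConfig:
    seed: int = 1
    alpha: float = 0.05                 # adjusted-p gate for DE/DA
    enrich_padj_gate: float = 0.01
    enrich_q_gate: float = 0.05
    corr_threshold: float = 0.5
    max_tss_dist: int = 50_000
    consensus_width: int = 500
    promoter_window: tuple = (-3000, 3000)
    k_genes: int = 6
    k_pairs: int = 5
    k_family: int = 2
    motif_family: str = "TEA"
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in [0, 1]")
        if self.consensus_width <= 0 or self.max_tss_dist <= 0:
            raise ValueError("width and TSS window must be positive")


def stage_seed(seed: int, stage: str) -> int:
    """Stage-specific seed below 2^31 derived from the run seed."""
    return (zlib.crc32(stage.encode()) ^ (seed & 0x7FFFFFFF)) % (2**31)


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv().encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig, experiment=None) -> dict:
    """Run every stage and return (report dict with embedded results).

    ``experiment`` may be a pre-built :class:`~tendomics.simulate.Experiment`;
    by default a synthetic study is generated from the run seed.
    The report's "counts" block lists the quantity surviving each stage.
    """
    config.validate()
    report: dict = {
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "enrich_padj_gate": config.enrich_padj_gate,
            "enrich_q_gate": config.enrich_q_gate,
            "corr_threshold": config.corr_threshold,
            "max_tss_dist": config.max_tss_dist,
            "consensus_width": config.consensus_width,
            "promoter_window": list(config.promoter_window),
            "k": {"genes": config.k_genes, "pairs": config.k_pairs,
                  "family_subset": config.k_family},
        },
        "counts": {}, "checksums": {}, "stages": [],
    }
    results: dict = {}

    # ---- simulate --------------------------------------------------------
    if experiment is None:
        sim_cfg = simulate.SimulationConfig(
            seed=stage_seed(config.seed, "simulate"), **config.sim_overrides)
        experiment = simulate.simulate_experiment(sim_cfg)
    report["stages"].append("simulate")
    report["checksums"]["rna_counts"] = _checksum(experiment.rna_counts)
    report["checksums"]["atac_counts"] = _checksum(experiment.atac_counts)
    results["experiment"] = experiment

    # ---- RNA differential expression ------------------------------------
    de = diffexpr.run_lrt(experiment.rna_counts, experiment.rna_samples,
                          rin=True, alpha_level=config.alpha)
    de_genes = de.index[(de["padj"] < config.alpha).fillna(False)].tolist()
    n_detected = int((~de["filtered"]).sum())
    report["stages"].append("diffexpr")
    report["counts"]["genes_total"] = int(len(de))
    report["counts"]["genes_detected"] = n_detected
    report["counts"]["de_genes"] = len(de_genes)
    report["counts"]["pct_de_of_detected"] = round(
        100.0 * len(de_genes) / max(n_detected, 1), 2)
    results["de"] = de

    # ---- ATAC consensus + DA ---------------------------------------------
    calls = peaks.filter_spurious(experiment.peak_calls, experiment.blacklist,
                                  experiment.control_peaks)
    consensus = peaks.build_consensus(calls, width=config.consensus_width)
    # map consensus intervals back to the simulated reads-in-peaks rows
    truth = experiment.peak_truth.set_index("peak_id")
    src = _match_to_truth(consensus, truth, config.consensus_width)
    consensus = consensus.assign(source_peak=src)
    counted = consensus.dropna(subset=["source_peak"])
    atac_counts = experiment.atac_counts.loc[counted["source_peak"]]
    atac_counts.index = counted["source_peak"].tolist()
    da = peaks.differential_accessibility(atac_counts, experiment.atac_samples,
                                          alpha_level=config.alpha)
    da_ids = da.index[(da["padj"] < config.alpha).fillna(False)].tolist()
    report["stages"].append("atac_peaks")
    report["counts"]["peak_calls"] = int(len(experiment.peak_calls))
    report["counts"]["peak_calls_after_filter"] = int(len(calls))
    report["counts"]["consensus_peaks"] = int(len(consensus))
    report["counts"]["da_peaks"] = len(da_ids)
    results["consensus"] = consensus
    results["da"] = da

    ann = peaks.annotate_peaks(
        counted.assign(peak_id=counted["source_peak"]).set_index("peak_id"),
        experiment.genes, promoter_window=config.promoter_window,
        max_tss_dist=config.max_tss_dist)
    ann = ann[~ann.index.duplicated()]
    results["annotation"] = ann
    cat_counts = ann["category"].value_counts().to_dict()
    report["counts"]["annotation_categories"] = {k: int(v) for k, v in cat_counts.items()}

    # ---- module clustering ------------------------------------------------
    norm_genes = cluster.normalize_for_clustering(
        experiment.rna_counts.loc[de_genes]) if len(de_genes) >= config.k_genes else None
    if norm_genes is not None:
        gene_modules = cluster.pam_cluster(norm_genes, k=config.k_genes,
                                           seed=stage_seed(config.seed, "cluster"))
        report["counts"]["gene_module_sizes"] = {
            str(k): int(v) for k, v in
            gene_modules["module"].value_counts().sort_index().items()}
        results["gene_modules"] = gene_modules
    report["stages"].append("coexpression")

    # ---- integration ------------------------------------------------------
    rna_qn = cluster.normalize_for_clustering(experiment.rna_counts, z_score=False)
    atac_qn = cluster.normalize_for_clustering(atac_counts[~atac_counts.index.duplicated()],
                                               z_score=False)
    gene_prof = integrate.timepoint_means(rna_qn, experiment.rna_samples)
    peak_prof = integrate.timepoint_means(atac_qn, experiment.atac_samples)
    da_ann = ann.loc[[i for i in da_ids if i in ann.index]]
    pairs = integrate.pair_peaks_genes(da_ann, peak_prof, gene_prof)
    pairs = integrate.pair_correlation(pairs, peak_prof, gene_prof)
    pairs = integrate.classify_pairs(pairs, threshold=config.corr_threshold)
    cls_counts = pairs["class"].value_counts().to_dict()
    report["stages"].append("integration")
    report["counts"]["pairs_total"] = int(len(pairs))
    report["counts"]["pairs_positive"] = int(cls_counts.get("positive", 0))
    report["counts"]["pairs_negative"] = int(cls_counts.get("negative", 0))
    report["counts"]["pairs_unclassified"] = int(cls_counts.get("unclassified", 0))
    results["pairs"] = pairs

    pair_modules = None
    if int(cls_counts.get("positive", 0)) >= config.k_pairs:
        pair_modules = integrate.cocluster_pairs(
            pairs, peak_prof, gene_prof, k=config.k_pairs,
            seed=stage_seed(config.seed, "integrate"))
        report["counts"]["pair_module_sizes"] = {
            str(k): int(v) for k, v in
            pair_modules["module"].value_counts().sort_index().items()}
        results["pair_modules"] = pair_modules

    # ---- motifs ------------------------------------------------------------
    hits = motifs.scan_library(experiment.peak_windows, experiment.pwms)
    hist, frac100 = motifs.summit_distance_profile(hits)
    report["stages"].append("motif_analysis")
    report["counts"]["motif_hits"] = int(len(hits))
    report["counts"]["motif_frac_within_100bp"] = (
        round(frac100, 4) if np.isfinite(frac100) else None)
    results["motif_hits"] = hits

    family_map = {m.motif_id: m.family for m in experiment.pwms}
    enriched_motifs: dict = {}
    if pair_modules is not None:
        universe_peaks = [p for p in atac_counts.index.unique()]
        for mod, sub in pair_modules.groupby("module"):
            fg = sub["peak_id"].unique().tolist()
            bg = [p for p in universe_peaks if p not in set(fg)]
            res = motifs.motif_enrichment(fg, bg, hits,
                                          padj_gate=config.enrich_padj_gate,
                                          q_gate=config.enrich_q_gate)
            enriched_motifs[int(mod)] = res.index[res["significant"]].tolist()
        report["counts"]["enriched_motifs_per_pair_module"] = {
            str(k): len(v) for k, v in enriched_motifs.items()}
        results["motif_enrichment"] = enriched_motifs

        fam = pair_modules[pair_modules["peak_id"].isin(
            set(hits.loc[hits["motif_id"].map(
                lambda m: family_map.get(m) == config.motif_family), "seq_id"]))]
        report["counts"]["family_subset_pairs"] = int(len(fam))
        if len(fam) >= config.k_family:
            fam_modules = integrate.subset_by_motif_family(
                pair_modules, hits, family_map, config.motif_family,
                peak_prof, gene_prof, k=config.k_family,
                seed=stage_seed(config.seed, "family"))
            report["counts"]["family_subset_module_sizes"] = {
                str(k): int(v) for k, v in
                fam_modules["module"].value_counts().sort_index().items()}
            results["family_modules"] = fam_modules

    # ---- gene-set ORA -------------------------------------------------------
    truth_sets = {
        f"planted_{mod}": set(g)
        for mod, g in experiment.gene_truth.groupby("module")["gene_id"]
        if mod != "flat" and len(g) > 0
    }
    universe = set(de.index[~de["filtered"]])
    enriched_sets = {}
    if norm_genes is not None and truth_sets:
        for mod, sub in results["gene_modules"].groupby("module"):
            module_genes = set(sub.index) & universe
            if not module_genes:
                continue
            res = ora(module_genes, truth_sets, universe,
                      padj_gate=config.enrich_padj_gate, q_gate=config.enrich_q_gate)
            enriched_sets[int(mod)] = res.index[res["significant"]].tolist()
        report["counts"]["enriched_sets_per_gene_module"] = {
            str(k): len(v) for k, v in enriched_sets.items()}
        results["ora"] = enriched_sets
    report["stages"].append("enrichment_stats")

    report["checksums"]["report"] = hashlib.sha256(
        json.dumps(report["counts"], sort_keys=True).encode()).hexdigest()[:16]
    report["results"] = results
    return report


def _match_to_truth(consensus: pd.DataFrame, truth: pd.DataFrame,
                    width: int) -> list:
    """Nearest-summit match of consensus peaks to simulated truth peaks."""
    out = []
    t_by_chrom = {c: s.sort_values("summit") for c, s in truth.groupby("chrom")}
    for row in consensus.itertuples():
        sub = t_by_chrom.get(row.chrom)
        if sub is None or sub.empty:
            out.append(None)
            continue
        summits = sub["summit"].to_numpy()
        i = int(np.argmin(np.abs(summits - row.summit)))
        out.append(sub.index[i] if abs(int(summits[i]) - row.summit) <= width // 2
                   else None)
    return out


def write_report(report: dict, out_json, out_md=None) -> None:
    """Serialize the report (without embedded result frames) as JSON (+ MD)."""
    slim = {k: v for k, v in report.items() if k != "results"}
    with open(out_json, "w") as fh:
        json.dump(slim, fh, indent=2, sort_keys=True)
    if out_md:
        lines = ["# Pipeline report", "",
                 f"Seed: {slim['seed']}", "", "## Stage counts", ""]
        for k, v in slim["counts"].items():
            lines.append(f"- **{k}**: {v}")
        lines += ["", "## Thresholds", ""]
        for k, v in slim["thresholds"].items():
            lines.append(f"- {k}: {v}")
        lines += ["", "## Input checksums", ""]
        for k, v in slim["checksums"].items():
            lines.append(f"- {k}: `{v}`")
        with open(out_md, "w") as fh:
            fh.write("\n".join(lines) + "\n")
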