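"""Synthetic multi-omic study generator.

Emulates the structure of a postnatal tendon growth time course: weekly
time points P0..P35, 6-9 bulk RNA-seq replicates per time point, 2 ATAC-seq
replicates per time point with one time point droppable (the 4th, mirroring
a failed P21 collection), NB-distributed counts with planted temporal
modules, a per-sample RIN nuisance covariate acting on log-mean expression,
peaks linked to genes with planted accessibility-expression correlation,
and PWM motif instances planted near peak summits and in promoters.

Everything is driven by a single integer seed and is deterministic given
the seed and configuration.  Counts are reads-in-peaks / gene-level counts
directly (no read-level simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .motifs import PWM

__all__ = [
    "SimulationConfig", "Experiment", "default_profiles", "builtin_motifs",
    "simulate_experiment", "plant_motifs", "revcomp",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_profiles(n_timepoints: int = 6, amplitude: float = 2.0) -> dict:
    """Six temporal mean-shape vectors (natural-log units) plus implicit flat.

    Shapes cover the three broad patterns seen in postnatal tendon modules:
    monotone up (early or late onset), monotone down (early or late), a
    transient burst at the second time point, and an intermittent
    oscillation.  ``amplitude`` is the log-scale swing (2.0 ~ 7-fold).
    """
    t = np.linspace(0.0, 1.0, n_timepoints)
    shapes = {
        "up_early": np.minimum(t * (n_timepoints - 1) / 2.0, 1.0),
        "up_late": np.maximum(t * (n_timepoints - 1) / 2.0 - (n_timepoints - 1) / 2.0 + 1.0, 0.0),
        "down_early": 1.0 - np.minimum(t * (n_timepoints - 1) / 2.0, 1.0),
        "down_late": 1.0 - np.maximum(t * (n_timepoints - 1) / 2.0 - (n_timepoints - 1) / 2.0 + 1.0, 0.0),
        "transient": np.where(np.arange(n_timepoints) == 1, 1.0, 0.0).astype(float),
        "intermittent": (np.arange(n_timepoints) % 2).astype(float),
    }
    return {name: vec * amplitude for name, vec in shapes.items()}


def builtin_motifs(pseudocount: float = 0.01) -> list:
    """A small synthetic PWM library (one informative consensus per family).

    These are synthetic stand-ins whose consensus strings echo the canonical
    cores of the respective families (TEA 'GGAATG', bHLH E-box 'CAGCTG',
    MADS A/T box, bZIP TRE, Zf G-box); they are not database matrices.
    """
    consensi = {
        "TEAD_syn": ("TEA", "GGAATGTG"),
        "EBOX_syn": ("bHLH", "ACAGCTGT"),
        "MEF2_syn": ("MADS", "CTAAAAATAG"),
        "AP1_syn": ("bZIP", "TGACTCAT"),
        "KLF_syn": ("Zf", "GGGGCGGGG"),
    }
    out = []
    for mid, (family, cons) in consensi.items():
        L = len(cons)
        mat = np.full((L, 4), 0.04)
        for i, base in enumerate(cons):
            mat[i, "ACGT".index(base)] = 0.88
        out.append(PWM.from_probabilities(mid, mat, family=family,
                                          pseudocount=pseudocount))
    return out


#: which planted motif goes into peaks/promoters of which temporal module
DEFAULT_MOTIF_PLAN = {
    "TEAD_syn": ("down_early", "down_late", "up_late"),
    "AP1_syn": ("down_early",),
    "EBOX_syn": ("up_early",),
    "MEF2_syn": ("up_late",),
    "KLF_syn": ("up_early", "transient"),
}


@dataclass
class SimulationConfig:
    n_timepoints: int = 6
    tp_spacing_days: int = 7
    rna_reps_per_tp: tuple = (6, 9)      # inclusive range, drawn per tp
    atac_reps_per_tp: int = 2
    dropped_atac_tp: int | None = 3      # 0-based index; mirrors P21 exclusion
    n_genes: int = 400
    n_peaks: int = 300
    module_profiles: dict | None = None    # defaults to default_profiles(n_timepoints)
    frac_de: float = 0.22
    nb_dispersion: tuple = (0.05, 0.15)
    rin_effect: float = 0.15             # per RIN unit on log-mean counts
    rin_range: tuple = (6.7, 10.0)
    linked_frac: float = 0.6
    pos_link_frac: float = 0.62          # of linked peaks, fraction positive
    baseline_log_mean: tuple = (3.0, 6.5)
    libsize_sigma: float = 0.25
    peak_window: int = 500
    promoter_halfwidth: int = 1000
    gene_spacing: int = 20_000
    gene_length: int = 5_000
    n_irreproducible: int = 30
    n_spurious: int = 12
    motif_library: list = field(default_factory=builtin_motifs)
    motif_plan: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_PLAN))
    motif_offset_sd: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.module_profiles is None:
            self.module_profiles = default_profiles(self.n_timepoints)
        if (self.dropped_atac_tp is not None
                and not 0 <= self.dropped_atac_tp < self.n_timepoints):
            self.dropped_atac_tp = None

    def validate(self) -> None:
        if min(self.n_timepoints, self.n_genes, self.n_peaks,
               self.atac_reps_per_tp) <= 0:
            raise ValueError("all counts must be positive")
        for name, vec in self.module_profiles.items():
            if len(vec) != self.n_timepoints:
                raise ValueError(
                    f"profile '{name}' has length {len(vec)}, "
                    f"expected n_timepoints={self.n_timepoints}")
        for frac, name in ((self.frac_de, "frac_de"),
                           (self.linked_frac, "linked_frac"),
                           (self.pos_link_frac, "pos_link_frac")):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion[0] <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def timepoints(self) -> list:
        return [f"P{self.tp_spacing_days * i}" for i in range(self.n_timepoints)]


@dataclass
class Experiment:
    """The full synthetic study bundle produced by :func:`simulate_experiment`."""

    config: SimulationConfig
    rna_counts: pd.DataFrame
    rna_samples: pd.DataFrame
    atac_counts: pd.DataFrame
    atac_samples: pd.DataFrame
    peak_calls: pd.DataFrame
    blacklist: pd.DataFrame
    control_peaks: pd.DataFrame
    genes: pd.DataFrame          # gene + exon rows, 0-based half-open
    peak_windows: dict           # peak id -> sequence (peak_window bp, summit-centered)
    promoter_windows: dict       # gene id -> sequence around TSS
    pwms: list
    gene_truth: pd.DataFrame
    peak_truth: pd.DataFrame
    tf_map: dict                 # motif id -> factor gene id

    def write(self, outdir) -> None:
        """Serialize every component in its plain-text interchange format."""
        import pathlib

        from . import io as tio

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tio.write_counts_tsv(self.rna_counts, out / "rna_counts.tsv")
        tio.write_sample_sheet(self.rna_samples, out / "rna_samples.tsv")
        tio.write_counts_tsv(self.atac_counts, out / "atac_counts.tsv")
        tio.write_sample_sheet(self.atac_samples, out / "atac_samples.tsv")
        tio.write_narrowpeak(self.peak_calls, out / "peak_calls.narrowPeak",
                             extra_cols=("timepoint", "replicate"))
        tio.write_bed(self.blacklist, out / "blacklist.bed")
        tio.write_bed(self.control_peaks, out / "naked_dna_peaks.bed")
        tio.write_gtf_lite(self.genes, out / "genes.gtf")
        tio.write_fasta(self.peak_windows, out / "peak_windows.fa")
        tio.write_fasta(self.promoter_windows, out / "promoter_windows.fa")
        self.gene_truth.to_csv(out / "gene_truth.tsv", sep="\t", index=False)
        self.peak_truth.to_csv(out / "peak_truth.tsv", sep="\t", index=False)
        with open(out / "pwms.jaspar", "w") as fh:
            for pwm in self.pwms:
                fh.write(pwm.to_jaspar() + "\n")


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _nb_draw(rng, mean, alpha):
    """NB2 draw with mean ``mean`` and dispersion ``alpha`` (var = m + a m^2)."""
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def simulate_experiment(config: SimulationConfig) -> Experiment:
    config.validate()
    rng = np.random.default_rng(config.seed)
    tps = config.timepoints
    profiles = {k: np.asarray(v, dtype=float) for k, v in config.module_profiles.items()}
    profile_names = list(profiles)

    # --- gene models along one chromosome, desert region at the far end ----
    n_g = config.n_genes
    gene_ids = [f"gene_{i:04d}" for i in range(n_g)]
    starts = 50_000 + config.gene_spacing * np.arange(n_g)
    strands = np.where(np.arange(n_g) % 2 == 0, "+", "-")
    ends = starts + config.gene_length
    tss = np.where(strands == "+", starts, ends - 1)
    gene_rows = []
    for i, gid in enumerate(gene_ids):
        gene_rows.append(("chr1", "gene", int(starts[i]), int(ends[i]), strands[i], gid))
        gene_rows.append(("chr1", "exon", int(starts[i]), int(starts[i]) + 1000, strands[i], gid))
        gene_rows.append(("chr1", "exon", int(ends[i]) - 1000, int(ends[i]), strands[i], gid))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "feature", "start", "end",
                                             "strand", "gene_id"])
    desert_start = int(ends[-1]) + 100_000

    # --- gene truth: DE assignment over module profiles -------------------
    n_de = int(round(config.frac_de * n_g))
    de_idx = rng.choice(n_g, size=n_de, replace=False)
    gene_module = np.array(["flat"] * n_g, dtype=object)
    gene_module[de_idx] = [profile_names[i % len(profile_names)]
                           for i in range(n_de)]
    gene_truth = pd.DataFrame({
        "gene_id": gene_ids, "module": gene_module,
        "is_de": gene_module != "flat",
    })  # per-gene dispersion appended below once drawn

    # --- RNA samples and counts ------------------------------------------
    lo, hi = config.rna_reps_per_tp
    reps_per_tp = rng.integers(lo, hi + 1, size=config.n_timepoints)
    sample_rows = []
    for ti, tp in enumerate(tps):
        for r in range(reps_per_tp[ti]):
            sample_rows.append((f"rna_{tp}_r{r + 1}", tp,
                                float(rng.uniform(*config.rin_range)),
                                rng.choice(["F", "M"]),
                                rng.choice(["pool1", "pool2", "pool3"])))
    rna_samples = pd.DataFrame(sample_rows,
                               columns=["sample", "timepoint", "RIN", "sex", "pool"]
                               ).set_index("sample")
    rna_samples["timepoint"] = pd.Categorical(rna_samples["timepoint"],
                                              categories=tps, ordered=True)
    tp_index = rna_samples["timepoint"].cat.codes.to_numpy()
    rin = rna_samples["RIN"].to_numpy()
    rin_centered = rin - rin.mean()
    libsize = np.exp(rng.normal(0.0, config.libsize_sigma, size=len(rna_samples)))

    base = rng.uniform(*config.baseline_log_mean, size=n_g)
    disp_g = rng.uniform(*config.nb_dispersion, size=n_g)
    rna = np.empty((n_g, len(rna_samples)), dtype=np.int64)
    for i in range(n_g):
        prof = profiles.get(gene_module[i], np.zeros(config.n_timepoints))
        logmu = (base[i] + prof[tp_index]
                 + config.rin_effect * rin_centered + np.log(libsize))
        rna[i] = _nb_draw(rng, np.exp(logmu), disp_g[i])
    rna_counts = pd.DataFrame(rna, index=gene_ids, columns=rna_samples.index)
    gene_truth["dispersion"] = disp_g

    # --- ATAC samples -----------------------------------------------------
    atac_tp_idx = [i for i in range(config.n_timepoints)
                   if i != config.dropped_atac_tp]
    atac_rows = [(f"atac_{tps[ti]}_r{r + 1}", tps[ti])
                 for ti in atac_tp_idx for r in range(config.atac_reps_per_tp)]
    atac_samples = pd.DataFrame(atac_rows, columns=["sample", "timepoint"]
                                ).set_index("sample")
    atac_samples["timepoint"] = pd.Categorical(
        atac_samples["timepoint"], categories=[tps[i] for i in atac_tp_idx],
        ordered=True)
    atac_tp_codes = atac_samples["timepoint"].cat.codes.to_numpy()
    atac_tp_global = np.array(atac_tp_idx)[atac_tp_codes]  # index into full tp axis
    atac_libsize = np.exp(rng.normal(0.0, config.libsize_sigma,
                                     size=len(atac_samples)))

    # --- peaks: placement, linkage, truth ---------------------------------
    n_p = config.n_peaks
    peak_ids = [f"peak_{i:04d}" for i in range(n_p)]
    n_linked = int(round(config.linked_frac * n_p))
    de_gene_pos = np.flatnonzero(gene_truth["is_de"].to_numpy())
    if n_linked > 0 and len(de_gene_pos) == 0:
        raise ValueError("cannot plant linked peaks with frac_de=0; "
                         "set linked_frac=0 for a null study")
    summits = np.empty(n_p, dtype=np.int64)
    linked_gene = np.array([""] * n_p, dtype=object)
    corr_sign = np.zeros(n_p, dtype=np.int64)
    half = config.peak_window // 2
    for p in range(n_p):
        if p < n_linked:
            g = int(rng.choice(de_gene_pos))
            linked_gene[p] = gene_ids[g]
            corr_sign[p] = 1 if rng.random() < config.pos_link_frac else -1
            offset = int(rng.integers(1_500, 6_000)) * (1 if rng.random() < 0.5 else -1)
            summits[p] = tss[g] + offset
        elif rng.random() < 0.8:
            # intergenic but within annotation range: midway between genes
            g = int(rng.integers(0, n_g - 1))
            summits[p] = (tss[g] + tss[g + 1]) // 2 + int(rng.integers(-1_000, 1_000))
        else:
            # gene desert, > 50 kb from every TSS
            summits[p] = desert_start + 60_000 + int(rng.integers(0, 200_000))

    # peak module follows the linked gene's module (possibly inverted)
    peak_module = np.array(["flat"] * n_p, dtype=object)
    gene_mod_by_id = dict(zip(gene_ids, gene_module))
    for p in range(n_linked):
        peak_module[p] = gene_mod_by_id[linked_gene[p]]

    # --- ATAC reads-in-peaks counts ---------------------------------------
    atac_base = rng.uniform(*config.baseline_log_mean, size=n_p)
    disp_p = rng.uniform(*config.nb_dispersion, size=n_p)
    atac = np.empty((n_p, len(atac_samples)), dtype=np.int64)
    for p in range(n_p):
        prof = profiles.get(peak_module[p], np.zeros(config.n_timepoints))
        shape = prof[atac_tp_global]
        if corr_sign[p] < 0:
            shape = shape.max() - shape
        logmu = atac_base[p] + shape + np.log(atac_libsize)
        atac[p] = _nb_draw(rng, np.exp(logmu), disp_p[p])
    atac_counts = pd.DataFrame(atac, index=peak_ids, columns=atac_samples.index)

    # --- per-replicate narrowPeak calls -----------------------------------
    call_rows = []
    for p in range(n_p):
        for ti in atac_tp_idx:
            for r in range(config.atac_reps_per_tp):
                w = int(rng.integers(300, 800))
                jitter = int(rng.integers(-25, 26))
                s = summits[p] + jitter
                start = max(0, s - w // 2)
                call_rows.append(("chr1", start, start + w, s,
                                  float(rng.uniform(50, 1000)),
                                  tps[ti], f"rep{r + 1}", peak_ids[p], "true"))
    # irreproducible peaks: one replicate of one timepoint only
    for k in range(config.n_irreproducible):
        s = desert_start + 400_000 + 5_000 * k
        ti = atac_tp_idx[int(rng.integers(len(atac_tp_idx)))]
        r = int(rng.integers(config.atac_reps_per_tp))
        call_rows.append(("chr1", s - 200, s + 200, s,
                          float(rng.uniform(50, 1000)),
                          tps[ti], f"rep{r + 1}", f"irr_{k:03d}", "irreproducible"))
    # spurious peaks inside blacklist / naked-DNA control regions
    bl_rows, ctrl_rows = [], []
    spur_base = desert_start + 700_000
    for k in range(config.n_spurious):
        s = spur_base + 4_000 * k
        target = bl_rows if k % 2 == 0 else ctrl_rows
        target.append(("chr1", s - 500, s + 500))
        for ti in atac_tp_idx:
            for r in range(config.atac_reps_per_tp):
                call_rows.append(("chr1", s - 150, s + 150, s,
                                  float(rng.uniform(50, 1000)),
                                  tps[ti], f"rep{r + 1}", f"spur_{k:03d}", "spurious"))
    peak_calls = pd.DataFrame(call_rows, columns=[
        "chrom", "start", "end", "summit", "score", "timepoint", "replicate",
        "name", "provenance"])
    blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])
    control_peaks = pd.DataFrame(ctrl_rows, columns=["chrom", "start", "end"])

    # --- sequences and planted motifs -------------------------------------
    pwms = list(config.motif_library)
    pwm_by_id = {m.motif_id: m for m in pwms}
    peak_windows = {pid: _random_seq(rng, config.peak_window) for pid in peak_ids}
    prom_w = 2 * config.promoter_halfwidth
    promoter_windows = {gid: _random_seq(rng, prom_w) for gid in gene_ids}

    planted = {pid: [] for pid in peak_ids}
    placements = []
    module_by_gene = dict(zip(gene_ids, gene_module))
    prom_placements = []
    for mid, modules in config.motif_plan.items():
        if mid not in pwm_by_id:
            continue
        for p in range(n_p):
            if peak_module[p] in modules:
                off = int(np.clip(rng.normal(0.0, config.motif_offset_sd),
                                  -half + len(pwm_by_id[mid]), half - len(pwm_by_id[mid])))
                strand = "+" if rng.random() < 0.5 else "-"
                placements.append((peak_ids[p], mid, off, strand))
                planted[peak_ids[p]].append((mid, off, strand))
        for gi, gid in enumerate(gene_ids):
            if module_by_gene[gid] in modules:
                off = int(np.clip(rng.normal(0.0, 150.0),
                                  -config.promoter_halfwidth + len(pwm_by_id[mid]),
                                  config.promoter_halfwidth - len(pwm_by_id[mid])))
                prom_placements.append((gid, mid, off, "+"))
    peak_windows = plant_motifs(peak_windows, pwm_by_id, placements,
                                center_relative=True)
    promoter_windows = plant_motifs(promoter_windows, pwm_by_id, prom_placements,
                                    center_relative=True)

    # each motif's transcription factor mapped onto a simulated (expressed) gene
    tf_map = {m.motif_id: gene_ids[i] for i, m in enumerate(pwms)}

    peak_truth = pd.DataFrame({
        "peak_id": peak_ids,
        "chrom": "chr1",
        "summit": summits,
        "linked_gene": linked_gene,
        "corr_sign": corr_sign,
        "module": peak_module,
        "planted_motifs": [";".join(f"{m}@{o}{s}" for m, o, s in planted[pid])
                           for pid in peak_ids],
    })
    return Experiment(
        config=config, rna_counts=rna_counts, rna_samples=rna_samples,
        atac_counts=atac_counts, atac_samples=atac_samples,
        peak_calls=peak_calls, blacklist=blacklist, control_peaks=control_peaks,
        genes=genes, peak_windows=peak_windows,
        promoter_windows=promoter_windows, pwms=pwms,
        gene_truth=gene_truth, peak_truth=peak_truth, tf_map=tf_map,
    )


def plant_motifs(sequences: dict, pwms: dict, placements,
                 center_relative: bool = True) -> dict:
    """Insert PWM consensus strings into background sequences.

    ``placements`` is an iterable of (seq_id, motif_id, offset, strand).
    With ``center_relative=True`` the offset is relative to the sequence
    midpoint (the peak summit / TSS convention used throughout); the motif
    is written starting at that position.  Minus-strand placements insert
    the reverse complement.
    """
    out = dict(sequences)
    for seq_id, motif_id, offset, strand in placements:
        seq = out[seq_id]
        cons = pwms[motif_id].consensus if not isinstance(pwms[motif_id], str) \
            else pwms[motif_id]
        if strand == "-":
            cons = revcomp(cons)
        pos = offset + (len(seq) // 2 if center_relative else 0)
        if pos < 0 or pos + len(cons) > len(seq):
            raise ValueError(
                f"placement of {motif_id} at offset {offset} does not fit in "
                f"sequence {seq_id} (length {len(seq)})")
        out[seq_id] = seq[:pos] + cons + seq[pos + len(cons):]
    return out


def null_config(seed: int = 0, n_genes: int = 2000, **overrides) -> SimulationConfig:
    """A no-time-effect configuration (RIN effect retained) for calibration."""
    cfg = SimulationConfig(seed=seed, n_genes=n_genes, frac_de=0.0,
                           linked_frac=0.0, n_peaks=20)
    return replace(cfg, **overrides)
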