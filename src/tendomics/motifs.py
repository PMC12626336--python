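"""PWM motif scanning and module-wise motif enrichment.

Scanning is plain log-odds scoring: score(window) = sum over positions of
log2(p_pos(base) / bg(base)), evaluated on both strands; a hit is any
window scoring at or above the motif's threshold (by default 60% of the
motif's maximal attainable score).  Enrichment is a one-sided
hypergeometric test on the peak-level (or gene-level) hit indicator, with
BH adjustment across motifs; family-level results pool member hits into a
single indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import adjust_bh

__all__ = [
    "PWM", "read_jaspar", "scan_pwm", "scan_library",
    "summit_distance_profile", "motif_enrichment", "promoter_enrichment",
    "family_aggregate", "expressed_factor_gate",
]

_ALPHABET = "ACGT"
_DEFAULT_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """Position probability matrix with background and a score threshold."""

    motif_id: str
    probs: np.ndarray                    # (length, 4) over A,C,G,T
    family: str = "unassigned"
    background: np.ndarray = field(default_factory=lambda: _DEFAULT_BG.copy())
    threshold_frac: float = 0.6

    @classmethod
    def from_probabilities(cls, motif_id, probs, family="unassigned",
                           pseudocount=0.01, background=None,
                           threshold_frac=0.6) -> "PWM":
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if probs.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        probs = probs + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        bg = _DEFAULT_BG.copy() if background is None else np.asarray(background, float)
        return cls(motif_id=motif_id, probs=probs, family=family,
                   background=bg, threshold_frac=threshold_frac)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def threshold(self) -> float:
        return self.threshold_frac * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(motif_id=self.motif_id, probs=self.probs[::-1, ::-1].copy(),
                   family=self.family, background=self.background[::-1].copy(),
                   threshold_frac=self.threshold_frac)

    def to_jaspar(self) -> str:
        lines = [f">{self.motif_id} {self.family}"]
        for bi, base in enumerate(_ALPHABET):
            vals = " ".join(f"{v:.4f}" for v in self.probs[:, bi])
            lines.append(f"{base} [ {vals} ]")
        return "\n".join(lines)


def read_jaspar(path, families: dict | None = None, pseudocount: float = 0.01,
                threshold_frac: float = 0.6) -> list:
    """Read a JASPAR-format PWM file via Bio.motifs.

    ``families`` optionally maps motif id -> family label; a family token
    after the id on the header line is used otherwise.
    """
    from Bio import motifs as bio_motifs

    out = []
    header_families = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith(">"):
            parts = line[1:].split()
            if len(parts) >= 2:
                header_families[parts[0]] = parts[1]
    from io import StringIO

    for m in bio_motifs.parse(StringIO(text), "jaspar"):
        counts = np.array([[m.counts[b][i] for b in _ALPHABET]
                           for i in range(m.length)], dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        mid = m.matrix_id or m.name
        family = (families or {}).get(mid) or header_families.get(mid, "unassigned")
        out.append(PWM.from_probabilities(mid, probs, family=family,
                                          pseudocount=pseudocount,
                                          threshold_frac=threshold_frac))
    return out


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_ALPHABET):
        code[ord(b)] = i
    return code[arr]


def _scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; windows containing N -> -inf."""
    L = lom.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([lom.T, np.full((1, L), -np.inf)])  # row 4 = N
    out = np.zeros(n)
    for j in range(L):
        out += padded[codes[j : j + n], j]
    return out


def scan_pwm(sequences: dict, pwm: PWM, center_relative: bool = True) -> pd.DataFrame:
    """Scan summit/TSS-centered windows with one PWM on both strands.

    Returns hits as a frame (seq_id, motif_id, offset, strand, score) where
    ``offset`` is the hit's start position relative to the window midpoint
    (or to the window start with ``center_relative=False``).  Overlapping
    same-strand hits within 1 bp are collapsed to the best-scoring one.
    """
    lom = pwm.log_odds
    thr = pwm.threshold
    rows = []
    for sid, seq in sequences.items():
        codes = _encode(seq)
        mid = len(seq) // 2 if center_relative else 0
        for strand, mat in (("+", lom), ("-", pwm.reverse_complement().log_odds)):
            s = _scores(codes, mat)
            idx = np.flatnonzero(s >= thr)
            for pos in _collapse(idx, s):
                rows.append((sid, pwm.motif_id, int(pos) - mid, strand,
                             float(s[pos])))
    return pd.DataFrame(rows, columns=["seq_id", "motif_id", "offset",
                                       "strand", "score"])


def _collapse(idx: np.ndarray, scores: np.ndarray):
    """Merge runs of hit positions within 1 bp, keeping the best scorer."""
    if idx.size == 0:
        return []
    out = []
    run = [idx[0]]
    for pos in idx[1:]:
        if pos - run[-1] <= 1:
            run.append(pos)
        else:
            out.append(max(run, key=lambda p: (scores[p], -p)))
            run = [pos]
    out.append(max(run, key=lambda p: (scores[p], -p)))
    return out


def scan_library(sequences: dict, pwms, center_relative: bool = True) -> pd.DataFrame:
    frames = [scan_pwm(sequences, p, center_relative) for p in pwms]
    if not frames:
        return pd.DataFrame(columns=["seq_id", "motif_id", "offset", "strand", "score"])
    return pd.concat(frames, ignore_index=True)


def summit_distance_profile(hits: pd.DataFrame, bin_width: int = 25,
                            max_dist: int = 250) -> tuple[pd.Series, float]:
    """Histogram of |offset from summit| plus the fraction within 100 bp."""
    if hits.empty:
        edges = np.arange(0, max_dist + bin_width, bin_width)
        empty = pd.Series(0, index=pd.IntervalIndex.from_breaks(edges))
        return empty, float("nan")
    d = hits["offset"].abs().to_numpy()
    edges = np.arange(0, max_dist + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(d, 0, max_dist - 1), bins=edges)
    hist = pd.Series(counts, index=pd.IntervalIndex.from_breaks(edges))
    frac100 = float((d <= 100).mean())
    return hist, frac100


def _hyper_table(fg_with, fg_total, uni_with, uni_total):
    """One-sided hypergeometric upper tail P(X >= fg_with)."""
    return float(scipy.stats.hypergeom.sf(fg_with - 1, uni_total, uni_with,
                                          fg_total))


def motif_enrichment(foreground, background, hits: pd.DataFrame, *,
                     padj_gate: float = 0.01, q_gate: float = 0.05) -> pd.DataFrame:
    """Per-motif over-representation of hits in foreground vs background peaks.

    The universe is foreground + background; the statistic is the one-sided
    hypergeometric tail on the count of foreground peaks carrying >= 1 hit.
    ``q`` defaults to the BH-adjusted p (see docs/methods.md).
    """
    fg = list(dict.fromkeys(foreground))
    bg = [b for b in dict.fromkeys(background) if b not in set(fg)]
    if not fg:
        raise ValueError("empty foreground set")
    universe = fg + bg
    uni_set = set(universe)
    rows = []
    for motif_id, sub in hits.groupby("motif_id", sort=True):
        with_hit = set(sub["seq_id"]) & uni_set
        k = len(with_hit & set(fg))
        K = len(with_hit)
        p = _hyper_table(k, len(fg), K, len(universe))
        rows.append((motif_id, k, len(fg), K, len(universe), p))
    res = pd.DataFrame(rows, columns=["motif_id", "fg_with_hit", "fg_size",
                                      "universe_with_hit", "universe_size", "p"])
    res["padj"] = adjust_bh(res["p"].to_numpy())
    res["q"] = res["padj"]
    res["significant"] = (res["padj"] < padj_gate) & (res["q"] < q_gate)
    return res.set_index("motif_id")


def promoter_enrichment(module_genes, universe_genes, promoter_hits: pd.DataFrame,
                        **kw) -> pd.DataFrame:
    """Motif over-representation in the promoters of a module's target genes.

    Identical statistic to :func:`motif_enrichment` with genes as units;
    universe = all genes under consideration.
    """
    module_genes = list(dict.fromkeys(module_genes))
    universe_genes = list(dict.fromkeys(universe_genes))
    if len(universe_genes) < 2:
        raise ValueError("degenerate gene universe")
    background = [g for g in universe_genes if g not in set(module_genes)]
    return motif_enrichment(module_genes, background, promoter_hits, **kw)


def both_distal_and_promoter(peak_enrich: pd.DataFrame,
                             promoter_enrich: pd.DataFrame) -> list:
    """Motifs significant in both the distal-peak and promoter tests."""
    a = set(peak_enrich.index[peak_enrich["significant"]])
    b = set(promoter_enrich.index[promoter_enrich["significant"]])
    return sorted(a & b)


def family_aggregate(foreground, background, hits: pd.DataFrame,
                     family_map: dict, *, padj_gate: float = 0.01,
                     q_gate: float = 0.05) -> pd.DataFrame:
    """Family-level enrichment: a unit counts if any member motif hits it.

    Motifs absent from ``family_map`` are grouped under "unassigned" with a
    warning; empty families are skipped.
    """
    hits = hits.copy()
    missing = sorted(set(hits["motif_id"]) - set(family_map))
    if missing:
        warnings.warn(f"motifs missing from family map: {missing}; "
                      "grouped as 'unassigned'")
    hits["family"] = hits["motif_id"].map(lambda m: family_map.get(m, "unassigned"))
    fg = list(dict.fromkeys(foreground))
    bg = [b for b in dict.fromkeys(background) if b not in set(fg)]
    if not fg:
        raise ValueError("empty foreground set")
    universe = fg + bg
    uni_set = set(universe)
    rows = []
    for family, sub in hits.groupby("family", sort=True):
        if sub.empty:
            continue
        with_hit = set(sub["seq_id"]) & uni_set
        k = len(with_hit & set(fg))
        K = len(with_hit)
        p = _hyper_table(k, len(fg), K, len(universe))
        # best member = member with minimal per-motif enrichment p
        member_p = {}
        for mid, msub in sub.groupby("motif_id"):
            mwith = set(msub["seq_id"]) & uni_set
            member_p[mid] = _hyper_table(len(mwith & set(fg)), len(fg),
                                         len(mwith), len(universe))
        best = min(member_p, key=lambda m: (member_p[m], m))
        rows.append((family, k, len(fg), K, len(universe), p, best))
    res = pd.DataFrame(rows, columns=["family", "fg_with_hit", "fg_size",
                                      "universe_with_hit", "universe_size",
                                      "p", "best_member"])
    res["padj"] = adjust_bh(res["p"].to_numpy())
    res["q"] = res["padj"]
    res["significant"] = (res["padj"] < padj_gate) & (res["q"] < q_gate)
    return res.set_index("family")


def expressed_factor_gate(enrichment: pd.DataFrame, tf_map: dict,
                          expression: pd.DataFrame,
                          min_count: float = 1.0) -> pd.DataFrame:
    """Keep enriched motifs whose transcription factor is expressed.

    A factor counts as expressed if its gene reaches ``min_count`` in at
    least one sample of the expression matrix.
    """
    keep = []
    for motif_id in enrichment.index:
        gene = tf_map.get(motif_id)
        expressed = (gene in expression.index
                     and float(expression.loc[gene].max()) >= min_count)
        keep.append(bool(enrichment.loc[motif_id, "significant"]) and expressed)
    out = enrichment.copy()
    out["factor_expressed"] = [
        tf_map.get(m) in expression.index
        and float(expression.loc[tf_map[m]].max()) >= min_count
        for m in enrichment.index
    ]
    return out[np.asarray(keep)]
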