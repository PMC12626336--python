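"""Gene-set over-representation analysis and small-sample qPCR statistics.

ORA is a one-sided hypergeometric test of module/gene-set overlap against
a detected-genes universe, BH-adjusted, gated at padj < 0.01 and q < 0.05.
The qPCR path implements relative quantification by the delta-delta-Ct
method (reference gene Ppia in the source assay) with group comparisons by
Kruskal-Wallis followed by Dunn's pairwise z test under BH correction;
tests operate on the delta-Ct values.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import adjust_bh

__all__ = ["ora", "ddct", "kw_dunn"]


def ora(module_genes, gene_sets: dict, universe, *, padj_gate: float = 0.01,
        q_gate: float = 0.05) -> pd.DataFrame:
    """Over-representation of each gene set in a module.

    Hypergeometric upper tail on |module ∩ set| with universe size N,
    set size K, module size n; reports the gene ratio (overlap / module
    size) used for bubble sizing in enrichment plots.
    """
    module = set(module_genes)
    universe = set(universe)
    if not module:
        raise ValueError("empty module")
    if not module <= universe:
        raise ValueError("module genes must be contained in the universe")
    N, n = len(universe), len(module)
    rows = []
    for name, genes in gene_sets.items():
        hit_set = set(genes) & universe
        K = len(hit_set)
        k = len(hit_set & module)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, n, K, N, k / n, p))
    res = pd.DataFrame(rows, columns=["gene_set", "overlap", "module_size",
                                      "set_size", "universe_size",
                                      "gene_ratio", "p"]).set_index("gene_set")
    res["padj"] = adjust_bh(res["p"].to_numpy())
    res["q"] = res["padj"]
    res["significant"] = (res["padj"] < padj_gate) & (res["q"] < q_gate)
    return res


def ddct(ct: pd.DataFrame, calibrator: str, target_col: str = "ct_target",
         reference_col: str = "ct_reference",
         group_col: str = "timepoint") -> pd.DataFrame:
    """Delta-delta-Ct relative expression.

    Technical replicates (rows sharing sample id and group) are collapsed
    by mean Ct first.  Per sample: dCt = Ct_target - Ct_reference;
    ddCt = dCt - mean dCt of the calibrator group; fold = 2^(-ddCt).
    Samples missing the reference Ct are dropped with a warning.
    Downstream statistics should use the ``dct`` column.
    """
    import warnings

    df = ct.copy()
    missing = df[reference_col].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} samples without a reference Ct")
        df = df[~missing]
    df = (df.groupby(["sample", group_col], sort=False, observed=True)
          [[target_col, reference_col]].mean().reset_index())
    df["dct"] = df[target_col] - df[reference_col]
    cal = df.loc[df[group_col] == calibrator, "dct"]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator!r} absent")
    df["ddct"] = df["dct"] - cal.mean()
    df["fold_change"] = 2.0 ** (-df["ddct"])
    return df


def kw_dunn(values_by_group: dict) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis test plus Dunn's pairwise post hoc under BH.

    ``values_by_group`` maps group label -> 1-D array of observations
    (each group needs >= 2).  Returns (H, p_overall, pairwise frame with
    z, p, padj).  Ties are handled by midranks; Dunn's z uses the
    tie-corrected variance

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
        T = sum(t^3 - t) / (12 (N - 1)).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    H, p_overall = scipy.stats.kruskal(*groups.values())

    pooled = np.concatenate(list(groups.values()))
    N = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    offsets = np.cumsum([0] + [v.size for v in groups.values()])
    rank_means = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                  for i, g in enumerate(groups)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - T

    rows = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(base_var * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (rank_means[a] - rank_means[b]) / se
        rows.append((a, b, float(z), 2.0 * float(scipy.stats.norm.sf(abs(z)))))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    pairwise["padj"] = adjust_bh(pairwise["p"].to_numpy())
    return float(H), float(p_overall), pairwise
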