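"""Consensus construction, counting and annotation against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from tendomics.peaks import (annotate_peaks, build_consensus, count_in_peaks,
                             differential_accessibility, filter_spurious)


def _random_calls(rng, n=50, n_tp=2, n_rep=2, span=20_000):
    rows = []
    for i in range(n):
        start = int(rng.integers(0, span))
        w = int(rng.integers(100, 600))
        rows.append(("chr1", start, start + w,
                     start + int(rng.integers(0, w)),
                     float(rng.uniform(1, 100)),
                     f"T{int(rng.integers(n_tp))}",
                     f"rep{int(rng.integers(n_rep)) + 1}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit",
                                       "score", "timepoint", "replicate"])


def _brute_consensus(calls: pd.DataFrame, width=500):
    """Independent oracle: union-find over pairwise overlaps, then the
    both-replicates-of-some-timepoint rule, then fixed-width re-centering."""
    idx = list(calls.index)
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in idx:
        for j in idx:
            if i < j:
                a, b = calls.loc[i], calls.loc[j]
                if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                    parent[find(i)] = find(j)
    comps = {}
    for i in idx:
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        sub = calls.loc[members]
        ok = False
        for _, tp_sub in sub.groupby("timepoint"):
            if tp_sub["replicate"].nunique() >= 2:
                ok = True
        if not ok:
            continue
        best = sub.sort_values(["score", "summit"], ascending=[False, True]).iloc[0]
        s = int(best["summit"])
        out.append((best["chrom"], s - width // 2, s - width // 2 + width, s))
    return sorted(out)


class TestFilterSpurious:
    def test_empty_filters_are_identity(self, rng):
        calls = _random_calls(rng, 20)
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        out = filter_spurious(calls, empty, empty)
        pd.testing.assert_frame_equal(out, calls)

    def test_abutting_interval_is_retained(self):
        calls = pd.DataFrame([("chr1", 100, 200, 150, 1.0, "T0", "rep1")],
                             columns=["chrom", "start", "end", "summit",
                                      "score", "timepoint", "replicate"])
        bl = pd.DataFrame([("chr1", 200, 300)], columns=["chrom", "start", "end"])
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        assert len(filter_spurious(calls, bl, empty)) == 1
        bl2 = pd.DataFrame([("chr1", 199, 300)], columns=["chrom", "start", "end"])
        assert len(filter_spurious(calls, bl2, empty)) == 0

    def test_matches_bruteforce_overlap_oracle(self, rng):
        calls = _random_calls(rng, 200)
        bl = pd.DataFrame(
            [("chr1", int(s), int(s) + int(rng.integers(50, 400)))
             for s in rng.integers(0, 20_000, size=15)],
            columns=["chrom", "start", "end"])
        ctrl = pd.DataFrame(
            [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 20_000, size=10)],
            columns=["chrom", "start", "end"])
        out = filter_spurious(calls, bl, ctrl)
        bad = pd.concat([bl, ctrl])
        survivors = [
            i for i, row in calls.iterrows()
            if not any((row["start"] < b.end) and (b.start < row["end"])
                       for b in bad.itertuples())
        ]
        assert list(out.index) == survivors

    def test_idempotent(self, rng):
        calls = _random_calls(rng, 100)
        bl = pd.DataFrame([("chr1", 5000, 9000)], columns=["chrom", "start", "end"])
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        once = filter_spurious(calls, bl, empty)
        twice = filter_spurious(once, bl, empty)
        pd.testing.assert_frame_equal(once, twice)

    def test_warns_on_chromosome_mismatch(self, rng):
        calls = _random_calls(rng, 5)
        bl = pd.DataFrame([("chrX", 0, 100)], columns=["chrom", "start", "end"])
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        with pytest.warns(UserWarning, match="chromosome"):
            filter_spurious(calls, bl, empty)


class TestBuildConsensus:
    def test_single_replicate_peak_excluded(self):
        calls = pd.DataFrame([("chr1", 1000, 1400, 1200, 5.0, "T0", "rep1")],
                             columns=["chrom", "start", "end", "summit",
                                      "score", "timepoint", "replicate"])
        calls2 = pd.concat([calls, pd.DataFrame(
            [("chr1", 5000, 5400, 5200, 5.0, "T0", "rep2")], columns=calls.columns)],
            ignore_index=True)
        out = build_consensus(calls2)
        assert len(out) == 0

    def test_identical_peak_in_both_replicates_yields_one_500bp_peak(self):
        calls = pd.DataFrame(
            [("chr1", 1000, 1400, 1200, 5.0, "T0", "rep1"),
             ("chr1", 1000, 1400, 1200, 7.0, "T0", "rep2")],
            columns=["chrom", "start", "end", "summit", "score",
                     "timepoint", "replicate"])
        out = build_consensus(calls)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["end"] - row["start"] == 500
        assert row["summit"] == 1200
        assert row["start"] == 1200 - 250

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        calls = _random_calls(rng, n=int(rng.integers(10, 50)))
        out = build_consensus(calls)
        got = sorted(zip(out["chrom"], out["start"], out["end"], out["summit"]))
        assert got == _brute_consensus(calls)

    def test_every_output_peak_is_500bp_with_dual_support(self, small_experiment):
        out = build_consensus(small_experiment.peak_calls)
        assert ((out["end"] - out["start"]) == 500).all()
        for support in out["support"]:
            pairs = [s.split(":") for s in support.split(";")]
            by_tp = {}
            for tp, rep in pairs:
                by_tp.setdefault(tp, set()).add(rep)
            assert any(len(reps) >= 2 for reps in by_tp.values())

    def test_single_replicate_timepoint_dropped_with_warning(self):
        calls = pd.DataFrame(
            [("chr1", 0, 400, 200, 1.0, "T0", "rep1"),
             ("chr1", 0, 400, 210, 2.0, "T0", "rep2"),
             ("chr1", 900, 1300, 1100, 9.0, "T1", "rep1")],
            columns=["chrom", "start", "end", "summit", "score",
                     "timepoint", "replicate"])
        with pytest.warns(UserWarning, match="single replicate"):
            out = build_consensus(calls)
        assert len(out) == 1 and out.iloc[0]["summit"] == 210


class TestCountInPeaks:
    def _peaks(self):
        return pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [100, 1000],
                             "end": [600, 1500], "peak_id": ["p1", "p2"]})

    def test_no_fragments_gives_zero_matrix(self):
        frags = {"r1": pd.DataFrame(columns=["chrom", "start", "end"])}
        out = count_in_peaks(frags, self._peaks())
        assert (out.to_numpy() == 0).all()

    def test_halfopen_midpoint_boundaries(self):
        # midpoints: 100 (at start, counted), 600 (at end, not counted)
        frags = {"r1": pd.DataFrame({"chrom": ["chr1", "chr1"],
                                     "start": [50, 550], "end": [150, 650]})}
        out = count_in_peaks(frags, self._peaks())
        assert out.loc["p1", "r1"] == 1

    def test_matches_bruteforce_midpoint_containment(self, rng):
        peaks = pd.DataFrame({
            "chrom": "chr1",
            "start": np.sort(rng.integers(0, 50_000, size=20)),
        })
        peaks["end"] = peaks["start"] + 500
        peaks["peak_id"] = [f"p{i}" for i in range(20)]
        starts = rng.integers(0, 50_000, size=1000)
        frags = {"r1": pd.DataFrame({"chrom": "chr1", "start": starts,
                                     "end": starts + rng.integers(50, 300, size=1000)})}
        out = count_in_peaks(frags, peaks)
        mids = (frags["r1"]["start"] + frags["r1"]["end"]) / 2.0
        for _, p in peaks.iterrows():
            brute = int(((mids >= p["start"]) & (mids < p["end"])).sum())
            assert out.loc[p["peak_id"], "r1"] == brute


class TestDifferentialAccessibility:
    def test_single_timepoint_rejected(self, small_experiment):
        counts = small_experiment.atac_counts.iloc[:5]
        samples = small_experiment.atac_samples
        one_tp = samples[samples["timepoint"] == samples["timepoint"].iloc[0]]
        with pytest.raises(ValueError, match="timepoint"):
            differential_accessibility(counts[one_tp.index], samples)

    def test_planted_da_recovered_and_null_controlled(self, small_experiment):
        exp = small_experiment
        res = differential_accessibility(exp.atac_counts, exp.atac_samples)
        sig = (res["padj"] < 0.05).fillna(False)
        truth = exp.peak_truth.set_index("peak_id")
        planted = truth["module"] != "flat"
        recall = (sig & planted).sum() / planted.sum()
        fdr = (sig & ~planted).sum() / max(int(sig.sum()), 1)
        assert recall >= 0.9
        # chi-square LRT asymptotics are mildly liberal at 2 replicates per
        # timepoint, so realized FDR sits somewhat above the nominal 5%
        assert fdr <= 0.10


class TestAnnotation:
    def _genes(self):
        rows = [
            ("chr1", "gene", 10_000, 15_000, "+", "gA"),
            ("chr1", "exon", 10_000, 11_000, "+", "gA"),
            ("chr1", "gene", 100_000, 105_000, "-", "gB"),
            ("chr1", "exon", 104_000, 105_000, "-", "gB"),
        ]
        return pd.DataFrame(rows, columns=["chrom", "feature", "start", "end",
                                           "strand", "gene_id"])

    def _peak(self, summit):
        return pd.DataFrame({"chrom": ["chr1"], "start": [summit - 250],
                             "end": [summit + 250], "summit": [summit],
                             "peak_id": ["p"]}).set_index("peak_id")

    def test_summit_at_tss_is_promoter_distance_zero(self):
        ann = annotate_peaks(self._peak(10_000), self._genes())
        row = ann.iloc[0]
        assert row["category"] == "promoter"
        assert row["tss_distance"] == 0
        assert row["nearest_gene"] == "gA"

    def test_minus_strand_tss_and_sign(self):
        # gB TSS at 104_999; summit 1 kb genomic-left of it = downstream (+)
        ann = annotate_peaks(self._peak(103_999), self._genes())
        row = ann.iloc[0]
        assert row["nearest_gene"] == "gB"
        assert row["tss_distance"] == 1000

    def test_beyond_50kb_unassigned_but_categorized(self):
        ann = annotate_peaks(self._peak(170_000), self._genes())
        row = ann.iloc[0]
        assert row["nearest_gene"] is None
        assert row["category"] == "distal intergenic"

    def test_matches_bruteforce_nearest_tss(self, rng):
        n_genes = 40
        starts = np.sort(rng.integers(0, 2_000_000, size=n_genes))
        strands = rng.choice(["+", "-"], size=n_genes)
        rows = [("chr1", "gene", int(s), int(s) + 3000, st, f"g{i:02d}")
                for i, (s, st) in enumerate(zip(starts, strands))]
        genes = pd.DataFrame(rows, columns=["chrom", "feature", "start", "end",
                                            "strand", "gene_id"])
        tss = np.where(strands == "+", starts, starts + 3000 - 1)
        summits = rng.integers(0, 2_000_000, size=100)
        peaks = pd.DataFrame({"chrom": "chr1", "start": summits - 250,
                              "end": summits + 250, "summit": summits,
                              "peak_id": [f"p{i}" for i in range(100)]}
                             ).set_index("peak_id")
        ann = annotate_peaks(peaks, genes)
        for pid, s in zip(peaks.index, summits):
            d = np.abs(int(s) - tss)
            best = np.lexsort(([f"g{i:02d}" for i in range(n_genes)], d))[0]
            expected = f"g{best:02d}" if d[best] <= 50_000 else None
            assert ann.loc[pid, "nearest_gene"] == expected
            if expected is not None:
                raw = int(s) - int(tss[best])
                signed = raw if strands[best] == "+" else -raw
                assert ann.loc[pid, "tss_distance"] == signed

    def test_category_partition_is_exhaustive(self, small_experiment):
        exp = small_experiment
        truth = exp.peak_truth
        peaks = pd.DataFrame({"chrom": truth["chrom"],
                              "start": truth["summit"] - 250,
                              "end": truth["summit"] + 250,
                              "summit": truth["summit"],
                              "peak_id": truth["peak_id"]}).set_index("peak_id")
        ann = annotate_peaks(peaks, exp.genes)
        assert len(ann) == len(peaks)
        assert ann["category"].isin([
            "promoter", "5'UTR", "3'UTR", "exon", "intron",
            "downstream", "distal intergenic"]).all()
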