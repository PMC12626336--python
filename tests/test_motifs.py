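"""PWM scanning, summit-distance profiles and motif enrichment exactness."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tendomics.motifs import (PWM, both_distal_and_promoter,
                              expressed_factor_gate, family_aggregate,
                              motif_enrichment, promoter_enrichment,
                              read_jaspar, scan_library, scan_pwm,
                              summit_distance_profile)
from tendomics.simulate import builtin_motifs, plant_motifs, revcomp


def _background_seqs(rng, n=50, length=200):
    return {f"s{i}": "".join(rng.choice(list("ACGT"), size=length))
            for i in range(n)}


@pytest.fixture(scope="module")
def tead():
    return next(m for m in builtin_motifs() if m.motif_id == "TEAD_syn")


class TestPWM:
    def test_probabilities_normalized_and_consensus(self, tead):
        assert np.allclose(tead.probs.sum(axis=1), 1.0)
        assert tead.consensus == "GGAATGTG"

    def test_uniform_pwm_scores_zero_everywhere(self, rng):
        uniform = PWM.from_probabilities("flat", np.full((6, 4), 0.25),
                                         pseudocount=0.0)
        assert uniform.max_score == pytest.approx(0.0)
        seqs = _background_seqs(rng, n=5)
        object.__setattr__(uniform, "threshold_frac", 1.0)
        hits = scan_pwm(seqs, uniform)
        # threshold 0 and all scores 0: every collapsed window position ties
        assert (hits["score"] == 0).all()

    def test_too_short_sequence_gives_no_hits(self, tead):
        assert scan_pwm({"tiny": "ACG"}, tead).empty

    def test_jaspar_roundtrip(self, tmp_path, tead):
        path = tmp_path / "m.jaspar"
        path.write_text(tead.to_jaspar() + "\n")
        back = read_jaspar(path)
        assert len(back) == 1
        assert back[0].family == "TEA"
        assert back[0].consensus == tead.consensus


class TestScanning:
    def test_planted_consensus_recovered_at_offset(self, rng, tead):
        seqs = _background_seqs(rng, n=100, length=500)
        placements = [(sid, "TEAD_syn", int(rng.integers(-100, 100)), "+")
                      for sid in seqs]
        seqs = plant_motifs(seqs, {"TEAD_syn": tead}, placements)
        hits = scan_pwm(seqs, tead)
        recovered = 0
        for sid, _, off, _ in placements:
            sub = hits[(hits["seq_id"] == sid) & (hits["strand"] == "+")]
            if np.any(np.abs(sub["offset"] - off) <= 2):
                recovered += 1
        assert recovered >= 95
        # the planted window scores the maximal attainable log-odds
        assert hits["score"].max() == pytest.approx(tead.max_score)

    def test_empty_pwm_set_scans_nothing(self, rng):
        assert scan_library(_background_seqs(rng, 5), []).empty

    def test_reverse_complement_symmetry(self, rng, tead):
        seqs = _background_seqs(rng, n=20, length=300)
        placements = [(sid, "TEAD_syn", 10, "+") for sid in seqs]
        seqs = plant_motifs(seqs, {"TEAD_syn": tead}, placements)
        fwd = scan_pwm(seqs, tead)
        rc = {sid: revcomp(s) for sid, s in seqs.items()}
        rev = scan_pwm(rc, tead)
        # identical hit multisets with strands flipped and offsets mirrored
        def key(df, L=len(tead)):
            # an L-long hit starting at offset o (from center of an even-length
            # window) maps to start -(o + L) with flipped strand
            return sorted(zip(df["seq_id"],
                              np.round(df["score"], 9),
                              [{"+": "-", "-": "+"}[s] for s in df["strand"]],
                              -(df["offset"] + L)))
        direct = sorted(zip(fwd["seq_id"], np.round(fwd["score"], 9),
                            fwd["strand"], fwd["offset"]))
        assert key(rev) == direct

    def test_minus_strand_plant_reported_on_minus(self, rng, tead):
        seqs = _background_seqs(rng, n=10, length=200)
        placements = [(sid, "TEAD_syn", -20, "-") for sid in seqs]
        seqs = plant_motifs(seqs, {"TEAD_syn": tead}, placements)
        hits = scan_pwm(seqs, tead)
        minus = hits[hits["strand"] == "-"]
        assert len(minus) >= 9
        assert (minus["offset"] == -20).sum() >= 9

    def test_n_bases_never_score(self, tead):
        hits = scan_pwm({"nn": "N" * 100}, tead)
        assert hits.empty


class TestSummitDistance:
    def test_all_at_summit_fraction_one(self):
        hits = pd.DataFrame({"seq_id": ["a", "b"], "motif_id": "m",
                             "offset": [0, 3], "strand": "+", "score": 1.0})
        _, frac = summit_distance_profile(hits)
        assert frac == 1.0

    def test_uniform_plant_fraction_near_two_fifths(self, rng):
        # |offset| uniform on [0, 250) -> P(|offset| <= 100) = 101/250
        offs = rng.integers(-249, 250, size=4000)
        hits = pd.DataFrame({"seq_id": "x", "motif_id": "m", "offset": offs,
                             "strand": "+", "score": 1.0})
        _, frac = summit_distance_profile(hits)
        assert frac == pytest.approx(101 / 250, abs=0.03)

    def test_empty_hits(self):
        hist, frac = summit_distance_profile(
            pd.DataFrame(columns=["seq_id", "motif_id", "offset", "strand",
                                  "score"]))
        assert hist.sum() == 0 and np.isnan(frac)


def _hyper_tail_bruteforce(k, N, K, n):
    """P(X >= k) by direct PMF summation."""
    from math import comb

    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x) / comb(N, n)
    return total


class TestEnrichment:
    def _hits(self, ids, motif="m1"):
        return pd.DataFrame({"seq_id": list(ids), "motif_id": motif,
                             "offset": 0, "strand": "+", "score": 1.0})

    def test_equal_hit_fractions_not_enriched(self):
        fg = [f"f{i}" for i in range(10)]
        bg = [f"b{i}" for i in range(10)]
        hits = self._hits(fg[:5] + bg[:5])
        res = motif_enrichment(fg, bg, hits)
        assert res.loc["m1", "p"] >= 0.5

    def test_small_case_matches_pmf_summation(self):
        # universe 20, foreground 5, 8 peaks with hits, all 5 fg among them
        fg = [f"f{i}" for i in range(5)]
        bg = [f"b{i}" for i in range(15)]
        hits = self._hits(fg + bg[:3])
        res = motif_enrichment(fg, bg, hits)
        assert res.loc["m1", "p"] == pytest.approx(
            _hyper_tail_bruteforce(5, 20, 8, 5), rel=1e-12)

    def test_exhaustive_sweep_universe_up_to_30(self):
        for N in (5, 12, 30):
            for n in (1, N // 3 + 1, N - 1):
                for K in (0, N // 2, N):
                    fg = [f"f{i}" for i in range(n)]
                    bg = [f"b{i}" for i in range(N - n)]
                    uni = fg + bg
                    for k in range(0, min(K, n) + 1):
                        with_hit = fg[:k] + bg[:K - k]
                        if len(with_hit) != K or not with_hit:
                            continue
                        res = motif_enrichment(fg, bg, self._hits(with_hit))
                        assert res.loc["m1", "p"] == pytest.approx(
                            _hyper_tail_bruteforce(k, N, K, n), rel=1e-10, abs=1e-300)

    def test_foreground_only_motif_is_significant(self, rng):
        fg = [f"f{i}" for i in range(60)]
        bg = [f"b{i}" for i in range(60)]
        res = motif_enrichment(fg, bg, self._hits(fg[:40]))
        assert res.loc["m1", "q"] < 0.05
        assert bool(res.loc["m1", "significant"])

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            motif_enrichment([], ["b1"], self._hits(["b1"]))

    def test_promoter_universe_of_one_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            promoter_enrichment(["g1"], ["g1"], self._hits(["g1"]))

    def test_no_promoter_hits_gives_p_one(self):
        res = promoter_enrichment(["g1", "g2"], ["g1", "g2", "g3", "g4"],
                                  self._hits([], motif="m9").iloc[:0])
        assert res.empty or (res["p"] == 1).all()


class TestFamilyAggregate:
    def _hits(self, pairs):
        return pd.DataFrame([{"seq_id": s, "motif_id": m, "offset": 0,
                              "strand": "+", "score": 1.0} for s, m in pairs])

    def test_single_member_family_equals_member_result(self):
        fg = [f"f{i}" for i in range(6)]
        bg = [f"b{i}" for i in range(6)]
        hits = self._hits([(x, "m1") for x in fg[:4]])
        fam = family_aggregate(fg, bg, hits, {"m1": "TEA"})
        mot = motif_enrichment(fg, bg, hits)
        assert fam.loc["TEA", "p"] == pytest.approx(mot.loc["m1", "p"])
        assert fam.loc["TEA", "best_member"] == "m1"

    def test_disjoint_members_pool_to_union(self):
        fg = [f"f{i}" for i in range(8)]
        bg = [f"b{i}" for i in range(8)]
        hits = self._hits([(x, "m1") for x in fg[:3]]
                          + [(x, "m2") for x in fg[3:6]])
        fam = family_aggregate(fg, bg, hits, {"m1": "TEA", "m2": "TEA"})
        assert fam.loc["TEA", "fg_with_hit"] == 6

    def test_unmapped_motif_warns_into_unassigned(self):
        fg, bg = ["f1", "f2"], ["b1", "b2"]
        hits = self._hits([("f1", "mystery")])
        with pytest.warns(UserWarning, match="family map"):
            fam = family_aggregate(fg, bg, hits, {})
        assert "unassigned" in fam.index


class TestExpressionGate:
    def test_planted_factors_recovered_exactly(self, small_experiment):
        """Enrichment + expression gate reproduces the planted factor list.

        Each motif is tested against the peaks of its own planted modules
        (the per-cluster foreground the reporting uses); the union of gated
        reports must equal the planted, expressed factor set exactly.
        """
        exp = small_experiment
        hits = scan_library(exp.peak_windows, exp.pwms)
        truth = exp.peak_truth.set_index("peak_id")
        planted_of = {
            pid: {s.split("@")[0] for s in cell.split(";")} if cell else set()
            for pid, cell in truth["planted_motifs"].items()
        }
        planted_motifs = sorted(set().union(*planted_of.values()))
        bg = [p for p, mots in planted_of.items() if not mots]
        reported = set()
        for motif_id in planted_motifs:
            fg = [p for p, mots in planted_of.items() if motif_id in mots]
            res = motif_enrichment(fg, bg, hits)
            gated = expressed_factor_gate(res, exp.tf_map, exp.rna_counts)
            reported |= set(gated.index) & {motif_id}
            # no motif absent from this foreground's plant list sneaks in
            assert motif_id in gated.index
        assert sorted(reported) == planted_motifs

    def test_unexpressed_factor_is_dropped(self, small_experiment):
        exp = small_experiment
        hits = scan_library(exp.peak_windows, exp.pwms)
        truth = exp.peak_truth.set_index("peak_id")
        fg = truth.index[truth["planted_motifs"] != ""].tolist()
        bg = truth.index[truth["planted_motifs"] == ""].tolist()
        res = motif_enrichment(fg, bg, hits)
        silenced = {m: "gene_that_does_not_exist" for m in exp.tf_map}
        gated = expressed_factor_gate(res, silenced, exp.rna_counts)
        assert gated.empty


def test_both_distal_and_promoter_reporting():
    a = pd.DataFrame({"significant": [True, True, False]},
                     index=["m1", "m2", "m3"])
    b = pd.DataFrame({"significant": [True, False, True]},
                     index=["m1", "m2", "m3"])
    assert both_distal_and_promoter(a, b) == ["m1"]
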