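import numpy as np
import pytest
from scipy import stats

from tescan import motif_tandem as mt
from tescan.motif_tandem import Motif, MotifHit

MYB = "AACTGYCW"  # AACTG(C/T)C(A/T)


class TestScanConsensus:
    def test_worked_example_single_forward_hit(self):
        hits = mt.scan_consensus("AACTGTCT", MYB)
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (0, "+")

    def test_reverse_complement_gives_minus_hit_same_span(self):
        hits = mt.scan_consensus(mt.revcomp("AACTGTCT"), MYB)
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (0, "-")

    def test_no_hits_in_homopolymer(self):
        assert mt.scan_consensus("A" * 40, MYB) == []

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            mt.scan_consensus("ACGT", "AXC")

    def test_internal_hit_offset(self):
        seq = "GGGG" + "AACTGCCA" + "GGGG"
        (hit,) = mt.scan_consensus(seq, MYB)
        assert hit.offset == 4


class TestScoreDistribution:
    def test_width1_uniform_pwm_is_degenerate(self):
        m = Motif(pwm=np.full((1, 4), 0.25))
        dist = mt.pwm_score_distribution(m)
        assert dist.probs.sum() == pytest.approx(1.0)
        # every base scores the same; P(>= that score) = 1
        s = int(dist.int_matrix[0, 0])
        assert dist.pvalue_int(s) == pytest.approx(1.0)

    def test_width8_tails_match_full_enumeration(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 40, size=(4, 8))
        m = Motif.from_counts(counts)
        dist = mt.pwm_score_distribution(m)
        int_m = dist.int_matrix
        # exhaustive oracle over all 4^8 words under uniform background
        scores = np.zeros(1, dtype=np.int64)
        for pos in range(8):
            scores = (scores[:, None] + int_m[pos][None, :]).ravel()
        assert len(scores) == 4**8
        for q in (0.5, 0.9, 0.99):
            s = int(np.quantile(scores, q))
            expected = (scores >= s).mean()
            assert dist.pvalue_int(s) == pytest.approx(expected, abs=1e-9)

    def test_distribution_sums_to_one(self):
        m = Motif.from_iupac(MYB)
        dist = mt.pwm_score_distribution(m)
        assert dist.probs.sum() == pytest.approx(1.0)

    def test_refining_resolution_is_stable(self):
        rng = np.random.default_rng(4)
        m = Motif.from_counts(rng.integers(1, 40, size=(4, 8)))
        coarse = mt.pwm_score_distribution(m, 0.01)
        fine = mt.pwm_score_distribution(m, 0.005)
        for bits in (-2.0, 0.0, 2.0, 4.0):
            assert abs(coarse.pvalue(bits) - fine.pvalue(bits)) < 1e-3


class TestScanPwm:
    def test_planted_site_recovered(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        seq = list("".join(bases[rng.integers(0, 4, 300)]))
        seq[100:108] = "AACTGTCT"
        m = Motif.from_iupac(MYB)
        hits = mt.scan_pwm("".join(seq), m, p_threshold=1e-3)
        assert any(h.offset == 100 and h.strand == "+" for h in hits)

    def test_threshold_one_saturates(self):
        m = Motif.from_iupac(MYB)
        seq = "ACGTACGTACGTACGTACGT"
        hits = mt.scan_pwm(seq, m, p_threshold=1.0)
        assert len(hits) == 2 * (len(seq) - m.width + 1)

    def test_tiny_pvalues_rare_in_random_sequence(self):
        m = Motif.from_iupac(MYB)
        dist = mt.pwm_score_distribution(m)
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        n_with_hit = 0
        for _ in range(200):
            seq = "".join(bases[rng.integers(0, 4, 100)])
            if mt.scan_pwm(seq, m, p_threshold=1e-6, dist=dist):
                n_with_hit += 1
        assert n_with_hit <= 2  # >= 99% of random sequences have none

    def test_short_sequence_yields_nothing(self):
        m = Motif.from_iupac(MYB)
        assert mt.scan_pwm("ACGT", m, p_threshold=1.0) == []

    def test_consensus_and_pwm_scans_agree(self):
        # a 0/1-style PWM thresholded at the minimal matching score
        # reproduces the degenerate-consensus hit set
        m = Motif.from_iupac(MYB)
        dist = mt.pwm_score_distribution(m)
        min_match_int = int(
            sum(
                min(dist.int_matrix[i, mt._BASE_INDEX[b]] for b in mt.IUPAC[c])
                for i, c in enumerate(MYB)
            )
        )
        threshold_p = dist.pvalue_int(min_match_int)
        rng = np.random.default_rng(10)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seq = list("".join(bases[rng.integers(0, 4, 120)]))
            seq[40:48] = "AACTGCCA"
            seq = "".join(seq)
            pwm_hits = {
                (h.offset, h.strand)
                for h in mt.scan_pwm(seq, m, threshold_p, dist=dist)
            }
            cons_hits = {(h.offset, h.strand) for h in mt.scan_consensus(seq, MYB)}
            assert cons_hits == pwm_hits


class TestSequenceEvalue:
    def test_zero_pbest(self):
        (res,) = mt.sequence_evalue({"s": (0.0, 10, None, 0, False)})
        assert res.p_sequence == 0.0 and res.e_value == 0.0

    def test_single_position_single_sequence(self):
        (res,) = mt.sequence_evalue({"s": (0.01, 1, None, 0, False)})
        assert res.p_sequence == pytest.approx(0.01)
        assert res.e_value == pytest.approx(0.01)

    def test_evalue_monotone_in_pbest_and_n(self):
        r1 = mt.sequence_evalue({"s": (0.01, 5, None, 0, False)})[0]
        r2 = mt.sequence_evalue({"s": (0.02, 5, None, 0, False)})[0]
        assert r2.e_value >= r1.e_value
        many = mt.sequence_evalue(
            {f"s{i}": (0.01, 5, None, 0, False) for i in range(4)}
        )
        assert many[0].e_value == pytest.approx(4 * r1.p_sequence)

    def test_p_sequence_matches_monte_carlo(self):
        m = Motif.from_iupac(MYB)
        dist = mt.pwm_score_distribution(m)
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        L = 30
        # pick a fixed reference score threshold, compute p_sequence for it
        ref_int = int(dist.int_matrix.max(axis=1).sum())  # perfect match
        p_best = dist.pvalue_int(ref_int)
        mpos = 2 * (L - m.width + 1)
        p_seq = 1 - (1 - p_best) ** mpos
        n_hit = 0
        n_rep = 10_000
        for _ in range(n_rep):
            seq = "".join(bases[rng.integers(0, 4, L)])
            best, _ = mt.best_pvalue(seq, m, dist=dist)
            n_hit += best <= p_best
        se = np.sqrt(p_seq * (1 - p_seq) / n_rep)
        assert abs(n_hit / n_rep - p_seq) <= 3 * se


class TestTandemSites:
    def hits(self, offsets, strand="+"):
        return [MotifHit("s", o, strand) for o in offsets]

    def test_four_tandem_sites_in_five_prime(self):
        count, in5 = mt.tandem_sites(
            self.hits([10, 30, 50, 70]), 500, width=8, max_gap=30
        )
        assert (count, in5) == (4, True)

    def test_interspersed_sites_break_the_run(self):
        count, in5 = mt.tandem_sites(self.hits([10, 400]), 500, width=8, max_gap=30)
        assert count == 1

    def test_no_hits(self):
        assert mt.tandem_sites([], 500, width=8) == (0, False)

    def test_opposite_strands_do_not_chain(self):
        hits = [MotifHit("s", 10, "+"), MotifHit("s", 30, "-"), MotifHit("s", 35, "+")]
        count, _ = mt.tandem_sites(hits, 500, width=8, max_gap=30)
        assert count == 2  # the + hits chain (gap 25); the - hit does not join

    def test_run_outside_five_prime_region(self):
        count, in5 = mt.tandem_sites(
            self.hits([300, 320, 340]), 500, width=8, max_gap=30
        )
        assert (count, in5) == (3, False)


class TestClusterMotifEnrichment:
    def test_perfect_separation_matches_hypergeometric(self):
        presence = {f"a{i}": True for i in range(10)}
        presence.update({f"b{i}": False for i in range(10)})
        clusters = {f"a{i}": 1 for i in range(10)}
        clusters.update({f"b{i}": 2 for i in range(10)})
        res = mt.cluster_motif_enrichment(presence, clusters)
        # exact two-sided p: the two extreme tables each with prob 1/C(20,10)
        from math import comb

        assert res["p_value"] == pytest.approx(2 / comb(20, 10))
        assert res["odds_ratio"] > 100

    def test_balanced_identical_rates_give_p_one(self):
        presence = {f"e{i}": i % 2 == 0 for i in range(20)}
        clusters = {f"e{i}": 1 if i < 10 else 2 for i in range(20)}
        res = mt.cluster_motif_enrichment(presence, clusters)
        assert res["p_value"] == pytest.approx(1.0)

    def test_label_swap_inverts_odds_preserves_p(self):
        rng = np.random.default_rng(14)
        presence = {f"e{i}": bool(rng.integers(0, 2)) for i in range(30)}
        clusters = {f"e{i}": 1 if i < 14 else 2 for i in range(30)}
        swapped = {k: 3 - v for k, v in clusters.items()}
        r1 = mt.cluster_motif_enrichment(presence, clusters)
        r2 = mt.cluster_motif_enrichment(presence, swapped)
        assert r1["p_value"] == pytest.approx(r2["p_value"])
        assert r1["odds_ratio"] == pytest.approx(1 / r2["odds_ratio"])

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            mt.cluster_motif_enrichment({"a": True}, {"a": 1, "b": 1})


class TestLibraryAnalysis:
    def test_motif_class_ranks_first(self, default_world):
        motif = Motif.from_iupac(default_world.config.motif)
        results = mt.analyze_library(default_world.library.sequences, motif)
        assert results[0].seq_id == default_world.config.motif_class_id
        assert results[0].tandem_count == default_world.config.n_tandem_sites
        assert results[0].tandem_in_5prime


class TestJasparInput:
    def test_bracketed_count_matrix(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(
            ">MA0100.1 test\n"
            "A [ 10  0 ]\n"
            "C [  0 10 ]\n"
            "G [  0  0 ]\n"
            "T [  0  0 ]\n"
        )
        m = Motif.from_jaspar_file(path)
        assert m.width == 2
        assert m.pwm[0, 0] == pytest.approx(1.0)
        assert m.pwm[1, 1] == pytest.approx(1.0)
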