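import numpy as np
import pytest

from tescan import peak_landscape as pl
from tescan.io_formats import AlignmentRecord, GeneModel, GenomicInterval


def make_gene(gene_id, chrom, start, end, strand="+"):
    tss, tes = (start, end) if strand == "+" else (end, start)
    return GeneModel(gene_id, chrom, tss, tes, strand)


GENES = [
    make_gene("g1", "chr1", 10_000, 20_000, "+"),
    make_gene("g2", "chr1", 40_000, 48_000, "+"),
    make_gene("g3", "chr2", 25_000, 30_000, "-"),
]


class TestClassifyPeaks:
    def test_peak_upstream_of_tss_is_promoter(self):
        peaks = [GenomicInterval("chr1", 9_400, 9_600)]  # midpoint 9500
        res = pl.classify_peaks(peaks, GENES)
        assert res["labels"] == ["promoter"]

    def test_midgene_peak_is_intragenic(self):
        peaks = [GenomicInterval("chr1", 14_900, 15_100)]  # 5 kb from TSS
        res = pl.classify_peaks(peaks, GENES)
        assert res["labels"] == ["intragenic"]

    def test_far_peak_is_intergenic(self):
        peaks = [GenomicInterval("chr1", 80_000, 80_200)]
        res = pl.classify_peaks(peaks, GENES)
        assert res["labels"] == ["intergenic"]

    def test_percentages_partition_to_100(self):
        rng = np.random.default_rng(0)
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 100_000, size=97)
        ]
        res = pl.classify_peaks(peaks, GENES)
        assert sum(res["counts"].values()) == len(peaks)
        assert sum(res["percent"].values()) == pytest.approx(100.0)


class TestMetagene:
    def test_reads_at_tss_peak_at_body_start_bin(self):
        aln = [
            AlignmentRecord(f"r{i}", g.chrom, g.tss - 25, 50)
            for g in GENES
            if g.strand == "+"
            for i in range(10)
        ]
        prof = pl.metagene_profile(aln, [g for g in GENES if g.strand == "+"])
        n_flank = 2000 // 50
        assert prof.argmax() == n_flank

    def test_minus_strand_gene_is_reversed(self):
        g = GENES[2]  # minus strand, span [25000, 30000), TSS at 30000
        aln = [AlignmentRecord(f"r{i}", "chr2", 29_925 + i, 50) for i in range(20)]
        prof = pl.metagene_profile(aln, [g])
        n_flank = 2000 // 50
        # reads near the TSS must land at the profile's 5' body edge
        assert prof[: len(prof) // 2].sum() > prof[len(prof) // 2 :].sum()
        assert prof.argmax() == n_flank

    def test_bin_totals_match_per_base_oracle(self):
        rng = np.random.default_rng(3)
        genes = GENES[:2]
        aln = [
            AlignmentRecord(f"r{i}", "chr1", int(s), 50)
            for i, s in enumerate(rng.integers(0, 60_000, size=800))
        ]
        prof = pl.metagene_profile(aln, genes, flank=2000, body_bins=100)
        # independent oracle: explicit per-base bin map per gene
        n_flank = 2000 // 50
        acc = np.zeros(2 * n_flank + 100)
        for g in genes:
            length = g.span_end - g.span_start
            contrib = np.zeros_like(acc)
            for rec in aln:
                m = rec.midpoint
                if g.span_start - 2000 <= m < g.span_start:
                    b = (m - (g.span_start - 2000)) // 50
                    w = 50
                elif g.span_start <= m < g.span_end:
                    b = n_flank + (m - g.span_start) * 100 // length
                    w = length / 100
                elif g.span_end <= m < g.span_end + 2000:
                    b = n_flank + 100 + (m - g.span_end) // 50
                    w = 50
                else:
                    continue
                contrib[int(b)] += 1 / w
            acc += contrib if g.strand == "+" else contrib[::-1]
        assert prof == pytest.approx(acc / len(genes))


class TestAnchoredMatrix:
    def test_midpoint_at_anchor_lands_in_center_bin(self):
        aln = [AlignmentRecord("r", "chr1", 5000 - 25, 50)]  # midpoint 5000
        mat = pl.anchored_matrix(aln, [("a", "chr1", 5000)])
        assert mat.n_bins == 120
        assert mat.values[0, 60] == 1
        assert mat.values.sum() == 1

    def test_matrix_sum_matches_filter_count_oracle(self):
        rng = np.random.default_rng(5)
        aln = [
            AlignmentRecord(f"r{i}", "chr1", int(s), 50)
            for i, s in enumerate(rng.integers(0, 50_000, size=500))
        ]
        anchors = [("a1", "chr1", 10_000), ("a2", "chr1", 12_000)]
        mat = pl.anchored_matrix(aln, anchors, half_window=3000, bin_width=50)
        expected = sum(
            1
            for rec in aln
            for _, _, pos in anchors
            if pos - 3000 <= rec.midpoint < pos + 3000
        )
        assert mat.values.sum() == expected

    def test_empty_alignments_give_zero_matrix(self):
        mat = pl.anchored_matrix([], [("a", "chr1", 5000)])
        assert (mat.values == 0).all()

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError):
            pl.anchored_matrix([], [("a", "chr1", 5000)], half_window=3000, bin_width=70)


class TestElementProfile:
    @pytest.fixture()
    def instances(self, small_world):
        return small_world.instances

    def test_all_unique_reads_give_identical_tracks(self, small_world, instances):
        aln = [r.to_alignment(mapq=42) for r in small_world.reads("chip")[:2000]]
        track_all, track_filt = pl.element_profile(aln, instances)
        assert track_all == pytest.approx(track_filt)

    def test_all_multimapped_reads_give_zero_filtered_track(self, small_world, instances):
        aln = [r.to_alignment(mapq=0) for r in small_world.reads("chip")[:2000]]
        track_all, track_filt = pl.element_profile(aln, instances)
        assert (track_filt == 0).all()
        assert track_all.sum() > 0

    def test_filtered_never_exceeds_unfiltered(self, small_world, instances):
        rng = np.random.default_rng(9)
        aln = [
            r.to_alignment(mapq=int(q))
            for r, q in zip(
                small_world.reads("chip"), rng.integers(0, 43, size=small_world.config.depth)
            )
        ]
        track_all, track_filt = pl.element_profile(aln, instances)
        assert (track_filt <= track_all + 1e-12).all()


class TestSubsample:
    ALN = [AlignmentRecord(f"r{i}", "chr1", i * 10, 50) for i in range(20)]

    def test_full_subsample_is_identity_as_set(self):
        out = pl.subsample(self.ALN, 20, seed=1)
        assert set(r.read_id for r in out) == set(r.read_id for r in self.ALN)

    def test_two_seeds_differ(self):
        a = pl.subsample(self.ALN, 5, seed=1)
        b = pl.subsample(self.ALN, 5, seed=2)
        assert len(a) == len(b) == 5
        assert set(r.read_id for r in a) != set(r.read_id for r in b)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            pl.subsample(self.ALN, 21, seed=1)

    def test_inclusion_frequency_binomial_oracle(self):
        hits = np.zeros(20)
        n_rep = 1000
        for rep in range(n_rep):
            for rec in pl.subsample(self.ALN, 5, seed=rep):
                hits[int(rec.read_id[1:])] += 1
        freq = hits / n_rep
        p = 5 / 20
        se = np.sqrt(p * (1 - p) / n_rep)
        assert (np.abs(freq - p) <= 3 * se).all()


class TestClusterMatrix:
    def test_two_exact_patterns_separate_perfectly(self):
        a = np.tile([1.0, 0.0, 0.0, 0.0], (5, 1))
        b = np.tile([0.0, 0.0, 0.0, 1.0], (5, 1))
        mat = pl.DensityMatrix(
            anchor_ids=[f"x{i}" for i in range(10)],
            bin_width=50,
            values=np.vstack([a, b]),
        )
        assign = pl.cluster_matrix(mat, 2, seed=0)
        first = {assign.labels[f"x{i}"] for i in range(5)}
        second = {assign.labels[f"x{i}"] for i in range(5, 10)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_k1_puts_everything_together(self):
        mat = pl.DensityMatrix(["a", "b"], 50, np.random.default_rng(0).random((2, 8)))
        assign = pl.cluster_matrix(mat, 1)
        assert set(assign.labels.values()) == {1}

    def test_within_cluster_ss_beats_random_assignments(self):
        rng = np.random.default_rng(11)
        vals = np.vstack(
            [rng.normal(0, 1, (10, 12)), rng.normal(4, 1, (10, 12))]
        ).clip(min=0)
        mat = pl.DensityMatrix([f"e{i}" for i in range(20)], 50, vals)
        assign = pl.cluster_matrix(mat, 2, seed=0)

        row_max = vals.max(axis=1, keepdims=True)
        normed = np.where(row_max > 0, vals / row_max, vals)

        def wss(labels):
            total = 0.0
            for k in set(labels):
                rows = normed[np.array(labels) == k]
                total += ((rows - rows.mean(axis=0)) ** 2).sum()
            return total

        ours = wss([assign.labels[f"e{i}"] for i in range(20)])
        random_wss = [
            wss(list(rng.integers(1, 3, size=20))) for _ in range(100)
        ]
        assert ours <= min(random_wss) + 1e-9

    def test_k_bounds(self):
        mat = pl.DensityMatrix(["a"], 50, np.ones((1, 4)))
        with pytest.raises(ValueError):
            pl.cluster_matrix(mat, 0)
        with pytest.raises(ValueError):
            pl.cluster_matrix(mat, 2)
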