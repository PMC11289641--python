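"""Interval algebra, peak calling, and target classification."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests
from scipy import stats as sps

from readerdecay.intervals import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    assign_to_genes,
    binding_ability,
    call_peaks_windowed,
    classify_targets,
    combine_replicates,
    intersect,
    metagene_distribution,
    overlap_fraction,
)


def iv(chrom, start, end, strand="+", name="."):
    return GenomicInterval(chrom, start, end, strand, name)


def peaks(ivs, label=""):
    n = len(ivs)
    return PeakSet(list(ivs), np.ones(n), np.zeros(n), label)


class TestIntersect:
    @pytest.mark.parametrize(
        "a,b,expect_overlap",
        [
            (iv("chr1", 100, 200), iv("chr1", 199, 300), True),   # 1-nt overlap
            (iv("chr1", 100, 200), iv("chr1", 200, 300), False),  # half-open adjacency
            (iv("chr1", 100, 200), iv("chr1", 150, 250, "-"), False),  # strand gate
            (iv("chr1", 100, 200), iv("chr2", 100, 200), False),
        ],
    )
    def test_pairwise_overlap_rules(self, a, b, expect_overlap):
        pairs, hits = intersect([a], [b])
        assert bool(pairs) is expect_overlap

    def test_strand_gate_can_be_disabled(self):
        pairs, _ = intersect([iv("chr1", 100, 200)], [iv("chr1", 150, 250, "-")],
                             same_strand=False)
        assert pairs == [(0, 0)]

    def test_min_overlap_threshold(self):
        a, b = [iv("chr1", 100, 200)], [iv("chr1", 195, 300)]
        assert intersect(a, b, min_overlap=5)[0] == [(0, 0)]
        assert intersect(a, b, min_overlap=6)[0] == []

    def test_empty_sets_allowed(self):
        assert intersect([], [iv("chr1", 0, 10)]) == ([], [])
        assert intersect([iv("chr1", 0, 10)], []) == ([], [])

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        """Sweep implementation agrees with exhaustive all-pairs comparison,
        including strand and boundary cases."""
        for _ in range(200):
            n_a, n_b = rng.integers(0, 30, size=2)
            min_ov = int(rng.integers(1, 4))
            same = bool(rng.integers(0, 2))

            def draw(n):
                out = []
                for k in range(n):
                    start = int(rng.integers(0, 400))
                    out.append(
                        iv(f"chr{rng.integers(1, 3)}", start,
                           start + int(rng.integers(1, 60)),
                           "+" if rng.random() < 0.5 else "-", f"x{k}")
                    )
                return out

            A, B = draw(int(n_a)), draw(int(n_b))
            expected = []
            for i, p in enumerate(A):
                for j, q in enumerate(B):
                    if (p.chrom == q.chrom
                            and (not same or p.strand == q.strand)
                            and p.overlap_length(q) >= min_ov):
                        expected.append((i, j))
            got, hits = intersect(A, B, min_overlap=min_ov, same_strand=same)
            assert sorted(got) == sorted(expected)
            assert hits == sorted({i for i, _ in expected})


class TestOverlapFraction:
    def test_counts(self):
        a = peaks([iv("chr1", i * 1000, i * 1000 + 100) for i in range(4)])
        b = peaks([iv("chr1", i * 1000 + 50, i * 1000 + 150) for i in range(3)])
        assert overlap_fraction(a, b) == 0.75

    def test_subset_gives_one(self):
        a = peaks([iv("chr1", 10, 20), iv("chr1", 40, 50)])
        b = peaks([iv("chr1", 0, 100)])
        assert overlap_fraction(a, b) == 1.0

    def test_empty_query_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(peaks([]), peaks([iv("chr1", 0, 10)]))


class TestClassifyTargets:
    def test_three_group_partition(self):
        cls = classify_targets({"g1", "g2"}, {"g2"}, {"g1", "g2", "g3", "g4"},
                               {"g1": 1, "g2": 2})
        assert cls.reader_targets == {"g1", "g2"}
        assert cls.reader_m6a_targets == {"g2"}
        assert cls.non_targets == {"g3", "g4"}

    def test_empty_clip_means_all_non_targeted(self):
        cls = classify_targets(set(), set(), {"a", "b"}, {})
        assert cls.non_targets == {"a", "b"}

    def test_full_clip_means_no_non_targeted(self):
        u = {"a", "b"}
        cls = classify_targets(u, u, u, {"a": 1, "b": 1})
        assert cls.non_targets == set()

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            classify_targets({"g1"}, {"g2"}, {"g1", "g2"}, {"g1": 1})

    def test_partition_invariants_on_random_inputs(self, rng):
        universe = [f"g{i}" for i in range(50)]
        for _ in range(30):
            clip = set(rng.choice(universe, size=rng.integers(0, 50), replace=False))
            m6a = set(x for x in clip if rng.random() < 0.6)
            counts = {g: int(rng.integers(1, 5)) for g in clip}
            cls = classify_targets(clip, m6a, universe, counts)
            assert len(cls.reader_targets) + len(cls.non_targets) == len(universe)
            assert cls.reader_m6a_targets <= cls.reader_targets


class TestAssignToGenes:
    def make_models(self):
        # two overlapping plus-strand genes and one minus-strand gene
        g1 = GeneModel("g1", "chr1", "+", (0, 100), (100, 700), (700, 1000))
        g2 = GeneModel("g2", "chr1", "+", (800, 900), (900, 1500), (1500, 1800))
        g3 = GeneModel("g3", "chr1", "-", (2900, 3000), (2300, 2900), (2000, 2300))
        return [g1, g2, g3]

    def test_single_gene_assignment(self):
        per_gene, counts, inter = assign_to_genes(
            peaks([iv("chr1", 150, 200)]), self.make_models()
        )
        assert counts == {"g1": 1} and inter == []

    def test_three_disjoint_peaks_count_three(self):
        ps = peaks([iv("chr1", 100, 150), iv("chr1", 300, 350), iv("chr1", 600, 650)])
        _, counts, _ = assign_to_genes(ps, self.make_models())
        assert counts == {"g1": 3}

    def test_peak_spanning_two_genes_assigned_to_both(self):
        _, counts, _ = assign_to_genes(peaks([iv("chr1", 790, 900)]), self.make_models())
        assert counts == {"g1": 1, "g2": 1}

    def test_intergenic_and_wrong_strand_reported(self):
        ps = peaks([iv("chr1", 5000, 5100), iv("chr1", 2400, 2500)])  # 2nd in g3 but +
        per_gene, counts, inter = assign_to_genes(ps, self.make_models())
        assert counts == {} and inter == [0, 1]


class TestMetagene:
    def test_all_three_prime_utr(self):
        m = GeneModel("g1", "chr1", "+", (0, 100), (100, 700), (700, 1000))
        dist = metagene_distribution(peaks([iv("chr1", 800, 850), iv("chr1", 900, 950)]), [m])
        assert dist == {"5UTR": 0.0, "CDS": 0.0, "3UTR": 1.0}

    def test_one_peak_per_region(self):
        m = GeneModel("g1", "chr1", "+", (0, 100), (100, 700), (700, 1000))
        ps = peaks([iv("chr1", 10, 50), iv("chr1", 300, 350), iv("chr1", 800, 850)])
        dist = metagene_distribution(ps, [m])
        assert all(abs(v - 1 / 3) < 1e-12 for v in dist.values())
        assert abs(sum(dist.values()) - 1.0) < 1e-12

    def test_no_assignable_peaks_is_an_error(self):
        m = GeneModel("g1", "chr1", "+", (0, 100), (100, 700), (700, 1000))
        with pytest.raises(ValueError, match="undefined"):
            metagene_distribution(peaks([iv("chr1", 5000, 5100)]), [m])


class TestCallPeaks:
    def test_flat_equal_tracks_give_no_peaks(self):
        track = {"chr1": np.full(200, 50.0)}
        assert len(call_peaks_windowed(track, track, bin_size=25)) == 0

    def test_single_enriched_window_recovered_against_hand_bh(self):
        """The caller reproduces a by-hand per-window Poisson + BH analysis
        for one fourfold-enriched two-window block."""
        n = 400
        inp = np.full(n, 100.0)
        ip = np.full(n, 100.0)
        ip[50:52] = 400.0  # fold 4 over two adjacent windows
        got = call_peaks_windowed({"chr1": ip}, {"chr1": inp}, bin_size=25)
        assert len(got) == 1
        assert (got.intervals[0].start, got.intervals[0].end) == (50 * 25, 52 * 25)

        # independent oracle: per-window Poisson tail + BH, fold gate, merge
        scale = ip.sum() / inp.sum()
        pv = sps.poisson.sf(ip - 1, np.maximum(inp, 1.0) * scale)
        q = multipletests(pv, method="fdr_bh")[1]
        ip_cpm = ip / ip.sum() * 1e6
        in_cpm = inp / inp.sum() * 1e6
        fold = (ip_cpm + 0.01) / (in_cpm + 0.01)
        expected_windows = np.flatnonzero((fold >= 2.0) & (q < 0.05))
        assert expected_windows.tolist() == [50, 51]

    def test_high_fold_single_window_rejected_by_min_width(self):
        inp = np.full(400, 100.0)
        ip = np.full(400, 100.0)
        ip[50] = 400.0
        assert len(call_peaks_windowed({"chr1": ip}, {"chr1": inp}, bin_size=25)) == 0

    def test_subthreshold_fold_rejected_despite_tiny_p(self):
        inp = np.full(400, 10000.0)
        ip = np.full(400, 10000.0)
        ip[50:52] = 15000.0  # fold 1.5, astronomically significant
        assert len(call_peaks_windowed({"chr1": ip}, {"chr1": inp}, bin_size=25)) == 0

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError, match="binned"):
            call_peaks_windowed({"chr1": np.ones(10)}, {"chr1": np.ones(11)}, 25)


class TestBindingAbility:
    def test_ratio_of_enrichments(self):
        n = 100
        inp = {"chr1": np.full(n, 100.0)}
        reader = {"chr1": np.full(n, 100.0)}
        impaired = {"chr1": np.full(n, 100.0)}
        reader["chr1"][10:12] = 400.0    # fold ~4 at the peak
        impaired["chr1"][10:12] = 200.0  # fold ~2
        ps = peaks([iv("chr1", 250, 300)])
        ratio = binding_ability(reader, impaired, inp, ps, bin_size=25)
        # exact oracle: CPM ratios with library totals 10600/10200/10000
        expected = (400 / 10600) / (200 / 10200)
        assert ratio == pytest.approx([expected], rel=1e-4)
        assert ratio == pytest.approx([2.0], rel=0.05)  # ~2 up to composition

    def test_identical_tracks_give_unity(self):
        t = {"chr1": np.full(50, 70.0)}
        ps = peaks([iv("chr1", 100, 200), iv("chr1", 700, 800)])
        assert binding_ability(t, t, t, ps, 25) == pytest.approx([1.0, 1.0])

    def test_peak_outside_coverage_rejected(self):
        t = {"chr1": np.full(50, 70.0)}
        with pytest.raises(ValueError, match="coverage"):
            binding_ability(t, t, t, peaks([iv("chr2", 0, 10)]), 25)


class TestCombineReplicates:
    def test_requires_overlap_in_every_replicate(self):
        r1 = PeakSet([iv("chr1", 100, 200), iv("chr1", 500, 600)],
                     np.array([4.0, 3.0]), np.array([0.01, 0.01]), "r1")
        r2 = PeakSet([iv("chr1", 150, 260)], np.array([2.0]), np.array([0.02]), "r2")
        combined = combine_replicates([r1, r2])
        assert len(combined) == 1
        assert (combined.intervals[0].start, combined.intervals[0].end) == (100, 260)
        assert combined.enrichment[0] == pytest.approx(3.0)  # mean of 4 and 2
        assert combined.fdr[0] == pytest.approx(0.02)        # max FDR

    def test_single_replicate_passes_through(self):
        r1 = peaks([iv("chr1", 0, 10)])
        assert combine_replicates([r1]) is r1
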