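"""Redundancy collapse, annotation, stratification, and AUC evaluation."""

import itertools

import numpy as np
import pytest

from motifatlas import (
    ConservedSite,
    MapRecord,
    ScoredSite,
    TranscriptAnnotation,
    bbls_quartile_stratify,
    evaluate_auc,
    promoter_window_select,
    redundancy_filter,
    snp_overlap,
    tss_distance,
)


def csite(start, end, bbls, nlod=0.9, matrix_id="m1", chrom="chr1"):
    site = ScoredSite(matrix_id, chrom, start, end, "+", "A" * (end - start),
                      0.0, nlod, 5.0)
    return ConservedSite(site, bbls, {}, 3)


def record(start, end, bbls=1.0, dist=None, gene=None, tf="TF"):
    return MapRecord(csite(start, end, bbls), tf, 0.05, gene, dist)


class TestRedundancyFilter:
    def test_same_tf_keeps_max_bbls(self):
        sites = [csite(100, 112, 2.0), csite(105, 117, 3.5)]
        kept = redundancy_filter(sites, {"m1": "TF1"})
        assert [s.bbls for s in kept] == [3.5]

    def test_different_tfs_do_not_compete(self):
        sites = [csite(100, 112, 2.0, matrix_id="m1"),
                 csite(105, 117, 3.5, matrix_id="m2")]
        kept = redundancy_filter(sites, {"m1": "TF1", "m2": "TF2"})
        assert len(kept) == 2

    def test_bbls_tie_breaks_on_nlod_then_leftmost(self):
        tie_nlod = [csite(100, 112, 2.0, nlod=0.8), csite(105, 117, 2.0, nlod=0.95)]
        assert redundancy_filter(tie_nlod, {"m1": "T"})[0].nlod == 0.95
        tie_all = [csite(100, 112, 2.0, nlod=0.9), csite(105, 117, 2.0, nlod=0.9)]
        assert redundancy_filter(tie_all, {"m1": "T"})[0].start == 100

    def test_transitive_overlap_forms_one_group(self):
        # a-b overlap, b-c overlap, a-c do not: still one group
        sites = [csite(0, 10, 1.0), csite(8, 18, 5.0), csite(16, 26, 3.0)]
        kept = redundancy_filter(sites, {"m1": "T"})
        assert [(s.start, s.bbls) for s in kept] == [(8, 5.0)]

    def test_unmapped_matrix_id_errors(self):
        with pytest.raises(KeyError):
            redundancy_filter([csite(0, 10, 1.0)], {})

    def test_matches_bruteforce_grouping_oracle(self):
        """Sweep-line grouping equals transitive-closure enumeration."""
        rng = np.random.default_rng(31)
        sites = []
        for i in range(400):
            start = int(rng.integers(0, 3_000))
            m = f"m{rng.integers(3)}"
            sites.append(
                csite(start, start + 12, float(rng.random()),
                      nlod=float(rng.random()), matrix_id=m,
                      chrom=f"chr{rng.integers(2)}")
            )
        mapping = {"m0": "TFa", "m1": "TFa", "m2": "TFb"}
        kept = redundancy_filter(sites, mapping)

        # oracle: per TF, union-find over all overlapping pairs
        def overlaps(a, b):
            return a.chrom == b.chrom and a.start < b.end and b.start < a.end

        expected = []
        for tf in set(mapping.values()):
            members = [s for s in sites if mapping[s.matrix_id] == tf]
            parent = list(range(len(members)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i, j in itertools.combinations(range(len(members)), 2):
                if overlaps(members[i], members[j]):
                    parent[find(i)] = find(j)
            groups = {}
            for i, s in enumerate(members):
                groups.setdefault(find(i), []).append(s)
            for group in groups.values():
                expected.append(max(group, key=lambda s: (s.bbls, s.nlod, -s.start)))
        key = lambda s: (s.chrom, s.start, s.end, s.matrix_id, s.bbls)
        assert sorted(map(key, kept)) == sorted(map(key, expected))
        # and no overlapping pair survives within a TF
        for tf in set(mapping.values()):
            reps = [s for s in kept if mapping[s.matrix_id] == tf]
            for a, b in itertools.combinations(reps, 2):
                assert not overlaps(a, b)
        assert len(kept) <= len(sites)


class TestTssDistance:
    ANN = [
        TranscriptAnnotation("g1", "t1", "chr1", "+", 1_000),
        TranscriptAnnotation("g2", "t2", "chr1", "-", 5_000),
    ]

    def test_midpoint_at_tss_is_zero(self):
        gene, dist = tss_distance(csite(994, 1006, 1.0), self.ANN)
        assert (gene, dist) == ("g1", 0.0)

    def test_upstream_of_plus_strand_is_negative(self):
        gene, dist = tss_distance(csite(494, 506, 1.0), self.ANN)
        assert (gene, dist) == ("g1", -500.0)

    def test_upstream_of_minus_strand_is_negative(self):
        gene, dist = tss_distance(csite(5_494, 5_506, 1.0), self.ANN)
        assert (gene, dist) == ("g2", -500.0)

    def test_nearest_of_two_wins(self):
        ann = [
            TranscriptAnnotation("near", "t", "chr1", "+", 1_300),
            TranscriptAnnotation("far", "t", "chr1", "+", 1_800),
        ]
        gene, dist = tss_distance(csite(994, 1006, 1.0), ann)
        assert gene == "near"
        assert dist == -300.0

    def test_no_annotation_on_chromosome(self):
        gene, dist = tss_distance(csite(0, 12, 1.0, chrom="chrX"), self.ANN)
        assert gene is None and dist is None


class TestPromoterWindow:
    def test_inclusive_boundaries(self):
        records = [record(0, 10, dist=d, gene="g") for d in
                   (-15_000, -15_001, 3_000, 3_001, 0)]
        kept = promoter_window_select(records)
        assert [r.distance_to_tss for r in kept] == [-15_000, 3_000, 0]

    def test_gene_set_restriction(self):
        records = [record(0, 10, dist=-100, gene="a"), record(0, 10, dist=-100, gene="b")]
        kept = promoter_window_select(records, genes={"a"})
        assert [r.nearest_gene for r in kept] == ["a"]


class TestSnpOverlap:
    def test_half_open_semantics(self):
        records = [record(100, 112)]
        snps = [("chr1", 100, "at_start"), ("chr1", 112, "at_end"),
                ("chr1", 99, "before"), ("chr1", 111, "last_base")]
        hits = {snp for _, snp in snp_overlap(records, snps)}
        assert hits == {"at_start", "last_base"}

    def test_multiple_sites_and_chromosome_separation(self):
        records = [record(100, 112), record(105, 117)]
        pairs = snp_overlap(records, [("chr1", 110, "s"), ("chr2", 110, "other")])
        assert len(pairs) == 2
        assert all(snp == "s" for _, snp in pairs)


class TestQuartiles:
    def test_eight_distinct_records_split_two_each(self):
        records = [record(i * 20, i * 20 + 10, bbls=float(i), dist=100.0 * i)
                   for i in range(8)]
        groups, hists = bbls_quartile_stratify(records)
        assert [len(g) for g in groups] == [2, 2, 2, 2]
        assert [r.bbls for r in groups[3]] == [6.0, 7.0]

    def test_ties_fill_in_stable_order(self):
        records = [record(i * 20, i * 20 + 10, bbls=1.0, dist=0.0) for i in range(8)]
        groups, _ = bbls_quartile_stratify(records)
        assert [len(g) for g in groups] == [2, 2, 2, 2]
        assert [r.start for r in groups[0]] == [0, 20]

    def test_histogram_counts_distances(self):
        records = [record(0, 10, bbls=float(i), dist=(-1)**i * 500.0) for i in range(8)]
        _, hists = bbls_quartile_stratify(records, bin_width=1000, max_distance=2000)
        counts, edges = hists[0]
        assert counts.sum() == 2
        assert edges[0] == -2000

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            bbls_quartile_stratify([record(0, 10)] * 3)


class TestAuc:
    def test_worked_four_region_case(self):
        """pos scores {5, 3}, neg {4, no-site}: 3 of 4 pairs won -> 0.75."""
        records = [csite(100, 110, 5.0), csite(300, 310, 3.0), csite(500, 510, 4.0)]
        regions = [("chr1", 95, 115, 1), ("chr1", 295, 315, 1),
                   ("chr1", 495, 515, 0), ("chr1", 700, 720, 0)]
        assert evaluate_auc(records, regions) == pytest.approx(0.75)

    def test_perfect_separation(self):
        records = [csite(100, 110, 9.0), csite(500, 510, 1.0)]
        regions = [("chr1", 95, 115, 1), ("chr1", 495, 515, 0)]
        assert evaluate_auc(records, regions) == pytest.approx(1.0)

    def test_exclude_mode_drops_empty_regions(self):
        records = [csite(100, 110, 5.0), csite(300, 310, 3.0), csite(500, 510, 4.0)]
        regions = [("chr1", 95, 115, 1), ("chr1", 295, 315, 1),
                   ("chr1", 495, 515, 0), ("chr1", 700, 720, 0)]
        # dropping the site-free negative leaves pairs (5>4, 3<4) -> 0.5
        assert evaluate_auc(records, regions, negatives_mode="exclude") == pytest.approx(0.5)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(13)
        records = [csite(i * 20, i * 20 + 10, float(rng.random())) for i in range(600)]
        regions = [("chr1", i * 20, i * 20 + 10, int(rng.random() < 0.5))
                   for i in range(600)]
        assert evaluate_auc(records, regions) == pytest.approx(0.5, abs=0.07)

    def test_rank_formula_matches_pairwise_counting(self):
        rng = np.random.default_rng(19)
        records = [csite(i * 20, i * 20 + 10, float(rng.integers(0, 5)))
                   for i in range(200)]
        regions = []
        for i in range(250):
            start = int(rng.integers(0, 200)) * 20
            regions.append(("chr1", start, start + 10, int(rng.random() < 0.4)))
        auc = evaluate_auc(records, regions)

        # brute force over all positive/negative region pairs
        by_pos = {}
        for r in records:
            by_pos[r.start] = max(r.bbls, by_pos.get(r.start, -np.inf))
        scores = [(by_pos.get(s, -np.inf), label) for _, s, _, label in regions]
        pos = [v for v, l in scores if l == 1]
        neg = [v for v, l in scores if l == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_missing_class_errors(self):
        records = [csite(100, 110, 5.0)]
        with pytest.raises(ValueError):
            evaluate_auc(records, [("chr1", 95, 115, 1)])
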