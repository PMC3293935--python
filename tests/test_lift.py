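"""MAF block extraction, merging, and cross-species best-hit rescans."""

import numpy as np
import pytest

from motifatlas import (
    AlignmentBlock,
    Background,
    LogOddsMatrix,
    MafBlockSet,
    ScoredSite,
    SeqRow,
    best_species_hits,
    calibrate_z,
    extract_blocks,
    matrix_from_consensus,
    merge_blocks,
    min_species_filter,
    read_maf,
    reverse_complement,
    write_maf,
)
from motifatlas.lift import SpeciesHitSet


def row(species, start, text, chrom="chr1", strand="+", src_size=10_000):
    return SeqRow(species, chrom, start, len(text.replace("-", "")), strand, text, src_size)


def block(ref_row, *others):
    rows = {ref_row.species: ref_row}
    for r in others:
        rows[r.species] = r
    return AlignmentBlock(rows, ref_row.species)


def site(start, end, chrom="chr1"):
    return ScoredSite("m", chrom, start, end, "+", "A" * (end - start), 0.0, 1.0, 6.0)


@pytest.fixture
def three_block_maf():
    """Reference blocks [100,150), [150,200), [225,260): the third sits 25 bp
    from the second, reachable only through the 15 bp pad from a site that
    ends within 15 bp of 225."""
    b1 = block(row("ref", 100, "A" * 50), row("sp1", 300, "C" * 50))
    b2 = block(row("ref", 150, "G" * 50), row("sp1", 350, "T" * 50))
    b3 = block(row("ref", 225, "A" * 35), row("sp1", 500, "G" * 35))
    return MafBlockSet([b1, b2, b3])


class TestExtractBlocks:
    def test_site_inside_one_block(self, three_block_maf):
        found = extract_blocks(site(110, 122), three_block_maf, pad=0)
        assert [b.ref_row.start for b in found] == [100]

    def test_site_spanning_two_blocks(self, three_block_maf):
        found = extract_blocks(site(145, 157), three_block_maf, pad=0)
        assert [b.ref_row.start for b in found] == [100, 150]

    def test_pad_reaches_nearby_block(self, three_block_maf):
        # site ends at 211; the third block starts 14 bp later, inside the pad
        found = extract_blocks(site(199, 211), three_block_maf, pad=15)
        assert [b.ref_row.start for b in found] == [150, 225]
        found_nopad = extract_blocks(site(199, 211), three_block_maf, pad=0)
        assert [b.ref_row.start for b in found_nopad] == [150]

    def test_no_overlap_gives_empty(self, three_block_maf):
        assert extract_blocks(site(1000, 1012), three_block_maf) == []


class TestMergeBlocks:
    def test_zero_gap_concatenates(self):
        b1 = block(row("ref", 0, "AAAA"), row("sp1", 10, "ACGT"))
        b2 = block(row("ref", 4, "AAAA"), row("sp1", 14, "TTTT"))
        assert merge_blocks([b1, b2], "sp1") == ["ACGTTTTT"]

    def test_gap_over_threshold_splits(self):
        b1 = block(row("ref", 0, "AAAA"), row("sp1", 10, "ACGT"))
        b2 = block(row("ref", 4, "AAAA"), row("sp1", 45, "TTTT"))  # gap 31
        assert merge_blocks([b1, b2], "sp1", max_gap=30) == ["ACGT", "TTTT"]

    def test_gap_at_threshold_merges(self):
        b1 = block(row("ref", 0, "AAAA"), row("sp1", 10, "ACGT"))
        b2 = block(row("ref", 4, "AAAA"), row("sp1", 44, "TTTT"))  # gap 30
        (merged,) = merge_blocks([b1, b2], "sp1", max_gap=30)
        assert merged == "ACGT" + "N" * 30 + "TTTT"

    def test_gap_filled_with_n_without_lookup(self):
        b1 = block(row("ref", 0, "AAAA"), row("sp1", 10, "ACGT"))
        b2 = block(row("ref", 4, "AAAA"), row("sp1", 19, "TTTT"))  # gap 5
        (merged,) = merge_blocks([b1, b2], "sp1")
        assert merged == "ACGT" + "NNNNN" + "TTTT"
        assert len(merged) == 4 + 5 + 4

    def test_gap_filled_from_genome_lookup(self):
        genome = {"sp1": {"chr1": "X" * 10 + "ACGTGGGGGTTTT"}}

        def lookup(sp, chrom, start, end):
            return genome[sp][chrom][start:end]

        b1 = block(row("ref", 0, "AAAA"), row("sp1", 10, "ACGT"))
        b2 = block(row("ref", 4, "AAAA"), row("sp1", 19, "TTTT"))
        (merged,) = merge_blocks([b1, b2], "sp1", genome_lookup=lookup)
        assert merged == "ACGTGGGGGTTTT"

    def test_minus_strand_lookup_uses_forward_coordinates(self):
        # species chromosome of length 30; rows on '-' strand
        fwd = "A" * 10 + "CCCGG" + "A" * 15
        rc = reverse_complement(fwd)  # '-' strand coordinates index into this
        genome = {"sp1": {"chr1": fwd}}

        def lookup(sp, chrom, start, end):
            return genome[sp][chrom][start:end]

        b1 = block(row("ref", 0, "AAAA"), row("sp1", 5, rc[5:9], strand="-", src_size=30))
        b2 = block(row("ref", 4, "AAAA"), row("sp1", 14, rc[14:18], strand="-", src_size=30))
        (merged,) = merge_blocks([b1, b2], "sp1", genome_lookup=lookup)
        assert merged == rc[5:18]

    def test_never_joins_across_chrom_or_strand(self):
        b1 = block(row("ref", 0, "AAAA"), row("sp1", 10, "ACGT"))
        b2 = block(row("ref", 4, "AAAA"), row("sp1", 14, "TTTT", chrom="chr2"))
        b3 = block(row("ref", 8, "AAAA"), row("sp1", 18, "GGGG", strand="-"))
        assert len(merge_blocks([b1, b2, b3], "sp1")) == 3

    def test_gapped_rows_drop_dashes(self):
        b1 = block(row("ref", 0, "AAAAAA"), row("sp1", 10, "AC--GT"))
        assert merge_blocks([b1], "sp1") == ["ACGT"]


@pytest.fixture
def scoring(uniform_bg):
    m = matrix_from_consensus("M8", "TF8", "TGACGTCA")
    lom = LogOddsMatrix.build(m, uniform_bg)
    rng = np.random.default_rng(3)
    genome = {"c": "".join("ACGT"[i] for i in rng.integers(0, 4, size=5_000))}
    cal = calibrate_z(lom, genome, n_samples=50_000, seed=8)
    return m, lom, cal


class TestBestSpeciesHits:
    def test_identical_row_matches_reference_nlod(self, scoring):
        m, lom, cal = scoring
        cons = m.consensus()
        ref_site = ScoredSite("M8", "chr1", 100, 108, "+", cons, lom.ymax, 1.0, 6.0)
        b = block(row("ref", 100, cons), row("sp1", 40, cons))
        hs = best_species_hits(ref_site, [b], lom, cal, "ref")
        assert hs.hits["sp1"][1] == pytest.approx(ref_site.nlod)
        assert hs.hits["ref"] == (cons, 1.0, 6.0)

    def test_gap_only_species_omitted(self, scoring):
        m, lom, cal = scoring
        cons = m.consensus()
        ref_site = ScoredSite("M8", "chr1", 100, 108, "+", cons, lom.ymax, 1.0, 6.0)
        b = block(row("ref", 100, cons), row("sp1", 40, "-" * 8))
        hs = best_species_hits(ref_site, [b], lom, cal, "ref")
        assert "sp1" not in hs.hits

    def test_all_n_species_omitted(self, scoring):
        m, lom, cal = scoring
        cons = m.consensus()
        ref_site = ScoredSite("M8", "chr1", 100, 108, "+", cons, lom.ymax, 1.0, 6.0)
        b = block(row("ref", 100, cons), row("sp1", 40, "N" * 8))
        hs = best_species_hits(ref_site, [b], lom, cal, "ref")
        assert "sp1" not in hs.hits

    def test_shifted_motif_found_inside_pad(self, scoring):
        """Motif 4 bp out of alignment frame still scores full NLOD."""
        m, lom, cal = scoring
        cons = m.consensus()
        rng = np.random.default_rng(5)
        pad_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=38))
        ref_text = pad_seq[:15] + cons + pad_seq[15:30]  # site at offset 15
        sp_text = pad_seq[:19] + cons + pad_seq[19:30]  # motif shifted +4
        sp_text = sp_text[: len(ref_text)]
        ref_site = ScoredSite("M8", "chr1", 115, 123, "+", cons, lom.ymax, 1.0, 6.0)
        b = block(row("ref", 100, ref_text), row("sp1", 0, sp_text))
        hs = best_species_hits(ref_site, [b], lom, cal, "ref")
        assert hs.hits["sp1"][1] == pytest.approx(1.0)

    def test_reverse_strand_hit_found(self, scoring):
        m, lom, cal = scoring
        cons = m.consensus()
        ref_site = ScoredSite("M8", "chr1", 100, 108, "+", cons, lom.ymax, 1.0, 6.0)
        b = block(row("ref", 100, cons), row("sp1", 40, reverse_complement(cons)))
        hs = best_species_hits(ref_site, [b], lom, cal, "ref")
        assert hs.hits["sp1"][1] == pytest.approx(1.0)


class TestMinSpeciesFilter:
    def _hitset(self, hits):
        return SpeciesHitSet("s", "ref", hits, aligned_species_count=len(hits))

    def test_single_conserved_species_passes(self):
        hs = self._hitset({"ref": ("A", 1.0, 6.0), "sp1": ("A", 0.9, 5.0)})
        assert min_species_filter(hs, 1, z_floor=4.27)

    def test_nonprimate_requirement(self):
        hits = {"ref": ("A", 1.0, 6.0)}
        for sp in ("chimp", "gorilla"):
            hits[sp] = ("A", 0.95, 5.0)
        for sp in ("mouse", "rat", "dog"):
            hits[sp] = ("A", 0.9, 5.0)
        hs = self._hitset(hits)
        nonprimates = {"mouse", "rat", "dog", "cow"}
        assert not min_species_filter(hs, 4, z_floor=4.27, eligible_species=nonprimates)
        assert min_species_filter(hs, 3, z_floor=4.27, eligible_species=nonprimates)

    def test_required_zero_always_true(self):
        hs = self._hitset({"ref": ("A", 1.0, 6.0)})
        assert min_species_filter(hs, 0)

    def test_negative_required_rejected(self):
        hs = self._hitset({"ref": ("A", 1.0, 6.0)})
        with pytest.raises(ValueError):
            min_species_filter(hs, -1)


class TestMafIO:
    def test_round_trip(self, tmp_path, planted_world):
        _, _, _, alignment = planted_world
        path = tmp_path / "a.maf"
        write_maf(alignment.blocks, path)
        again = read_maf(path, "ref")
        assert len(again) == len(alignment.blocks)
        for a, b in zip(alignment.blocks, again):
            assert set(a.rows) == set(b.rows)
            for sp in a.rows:
                ra, rb = a.rows[sp], b.rows[sp]
                assert (ra.chrom, ra.start, ra.size, ra.strand, ra.text, ra.src_size) == (
                    rb.chrom, rb.start, rb.size, rb.strand, rb.text, rb.src_size
                )

    def test_inconsistent_block_rejected(self):
        with pytest.raises(ValueError):
            block(row("ref", 0, "AAAA"), row("sp1", 0, "AAAAA"))
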