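"""Lift reference binding sites through a multiple whole-genome alignment.

Whole-genome alignments are low-resolution: a motif that is perfectly
conserved in another species may sit a few bases out of the aligned columns,
or be split across two alignment blocks.  Rather than reading the aligned
columns directly, each reference site is expanded by a pad (15 bp on each
side), every MAF block overlapping the expanded interval is collected, each
species' rows are concatenated when they are within 30 bp of each other on
that species' chromosome (keeping the intervening sequence), and the merged
segments are rescanned on both strands for the best motif match per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .pwm import (
    LogOddsMatrix,
    ZCalibration,
    encode,
    reverse_complement,
    window_lod_scores,
)
from .scan import ScoredSite

# genome_lookup(species, chrom, start, end) -> forward-strand sequence or None
GenomeLookup = Callable[[str, str, int, int], str | None]


@dataclass(frozen=True)
class SeqRow:
    """One 's' line of a MAF block: a segment of one species' chromosome.

    ``start``/``size`` follow MAF semantics: coordinates on ``strand``
    (i.e. counted from the reverse-complement origin when strand is '-'),
    with ``src_size`` the full chromosome length.
    """

    species: str
    chrom: str
    start: int
    size: int
    strand: str
    text: str
    src_size: int

    @property
    def end(self) -> int:
        return self.start + self.size

    @property
    def ungapped(self) -> str:
        return self.text.replace("-", "")


@dataclass
class AlignmentBlock:
    """One MAF alignment block: one row per species, equal text lengths."""

    rows: dict[str, SeqRow]
    ref: str

    def __post_init__(self) -> None:
        lengths = {len(r.text) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("aligned rows differ in text length")
        for r in self.rows.values():
            if len(r.ungapped) != r.size:
                raise ValueError(
                    f"row {r.species}.{r.chrom}: ungapped length != size field"
                )
        if self.ref not in self.rows:
            raise ValueError(f"reference species {self.ref!r} missing from block")

    @property
    def ref_row(self) -> SeqRow:
        return self.rows[self.ref]


def read_maf(path, ref_species: str) -> list[AlignmentBlock]:
    """Read MAF blocks; only 's' lines are used (Biopython skips 'i'/'e'
    context lines).  Species = source name before the first dot, per UCSC
    convention.  If a species appears twice in one block the first row wins."""
    from Bio import AlignIO

    blocks = []
    for msa in AlignIO.parse(path, "maf"):
        rows: dict[str, SeqRow] = {}
        for rec in msa:
            species, _, chrom = rec.id.partition(".")
            ann = rec.annotations
            row = SeqRow(
                species=species,
                chrom=chrom or species,
                start=int(ann["start"]),
                size=int(ann["size"]),
                strand="+" if ann.get("strand", 1) in (1, "+") else "-",
                text=str(rec.seq),
                src_size=int(ann.get("srcSize", 0)),
            )
            rows.setdefault(species, row)
        if rows:
            blocks.append(AlignmentBlock(rows, ref_species))
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path) -> None:
    from Bio import AlignIO
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msas = []
    for block in blocks:
        recs = []
        for row in block.rows.values():
            recs.append(
                SeqRecord(
                    Seq(row.text),
                    id=f"{row.species}.{row.chrom}",
                    annotations={
                        "start": row.start,
                        "size": row.size,
                        "strand": row.strand,
                        "srcSize": row.src_size,
                    },
                )
            )
        msas.append(MultipleSeqAlignment(recs))
    with open(path, "w") as handle:
        AlignIO.write(msas, handle, "maf")


class MafBlockSet:
    """Interval-indexed collection of MAF blocks, keyed by reference row."""

    def __init__(self, blocks: Sequence[AlignmentBlock]):
        self.blocks = list(blocks)
        self._trees: dict[str, IntervalTree] = {}
        for i, block in enumerate(self.blocks):
            row = block.ref_row
            if row.size > 0:
                self._trees.setdefault(row.chrom, IntervalTree()).addi(
                    row.start, row.end, i
                )

    def overlapping(self, chrom: str, start: int, end: int) -> list[AlignmentBlock]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        idx = sorted(iv.data for iv in tree.overlap(max(start, 0), end))
        return [self.blocks[i] for i in idx]


def extract_blocks(
    site: ScoredSite, maf: MafBlockSet | Sequence[AlignmentBlock], pad: int = 15
) -> list[AlignmentBlock]:
    """All blocks whose reference row overlaps the site expanded by ``pad``
    bases on each side (clipped at the chromosome start)."""
    if not isinstance(maf, MafBlockSet):
        maf = MafBlockSet(maf)
    return maf.overlapping(site.chrom, site.start - pad, site.end + pad)


def _fill(
    row_prev: SeqRow, row_next: SeqRow, gap: int, genome_lookup: GenomeLookup | None
) -> str:
    """Intervening species sequence between two adjacent rows, or N-fill."""
    if genome_lookup is not None:
        if row_prev.strand == "+":
            seq = genome_lookup(row_prev.species, row_prev.chrom, row_prev.end,
                                row_prev.end + gap)
        else:
            # '-' strand MAF coordinates count from the chromosome's 3' end
            fwd_end = row_prev.src_size - row_prev.end
            seq = genome_lookup(row_prev.species, row_prev.chrom, fwd_end - gap, fwd_end)
            seq = reverse_complement(seq) if seq is not None else None
        if seq is not None and len(seq) == gap:
            return seq
    return "N" * gap


def merge_blocks(
    blocks: Sequence[AlignmentBlock],
    species: str,
    max_gap: int = 30,
    genome_lookup: GenomeLookup | None = None,
) -> list[str]:
    """Concatenate one species' rows into locally contiguous segments.

    Rows on the same chromosome and strand whose gap (in that species'
    coordinates) is between 0 and ``max_gap`` are joined, with the
    intervening bases taken from ``genome_lookup`` when available and from
    'N' otherwise.  Rows farther apart, overlapping, or on different
    chromosomes/strands start new segments.  Gap-only rows are dropped.
    Returns the ungapped merged segment strings.
    """
    rows = [
        b.rows[species]
        for b in blocks
        if species in b.rows and b.rows[species].size > 0
    ]
    rows.sort(key=lambda r: (r.chrom, r.strand, r.start))
    segments: list[str] = []
    current: str | None = None
    prev: SeqRow | None = None
    for row in rows:
        if (
            prev is not None
            and row.chrom == prev.chrom
            and row.strand == prev.strand
            and 0 <= row.start - prev.end <= max_gap
        ):
            current += _fill(prev, row, row.start - prev.end, genome_lookup)  # type: ignore[operator]
            current += row.ungapped
        else:
            if current:
                segments.append(current)
            current = row.ungapped
        prev = row
    if current:
        segments.append(current)
    return segments


@dataclass
class SpeciesHitSet:
    """Best motif match per species for one reference site."""

    site_ref: str
    ref_species: str
    hits: dict[str, tuple[str, float, float]]  # species -> (seq, nlod, z)
    aligned_species_count: int


def best_species_hits(
    site: ScoredSite,
    blocks: Sequence[AlignmentBlock],
    lom: LogOddsMatrix,
    cal: ZCalibration,
    ref_species: str,
    genome_lookup: GenomeLookup | None = None,
    max_gap: int = 30,
    merging: bool = True,
) -> SpeciesHitSet:
    """Rescan each aligned species' merged segments for the best motif hit.

    Both strands of every merged segment are scanned; windows containing N
    are skipped; species with no scorable window are omitted.  The reference
    species' hit is taken from the already-scored site, not re-derived from
    its MAF row.  ``merging=False`` scans each block's row separately (for
    diagnosing what the 30 bp concatenation recovers).
    """
    species_names: set[str] = set()
    for block in blocks:
        for name, row in block.rows.items():
            if row.size > 0:
                species_names.add(name)
    species_names.add(ref_species)

    hits: dict[str, tuple[str, float, float]] = {
        ref_species: (site.seq, site.nlod, site.z)
    }
    # all species' segments are scored in one N-joined string (an N window
    # is unscorable, so the joints cannot produce spurious cross-segment
    # windows); this keeps the per-site cost to two vectorised scans
    spans: list[tuple[str, int, int]] = []  # (species, start, end) in combined
    parts: list[str] = []
    offset = 0
    for species in sorted(species_names - {ref_species}):
        for segment in merge_blocks(
            blocks, species, max_gap=max_gap if merging else -1,
            genome_lookup=genome_lookup,
        ):
            parts.append(segment)
            spans.append((species, offset, offset + len(segment)))
            offset += len(segment) + 1  # +1 for the N separator
    if spans:
        combined = "N".join(parts)
        codes = encode(combined)
        L = lom.length
        fwd = window_lod_scores(codes, lom.entries)
        rev = window_lod_scores(codes, lom.entries[::-1, ::-1])
        fwd = np.where(np.isnan(fwd), -np.inf, fwd)
        rev = np.where(np.isnan(rev), -np.inf, rev)
        best: dict[str, tuple[float, str]] = {}
        for species, start, end in spans:
            width = end - start - L + 1
            if width <= 0:
                continue
            for strand, lods in (("+", fwd), ("-", rev)):
                window_lods = lods[start : start + width]
                idx = int(np.argmax(window_lods))
                if window_lods[idx] == -np.inf:
                    continue
                window = combined[start + idx : start + idx + L].upper()
                if strand == "-":
                    window = reverse_complement(window)
                nlod = float(np.clip((window_lods[idx] - lom.ymin) / lom.span, 0.0, 1.0))
                if species not in best or nlod > best[species][0]:
                    best[species] = (nlod, window)
        for species, (nlod, window) in best.items():
            hits[species] = (window, nlod, (nlod - cal.mu) / cal.sigma)
    return SpeciesHitSet(
        site_ref=site.key,
        ref_species=ref_species,
        hits=hits,
        aligned_species_count=len(species_names),
    )


def min_species_filter(
    hitset: SpeciesHitSet,
    required: int,
    z_floor: float = 1.64,
    eligible_species: set[str] | None = None,
) -> bool:
    """True iff at least ``required`` non-reference species (restricted to
    ``eligible_species`` when given, e.g. non-primates) have a hit with
    z >= z_floor."""
    if required < 0:
        raise ValueError("required must be >= 0")
    ref = hitset.ref_species
    count = 0
    for species, (_, _, z) in hitset.hits.items():
        if species == ref:
            continue
        if eligible_species is not None and species not in eligible_species:
            continue
        if z >= z_floor:
            count += 1
    return count >= required
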