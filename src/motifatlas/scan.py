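"""Scan a reference genome for candidate binding sites.

Both strands are scanned with the bounded log-odds matrix; windows with
ambiguity codes are skipped, windows overlapping mask intervals (exons,
repeats) are excluded, and candidates are kept when their calibrated
z-score clears the profile threshold (4.27 for mammalian-scale genomes,
2.57-3.72 for compact genomes).  A per-matrix cap keeps every site whose z
is at least that of the k-th best site, ties included.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .pwm import (
    LogOddsMatrix,
    ZCalibration,
    encode,
    reverse_complement,
    window_lod_scores,
)

Interval = tuple[str, int, int]


@dataclass(frozen=True, order=True)
class ScoredSite:
    """One matrix hit on the reference genome (0-based half-open)."""

    matrix_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    lod: float
    nlod: float
    z: float

    @property
    def key(self) -> str:
        return f"{self.matrix_id}:{self.chrom}:{self.start}:{self.strand}"


@dataclass
class ScanConfig:
    """Scan thresholds and masks.

    z_min defaults to the mammalian profile (upper-tail p = 1e-5); use
    2.57-3.72 for yeast/fly/worm-sized genomes.  k caps the number of sites
    per matrix (ties at the k-th z are kept).
    """

    z_min: float = 4.27
    k: int = 100_000
    masks: Sequence[Interval] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _mask_trees(masks: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in masks:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def scan(
    genome: Mapping[str, str],
    lom: LogOddsMatrix,
    cal: ZCalibration,
    cfg: ScanConfig | None = None,
) -> list[ScoredSite]:
    """All sites with z >= cfg.z_min on both strands, masked and sorted.

    Any overlap (>= 1 bp) with a mask interval excludes a site.  The top-k
    cap is a separate step (`top_k_filter`), applied after masking.
    """
    if cal is None:
        raise ValueError("a ZCalibration is required to scan")
    cfg = cfg or ScanConfig()
    trees = _mask_trees(cfg.masks)
    L = lom.length
    sites: list[ScoredSite] = []
    for chrom in sorted(genome):
        seq = str(genome[chrom])
        codes = encode(seq)
        tree = trees.get(chrom)
        for strand, entries in (("+", lom.entries), ("-", lom.entries[::-1, ::-1])):
            lods = window_lod_scores(codes, entries)
            if lods.size == 0:
                continue
            nlods = (lods - lom.ymin) / lom.span
            zs = (nlods - cal.mu) / cal.sigma
            with np.errstate(invalid="ignore"):
                hits = np.flatnonzero(zs >= cfg.z_min)
            for start in hits:
                start = int(start)
                end = start + L
                if tree is not None and tree.overlap(start, end):
                    continue
                window = seq[start:end].upper()
                if strand == "-":
                    window = reverse_complement(window)
                sites.append(
                    ScoredSite(
                        matrix_id=lom.source,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        seq=window,
                        lod=float(lods[start]),
                        nlod=float(np.clip(nlods[start], 0.0, 1.0)),
                        z=float(zs[start]),
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def top_k_filter(sites: Sequence[ScoredSite], k: int) -> list[ScoredSite]:
    """Keep every site whose z is at least the k-th highest z (ties kept,
    so the result may exceed k).  Input order is preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sites) <= k:
        return list(sites)
    kth = sorted((s.z for s in sites), reverse=True)[k - 1]
    return [s for s in sites if s.z >= kth]


# ---------------------------------------------------------------------------
# writers (0-based half-open BED; 1-based closed GFF)
# ---------------------------------------------------------------------------


def write_sites_bed(sites: Iterable[ScoredSite], path) -> None:
    with open(path, "w") as handle:
        for s in sites:
            handle.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.matrix_id}\t{s.z:.4f}\t{s.strand}\n"
            )


def write_sites_gff(sites: Iterable[ScoredSite], path, source: str = "motifatlas") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for s in sites:
            attrs = f"ID={s.key};matrix_id={s.matrix_id};nlod={s.nlod:.4f};z={s.z:.4f}"
            handle.write(
                f"{s.chrom}\t{source}\tTF_binding_site\t{s.start + 1}\t{s.end}\t"
                f"{s.z:.4f}\t{s.strand}\t.\t{attrs}\n"
            )


def write_sites_csv(sites: Iterable[ScoredSite], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["matrix_id", "chrom", "start", "end", "strand", "seq", "lod", "nlod", "z"]
        )
        for s in sites:
            writer.writerow(
                [s.matrix_id, s.chrom, s.start, s.end, s.strand, s.seq,
                 f"{s.lod:.6g}", f"{s.nlod:.6g}", f"{s.z:.6g}"]
            )
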