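"""Map post-processing: per-factor redundancy collapse, TSS-distance and
SNP annotation, conservation stratification, and ranked-recovery AUC.

A transcription factor often has several matrices; to count a genomic site
once per factor, overlapping sites of the same factor are grouped by
transitive overlap and represented by their highest-BBLS member.  Sites are
then annotated with the signed distance from their midpoint to the nearest
transcription start site (negative = upstream on the gene's strand) and
with overlapping SNPs, stratified into BBLS quartiles, and optionally
scored against labelled region sets with a Mann-Whitney AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import rankdata

from .conservation import ConservedSite


@dataclass(frozen=True)
class TranscriptAnnotation:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tss: int  # 0-based position


@dataclass
class MapRecord:
    """Final map row: a conserved site with factor, FDR and gene context."""

    site: ConservedSite
    tf_name: str
    fdr: float
    nearest_gene: str | None = None
    distance_to_tss: float | None = None

    @property
    def bbls(self) -> float:
        return self.site.bbls

    @property
    def nlod(self) -> float:
        return self.site.nlod

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def start(self) -> int:
        return self.site.start

    @property
    def end(self) -> int:
        return self.site.end


# ---------------------------------------------------------------------------
# redundancy filter
# ---------------------------------------------------------------------------


def redundancy_filter(
    sites: Sequence[ConservedSite], matrix_to_tf: Mapping[str, str]
) -> list[ConservedSite]:
    """One representative per overlap group per transcription factor.

    Overlap (any shared base, strand-agnostic) is closed transitively within
    each factor; the representative is the group's max-BBLS site, ties
    broken by higher NLOD, then leftmost start.  Sites of different factors
    never compete.
    """
    by_tf: dict[str, list[ConservedSite]] = {}
    for site in sites:
        if site.matrix_id not in matrix_to_tf:
            raise KeyError(f"matrix id {site.matrix_id!r} has no factor mapping")
        by_tf.setdefault(matrix_to_tf[site.matrix_id], []).append(site)

    kept: list[ConservedSite] = []
    for members in by_tf.values():
        members.sort(key=lambda s: (s.chrom, s.start, s.end))
        group: list[ConservedSite] = []
        group_chrom, group_end = None, -1
        for site in members + [None]:  # type: ignore[list-item]
            if (
                site is not None
                and site.chrom == group_chrom
                and site.start < group_end
            ):
                group.append(site)
                group_end = max(group_end, site.end)
            else:
                if group:
                    kept.append(
                        max(group, key=lambda s: (s.bbls, s.nlod, -s.start))
                    )
                if site is not None:
                    group = [site]
                    group_chrom, group_end = site.chrom, site.end
    kept.sort(key=lambda s: (s.chrom, s.start))
    return kept


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _midpoint(site) -> float:
    return (site.start + site.end) / 2.0


def tss_distance(
    site, annotations: Sequence[TranscriptAnnotation]
) -> tuple[str | None, float | None]:
    """Nearest TSS by absolute distance from the site midpoint.

    Returns (gene_id, signed distance); the sign is negative when the site
    lies upstream of the TSS relative to the gene's strand.  (None, None)
    when the site's chromosome carries no annotation.
    """
    mid = _midpoint(site)
    best: tuple[float, float, str] | None = None
    for ann in annotations:
        if ann.chrom != site.chrom:
            continue
        signed = mid - ann.tss if ann.strand == "+" else ann.tss - mid
        key = (abs(signed), signed, ann.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[2], best[1]


def annotate_records(
    sites: Sequence[ConservedSite],
    matrix_to_tf: Mapping[str, str],
    fdrs: Sequence[float],
    annotations: Sequence[TranscriptAnnotation],
) -> list[MapRecord]:
    records = []
    for site, fdr in zip(sites, fdrs):
        gene, dist = tss_distance(site, annotations)
        records.append(
            MapRecord(site, matrix_to_tf[site.matrix_id], float(fdr), gene, dist)
        )
    return records


def promoter_window_select(
    records: Sequence[MapRecord],
    upstream: int = 15_000,
    downstream: int = 3_000,
    genes: set[str] | None = None,
) -> list[MapRecord]:
    """Records whose signed TSS distance lies in [-upstream, +downstream]
    (inclusive), optionally restricted to a named gene set."""
    out = []
    for rec in records:
        if rec.distance_to_tss is None:
            continue
        if genes is not None and rec.nearest_gene not in genes:
            continue
        if -upstream <= rec.distance_to_tss <= downstream:
            out.append(rec)
    return out


def snp_overlap(
    records: Sequence[MapRecord], snps: Sequence[tuple[str, int, str]]
) -> list[tuple[MapRecord, str]]:
    """Every (record, snp_id) pair where the SNP's 0-based position lies in
    the half-open site interval [start, end)."""
    trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(records):
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, i)
    pairs = []
    for chrom, pos, snp_id in snps:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in sorted(tree.at(pos), key=lambda iv: iv.data):
            pairs.append((records[iv.data], snp_id))
    return pairs


# ---------------------------------------------------------------------------
# stratification and evaluation
# ---------------------------------------------------------------------------


def bbls_quartile_stratify(
    records: Sequence[MapRecord],
    bin_width: float = 1_000.0,
    max_distance: float = 10_000.0,
) -> tuple[list[list[MapRecord]], list[tuple[np.ndarray, np.ndarray]]]:
    """Split records into four equal-size BBLS groups (ascending; sizes
    differ by at most 1, ties filled in stable input order) and histogram
    each group's TSS distances over [-max_distance, max_distance]."""
    if len(records) < 4:
        raise ValueError("need at least 4 records to form quartiles")
    order = np.argsort([r.bbls for r in records], kind="stable")
    groups = [
        [records[i] for i in chunk] for chunk in np.array_split(order, 4)
    ]
    bins = np.arange(-max_distance, max_distance + bin_width, bin_width)
    histograms = []
    for group in groups:
        dists = [
            r.distance_to_tss for r in group if r.distance_to_tss is not None
        ]
        histograms.append(np.histogram(dists, bins=bins))
    return groups, histograms


def evaluate_auc(
    records: Sequence,
    regions: Sequence[tuple[str, int, int, int]],
    negatives_mode: str = "include",
    score: Callable[[object], float] | None = None,
) -> float:
    """Mann-Whitney AUC of labelled regions ranked by their best site score.

    ``regions`` are (chrom, start, end, label) with label 1 = positive.
    Each region takes the maximum ``score`` (default: BBLS) of the sites
    overlapping it; regions containing no site rank below every scored
    region when ``negatives_mode="include"`` and are dropped when
    ``"exclude"``.  Ties contribute 0.5 (Mann-Whitney convention).
    """
    if negatives_mode not in ("include", "exclude"):
        raise ValueError("negatives_mode must be 'include' or 'exclude'")
    score = score or (lambda r: r.bbls)
    trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(records):
        if rec.end > rec.start:
            trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, i)
    scores, labels = [], []
    for chrom, start, end, label in regions:
        tree = trees.get(chrom)
        hits = tree.overlap(start, end) if tree is not None else ()
        if hits:
            best = max(score(records[iv.data]) for iv in hits)
        elif negatives_mode == "exclude":
            continue
        else:
            best = -np.inf
        scores.append(best)
        labels.append(int(label))
    labels_arr = np.asarray(labels)
    n_pos = int(labels_arr.sum())
    n_neg = len(labels_arr) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[labels_arr == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
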