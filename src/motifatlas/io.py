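"""Readers and writers for the standard flat formats the pipeline touches:
FASTA genomes, BED intervals, a minimal transcript GFF, and SNP positions
from BED or a minimal VCF (CHROM/POS/ID)."""

from __future__ import annotations

import textwrap
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .postprocess import MapRecord, TranscriptAnnotation


def load_fasta(path) -> dict[str, str]:
    """Load a FASTA file into {name: sequence} via a pyfaidx index."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fasta:
        return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name in genome:
            handle.write(f">{name}\n")
            for line in textwrap.wrap(str(genome[name]), width):
                handle.write(line + "\n")


def read_bed(path) -> list[tuple]:
    """BED rows as tuples (chrom, start, end[, name[, score[, strand]]])."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    rows = []
    for row in frame.itertuples(index=False):
        values = list(row)
        values[1] = int(values[1])
        values[2] = int(values[2])
        rows.append(tuple(values))
    return rows


def write_bed(intervals: Iterable[Sequence], path) -> None:
    with open(path, "w") as handle:
        for interval in intervals:
            handle.write("\t".join(str(v) for v in interval) + "\n")


def read_snps_bed(path) -> list[tuple[str, int, str]]:
    """SNP positions from BED: (chrom, pos0, id); id defaults to coordinates."""
    out = []
    for row in read_bed(path):
        chrom, start = row[0], row[1]
        snp_id = str(row[3]) if len(row) > 3 else f"{chrom}:{start}"
        out.append((chrom, int(start), snp_id))
    return out


def read_snps_vcf(path) -> list[tuple[str, int, str]]:
    """SNP positions from a VCF (CHROM/POS/ID only; POS converted to 0-based)."""
    from pysam import VariantFile

    out = []
    with VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append((rec.chrom, rec.pos - 1, rec.id or f"{rec.chrom}:{rec.pos}"))
    return out


def write_transcripts_gff(
    transcripts: Iterable[TranscriptAnnotation], path, source: str = "motifatlas"
) -> None:
    """One-bp TSS features, 1-based closed per GFF."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for t in transcripts:
            attrs = f"ID={t.transcript_id};gene_id={t.gene_id}"
            handle.write(
                f"{t.chrom}\t{source}\tTSS\t{t.tss + 1}\t{t.tss + 1}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )


def read_transcripts_gff(path) -> list[TranscriptAnnotation]:
    transcripts = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            transcripts.append(
                TranscriptAnnotation(
                    gene_id=attrs.get("gene_id", attrs.get("ID", "?")),
                    transcript_id=attrs.get("ID", "?"),
                    chrom=fields[0],
                    strand=fields[6],
                    tss=int(fields[3]) - 1,
                )
            )
    return transcripts


def write_map_csv(records: Iterable[MapRecord], path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "tf_name": rec.tf_name,
                "matrix_id": rec.site.matrix_id,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "strand": rec.site.site.strand,
                "nlod": rec.nlod,
                "z": rec.site.site.z,
                "bbls": rec.bbls,
                "fdr": rec.fdr,
                "nearest_gene": rec.nearest_gene,
                "distance_to_tss": rec.distance_to_tss,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
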