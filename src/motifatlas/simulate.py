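"""Seeded synthetic fixtures: toy genomes, alignments, trees, annotations.

The generator produces a coherent miniature study system — an i.i.d.
background reference genome with planted motif instances, per-species
genomes derived from it by point substitutions, a MAF alignment whose block
structure can reproduce the pathologies the lifting stage exists for (a
motif shifted a few bases out of alignment frame, or split across two
blocks with an insertion between them), a phylogeny, and the surrounding
annotations (TSSs, masks, SNPs, labelled regions).  Everything is
reproducible bit-for-bit from the spec's seed.

The mutation model is deliberately simple: uniform point substitutions at a
fixed per-species rate, with indels emulated through inter-block insertions
rather than within-block gaps.  Species that "carry" a plant hold the exact
consensus (optionally degraded by a counted number of substitutions);
non-carriers get the motif footprint re-randomised so no signal remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conservation import Phylogeny
from .lift import AlignmentBlock, GenomeLookup, SeqRow
from .pwm import ALPHABET, MotifMatrix, encode

_BASES = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def matrix_from_consensus(
    matrix_id: str, tf_name: str, consensus: str, certainty: float = 0.97
) -> MotifMatrix:
    """A sharply peaked matrix around a consensus string: the consensus base
    gets ``certainty``, the rest split the remainder evenly."""
    codes = encode(consensus)
    if np.any(codes >= 4):
        raise ValueError("consensus must be over ACGT")
    probs = np.full((len(consensus), 4), (1.0 - certainty) / 3.0)
    probs[np.arange(len(consensus)), codes] = certainty
    return MotifMatrix(matrix_id, tf_name, probs)


@dataclass
class PlantSpec:
    """One planted motif instance.

    ``carriers`` limits which non-reference species hold the motif (None =
    all); ``mutations`` counts per-species substitutions applied inside a
    carried motif; ``shift`` offsets a carrier's motif in its own genome
    relative to the aligned position (exercising the lift pad)."""

    matrix_id: str
    position: int
    carriers: set[str] | None = None
    mutations: dict[str, int] = field(default_factory=dict)
    shift: dict[str, int] = field(default_factory=dict)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    The first species is the reference.  ``block_structure`` is a repeating
    pattern of (block_length, inter_block_insertion) pairs; the insertion
    is extra sequence present in every non-reference species between two
    adjacent alignment blocks (the reference stays contiguous)."""

    seed: int
    species: Sequence[str] = ("ref", "sp1", "sp2", "sp3", "sp4", "sp5")
    genome_length: int = 20_000
    chrom: str = "chr1"
    tree: str = "random"
    plants: list[PlantSpec] = field(default_factory=list)
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    block_structure: Sequence[tuple[int, int]] = ((1000, 0),)
    mutation_rate: float = 0.1

    @property
    def reference(self) -> str:
        return self.species[0]


def resolve_tree(spec: FixtureSpec) -> Phylogeny:
    newick = (
        random_tree(spec.species, seed=spec.seed)
        if spec.tree == "random"
        else spec.tree
    )
    return Phylogeny.from_newick(newick)


def random_tree(
    species: Sequence[str], seed: int, mean_branch: float = 0.4
) -> str:
    """Random topology by iteratively joining two subtrees, with
    exponentially distributed branch lengths (mean ``mean_branch``
    substitutions/site)."""
    rng = np.random.default_rng([seed, 3])
    nodes = list(species)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.exponential(mean_branch, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return nodes[0] + ";"


def _blocks_layout(spec: FixtureSpec) -> list[tuple[int, int, int]]:
    """Tile the reference with the repeating block pattern.

    Returns (ref_start, ref_end, insertion_after) triples; the final block
    is clipped to the genome end and has no trailing insertion."""
    layout = []
    pos = 0
    i = 0
    pattern = list(spec.block_structure)
    while pos < spec.genome_length:
        length, gap = pattern[i % len(pattern)]
        end = min(pos + length, spec.genome_length)
        layout.append((pos, end, gap if end < spec.genome_length else 0))
        pos = end
        i += 1
    return layout


def _check_plants(spec: FixtureSpec, matrices: Mapping[str, MotifMatrix]) -> None:
    intervals = []
    for plant in spec.plants:
        L = matrices[plant.matrix_id].length
        if not 0 <= plant.position <= spec.genome_length - L:
            raise ValueError(f"plant at {plant.position} outside genome bounds")
        intervals.append((plant.position, plant.position + L))
    intervals.sort()
    for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping plants at {s1} and {s2}")


def simulate_reference(
    spec: FixtureSpec, matrices: Mapping[str, MotifMatrix]
) -> dict[str, str]:
    """I.i.d. background genome with consensus plants at the stated loci."""
    _check_plants(spec, matrices)
    rng = np.random.default_rng([spec.seed, 0])
    codes = rng.choice(4, size=spec.genome_length, p=spec.background).astype(np.int8)
    for plant in spec.plants:
        motif = encode(matrices[plant.matrix_id].consensus())
        codes[plant.position : plant.position + len(motif)] = motif
    return {spec.chrom: _decode(codes.astype(np.uint8))}


@dataclass
class SimulatedAlignment:
    blocks: list[AlignmentBlock]
    species_genomes: dict[str, dict[str, str]]

    def genome_lookup(self) -> GenomeLookup:
        def lookup(species: str, chrom: str, start: int, end: int) -> str | None:
            genome = self.species_genomes.get(species)
            if genome is None or chrom not in genome:
                return None
            seq = genome[chrom]
            if start < 0 or end > len(seq):
                return None
            return seq[start:end]

        return lookup


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if hits.size:
        # shift by 1..3 mod 4: always a different base
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def simulate_alignment(
    spec: FixtureSpec,
    reference: Mapping[str, str],
    matrices: Mapping[str, MotifMatrix],
) -> SimulatedAlignment:
    """Per-species genomes plus the MAF blocks aligning them to the
    reference.

    Each non-reference species copies the reference block-by-block with
    point substitutions, separated by the pattern's insertions.  Plant
    handling per species: carriers get the intact consensus written at the
    mapped (contiguous) species position — so a plant whose footprint spans
    a block boundary with an insertion becomes the split-block scenario —
    then the counted substitutions; shifted carriers get the motif at an
    offset inside the pad; non-carriers get the aligned footprint
    re-randomised.
    """
    _check_plants(spec, matrices)
    ref_seq = reference[spec.chrom]
    ref_codes = encode(ref_seq)
    layout = _blocks_layout(spec)
    bg = np.asarray(spec.background)

    # cumulative insertion offset before each block, shared by all species
    cum = []
    total = 0
    for _, _, gap in layout:
        cum.append(total)
        total += gap

    def species_pos(ref_pos: int) -> int:
        for t, (s, e, _) in enumerate(layout):
            if s <= ref_pos < e:
                return ref_pos + cum[t]
        raise ValueError(f"position {ref_pos} outside genome")

    species_genomes: dict[str, dict[str, str]] = {
        spec.reference: {spec.chrom: ref_seq}
    }
    per_species_codes: dict[str, np.ndarray] = {}
    for idx, sp in enumerate(spec.species[1:], start=1):
        rng = np.random.default_rng([spec.seed, 1, idx])
        pieces = []
        for s, e, gap in layout:
            pieces.append(_mutate(ref_codes[s:e], spec.mutation_rate, rng))
            if gap:
                pieces.append(rng.choice(4, size=gap, p=bg).astype(np.int8))
        codes = np.concatenate(pieces)

        for plant in spec.plants:
            motif = encode(matrices[plant.matrix_id].consensus())
            L = len(motif)
            is_carrier = plant.carriers is None or sp in plant.carriers
            shift = plant.shift.get(sp, 0)
            if abs(shift) >= L:
                raise ValueError("shift must be smaller than the motif length")
            # re-randomise the aligned footprint (per-base mapping)
            aligned = np.array(
                [species_pos(x) for x in range(plant.position, plant.position + L)]
            )
            codes[aligned] = rng.choice(4, size=L, p=bg)
            if is_carrier:
                q = species_pos(plant.position) + shift
                if not 0 <= q <= len(codes) - L:
                    raise ValueError("shifted plant outside species genome")
                codes[q : q + L] = motif
                n_mut = plant.mutations.get(sp, 0)
                if n_mut:
                    where = rng.choice(L, size=n_mut, replace=False)
                    codes[q + where] = (
                        codes[q + where] + rng.integers(1, 4, size=n_mut)
                    ) % 4
        per_species_codes[sp] = codes
        species_genomes[sp] = {spec.chrom: _decode(codes.astype(np.uint8))}

    blocks = []
    for t, (s, e, _) in enumerate(layout):
        rows = {
            spec.reference: SeqRow(
                species=spec.reference,
                chrom=spec.chrom,
                start=s,
                size=e - s,
                strand="+",
                text=ref_seq[s:e],
                src_size=len(ref_seq),
            )
        }
        for sp in spec.species[1:]:
            codes = per_species_codes[sp]
            start = s + cum[t]
            rows[sp] = SeqRow(
                species=sp,
                chrom=spec.chrom,
                start=start,
                size=e - s,
                strand="+",
                text=_decode(codes[start : start + (e - s)].astype(np.uint8)),
                src_size=len(codes),
            )
        blocks.append(AlignmentBlock(rows, spec.reference))
    return SimulatedAlignment(blocks, species_genomes)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass
class Annotations:
    transcripts: list
    masks: list[tuple[str, int, int]]
    snps: list[tuple[str, int, str]]
    regions: list[tuple[str, int, int, int]]


def simulate_annotations(
    spec: FixtureSpec,
    matrices: Mapping[str, MotifMatrix],
    tss_fraction: float = 1.0,
    tss_plants: Sequence[int] | None = None,
    tss_max_offset: int = 800,
    masked_plants: Sequence[int] = (),
    positive_plants: Sequence[int] | None = None,
    negative_plants: Sequence[int] = (),
    n_extra_genes: int = 3,
    n_background_snps: int = 5,
    region_halfwidth: int = 50,
) -> Annotations:
    """Gene/region scaffolding around the plants.

    A ``tss_fraction`` of plants get a transcription start site within
    ``tss_max_offset`` bp downstream (emulating the promoter-proximal
    concentration of regulatory sites); ``tss_plants`` instead names the
    exact plants to anchor (overriding the fraction); masks cover the
    listed plants;
    labelled regions wrap the listed positive/negative plants for ranked
    recovery evaluation; SNPs fall inside the first plants and at random
    background positions.
    """
    from .postprocess import TranscriptAnnotation

    rng = np.random.default_rng([spec.seed, 2])
    plant_spans = [
        (p.position, p.position + matrices[p.matrix_id].length)
        for p in spec.plants
    ]
    transcripts = []
    for i, (start, end) in enumerate(plant_spans):
        anchored = (
            i in set(tss_plants)
            if tss_plants is not None
            else rng.random() < tss_fraction
        )
        if anchored:
            offset = int(rng.integers(50, tss_max_offset + 1))
            tss = min(end + offset, spec.genome_length - 1)
            transcripts.append(
                TranscriptAnnotation(f"gene{i}", f"tx{i}", spec.chrom, "+", tss)
            )
    for j in range(n_extra_genes):
        tss = int(rng.integers(0, spec.genome_length))
        transcripts.append(
            TranscriptAnnotation(f"bg_gene{j}", f"bg_tx{j}", spec.chrom, "+", tss)
        )

    masks = [
        (spec.chrom, max(plant_spans[i][0] - 5, 0), plant_spans[i][1] + 5)
        for i in masked_plants
    ]

    snps = []
    for i, (start, end) in enumerate(plant_spans[:2]):
        snps.append((spec.chrom, (start + end) // 2, f"rs_plant{i}"))
    for j in range(n_background_snps):
        snps.append(
            (spec.chrom, int(rng.integers(0, spec.genome_length)), f"rs_bg{j}")
        )

    if positive_plants is None:
        positive_plants = range(len(spec.plants))
    regions = []
    for i in positive_plants:
        s, e = plant_spans[i]
        regions.append(
            (spec.chrom, max(s - region_halfwidth, 0), e + region_halfwidth, 1)
        )
    for i in negative_plants:
        s, e = plant_spans[i]
        regions.append(
            (spec.chrom, max(s - region_halfwidth, 0), e + region_halfwidth, 0)
        )
    return Annotations(transcripts, masks, snps, regions)


# ---------------------------------------------------------------------------
# YAML fixture specs (CLI)
# ---------------------------------------------------------------------------


def load_fixture_yaml(path) -> tuple[FixtureSpec, dict[str, MotifMatrix]]:
    """Read a fixture spec plus its inline matrix definitions from YAML."""
    import yaml

    with open(path) as handle:
        data = yaml.safe_load(handle)
    matrices = {}
    for m in data.get("matrices", []):
        matrices[m["id"]] = matrix_from_consensus(
            m["id"], m.get("tf_name", m["id"]), m["consensus"],
            m.get("certainty", 0.97),
        )
    plants = [
        PlantSpec(
            matrix_id=p["matrix_id"],
            position=int(p["position"]),
            carriers=set(p["carriers"]) if "carriers" in p else None,
            mutations={k: int(v) for k, v in p.get("mutations", {}).items()},
            shift={k: int(v) for k, v in p.get("shift", {}).items()},
        )
        for p in data.get("plants", [])
    ]
    spec = FixtureSpec(
        seed=int(data["seed"]),
        species=tuple(data.get("species", FixtureSpec.species)),
        genome_length=int(data.get("genome_length", 20_000)),
        chrom=data.get("chrom", "chr1"),
        tree=data.get("tree", "random"),
        plants=plants,
        background=tuple(data.get("background", (0.25, 0.25, 0.25, 0.25))),
        block_structure=tuple(
            tuple(b) for b in data.get("block_structure", ((1000, 0),))
        ),
        mutation_rate=float(data.get("mutation_rate", 0.1)),
    )
    return spec, matrices
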