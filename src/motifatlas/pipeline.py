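"""End-to-end orchestration: calibrate, scan, lift, score, estimate FDR.

Thin glue over the stage modules; every stage remains usable on its own.
Seeds for the per-matrix calibrations and the column shuffling are derived
deterministically from one pipeline seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conservation import ConservedSite, Phylogeny, bbls_dp, leaf_probabilities
from .fdr import FdrTable, default_grid, fdr_table, generate_controls
from .lift import (
    GenomeLookup,
    MafBlockSet,
    best_species_hits,
    extract_blocks,
    min_species_filter,
)
from .pwm import Background, LogOddsMatrix, MotifMatrix, ZCalibration, calibrate_z
from .scan import ScanConfig, ScoredSite, scan, top_k_filter


@dataclass
class PipelineConfig:
    """Knobs shared across the pipeline stages.

    Defaults follow the mammalian-scale profile: c = -3 bounding constant,
    z >= 4.27 scan threshold, 100k calibration samples, k = 100,000 site
    cap, +-15 bp lift pad, 30 bp block merging.

    z_floor gates which species contribute their NLOD as a presence
    probability.  It defaults to the scan threshold rather than a plain
    one-sided 0.05 cutoff because each species' lifted hit is the best of
    roughly a hundred windows: under the null that maximum alone reaches z
    of 2-3, and a permissive floor lets unrelated species saturate BBLS.
    """

    c: float = -3.0
    n_samples: int = 100_000
    scan: ScanConfig = field(default_factory=ScanConfig)
    pad: int = 15
    max_gap: int = 30
    z_floor: float = 4.27
    min_species: int = 0
    eligible_species: set[str] | None = None
    merging: bool = True


def derive_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (each < 2^31) from one master seed."""
    return [int(s) for s in np.random.default_rng(seed).integers(2**31, size=n)]


def calibrated_scan(
    genome: Mapping[str, str],
    matrix: MotifMatrix,
    background: Background,
    seed: int,
    cfg: PipelineConfig,
) -> tuple[LogOddsMatrix, ZCalibration, list[ScoredSite]]:
    """Build the scoring matrix, calibrate its z, scan, and apply the cap."""
    lom = LogOddsMatrix.build(matrix, background, c=cfg.c)
    cal = calibrate_z(lom, genome, n_samples=cfg.n_samples, seed=seed)
    sites = top_k_filter(scan(genome, lom, cal, cfg.scan), cfg.scan.k)
    return lom, cal, sites


def conserve_sites(
    sites: Sequence[ScoredSite],
    maf: MafBlockSet,
    lom: LogOddsMatrix,
    cal: ZCalibration,
    tree: Phylogeny,
    ref_species: str,
    cfg: PipelineConfig,
    genome_lookup: GenomeLookup | None = None,
) -> list[ConservedSite]:
    """Lift each site through the alignment and attach its BBLS.

    Sites failing the minimum-conserved-species requirement are dropped
    (cfg.min_species, restricted to cfg.eligible_species when set)."""
    out = []
    for site in sites:
        blocks = extract_blocks(site, maf, pad=cfg.pad)
        hitset = best_species_hits(
            site,
            blocks,
            lom,
            cal,
            ref_species=ref_species,
            genome_lookup=genome_lookup,
            max_gap=cfg.max_gap,
            merging=cfg.merging,
        )
        if not min_species_filter(
            hitset, cfg.min_species, cfg.z_floor, cfg.eligible_species
        ):
            continue
        probs = leaf_probabilities(hitset, tree, z_floor=cfg.z_floor)
        out.append(
            ConservedSite(
                site=site,
                bbls=bbls_dp(tree, probs),
                probs=probs,
                aligned_species_count=hitset.aligned_species_count,
            )
        )
    return out


@dataclass
class FdrRunResult:
    matrix: MotifMatrix
    controls: list
    real_sites: list[ConservedSite]
    control_sites: list[list[ConservedSite]]
    table: FdrTable


def run_fdr(
    matrix: MotifMatrix,
    genome: Mapping[str, str],
    tree: Phylogeny,
    maf: MafBlockSet,
    ref_species: str,
    seed: int,
    cfg: PipelineConfig | None = None,
    n_controls: int = 10,
    cg_constrained: bool = False,
    grid: Sequence[tuple[float, float]] | None = None,
    genome_lookup: GenomeLookup | None = None,
    background: Background | None = None,
) -> FdrRunResult:
    """Run the identical scan + conservation pipeline for the real matrix
    and its shuffled controls, then tabulate the Monte-Carlo FDR."""
    cfg = cfg or PipelineConfig()
    background = background or Background.from_genome(genome)
    shuffle_seed, *cal_seeds = derive_seeds(seed, n_controls + 2)
    controls = generate_controls(
        matrix, n_controls=n_controls, cg_constrained=cg_constrained,
        seed=shuffle_seed,
    )
    queries = [matrix] + [c.as_motif(i, matrix.tf_name) for i, c in enumerate(controls)]
    per_query: list[list[ConservedSite]] = []
    for q, cal_seed in zip(queries, cal_seeds):
        lom, cal, sites = calibrated_scan(genome, q, background, cal_seed, cfg)
        per_query.append(
            conserve_sites(
                sites, maf, lom, cal, tree, ref_species, cfg, genome_lookup
            )
        )
    grid = grid if grid is not None else default_grid(tree.total_length)
    table = fdr_table(per_query[0], per_query[1:], grid, matrix_id=matrix.id)
    return FdrRunResult(matrix, controls, per_query[0], per_query[1:], table)
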