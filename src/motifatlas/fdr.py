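"""Monte-Carlo false discovery rate from column-shuffled control matrices.

For each motif matrix, control matrices are made by randomly permuting its
columns (positions).  A permutation is accepted only if the shuffled matrix
is sufficiently dissimilar from the original — similarity is the maximum,
over all pairs of length-8 window offsets, of the average Pearson
correlation between the paired probability columns — and, optionally, if
its expected CG-dinucleotide frequency stays within a tolerance of the
original (CpG content strongly shapes background hit rates in mammalian
genomes).  The full scan + conservation pipeline is run with each control,
and the FDR at a threshold pair (NLOD >= a, BBLS >= b) is the median
control site count divided by the real matrix's site count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservedSite
from .pwm import MotifMatrix

SIMILARITY_WINDOW = 8
MIN_CONTROL_LENGTH = 8


def _normalise_columns(probs: np.ndarray) -> np.ndarray:
    """Centre and scale each probability column; zero-variance columns map
    to the zero vector so their correlation with anything is 0."""
    centred = probs - probs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    out = np.zeros_like(centred)
    np.divide(centred, norms, out=out, where=norms > 1e-12)
    return out


def matrix_similarity(
    a: MotifMatrix, b: MotifMatrix, normalize_by_length: bool = False
) -> float:
    """Max over window-offset pairs of the mean per-column correlation.

    Both matrices must share a length >= 8.  ``normalize_by_length``
    additionally divides by the motif length (off by default: that scaling
    would make any fixed cutoff in (0.125, 1] unreachable).
    """
    if a.length != b.length:
        raise ValueError("matrices must have equal length")
    if a.length < SIMILARITY_WINDOW:
        raise ValueError(f"matrix shorter than {SIMILARITY_WINDOW} columns")
    na = _normalise_columns(a.probs)
    nb = _normalise_columns(b.probs)
    corr = na @ nb.T  # corr[i, j] = Pearson r between column i of a, j of b
    w = SIMILARITY_WINDOW
    offsets = a.length - w + 1
    best = -1.0
    for i in range(offsets):
        for j in range(offsets):
            mean_r = float(np.trace(corr[i : i + w, j : j + w])) / w
            if mean_r > best:
                best = mean_r
    if normalize_by_length:
        best /= a.length
    return best


def cg_dinucleotide_freq(m: MotifMatrix) -> float:
    """Expected frequency of the CG dinucleotide under the matrix:
    mean over adjacent position pairs of P(C at j) * P(G at j+1)."""
    if m.length < 2:
        raise ValueError("CG frequency needs at least 2 columns")
    c = m.probs[:-1, 1]
    g = m.probs[1:, 2]
    return float(np.mean(c * g))


@dataclass(frozen=True)
class ControlMatrix:
    """A column permutation of a parent matrix accepted as a null control."""

    parent_id: str
    permutation: tuple[int, ...]
    probs: np.ndarray
    similarity_to_parent: float

    def as_motif(self, index: int, tf_name: str = "") -> MotifMatrix:
        return MotifMatrix(
            f"{self.parent_id}__shuffle{index}", tf_name or self.parent_id, self.probs
        )


def generate_controls(
    m: MotifMatrix,
    n_controls: int = 10,
    max_attempts: int = 10_000,
    sim_cutoff: float = 0.35,
    cg_constrained: bool = False,
    cg_tol: float = 0.01,
    seed: int | None = None,
) -> list[ControlMatrix]:
    """Draw random column permutations until ``n_controls`` are accepted or
    ``max_attempts`` are exhausted (may return fewer).

    A draw is accepted iff its permutation differs from all previously
    accepted ones, its similarity to the parent is <= ``sim_cutoff`` and,
    when ``cg_constrained``, its expected CG-dinucleotide frequency is
    within ``cg_tol`` of the parent's.  Deterministic given ``seed``.
    """
    if seed is None:
        raise ValueError("shuffling seed is mandatory for reproducibility")
    if m.length < MIN_CONTROL_LENGTH:
        raise ValueError(
            f"matrix {m.id}: length {m.length} < {MIN_CONTROL_LENGTH}, not eligible"
        )
    rng = np.random.default_rng(seed)
    parent_cg = cg_dinucleotide_freq(m)
    accepted: list[ControlMatrix] = []
    seen: set[tuple[int, ...]] = set()
    for _ in range(max_attempts):
        if len(accepted) >= n_controls:
            break
        perm = tuple(int(i) for i in rng.permutation(m.length))
        if perm in seen:
            continue
        probs = m.probs[list(perm), :]
        shuffled = MotifMatrix(f"{m.id}~", m.tf_name, probs)
        sim = matrix_similarity(m, shuffled)
        if sim > sim_cutoff:
            continue
        if cg_constrained and abs(cg_dinucleotide_freq(shuffled) - parent_cg) > cg_tol:
            continue
        seen.add(perm)
        accepted.append(ControlMatrix(m.id, perm, probs, sim))
    return accepted


def matrix_retention(m: MotifMatrix, controls: Sequence[ControlMatrix]) -> bool:
    """A matrix enters the map only if it is at least 8 columns long and
    produced at least 3 acceptable shuffles."""
    return m.length >= MIN_CONTROL_LENGTH and len(controls) >= 3


# ---------------------------------------------------------------------------
# FDR table over (NLOD, BBLS) threshold grids
# ---------------------------------------------------------------------------


@dataclass
class FdrTable:
    """Per-matrix FDR estimates on a grid of (nlod_min, bbls_min) pairs.

    ``table`` columns: nlod_min, bbls_min, real_count, control_0..control_k,
    fdr.  fdr is NaN where real_count == 0 (undefined, not zero).  Values
    above 1 are reported as computed; `clipped()` caps them for display.
    """

    matrix_id: str
    table: pd.DataFrame

    def clipped(self) -> pd.DataFrame:
        out = self.table.copy()
        out["fdr"] = out["fdr"].clip(upper=1.0)
        return out

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _score_arrays(sites: Iterable) -> tuple[np.ndarray, np.ndarray]:
    nlods, bblss = [], []
    for site in sites:
        if isinstance(site, ConservedSite):
            nlods.append(site.nlod)
            bblss.append(site.bbls)
        else:  # (nlod, bbls) pair
            nlods.append(float(site[0]))
            bblss.append(float(site[1]))
    return np.asarray(nlods), np.asarray(bblss)


def default_grid(
    total_branch_length: float,
    nlod_start: float = 0.70,
    nlod_step: float = 0.05,
    bbls_step: float = 0.5,
) -> list[tuple[float, float]]:
    nlods = np.arange(nlod_start, 1.0 + 1e-9, nlod_step)
    bblss = np.arange(0.0, total_branch_length + 1e-9, bbls_step)
    return [(float(a), float(b)) for a in nlods for b in bblss]


def fdr_table(
    real_sites: Sequence,
    control_sites: Sequence[Sequence],
    grid: Sequence[tuple[float, float]],
    matrix_id: str = "",
) -> FdrTable:
    """Median control count over real count at every grid point.

    ``real_sites`` and each entry of ``control_sites`` are ConservedSite
    lists (or bare (nlod, bbls) pairs) produced with identical scan and
    conservation parameters.
    """
    real_n, real_b = _score_arrays(real_sites)
    ctrl = [_score_arrays(sites) for sites in control_sites]
    rows = []
    for nlod_min, bbls_min in grid:
        real_count = int(np.sum((real_n >= nlod_min) & (real_b >= bbls_min)))
        counts = [
            int(np.sum((cn >= nlod_min) & (cb >= bbls_min))) for cn, cb in ctrl
        ]
        fdr = float(np.median(counts)) / real_count if real_count > 0 else np.nan
        rows.append(
            {"nlod_min": nlod_min, "bbls_min": bbls_min, "real_count": real_count}
            | {f"control_{i}": c for i, c in enumerate(counts)}
            | {"fdr": fdr}
        )
    return FdrTable(matrix_id, pd.DataFrame(rows))


def assign_site_fdr(sites: Sequence, table: FdrTable) -> np.ndarray:
    """Per-site FDR: the minimum table FDR over all grid points the site
    satisfies (NaN when it satisfies none with a defined FDR)."""
    nlods, bblss = _score_arrays(sites)
    t = table.table
    out = np.full(len(nlods), np.nan)
    defined = t["fdr"].notna().to_numpy()
    grid_n = t["nlod_min"].to_numpy()
    grid_b = t["bbls_min"].to_numpy()
    grid_f = t["fdr"].to_numpy()
    for i, (n, b) in enumerate(zip(nlods, bblss)):
        ok = defined & (grid_n <= n) & (grid_b <= b)
        if ok.any():
            out[i] = grid_f[ok].min()
    return out
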