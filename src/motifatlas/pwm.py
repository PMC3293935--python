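"""Position weight matrix scoring with a bounded log-odds transform.

A transcription factor's sequence preference is summarised by a position
probability matrix ``q`` (one row per motif position, one column per
nucleotide A/C/G/T).  A candidate window ``S`` is scored against genomic
background frequencies ``b`` with a log-odds sum

    LOD(S) = sum_j f(q[S_j, j] / b[S_j])

where ``f`` equals ``log2`` for arguments above ``x0 = e^{2c}`` and, below
that, the tangent line to ``log2`` at ``x0``.  The linear piece keeps the
score finite at zero-probability cells, which replaces the classical
pseudocount heuristic: the score of a never-observed base is bounded instead
of being pushed to minus infinity.  ``c = -3`` by default.

``NLOD`` rescales LOD to [0, 1] between the matrix's worst and best
achievable scores (``ymin``/``ymax``), so thresholds are comparable across
matrices of different lengths and information contents.  A per-matrix
z-score is then calibrated by sampling random genomic windows and
standardising NLOD against their empirical mean and standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

ALPHABET = "ACGT"

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


class UnscorableWindowError(ValueError):
    """Window contains a symbol outside {A, C, G, T}."""


class UninformativeMatrixError(ValueError):
    """Matrix assigns the same score to every sequence (ymax == ymin or
    zero score variance on the calibration genome)."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifMatrix:
    """Position probability matrix over {A, C, G, T}.

    ``probs`` has shape (L, 4): ``probs[j, i]`` is the probability of
    nucleotide ``i`` at motif position ``j``.  Columns (positions) must each
    sum to 1.
    """

    id: str
    tf_name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must have shape (L, 4) with L >= 1")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each motif position must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls, matrix_id: str, tf_name: str, counts: np.ndarray, pseudocount: float = 0.0
    ) -> "MotifMatrix":
        """Column-normalise a count matrix.  No pseudocounts by default: the
        bounded log transform makes zero cells legal."""
        counts = np.asarray(counts, dtype=float) + pseudocount
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("motif position with zero total count")
        return cls(matrix_id, tf_name, counts / totals)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def anti_consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmin(self.probs, axis=1))

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(self.id, self.tf_name, self.probs[::-1, ::-1].copy())


@dataclass(frozen=True)
class Background:
    """Genome-wide nucleotide probabilities (A, C, G, T)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if freqs.shape != (4,):
            raise ValueError("background must be a 4-vector")
        if np.any(freqs <= 0):
            raise ValueError("background frequencies must be positive")
        if not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_genome(cls, genome: Mapping[str, str]) -> "Background":
        """Empirical frequencies over both strands (so A/T and C/G are
        symmetrised); N and other ambiguity codes are excluded."""
        counts = np.zeros(4)
        for seq in genome.values():
            codes = encode(seq)
            counts += np.bincount(codes[codes < 4], minlength=4)
        if counts.sum() == 0:
            raise ValueError("genome contains no A/C/G/T bases")
        both = counts + counts[::-1]  # complement of A is T, of C is G
        return cls(both / both.sum())


def bounded_log(x, c: float = -3.0):
    """log2 bounded below by its tangent line at ``x0 = e^{2c}``.

    For ``x > x0`` this is exactly ``log2(x)``; at and below ``x0`` it is the
    tangent ``log2(x0) + (x - x0) / (x0 * ln 2)``, which is continuous and
    differentiable at the junction and finite at ``x = 0``.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("bounded_log requires x >= 0")
    x0 = math.exp(2.0 * c)
    junction = 2.0 * c * math.log2(math.e)
    out = np.where(
        arr > x0,
        np.log2(np.maximum(arr, x0)),  # maximum() only guards log2(0) warnings
        junction + (arr - x0) / (x0 * math.log(2.0)),
    )
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class LogOddsMatrix:
    """Bounded log-odds scoring matrix derived from a MotifMatrix.

    ``entries[j, i] = f(q[j, i] / b[i])`` with ``f = bounded_log(., c)``.
    ``ymax``/``ymin`` are the best/worst achievable LOD scores.
    """

    source: str
    c: float
    entries: np.ndarray
    ymin: float
    ymax: float

    @classmethod
    def build(
        cls, matrix: MotifMatrix, background: Background, c: float = -3.0
    ) -> "LogOddsMatrix":
        entries = bounded_log(matrix.probs / background.freqs[None, :], c)
        return cls(
            source=matrix.id,
            c=c,
            entries=entries,
            ymin=float(entries.min(axis=1).sum()),
            ymax=float(entries.max(axis=1).sum()),
        )

    @property
    def length(self) -> int:
        return self.entries.shape[0]

    @property
    def span(self) -> float:
        return self.ymax - self.ymin

    def reverse_complement(self) -> "LogOddsMatrix":
        return replace(self, entries=self.entries[::-1, ::-1].copy())


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def lod_score(seq: str, lom: LogOddsMatrix) -> float:
    if len(seq) != lom.length:
        raise ValueError(f"sequence length {len(seq)} != matrix length {lom.length}")
    codes = encode(seq)
    if np.any(codes >= 4):
        raise UnscorableWindowError(f"window {seq!r} contains a non-ACGT symbol")
    return float(lom.entries[np.arange(lom.length), codes].sum())


def nlod_score(seq: str, lom: LogOddsMatrix) -> float:
    if lom.span <= 0:
        raise UninformativeMatrixError(f"matrix {lom.source}: ymax == ymin")
    return float(np.clip((lod_score(seq, lom) - lom.ymin) / lom.span, 0.0, 1.0))


def window_lod_scores(codes: np.ndarray, entries: np.ndarray) -> np.ndarray:
    """LOD of every length-L window of an encoded sequence.

    Returns an array of length ``len(codes) - L + 1`` with NaN at windows
    containing non-ACGT codes.  Vectorised; the workhorse behind both the
    genome scanner and the cross-species rescans.
    """
    L = entries.shape[0]
    n = len(codes)
    if n < L:
        return np.empty(0, dtype=float)
    bad = codes >= 4
    safe = np.where(bad, 0, codes)
    windows = np.lib.stride_tricks.sliding_window_view(safe, L)
    scores = entries[np.arange(L), windows].sum(axis=1)
    if bad.any():
        cum = np.concatenate([[0], np.cumsum(bad)])
        scores[cum[L:] - cum[:-L] > 0] = np.nan
    return scores


# ---------------------------------------------------------------------------
# z-score calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZCalibration:
    """Mean/stdev of NLOD over random genomic windows, for one matrix."""

    matrix_id: str
    mu: float
    sigma: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise UninformativeMatrixError(
                f"matrix {self.matrix_id}: zero score variance on this genome"
            )
        if self.n_samples < 1000:
            raise ValueError("calibration needs at least 1000 samples")


def calibrate_z(
    lom: LogOddsMatrix,
    genome: Mapping[str, str],
    n_samples: int = 100_000,
    seed: int | None = None,
) -> ZCalibration:
    """Estimate the NLOD null distribution on a genome.

    Windows are drawn uniformly with replacement over all scorable positions
    of both strands.  Deterministic for a given seed (which is mandatory).
    """
    if seed is None:
        raise ValueError("calibration seed is mandatory for reproducibility")
    if lom.span <= 0:
        raise UninformativeMatrixError(f"matrix {lom.source}: ymax == ymin")
    pools: list[np.ndarray] = []
    rc_entries = lom.entries[::-1, ::-1]
    for chrom in sorted(genome):
        codes = encode(str(genome[chrom]))
        for entries in (lom.entries, rc_entries):
            lods = window_lod_scores(codes, entries)
            lods = lods[np.isfinite(lods)]
            if lods.size:
                pools.append(lods)
    if not pools:
        raise ValueError("genome has no scorable windows for this matrix")
    lods = np.concatenate(pools)
    rng = np.random.default_rng(seed)
    sample = lods[rng.integers(0, lods.size, size=n_samples)]
    nlods = (sample - lom.ymin) / lom.span
    mu = float(nlods.mean())
    sigma = float(nlods.std(ddof=1))
    if sigma == 0:
        raise UninformativeMatrixError(
            f"matrix {lom.source}: constant score on this genome"
        )
    return ZCalibration(lom.source, mu, sigma, n_samples, seed)


def z_score(nlod, cal: ZCalibration):
    """Standardise NLOD against the calibrated null (scalar or array)."""
    out = (np.asarray(nlod, dtype=float) - cal.mu) / cal.sigma
    return float(out) if np.isscalar(nlod) else out


def z_threshold_for_p(p: float) -> float:
    """Upper-tail standard-normal quantile: the z cutoff whose exceedance
    probability is ``p`` (e.g. p = 1e-5 -> z = 4.27)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    return float(stats.norm.isf(p))


def p_value_for_z(z: float) -> float:
    """Upper-tail standard-normal probability of ``z``."""
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# matrix file formats
# ---------------------------------------------------------------------------


def read_jaspar(path, pseudocount: float = 0.0) -> list[MotifMatrix]:
    """Read JASPAR plain-text matrices (4 labelled A/C/G/T rows)."""
    from Bio import motifs as bio_motifs

    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in ALPHABET]).T
        matrix_id = getattr(m, "matrix_id", None) or m.name
        out.append(MotifMatrix.from_counts(matrix_id, m.name or matrix_id, counts, pseudocount))
    return out


def read_transfac(path, pseudocount: float = 0.0) -> list[MotifMatrix]:
    """Read TRANSFAC-style matrices (position-per-row with P0 header)."""
    from Bio import motifs as bio_motifs

    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "TRANSFAC")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in ALPHABET]).T
        matrix_id = m.get("AC") or m.get("ID") or m.name
        name = m.get("ID") or m.name or matrix_id
        out.append(MotifMatrix.from_counts(matrix_id, name, counts, pseudocount))
    return out


def write_matrix_tsv(matrix: MotifMatrix, path) -> None:
    """Internal TSV dialect: header comments with id/tf_name, then one row
    per motif position with A/C/G/T probabilities."""
    with open(path, "w") as handle:
        handle.write(f"#id={matrix.id}\n#tf_name={matrix.tf_name}\n")
        handle.write("pos\tA\tC\tG\tT\n")
        for j, row in enumerate(matrix.probs):
            handle.write(f"{j}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix_tsv(path) -> MotifMatrix:
    matrix_id = tf_name = "unknown"
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith("#id="):
                matrix_id = line[4:]
            elif line.startswith("#tf_name="):
                tf_name = line[9:]
            elif line and not line.startswith(("#", "pos\t")):
                rows.append([float(v) for v in line.split("\t")[1:5]])
    return MotifMatrix(matrix_id, tf_name, np.array(rows))
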