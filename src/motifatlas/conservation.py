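"""Branch Length Score (BLS) and its Bayesian extension (BBLS).

Given a phylogeny with branch lengths and, per species, either a binary
presence call sigma_i or a presence probability p_i for a motif, the BLS of
a binary vector is the total branch length of the minimal subtree spanning
the present leaves (0 when fewer than two leaves are present; the tree is
treated as unrooted for branch inclusion).  The BBLS is the expectation of
BLS when presence events are independent Bernoulli(p_i):

    BBLS = E[BLS] = sum over all 2^N binary vectors of P(sigma) * BLS(sigma)

The expectation factorises per branch: a branch b belongs to the spanning
subtree exactly when at least one present leaf lies on each of its two
sides, so

    BBLS = sum_b len(b) * (1 - prod_{i in A_b} (1 - p_i))
                        * (1 - prod_{i not in A_b} (1 - p_i))

with A_b the leaves below b.  One post-order pass computes the inside
products and one pre-order pass the outside products, giving a linear-time
dynamic program; `bbls_bruteforce` keeps the exponential enumeration as an
independent oracle for small trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct
from typing import Mapping

import numpy as np

from .lift import SpeciesHitSet
from .scan import ScoredSite

_BRUTEFORCE_MAX_LEAVES = 15


class Phylogeny:
    """Newick tree with branch lengths, flattened to index arrays.

    Nodes are stored in post-order; ``parent[i]`` indexes into the same
    order (root has parent -1), ``length[i]`` is the branch above node i
    (0 when absent), leaves carry species names.
    """

    def __init__(self, dendropy_tree) -> None:
        nodes = list(dendropy_tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.length = np.zeros(n, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.leaf_name: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.length[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else None
                if label is None:
                    raise ValueError("tree has an unlabelled leaf")
                self.leaf_name[i] = label
        self.root = n - 1
        self.leaves = [name for name in self.leaf_name if name is not None]
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("leaf names must be unique")
        if len(self.leaves) < 2:
            raise ValueError("tree must have at least 2 leaves")
        if np.any(self.length < 0):
            raise ValueError("branch lengths must be non-negative")
        self.leaf_index = {
            name: i for i, name in enumerate(self.leaf_name) if name is not None
        }
        # root's branch (if any in the file) is excluded: unrooted convention
        self.total_length = float(self.length.sum() - self.length[self.root])

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        import dendropy

        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # normalise dendropy's parse errors
            raise ValueError(f"invalid Newick tree: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as handle:
            return cls.from_newick(handle.read())

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if self.leaf_name[i] is not None:
                body = self.leaf_name[i]
            else:
                body = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if i == self.root:
                return body
            return f"{body}:{self.length[i]:.6g}"

        return render(self.root) + ";"

    def _check_species(self, names) -> None:
        unknown = [s for s in names if s not in self.leaf_index]
        if unknown:
            raise ValueError(f"species not in tree: {', '.join(sorted(unknown))}")


def _as_present_set(sigma) -> set[str]:
    if isinstance(sigma, (set, frozenset)):
        return set(sigma)
    present = set()
    for species, value in sigma.items():
        if value not in (0, 1, True, False):
            raise ValueError("bls requires a binary presence vector")
        if value:
            present.add(species)
    return present


def bls(tree: Phylogeny, sigma) -> float:
    """Total branch length of the minimal subtree spanning the present
    leaves (``sigma``: a binary {species: 0/1} mapping or a set of present
    species).  0 when fewer than two leaves are present."""
    present = _as_present_set(sigma)
    tree._check_species(present)
    total = len(present)
    if total <= 1:
        return 0.0
    count = np.zeros(len(tree.parent), dtype=int)
    for i in range(len(tree.parent)):
        name = tree.leaf_name[i]
        if name is not None:
            if name in present:
                count[i] = 1
        else:
            count[i] = sum(count[c] for c in tree.children[i])
    # a branch is spanned iff present leaves exist on both of its sides
    inner = (count > 0) & (count < total)
    inner[tree.root] = False
    return float(tree.length[inner].sum())


def _validate_probs(tree: Phylogeny, p: Mapping[str, float]) -> np.ndarray:
    tree._check_species(p)
    probs = np.zeros(len(tree.parent))
    for species, value in p.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"p[{species!r}] = {value} outside [0, 1]")
        probs[tree.leaf_index[species]] = value
    return probs


def bbls_bruteforce(tree: Phylogeny, p: Mapping[str, float]) -> float:
    """Expected BLS by explicit enumeration of all 2^N presence vectors.

    Exponential oracle: refuses trees with more than 15 leaves (use
    `bbls_dp`).  Zero-probability assignments are pruned, so binary inputs
    reduce to a single BLS evaluation.
    """
    names = tree.leaves
    if len(names) > _BRUTEFORCE_MAX_LEAVES:
        raise ValueError(
            f"{len(names)} leaves is too many for enumeration; use bbls_dp"
        )
    probs = [p.get(name, 0.0) for name in names]
    for name in p:
        if name not in tree.leaf_index:
            raise ValueError(f"species not in tree: {name}")
    expected = 0.0
    for sigma in _iterproduct((0, 1), repeat=len(names)):
        weight = 1.0
        for value, prob in zip(sigma, probs):
            weight *= prob if value else 1.0 - prob
            if weight == 0.0:
                break
        if weight == 0.0:
            continue
        present = {name for name, value in zip(names, sigma) if value}
        expected += weight * bls(tree, present)
    return expected


def bbls_dp(tree: Phylogeny, p: Mapping[str, float]) -> float:
    """Expected BLS in linear time via per-branch spanning probabilities."""
    probs = _validate_probs(tree, p)
    n = len(tree.parent)
    # inside[i]: product of (1 - p) over leaves below node i (post-order)
    inside = np.ones(n)
    for i in range(n):
        if tree.leaf_name[i] is not None:
            inside[i] = 1.0 - probs[i]
        else:
            for c in tree.children[i]:
                inside[i] *= inside[c]
    # outside[i]: product of (1 - p) over leaves NOT below node i (pre-order)
    outside = np.ones(n)
    for i in range(n - 1, -1, -1):
        kids = tree.children[i]
        if not kids:
            continue
        # prefix/suffix sibling products avoid dividing by zero factors
        k = len(kids)
        prefix = np.ones(k + 1)
        for j in range(k):
            prefix[j + 1] = prefix[j] * inside[kids[j]]
        suffix = np.ones(k + 1)
        for j in range(k - 1, -1, -1):
            suffix[j] = suffix[j + 1] * inside[kids[j]]
        for j, c in enumerate(kids):
            outside[c] = outside[i] * prefix[j] * suffix[j + 1]
    expected = 0.0
    for i in range(n):
        if i == tree.root:
            continue
        expected += tree.length[i] * (1.0 - inside[i]) * (1.0 - outside[i])
    return float(expected)


def leaf_probabilities(
    hitset: SpeciesHitSet, tree: Phylogeny, z_floor: float = 1.64
) -> dict[str, float]:
    """Per-leaf presence probabilities from lifted hits.

    p_i is the species' best NLOD when its z-score reaches ``z_floor``, 0
    otherwise; species absent from the alignment get 0.  The reference
    species keeps its own NLOD (scan thresholds guarantee it is high).
    """
    tree._check_species(hitset.hits)
    probs = {name: 0.0 for name in tree.leaves}
    for species, (_, nlod, z) in hitset.hits.items():
        if species == hitset.ref_species or z >= z_floor:
            probs[species] = nlod
    return probs


@dataclass(frozen=True)
class ConservedSite:
    """A scanned site with its conservation annotation."""

    site: ScoredSite
    bbls: float
    probs: dict[str, float]
    aligned_species_count: int

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

    @property
    def matrix_id(self) -> str:
        return self.site.matrix_id
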