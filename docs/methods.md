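# Methods

This note documents the models and procedures implemented in `motifatlas`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic test system does and does not show
about real data.

## Bounded log-odds scoring

A motif is a position probability matrix q (L positions × 4 nucleotides).
A window S is scored as LOD(S) = Σ_j f(q[S_j, j] / b[S_j]) against
genome-wide background frequencies b (estimated from both strands of the
supplied genome, ambiguity codes excluded, so A/T and C/G are symmetric;
overridable). The transform f equals log2 above x0 = e^{2c} and, at and
below x0, the tangent line to log2 at x0:

    f(x) = log2(x0) + (x - x0) / (x0 ln 2)   for x <= x0.

The tangent is the unique linear piece that keeps f continuous and
differentiable at the junction, and it is finite at x = 0
(f(0) = (2c - 1) log2 e ≈ -10.10 for c = -3). Bounding the score this way
replaces per-matrix pseudocount heuristics: count matrices are
column-normalised with no pseudocount by default (a `pseudocount` argument
restores the classical behaviour for comparison). c = -3 throughout.

NLOD min-max rescales LOD to [0, 1] between the matrix's worst (ymin) and
best (ymax) achievable scores; a matrix with ymax = ymin carries no
information and is rejected. Each matrix's z-score is calibrated by
sampling windows uniformly with replacement over all scorable positions of
both strands (default n = 100,000; seed mandatory) and standardising NLOD
against the sample mean and standard deviation. Sampling with replacement
means small toy genomes calibrate fine; the only hard failure is a genome
with no scorable window at all. z is computed on NLOD, not raw LOD.

Scan profiles: z >= 4.27 (upper-tail p = 1e-5) for mammalian-scale
genomes; 2.57–3.72 (p = 5e-3 to 1e-4) for compact genomes. Per matrix, at
most the k = 100,000 best sites are kept, where "best" keeps every site
whose z is at least the k-th highest (ties included). Masks (exons,
repeats) remove a site on any >= 1 bp overlap — the conservative reading —
and masking precedes the cap. Windows containing non-ACGT symbols are
skipped, not penalised. Coordinates are 0-based half-open internally and
in BED output; GFF output is 1-based closed.

## Lifting sites through the alignment

Whole-genome alignments are low-resolution, so reading the aligned columns
directly misses real conservation. Each reference site is expanded by
pad = 15 bp per side; every MAF block whose reference row overlaps the
expanded interval is collected; per species, rows on the same chromosome
and strand within max_gap = 30 bp (measured in that species' own
coordinates, since the aim is reconstructing its local sequence) are
concatenated, keeping the intervening bases (from the species genome when
a lookup is available, N otherwise — N windows are simply unscorable);
and each merged segment is rescanned on both strands for the species'
best NLOD. Both strands are scanned because alignment strand assignments
are unreliable for short motifs. Only MAF "s" lines are used; species
names follow the UCSC source-prefix convention; the reference species'
hit is taken from the already-scored site rather than re-derived.

## Conservation: BLS and BBLS

For a binary presence vector over the tree's leaves, BLS is the total
branch length of the minimal subtree spanning the present leaves, with
the tree treated as unrooted for branch inclusion (the standard branch
length score convention); fewer than two present leaves give 0. With
independent per-species presence probabilities p_i, BBLS = E[BLS]. The
expectation factorises per branch — a branch is spanned exactly when at
least one present leaf lies on each of its sides — giving

    BBLS = Σ_b len(b) · (1 - Π_{i below b} (1 - p_i))
                      · (1 - Π_{i not below b} (1 - p_i)),

computed in one post-order and one pre-order pass (sibling prefix/suffix
products avoid dividing by zero factors when some p_i = 1). The
exponential enumeration over all 2^N presence vectors is retained as
`bbls_bruteforce` (refusing N > 15) and serves as the independent oracle;
the two agree to < 1e-9 on random trees, and BBLS reduces exactly to BLS
for binary p. BBLS is monotone in every p_i and bounded by the total
branch length; a single carrier species gives BBLS = 0, which grounds the
"conserved in at least one other species" (BBLS > 0) filter.

Leaf probabilities: p_i is the species' best lifted NLOD when its z
reaches a floor, else 0; unaligned species get 0; the reference
contributes its own NLOD rather than a forced 1 (configurable). The
function default floor is 1.64 (one-sided p = 0.05), but the pipeline
profile deliberately reuses the scan threshold (4.27) instead: each
species' lifted hit is the maximum over roughly a hundred windows, and
under the null that maximum alone typically reaches z of 2–3, so a 1.64
floor lets every aligned species contribute a substantial p_i and
saturates BBLS for signal and noise alike. With the stricter floor,
species lacking the motif contribute 0 with high probability while exact
motif copies (NLOD 1, z ≈ 6 for an informative 12-mer) always pass.

## Monte-Carlo FDR

Controls are random column permutations of the matrix. A draw is accepted
iff (1) its permutation differs from every previously accepted one —
distinctness is by permutation, not content hash; (2) its similarity to
the parent is <= 0.35, where similarity is the maximum over all pairs of
length-8 window offsets of the average Pearson correlation between the
paired probability columns (zero-variance columns correlate 0 by
definition: a uniform column has no shape); and (3) optionally, its
expected CG-dinucleotide frequency — mean over adjacent position pairs of
P(C at j)·P(G at j+1) — is within 0.01 of the parent's (exact equality is
generally impossible under column permutation). Up to 10,000 draws yield
up to 10 controls. Dividing the window correlation additionally by the
motif length is available as a flag but off by default: with length >= 8
that scaling caps the measure at 0.125, making a 0.35 cutoff unreachable.
Matrices shorter than 8 columns, or yielding fewer than 3 acceptable
shuffles, are not retained.

The identical scan + lift + BBLS pipeline runs for the real matrix and
every control; at each grid point (NLOD >= a, BBLS >= b) the FDR is the
median control count over the real count — undefined (NaN), not zero,
when the real count is 0, and reported uncapped (a display option clips
at 1). A site's FDR is the minimum over the grid points it satisfies.
The default grid is NLOD ∈ {0.70, 0.75, …, 1.0} × BBLS ∈ {0, 0.5, …,
total branch length}.

## Post-processing

Redundancy: per transcription factor, overlapping sites (any shared base,
strand-agnostic, transitively closed) collapse to the max-BBLS member;
ties break by higher NLOD, then leftmost start (the tie rule is this
package's choice). Sites of different factors never compete. TSS
distance is signed from the site midpoint (symmetric for motif-length
intervals; the nearest-edge alternative differs by at most half a motif
length), negative upstream of the gene's strand. Promoter windows are
15 kb upstream to 3 kb downstream, inclusive. SNP overlap uses half-open
[start, end). BBLS quartiles are equal-size groups (±1, ties filled in
stable input order). Region AUC ranks regions by the maximum score of
their overlapping sites (max is the standard choice for multi-site
regions); site-free regions rank below all scored regions when included
as negatives, or can be excluded; ties credit 0.5 (Mann-Whitney).

## Synthetic study system

The generator emulates exactly the structures the pipeline consumes: an
i.i.d. background reference genome (default uniform base composition)
with planted consensus motifs; per-species genomes copied block-by-block
with uniform point substitutions at rate 0.1 per site (roughly the
neutral divergence of moderately separated vertebrates); a pure-birth
random tree with exponential branch lengths (mean 0.4
substitutions/site); and MAF blocks tiling the reference, with optional
per-species insertions between blocks. Indels inside blocks are not
modelled — the block gaps emulate them — and there is no substitution
rate matrix, no CpG hypermutability, and no alignment error beyond the
constructed shift/split pathologies. Carrier species hold the exact
consensus (optionally degraded by a counted number of substitutions);
non-carriers have the motif footprint re-randomised. A plant whose
footprint spans a block boundary with an insertion becomes the
split-block scenario; a per-species shift places the motif a few bases
out of alignment frame within the pad.

Consequently, passing tests demonstrate the machinery — scoring,
calibration, lifting, the conservation expectation, the shuffling null,
the filters — under controlled conditions; they do not demonstrate
performance on real genomes, where background composition, repeat
structure, alignment quality and motif degeneracy are all harsher.

## Problem sizes and study conditions

The self-check studies use: 100 random trees of 3–12 leaves for the
DP-vs-enumeration oracle; a 20 kb genome for the exhaustive scan oracle;
6 kb two-species fixtures for the shift (8 bp) and split (5 bp insertion)
recoveries; 50 planted conserved sites in 100 kb of background with 10
controls for the planted-signal FDR (read out at NLOD >= 0.95, BBLS >=
half the tree length — the planted sites sit at NLOD 1 and full tree
length); 20 seeds × 20 kb background genomes at the z = 2.57 compact
profile for the self-shuffle null (several hundred sites per matrix per
seed keep the median/real ratio stable); 1,000 random sites for the
redundancy oracle; and a 40 kb genome with 8 conserved plants and 8
reference-only decoys for the ranked-recovery AUC and the TSS-distance
quartile contrast.

## Known limitations

- Presence probabilities are treated as independent across species; the
  phylogenetic correlation of presence/absence is not modelled (this
  independence is what makes the per-branch factorisation exact).
- The lift trusts the input alignment plus local rescanning; no
  realignment is attempted.
- FDR is Monte-Carlo with at most 10 controls, so per-matrix FDR has
  sizeable sampling noise at low counts; grid points with zero real
  count are reported as undefined rather than extrapolated.
- The scanner is a plain linear scan — adequate at desk scale, with no
  index acceleration.
- PhastCons/PhyloP-style substitution models are out of scope; externally
  computed per-site scores can be supplied to the AUC evaluator instead.
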