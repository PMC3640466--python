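# Methods

This note documents the models, conventions and numerical choices behind
`molkit`, and what the synthetic test fixtures do and do not demonstrate.

## Data model: handles and views

A structure is owned by an `Entity` handle — a tree of chains, residues and
atoms with a flat bond list at the root.  An `EntityView` is a parallel
subset hierarchy whose elements hold *references* into the handle: moving a
handle atom is immediately visible through every view, and generic
properties (typed key-value annotations on any element) are stored on the
handle and merely exposed by view elements.  Views are minimal and
consistent by construction: a view atom's residue and chain are always
included, and a bond is included only when both endpoint atoms are.

Views do not survive structural edits.  Deleting handle atoms bumps a
generation counter on the entity; any older view raises `StaleViewError` on
its next traversal rather than returning dangling references.  Views of
views are allowed to any depth — each level materialises its own subset, so
a deep chain costs memory proportional to the selected atoms per level.

Coordinates are ångströms in a right-handed Cartesian frame.  Residue
numbers follow PDB convention (1-based, negative allowed, insertion codes
honoured).  Generic-property values are strictly typed (`str`, `float`,
`int`, `bool`); reading through a wrong-typed accessor raises instead of
coercing, and `bool` never aliases `int`.

## Selection language

The grammar is documented in `query-language.md`.  Two semantic choices
deserve justification:

- **Strict atom-set semantics.**  Residue- and chain-level predicates
  match all atoms of matching residues/chains, but combining residue and
  atom predicates never promotes whole residues into the result;
  `rname=HIS and aname=CA` selects only the Cα atoms of histidines.
- **`within` reference scope.**  The reference sub-query of
  `R <> [subquery]` is matched against the *underlying entity*, while the
  candidates remain the atoms of the current target.  The alternative —
  scoping the reference to the current view — breaks idempotence for
  chained queries (re-selecting `occ>0.5 and 5 <> [ele=FE]` on its own
  result loses everything whenever the iron fails the occupancy test).
  With root scope, selection is idempotent and chaining equals
  conjunction for all queries, which is what the property suite asserts.

Evaluation is per-atom against the candidate list, with proximity handled
by a uniform spatial grid whose cell size equals the query radius.  The
grid is an implementation detail: the tested contract is exhaustive
agreement with an O(n) distance scan.

## Connectivity

The rule-based builder consumes a compound library (JSON; bundled entries
for the 20 standard amino acids, 8 standard nucleotides, water and haem,
heavy atoms only).  Intra-residue bonds are the library's bond list
restricted to atoms present; unknown residues/atoms and missing atoms are
reported as diagnostics, and strict mode raises on the first unknown.
Consecutive residues are linked — peptide C(i)–N(i+1) or phosphodiester
O3'(i)–P(i+1) — when the distance is ≤ 2.5 Å; "consecutive" means list
order within a chain, so chain breaks manifest as distances over the
cutoff, not as special cases.

The heuristic builder uses the same tables for known residues and falls
back to a covalent-radius rule for anything else: atoms bond when their
distance is at most r(a) + r(b) + 0.4 Å with radii (Å) H 0.31, C 0.77,
N 0.71, O 0.66, S 1.05, P 1.07, Fe 1.32 and 1.5 for anything unlisted
(deliberately generous so unknown chemistry over- rather than
under-connects).  Hydrogens get exactly one bond, to the nearest heavy atom
in range.  These constants are conventional values; the approach is a
quick-and-dirty interactive tool, not a perception algorithm — bond orders,
aromaticity and protonation are out of scope.

## Structure I/O

PDB import parses ATOM/HETATM records by the v3.3 fixed columns, first
MODEL only.  Alternate locations are resolved at import to the highest
occupancy (ties: lowest alt-loc letter).  An `IOProfile` bundles the
behaviour flags; the default profile is strict and non-fault-tolerant —
the import aborts with the offending line number on the first malformed
record — with rule-based connectivity and HETATM reading on.  The
fault-tolerant profile skips bad records and reports them as diagnostics.
The writer guarantees that a strict re-read reproduces chains, residues,
atom names and coordinates to the printed precision (3 decimals).

DCD reading supports the CHARMM dialect: 4-byte Fortran record markers,
`CORD` magic, single-precision coordinates, an optional unit-cell block
that is honoured and skipped, and either endianness (detected from the
first record marker).  When the header's frame count exceeds what the file
actually contains, the file wins — truncated trailing frames are dropped.
In-memory mode loads every strided frame up front; lazy mode records
per-frame byte offsets and fetches frames on demand through an LRU cache
(default 16 frames, configurable), counting disk fetches so the cache
bound is testable.  Both modes return bit-identical coordinates.  Writing
DCD exists only as a little-endian fixture writer for tests.

## Sequences and mapping

Sequences store one-letter codes, uppercase, with `-` as the only gap
character (`.` is normalised on input).  The gap list is a run-length
encoding of gap positions; mapping between alignment position and residue
index traverses only this list, so the cost is bounded by the number of
gap runs rather than by the position — the property suite instruments the
traversal and asserts the bound.  Positions and indices are 0-based with a
sequence `offset` (default 0) added to residue indices.

Attaching a structure validates residue counts and one-letter codes
position-wise; `X` matches anything on either side (wildcards are common in
modelling pipelines, and rejecting them would make attachment useless for
engineered or partially annotated chains).

Alignment editing is column-wise; removing a column containing non-gap
characters requires `force=True`.  FASTA and ClustalW pass through
Biopython; PIR is read and written natively so the two-letter sequence
type code (`P1`, `F1`, …) survives a round trip.

## Pairwise alignment and conservation

Both aligners are the three-matrix affine-gap dynamic programme: a gap of
length L costs `gap_open + (L−1)·gap_extend`.  The default scheme is
BLOSUM62 with open −10, extend −1.  Traceback ties break
deterministically: diagonal, then gap-in-second-sequence, then
gap-in-first.  Local alignment floors the match matrix at zero and reports
the aligned region's start offsets through the emitted sequence offsets.
Sequence identity is 100 × identical columns / both-non-gap columns — the
aligned-columns denominator, the most common convention.

Column conservation is the mean over unordered sequence pairs of a
residue-pair similarity; pairs involving a gap contribute 0.  The
similarity derives from BLOSUM62 as

    sim(a, b) = (B(a,b) − Bmin) / ((B(a,a) + B(b,b))/2 − Bmin),

clamped to [0, 1].  A plain min-max rescaling of the matrix was rejected
because BLOSUM62 self-scores vary (4–11), which would make a column of
identical alanines score lower than identical tryptophans; dividing by the
shifted mean self-score anchors every identical pair at exactly 1, so a
fully conserved, gap-free column scores 1.0 and an all-gap column 0.0.
The matrix is pluggable for users with a dedicated physico-chemical scale.

## Superposition and annotation transfer

Superposition is the Kabsch algorithm (SVD of the centred covariance
matrix) with reflection correction — the sign of the smallest singular
vector flips when the determinant is negative, so the result is always a
proper rotation.  **Correspondence is positional**: the i-th atom of the
mobile view pairs with the i-th atom of the reference view regardless of
names.  This is deliberate and matters silently; callers selecting with
queries get handle order, which matches like with like when the selections
are analogous.  A (near-)collinear reference triggers a warning because
the rotation about the line is then arbitrary.

Annotation transfer composes the machinery: select source residues (for
binding sites, typically a `within` query around a ligand), map each one
through its sequence's gap list to the alignment column, map the column to
the destination sequence, and set a boolean generic property on the
destination residue; columns opposite a gap are skipped.

## Images and density

An `ImageHandle` is a 1/2/3-D buffer with per-dimension sampling (Å/pixel),
an origin (Å position of pixel 0, corner convention: centre of voxel i is
`origin + i·sampling`), and an active domain flag.  The FT uses the
unitary-pair convention (forward unscaled, inverse 1/N), so
Σ|x|² = Σ|X|²/N.  A real spatial image transforms to a frequency image
flagged conjugate-symmetric; transforming that flag back yields a real
image, while a non-symmetric frequency image yields a complex spatial one.

Filters operate on spatial images and transform internally: Gaussian blur
multiplies the spectrum by exp(−2π²σ²|k|²) (unit DC gain, so the mean is
preserved); low/high-pass zero frequencies beyond/below 1/cutoff.

Structure→density places a Gaussian of width σ (default 1.5 Å) and
amplitude 1 (or the atomic number in element-weighted mode) at each atom,
evaluated within 4σ; the grid covers the bounding box plus padding
(default 3 Å).  The 4σ truncation bounds the per-atom error by exp(−8) ≈
3.4×10⁻⁴, which is the tolerance the oracle tests use.  Density is
computed in real space only.

Map comparison is Pearson correlation over voxels; congruent grids
correlate directly, otherwise the second map is resampled onto the first
by trilinear interpolation over the overlap.  Fragment scoring correlates
each candidate's density against the experimental map over the fragment's
own footprint (voxels within 4σ of any fragment atom) — correlating over
the full box would dilute the signal with empty space far from any
candidate.

MRC/CCP4 I/O supports mode 2 (float32).  Files are written x-fastest with
MAPC/MAPR/MAPS = 1,2,3 and the origin in the ORIGIN header words; reading
honours arbitrary axis permutations and falls back to N*START × sampling
when ORIGIN is unset.  Round trips are voxel-exact.

## Synthetic fixtures: what they show

The fixture generator produces ideal poly-alanine α-helices from standard
internal coordinates (φ = −57°, ψ = −47°, ω = 180°; Cα–Cα ≈ 3.80 Å),
random mixed-composition entities with randomised occupancies, B factors
and generic properties, unknown-residue point clouds, DCD trajectories
with an analytic sinusoidal centroid or a seeded Brownian walk, and noised
density maps.  All randomness is seeded; every fixture is reproducible
from (kind, n, seed) alone.

These fixtures exercise the *contracts* — parser fidelity, oracle
equivalence, round trips, invariants — on clean, well-formed data.  They
do not emulate the pathologies of real deposited files (nonstandard
ligands, chain breaks, insertion-code-heavy numbering, multi-model
ensembles beyond the first, unusual element columns), so passing tests
demonstrate correctness of the specified behaviour, not robustness to
every archive quirk.  The one check that requires real data — the dengue
methyltransferase annotation-transfer example, whose two chains align at
77% identity — needs the wwPDB entries 1r6a and 3p97 and runs only where
those files can be obtained.

## Problem sizes

The property suites use sizes chosen to keep the whole test run around a
minute on one core while still being adversarial: 500 random queries on
≤300-atom entities, 1000 random gapped strings, 200 alignment pairs short
enough for exhaustive enumeration (≤7 residues global, ≤6 local), 100
random clouds for superposition, 8³–16³ images, and 20-frame trajectories.
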