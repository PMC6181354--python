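# Methods

`domarch` analyses how the conservation pattern of a protein domain depends
on the *domain architecture* (the ordered combination of domains along the
protein) it occurs in, with the ARID / BAF250_C pair of the BAF250a
(ARID1A) chromatin-remodelling subunit as the motivating system.  This note
records the models, the parameters that matter, the synthetic data model,
and the numerical choices, in the package's own terms.

## Architectures and redundancy removal

An architecture is the ordered list of a sequence's domain assignments with
*consecutive* duplicate runs collapsed to one occurrence, so tandem-repeat
copy number does not multiply combinations (two and three tandem PLU-1
copies are the same context).  Non-adjacent repeats are kept as distinct
positions because order is part of the context; a `collapse_all` mode
discards all duplicates for users who prefer set semantics.  When two
hits overlap on one sequence the higher-scoring (else earlier-starting)
hit wins; pfamscan-style inputs are normally pre-resolved.

Within an architecture, near-identical sequences are removed by
single-linkage clustering: an edge joins two sequences when their
global-alignment identity is ≥ 80% **and** the mutually aligned (both
non-gap) columns cover ≥ 90% of the shorter sequence.  Alignment uses
BLOSUM62 with affine gaps (open 10, extend 0.5).  Because the inputs are
pre-cut domains of similar length, a global alignment with this coverage
definition carries the same intent as local-alignment clustering tools
while being deterministic and dependency-free.  The cluster representative
is the longest member (ties: lexicographically smallest id).  A length
filter then keeps sequences within ±15 residues of the mean domain length;
the mean is computed once over the post-clustering representatives
(cluster-then-filter order; the opposite order is available).

## Property-class consensus fingerprints

For each alignment column, a consensus symbol is derived at a conservation
threshold *t* (default 0.70):

1. if a single residue accounts for ≥ *t* of the column, its uppercase
   letter;
2. else, among the eleven MView biochemical equivalence classes (alcohol,
   aliphatic, aromatic, charged, hydrophobic, negative, polar, positive,
   small, tiny, turn-like) whose summed member fraction reaches *t*, the
   **smallest** class — the most discriminating one;
3. else `.` (unconserved).

Gaps count in the denominator by default, so gappy columns read
unconserved; `count_gaps=False` switches to residue-only counting.  `X` is
tolerated but never contributes to a residue or class.  Exact ties in class
size are resolved by a fixed priority order (the legend order of the class
table); thresholds are compared with a 1e-9 absolute slack so that exact
fractions like 7/10 at *t* = 0.7 qualify regardless of floating-point
representation.

Position classification compares per-architecture consensus columns on a
shared reference alignment (the cross-architecture correspondence is an
input artifact, produced once by profile-aligning per-architecture
representatives):

* **universal** — every architecture shows a symbol and the winning residue
  sets share at least one member (letters count as singletons); this is a
  property-compatibility test, not an identity test;
* **focal-specific** — the focal architecture shows a symbol, the column is
  not universal, and pooling all non-focal rows yields `.` at the same
  threshold;
* **variable** — everything else.

## Phylogenetics

Distances default to the p-distance with pairwise deletion (fraction of
mismatches over mutually non-gap columns); a Kimura-corrected protein
distance (−ln(1 − p − p²/5)) is available behind a flag.  Trees are built
by standard Saitou–Nei neighbor joining with two pinned conventions: ties
in the Q matrix resolve to the first minimal cell in active-node order, and
negative branch-length estimates are clamped to zero (logged), matching
common Phylip-style reporting.  Bootstrap resamples columns with
replacement; the support of an internal edge of the full-data tree is the
count (not percentage) of replicates containing the same bipartition.
Congruence between the trees of two co-occurring domains is the
Robinson–Foulds symmetric difference over non-trivial bipartitions; 0 means
identical topologies — the desk-scale analogue of two domain trees
mirroring each other.  Label transfer assigns each unlabeled leaf the label
of its nearest labeled leaf by patristic distance, with exact ties (within
1e-12) reported as `unassigned`.

## Solvent accessibility

SASA uses the Shrake–Rupley algorithm with a golden-spiral point lattice
(default 92 points, probe 1.4 Å) over NACCESS/Chothia-style van der Waals
radii (C 1.87, N 1.65, O 1.40, S 1.85 Å, configurable).  Because the
lattice weights every point equally, an isolated atom reproduces the
analytic sphere area 4π(r + probe)² exactly.  Relative SASA divides by the
residue's theoretical maximum exposure in an extended Gly-X-Gly tripeptide
(Tien et al. 2013 values, shipped as data); termini can mildly exceed
100%.  Exposure classes are exposed (≥ 25%), buried (≤ 7%), partial
(between) — the three-way scheme is standard, the numeric cutoffs are this
package's documented defaults.  Inter-residue distances default to CA
atoms; side-chain atoms (e.g. lysine NZ) are selectable.  Numbering
offsets between structure and sequence coordinates are explicit
configuration, never inferred.

## Motif scanning

Degenerate motifs are whitespace-tokenized patterns over fixed residues,
the wildcard `x`, named residue classes and bounded runs `x(min,max)`.  The
shipped default classes are Ф (aromatic) = {F, W, Y, H} and Ө (hydrophobic)
= {A, C, F, G, I, L, M, P, V, W, Y}.  Ө deliberately includes proline: of
the three SWI/SNF peptides known to carry the β-catenin-groove-binding
motif `D x Ө Ө x Ф x(2,7) E` (BAF60B DKVASWELRVE, BRG1 DELPSWIIKDDAE,
BAF53B DIIPPYMIAAKE), two place P at a Ө slot, so any class that accepts
all three must contain P.  Both class bindings are configurable.  Scanning
enumerates every start and run-length assignment; distinct (start, end)
spans are reported once by default, with `all_expansions` retaining every
run assignment.

## Mutation mapping

Somatic missense mutations (1-based protein positions) are assigned to
non-overlapping domain regions and intersected with functional residue
sets.  Counts are over distinct mutated residues — published accounts
enumerate residues, not records — with record counts kept in a separate
column; duplicate (position, alt) rows collapse.  Both boundary
conventions for the two BAF250a domains ship as presets: hydrophobic-
cluster segmentation (ARID 1008–1107, BAF250_C 1939–2282) and Pfam (ARID
1000–1119, BAF250_C 1974–2231); all reference residue sets fall inside
both.  The DNA-binding and architecture-specific conserved residue sets
are compiled from published structural work; because several positions
(R1046, R1074) belong to both, a disjoint "conserved, non-DNA-binding"
preset supports the published two-category accounting.  The shipped
mutation list is a reconstruction restricted to the residues published for
the two domains; its alt alleles are placeholders, which affects nothing
the package counts.

## Synthetic data model

`generate_families` emits per-architecture alignments with planted column
classes.  Universal columns draw one residue shared by all architectures
with probability equal to the conservation level, background otherwise;
focal-specific columns are conserved (at residue or property-class level)
only in the focal architecture; variable columns are background.  The
background is uniform over the 20 residues — the worst case for
property-class false positives.  Defaults (3 architectures × 10 sequences,
120 columns, 20 universal + 20 focal-specific, conservation 1.0, no
indels) are sized so every downstream stage runs in well under a second.

One property of the generator deserves emphasis: planted labels are
*guaranteed*, not merely probable.  A uniform background column of depth
10 qualifies for the 14-member hydrophobic class in roughly 65% of draws,
so naively sampled "variable" columns would frequently be conserved under
the classifier's own definition and the truth labels would be lies.
Variable columns and the non-focal blocks of focal-specific columns are
therefore rejection-sampled until no class reaches the threshold in the
emitting block; since 70% of 20 pooled rows needs ≥ 14 hits and each
rejected 10-row block contributes ≤ 6, the pooled non-focal consensus is
unconserved by construction.  This is a property of what "variable" means,
not a tuning of the test conditions.

`generate_coevolved_pair` evolves two alignments independently down one
random tree (uniform Jukes–Cantor-style substitution over 20 letters,
random topology, branch lengths uniform on [0.05, 0.25]).  Congruence
tests use the high-signal regime (substitution rate 0.3, 600 columns per
domain), where both neighbor-joining trees recover the generating topology
essentially always.  At realistic single-domain lengths (a ~110-residue
domain) and 8 taxa, recovery of the shortest internal branches is less
reliable — a known limitation of distance methods at short alignments, and
the reason the congruence property is stated at high signal.

`generate_helix_pdb` writes an ideal poly-alanine α-helix (rise 1.5 Å,
twist 100°/residue, backbone N/CA/C/O) with the residues of one helical
face recorded as planted truth; a short isolated helix has no buried
residues, so the conserved∧exposed intersection must recover the full
planted face.  `generate_mutation_table` plants exact per-region counts.

What passing these tests does **not** show: real protein families have
phylogenetic correlation between rows, compositional bias, and indel
structure that the generators do not model (indels are i.i.d. gap noise;
there is no site-rate heterogeneity).  Recovery rates on the synthetic
families are therefore upper bounds on what identically parameterized real
alignments would give.

## Reference-data-dependent checks

Two published quantities — the paralogue identity of the two BAF250
proteins (59% full length, 83%/80% over the two domains, lengths
2285/2236) and the ~32 Å CA–CA spacing of the groove lysines K312/K435 in
the β-catenin crystal structure — require the real UniProt/PDB records,
which are not shipped (they are third-party database records).  The
corresponding tests read `data/reference/` or fetch the records when a
network is available, and fail with an explanatory message otherwise
rather than passing vacuously.

## Problem sizes

Default test and acceptance problem sizes: 120-column families (20 seeds at
partial conservation), 8-taxon coevolution pairs (20 seeds), 1000 bootstrap
replicates on an 8-row alignment, 100 random additive matrices for the
neighbor-joining oracle, 1000 random columns for the consensus oracle, and
92-point spheres for SASA.  These sizes make every statistical check
deterministic-in-practice while the whole suite runs in seconds.
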