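# Methods

## Taxonomy model

Lineages are fixed to the seven canonical GTDB ranks (domain, phylum, class,
order, family, genus, species). A missing rank is kept as an explicit
placeholder token — the bare GTDB prefix, e.g. `g__` — and placeholders are
scoped by their parent node, so two unnamed genera under different families
are distinct taxa. This keeps stratification sound: unrelated unnamed clades
are never merged into one stratum.

Two sources feed the same in-memory index. GTDB metadata supplies a
7-field taxonomy string per assembly; NCBI taxdump lineages are
reconstructed by walking `nodes.dmp` parent links and keeping only the
canonical ranks (intermediate ranks such as suborder are skipped;
`superkingdom` folds onto domain), with names taken from the
"scientific name" class of `names.dmp`. With both encodings of the same
genome the two readers produce identical lineages, which is tested.
Accessions are normalized by stripping GTDB's `RS_`/`GB_` prefixes; the
source database is derived from the prefix (`GCF_` → RefSeq, `GCA_` →
GenBank).

## Sampling schemes and hierarchical processing

A scheme is an ordered list of criteria `(taxon, sampling_rank, quota)`:
sample `quota` genomes from *each* clade at `sampling_rank` inside `taxon`.
Criteria are processed from the most specific sampling rank upward (species
before genus before family, ...), ties broken by file order, and a clade
contained in the target taxon of an earlier-processed criterion is skipped.
The consequence is the intended "dense where asked, sparse elsewhere"
behavior: an order-rank criterion on one phylum together with a class-rank
criterion on the whole domain never double-samples the densely covered
phylum, which holds exactly (not just in expectation) because exclusion is
by clade containment, not by drawn-genome overlap.

Within a clade, each draw descends the taxonomy one rank at a time, choosing
uniformly at random among the child taxa that still contain unselected
eligible genomes, and finally uniformly among the remaining genomes of the
chosen species. Draws are without replacement. This equalizes the selection
probability of sibling taxa at *every* intermediate rank regardless of their
genome counts: a 99-genome order and a 1-genome order are each picked with
probability 1/2 under quota 1. The published description applies the
equalization to the ranks between the target taxon and the sampling rank;
since per-clade quotas make that span inert, the implementation applies the
same uniform-descent rule at every rank below the sampling rank as well,
which is the reading with observable effect. Per-node counters of remaining
eligible genomes, decremented along the species-to-root path after each
draw, make a draw O(depth · max-children).

Quality filters (minimum CheckM completeness, maximum contamination,
source database) run before sampling. A record lacking a metric is dropped
when the corresponding threshold is set (strict mode); the
`keep_missing_metrics` flag inverts this. Required accessions are exempt
from the filters, are placed first, and count against the quota of their
containing sampling-rank clade under the criterion that covers them;
required genomes no criterion covers are still included, tagged
`required-only`.

Determinism: a single `numpy` generator seeded by the user drives all
stochastic choices in a documented order — criteria in processing order,
clades in lexicographic path order, then the descent — so identical inputs
and seed give a byte-identical selection table.

## Tree pruning

Candidate pairs are *cherries* — sibling leaf pairs — with distance equal to
the sum of the two pendant branch lengths; non-sibling leaf pairs are never
candidates. This restriction is what makes incremental updating sound:
removing a leaf and suppressing the resulting unary parent (the surviving
child's branch absorbs the suppressed branch, conserving root-to-leaf path
lengths) can only create new cherries around the surviving sibling, and only
when that survivor is itself a leaf. The pruner therefore computes all
cherry distances once, keeps them in a min-heap with lazy invalidation
(entries whose leaves are gone are discarded when popped), and after each
removal computes exactly the distances of the survivor's new leaf-sibling
pairs. Total distance computations are bounded by the initial cherry count
plus two per removal; the bound is asserted by an instrumentation counter in
the tests, as the machine-independent form of the speed advantage over
full-recompute pruning (the measured ratio on a 2000→200-leaf run is
~300×). A reference implementation that rescans every cherry each iteration
(`prune_tree_naive`) shares the same contract and tie rules and must produce
identical output for any seed — the equivalence is tested over hundreds of
random trees and all policies.

Keep policies: `keep_shortest` removes the longer-pendant member of the
minimum cherry (discarding fast-evolving tips, the default), `keep_longest`
the shorter, `random` a fair coin. Ties are fixed so that the heap and naive
paths are comparable test-for-test: equal cherry distances order by
lexicographic (min leaf, max leaf); equal pendant lengths remove the
lexicographically later leaf. The coin is drawn only when neither member is
protected, keeping the two implementations' random streams aligned.

Protected leaves are never removed. A cherry whose two members are both
protected is permanently ineligible; if at some point every remaining cherry
is fully protected the pruner signals exhaustion rather than removing a
protected leaf — a genuine dead-end of cherry-restricted pruning that both
implementations reach identically. Restricting pruning to part of the tree
(`restrict_taxon`, a clade label or a leaf set) extracts the minimal
spanning (MRCA) subtree first and prunes only it; the remainder of the tree
is discarded, not re-attached. Trees are treated as rooted exactly as
written in the Newick file; a root left with a single child is collapsed
onto that child.

## Balance diagnostics

`colless_index` requires a strictly bifurcating rooted tree and errors on
polytomies, identifying the offending node; an opt-in deterministic
resolution folds polytomies in input order with zero-length branches and is
documented as altering the index. The index is branch-length invariant;
closed forms (0 balanced, `(n−1)(n−2)/2` caterpillar) and an independent
dendropy-based traversal serve as oracles. `node_depths` reports
root-to-internal-node path lengths in branch-length units, root excluded.
No rerooting is ever performed, so values are reproducible against trees
consumed as deposited.

## Synthetic data

The taxonomy generator emulates the one feature of real catalogs that
matters here: rank-structured skew. A spec fixes total genomes, class
count, and the fraction concentrated in the first `k` classes (split among
them with descending integer weights, 2:1 for `k = 2`; the remainder spread
uniformly), with per-class order/family/genus structure drawn from
configurable ranges and genomes assigned to genera uniformly. The default
preset is 2450 genomes, 28 classes, 78% in two classes. Quality metrics are
uniform in configurable ranges (defaults 80–100% completeness, 0–10%
contamination) and ~30% of accessions are RefSeq-prefixed. The generator
does **not** emulate correlated metric/lineage structure, synonym noise,
or real GTDB names — passing tests show the sampling logic is correct under
skew, not that real-catalog parsing corner cases are covered beyond the
formats exercised.

Random trees use sequential leaf attachment (a uniformly chosen leaf is
replaced by a cherry; the new internal branch inherits the old pendant
length and both pendants are redrawn), giving a random bifurcating topology
with i.i.d. branch lengths, exponential with mean 0.1 by default — the
scale of typical reference-tree branch lengths. This is an
attachment-process shape, not a coalescent; pruning correctness only needs
valid topology and lengths.

Problem sizes in the test and acceptance runs (500 oracle trees of 8–64
leaves, a 2000-leaf complexity fixture, 10 000 stratification draws, 200
paired coverage seeds) were chosen to give stable statistics for each check
while keeping the default suite quick to run.

## Numerical and formatting choices

Branch lengths are serialized with `repr` (shortest exact float
representation), so Newick write→read→write is the identity and outputs are
byte-stable across runs. Missing branch lengths parse as 0 with a warning.
Chi-square goodness-of-fit (scipy) at p > 0.001 is the acceptance bar for
the equal-probability property at 10 000 replicates — loose enough to be
seed-robust, tight enough to catch any size-proportional bias, which at the
99:1 split would give p ≈ 0 immediately.

## Known limitations

* Cherry-restricted pruning cannot remove a leaf whose sibling is internal;
  with ≥ 2 protected leaves this can dead-end before the target (signalled,
  never silently violated).
* Scheme quotas are per clade at the sampling rank; there is no global
  "total dataset size" knob for taxonomic sampling — compose criteria, or
  use phylogenomic pruning when an exact output size is required.
* Quality thresholds are global, not per criterion, and NCBI-sourced
  metadata carries no CheckM values, so thresholds set there drop everything
  unless `keep_missing_metrics` is used.
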