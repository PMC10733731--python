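# phylosample

Taxonomy-aware genome subsampling and diversity-preserving phylogeny pruning
for phylogenomics.

## The problem

Genome catalogs for bacteria and archaea are enormous and badly skewed:
clinically and environmentally popular lineages are sequenced thousands of
times while most of the diversity is covered by a handful of assemblies.
Building a phylogenomic dataset by taking everything is computationally
intractable, and taking a uniform random subset reproduces the skew — the
resulting phylogenies are unbalanced, with few, long branches covering the
deep diversity. `phylosample` builds *balanced* genome datasets from such
catalogs in two complementary ways:

* **Taxonomic sampling** — stratified, hierarchical sampling over a
  GTDB-style or NCBI taxonomy under a user-written *sampling scheme*: rules
  of the form "within taxon *T*, sample *q* genomes from each clade at rank
  *r*". When several criteria nest, the most finely sampled criterion wins;
  clades it covers are excluded from coarser criteria. Between the target
  taxon and the sampling rank, draws descend the taxonomy choosing uniformly
  among child taxa at every rank, so intermediate taxa have equal sampling
  probability regardless of how many genomes they contain.
* **Phylogenomic sampling** — pruning a reference phylogeny down to a target
  leaf count by repeatedly deleting one member of the *cherry* (sibling leaf
  pair) with the smallest pendant-distance sum
  `d(a, b) = len(a) + len(b)`. The default policy keeps the shorter branch
  of the pair, discarding fast-evolving taxa that promote long-branch
  attraction. Deleting a leaf only creates new cherries around the surviving
  sibling, so distances are computed once up front and then only for newly
  formed pairs — a lazily invalidated min-heap makes each step logarithmic,
  instead of rescanning the whole tree per deletion as a full-recompute
  pruner must.

Balance of the result is quantified with the Colless imbalance index
`C = Σ_v |L(v) − R(v)|` (0 for a perfectly balanced rooted bifurcating tree,
`(n−1)(n−2)/2` for a caterpillar) and with the distribution of
root-to-internal-node path lengths.

Quality gates (CheckM completeness/contamination, GenBank vs RefSeq source)
apply before sampling; a required-accession list forces genomes into the
selection regardless of the gates.

## Worked example

Generate a skewed synthetic catalog (2450 genomes, 28 classes, 78% of
genomes in the two largest classes), sample 4 genomes per class, and compare
against the catalog:

```sh
phylosample fixtures taxonomy --preset planctomycetota-like --seed 1 -o meta.tsv
printf 'taxon\tsampling_rank\tquota\np001\tclass\t4\n' > scheme.tsv
phylosample sample taxonomy --metadata meta.tsv --scheme scheme.tsv \
    --min-completeness 90 --seed 1 -o selection.tsv
phylosample stats ranks --selection selection.tsv --rank class --metadata meta.tsv
```

which prints (first rows):

```
taxon	sampled	available
c001	4	1274
c002	4	637
c003	4	21
```

Every one of the 28 classes contributes exactly `min(4, eligible)` genomes —
the two classes holding 78% of the catalog get no more weight than the
rarest ones. A uniform random sample of the same size typically covers only
17–19 of the 28 classes.

Pruning a phylogeny and checking its balance:

```sh
phylosample fixtures tree --n 64 --seed 7 -o big.nwk
phylosample sample phylogeny --tree big.nwk --n-taxa 10 --keep shortest \
    --seed 1 -o pruned.nwk
phylosample stats colless --tree pruned.nwk
```

prints `21`, the Colless index of the 10-leaf pruned tree. Every command
writes a `<output>.config.yaml` sidecar with its resolved settings, and
re-running with the same seed reproduces outputs byte for byte.

The same operations are available as a library
(`phylosample.sample_taxonomic`, `phylosample.prune_tree`,
`phylosample.colless_index`, ...); see `docs/methods.md` for the model and
parameter details.

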