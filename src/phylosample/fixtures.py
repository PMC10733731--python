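"""Synthetic data generation: skewed taxonomies and random trees.

Real genome catalogs are heavily skewed — most assemblies sit in a handful
of well-studied classes.  :func:`make_taxonomy` emulates that situation so
the sampler can be exercised without any downloads, including a preset that
mirrors a phylum of 2450 genomes spread over 28 classes with 78% of genomes
concentrated in just two of them.  :func:`make_tree` produces random
bifurcating trees with i.i.d. branch lengths for pruning tests.  Everything
is deterministic given the seed; generated metadata round-trips through
``read_gtdb_metadata`` unchanged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .taxonomy_io import PhyloTree, TreeNode


@dataclass(frozen=True)
class TaxonomySpec:
    """Shape of a synthetic genome catalog.

    ``skew_fraction`` of all genomes is concentrated in the first
    ``n_skew_classes`` classes (split between them proportionally with
    descending integer weights, e.g. 2:1 for two classes); the remainder is
    spread uniformly over the other classes.  ``*_range`` fields are
    inclusive (lo, hi) child-count ranges drawn per parent node.
    """

    n_genomes: int = 2450
    n_phyla: int = 1
    n_classes: int = 28
    skew_fraction: float = 0.78
    n_skew_classes: int = 2
    orders_per_class: tuple[int, int] = (1, 3)
    families_per_order: tuple[int, int] = (1, 2)
    genera_per_family: tuple[int, int] = (1, 3)
    completeness_range: tuple[float, float] = (80.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 10.0)
    refseq_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.skew_fraction <= 1):
            raise ValidationError("skew_fraction must be in (0, 1]")
        if self.n_skew_classes > self.n_classes:
            raise ValidationError("n_skew_classes exceeds n_classes")
        if self.n_classes > self.n_genomes:
            raise ValidationError(
                f"infeasible spec: {self.n_classes} classes but only "
                f"{self.n_genomes} genomes"
            )
        if self.n_phyla > self.n_classes:
            raise ValidationError("more phyla than classes")


def planctomycetota_like(seed: int = 0) -> TaxonomySpec:
    """Preset mimicking a skewed phylum: 2450 genomes, 28 classes, 78% in two."""
    return TaxonomySpec(seed=seed)


def _class_allocation(spec: TaxonomySpec) -> list[int]:
    """Genomes per class: skewed head (descending-integer weights), uniform tail."""
    n_skew = math.ceil(spec.skew_fraction * spec.n_genomes)
    k = spec.n_skew_classes
    weights = list(range(k, 0, -1))
    wsum = sum(weights)
    head = [n_skew * w // wsum for w in weights]
    head[0] += n_skew - sum(head)
    rest = spec.n_genomes - n_skew
    tail_classes = spec.n_classes - k
    if tail_classes:
        if rest < tail_classes:
            raise ValidationError(
                f"infeasible spec: {rest} genomes left for {tail_classes} classes"
            )
        base, extra = divmod(rest, tail_classes)
        tail = [base + (1 if i < extra else 0) for i in range(tail_classes)]
    else:
        if rest:
            head[0] += rest
        tail = []
    return head + tail


def make_taxonomy(spec: TaxonomySpec, path=None) -> pd.DataFrame:
    """Generate a GTDB-style metadata table for the spec; optionally write a TSV.

    Names are generated deterministically (p001, c001, o0001, ...); class
    genome counts follow the skew allocation exactly; quality metrics and
    the GenBank/RefSeq split are drawn from the seeded generator.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    per_class = _class_allocation(spec)

    order_counter = family_counter = genus_counter = 0
    rows = []
    serial = 0
    for ci in range(spec.n_classes):
        phylum = f"p{ci % spec.n_phyla + 1:03d}"
        class_name = f"c{ci + 1:03d}"
        # nested structure for this class
        genera: list[tuple[str, str, str]] = []  # (order, family, genus)
        n_orders = int(rng.integers(spec.orders_per_class[0], spec.orders_per_class[1] + 1))
        for _ in range(n_orders):
            order_counter += 1
            order = f"o{order_counter:04d}"
            n_fams = int(rng.integers(spec.families_per_order[0], spec.families_per_order[1] + 1))
            for _ in range(n_fams):
                family_counter += 1
                family = f"f{family_counter:04d}"
                n_gen = int(rng.integers(spec.genera_per_family[0], spec.genera_per_family[1] + 1))
                for _ in range(n_gen):
                    genus_counter += 1
                    genera.append((order, family, f"g{genus_counter:05d}"))
        for _ in range(per_class[ci]):
            serial += 1
            order, family, genus = genera[int(rng.integers(len(genera)))]
            species = f"{genus} sp{serial}"
            prefix = "GCF" if rng.random() < spec.refseq_fraction else "GCA"
            accession = f"{prefix}_{serial:09d}.1"
            taxonomy = (
                f"d__Bacteria;p__{phylum};c__{class_name};o__{order};"
                f"f__{family};g__{genus};s__{species}"
            )
            comp = rng.uniform(*spec.completeness_range)
            cont = rng.uniform(*spec.contamination_range)
            rows.append(
                {
                    "accession": accession,
                    "gtdb_taxonomy": taxonomy,
                    "checkm_completeness": f"{comp:.2f}",
                    "checkm_contamination": f"{cont:.2f}",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "accession",
            "gtdb_taxonomy",
            "checkm_completeness",
            "checkm_contamination",
        ],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return df


# ---------------------------------------------------------------------------
# Random trees
# ---------------------------------------------------------------------------

Law = Union[str, tuple]


def _length_sampler(law: Law, rng: np.random.Generator):
    """Branch-length law: ('exponential', mean) / ('uniform', a, b) or 'exp:0.05'."""
    if isinstance(law, str):
        parts = law.split(":")
        name = parts[0]
        args = tuple(float(p) for p in parts[1:])
    else:
        name, *args = law
    if name in ("exp", "exponential"):
        (mean,) = args
        return lambda: float(rng.exponential(mean))
    if name in ("unif", "uniform"):
        a, b = args
        return lambda: float(rng.uniform(a, b))
    raise ValidationError(f"unknown branch-length law {law!r}")


def make_tree(
    n_leaves: int,
    law: Law = ("exponential", 0.1),
    seed: Optional[int] = None,
) -> PhyloTree:
    """Random bifurcating tree by sequential leaf attachment.

    Each step replaces a uniformly chosen leaf by a cherry of (old leaf, new
    leaf); the new internal branch inherits the old pendant length and both
    pendant branches are redrawn, so all branch lengths are i.i.d. from the
    law.  Leaves are labelled L1..Ln.  Deterministic given the seed.
    """
    if n_leaves < 2:
        raise ValidationError(f"a tree needs at least 2 leaves, got {n_leaves}")
    rng = np.random.default_rng(seed)
    draw = _length_sampler(law, rng)
    root = TreeNode()
    leaves = [root.add_child(TreeNode("L1", draw())), root.add_child(TreeNode("L2", draw()))]
    for i in range(3, n_leaves + 1):
        old = leaves[int(rng.integers(len(leaves)))]
        parent = old.parent
        internal = TreeNode(None, old.length)
        parent.children[parent.children.index(old)] = internal
        internal.parent = parent
        old.length = draw()
        internal.add_child(old)
        new = internal.add_child(TreeNode(f"L{i}", draw()))
        leaves.append(new)
    return PhyloTree(root)
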