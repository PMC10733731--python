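"""Readers/writers for the external formats and the in-memory taxonomy index.

Handles GTDB-style assembly metadata (TSV), the NCBI taxdump dialect
(``nodes.dmp``/``names.dmp`` plus an accession-to-taxid table), Newick trees
with branch lengths, and the selection table the sampler produces.  All
readers accept gzip-compressed input transparently (by ``.gz`` suffix).

Two in-memory containers are defined here:

* :class:`TaxonomyIndex` — a rank-labelled tree over taxa whose species-level
  leaves hold :class:`GenomeRecord` objects; this is what the hierarchical
  sampler descends.
* :class:`PhyloTree` — a rooted, leaf-labelled tree with branch lengths that
  supports leaf removal with unary-node suppression and cherry enumeration;
  this is what the pruner operates on.  Newick parsing is delegated to
  dendropy; the serializer here emits shortest-exact-repr branch lengths so
  that read -> write -> read is the identity.
"""
from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import pandas as pd

from .errors import (
    AmbiguousTaxonError,
    FormatError,
    NewickParseError,
    SchemaError,
    TaxonomyError,
)

# canonical GTDB ranks, most inclusive first
CANONICAL_RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
RANK_DEPTH = {r: i for i, r in enumerate(CANONICAL_RANKS)}
GTDB_PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_BY_RANK = dict(zip(CANONICAL_RANKS, GTDB_PREFIXES))

# NCBI rank tokens folded onto the canonical seven; everything else is skipped
_NCBI_RANK_MAP = {
    "superkingdom": "domain",
    "domain": "domain",
    "kingdom": "domain",
    "phylum": "phylum",
    "class": "class",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "species": "species",
}


def _open_text(path):
    """Open a path for reading text, transparently decompressing ``.gz``."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def placeholder(rank: str) -> str:
    """The explicit missing-taxon token for a rank (the bare GTDB prefix)."""
    return _PREFIX_BY_RANK[rank]


def is_placeholder(name: str) -> bool:
    return name in GTDB_PREFIXES


@dataclass(frozen=True)
class Lineage:
    """Ordered (rank, taxon-name) pairs, domain through species.

    A missing rank is represented by its placeholder token (e.g. ``"g__"``),
    never dropped, so every lineage always has the full canonical rank set.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self):
        rank_names = tuple(r for r, _ in self.ranks)
        if rank_names != CANONICAL_RANKS[: len(rank_names)]:
            raise FormatError(f"ranks out of canonical order: {rank_names}")
        for r, name in self.ranks:
            if not name:
                raise FormatError(f"empty taxon name at rank {r}")

    def get(self, rank: str) -> str:
        for r, name in self.ranks:
            if r == rank:
                return name
        raise KeyError(rank)

    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.ranks)

    def to_gtdb_string(self) -> str:
        parts = []
        for rank, name in self.ranks:
            prefix = _PREFIX_BY_RANK[rank]
            parts.append(prefix if is_placeholder(name) else prefix + name)
        return ";".join(parts)


def normalize_accession(accession: str) -> str:
    """Strip GTDB 'RS_'/'GB_' prefixes so NCBI-style accessions compare equal."""
    if accession.startswith(("RS_", "GB_")):
        return accession[3:]
    return accession


def detect_source(accession: str) -> str:
    acc = normalize_accession(accession)
    if acc.startswith("GCF_"):
        return "refseq"
    if acc.startswith("GCA_"):
        return "genbank"
    return "unknown"


@dataclass(frozen=True)
class GenomeRecord:
    """One assembly: accession, lineage, optional CheckM metrics, source db."""

    accession: str
    lineage: Lineage
    completeness: Optional[float] = None
    contamination: Optional[float] = None
    source: str = field(default="unknown")

    @classmethod
    def make(cls, accession, lineage, completeness=None, contamination=None):
        return cls(
            accession=normalize_accession(accession),
            lineage=lineage,
            completeness=completeness,
            contamination=contamination,
            source=detect_source(accession),
        )


def parse_gtdb_taxonomy_string(s: str) -> Lineage:
    """Parse a 7-rank GTDB taxonomy string (``d__...;p__...;...;s__...``).

    Empty fields (bare prefix, e.g. ``g__``) become placeholder tokens.
    Raises :class:`FormatError` naming the offending field on a malformed
    prefix or a wrong field count.
    """
    fields = [f.strip() for f in s.split(";")]
    if len(fields) != 7:
        raise FormatError(
            f"expected 7 semicolon-separated ranks, got {len(fields)}: {s!r}"
        )
    pairs = []
    for rank, prefix, fld in zip(CANONICAL_RANKS, GTDB_PREFIXES, fields):
        if not fld.startswith(prefix):
            raise FormatError(
                f"field {fld!r} lacks the expected {prefix!r} prefix for rank {rank}"
            )
        name = fld[len(prefix):].strip()
        pairs.append((rank, name if name else placeholder(rank)))
    return Lineage(tuple(pairs))


def read_gtdb_metadata(path) -> list[GenomeRecord]:
    """Read a GTDB-style metadata TSV into genome records.

    Required columns: ``accession``, ``gtdb_taxonomy``; optional:
    ``checkm_completeness``, ``checkm_contamination``.  Unknown extra columns
    are ignored.  Rows whose taxonomy string does not parse are rejected with
    their row number.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("accession", "gtdb_taxonomy"):
        if col not in df.columns:
            raise SchemaError(f"metadata file {path} lacks required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            lineage = parse_gtdb_taxonomy_string(getattr(row, "gtdb_taxonomy"))
        except FormatError as exc:
            raise FormatError(f"row {i}: unparseable taxonomy: {exc}") from exc
        comp = cont = None
        if "checkm_completeness" in df.columns:
            v = getattr(row, "checkm_completeness")
            comp = float(v) if v not in (None, "") and not pd.isna(v) else None
        if "checkm_contamination" in df.columns:
            v = getattr(row, "checkm_contamination")
            cont = float(v) if v not in (None, "") and not pd.isna(v) else None
        records.append(GenomeRecord.make(getattr(row, "accession"), lineage, comp, cont))
    return records


def _read_dmp(path) -> Iterator[list[str]]:
    """Yield field lists from an NCBI taxdump .dmp file (pipe-delimited)."""
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.endswith("\t|"):
                line = line[:-2]
            if not line.strip():
                continue
            yield [f.strip() for f in line.split("\t|\t")]


def read_ncbi_taxonomy(nodes_path, names_path, assembly_table_path) -> list[GenomeRecord]:
    """Build genome records from an NCBI taxdump plus an accession->taxid table.

    Lineages are reconstructed by walking parent links in ``nodes.dmp``,
    keeping only the canonical seven ranks (intermediate NCBI ranks such as
    suborder are skipped); names come from the "scientific name" class in
    ``names.dmp``.  Missing canonical ranks become placeholder tokens.
    """
    parent: dict[int, int] = {}
    rank_of: dict[int, str] = {}
    for fields in _read_dmp(nodes_path):
        if len(fields) < 3:
            raise FormatError(f"nodes.dmp line with {len(fields)} fields")
        taxid, par, rank = int(fields[0]), int(fields[1]), fields[2]
        parent[taxid] = par
        rank_of[taxid] = rank

    name_of: dict[int, str] = {}
    for fields in _read_dmp(names_path):
        if len(fields) < 4:
            continue
        taxid, name_txt, _, name_class = int(fields[0]), fields[1], fields[2], fields[3]
        if name_class == "scientific name":
            name_of[taxid] = name_txt

    with _open_text(assembly_table_path) as fh:
        table = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("accession", "taxid"):
        if col not in table.columns:
            raise SchemaError(
                f"assembly table {assembly_table_path} lacks required column {col!r}"
            )

    orphans = [
        row.accession
        for row in table.itertuples(index=False)
        if int(row.taxid) not in parent
    ]
    if orphans:
        raise TaxonomyError(
            "accessions with taxids absent from nodes.dmp: " + ", ".join(sorted(orphans))
        )

    records = []
    for row in table.itertuples(index=False):
        taxid = int(row.taxid)
        found: dict[str, str] = {}
        seen: set[int] = set()
        t = taxid
        while True:
            if t in seen:
                raise TaxonomyError(f"cycle detected in nodes.dmp at taxid {t}")
            seen.add(t)
            canon = _NCBI_RANK_MAP.get(rank_of[t])
            if canon is not None and canon not in found:
                found[canon] = name_of.get(t, f"taxid-{t}")
            par = parent[t]
            if par == t:  # NCBI root points to itself
                break
            t = par
        pairs = tuple(
            (r, found.get(r, placeholder(r))) for r in CANONICAL_RANKS
        )
        records.append(GenomeRecord.make(row.accession, Lineage(pairs)))
    return records


class TaxonNode:
    """One taxon in the index: rank, name, children by name, records at species."""

    __slots__ = ("rank", "name", "parent", "children", "records")

    def __init__(self, rank: str, name: str, parent: Optional["TaxonNode"]):
        self.rank = rank
        self.name = name
        self.parent = parent
        self.children: dict[str, TaxonNode] = {}
        self.records: list[GenomeRecord] = []

    def genome_count(self) -> int:
        if self.rank == "species":
            return len(self.records)
        return sum(c.genome_count() for c in self.children.values())

    def iter_records(self) -> Iterator[GenomeRecord]:
        if self.rank == "species":
            yield from self.records
        for c in sorted(self.children):
            yield from self.children[c].iter_records()

    def descendants_at_rank(self, rank: str) -> list["TaxonNode"]:
        """All descendant (or self) nodes at the given rank, lexicographic order."""
        if self.rank == rank:
            return [self]
        if RANK_DEPTH.get(self.rank, -1) >= RANK_DEPTH[rank]:
            return []
        out = []
        for name in sorted(self.children):
            out.extend(self.children[name].descendants_at_rank(rank))
        return out

    def is_ancestor_of(self, other: "TaxonNode") -> bool:
        node = other
        while node is not None:
            if node is self:
                return True
            node = node.parent
        return False

    def path(self) -> tuple[str, ...]:
        names = []
        node = self
        while node is not None and node.rank != "root":
            names.append(node.name)
            node = node.parent
        return tuple(reversed(names))

    def __repr__(self):
        return f"TaxonNode({self.rank}:{self.name}, n={self.genome_count()})"


class TaxonomyIndex:
    """Rank-labelled taxonomy tree with genome records at species leaves.

    Placeholder taxa (``g__`` etc.) are scoped by their parent: two unnamed
    genera under different families are distinct nodes, so stratified
    sampling never merges unrelated unnamed clades.  Name lookup is by bare
    taxon name; a name present at two ranks must be qualified as
    ``"rank:name"``.
    """

    def __init__(self):
        self.root = TaxonNode("root", "root", None)
        self._by_name: dict[str, list[TaxonNode]] = {}
        self._species_of: dict[str, TaxonNode] = {}
        self._record_of: dict[str, GenomeRecord] = {}

    def insert(self, record: GenomeRecord) -> None:
        if record.accession in self._record_of:
            raise TaxonomyError(f"duplicate accession {record.accession}")
        node = self.root
        for rank, name in record.lineage.ranks:
            child = node.children.get(name)
            if child is None:
                child = TaxonNode(rank, name, node)
                node.children[name] = child
                self._by_name.setdefault(name, []).append(child)
            node = child
        node.records.append(record)
        self._species_of[record.accession] = node
        self._record_of[record.accession] = record

    @property
    def records(self) -> list[GenomeRecord]:
        return list(self._record_of.values())

    def record(self, accession: str) -> GenomeRecord:
        return self._record_of[accession]

    def species_node(self, accession: str) -> TaxonNode:
        return self._species_of[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._record_of

    def find(self, name: str, rank: Optional[str] = None) -> Optional[TaxonNode]:
        """Resolve a taxon name (optionally ``'rank:name'``-qualified) to a node.

        Returns None for unknown names; raises :class:`AmbiguousTaxonError`
        when the bare name occurs at more than one rank and no rank is given.
        """
        if rank is None and ":" in name:
            rank, name = name.split(":", 1)
            rank = rank.strip().lower()
            if rank not in RANK_DEPTH:
                raise AmbiguousTaxonError(f"unknown rank qualifier {rank!r}")
        hits = self._by_name.get(name, [])
        if rank is not None:
            hits = [h for h in hits if h.rank == rank]
        if not hits:
            return None
        ranks = {h.rank for h in hits}
        if len(ranks) > 1:
            raise AmbiguousTaxonError(
                f"taxon name {name!r} occurs at ranks {sorted(ranks)}; "
                f"qualify as 'rank:{name}'"
            )
        if len(hits) > 1:
            # same name, same rank, different parents (placeholder collision)
            raise AmbiguousTaxonError(
                f"taxon name {name!r} is not unique at rank {hits[0].rank}"
            )
        return hits[0]


def build_index(records: Sequence[GenomeRecord]) -> TaxonomyIndex:
    """Build a taxonomy index; raises on an empty list or duplicate accessions."""
    if not records:
        raise TaxonomyError("cannot build an index from zero records")
    index = TaxonomyIndex()
    for rec in records:
        index.insert(rec)
    return index


# ---------------------------------------------------------------------------
# Phylogenetic trees
# ---------------------------------------------------------------------------

class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label: Optional[str] = label
        self.length: Optional[float] = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted, leaf-labelled tree with branch lengths.

    Supports the operations pruning needs: leaf removal with suppression of
    the resulting unary node (branch lengths are summed, so root-to-leaf path
    lengths are conserved), cherry enumeration, and MRCA-subtree extraction.
    Leaf labels must be unique.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._leaves: dict[str, TreeNode] = {}
        for node in self.iter_nodes():
            if node.is_leaf:
                if node.label is None:
                    raise FormatError("unlabelled leaf")
                if node.label in self._leaves:
                    raise FormatError(f"duplicate leaf label {node.label!r}")
                self._leaves[node.label] = node

    # -- traversal ---------------------------------------------------------
    def iter_nodes(self) -> Iterator[TreeNode]:
        """Preorder traversal (iterative; safe for deep caterpillar trees)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_labels(self) -> set[str]:
        return set(self._leaves)

    def leaf_count(self) -> int:
        return len(self._leaves)

    def leaf(self, label: str) -> TreeNode:
        return self._leaves[label]

    def has_leaf(self, label: str) -> bool:
        return label in self._leaves

    # -- editing -----------------------------------------------------------
    def remove_leaf(self, label: str) -> Optional[TreeNode]:
        """Remove a leaf and suppress the resulting unary parent.

        Returns the surviving sibling subtree root after suppression (the
        node that moved up), or None when the parent still has >= 2 children.
        """
        node = self._leaves.pop(label)
        parent = node.parent
        if parent is None:
            raise ValueError("cannot remove the only node of the tree")
        parent.children.remove(node)
        node.parent = None
        if len(parent.children) != 1:
            return None
        child = parent.children[0]
        if parent.parent is None:
            # root left with one child: collapse root onto the child
            child.parent = None
            child.length = None
            self.root = child
            return child
        child.length = (child.length or 0.0) + (parent.length or 0.0)
        grand = parent.parent
        grand.children[grand.children.index(parent)] = child
        child.parent = grand
        return child

    def cherries(self) -> list[tuple[str, str, float]]:
        """All sibling leaf pairs as (leafA, leafB, pendant-length sum).

        For a node with k leaf children all k*(k-1)/2 pairs are returned;
        pair names are ordered lexicographically within the tuple, and the
        list is sorted by (distance, leafA, leafB).
        """
        out = []
        for node in self.iter_nodes():
            leaf_kids = sorted(
                (c for c in node.children if c.is_leaf), key=lambda c: c.label
            )
            for i in range(len(leaf_kids)):
                for j in range(i + 1, len(leaf_kids)):
                    a, b = leaf_kids[i], leaf_kids[j]
                    out.append((a.label, b.label, (a.length or 0.0) + (b.length or 0.0)))
        out.sort(key=lambda t: (t[2], t[0], t[1]))
        return out

    def copy(self) -> "PhyloTree":
        def clone(node):
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        # iterative clone to stay safe on deep trees
        new_root = TreeNode(self.root.label, self.root.length)
        stack = [(self.root, new_root)]
        while stack:
            old, new = stack.pop()
            for c in old.children:
                nc = TreeNode(c.label, c.length)
                new.add_child(nc)
                stack.append((c, nc))
        return PhyloTree(new_root)

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        labels = list(labels)
        missing = [l for l in labels if l not in self._leaves]
        if missing:
            raise ValueError(f"labels not in tree: {missing}")
        paths = []
        for l in labels:
            path = []
            node = self._leaves[l]
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            first = paths[0][depth]
            if all(p[depth] is first for p in paths):
                mrca = first
            else:
                break
        return mrca

    def extract_subtree(self, labels: Iterable[str]) -> "PhyloTree":
        """Minimal subtree spanning the labels (MRCA subtree), other leaves pruned."""
        keep = set(labels)
        mrca = self.mrca(keep)
        sub_root = TreeNode(mrca.label, None)
        stack = [(mrca, sub_root)]
        while stack:
            old, new = stack.pop()
            for c in old.children:
                nc = TreeNode(c.label, c.length)
                new.add_child(nc)
                stack.append((c, nc))
        sub = PhyloTree(sub_root)
        for label in sorted(sub.leaf_labels() - keep):
            sub.remove_leaf(label)
        return sub

    def extract_clade(self, clade_label: str) -> "PhyloTree":
        """Subtree rooted at the internal node carrying the given label."""
        for node in self.iter_nodes():
            if not node.is_leaf and node.label == clade_label:
                new_root = TreeNode(node.label, None)
                stack = [(node, new_root)]
                while stack:
                    old, new = stack.pop()
                    for c in old.children:
                        nc = TreeNode(c.label, c.length)
                        new.add_child(nc)
                        stack.append((c, nc))
                return PhyloTree(new_root)
        raise ValueError(f"no internal node labelled {clade_label!r}")

    # -- serialization -----------------------------------------------------
    def newick(self) -> str:
        return _to_newick(self.root) + ";"

    def __repr__(self):
        return f"PhyloTree({self.leaf_count()} leaves)"


_UNQUOTED_OK = re.compile(r"^[^\s()\[\]{}:;,']+$")


def _format_label(label: str) -> str:
    if _UNQUOTED_OK.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(length: Optional[float]) -> str:
    if length is None:
        return ""
    return ":" + repr(float(length))


def _to_newick(root: TreeNode) -> str:
    # post-order assembly with an explicit stack (deep caterpillars are fine)
    out: dict[int, str] = {}
    stack: list[tuple[TreeNode, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf:
            out[id(node)] = _format_label(node.label or "") + _format_length(
                node.length if node.parent is not None else None
            )
        elif not expanded:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children)
        else:
            inner = ",".join(out.pop(id(c)) for c in node.children)
            label = _format_label(node.label) if node.label else ""
            length = _format_length(node.length if node.parent is not None else None)
            out[id(node)] = f"({inner}){label}{length}"
    return out[id(root)]


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree` (via dendropy)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"newick parse error: {exc}") from exc

    def label_of(dnode):
        if dnode.taxon is not None:
            return dnode.taxon.label
        return dnode.label

    seed = dtree.seed_node
    root = TreeNode(label_of(seed), None)
    stack = [(seed, root)]
    missing_length = False
    while stack:
        dold, new = stack.pop()
        for dchild in dold.child_nodes():
            length = dchild.edge.length
            if length is None:
                missing_length = True
                length = 0.0
            nc = TreeNode(label_of(dchild), float(length))
            new.add_child(nc)
            stack.append((dchild, nc))
    if missing_length:
        warnings.warn("branch length(s) absent; treated as 0", stacklevel=2)
    return PhyloTree(root)


def read_newick(path) -> PhyloTree:
    with _open_text(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Selection table
# ---------------------------------------------------------------------------

SELECTION_COLUMNS = [
    "accession",
    *CANONICAL_RANKS,
    "criterion_id",
    "required",
]


def selection_frame(selection) -> pd.DataFrame:
    """Tabulate a Selection (criterion order, then accession lexicographic)."""
    rows = []
    for entry in selection.entries:
        rec = entry.record
        row = {"accession": rec.accession}
        for rank, name in rec.lineage.ranks:
            row[rank] = name
        row["criterion_id"] = str(entry.criterion_id)
        row["required"] = "true" if entry.required else "false"
        rows.append(row)

    def sort_key(row):
        cid = row["criterion_id"]
        return (0, int(cid)) if cid.isdigit() else (1, 0), row["accession"]

    rows.sort(key=sort_key)
    return pd.DataFrame(rows, columns=SELECTION_COLUMNS)


def write_selection(selection, path) -> None:
    """Write a selection TSV with deterministic row order."""
    df = selection_frame(selection)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
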