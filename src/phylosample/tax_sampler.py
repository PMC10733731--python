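"""Hierarchical, taxonomy-aware genome sampling.

The sampler walks a taxonomy index under a validated scheme.  For each
criterion it visits every clade at the criterion's sampling rank inside the
target taxon and draws the quota by *stratified descent*: starting at the
clade node, at each rank below it picks uniformly at random among the child
taxa that still contain unselected eligible genomes, descends, and finally
picks a genome; repeated without replacement.  This equalizes the sampling
probability of intermediate taxa (a family with 3 genomes and a sibling
family with 300 are equally likely to contribute the next draw), which is
what keeps skewed taxonomies from dominating the selection.

Criteria are processed from the most specific sampling rank upward; clades
already inside an earlier criterion's target taxon are excluded, so a denser
local criterion always wins over a coarser global one.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SamplingError
from .scheme import SamplingScheme, processing_order
from .taxonomy_io import GenomeRecord, RANK_DEPTH, TaxonNode, TaxonomyIndex


@dataclass(frozen=True)
class QualityFilters:
    """Global genome-quality gate applied before sampling.

    With ``keep_missing_metrics=False`` (strict, the default) a record that
    lacks a metric is dropped whenever the corresponding threshold is set.
    """

    min_completeness: Optional[float] = None
    max_contamination: Optional[float] = None
    source: str = "any"  # any | genbank | refseq
    keep_missing_metrics: bool = False


@dataclass(frozen=True)
class SelectionEntry:
    record: GenomeRecord
    criterion_id: object  # int ordinal, or "required-only" / "random"
    required: bool = False


@dataclass
class Selection:
    """An ordered genome selection plus the settings that produced it."""

    entries: list[SelectionEntry]
    seed: Optional[int] = None
    filters: Optional[QualityFilters] = None

    @property
    def accessions(self) -> list[str]:
        return [e.record.accession for e in self.entries]

    def __len__(self):
        return len(self.entries)


def apply_quality_filters(
    records: Sequence[GenomeRecord],
    min_completeness: Optional[float] = None,
    max_contamination: Optional[float] = None,
    source: str = "any",
    keep_missing_metrics: bool = False,
) -> list[GenomeRecord]:
    """Filter records on CheckM completeness/contamination and source database."""
    if min_completeness is not None and not (0 <= min_completeness <= 100):
        raise SamplingError("min_completeness must be in [0, 100]")
    if max_contamination is not None and max_contamination < 0:
        raise SamplingError("max_contamination must be >= 0")
    if source not in ("any", "genbank", "refseq"):
        raise SamplingError(f"unknown source filter {source!r}")

    kept = []
    for rec in records:
        if source != "any" and rec.source != source:
            continue
        if min_completeness is not None:
            if rec.completeness is None:
                if not keep_missing_metrics:
                    continue
            elif rec.completeness < min_completeness:
                continue
        if max_contamination is not None:
            if rec.contamination is None:
                if not keep_missing_metrics:
                    continue
            elif rec.contamination > max_contamination:
                continue
        kept.append(rec)
    return kept


def _eligible_counts(node: TaxonNode, eligible: set[str], counts: dict) -> int:
    if node.rank == "species":
        n = sum(1 for r in node.records if r.accession in eligible)
    else:
        n = sum(
            _eligible_counts(node.children[c], eligible, counts)
            for c in node.children
        )
    counts[node] = n
    return n


def _decrement_path(species_node: TaxonNode, counts: dict) -> None:
    node = species_node
    while node is not None:
        if node in counts:
            counts[node] -= 1
        node = node.parent


def _sample_clade(
    clade: TaxonNode,
    quota: int,
    selected: set[str],
    rng: np.random.Generator,
    eligible: set[str],
    counts: dict,
) -> list[GenomeRecord]:
    """Stratified descent, without replacement; mutates selected and counts."""
    picked: list[GenomeRecord] = []
    for _ in range(quota):
        if counts.get(clade, 0) <= 0:
            break
        node = clade
        while node.rank != "species":
            cands = [
                node.children[name]
                for name in sorted(node.children)
                if counts.get(node.children[name], 0) > 0
            ]
            node = cands[int(rng.integers(len(cands)))]
        accs = sorted(
            r.accession
            for r in node.records
            if r.accession in eligible and r.accession not in selected
        )
        acc = accs[int(rng.integers(len(accs)))]
        rec = next(r for r in node.records if r.accession == acc)
        selected.add(acc)
        _decrement_path(node, counts)
        picked.append(rec)
    return picked


def sample_clade(
    clade: TaxonNode,
    quota: int,
    already_selected: Iterable[str] = (),
    rng: Optional[np.random.Generator] = None,
    eligible: Optional[set[str]] = None,
) -> list[GenomeRecord]:
    """Sample up to ``quota`` genomes from one clade by stratified descent.

    Returns min(quota, remaining eligible) genomes; an exhausted clade
    returns an empty list.  Does not mutate ``already_selected``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    selected = set(already_selected)
    if eligible is None:
        eligible = {r.accession for r in clade.iter_records()}
    eligible = eligible - selected
    counts: dict = {}
    _eligible_counts(clade, eligible, counts)
    return _sample_clade(clade, quota, selected, rng, eligible, counts)


def sample_taxonomic(
    index: TaxonomyIndex,
    scheme: SamplingScheme,
    filters: Optional[QualityFilters] = None,
    required_accessions: Sequence[str] = (),
    seed: int = 0,
) -> Selection:
    """Run a validated scheme over the index and return the selection.

    Required accessions are added first (flagged, exempt from quality
    filters) and count against the quota of their containing sampling-rank
    clade under the criterion that covers them; required genomes covered by
    no criterion are appended with criterion_id ``"required-only"``.
    Deterministic for fixed (index, scheme, filters, required, seed).
    """
    if not scheme.validated:
        raise SamplingError("scheme must pass validate_scheme() before sampling")
    filters = filters or QualityFilters()

    required = list(dict.fromkeys(list(scheme.required_accessions) + list(required_accessions)))
    missing = [a for a in required if a not in index]
    if missing:
        raise SamplingError(
            "required accessions absent from the metadata: " + ", ".join(sorted(missing))
        )

    eligible = {
        r.accession
        for r in apply_quality_filters(
            index.records,
            filters.min_completeness,
            filters.max_contamination,
            filters.source,
            filters.keep_missing_metrics,
        )
    }
    rng = np.random.default_rng(seed)
    counts: dict = {}
    _eligible_counts(index.root, eligible, counts)

    selected: set[str] = set()
    entries: list[SelectionEntry] = []

    def take_required(acc: str, criterion_id) -> None:
        rec = index.record(acc)
        selected.add(acc)
        if acc in eligible:
            _decrement_path(index.species_node(acc), counts)
        entries.append(SelectionEntry(rec, criterion_id, required=True))

    unassigned_required = set(required)
    earlier_targets: list[TaxonNode] = []
    for crit in processing_order([c for c in scheme.criteria if c.node is not None]):
        clades = [
            cl
            for cl in crit.node.descendants_at_rank(crit.sampling_rank)
            if not any(t.is_ancestor_of(cl) for t in earlier_targets)
        ]
        for clade in clades:
            quota = crit.quota
            reqs_here = sorted(
                a
                for a in unassigned_required
                if a not in selected and clade.is_ancestor_of(index.species_node(a))
            )
            for acc in reqs_here:
                take_required(acc, crit.id)
                unassigned_required.discard(acc)
                quota -= 1
            if quota <= 0:
                continue
            for rec in _sample_clade(clade, quota, selected, rng, eligible, counts):
                entries.append(SelectionEntry(rec, crit.id, required=False))
        earlier_targets.append(crit.node)

    for acc in sorted(unassigned_required):
        if acc not in selected:
            take_required(acc, "required-only")

    return Selection(entries, seed=seed, filters=filters)


def sample_random(
    index: TaxonomyIndex,
    n: int,
    filters: Optional[QualityFilters] = None,
    seed: int = 0,
) -> Selection:
    """Uniform random selection of ``n`` eligible genomes (baseline comparator)."""
    filters = filters or QualityFilters()
    pool = sorted(
        r.accession
        for r in apply_quality_filters(
            index.records,
            filters.min_completeness,
            filters.max_contamination,
            filters.source,
            filters.keep_missing_metrics,
        )
    )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    entries = [
        SelectionEntry(index.record(pool[i]), "random", required=False)
        for i in sorted(int(i) for i in chosen)
    ]
    return Selection(entries, seed=seed, filters=filters)


def coverage_report(selection: Selection, index: TaxonomyIndex, rank: str) -> pd.DataFrame:
    """Per-taxon sampled vs available genome counts at one rank.

    Rows cover every taxon at the rank present in the index (zero-count rows
    included); the sampled column sums to the selection size.
    """
    if rank not in RANK_DEPTH:
        raise SamplingError(f"unknown rank {rank!r}")
    taxa = index.root.descendants_at_rank(rank)
    sampled: dict[int, int] = {id(t): 0 for t in taxa}
    for entry in selection.entries:
        node = index.species_node(entry.record.accession)
        while node is not None and node.rank != rank:
            node = node.parent
        if node is not None:
            sampled[id(node)] += 1
    return pd.DataFrame(
        {
            "taxon": [t.name for t in taxa],
            "sampled": [sampled[id(t)] for t in taxa],
            "available": [t.genome_count() for t in taxa],
        }
    )
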