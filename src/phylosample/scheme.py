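"""Sampling schemes: the user-facing rule language for taxonomic sampling.

A scheme is an ordered list of criteria, each saying "within taxon X, sample
Q genomes from every clade at rank R".  Schemes are read from a TSV with
columns ``taxon``, ``sampling_rank``, ``quota`` ('#' comment lines allowed)
and validated against a taxonomy index before use.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import AmbiguousTaxonError, SchemaError, ValidationError
from .taxonomy_io import (
    CANONICAL_RANKS,
    RANK_DEPTH,
    TaxonNode,
    TaxonomyIndex,
    _open_text,
)


@dataclass
class SamplingCriterion:
    """One rule: sample `quota` genomes from each `sampling_rank` clade of `taxon_name`.

    ``id`` is the 1-based ordinal from file order and is stable across runs.
    ``taxon_rank`` and ``node`` are filled in by validation.
    """

    taxon_name: str
    sampling_rank: str
    quota: int
    id: int
    taxon_rank: Optional[str] = None
    node: Optional[TaxonNode] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.sampling_rank not in RANK_DEPTH:
            raise ValidationError(
                f"criterion {self.id}: unknown rank token {self.sampling_rank!r}"
            )
        if self.quota < 1:
            raise ValidationError(
                f"criterion {self.id}: quota must be >= 1, got {self.quota}"
            )


@dataclass
class SamplingScheme:
    criteria: list[SamplingCriterion]
    min_completeness: Optional[float] = None
    max_contamination: Optional[float] = None
    source: str = "any"
    required_accessions: tuple[str, ...] = ()
    validated: bool = False

    def __post_init__(self):
        seen = set()
        for c in self.criteria:
            key = (c.taxon_name, c.sampling_rank)
            if key in seen:
                raise ValidationError(
                    f"duplicate criterion for taxon {c.taxon_name!r} "
                    f"at rank {c.sampling_rank}"
                )
            seen.add(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"taxon": c.taxon_name, "sampling_rank": c.sampling_rank, "quota": c.quota}
                for c in self.criteria
            ],
            columns=["taxon", "sampling_rank", "quota"],
        )


def read_scheme(path) -> SamplingScheme:
    """Read a scheme TSV (columns: taxon, sampling_rank, quota)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    for col in ("taxon", "sampling_rank", "quota"):
        if col not in df.columns:
            raise SchemaError(f"scheme file {path} lacks required column {col!r}")
    criteria = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rank = str(row.sampling_rank).strip().lower()
        try:
            quota = int(str(row.quota).strip())
        except ValueError as exc:
            raise ValidationError(f"criterion {i}: quota {row.quota!r} is not an integer") from exc
        criteria.append(
            SamplingCriterion(
                taxon_name=str(row.taxon).strip(),
                sampling_rank=rank,
                quota=quota,
                id=i,
            )
        )
    return SamplingScheme(criteria)


def write_scheme(scheme: SamplingScheme, path) -> None:
    scheme.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is 'error' or 'note'."""

    severity: str
    criterion_id: int
    code: str
    message: str


def validate_scheme(scheme: SamplingScheme, index: TaxonomyIndex) -> list[Finding]:
    """Resolve criterion taxa against the index and collect findings.

    Side-effect: successful resolutions are recorded on the criteria
    (``taxon_rank``, ``node``) and the scheme is flagged validated when no
    error-severity finding was produced.  Validation itself is total on
    well-formed schemes: problems come back as findings, not exceptions,
    except for ambiguous bare names which need 'rank:name' qualification.
    """
    findings: list[Finding] = []
    for crit in scheme.criteria:
        node = index.find(crit.taxon_name)  # may raise AmbiguousTaxonError
        if node is None:
            findings.append(
                Finding("error", crit.id, "unknown-taxon",
                        f"taxon {crit.taxon_name!r} not found in the taxonomy")
            )
            continue
        crit.node = node
        crit.taxon_rank = node.rank
        if RANK_DEPTH[crit.sampling_rank] <= RANK_DEPTH[node.rank]:
            findings.append(
                Finding("error", crit.id, "invalid-rank",
                        f"sampling rank {crit.sampling_rank} is not below the "
                        f"rank of {crit.taxon_name!r} ({node.rank})")
            )

    # precedence notes and full shadowing: a criterion whose every
    # sampling-rank clade lies inside the target of a more specific
    # (earlier-processed) criterion will never sample anything
    resolved = [c for c in scheme.criteria if c.node is not None and c.taxon_rank]
    order = processing_order(resolved)
    for pos, crit in enumerate(order):
        earlier = order[:pos]
        inside = [e for e in earlier if e.node is not None and e.node.is_ancestor_of(crit.node)]
        if inside:
            clades = crit.node.descendants_at_rank(crit.sampling_rank)
            covered = [
                cl for cl in clades
                if any(e.node.is_ancestor_of(cl) for e in earlier if e.node is not None)
            ]
            strictly_finer = [
                e for e in inside
                if RANK_DEPTH[e.sampling_rank] > RANK_DEPTH[crit.sampling_rank]
            ]
            code = (
                "shadowed"
                if len(covered) == len(clades) and strictly_finer
                else "precedence"
            )
            findings.append(
                Finding("note", crit.id, code,
                        f"criterion {crit.id} overlaps the target of more specific "
                        f"criteria {[e.id for e in inside]}"
                        + ("; all its clades are already covered" if code == "shadowed" else ""))
            )
        else:
            # overlap without containment of the whole target
            for e in earlier:
                if e.node is not None and crit.node.is_ancestor_of(e.node):
                    findings.append(
                        Finding("note", crit.id, "precedence",
                                f"criterion {e.id} takes precedence inside "
                                f"{e.taxon_name!r}; criterion {crit.id} skips those clades")
                    )
    scheme.validated = not any(f.severity == "error" for f in findings)
    return findings


def processing_order(criteria: list[SamplingCriterion]) -> list[SamplingCriterion]:
    """Most specific sampling rank first (species before genus ...), ties by file order."""
    return sorted(criteria, key=lambda c: (-RANK_DEPTH[c.sampling_rank], c.id))
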