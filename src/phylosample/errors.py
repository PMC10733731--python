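"""Exception hierarchy.

Validation problems (bad user input that parsed fine) and format problems
(input that could not be parsed) are kept distinct so the CLI can map them
to different exit codes.
"""


class PhylosampleError(Exception):
    """Base class for all package errors."""


class FormatError(PhylosampleError):
    """Input content is malformed (bad taxonomy string, bad Newick, ...)."""


class SchemaError(FormatError):
    """A tabular input lacks required columns or has an invalid layout."""


class NewickParseError(FormatError):
    """A Newick string could not be parsed."""


class TaxonomyError(PhylosampleError):
    """Inconsistent taxonomy data (duplicate accessions, orphan taxids, cycles)."""


class AmbiguousTaxonError(TaxonomyError):
    """A taxon name matches nodes at more than one rank; qualify as 'rank:name'."""


class ValidationError(PhylosampleError):
    """A well-formed input fails semantic validation (scheme, quotas, flags)."""


class SamplingError(PhylosampleError):
    """Sampling cannot proceed (unvalidated scheme, missing required accession)."""


class PruneError(PhylosampleError):
    """Tree pruning cannot proceed (bad target, protected set too large)."""


class PruneExhaustedError(PruneError):
    """No eligible cherry remains (all current cherries fully protected)."""


class BalanceError(PhylosampleError):
    """A balance statistic is undefined for this tree (polytomy/unary node)."""
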