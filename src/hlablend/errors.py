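"""Exception hierarchy for hlablend.

Every error raised by the library derives from :class:`HlaBlendError`, so
callers (and the CLI) can catch one base class and map it to a diagnostic.
"""


class HlaBlendError(Exception):
    """Base class for all hlablend errors."""


# --- marker / allele parsing -------------------------------------------------

class UnparseableMarker(HlaBlendError):
    """Marker ID matches no known HLA binary-marker dialect."""


class AmbiguousMarker(HlaBlendError):
    """SNP2HLA-style suffix of odd digit length cannot be split into two fields."""


# --- ingestion ---------------------------------------------------------------

class MissingProbabilityField(HlaBlendError):
    """VCF carries no per-sample genotype-probability (GP-like) FORMAT field."""


class MalformedRecord(HlaBlendError):
    """Genotype-probability triple violates its invariants beyond tolerance."""


class SchemaError(HlaBlendError):
    """Tabular input is missing required columns."""


class GeneMismatch(HlaBlendError):
    """Two alleles that must share a gene do not."""


# --- merging -----------------------------------------------------------------

class DomainError(HlaBlendError):
    """A numeric argument is outside its mathematically valid domain."""


class EmptySubset(HlaBlendError):
    """Weight rescaling requested over an empty panel subset."""


class ZeroMass(HlaBlendError):
    """Weight rescaling requested over a subset whose weights sum to zero."""


class NoCommonSamples(HlaBlendError):
    """Panels being merged share no sample IDs."""


class WeightMismatch(HlaBlendError):
    """Panel weights do not cover the panels being merged, or do not sum to 1."""


class EmptyGene(HlaBlendError):
    """A (sample, gene) group contains no genotype-pair probabilities."""


# --- calling -----------------------------------------------------------------

class NoCandidates(HlaBlendError):
    """No candidate alleles available for a call or a ranking."""


# --- evaluation --------------------------------------------------------------

class NoOverlap(HlaBlendError):
    """Truth table and calls share no (sample, gene) pair."""


class MissingFrequency(HlaBlendError):
    """A truth allele has no frequency in the supplied MAF mapping."""


# --- tuning ------------------------------------------------------------------

class TooFewSamples(HlaBlendError):
    """Fewer than two samples: a two-fold split is impossible."""


class GridEmpty(HlaBlendError):
    """The weight grid for the requested step/panel count is empty."""


# --- synthetic ---------------------------------------------------------------

class CoverageTooSmall(HlaBlendError):
    """A simulated panel's covered universe has fewer than two alleles for a gene."""
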