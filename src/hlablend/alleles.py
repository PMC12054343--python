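"""Two-field HLA allele identifiers and binary-marker name parsing.

HLA imputation engines that work through binary (presence/absence) marker
encodings name each pseudo-SNP after the allele it represents, but the
naming convention differs between toolchains:

* SNP2HLA / CookHLA style: ``HLA_A_0201`` — gene and a concatenated digit
  suffix, two digits per field.
* Michigan-server style: ``HLA_A*02:01`` — colon-separated fields.
* Canonical nomenclature: ``HLA-A*02:01``.

This module normalises all of these into :class:`AlleleId`, the package-wide
allele key. The method operates at two-field (protein-level) resolution, so
higher-resolution names are truncated to two fields.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum

from .errors import AmbiguousMarker, UnparseableMarker

logger = logging.getLogger(__name__)

#: HLA genes the package supports (classical class I and II loci).
SUPPORTED_GENES = frozenset({"A", "B", "C", "DPA1", "DPB1", "DQA1", "DQB1", "DRB1"})


class Dialect(str, Enum):
    """Marker-naming dialect of a binary HLA marker ID."""

    SNP2HLA = "snp2hla"
    MICHIGAN = "michigan"
    CANONICAL = "canonical"
    AUTO = "auto"


@dataclass(frozen=True, order=True)
class AlleleId:
    """A two-field HLA allele (gene, allele-group field, protein field).

    Ordering is lexicographic on (gene, field1, field2); this is the
    package-wide canonical order used for deterministic tie-breaking.
    """

    gene: str
    field1: int
    field2: int

    def __post_init__(self) -> None:
        if self.gene not in SUPPORTED_GENES:
            raise UnparseableMarker(f"unsupported HLA gene: {self.gene!r}")
        if self.field1 < 0 or self.field2 < 0:
            raise UnparseableMarker(
                f"negative allele field in {self.gene}*{self.field1}:{self.field2}"
            )

    def __str__(self) -> str:
        return f"HLA-{self.gene}*{self.field1:02d}:{self.field2:02d}"

    @property
    def name(self) -> str:
        """Canonical rendering, e.g. ``HLA-A*02:01``."""
        return str(self)


_GENE_PAT = "|".join(sorted(SUPPORTED_GENES, key=len, reverse=True))
_RE_SNP2HLA = re.compile(rf"^HLA_({_GENE_PAT})_(\d+)$")
# Michigan-server marker IDs use an underscore or hyphen after HLA and a star.
_RE_STARRED = re.compile(rf"^HLA[_\-]({_GENE_PAT})\*(\d+)(?::(\d+))?((?::\d+)*)[A-Z]?$")


def parse_allele_marker(marker_id: str, dialect: Dialect | str = Dialect.AUTO) -> AlleleId:
    """Parse a binary HLA marker ID into a two-field :class:`AlleleId`.

    Parameters
    ----------
    marker_id
        The marker name as it appears in the imputation output (VCF ID
        column or table header).
    dialect
        Which naming convention to assume; ``auto`` detects by pattern.

    Raises
    ------
    UnparseableMarker
        If the ID matches no dialect (e.g. an ordinary rsID), names an
        unsupported gene, or is a one-field marker with no two-field identity.
    AmbiguousMarker
        For SNP2HLA digit suffixes of odd length ≥ 3, which cannot be split
        two digits per field.
    """
    if not marker_id:
        raise UnparseableMarker("empty marker ID")
    dialect = Dialect(dialect)

    m = _RE_SNP2HLA.match(marker_id)
    if m and dialect in (Dialect.SNP2HLA, Dialect.AUTO):
        gene, digits = m.group(1), m.group(2)
        if len(digits) % 2 == 1:
            raise AmbiguousMarker(
                f"{marker_id!r}: odd-length digit suffix cannot split into two fields"
            )
        if len(digits) == 2:
            # One-field (allele-group) marker: no two-field identity exists.
            raise UnparseableMarker(f"{marker_id!r} is a one-field marker")
        if len(digits) > 4:
            logger.warning(
                "%s: suffix longer than four digits truncated to two fields", marker_id
            )
        return AlleleId(gene, int(digits[0:2]), int(digits[2:4]))

    m = _RE_STARRED.match(marker_id)
    if m and dialect in (Dialect.MICHIGAN, Dialect.CANONICAL, Dialect.AUTO):
        gene, f1, f2, extra = m.groups()
        if f2 is None:
            raise UnparseableMarker(f"{marker_id!r} is a one-field marker")
        if extra:
            logger.warning("%s: fields beyond two truncated", marker_id)
        return AlleleId(gene, int(f1), int(f2))

    raise UnparseableMarker(f"{marker_id!r} matches no HLA binary-marker dialect")


def parse_allele(text: str) -> AlleleId:
    """Parse an allele written in any accepted spelling.

    Accepts the canonical ``HLA-A*02:01``, the bare ``A*02:01`` used in
    interchange tables, and the marker dialects of
    :func:`parse_allele_marker`.
    """
    text = text.strip()
    m = re.match(rf"^(?:HLA[-_])?({_GENE_PAT})\*(\d+):(\d+)(?::\d+)*[A-Z]?$", text)
    if m:
        return AlleleId(m.group(1), int(m.group(2)), int(m.group(3)))
    return parse_allele_marker(text)


def render_snp2hla(allele: AlleleId) -> str:
    """Render an allele as a SNP2HLA-style binary marker ID."""
    return f"HLA_{allele.gene}_{allele.field1:02d}{allele.field2:02d}"


def render_michigan(allele: AlleleId) -> str:
    """Render an allele as a Michigan-server-style marker ID."""
    return f"HLA_{allele.gene}*{allele.field1:02d}:{allele.field2:02d}"
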