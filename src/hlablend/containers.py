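"""In-memory containers shared across the package.

The central object is :class:`PosteriorTable`: one imputation run's
per-sample, per-allele presence posteriors together with that run's allele
universe — the set of two-field alleles the run could possibly have imputed.
Merging operates on unions and intersections of these universes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .alleles import AlleleId
from .errors import GeneMismatch, MalformedRecord

logger = logging.getLogger(__name__)

#: Tolerance for genotype-probability triples summing to 1 (imputation
#: engines emit rounded values).
PROB_SUM_TOL = 1e-3


@dataclass(frozen=True)
class GenotypeProbRecord:
    """One sample × binary-marker genotype-probability triple.

    ``p_presence_hom`` is always the probability of carrying two copies of
    the allele the marker encodes, regardless of how the source VCF oriented
    its REF/ALT columns; readers perform the orientation flip.
    """

    sample_id: str
    allele: AlleleId
    p_presence_hom: float
    p_het: float
    p_absence_hom: float

    def __post_init__(self) -> None:
        triple = (self.p_presence_hom, self.p_het, self.p_absence_hom)
        for p in triple:
            if not -PROB_SUM_TOL <= p <= 1 + PROB_SUM_TOL:
                raise MalformedRecord(
                    f"{self.sample_id}/{self.allele}: probability {p} outside [0, 1]"
                )


@dataclass
class PosteriorTable:
    """One panel's per-sample allele-presence posteriors.

    Attributes
    ----------
    panel_id
        Opaque identifier for the imputation run / reference panel.
    allele_universe
        Every two-field allele this run can impute (its marker set).
    values
        Mapping ``(sample_id, AlleleId) -> posterior`` in [0, 1].
    sample_ids
        Ordered sample IDs.
    """

    panel_id: str
    allele_universe: frozenset[AlleleId]
    values: dict[tuple[str, AlleleId], float]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for (sample, allele), p in self.values.items():
            if allele not in self.allele_universe:
                raise ValueError(
                    f"panel {self.panel_id}: allele {allele} outside its universe"
                )
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"panel {self.panel_id}: posterior {p} for {sample}/{allele} "
                    "outside [0, 1]"
                )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(a.gene for a in self.allele_universe)

    def universe_for_gene(self, gene: str) -> frozenset[AlleleId]:
        return frozenset(a for a in self.allele_universe if a.gene == gene)

    def get(self, sample_id: str, allele: AlleleId) -> float:
        """Posterior for a (sample, allele); 0.0 when the run emitted none.

        A missing value for an allele the universe covers is absence of
        evidence from that run, not panel non-membership.
        """
        return self.values.get((sample_id, allele), 0.0)

    @classmethod
    def from_records(
        cls, panel_id: str, records: Iterable[GenotypeProbRecord]
    ) -> "PosteriorTable":
        """Build a table from genotype-probability records.

        Presence posteriors are computed as p(two copies) + p(one copy)/2,
        i.e. half the expected allele dosage.
        """
        from .merge import posterior_from_genotype_probs

        values: dict[tuple[str, AlleleId], float] = {}
        universe: set[AlleleId] = set()
        samples: list[str] = []
        seen: set[str] = set()
        for rec in records:
            universe.add(rec.allele)
            if rec.sample_id not in seen:
                seen.add(rec.sample_id)
                samples.append(rec.sample_id)
            values[(rec.sample_id, rec.allele)] = posterior_from_genotype_probs(
                rec.p_presence_hom, rec.p_het, rec.p_absence_hom
            )
        return cls(panel_id, frozenset(universe), values, tuple(samples))


@dataclass(frozen=True)
class HibagGenotypeProb:
    """Probability of an unordered allele pair for one sample, HIBAG-style."""

    sample_id: str
    gene: str
    allele1: AlleleId
    allele2: AlleleId
    probability: float

    def __post_init__(self) -> None:
        if self.allele1.gene != self.gene or self.allele2.gene != self.gene:
            raise GeneMismatch(
                f"{self.sample_id}: pair ({self.allele1}, {self.allele2}) does not "
                f"match gene {self.gene}"
            )
        if not -PROB_SUM_TOL <= self.probability <= 1 + PROB_SUM_TOL:
            raise MalformedRecord(
                f"{self.sample_id}/{self.gene}: pair probability "
                f"{self.probability} outside [0, 1]"
            )

    @property
    def sorted_pair(self) -> tuple[AlleleId, AlleleId]:
        a, b = sorted((self.allele1, self.allele2))
        return (a, b)


@dataclass(frozen=True)
class GenotypeCall:
    """A called two-field genotype for one sample × gene.

    ``allele_1 is None`` marks a no-call (all candidate posteriors were
    zero); no-calls are excluded from accuracy scoring.
    """

    sample_id: str
    gene: str
    allele_1: AlleleId | None
    allele_2: AlleleId | None
    zygosity: str  # "hom" | "het" | "nocall"
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.zygosity not in ("hom", "het", "nocall"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.p1 < self.p2 or self.p2 < 0:
            raise ValueError(f"call posteriors must satisfy p1 >= p2 >= 0, got "
                             f"({self.p1}, {self.p2})")

    @property
    def is_nocall(self) -> bool:
        return self.allele_1 is None

    @property
    def pair(self) -> tuple[AlleleId, AlleleId]:
        if self.allele_1 is None or self.allele_2 is None:
            raise ValueError("no-call record has no allele pair")
        return (self.allele_1, self.allele_2)


@dataclass
class TruthTable:
    """Gold-standard two-field genotypes: (sample, gene) → unordered pair."""

    records: dict[tuple[str, str], tuple[AlleleId, AlleleId]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for (sample, gene), (a1, a2) in self.records.items():
            if a1.gene != gene or a2.gene != gene:
                raise GeneMismatch(
                    f"{sample}/{gene}: truth pair ({a1}, {a2}) names another gene"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.items())

    @property
    def sample_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for sample, _ in self.records:
            seen.setdefault(sample)
        return tuple(seen)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.records)

    def restrict_samples(self, sample_ids: Iterable[str]) -> "TruthTable":
        keep = set(sample_ids)
        return TruthTable(
            {k: v for k, v in self.records.items() if k[0] in keep}
        )


def restrict_table(table: PosteriorTable, sample_ids: Iterable[str]) -> PosteriorTable:
    """A copy of *table* restricted to the given samples (universe unchanged)."""
    keep = set(sample_ids)
    return PosteriorTable(
        panel_id=table.panel_id,
        allele_universe=table.allele_universe,
        values={k: v for k, v in table.values.items() if k[0] in keep},
        sample_ids=tuple(s for s in table.sample_ids if s in keep),
    )
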