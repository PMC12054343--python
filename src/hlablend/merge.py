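"""Ensemble combination of allele-presence posteriors across imputation runs.

The model: each single-panel imputation run reports, per sample and per
two-field HLA allele, a genotype-probability triple for the binary
presence/absence marker of that allele. The presence posterior is

    P(presence) = P(Presence/Presence) + P(Presence/Absence) / 2,

i.e. half the expected allele dosage. Runs from different reference panels
are then combined linearly at user weights w_X (summing to 1). Because each
panel covers a different allele universe M_X, an allele present in only a
subset of panels has the weights of that subset rescaled to sum to 1:

    P_{n,m} = sum over panels X with m in M_X of  (w_X / sum_{Y: m in M_Y} w_Y) · X_{n,m}.

Alleles covered by a single panel pass through with that panel's posterior
unchanged. Merged posteriors are deliberately *not* renormalised per gene:
the downstream genotype-calling rule depends only on the ranking and the
ratio of the top two posteriors, both invariant to a common positive scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .alleles import AlleleId
from .containers import PROB_SUM_TOL, HibagGenotypeProb, PosteriorTable
from .errors import (
    DomainError,
    EmptyGene,
    EmptySubset,
    NoCommonSamples,
    WeightMismatch,
    ZeroMass,
)

logger = logging.getLogger(__name__)

WEIGHT_SUM_TOL = 1e-9


def posterior_from_genotype_probs(
    p_presence_hom: float, p_het: float, p_absence_hom: float
) -> float:
    """Posterior probability of allele presence from a genotype triple.

    Returns ``p_presence_hom + p_het / 2``, clipped to [0, 1].

    Raises
    ------
    DomainError
        If any input is outside [0, 1] beyond tolerance, or the triple does
        not sum to 1 within tolerance.
    """
    triple = (p_presence_hom, p_het, p_absence_hom)
    for p in triple:
        if not -PROB_SUM_TOL <= p <= 1 + PROB_SUM_TOL:
            raise DomainError(f"genotype probability {p} outside [0, 1]")
    total = sum(triple)
    if abs(total - 1.0) > PROB_SUM_TOL:
        raise DomainError(f"genotype probabilities sum to {total}, not 1")
    return min(1.0, max(0.0, p_presence_hom + p_het / 2.0))


@dataclass(frozen=True)
class PanelWeighting:
    """User-specified panel weights; must sum to 1.

    Weights that do not sum to 1 are rejected rather than silently rescaled,
    to keep the user's intent explicit.
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise WeightMismatch("empty weighting")
        for panel, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise WeightMismatch(f"weight {w} for panel {panel!r} outside [0, 1]")
        total = sum(self.weights.values())
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise WeightMismatch(f"weights sum to {total!r}, not 1")

    def __getitem__(self, panel_id: str) -> float:
        return self.weights[panel_id]

    @property
    def panel_ids(self) -> frozenset[str]:
        return frozenset(self.weights)

    @classmethod
    def equal(cls, panel_ids: Iterable[str]) -> "PanelWeighting":
        ids = list(panel_ids)
        return cls({p: 1.0 / len(ids) for p in ids})


def rescale_weights(weights: PanelWeighting, subset: Iterable[str]) -> PanelWeighting:
    """Rescale the weights of a panel subset to sum to 1.

    This is the partial-overlap rule: when an allele is covered by only some
    panels, each covering panel's weight becomes w_X / Σ_{Y in subset} w_Y.
    """
    subset = frozenset(subset)
    if not subset:
        raise EmptySubset("cannot rescale over an empty panel subset")
    missing = subset - weights.panel_ids
    if missing:
        raise WeightMismatch(f"panels without a weight: {sorted(missing)}")
    mass = sum(weights[p] for p in subset)
    if mass <= 0.0:
        raise ZeroMass(f"subset {sorted(subset)} carries zero total weight")
    return PanelWeighting({p: weights[p] / mass for p in subset})


@dataclass
class MergedPosteriorTable:
    """Combined posteriors over the union allele universe.

    ``provenance`` records, per allele, which panels contributed to it (the
    membership subset whose weights were rescaled).
    """

    values: dict[tuple[str, AlleleId], float]
    allele_universe: frozenset[AlleleId]
    provenance: dict[AlleleId, frozenset[str]]
    sample_ids: tuple[str, ...]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(a.gene for a in self.allele_universe)

    def gene_posteriors(self, sample_id: str, gene: str) -> dict[AlleleId, float]:
        """All posteriors of one sample for one gene (absent values are 0)."""
        return {
            a: self.values.get((sample_id, a), 0.0)
            for a in self.allele_universe
            if a.gene == gene
        }


def merge_posteriors(
    tables: Sequence[PosteriorTable],
    weights: PanelWeighting,
    *,
    union_samples: bool = False,
) -> MergedPosteriorTable:
    """Linearly combine posterior tables with partial-overlap rescaling.

    Parameters
    ----------
    tables
        One table per imputation run. Generalises to any number of panels.
    weights
        A weight per ``panel_id``; must cover every table and sum to 1.
    union_samples
        By default the merge operates on the intersection of the panels'
        sample sets. With ``union_samples=True`` every sample appearing in
        any panel is merged, rescaling weights per sample over the panels
        that actually contain it (the same rule as per-allele rescaling).

    Raises
    ------
    WeightMismatch
        If some table's panel has no weight.
    NoCommonSamples
        If the intersection of sample sets is empty (default mode).
    """
    if not tables:
        raise WeightMismatch("no tables to merge")
    ids = [t.panel_id for t in tables]
    if len(set(ids)) != len(ids):
        raise WeightMismatch(f"duplicate panel_ids among tables: {ids}")
    missing = set(ids) - weights.panel_ids
    if missing:
        raise WeightMismatch(f"tables without a weight: {sorted(missing)}")

    if union_samples:
        samples: list[str] = []
        seen: set[str] = set()
        for t in tables:
            for s in t.sample_ids:
                if s not in seen:
                    seen.add(s)
                    samples.append(s)
    else:
        common = set(tables[0].sample_ids)
        for t in tables[1:]:
            common &= set(t.sample_ids)
        if not common:
            raise NoCommonSamples("panels share no samples")
        samples = [s for s in tables[0].sample_ids if s in common]

    by_panel = {t.panel_id: t for t in tables}
    union_universe: frozenset[AlleleId] = frozenset().union(
        *(t.allele_universe for t in tables)
    )
    membership = {
        m: frozenset(pid for pid, t in by_panel.items() if m in t.allele_universe)
        for m in union_universe
    }

    sample_sets = {pid: set(t.sample_ids) for pid, t in by_panel.items()}
    values: dict[tuple[str, AlleleId], float] = {}
    for m in union_universe:
        panels_m = membership[m]
        scaled = rescale_weights(weights, panels_m)
        for n in samples:
            if union_samples:
                present = frozenset(p for p in panels_m if n in sample_sets[p])
                if not present:
                    continue
                w_n = rescale_weights(weights, present)
                values[(n, m)] = sum(
                    w_n[p] * by_panel[p].get(n, m) for p in present
                )
            else:
                values[(n, m)] = sum(
                    scaled[p] * by_panel[p].get(n, m) for p in panels_m
                )

    return MergedPosteriorTable(
        values=values,
        allele_universe=union_universe,
        provenance=membership,
        sample_ids=tuple(samples),
    )


def hibag_to_posteriors(
    records: Iterable[HibagGenotypeProb], panel_id: str = "hibag"
) -> PosteriorTable:
    """Convert genotype-pair probabilities into presence posteriors.

    Attribute-bagging imputation reports a probability per unordered allele
    *pair* rather than per allele. For each allele a, S(a) sums the
    probabilities of all pairs containing a (a homozygous pair counts once,
    with its full probability). Pair-based output concentrates the top two
    S(a) near 1 for heterozygotes as well as homozygotes, whereas the
    triple-based posterior convention puts heterozygous alleles near 0.5 —
    so the sums are rescaled before merging: with S1 ≥ S2 the two largest
    sums for a (sample, gene), if S1 > 2·S2 the genotype is classified
    homozygous and all S(a) pass through unchanged; if S1 < 2·S2 it is
    classified heterozygous and all S(a) are halved. The boundary
    S1 = 2·S2 is treated as homozygous, mirroring the "≥" of the calling
    rule. Outputs are clipped to [0, 1].
    """
    groups: dict[tuple[str, str], dict[tuple[AlleleId, AlleleId], float]] = {}
    order: list[str] = []
    seen_samples: set[str] = set()
    for rec in records:
        key = (rec.sample_id, rec.gene)
        pairs = groups.setdefault(key, {})
        pair = rec.sorted_pair
        if pair in pairs:
            logger.debug(
                "duplicate pair %s for %s/%s collapsed", pair, rec.sample_id, rec.gene
            )
        pairs[pair] = rec.probability
        if rec.sample_id not in seen_samples:
            seen_samples.add(rec.sample_id)
            order.append(rec.sample_id)

    values: dict[tuple[str, AlleleId], float] = {}
    universe: set[AlleleId] = set()
    for (sample, gene), pairs in groups.items():
        if not pairs:
            raise EmptyGene(f"{sample}/{gene}: no genotype pairs")
        sums: dict[AlleleId, float] = {}
        for (a1, a2), p in pairs.items():
            sums[a1] = sums.get(a1, 0.0) + p
            if a2 != a1:
                sums[a2] = sums.get(a2, 0.0) + p
        ranked = sorted(sums.values(), reverse=True)
        s1 = ranked[0]
        s2 = ranked[1] if len(ranked) > 1 else 0.0
        halve = s1 < 2.0 * s2  # boundary s1 == 2*s2 -> homozygous, unchanged
        for allele, s in sums.items():
            post = s / 2.0 if halve else s
            values[(sample, allele)] = min(1.0, max(0.0, post))
            universe.add(allele)

    return PosteriorTable(
        panel_id=panel_id,
        allele_universe=frozenset(universe),
        values=values,
        sample_ids=tuple(order),
    )
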