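"""Accuracy statistics for two-field HLA genotype calls.

The headline statistic scores each called pair against the truth pair in
whichever of the two orientations matches best:

    accuracy = (1 / 2N) · Σ_n max( I(X1=Y1)+I(X2=Y2), I(X1=Y2)+I(X2=Y1) )

so each (sample, gene) contributes 0, 0.5 or 1. Supporting analyses:
per-gene error rates and their variance (a stability measure), minor
allele frequency (MAF) computation pooled across target sets, accuracy
stratified into MAF bins at nominal two-field resolution, and allelic
coverage (how many alleles each panel — and their union — can impute).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alleles import AlleleId
from .containers import GenotypeCall, PosteriorTable, TruthTable
from .errors import GeneMismatch, MissingFrequency, NoOverlap

logger = logging.getLogger(__name__)

Pair = tuple[AlleleId, AlleleId]


def _orientation_score(truth_pair, called_pair) -> float:
    x1, x2 = truth_pair
    y1, y2 = called_pair
    straight = int(x1 == y1) + int(x2 == y2)
    crossed = int(x1 == y2) + int(x2 == y1)
    return max(straight, crossed) / 2.0


def pair_accuracy(truth_pair: Pair, called_pair: Pair) -> float:
    """Best-orientation concordance of two unordered allele pairs: 0, 0.5 or 1."""
    genes = {a.gene for a in (*truth_pair, *called_pair)}
    if len(genes) != 1:
        raise GeneMismatch(f"pairs span genes {sorted(genes)}")
    return _orientation_score(truth_pair, called_pair)


def best_orientation(truth_pair: Pair, called_pair: Pair) -> tuple[Pair, Pair]:
    """The called pair re-ordered into its best-scoring orientation.

    Returns (truth_pair, oriented_call) such that slot i of the call is the
    counterpart of truth slot i under the orientation that maximises the
    concordance score; ties keep the straight orientation.
    """
    x1, x2 = truth_pair
    y1, y2 = called_pair
    straight = int(x1 == y1) + int(x2 == y2)
    crossed = int(x1 == y2) + int(x2 == y1)
    if crossed > straight:
        return truth_pair, (y2, y1)
    return truth_pair, (y1, y2)


@dataclass
class AccuracyReport:
    """Per-gene and overall accuracy, with per-gene error-rate variance.

    ``overall`` is the unweighted mean of per-gene accuracies;
    ``error_variance`` is the unbiased sample variance over genes of the
    percentage error rates 100·(1 − accuracy); NaN with fewer than two
    genes.
    """

    per_gene: dict[str, float]
    overall: float
    n_pairs: dict[str, int]
    error_variance: float
    excluded: int = 0

    def error_rates(self) -> dict[str, float]:
        """Per-gene error rates as percentages."""
        return {g: 100.0 * (1.0 - a) for g, a in self.per_gene.items()}


def _map_pair(pair: Pair, group_map: Mapping[AlleleId, object] | None):
    if group_map is None:
        return pair
    return tuple(group_map.get(a, a) for a in pair)


def accuracy(
    truth: TruthTable,
    calls: Iterable[GenotypeCall],
    exclusions: set[AlleleId] | None = None,
    group_map: Mapping[AlleleId, object] | None = None,
) -> AccuracyReport:
    """Score calls against truth, per gene and overall.

    Parameters
    ----------
    truth
        Gold-standard genotypes.
    calls
        Called genotypes; no-calls are excluded (and counted).
    exclusions
        Alleles to drop: any (sample, gene) whose truth or called pair
        contains one is removed from both numerator and denominator
        (deprecated-name handling).
    group_map
        Optional mapping collapsing alleles to functional groups (P-group
        mode); applied to both pairs before comparison. Alleles missing
        from the map keep their own identity.

    Raises
    ------
    NoOverlap
        If no (sample, gene) is shared between truth and calls.
    """
    exclusions = exclusions or set()
    per_gene_scores: dict[str, list[float]] = {}
    excluded = 0
    overlap = 0
    for call in calls:
        key = (call.sample_id, call.gene)
        if key not in truth.records:
            continue
        overlap += 1
        if call.is_nocall:
            excluded += 1
            continue
        truth_pair = truth.records[key]
        called_pair = call.pair
        if exclusions & set(truth_pair + called_pair):
            excluded += 1
            continue
        score = _orientation_score(
            _map_pair(truth_pair, group_map), _map_pair(called_pair, group_map)
        )
        per_gene_scores.setdefault(call.gene, []).append(score)
    if overlap == 0:
        raise NoOverlap("truth and calls share no (sample, gene)")
    if excluded:
        logger.info("excluded %d (sample, gene) pairs from scoring", excluded)

    per_gene = {g: sum(s) / len(s) for g, s in per_gene_scores.items()}
    n_pairs = {g: len(s) for g, s in per_gene_scores.items()}
    overall = sum(per_gene.values()) / len(per_gene) if per_gene else math.nan
    errors = [100.0 * (1.0 - a) for a in per_gene.values()]
    if len(errors) >= 2:
        mean_e = sum(errors) / len(errors)
        error_variance = sum((e - mean_e) ** 2 for e in errors) / (len(errors) - 1)
    else:
        error_variance = math.nan
    return AccuracyReport(per_gene, overall, n_pairs, error_variance, excluded)


def compute_maf(truths: Sequence[TruthTable]) -> dict[AlleleId, float]:
    """Allele frequencies pooled across target truth sets.

    Each allele's frequency is its chromosome count divided by 2 × the
    number of individuals typed for its gene, summed over only the data
    sets in which the allele appears at least once — data sets where a
    panel simply lacks the allele do not dilute its frequency.
    """
    # per data set: allele -> chromosome count; gene -> individuals typed
    counts: list[dict[AlleleId, int]] = []
    gene_n: list[dict[str, int]] = []
    for truth in truths:
        c: dict[AlleleId, int] = {}
        g: dict[str, int] = {}
        for (_, gene), (a1, a2) in truth:
            c[a1] = c.get(a1, 0) + 1
            c[a2] = c.get(a2, 0) + 1
            g[gene] = g.get(gene, 0) + 1
        counts.append(c)
        gene_n.append(g)

    all_alleles = set().union(*counts) if counts else set()
    freqs: dict[AlleleId, float] = {}
    for allele in all_alleles:
        num = 0
        den = 0
        for c, g in zip(counts, gene_n):
            if allele in c:
                num += c[allele]
                den += 2 * g.get(allele.gene, 0)
        freqs[allele] = num / den
    return freqs


def minor_frequency(freq: float) -> float:
    """Fold a frequency into the minor range [0, 0.5]."""
    return min(freq, 1.0 - freq)


@dataclass(frozen=True)
class MafBinSpec:
    """Five half-open MAF bins over [0, 0.5] from ascending interior edges.

    Default edges 0.01, 0.05, 0.10, 0.25 give the bins
    [0, 0.01), [0.01, 0.05), [0.05, 0.10), [0.10, 0.25), [0.25, 0.5].
    """

    edges: tuple[float, ...] = (0.01, 0.05, 0.10, 0.25)

    def __post_init__(self) -> None:
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("bin edges must be strictly ascending")
        if self.edges and (self.edges[0] <= 0 or self.edges[-1] > 0.5):
            raise ValueError("bin edges must lie in (0, 0.5]")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def bin_index(self, maf: float) -> int:
        for i, edge in enumerate(self.edges):
            if maf < edge:
                return i
        return len(self.edges)

    def labels(self) -> list[str]:
        bounds = (0.0, *self.edges, 0.5)
        out = []
        for i in range(self.n_bins):
            lo, hi = bounds[i], bounds[i + 1]
            out.append(f"[{lo:g},{hi:g})" if i < self.n_bins - 1 else f"[{lo:g},{hi:g}]")
        return out


def binned_accuracy(
    truth: TruthTable,
    calls: Iterable[GenotypeCall],
    maf: Mapping[AlleleId, float],
    bins: MafBinSpec = MafBinSpec(),
) -> dict[str, float]:
    """Proportion of correctly imputed allele slots per MAF bin.

    For each (sample, gene) the called pair is fixed in its best-scoring
    orientation; each true allele slot then contributes 1 to its allele's
    bin if its called counterpart equals it at nominal two-field
    resolution, else 0. Empty bins are reported as NaN, not 0.

    Raises
    ------
    MissingFrequency
        If a truth allele has no entry in *maf*.
    """
    correct = [0] * bins.n_bins
    total = [0] * bins.n_bins
    for call in calls:
        key = (call.sample_id, call.gene)
        if key not in truth.records or call.is_nocall:
            continue
        truth_pair, oriented = best_orientation(truth.records[key], call.pair)
        for t_allele, c_allele in zip(truth_pair, oriented):
            if t_allele not in maf:
                raise MissingFrequency(f"no frequency for truth allele {t_allele}")
            idx = bins.bin_index(minor_frequency(maf[t_allele]))
            total[idx] += 1
            correct[idx] += int(t_allele == c_allele)
    labels = bins.labels()
    return {
        labels[i]: (correct[i] / total[i] if total[i] else math.nan)
        for i in range(bins.n_bins)
    }


@dataclass
class CoverageReport:
    """Allele counts per gene: the merged union and each panel alone."""

    union_per_gene: dict[str, int]
    panel_per_gene: dict[str, dict[str, int]]  # panel_id -> gene -> count

    @property
    def union_total(self) -> int:
        return sum(self.union_per_gene.values())

    def panel_total(self, panel_id: str) -> int:
        return sum(self.panel_per_gene[panel_id].values())


def allele_coverage(panels: Sequence[PosteriorTable]) -> CoverageReport:
    """Count alleles covered per gene by each panel and by their union."""
    genes = sorted(set().union(*(p.genes for p in panels))) if panels else []
    union_per_gene = {
        g: len(set().union(*(p.universe_for_gene(g) for p in panels))) for g in genes
    }
    panel_per_gene = {
        p.panel_id: {g: len(p.universe_for_gene(g)) for g in genes} for p in panels
    }
    return CoverageReport(union_per_gene, panel_per_gene)
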