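"""Two-field genotype calling from combined presence posteriors.

The rule: per sample and gene, rank the combined posteriors; with m1 the
top allele (posterior P1) and m2 the runner-up (P2), call the homozygote
(m1, m1) when P1 ≥ 2·P2 and the heterozygote (m1, m2) otherwise. The
intuition is dosage: a presence posterior near 1 means two copies of m1,
near 0.5 means one copy each of m1 and m2.

Both the ranking and the ratio P1/P2 are invariant to scaling all of a
gene's posteriors by a positive constant, so calls do not depend on whether
the merged posteriors were normalised.
"""

from __future__ import annotations

import logging

from .alleles import AlleleId
from .containers import GenotypeCall
from .errors import NoCandidates
from .merge import MergedPosteriorTable

logger = logging.getLogger(__name__)


def call_gene(
    sample_id: str, gene: str, posteriors: dict[AlleleId, float]
) -> GenotypeCall:
    """Call one sample × gene from its candidate-allele posteriors.

    Ties (equal posteriors) are broken by canonical allele order, smallest
    first, so calls are deterministic. A gene with a single candidate allele
    is called homozygous for it — the only consistent reading of the rule
    when no runner-up exists. All-zero posteriors yield a no-call record.

    Raises
    ------
    NoCandidates
        If the posterior mapping is empty.
    """
    if not posteriors:
        raise NoCandidates(f"{sample_id}/{gene}: no candidate alleles")
    for a, p in posteriors.items():
        if p < 0:
            raise ValueError(f"{sample_id}/{gene}: negative posterior {p} for {a}")

    ranked = sorted(posteriors.items(), key=lambda kv: (-kv[1], kv[0]))
    m1, p1 = ranked[0]
    if p1 == 0.0:
        logger.warning("%s/%s: all posteriors zero, emitting no-call", sample_id, gene)
        return GenotypeCall(sample_id, gene, None, None, "nocall", 0.0, 0.0)
    if len(ranked) == 1:
        logger.info(
            "%s/%s: single candidate %s, calling homozygous", sample_id, gene, m1
        )
        return GenotypeCall(sample_id, gene, m1, m1, "hom", p1, 0.0)

    m2, p2 = ranked[1]
    if p1 >= 2.0 * p2:
        return GenotypeCall(sample_id, gene, m1, m1, "hom", p1, p2)
    return GenotypeCall(sample_id, gene, m1, m2, "het", p1, p2)


def call_all(merged: MergedPosteriorTable) -> list[GenotypeCall]:
    """Call every (sample, gene) present in a merged table.

    Returns exactly one call per sample × gene, ordered by sample then gene;
    deterministic given the input.
    """
    if not merged.allele_universe:
        raise NoCandidates("merged table has an empty allele universe")
    genes = sorted(merged.genes)
    calls: list[GenotypeCall] = []
    for sample in merged.sample_ids:
        for gene in genes:
            calls.append(call_gene(sample, gene, merged.gene_posteriors(sample, gene)))
    return calls
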