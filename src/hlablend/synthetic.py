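"""Synthetic truth genotypes and multi-panel imputation outputs.

The generator emulates the situation the ensemble method targets: a target
cohort whose true two-field HLA genotypes are known, imputed by several
single-panel runs that differ in allele coverage (each reference panel can
only impute the alleles it has seen) and in error rate (a proxy for panel
size and ethnic match). Per gene, allele frequencies are drawn from a
symmetric Dirichlet — small concentrations give the skewed frequency
spectra typical of HLA loci — and genotypes follow Hardy–Weinberg
proportions.

Each simulated panel emits, per sample and gene, a presence-posterior
vector over its covered alleles: a Dirichlet draw concentrated on the true
genotype (mass 1 on the allele for homozygotes, 0.5/0.5 for
heterozygotes), with sharpness κ controlling how peaked the output is.
Errors enter two ways: with probability ε one true allele is swapped for a
frequency-weighted "confuser" before concentrating (common alleles confuse
more — the mechanism behind real-world misidentification of alleles that
are rare in the reference but common in the target), and any true allele
outside the panel's universe is always swapped (coverage-driven
irreducible error).

Randomness is organised as one stream per operation derived from
(seed, operation name, panel_id), so adding a panel never perturbs draws
made for the truth or for other panels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .alleles import AlleleId
from .containers import HibagGenotypeProb, PosteriorTable, TruthTable
from .errors import CoverageTooSmall

#: Baseline Dirichlet concentration added to every covered allele, so no
#: posterior is exactly zero and ties break stochastically.
BASE_ALPHA = 0.05

DEFAULT_GENES = ("A", "B", "C", "DQB1", "DRB1")


@dataclass(frozen=True)
class PanelSpec:
    """One simulated imputation run.

    error_rate ε: probability of swapping one true allele per (sample, gene);
    coverage_fraction: share of the gene's alleles in the panel's universe;
    sharpness κ: Dirichlet concentration of emitted posteriors.
    """

    panel_id: str
    error_rate: float = 0.1
    coverage_fraction: float = 1.0
    sharpness: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 1]")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError(
                f"coverage_fraction {self.coverage_fraction} outside (0, 1]"
            )
        if self.sharpness <= 0:
            raise ValueError(f"sharpness {self.sharpness} must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic data set."""

    n_samples: int = 500
    genes: tuple[str, ...] = DEFAULT_GENES
    n_alleles_per_gene: int = 12
    dirichlet_alpha: float = 0.5
    panel_specs: tuple[PanelSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_alleles_per_gene < 2:
            raise ValueError("n_alleles_per_gene must be >= 2")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")


@dataclass
class SimOutput:
    """Everything one simulation run produced."""

    truth: TruthTable
    panels: list[PosteriorTable]
    frequencies: dict[str, dict[AlleleId, float]]
    hibag_like: list[HibagGenotypeProb] = dc_field(default_factory=list)


def _rng(seed: int, *tokens: str) -> np.random.Generator:
    """Independent generator keyed on (seed, tokens)."""
    keys = [seed] + [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(keys))


def _gene_alleles(gene: str, n: int) -> list[AlleleId]:
    # unique (field1, field2) pairs: 3 protein variants per allele group
    return [AlleleId(gene, 1 + i // 3, 1 + i % 3) for i in range(n)]


def _sample_ids(n: int) -> tuple[str, ...]:
    return tuple(f"S{i:04d}" for i in range(n))


def simulate_truth(
    config: SimConfig,
) -> tuple[TruthTable, dict[str, dict[AlleleId, float]]]:
    """Draw allele frequencies and Hardy–Weinberg truth genotypes.

    Per gene, frequencies ~ symmetric Dirichlet(alpha); each individual's
    two alleles are drawn independently from them. Deterministic given the
    config seed.
    """
    samples = _sample_ids(config.n_samples)
    records: dict[tuple[str, str], tuple[AlleleId, AlleleId]] = {}
    frequencies: dict[str, dict[AlleleId, float]] = {}
    for gene in config.genes:
        rng = _rng(config.seed, "truth", gene)
        alleles = _gene_alleles(gene, config.n_alleles_per_gene)
        freqs = rng.dirichlet(
            np.full(config.n_alleles_per_gene, config.dirichlet_alpha)
        )
        frequencies[gene] = dict(zip(alleles, freqs.tolist()))
        draws = rng.choice(
            config.n_alleles_per_gene, size=(config.n_samples, 2), p=freqs
        )
        for i, sample in enumerate(samples):
            a1, a2 = sorted((alleles[draws[i, 0]], alleles[draws[i, 1]]))
            records[(sample, gene)] = (a1, a2)
    return TruthTable(records), frequencies


def _covered_universe(
    rng: np.random.Generator, alleles: list[AlleleId], freqs: np.ndarray, frac: float
) -> list[int]:
    """Indices of a random coverage subset, always including the top allele."""
    n = len(alleles)
    k = max(1, round(frac * n))
    if k < 2:
        raise CoverageTooSmall(
            f"coverage {frac} of {n} alleles leaves fewer than 2 covered"
        )
    top = int(np.argmax(freqs))
    rest = [i for i in range(n) if i != top]
    chosen = rng.choice(len(rest), size=k - 1, replace=False)
    return sorted([top] + [rest[i] for i in chosen])


def _corrupt_pair(
    rng: np.random.Generator,
    pair: tuple[int, int],
    covered: list[int],
    cov_freqs: np.ndarray,
    error_rate: float,
) -> tuple[int, int]:
    """Apply coverage replacement and the ε error swap to a truth pair."""
    covered_set = set(covered)
    p_conf = cov_freqs / cov_freqs.sum()

    def confuser(not_this: int) -> int:
        while True:
            c = covered[rng.choice(len(covered), p=p_conf)]
            if c != not_this:
                return c

    a1, a2 = pair
    if a1 not in covered_set:
        a1 = confuser(a1)
    if a2 not in covered_set:
        a2 = confuser(a2)
    if error_rate > 0 and rng.random() < error_rate:
        if rng.random() < 0.5:
            a1 = confuser(a1)
        else:
            a2 = confuser(a2)
    return a1, a2


def simulate_panel(
    truth: TruthTable,
    frequencies: dict[str, dict[AlleleId, float]],
    spec: PanelSpec,
    seed: int,
) -> PosteriorTable:
    """Emit one run's presence posteriors for every sample × covered allele.

    Posterior vectors sum to 1 over the covered alleles of each gene
    (Dirichlet normalisation), concentrated on the — possibly corrupted —
    truth with concentration κ.
    """
    samples = truth.sample_ids
    values: dict[tuple[str, AlleleId], float] = {}
    universe: set[AlleleId] = set()
    for gene in sorted(truth.genes):
        rng = _rng(seed, "panel", spec.panel_id, gene)
        alleles = list(frequencies[gene])
        freqs = np.array([frequencies[gene][a] for a in alleles])
        covered = _covered_universe(rng, alleles, freqs, spec.coverage_fraction)
        cov_freqs = freqs[covered]
        universe.update(alleles[i] for i in covered)
        idx_of = {a: i for i, a in enumerate(alleles)}
        pos_of = {g: j for j, g in enumerate(covered)}

        alpha = np.full((len(samples), len(covered)), BASE_ALPHA)
        for row, sample in enumerate(samples):
            if (sample, gene) not in truth.records:
                continue
            t1, t2 = truth.records[(sample, gene)]
            e1, e2 = _corrupt_pair(
                rng, (idx_of[t1], idx_of[t2]), covered, cov_freqs, spec.error_rate
            )
            alpha[row, pos_of[e1]] += spec.sharpness * 0.5
            alpha[row, pos_of[e2]] += spec.sharpness * 0.5

        gammas = rng.standard_gamma(alpha)
        posts = gammas / gammas.sum(axis=1, keepdims=True)
        for row, sample in enumerate(samples):
            for j, g in enumerate(covered):
                values[(sample, alleles[g])] = float(posts[row, j])

    return PosteriorTable(
        panel_id=spec.panel_id,
        allele_universe=frozenset(universe),
        values=values,
        sample_ids=samples,
    )


def simulate_hibag_like(
    truth: TruthTable,
    frequencies: dict[str, dict[AlleleId, float]],
    spec: PanelSpec,
    seed: int,
    n_decoy_pairs: int = 3,
) -> list[HibagGenotypeProb]:
    """Emit genotype-pair probabilities in the attribute-bagging style.

    Per (sample, gene) the probability mass concentrates on a single pair
    (the possibly-corrupted truth), so the per-allele sums S(a) sit near 1
    for heterozygotes as well as homozygotes — the pattern the pair-table
    adapter's halving branch exists to correct. Pair probabilities sum to 1
    per (sample, gene).
    """
    records: list[HibagGenotypeProb] = []
    for gene in sorted(truth.genes):
        rng = _rng(seed, "hibag", spec.panel_id, gene)
        alleles = list(frequencies[gene])
        freqs = np.array([frequencies[gene][a] for a in alleles])
        covered = _covered_universe(rng, alleles, freqs, spec.coverage_fraction)
        cov_freqs = freqs[covered]
        idx_of = {a: i for i, a in enumerate(alleles)}
        for sample in truth.sample_ids:
            if (sample, gene) not in truth.records:
                continue
            t1, t2 = truth.records[(sample, gene)]
            e1, e2 = _corrupt_pair(
                rng, (idx_of[t1], idx_of[t2]), covered, cov_freqs, spec.error_rate
            )
            top_pair = tuple(sorted((e1, e2)))
            pairs = {top_pair}
            while len(pairs) < 1 + n_decoy_pairs:
                d = rng.choice(len(covered), size=2, p=cov_freqs / cov_freqs.sum())
                pairs.add(tuple(sorted((covered[d[0]], covered[d[1]]))))
            ordered = sorted(pairs)
            alpha = np.array(
                [
                    BASE_ALPHA + (spec.sharpness if p == top_pair else 0.0)
                    for p in ordered
                ]
            )
            gammas = rng.standard_gamma(alpha)
            probs = gammas / gammas.sum()
            for (i1, i2), p in zip(ordered, probs):
                records.append(
                    HibagGenotypeProb(
                        sample, gene, alleles[i1], alleles[i2], float(p)
                    )
                )
    return records


def simulate(config: SimConfig, with_hibag: bool = False) -> SimOutput:
    """Full simulation: truth, one posterior table per panel spec, frequencies."""
    truth, frequencies = simulate_truth(config)
    panels = [
        simulate_panel(truth, frequencies, spec, config.seed)
        for spec in config.panel_specs
    ]
    hibag: list[HibagGenotypeProb] = []
    if with_hibag:
        for spec in config.panel_specs:
            hibag.extend(
                simulate_hibag_like(truth, frequencies, spec, config.seed)
            )
    return SimOutput(truth, panels, frequencies, hibag)
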