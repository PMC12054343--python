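import numpy as np
import pytest

from hlablend import AlleleId, PanelWeighting, PosteriorTable, TruthTable


def A(gene: str, f1: int, f2: int = 1) -> AlleleId:
    return AlleleId(gene, f1, f2)


@pytest.fixture
def small_alleles():
    return [A("A", 1), A("A", 2), A("A", 3), A("A", 4)]


@pytest.fixture
def two_panel_tables(small_alleles):
    """Two tiny panels sharing alleles a1, a2; a3 only in X, a4 only in Y."""
    a1, a2, a3, a4 = small_alleles
    x = PosteriorTable(
        "X",
        frozenset({a1, a2, a3}),
        {("s1", a1): 0.9, ("s1", a2): 0.05, ("s1", a3): 0.05,
         ("s2", a1): 0.5, ("s2", a2): 0.5, ("s2", a3): 0.0},
        ("s1", "s2"),
    )
    y = PosteriorTable(
        "Y",
        frozenset({a1, a2, a4}),
        {("s1", a1): 0.7, ("s1", a2): 0.1, ("s1", a4): 0.2,
         ("s2", a1): 0.4, ("s2", a2): 0.33, ("s2", a4): 0.27},
        ("s1", "s2"),
    )
    return x, y


def random_instance(rng, max_panels=4, max_alleles=6, max_samples=5):
    """A random multi-panel merge instance for oracle comparisons."""
    n_panels = rng.integers(1, max_panels + 1)
    n_alleles = rng.integers(2, max_alleles + 1)
    n_samples = rng.integers(1, max_samples + 1)
    alleles = [A("B", i + 1) for i in range(n_alleles)]
    samples = [f"s{i}" for i in range(n_samples)]
    tables = []
    for p in range(n_panels):
        # every allele has >= 1 covering panel: panel 0 covers all
        if p == 0:
            covered = list(alleles)
        else:
            mask = rng.random(n_alleles) < 0.6
            covered = [a for a, m in zip(alleles, mask) if m] or [alleles[0]]
        values = {}
        for s in samples:
            for a in covered:
                if rng.random() < 0.9:  # some covered values deliberately missing
                    values[(s, a)] = float(rng.random())
        tables.append(
            PosteriorTable(f"p{p}", frozenset(covered), values, tuple(samples))
        )
    raw = rng.random(n_panels) + 0.05
    weights = PanelWeighting(
        {f"p{p}": float(w) for p, w in enumerate(raw / raw.sum())}
    )
    return tables, weights, alleles, samples


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_truth(pairs):
    """TruthTable from {(sample, gene): (AlleleId, AlleleId)}."""
    return TruthTable({k: tuple(sorted(v)) for k, v in pairs.items()})
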