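"""Two-fold cross-validation for panel selection and weight tuning.

With no independent validation cohort, the target set is split into two
equal halves. One half serves as the validation set — ranking candidate
panels by accuracy, or grid-searching merge weights — for the other half,
and the roles are then swapped. Agreement between the two directions is
the robustness check: a panel ranking or weight vector chosen identically
from both halves is unlikely to be an overfitting artefact.

The weight grid enumerates all compositions of 1 in multiples of the step
(default 0.1) with every component at least one step, so no panel is ever
fully zeroed during tuning. Sample-size-based weighting schemes
(proportional, square-root, logarithmic) are provided as alternatives to
grid search when per-panel accuracies are unknown a priori.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calling import call_all
from .containers import PosteriorTable, TruthTable, restrict_table
from .errors import DomainError, GridEmpty, NoCandidates, TooFewSamples
from .evaluation import accuracy
from .merge import PanelWeighting, merge_posteriors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CvSplit:
    """A seeded, balanced two-fold partition of the sample IDs."""

    fold_a: frozenset[str]
    fold_b: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.fold_a & self.fold_b:
            raise ValueError("folds overlap")
        if abs(len(self.fold_a) - len(self.fold_b)) > 1:
            raise ValueError("folds are unbalanced")

    @property
    def all_samples(self) -> frozenset[str]:
        return self.fold_a | self.fold_b


def split_two_fold(sample_ids: Sequence[str], seed: int) -> CvSplit:
    """Randomly split samples into two (near-)equal folds, reproducibly."""
    ids = list(sample_ids)
    if len(ids) < 2:
        raise TooFewSamples(f"need at least 2 samples, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    half = (len(ids) + 1) // 2
    fold_a = frozenset(ids[i] for i in perm[:half])
    fold_b = frozenset(ids[i] for i in perm[half:])
    return CvSplit(fold_a, fold_b, seed)


def _score_panel(
    table: PosteriorTable, truth: TruthTable, fold: frozenset[str]
) -> float:
    sub = restrict_table(table, fold)
    merged = merge_posteriors([sub], PanelWeighting({table.panel_id: 1.0}))
    calls = call_all(merged)
    return accuracy(truth.restrict_samples(fold), calls).overall


@dataclass
class PanelSelection:
    """Per-direction candidate ranking with the cross-direction agreement flag."""

    ranking_a: list[str]  # ranked on fold_a as validation set
    ranking_b: list[str]
    top_k_a: list[str]
    top_k_b: list[str]
    accuracies_a: dict[str, float]
    accuracies_b: dict[str, float]

    @property
    def consistent(self) -> bool:
        """Whether both validation directions select the same panel set."""
        return set(self.top_k_a) == set(self.top_k_b)


def select_top_panels(
    candidates: Mapping[str, PosteriorTable],
    truth: TruthTable,
    split: CvSplit,
    k: int = 2,
) -> PanelSelection:
    """Rank candidate panels by validation-fold accuracy, both directions.

    Each fold in turn acts as the validation set: candidates are scored by
    single-panel call accuracy on that fold, and the top k are selected for
    use on the other fold. Ranking ties break on panel_id for determinism.
    """
    if not candidates:
        raise NoCandidates("no candidate panels")
    if k > len(candidates):
        raise NoCandidates(f"k={k} exceeds {len(candidates)} candidates")

    def direction(fold: frozenset[str]) -> tuple[list[str], dict[str, float]]:
        accs = {
            pid: _score_panel(tab, truth, fold)
            for pid, tab in sorted(candidates.items())
        }
        ranking = sorted(accs, key=lambda pid: (-accs[pid], pid))
        return ranking, accs

    ranking_a, accs_a = direction(split.fold_a)
    ranking_b, accs_b = direction(split.fold_b)
    sel = PanelSelection(
        ranking_a, ranking_b, ranking_a[:k], ranking_b[:k], accs_a, accs_b
    )
    if not sel.consistent:
        logger.warning(
            "validation directions disagree: %s vs %s", sel.top_k_a, sel.top_k_b
        )
    return sel


def weight_grid(n_panels: int, step: float = 0.1) -> list[tuple[float, ...]]:
    """All weight vectors summing to 1 in multiples of *step*, each ≥ step.

    For k panels and step s this enumerates C(1/s − 1, k − 1) compositions.
    """
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9 or units < 2:
        raise GridEmpty(f"step {step} does not divide 1 into >=2 parts")
    if n_panels > units:
        raise GridEmpty(f"{n_panels} panels cannot each receive >= {step}")
    grid: list[tuple[float, ...]] = []
    # compositions of `units` into n_panels positive parts via cut points
    for cuts in combinations(range(1, units), n_panels - 1):
        bounds = (0, *cuts, units)
        grid.append(
            tuple((bounds[i + 1] - bounds[i]) * step for i in range(n_panels))
        )
    return grid


@dataclass
class WeightGridResult:
    """Grid-search outcome per fold direction.

    ``grid_a``/``grid_b`` hold every (weight vector, validation accuracy);
    ``chosen_a``/``chosen_b`` are the per-direction argmax vectors (ties
    broken toward the most uniform vector). When the directions disagree,
    both are reported along with the accuracy gap — they are never
    averaged.
    """

    panel_ids: tuple[str, ...]
    grid_a: list[tuple[tuple[float, ...], float]]
    grid_b: list[tuple[tuple[float, ...], float]]
    chosen_a: tuple[float, ...]
    chosen_b: tuple[float, ...]
    step: float

    @property
    def consistent(self) -> bool:
        return self.chosen_a == self.chosen_b

    @property
    def accuracy_gap(self) -> float:
        """Absolute gap between the two directions' best validation accuracies."""
        best_a = max(acc for _, acc in self.grid_a)
        best_b = max(acc for _, acc in self.grid_b)
        return abs(best_a - best_b)

    def weighting(self, direction: str = "a") -> PanelWeighting:
        vec = self.chosen_a if direction == "a" else self.chosen_b
        return PanelWeighting(dict(zip(self.panel_ids, vec)))


def _uniformity(vec: tuple[float, ...]) -> float:
    mean = sum(vec) / len(vec)
    return sum((w - mean) ** 2 for w in vec)


def grid_search_weights(
    tables: Sequence[PosteriorTable],
    truth: TruthTable,
    split: CvSplit,
    step: float = 0.1,
) -> WeightGridResult:
    """Exhaustive weight search over the step grid, one argmax per direction.

    For each fold direction and each candidate vector: merge the panels on
    the validation fold, call genotypes, and score best-orientation
    accuracy against truth. Ties break toward the most uniform vector, then
    lexicographically, so results are deterministic.
    """
    if len(tables) < 2:
        raise GridEmpty("grid search needs at least two panels")
    panel_ids = tuple(t.panel_id for t in tables)
    grid = weight_grid(len(tables), step)

    def direction(fold: frozenset[str]) -> list[tuple[tuple[float, ...], float]]:
        subs = [restrict_table(t, fold) for t in tables]
        fold_truth = truth.restrict_samples(fold)
        out = []
        for vec in grid:
            weighting = PanelWeighting(dict(zip(panel_ids, vec)))
            calls = call_all(merge_posteriors(subs, weighting))
            out.append((vec, accuracy(fold_truth, calls).overall))
        return out

    grid_a = direction(split.fold_a)
    grid_b = direction(split.fold_b)

    def argmax(entries: list[tuple[tuple[float, ...], float]]) -> tuple[float, ...]:
        best_acc = max(acc for _, acc in entries)
        tied = [vec for vec, acc in entries if acc >= best_acc - 1e-12]
        return min(tied, key=lambda v: (_uniformity(v), v))

    chosen_a, chosen_b = argmax(grid_a), argmax(grid_b)
    result = WeightGridResult(panel_ids, grid_a, grid_b, chosen_a, chosen_b, step)
    if not result.consistent:
        logger.warning(
            "fold directions disagree on weights: %s vs %s (accuracy gap %.4f)",
            chosen_a,
            chosen_b,
            result.accuracy_gap,
        )
    return result


def size_based_weights(
    sample_sizes: Mapping[str, int], scheme: str = "proportional"
) -> PanelWeighting:
    """Panel weights from reference-panel sample sizes.

    Schemes: ``proportional`` (w ∝ N), ``sqrt`` (w ∝ √N), ``log``
    (w ∝ ln N, requiring every N ≥ 2 so no panel gets zero mass).
    """
    if not sample_sizes:
        raise DomainError("no sample sizes given")
    for pid, n in sample_sizes.items():
        if n < 1:
            raise DomainError(f"panel {pid!r}: sample size {n} < 1")
    if scheme == "proportional":
        raw = {p: float(n) for p, n in sample_sizes.items()}
    elif scheme == "sqrt":
        raw = {p: math.sqrt(n) for p, n in sample_sizes.items()}
    elif scheme == "log":
        bad = [p for p, n in sample_sizes.items() if n < 2]
        if bad:
            raise DomainError(
                f"log scheme undefined for size-1 panels (zero mass): {sorted(bad)}"
            )
        raw = {p: math.log(n) for p, n in sample_sizes.items()}
    else:
        raise DomainError(f"unknown weighting scheme {scheme!r}")
    total = sum(raw.values())
    return PanelWeighting({p: v / total for p, v in raw.items()})
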