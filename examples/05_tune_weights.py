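"""Choose merge weights by two-fold cross-validated grid search.

One panel is simulated much more accurate (5% error) than the other (30%).
The cohort is split in half; each half in turn grid-searches the weights
(step 0.1) that maximise call accuracy on itself, for use on the other
half. Agreement between the two directions is the overfitting check.
Size-based weighting schemes are shown for comparison.
"""

from hlablend import (
    PanelSpec,
    SimConfig,
    grid_search_weights,
    simulate,
    size_based_weights,
    split_two_fold,
)

config = SimConfig(
    n_samples=300,
    seed=3,
    panel_specs=(
        PanelSpec("good", error_rate=0.05, coverage_fraction=1.0, sharpness=30.0),
        PanelSpec("bad", error_rate=0.30, coverage_fraction=1.0, sharpness=30.0),
    ),
)
sim = simulate(config)
split = split_two_fold(sim.truth.sample_ids, seed=3)
result = grid_search_weights(sim.panels, sim.truth, split, step=0.1)

print(f"panels: {result.panel_ids}")
print(f"chosen weights, direction a: {result.chosen_a}")
print(f"chosen weights, direction b: {result.chosen_b}")
print("directions agree" if result.consistent
      else f"directions disagree (accuracy gap {result.accuracy_gap:.4f})")
# The grid search shifts most of the weight onto the low-error panel.

sizes = {"big": 9773, "small": 504}
for scheme in ("proportional", "sqrt", "log"):
    w = size_based_weights(sizes, scheme)
    rendered = ", ".join(f"{p}={v:.3f}" for p, v in w.weights.items())
    print(f"{scheme} weights for panel sizes {sizes}: {rendered}")
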