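"""Merge allele-presence posteriors from two imputation runs.

Two runs, from reference panels with different allele universes, report
presence posteriors for one sample. Merging combines shared alleles at the
given weights and passes panel-exclusive alleles through unchanged, after
rescaling the weights of whichever panels cover each allele.
"""

from hlablend import (
    AlleleId,
    PanelWeighting,
    PosteriorTable,
    merge_posteriors,
    posterior_from_genotype_probs,
)

# A genotype-probability triple (presence-hom, het, absence-hom) becomes a
# presence posterior: P = p_hom + p_het / 2.
p = posterior_from_genotype_probs(0.68, 0.32, 0.00)
print(f"presence posterior of (0.68, 0.32, 0.00): {p:.2f}")

a0201 = AlleleId("A", 2, 1)   # HLA-A*02:01
a0101 = AlleleId("A", 1, 1)   # HLA-A*01:01
a2402 = AlleleId("A", 24, 2)  # HLA-A*24:02 — only panel Q covers it

panel_p = PosteriorTable(
    "P", frozenset({a0201, a0101}),
    {("s1", a0201): 0.84, ("s1", a0101): 0.10},
    ("s1",),
)
panel_q = PosteriorTable(
    "Q", frozenset({a0201, a0101, a2402}),
    {("s1", a0201): 0.60, ("s1", a0101): 0.05, ("s1", a2402): 0.33},
    ("s1",),
)

merged = merge_posteriors([panel_p, panel_q], PanelWeighting({"P": 0.5, "Q": 0.5}))
for allele in sorted(merged.allele_universe):
    panels = ",".join(sorted(merged.provenance[allele]))
    print(f"{allele}: merged posterior {merged.values[('s1', allele)]:.3f} "
          f"(from panels {panels})")

# HLA-A*02:01 sits in both panels: 0.5*0.84 + 0.5*0.60 = 0.72.
# HLA-A*24:02 sits only in Q: its weight rescales to 1 and 0.33 passes through.
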