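"""Adapt genotype-pair probabilities (HIBAG-style) into presence posteriors.

Pair-based imputation reports one probability per unordered allele pair.
Per allele the probabilities of all pairs containing it are summed; because
this convention puts heterozygous alleles near 1 instead of 0.5, the sums
are halved whenever the top sum is less than twice the runner-up
(heterozygous pattern) and left unchanged otherwise.
"""

from hlablend import AlleleId, HibagGenotypeProb, hibag_to_posteriors

x = AlleleId("A", 1, 1)
y = AlleleId("A", 2, 1)
z = AlleleId("A", 3, 1)

# A confident homozygote: S(x) = 0.9 + 0.08 = 0.98 > 2 * S(y) = 0.20
hom_pairs = [
    HibagGenotypeProb("s1", "A", x, x, 0.90),
    HibagGenotypeProb("s1", "A", x, y, 0.08),
    HibagGenotypeProb("s1", "A", y, z, 0.02),
]
table = hibag_to_posteriors(hom_pairs)
print("homozygous pattern, sums unchanged:")
for a in (x, y, z):
    print(f"  {a}: {table.get('s1', a):.3f}")

# A certain heterozygote: S(x) = S(y) = 1.0, halved to the 0.5 convention
het_pairs = [HibagGenotypeProb("s2", "A", x, y, 1.0)]
table = hibag_to_posteriors(het_pairs)
print("heterozygous pattern, sums halved:")
for a in (x, y):
    print(f"  {a}: {table.get('s2', a):.3f}")
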