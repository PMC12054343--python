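"""Call two-field genotypes from combined posteriors.

The rule: with P1 the top posterior and P2 the runner-up, call the
homozygote when P1 >= 2*P2 (a posterior near 1 means two copies), the
heterozygote otherwise (two posteriors near 0.5 mean one copy each).
"""

from hlablend import AlleleId, call_gene

a0103 = AlleleId("A", 1, 3)
a0202 = AlleleId("A", 2, 2)

hom = call_gene("s1", "A", {a0103: 0.8, a0202: 0.2})
print(f"posteriors 0.8 vs 0.2 -> {hom.zygosity}: ({hom.allele_1}, {hom.allele_2})")

het = call_gene("s1", "A", {a0103: 0.8, a0202: 0.5})
print(f"posteriors 0.8 vs 0.5 -> {het.zygosity}: ({het.allele_1}, {het.allele_2})")

# 0.8 >= 2*0.2, so the first call is homozygous A*01:03; 0.8 < 2*0.5, so the
# second is heterozygous A*01:03 / A*02:02.
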