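"""Genotype probabilities, EAC and GPI on a hand-built pedigree.

A horned sire is certainly AA under the canonical penetrance start, so
his unphenotyped offspring carry at least one A allele: the peeled
probabilities, the expected allele count (EAC, the posterior mean
number of A copies) and the genotype probability index (GPI, 0 =
Hardy-Weinberg prior, 100 = certainty) all reflect that.
"""

from seggwas import (HORN_START, Individual, Pedigree, PhenotypeTable,
                     SegregationModel, compute_eac, compute_gpi,
                     peel_genotype_probabilities)

ped = Pedigree([
    Individual("sire", sex="male"),
    Individual("dam1", sex="female"),
    Individual("dam2", sex="female"),
    Individual("kid1", "sire", "dam1"),
    Individual("kid2", "sire", "dam2"),
])
phen = PhenotypeTable({"sire": 2, "dam1": 0})  # horned sire, polled dam

model = SegregationModel(q=0.4, penetrance=HORN_START)
probs = peel_genotype_probabilities(ped, phen, model)
eac = compute_eac(probs)
gpi = compute_gpi(probs, model.q)

print(f"{'id':6s} {'p(aa)':>7s} {'p(het)':>7s} {'p(AA)':>7s} {'EAC':>6s} {'GPI':>6s}")
for i, ident in enumerate(probs.ids):
    u = probs.unordered[i]
    print(f"{ident:6s} {u[0]:7.3f} {u[1]:7.3f} {u[2]:7.3f} "
          f"{eac[i]:6.3f} {gpi[i]:6.1f}")

print("\nThe horned sire is certain AA (EAC 2, GPI 100); each kid gets one")
print("A from him for sure, so kid EACs exceed 1 even without phenotypes.")
print("kid1's dam is polled (mostly aa, at worst a carrier), so kid1 is")
print("most likely a heterozygote; the unphenotyped dam2 sits at the")
print("Hardy-Weinberg prior (GPI 0).")
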