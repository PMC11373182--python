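"""How incomplete penetrance erodes the EAC-causal correlation.

Replays the gene-drop protocol for three generating penetrance
matrices of decreasing penetrance on one fixed synthetic pedigree and
prints the mean (SE) EAC-causal correlation and mean GPI across ten
replicates -- the maximum association any SNP could achieve under each
scenario.
"""

from seggwas import HORN_START, SCENARIO_PENETRANCE, SegregationModel
from seggwas.simulate import (PedigreeDesign, SimConfig, run_scenario,
                              synthesize_pedigree)

ped = synthesize_pedigree(PedigreeDesign(
    generations=3, sires_per_generation=8, dams_per_sire=10,
    offspring_per_dam=4, seed=11))
init = SegregationModel(0.5, HORN_START.soften(0.01))
print(f"pedigree of {len(ped)} animals, all phenotyped; 10 replicates each\n")
print(f"{'scenario':>8s} {'corr(EAC,causal)':>18s} {'mean GPI':>14s}")
for sc in (1, 2, 3):
    cfg = SimConfig(replicates=10, seed=100 + sc,
                    causal_rule="maf_at_least", causal_maf_min=0.4)
    summary = run_scenario(ped, SCENARIO_PENETRANCE[sc], cfg, init=init)
    (cm, cs), (gm, gs) = summary.corr_mean_se, summary.gpi_mean_se
    print(f"{sc:>8d} {cm:>11.3f} ({cs:.3f}) {gm:>8.2f} ({gs:.2f})")

print("\nComplete penetrance (scenario 1) pins every genotype: correlation 1,")
print("GPI 100. As off-diagonal penetrance mass grows, phenotypes identify")
print("genotypes less well and both numbers fall; mean GPI/100 tracks the")
print("correlation because EAC is the posterior-mean allele count.")
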