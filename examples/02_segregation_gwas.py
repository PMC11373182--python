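"""Segregation GWAS versus a binary-trait GWAS on simulated data.

Simulates a half-sib pedigree with a single causal locus under
moderately incomplete penetrance (scenario 2), fits the segregation
model by EM (penetrance + allele frequency, no genotype data), then
regresses the resulting EAC on every simulated SNP and compares the
causal SNP's signal with a horned/non-horned logistic GWAS.
"""

import numpy as np
import pandas as pd

from seggwas import (GenotypeMatrix, HORN_START, SCENARIO_PENETRANCE,
                     SegregationModel, binary_gwas, eac_gwas,
                     eac_snp_correlation, top_snp)
from seggwas.simulate import PedigreeDesign, SimConfig, run_replicate, \
    synthesize_pedigree

ped = synthesize_pedigree(PedigreeDesign(
    generations=3, sires_per_generation=8, dams_per_sire=8,
    offspring_per_dam=4, seed=2))
cfg = SimConfig(n_candidate_snps=300, seed=3,
                causal_rule="maf_at_least", causal_maf_min=0.4)
rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
init = SegregationModel(0.5, HORN_START.soften(0.01))

fit, truth, causal_idx, causal_maf, phen = run_replicate(
    ped, SCENARIO_PENETRANCE[2], cfg, rng, init=init)
print(f"pedigree: {len(ped)} animals; causal SNP index {causal_idx} "
      f"(MAF {causal_maf:.2f}); EM converged in {fit.n_em_iterations} iterations")
print(f"fitted q = {fit.model.q:.3f}; population mean GPI = {fit.gpi.mean():.1f}")

gm = GenotypeMatrix(truth.ids, truth.counts.astype(float))
assoc = eac_gwas(pd.Series(fit.eac, index=fit.ids), gm)
best = top_snp(assoc)
causal_row = assoc.iloc[causal_idx]
print(f"\nEAC GWAS: top SNP {best['snp']} -log10p={best['neglog10p']:.1f} "
      f"R2={best['r2']:.2f}")
print(f"causal SNP -log10p={causal_row['neglog10p']:.1f}")

y = pd.Series({i: 0.0 if phen.get(i) == 2 else 1.0 for i in truth.ids})
logistic = binary_gwas(y, gm)
print(f"binary (horned/non-horned) GWAS at causal SNP: "
      f"-log10p={logistic['neglog10p'][causal_idx]:.1f}")

r = eac_snp_correlation(fit.eac, truth.counts[:, causal_idx])
print(f"\ncorr(EAC, causal allele count) = {r:.3f} -- the maximum any")
print("marker in full LD with the mutation could reach at this penetrance;")
print("the EAC signal dwarfs the binary-trait signal because EAC is")
print("additive and pools information across the three phenotype classes.")
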