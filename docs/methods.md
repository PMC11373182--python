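# Methods

## Model

A single biallelic autosomal QTL with alleles `a` and `A`. Founders
draw *ordered* genotypes (paternal allele first: aa, aA, Aa, AA) from
Hardy–Weinberg proportions at frequency `q` of `A`; every non-founder
receives one allele from each parent by fair Mendelian sampling.  A
categorical phenotype `y ∈ {0..K−1}` (default horn-status coding
0 = polled, 1 = scurs/knobs, 2 = horned) is emitted with probability
`pen[y, class(g)]`, where `class` collapses ordered genotypes to the
unordered classes 0/1/2.  Each genotype column of the K×3 penetrance
matrix is a probability distribution over phenotype classes; incomplete
penetrance is off-diagonal mass.  A missing phenotype contributes a
likelihood factor of 1, so unphenotyped ancestors still conduct
relationship information.  Ordered genotypes are used internally
because they keep transmission exact with no inbreeding approximations;
all reporting collapses to the three classes.

Assumptions: one locus, two alleles, autosomal, no use of marker data
inside the segregation step (the EAC is computed *before* any genotype
file is read, which is what makes the subsequent GWAS a clean test of
association), no sex-specific penetrance within one likelihood — sex
effects are handled by masking the other sex's phenotypes and fitting
separately, with a pooled fit as the comparison.

## Genotype probabilities

`PeelingEngine` decomposes the pedigree into nuclear families
(sire, dam, full sibs).  A sweep updates, in family topological order,
every individual's *anterior* distribution (parents, their other
families, and full sibs) and then, in reverse order, the *posterior
message* each family sends to its two parents; posteriors are
`anterior × penetrance × Π(messages)`, renormalized.  Individuals with
exactly one recorded parent get a phantom founder mate (equivalent to
marginalizing over an unrelated population animal); parents named but
never listed become phantom founders.

Loop handling was decided by measurement.  On loop-free pedigrees the
message fixed point equals the exact marginals (verified to ~1e−13
against exhaustive enumeration).  Marriage-graph loops (mated relatives)
bias the fixed point: converged errors around 1e−2 on half-sib matings
with several joint offspring — an inherent property of iterating these
updates, not a convergence failure.  The engine therefore runs exact
greedy variable elimination (smallest-neighbourhood-first, intermediate
factors renormalized, width capped at 4^12 entries) whenever the
pedigree is loopy and has at most 64 individuals, and falls back to
fixed-point iteration (tol 1e−8 on the max posterior change, 200 sweeps,
no damping — oscillation has not been observed) for large or too-dense
pedigrees.  Large simulated pedigrees take the iterative path, which is
the standard scalable approximation in this field.

Contradictions (an observed phenotype with zero likelihood under every
genotype reachable in the pedigree) raise an error naming the
individual rather than returning a zero distribution.

`brute_force_probabilities` / `brute_force_loglikelihood` enumerate all
4^n configurations (n ≤ 12) and exist purely as an independent oracle;
the test suite compares peeling against them on 200 random pedigrees.

## EM estimation

E-step: peeling under the current model (messages warm-started between
iterations).  M-step:

- `pen[k, g] = Σ_{i: y_i=k} p_i(g) / Σ_{i phenotyped} p_i(g)` — the
  exact EM update given marginal posteriors; a column with total
  posterior weight < 1e−8 keeps its previous values;
- `q = mean founder EAC / 2`, clamped to [1e−6, 1−1e−6] — founders
  only, since `q` is a base-population parameter; re-estimated every
  iteration.

Convergence: max absolute change over all penetrance entries and `q`
below 1e−5, cap 500 iterations; non-convergence is flagged, not fatal.
With the exact E-step the observed-data log-likelihood is
non-decreasing, which the tests verify by enumeration on small
pedigrees.

Exact zeros in the penetrance matrix are *absorbing* under this M-step
(a zero entry can never regain mass), and the method deliberately does
not floor entries — fitted matrices legitimately contain exact zeros.
The flip side is that zeros in a *starting* matrix both lock entries
and can render plausible data impossible (with horned ⇒ certainly AA,
two horned parents cannot have a polled offspring, which incompletely
penetrant data will produce).  Scenario runs therefore default to the
canonical starting matrix blended 1% toward a uniform column
(`PenetranceMatrix.soften(0.01)`), preserving its orientation — which
allele is "A" is fixed by the start's asymmetry, never relabeled —
while keeping every phenotype–genotype pair admissible at
initialization.

## EAC and GPI

EAC is the posterior mean allele count.  GPI is defined here as

    GPI_i = 100 · sqrt(max(0, 1 − Var_i / 2q(1−q)))

with `Var_i` the posterior allele-count variance.  This satisfies every
property the index is used for: 0–100 range, 100 iff the distribution
is a point mass, 0 at the Hardy–Weinberg prior, and mean GPI/100
approximately equal to the EAC–truth correlation (law of total
variance: `corr(EAC, g) = sqrt(Var(EAC)/Var(g))`; measured 91.4 vs
0.911 and 62.6 vs 0.664 on scenario runs).  An entropy-ratio variant
was evaluated and rejected: it meets the endpoints but understates the
correlation badly (77 vs 0.91).  The exact historical index formula is
not public; this definition is isolated behind `compute_gpi` and
documented as substitutable.  Distributions more dispersed than the
prior clamp to 0; the zero endpoint is exact only to sqrt-of-rounding
(~1e−6 on the 0–100 scale).

## GWAS

QC removes SNPs with MAF < 0.01, Hardy–Weinberg goodness-of-fit
χ² > 600, call rate < 0.90, or non-autosomal chromosome codes, with a
per-rule report.  The EAC GWAS is closed-form single-SNP OLS with an
intercept, vectorized across SNPs with pairwise deletion of missing
genotypes; it is validated against statsmodels in the unit tests.
Two-sided p-values come from the t log-survival-function, switching to
the stable tail asymptotic `sf(t) ≈ pdf(t)·t/df` where the incomplete
beta underflows, so −log10 p stays finite and meaningful far beyond
the float-min ceiling of 321.  Residual sums of squares are floored at
`1e−24·Var(y)` so a perfectly predictive SNP reports a large finite
statistic instead of dividing by zero.  No covariates are fitted by
default (a hook exists in the design via pre-residualized EAC);
Bonferroni thresholds are drawn on plots only, never used to filter.

The comparison GWAS is per-SNP logistic regression (statsmodels, lbfgs,
100 iterations) on horned/non-horned or polled/non-polled binarizations,
with 1-df likelihood-ratio p-values — the LRT degrades gracefully under
the near-separation this kind of trait produces, where Wald collapses.
Separation is flagged (diverging slope, failed convergence, or
per-observation log-likelihood above −1e−3) and the capped LRT still
reported.  `top_snp` breaks −log10 p ties by |beta|, then genome order.
`adjust_eac_for_top_snp` residualizes EAC on the top SNP (re-centred at
the original mean; missing top-SNP genotypes contribute no correction)
for secondary-peak scans.

Allele-count orientation follows the input file (PLINK A1 or the TSV
column); slopes flip sign with orientation.

## Simulator

Defaults follow the standard protocol: founding population 100, 100
generations of pure-drift Wright–Fisher burn-in, 1000 candidate
unlinked biallelic SNPs of which 50% are singletons (one heterozygous
founder copy), ten replicates.  Non-singleton loci start at a frequency
drawn uniform(0.05, 0.95) — no mutation model is simulated, so loci
fixing during burn-in are redrawn (up to 1000 rounds, then marked
non-segregating).  Pedigree founders sample genotypes binomially from
the post-burn-in frequency, i.e. with replacement from the burned-in
population.  Gene drop phases founder heterozygotes uniformly once and
samples transmissions independently per locus; loci are mutually
independent, which also makes replicates independent.  Everything is
deterministic given the seed (replicates use spawned seed sequences).

The causal locus is drawn uniformly among segregating loci by default;
a `maf_at_least` rule exists because rare causal variants leave the
penetrance model unidentifiable (a singleton carrier is one data point)
and because reported protocols average causal MAF ≈ 0.5.  Desk-scale
scenario runs here use `maf_at_least 0.4`.  Phenotypes are drawn from
the penetrance column of each animal's causal genotype class; by
default all pedigree members are phenotyped, with `phenotyped_ids`
masking available to emulate terminal-generation recording.

`synthesize_pedigree` builds the multi-generation half-sib stand-in for
a real flock pedigree: each generation mates S sires × D dams each ×
O offspring, retains a fraction of offspring as next-generation parents
(random sexes) and tops up shortfalls with fresh founders.  Later
generations therefore mate relatives, giving the loop structure real
pedigrees have.

## Problem sizes used in the checks

Scenario-1 exactness and the reported mean GPI use a ~530-animal
pedigree with ten replicates; scenario ordering uses ~2,000 animals ×
ten replicates × three scenarios; penetrance recovery uses ~5,000
animals; oracle equivalence uses 200 random pedigrees of ≤ 10
individuals (120 loop-free, 80 looped); null calibration uses 10,000
independent SNPs.  These sizes make the whole suite run in about a
minute while leaving each check comfortably powered.

## Known limitations

- Single-locus, biallelic, autosomal only; no X-linkage, no multi-locus
  segregation, no modifier loci in the inference model (the simulator
  could emulate them, the fitted model cannot).
- Large loopy pedigrees use the iterative approximation; its error on
  dense loops is O(1e−2) in genotype probability, which propagates into
  EAC but washes out of rank-based GWAS results in practice.
- The simulator omits linkage, recombination maps, selection and
  genotyping error, and its half-sib designs are more regular than real
  flock pedigrees: passing scenario checks says the *method* behaves as
  designed under its own assumptions, not that real data meet them.
- EM finds a local optimum; with weakly informative data (rare causal
  allele, few phenotypes) label-permuted or boundary solutions exist.
  The canonical asymmetric start anchors orientation, and the stability
  test demonstrates start-independence only in well-identified settings.
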