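"""Gene-drop simulation of unlinked SNPs through a pedigree.

The protocol mirrors the classical forward-in-time SNP simulators used
in animal breeding: candidate biallelic loci acquire founder
frequencies from a Wright-Fisher burn-in (pure drift, loci fixed during
burn-in are redrawn), a configurable fraction of loci are instead
seeded as singletons (one heterozygous founder), founder alleles are
dropped through the pedigree by Mendelian sampling, one segregating
locus is picked as the causative mutation, and phenotypes are assigned
from a penetrance matrix conditional on the causal genotype.  Running
the segregation analysis on the result measures the maximum correlation
between the expected allele count (EAC) and the causal allele count
achievable under a given degree of penetrance.

All loci are mutually independent (no linkage), which also makes
replicates independent.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .pedigree import FEMALE, MALE, Individual, Pedigree, pedigree_summary
from .penetrance import HORN_START, PenetranceMatrix
from .phenotypes import PhenotypeTable
from .segregation import (FittedSegregation, SegregationModel,
                          fit_segregation_model)


class SimulationError(ValueError):
    """Invalid simulation configuration or state."""


@dataclass(frozen=True)
class SimConfig:
    """Gene-drop protocol parameters.

    Defaults follow the standard protocol: a founding population of
    100, a 100-generation drift burn-in, 1000 candidate SNPs of which
    half are singletons, ten replicates.
    """

    founders_n: int = 100
    burnin_generations: int = 100
    n_candidate_snps: int = 1000
    singleton_fraction: float = 0.5
    replicates: int = 10
    seed: int | None = None
    causal_rule: str = "any_segregating"   # or "maf_at_least"
    causal_maf_min: float = 0.0
    init_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.founders_n <= 0 or self.n_candidate_snps <= 0:
            raise SimulationError("counts must be positive")
        if self.replicates <= 0:
            raise SimulationError("replicates must be positive")
        if not (0.0 <= self.singleton_fraction <= 1.0):
            raise SimulationError("singleton_fraction must lie in [0, 1]")
        if self.burnin_generations < 0:
            raise SimulationError("burn-in length cannot be negative")
        if self.causal_rule not in ("any_segregating", "maf_at_least"):
            raise SimulationError(f"unknown causal rule {self.causal_rule!r}")


@dataclass(frozen=True)
class PedigreeDesign:
    """Multi-generation half-sib mating design.

    Each generation mates ``sires_per_generation`` sires to
    ``dams_per_sire`` dams each, every dam producing
    ``offspring_per_dam`` offspring.  A fraction of offspring is
    retained as the next generation's parents (sexes at random);
    shortfalls are topped up with fresh founders, which keeps the
    design feasible and mimics introduced animals.
    """

    generations: int = 3
    sires_per_generation: int = 10
    dams_per_sire: int = 10
    offspring_per_dam: int = 2
    replacement_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.generations, self.sires_per_generation,
               self.dams_per_sire, self.offspring_per_dam) <= 0:
            raise SimulationError("design counts must be positive")
        if not (0.0 < self.replacement_fraction <= 1.0):
            raise SimulationError("replacement_fraction must lie in (0, 1]")


@dataclass
class TrueGenotypes:
    """Simulated phased genotypes for every individual and locus."""

    ids: list[str]
    paternal: np.ndarray        # (n, L) 0/1 allele copies
    maternal: np.ndarray
    is_singleton: np.ndarray    # (L,) bool

    @property
    def counts(self) -> np.ndarray:
        return (self.paternal + self.maternal).astype(np.int64)

    @property
    def n_loci(self) -> int:
        return self.paternal.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.counts.mean(axis=0) / 2.0


def simulate_founder_snps(cfg: SimConfig, n_founders: int | None = None,
                          rng: np.random.Generator | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Founder allele counts per candidate locus.

    Non-singleton loci start at a uniform frequency and drift through a
    Wright-Fisher burn-in of ``cfg.burnin_generations`` generations in
    a population of ``cfg.founders_n`` diploids; loci fixed during the
    burn-in are redrawn.  Founder genotypes are then sampled from the
    post-burn-in frequency.  Singleton loci place a single heterozygous
    copy in one random founder.  Returns ``(counts, is_singleton)``
    with ``counts`` of shape (n_founders, L).
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_founders is None:
        n_founders = cfg.founders_n
    L = cfg.n_candidate_snps
    n_single = int(round(cfg.singleton_fraction * L))
    n_drift = L - n_single
    two_n = 2 * cfg.founders_n

    lo, hi = cfg.init_freq_range
    freqs = np.empty(n_drift)
    pending = np.arange(n_drift)
    attempts = 0
    while pending.size and attempts < 1000:
        attempts += 1
        p = rng.uniform(lo, hi, size=pending.size)
        for _ in range(cfg.burnin_generations):
            p = rng.binomial(two_n, p) / two_n
        seg = (p > 0) & (p < 1)
        freqs[pending[seg]] = p[seg]
        pending = pending[~seg]
    if pending.size:  # give up redrawing: mark as non-segregating
        freqs[pending] = 0.0

    counts = np.zeros((n_founders, L), dtype=np.int8)
    counts[:, :n_drift] = rng.binomial(2, freqs, size=(n_founders, n_drift))
    is_singleton = np.zeros(L, dtype=bool)
    is_singleton[n_drift:] = True
    carriers = rng.integers(0, n_founders, size=n_single)
    counts[carriers, np.arange(n_drift, L)] = 1
    return counts, is_singleton


def gene_drop(ped: Pedigree, founder_counts: np.ndarray,
              rng: np.random.Generator | int | None = None,
              is_singleton: np.ndarray | None = None) -> TrueGenotypes:
    """Drop founder alleles through the pedigree by Mendelian sampling.

    ``founder_counts`` has one row per pedigree founder (ordered as
    ``ped.founders``).  Unphased founder counts of 1 are phased
    uniformly at random once.  Each non-founder inherits one allele
    from each parent, drawn uniformly and independently per locus.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    founders = ped.founders
    founder_counts = np.asarray(founder_counts)
    if founder_counts.shape[0] != len(founders):
        raise SimulationError(
            f"founder genotypes cover {founder_counts.shape[0]} rows but the "
            f"pedigree has {len(founders)} founders")
    L = founder_counts.shape[1]
    ids = ped.ids
    pos = {ident: i for i, ident in enumerate(ids)}
    pat = np.zeros((len(ids), L), dtype=np.int8)
    mat = np.zeros((len(ids), L), dtype=np.int8)
    for row, ident in enumerate(founders):
        c = founder_counts[row]
        i = pos[ident]
        pat[i] = c // 2          # 0 for counts 0/1, 1 for count 2
        mat[i] = c - pat[i]
        het = c == 1
        flip = het & (rng.random(L) < 0.5)
        pat[i, flip], mat[i, flip] = 1, 0
    for ident in ped.topological_order():
        ind = ped[ident]
        if ind.sire is None:
            continue
        i, s, d = pos[ident], pos[ind.sire], pos[ind.dam]
        take_mat = rng.random(L) < 0.5
        pat[i] = np.where(take_mat, mat[s], pat[s])
        take_mat = rng.random(L) < 0.5
        mat[i] = np.where(take_mat, mat[d], pat[d])
    if is_singleton is None:
        is_singleton = np.zeros(L, dtype=bool)
    return TrueGenotypes(list(ids), pat, mat, np.asarray(is_singleton, dtype=bool))


def choose_causal_snp(tg: TrueGenotypes, rule: str = "any_segregating",
                      maf_min: float = 0.0,
                      rng: np.random.Generator | int | None = None
                      ) -> tuple[int, float]:
    """Pick the causative locus uniformly among qualifying loci.

    Returns ``(locus_index, causal_maf)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freq = tg.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    if rule == "any_segregating":
        ok = (freq > 0) & (freq < 1)
    elif rule == "maf_at_least":
        ok = maf >= maf_min
    else:
        raise SimulationError(f"unknown causal rule {rule!r}")
    candidates = np.flatnonzero(ok)
    if candidates.size == 0:
        raise SimulationError("no locus qualifies as causative mutation")
    locus = int(rng.choice(candidates))
    return locus, float(maf[locus])


def assign_phenotypes(ids: Sequence[str], causal_counts: np.ndarray,
                      pen: PenetranceMatrix,
                      rng: np.random.Generator | int | None = None
                      ) -> PhenotypeTable:
    """Draw each phenotype from the penetrance column of the causal genotype."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = np.asarray(causal_counts, dtype=np.int64)
    cdf = np.cumsum(pen.entries, axis=0)   # (K, 3)
    u = rng.random(len(counts))
    classes = (u[:, None] > cdf.T[counts]).sum(axis=1)
    classes = np.minimum(classes, pen.n_classes - 1)  # float-rounding guard
    return PhenotypeTable(dict(zip(ids, classes.tolist())), pen.labels)


def synthesize_pedigree(design: PedigreeDesign) -> Pedigree:
    """Build a multi-generation half-sib pedigree from the design.

    Deterministic given ``design.seed``.  Use
    :func:`seggwas.pedigree.pedigree_summary` to compare the realized
    animal/sire/dam counts against a target population.
    """
    rng = np.random.default_rng(design.seed)
    inds: list[Individual] = []
    counter = 0

    def founder(sex: str) -> str:
        nonlocal counter
        ident = f"F{counter:05d}"
        counter += 1
        inds.append(Individual(ident, None, None, sex))
        return ident

    n_s = design.sires_per_generation
    n_d = n_s * design.dams_per_sire
    sires = [founder(MALE) for _ in range(n_s)]
    dams = [founder(FEMALE) for _ in range(n_d)]
    for gen in range(1, design.generations + 1):
        males: list[str] = []
        females: list[str] = []
        k = 0
        for si, sire in enumerate(sires):
            for dj in range(design.dams_per_sire):
                dam = dams[si * design.dams_per_sire + dj]
                for _ in range(design.offspring_per_dam):
                    sex = MALE if rng.random() < 0.5 else FEMALE
                    ident = f"G{gen}I{k:05d}"
                    k += 1
                    inds.append(Individual(ident, sire, dam, sex))
                    (males if sex == MALE else females).append(ident)
        if gen == design.generations:
            break
        keep_m = rng.permutation(males)[:max(1, int(design.replacement_fraction * len(males)))]
        keep_f = rng.permutation(females)[:max(1, int(design.replacement_fraction * len(females)))]
        sires = list(keep_m[:n_s]) + [founder(MALE) for _ in range(max(0, n_s - keep_m.size))]
        dams = list(keep_f[:n_d]) + [founder(FEMALE) for _ in range(max(0, n_d - keep_f.size))]
    return Pedigree(inds)


# --------------------------------------------------------------------------
# scenario runner
# --------------------------------------------------------------------------

@dataclass
class ReplicateResult:
    replicate: int
    corr_eac_causal: float = math.nan
    mean_gpi: float = math.nan
    causal_index: int = -1
    causal_maf: float = math.nan
    q_hat: float = math.nan
    em_converged: bool = False
    error: str | None = None


@dataclass
class ReplicateSummary:
    """Per-replicate EAC-causal correlations and mean GPI, with SEs."""

    results: list[ReplicateResult] = field(default_factory=list)
    last_replicate_data: dict | None = None

    @property
    def ok(self) -> list[ReplicateResult]:
        return [r for r in self.results if r.error is None]

    @property
    def failures(self) -> list[ReplicateResult]:
        return [r for r in self.results if r.error is not None]

    def _stats(self, values: list[float]) -> tuple[float, float]:
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            return math.nan, math.nan
        se = v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else 0.0
        return float(v.mean()), float(se)

    @property
    def corr_mean_se(self) -> tuple[float, float]:
        return self._stats([r.corr_eac_causal for r in self.ok])

    @property
    def gpi_mean_se(self) -> tuple[float, float]:
        return self._stats([r.mean_gpi for r in self.ok])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "replicate": r.replicate, "corr_eac_causal": r.corr_eac_causal,
            "mean_gpi": r.mean_gpi, "causal_maf": r.causal_maf,
            "q_hat": r.q_hat, "em_converged": r.em_converged,
            "error": r.error or ""} for r in self.results])


def run_replicate(ped: Pedigree, pen: PenetranceMatrix, cfg: SimConfig,
                  rng: np.random.Generator, *, init: SegregationModel,
                  phenotyped_ids: Sequence[str] | None = None,
                  em_tol: float = 1e-5, max_em_iter: int = 500
                  ) -> tuple[FittedSegregation, TrueGenotypes, int, float,
                             PhenotypeTable]:
    """One gene-drop + segregation-analysis replicate (no error capture)."""
    founder_counts, is_singleton = simulate_founder_snps(
        cfg, n_founders=len(ped.founders), rng=rng)
    tg = gene_drop(ped, founder_counts, rng, is_singleton)
    locus, maf = choose_causal_snp(tg, cfg.causal_rule, cfg.causal_maf_min, rng)
    phen = assign_phenotypes(tg.ids, tg.counts[:, locus], pen, rng)
    if phenotyped_ids is not None:
        phen = phen.restrict(phenotyped_ids)
    fit = fit_segregation_model(ped, phen, init, em_tol=em_tol,
                                max_em_iter=max_em_iter)
    return fit, tg, locus, maf, phen


def run_scenario(ped: Pedigree, pen: PenetranceMatrix, cfg: SimConfig, *,
                 init: SegregationModel | None = None,
                 phenotyped_ids: Sequence[str] | None = None,
                 em_tol: float = 1e-5, max_em_iter: int = 500,
                 keep_last: bool = False) -> ReplicateSummary:
    """Replicate loop: simulate, fit the segregation model, summarise.

    Per replicate the Pearson correlation between EAC and the causal
    allele count, and the population mean GPI, are recorded; the
    summary reports their means and standard errors across replicates.
    Failed replicates are kept in the result list with their error.

    ``init`` defaults to the canonical starting penetrance softened by
    1% toward uniform (exact zeros in a starting matrix are absorbing
    under EM and can make incompletely penetrant data impossible) at
    q = 0.5.
    """
    if init is None:
        init = SegregationModel(0.5, HORN_START.soften(0.01))
    ss = np.random.SeedSequence(cfg.seed)
    summary = ReplicateSummary()
    for rep, child in enumerate(ss.spawn(cfg.replicates), start=1):
        rng = np.random.default_rng(child)
        res = ReplicateResult(replicate=rep)
        try:
            fit, tg, locus, maf, phen = run_replicate(
                ped, pen, cfg, rng, init=init, phenotyped_ids=phenotyped_ids,
                em_tol=em_tol, max_em_iter=max_em_iter)
            causal = tg.counts[:, locus].astype(float)
            res.corr_eac_causal = float(np.corrcoef(fit.eac, causal)[0, 1])
            res.mean_gpi = float(fit.gpi.mean())
            res.causal_index = locus
            res.causal_maf = maf
            res.q_hat = fit.model.q
            res.em_converged = fit.converged
            if keep_last:
                summary.last_replicate_data = {
                    "fit": fit, "true_genotypes": tg, "causal_index": locus,
                    "causal_maf": maf, "phenotypes": phen}
        except Exception as exc:  # noqa: BLE001 - reported, not dropped
            res.error = f"{type(exc).__name__}: {exc}"
        summary.results.append(res)
    return summary


def write_replicate_summary(summary: ReplicateSummary, path: str | Path) -> None:
    """TSV with one row per replicate plus aggregate `mean` / `se` rows."""
    df = summary.to_frame()
    cm, cs = summary.corr_mean_se
    gm, gs = summary.gpi_mean_se
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("replicate\tcorr_eac_causal\tmean_gpi\n")
        for _, row in df.iterrows():
            fh.write(f"{row['replicate']}\t{row['corr_eac_causal']:.6f}"
                     f"\t{row['mean_gpi']:.6f}\n")
        fh.write(f"mean\t{cm:.6f}\t{gm:.6f}\n")
        fh.write(f"se\t{cs:.6f}\t{gs:.6f}\n")


def write_truth(tg: TrueGenotypes, locus: int, maf: float,
                path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump({"causal_index": locus, "causal_maf": maf,
                   "causal_counts": dict(zip(tg.ids,
                                             tg.counts[:, locus].tolist()))},
                  fh)
        fh.write("\n")
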