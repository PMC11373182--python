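"""Per-SNP quality control and association testing.

Two association models are provided.  The segregation GWAS regresses
the expected allele count (EAC) from a fitted segregation model on each
SNP's allele count by ordinary least squares: because EAC is additive
by construction, an ordinary additive GWAS applies even though the
underlying phenotype is categorical, non-additive and incompletely
penetrant.  For comparison, a binarized phenotype can be regressed on
allele counts by per-SNP logistic regression with likelihood-ratio
p-values.

All p-values are computed in log space, so extreme associations keep a
finite, meaningful -log10(p) instead of saturating at the smallest
representable double (~1e-321).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

_LN10 = np.log(10.0)


class GwasError(ValueError):
    """Invalid association-analysis input."""


# --------------------------------------------------------------------------
# quality control
# --------------------------------------------------------------------------

_NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M", "0"}


def _is_autosome(chrom: str) -> bool:
    c = str(chrom).upper()
    return c.isdigit() and int(c) > 0 and c not in _NON_AUTOSOMES


def qc_filter(gm: GenotypeMatrix, *, maf_min: float = 0.01,
              hwe_chi2_max: float = 600.0, call_rate_min: float = 0.90,
              autosomes_only: bool = True
              ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove SNPs failing MAF, HWE, call-rate or autosome rules.

    The HWE statistic is the 1-df chi-square goodness of fit of the
    observed genotype counts against Hardy-Weinberg expectations at the
    sample allele frequency.  Returns the filtered matrix and a
    per-rule removal report.
    """
    counts = gm.counts
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(counts, axis=0) / 2.0
    freq = np.nan_to_num(freq)
    maf = np.minimum(freq, 1.0 - freq)
    call = gm.call_rates()

    n_obs = (~np.isnan(counts)).sum(axis=0).astype(float)
    o0 = np.nansum(counts == 0.0, axis=0)
    o1 = np.nansum(counts == 1.0, axis=0)
    o2 = n_obs - o0 - o1
    e0 = n_obs * (1 - freq) ** 2
    e1 = n_obs * 2 * freq * (1 - freq)
    e2 = n_obs * freq ** 2
    chi2 = np.zeros(gm.n_snps)
    for obs, exp in ((o0, e0), (o1, e1), (o2, e2)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (obs - exp) ** 2 / exp
        chi2 += np.where(exp > 0, term, 0.0)

    fail_maf = maf < maf_min
    fail_hwe = chi2 > hwe_chi2_max
    fail_call = call < call_rate_min
    fail_auto = (~gm.snps["chrom"].map(_is_autosome).to_numpy()
                 if autosomes_only else np.zeros(gm.n_snps, dtype=bool))
    fail_any = fail_maf | fail_hwe | fail_call | fail_auto
    report = pd.DataFrame({
        "rule": ["maf", "hwe", "call_rate", "non_autosome", "total_removed",
                 "retained"],
        "n_snps": [int(fail_maf.sum()), int(fail_hwe.sum()),
                   int(fail_call.sum()), int(fail_auto.sum()),
                   int(fail_any.sum()), int((~fail_any).sum())]})
    if fail_any.all():
        warnings.warn("all SNPs removed by QC", stacklevel=2)
    return gm.subset_snps(~fail_any), report


# --------------------------------------------------------------------------
# association models
# --------------------------------------------------------------------------

def _align(values: pd.Series | np.ndarray, gm: GenotypeMatrix
           ) -> tuple[np.ndarray, GenotypeMatrix]:
    """Align a response vector with the genotype rows via shared ids."""
    if isinstance(values, pd.Series):
        shared = [i for i in gm.ids if i in values.index]
        if not shared:
            raise GwasError("no overlapping ids between response and genotypes")
        sub = gm.subset_individuals(shared) if len(shared) != gm.n_individuals else gm
        return values.loc[shared].to_numpy(dtype=float), sub
    y = np.asarray(values, dtype=float)
    if y.shape[0] != gm.n_individuals:
        raise GwasError(f"response length {y.shape[0]} != {gm.n_individuals} "
                        "genotyped individuals (pass a pd.Series to align by id)")
    return y, gm


def _assoc_frame(gm: GenotypeMatrix) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": gm.snps["snp"].to_numpy(),
        "chrom": gm.snps["chrom"].astype(str).to_numpy(),
        "pos": gm.snps["pos"].to_numpy()})


def eac_gwas(eac: pd.Series | np.ndarray, gm: GenotypeMatrix,
             min_n: int = 3) -> pd.DataFrame:
    """OLS of EAC on allele count, one SNP at a time (vectorized).

    Missing genotypes are dropped pairwise per SNP.  Two-sided p-values
    come from the slope t statistic via the log survival function.
    Monomorphic SNPs yield NA statistics and a ``monomorphic`` flag.
    """
    y, gm = _align(eac, gm)
    x = gm.counts
    m = ~np.isnan(x)
    x0 = np.nan_to_num(x)
    n = m.sum(axis=0).astype(float)
    sx = x0.sum(axis=0)
    sxx = (x0 ** 2).sum(axis=0)
    sy = y @ m
    syy = (y ** 2) @ m
    sxy = y @ x0
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = sxx - sx ** 2 / n
        vy = syy - sy ** 2 / n
        cov = sxy - sx * sy / n
        beta = cov / vx
        df = n - 2
        sse = np.maximum(vy - cov ** 2 / vx, 1e-24 * np.maximum(vy, 1e-300))
        se = np.sqrt(sse / (df * vx))
        tstat = beta / se
        r2 = np.clip(cov ** 2 / (vx * vy), 0.0, 1.0)
        logsf = stats.t.logsf(np.abs(tstat), df)
        # betainc underflows to -inf for extreme t; use the stable tail
        # asymptotic sf(t) ~ pdf(t) * t / df instead
        extreme = np.isneginf(logsf)
        if np.any(extreme):
            ta, dfa = np.abs(tstat[extreme]), df[extreme]
            logsf[extreme] = (stats.t.logpdf(ta, dfa) + np.log(ta)
                              - np.log(dfa))
        neglog10p = -(np.log(2.0) + logsf) / _LN10

    bad = (n < min_n) | (vx <= 1e-12) | ~np.isfinite(beta)
    flags = np.where(vx <= 1e-12, "monomorphic",
                     np.where(n < min_n, "too_few", ""))
    tab = _assoc_frame(gm)
    tab["n"] = n.astype(int)
    for col, vals in (("beta", beta), ("se", se), ("stat", tstat),
                      ("neglog10p", neglog10p), ("r2", r2)):
        tab[col] = np.where(bad, np.nan, vals)
    tab["flags"] = flags
    return tab


def binary_gwas(y: pd.Series | np.ndarray, gm: GenotypeMatrix,
                maxiter: int = 100) -> pd.DataFrame:
    """Per-SNP logistic regression of a 0/1 phenotype on allele count.

    The p-value is a 1-df likelihood-ratio test against the
    intercept-only model, reported in log space.  Complete or
    quasi-complete separation is flagged (huge slope or failed
    convergence) and the LRT at the iteration cap is still reported,
    matching how near-deterministic traits behave in practice.
    """
    import statsmodels.api as sm

    yv, gm = _align(y, gm)
    uniq = np.unique(yv[~np.isnan(yv)])
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise GwasError("binary phenotype must contain only 0/1")
    if uniq.size < 2:
        raise GwasError("binary phenotype is constant")

    tab = _assoc_frame(gm)
    out = {k: [] for k in ("n", "beta", "se", "stat", "neglog10p", "r2", "flags")}
    for j in range(gm.n_snps):
        xj = gm.counts[:, j]
        keep = ~np.isnan(xj) & ~np.isnan(yv)
        xk, yk = xj[keep], yv[keep]
        nk = int(keep.sum())
        out["n"].append(nk)
        if nk < 3 or np.ptp(xk) == 0 or np.ptp(yk) == 0:
            for k in ("beta", "se", "stat", "neglog10p", "r2"):
                out[k].append(np.nan)
            out["flags"].append("monomorphic" if nk >= 3 and np.ptp(xk) == 0
                                else "degenerate")
            continue
        X = np.column_stack([np.ones(nk), xk])
        flag = ""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(yk, X)
            res = model.fit(disp=0, method="lbfgs", maxiter=maxiter)
        converged = bool(res.mle_retvals.get("converged", True))
        beta = float(res.params[1])
        pbar = yk.mean()
        llnull = nk * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
        # separation: slope diverging, optimizer stuck, or a (near-)perfect
        # fit -- the log-likelihood of a separating SNP approaches zero
        if not converged or abs(beta) > 20 or res.llf > -1e-3 * nk:
            flag = "separation"
        lrt = max(0.0, 2.0 * (res.llf - llnull))
        neglog10p = -stats.chi2.logsf(lrt, 1) / _LN10
        out["beta"].append(beta)
        out["se"].append(float(res.bse[1]))
        out["stat"].append(lrt)
        out["neglog10p"].append(float(neglog10p))
        out["r2"].append(float(1.0 - res.llf / llnull) if llnull != 0 else np.nan)
        out["flags"].append(flag)
    for k, v in out.items():
        tab[k] = v
    return tab


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def _chrom_key(c: str) -> tuple[int, str]:
    c = str(c)
    return (int(c), "") if c.isdigit() else (10 ** 6, c)


def top_snp(tab: pd.DataFrame) -> pd.Series:
    """Most significant SNP: max -log10 p, ties by |beta| then genome order."""
    usable = tab.dropna(subset=["neglog10p"])
    if usable.empty:
        raise GwasError("association table has no usable rows")
    keys = usable["chrom"].map(_chrom_key)
    usable = usable.assign(_ck=[k[0] for k in keys], _cs=[k[1] for k in keys],
                           _ab=usable["beta"].abs())
    usable = usable.sort_values(["_ck", "_cs", "pos"], kind="mergesort")
    usable = usable.sort_values(["neglog10p", "_ab"], ascending=False,
                                kind="mergesort")
    return usable.iloc[0].drop(["_ck", "_cs", "_ab"])


def eac_snp_correlation(eac: np.ndarray | pd.Series,
                        snp_counts: np.ndarray | pd.Series) -> float:
    """Pearson correlation between EAC and a SNP's allele counts."""
    a = np.asarray(eac, dtype=float)
    b = np.asarray(snp_counts, dtype=float)
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        warnings.warn("fewer than 3 paired values; correlation undefined",
                      stacklevel=2)
        return float("nan")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant vector; correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def adjust_eac_for_top_snp(eac: np.ndarray | pd.Series,
                           top_counts: np.ndarray | pd.Series) -> np.ndarray:
    """Residualize EAC on the top SNP, re-centred at the original EAC mean.

    Use before re-running :func:`eac_gwas` to look for secondary peaks
    once the main one is accounted for.  Missing top-SNP genotypes
    contribute no correction (treated as sitting at the SNP mean).
    """
    a = np.asarray(eac, dtype=float)
    b = np.asarray(top_counts, dtype=float)
    keep = ~np.isnan(b)
    if np.ptp(b[keep]) == 0:
        raise GwasError("top SNP is monomorphic; cannot adjust")
    bk = b[keep]
    slope = np.cov(a[keep], bk)[0, 1] / np.var(bk, ddof=1)
    centred = np.where(keep, b - bk.mean(), 0.0)
    return a - slope * centred


# --------------------------------------------------------------------------
# sex-subset workflows
# --------------------------------------------------------------------------

@dataclass
class SubsetResult:
    """One analysis subset: the fitted segregation model, its EAC, the GWAS."""

    name: str
    eac: pd.Series
    assoc: pd.DataFrame
    fit: object | None = None  # FittedSegregation (None for combined-from-separate)


def run_subsets(ped, phen, gm: GenotypeMatrix, init, *,
                subsets: tuple[str, ...] = ("female", "male", "combined",
                                            "combined-from-separate"),
                qc: bool = True, em_tol: float = 1e-5, max_em_iter: int = 500
                ) -> dict[str, SubsetResult]:
    """Run the segregation GWAS for the four canonical analysis subsets.

    ``female`` / ``male``: phenotypes of the other sex are masked to
    missing (the full pedigree is retained for relationship
    information) and the GWAS is run on that sex's genotyped animals.
    ``combined``: one pooled segregation analysis of all phenotypes.
    ``combined-from-separate``: the EAC vectors from the two
    single-sex fits are concatenated and analysed in one GWAS --
    the right choice when penetrance differs between the sexes, which a
    pooled analysis dilutes.
    """
    from .pedigree import FEMALE, MALE
    from .segregation import SegregationModel, fit_segregation_model

    if not isinstance(init, SegregationModel):
        raise GwasError("init must be a SegregationModel")
    if qc:
        gm, _ = qc_filter(gm)
    sex_of = {ind.id: ind.sex for ind in ped}
    by_sex = {MALE: [i for i in ped.ids if sex_of[i] == MALE],
              FEMALE: [i for i in ped.ids if sex_of[i] == FEMALE]}

    need_sex = [s for s in subsets
                if s in ("female", "male", "combined-from-separate")]
    if need_sex and not ped.sex_recorded:
        raise GwasError(f"subset(s) {need_sex} require a sex column")

    def sex_fit(sex: str):
        masked = phen.restrict(by_sex[sex])
        if len(masked) == 0 or all(v < 0 for _, v in masked.items()):
            raise GwasError(f"no phenotyped {sex} individuals for subset")
        return fit_segregation_model(ped, masked, init, em_tol=em_tol,
                                     max_em_iter=max_em_iter)

    results: dict[str, SubsetResult] = {}
    fits: dict[str, object] = {}
    for sex, name in ((FEMALE, "female"), (MALE, "male")):
        if name in subsets or "combined-from-separate" in subsets:
            fits[name] = sex_fit(sex)
    for sex, name in ((FEMALE, "female"), (MALE, "male")):
        if name in subsets:
            fit = fits[name]
            genotyped = [i for i in by_sex[sex] if i in set(gm.ids)]
            eac = fit.eac_series().loc[genotyped]
            results[name] = SubsetResult(name, eac, eac_gwas(eac, gm), fit)
    if "combined" in subsets:
        fit = fit_segregation_model(ped, phen, init, em_tol=em_tol,
                                    max_em_iter=max_em_iter)
        genotyped = [i for i in ped.ids if i in set(gm.ids)]
        eac = fit.eac_series().loc[genotyped]
        results["combined"] = SubsetResult("combined", eac, eac_gwas(eac, gm), fit)
    if "combined-from-separate" in subsets:
        parts = []
        for sex, name in ((FEMALE, "female"), (MALE, "male")):
            genotyped = [i for i in by_sex[sex] if i in set(gm.ids)]
            parts.append(fits[name].eac_series().loc[genotyped])
        eac = pd.concat(parts)
        results["combined-from-separate"] = SubsetResult(
            "combined-from-separate", eac, eac_gwas(eac, gm), None)
    return results


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def write_association(tab: pd.DataFrame, path) -> None:
    cols = ["snp", "chrom", "pos", "n", "beta", "se", "stat",
            "neglog10p", "r2", "flags"]
    tab.to_csv(path, sep="\t", index=False, columns=cols,
               float_format="%.6g", na_rep="NA")


def manhattan_plot(tab: pd.DataFrame, path, *, bonferroni: float = 0.05) -> None:
    """Manhattan plot with chromosome-alternating colors (optional PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = tab.dropna(subset=["neglog10p"]).copy()
    usable["_ck"] = usable["chrom"].map(lambda c: _chrom_key(c)[0])
    usable = usable.sort_values(["_ck", "pos"])
    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset = 0
    ticks, labels = [], []
    for k, (chrom, grp) in enumerate(usable.groupby("_ck", sort=True)):
        x = offset + np.arange(len(grp))
        ax.scatter(x, grp["neglog10p"], s=4,
                   color="#1f77b4" if k % 2 == 0 else "#ff7f0e")
        ticks.append(offset + len(grp) / 2)
        labels.append(str(grp["chrom"].iloc[0]))
        offset += len(grp)
    if len(usable):
        thr = -np.log10(bonferroni / len(usable))
        ax.axhline(thr, color="grey", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
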