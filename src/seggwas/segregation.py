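"""Single-locus segregation analysis on pedigrees.

Given a pedigree, categorical phenotypes and a penetrance model, this
module computes posterior genotype probabilities at a putative biallelic
QTL by iterative peeling, estimates the penetrance matrix and founder
allele frequency by EM, and linearizes the probabilities into the
expected allele count (EAC) and the genotype probability index (GPI).

The model: founders draw ordered genotypes from Hardy-Weinberg
proportions at frequency ``q`` of allele ``A``; offspring receive one
allele from each parent by fair Mendelian sampling; a phenotype ``y`` is
emitted with probability ``pen[y, class(g)]`` where ``class`` collapses
the ordered genotype (aa, aA, Aa, AA) to the unordered class (0, 1, 2).
Missing phenotypes contribute a factor of one, so unphenotyped relatives
still conduct pedigree information.

EAC is the posterior mean allele count, ``0 p(aa) + 1 p(aA) + 1 p(Aa)
+ 2 p(AA)``; being a posterior mean it is additive by construction even
when the phenotype itself is dominant, sex-modified or incompletely
penetrant.  GPI scores how far an individual's genotype distribution has
moved from the uninformative Hardy-Weinberg prior: 0 at the prior, 100
at certainty.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._peel_kernel import run_peeling
from .pedigree import Pedigree
from .penetrance import PenetranceMatrix
from .phenotypes import MISSING, PhenotypeTable

# ordered genotype states: 0=aa, 1=aA, 2=Aa, 3=AA (paternal allele first)
_FIRST = np.array([0, 0, 1, 1])
_SECOND = np.array([0, 1, 0, 1])
GENOTYPE_CLASS = _FIRST + _SECOND          # unordered class 0/1/2
EAC_WEIGHTS = GENOTYPE_CLASS.astype(float)  # allele-A count per state

Q_MIN = 1e-6
Q_MAX = 1.0 - 1e-6


def _transmission_tensor() -> np.ndarray:
    """T[a, b, g] = P(child ordered genotype g | sire state a, dam state b)."""
    p_a = (_FIRST + _SECOND) / 2.0  # P(parent transmits A | state)
    T = np.empty((4, 4, 4))
    for a in range(4):
        for b in range(4):
            for g in range(4):
                pp = p_a[a] if _FIRST[g] else 1.0 - p_a[a]
                pm = p_a[b] if _SECOND[g] else 1.0 - p_a[b]
                T[a, b, g] = pp * pm
    return T


TRANSMISSION = _transmission_tensor()
TRANSMISSION.setflags(write=False)


def hardy_weinberg_ordered(q: float) -> np.ndarray:
    """Ordered-genotype Hardy-Weinberg prior at frequency q of allele A."""
    return np.array([(1 - q) ** 2, (1 - q) * q, q * (1 - q), q ** 2])


def mendelian_transmission(parent_p: Sequence[float]) -> tuple[float, float]:
    """Allele distribution (P(a), P(A)) transmitted by a parent.

    ``parent_p`` is the parent's ordered genotype distribution.
    """
    p = np.asarray(parent_p, dtype=float)
    if p.shape != (4,):
        raise ValueError("parent distribution must have four ordered states")
    p_A = float(p @ (np.asarray([0, 0.5, 0.5, 1.0])))
    return 1.0 - p_A, p_A


class SegregationError(ValueError):
    """Invalid segregation-analysis input."""


class ModelDataContradiction(SegregationError):
    """The penetrance model assigns zero probability to an observed record."""

    def __init__(self, ident: str):
        super().__init__(
            f"phenotype of individual {ident!r} is impossible under the "
            "current penetrance model and pedigree")
        self.individual = ident


@dataclass
class SegregationModel:
    """Founder frequency of allele A plus the penetrance matrix."""

    q: float
    penetrance: PenetranceMatrix

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise SegregationError(f"q must lie strictly inside (0,1), got {self.q}")


@dataclass
class GenotypeProbabilities:
    """Per-individual posterior distributions over ordered genotypes."""

    ids: list[str]
    ordered: np.ndarray          # (n, 4) rows sum to 1
    converged: bool = True
    n_sweeps: int = 0

    @property
    def unordered(self) -> np.ndarray:
        """(n, 3) class probabilities with p(class 1) = p(aA) + p(Aa)."""
        u = np.empty((self.ordered.shape[0], 3))
        u[:, 0] = self.ordered[:, 0]
        u[:, 1] = self.ordered[:, 1] + self.ordered[:, 2]
        u[:, 2] = self.ordered[:, 3]
        return u

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> np.ndarray:
        index = {ident: i for i, ident in enumerate(self.ids)}
        return self.ordered[[index[i] for i in ids]]


class PeelingEngine:
    """Reusable peeling machinery for one (pedigree, phenotype) pair.

    Builds the nuclear-family decomposition once; ``peel`` can then be
    called repeatedly with different models, optionally warm-starting
    the messages from the previous call (the natural thing to do inside
    EM, where successive models differ little).

    Loop handling: on loop-free pedigrees the message fixed point is
    exact.  Marriage-graph loops (inbreeding, mate sharing through
    common ancestors) bias the fixed point, so for loopy pedigrees up
    to ``exact_loop_limit`` individuals the engine switches to exact
    variable elimination; beyond that it iterates the messages to a
    fixed point, which is the standard scalable approximation.
    """

    def __init__(self, ped: Pedigree, phen: PhenotypeTable, *,
                 exact_loop_limit: int = 64):
        phen.attach_check(ped)
        self.ped = ped
        self.phen = phen
        self.ids = ped.ids
        n = len(ped)
        pos = {ident: i for i, ident in enumerate(self.ids)}
        topo_rank = {ident: r for r, ident in enumerate(ped.topological_order())}

        fams: dict[tuple[int, int], list[int]] = {}
        for ind in ped:
            if ind.sire is None:
                continue
            fams.setdefault((pos[ind.sire], pos[ind.dam]), []).append(pos[ind.id])

        fam_keys = list(fams)
        self.fam_sire = np.array([k[0] for k in fam_keys], dtype=np.int64)
        self.fam_dam = np.array([k[1] for k in fam_keys], dtype=np.int64)
        off_lists = [fams[k] for k in fam_keys]
        self.off_start = np.zeros(len(fam_keys) + 1, dtype=np.int64)
        self.off_start[1:] = np.cumsum([len(o) for o in off_lists])
        self.off_idx = np.array(
            [c for o in off_lists for c in o], dtype=np.int64).reshape(-1)

        # family order: by topological rank of the earliest offspring
        first_child_rank = [min(topo_rank[self.ids[c]] for c in o) for o in off_lists]
        self.fam_order = np.argsort(first_child_rank, kind="stable").astype(np.int64)

        # CSR of (family, role) memberships per individual acting as parent
        memberships: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for f, (s, d) in enumerate(fam_keys):
            memberships[s].append((f, 0))
            memberships[d].append((f, 1))
        self.pf_start = np.zeros(n + 1, dtype=np.int64)
        self.pf_start[1:] = np.cumsum([len(m) for m in memberships])
        flat = [fr for m in memberships for fr in m]
        self.pf_fam = np.array([fr[0] for fr in flat], dtype=np.int64).reshape(-1)
        self.pf_role = np.array([fr[1] for fr in flat], dtype=np.int64).reshape(-1)

        self.founder_mask = np.array(
            [ind.sire is None for ind in ped], dtype=bool)
        self.y = phen.vector(self.ids)
        self._state: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

        # marriage graph is a forest iff edges == nodes - components
        n_nodes = n + len(fam_keys)
        n_edges = int(sum(2 + len(o) for o in off_lists))
        parent_uf = list(range(n_nodes))

        def find(a: int) -> int:
            while parent_uf[a] != a:
                parent_uf[a] = parent_uf[parent_uf[a]]
                a = parent_uf[a]
            return a

        for f, (s, d) in enumerate(fam_keys):
            for node in (s, d, *fams[(s, d)]):
                ra, rb = find(node), find(n + f)
                if ra != rb:
                    parent_uf[ra] = rb
        n_components = sum(1 for i in range(n_nodes) if find(i) == i)
        self.has_loops = n_edges > n_nodes - n_components
        self.exact_loop_limit = exact_loop_limit

    def _penetrance_vector(self, pen: PenetranceMatrix) -> np.ndarray:
        if pen.n_classes != self.phen.n_classes:
            raise SegregationError(
                f"penetrance has {pen.n_classes} classes, phenotypes have "
                f"{self.phen.n_classes}")
        penet = np.ones((len(self.ids), 4))
        observed = self.y >= 0
        penet[observed] = pen.entries[self.y[observed]][:, GENOTYPE_CLASS]
        dead = observed & (penet.max(axis=1) <= 0.0)
        if dead.any():
            raise ModelDataContradiction(self.ids[int(np.argmax(dead))])
        return penet

    def peel(self, model: SegregationModel, *, tol: float = 1e-8,
             max_sweeps: int = 200, warm: bool = False) -> GenotypeProbabilities:
        if tol <= 0:
            raise SegregationError("tol must be positive")
        n = len(self.ids)
        penet = self._penetrance_vector(model.penetrance)
        if self.has_loops and n <= self.exact_loop_limit:
            try:
                ordered = _eliminate_posteriors(self, model.q, penet)
                return GenotypeProbabilities(list(self.ids), ordered)
            except _EliminationTooWide:
                pass  # dense loops: fall through to fixed-point iteration
        hw = hardy_weinberg_ordered(model.q)
        if warm and self._state is not None:
            anterior, msg, posterior = self._state
            anterior = anterior.copy()
            msg = msg.copy()
            posterior = posterior.copy()
            anterior[self.founder_mask] = hw
        else:
            anterior = np.full((n, 4), 0.25)
            anterior[self.founder_mask] = hw
            msg = np.ones((len(self.fam_sire), 2, 4))
            posterior = np.full((n, 4), 0.25)
        sweeps, status, bad = run_peeling(
            TRANSMISSION, penet, anterior, msg, posterior,
            self.fam_sire, self.fam_dam, self.off_start, self.off_idx,
            self.pf_start, self.pf_fam, self.pf_role, self.fam_order,
            tol, max_sweeps)
        if status == -1:
            raise ModelDataContradiction(self.ids[bad])
        self._state = (anterior, msg, posterior)
        return GenotypeProbabilities(list(self.ids), posterior.copy(),
                                     converged=(status == 1), n_sweeps=sweeps)


class _EliminationTooWide(Exception):
    """Intermediate factor would exceed the elimination cost cap."""


_ELIM_MAX_VARS = 12  # largest intermediate factor: 4^12 entries


def _eliminate_posteriors(engine: "PeelingEngine", q: float,
                          penet: np.ndarray) -> np.ndarray:
    """Exact per-individual marginals by greedy variable elimination.

    Factors: Hardy-Weinberg priors on founders, the Mendelian
    transmission tensor per non-founder, penetrance per phenotyped
    individual.  Each marginal is computed by eliminating every other
    variable, smallest-neighbourhood first; intermediate factors are
    renormalized to dodge underflow.  Exact on loopy pedigrees, at a
    cost that grows with the loop density (guarded by a width cap).
    """
    ped = engine.ped
    n = len(ped)
    pos = {ident: i for i, ident in enumerate(ped.ids)}
    hw = hardy_weinberg_ordered(q)
    base: list[tuple[tuple[int, ...], np.ndarray]] = []
    for i, ind in enumerate(ped):
        if ind.sire is None:
            base.append(((i,), hw * penet[i]))
        else:
            base.append(((pos[ind.sire], pos[ind.dam], i), TRANSMISSION))
            if engine.y[i] != MISSING:
                base.append(((i,), penet[i]))

    def contract(factors: list[tuple[tuple[int, ...], np.ndarray]],
                 target: int) -> np.ndarray:
        factors = list(factors)
        alive = sorted({v for vars_, _ in factors for v in vars_} - {target})
        while alive:
            # cheapest variable: smallest union of neighbour variables
            best, best_nb = None, None
            for v in alive:
                nb = set()
                for vars_, _ in factors:
                    if v in vars_:
                        nb.update(vars_)
                if best is None or len(nb) < len(best_nb):
                    best, best_nb = v, nb
            if len(best_nb) > _ELIM_MAX_VARS:
                raise _EliminationTooWide
            v = best
            involved = [f for f in factors if v in f[0]]
            rest = [f for f in factors if v not in f[0]]
            out_vars = tuple(sorted(set(best_nb) - {v}))
            letters = {u: chr(ord('a') + j)
                       for j, u in enumerate(sorted(best_nb))}
            spec = ",".join("".join(letters[u] for u in vars_)
                            for vars_, _ in involved)
            spec += "->" + "".join(letters[u] for u in out_vars)
            new = np.einsum(spec, *[arr for _, arr in involved])
            tot = new.max()
            if tot <= 0.0:
                raise ModelDataContradiction(ped.ids[target])
            factors = rest + [(out_vars, new / tot)]
            alive.remove(v)
        out = np.ones(4)
        for vars_, arr in factors:
            out = out * (arr if vars_ else float(arr))
        return out

    ordered = np.empty((n, 4))
    for t in range(n):
        marg = contract(base, t)
        tot = marg.sum()
        if tot <= 0.0:
            raise ModelDataContradiction(ped.ids[t])
        ordered[t] = marg / tot
    return ordered


def peel_genotype_probabilities(ped: Pedigree, phen: PhenotypeTable,
                                model: SegregationModel, *, tol: float = 1e-8,
                                max_sweeps: int = 200) -> GenotypeProbabilities:
    """Posterior genotype probabilities at the putative QTL for a fixed model."""
    return PeelingEngine(ped, phen).peel(model, tol=tol, max_sweeps=max_sweeps)


# --------------------------------------------------------------------------
# exact enumeration oracle (small pedigrees only)
# --------------------------------------------------------------------------

def _joint_over_configs(ped: Pedigree, phen: PhenotypeTable,
                        model: SegregationModel, max_size: int):
    n = len(ped)
    if n > max_size:
        raise SegregationError(
            f"enumeration over 4^{n} configurations refused (limit {max_size})")
    ids = ped.ids
    pos = {ident: i for i, ident in enumerate(ids)}
    hw = hardy_weinberg_ordered(model.q)
    y = phen.vector(ids)
    pen = model.penetrance.entries

    confs = np.empty((4 ** n, n), dtype=np.int8)
    idx = np.arange(4 ** n)
    for i in range(n):
        confs[:, i] = (idx // 4 ** (n - 1 - i)) % 4
    joint = np.ones(4 ** n)
    for i, ind in enumerate(ped):
        g = confs[:, i]
        if ind.sire is None:
            joint *= hw[g]
        else:
            joint *= TRANSMISSION[confs[:, pos[ind.sire]],
                                  confs[:, pos[ind.dam]], g]
        if y[i] != MISSING:
            joint *= pen[y[i]][GENOTYPE_CLASS[g]]
    return confs, joint


def brute_force_probabilities(ped: Pedigree, phen: PhenotypeTable,
                              model: SegregationModel, *, max_size: int = 12
                              ) -> GenotypeProbabilities:
    """Exact posteriors by summing the joint over all 4^n configurations."""
    confs, joint = _joint_over_configs(ped, phen, model, max_size)
    total = joint.sum()
    if total <= 0:
        raise ModelDataContradiction(ped.ids[0])
    ordered = np.empty((len(ped), 4))
    for i in range(len(ped)):
        ordered[i] = np.bincount(confs[:, i], weights=joint, minlength=4)
    ordered /= total
    return GenotypeProbabilities(list(ped.ids), ordered)


def brute_force_loglikelihood(ped: Pedigree, phen: PhenotypeTable,
                              model: SegregationModel, *, max_size: int = 12
                              ) -> float:
    """Observed-data log-likelihood by exhaustive enumeration."""
    _, joint = _joint_over_configs(ped, phen, model, max_size)
    total = joint.sum()
    if total <= 0:
        return -math.inf
    return math.log(total)


# --------------------------------------------------------------------------
# EM steps
# --------------------------------------------------------------------------

def estimate_penetrance(probs: GenotypeProbabilities, phen: PhenotypeTable,
                        prev: PenetranceMatrix | None = None,
                        min_weight: float = 1e-8) -> PenetranceMatrix:
    """M-step for penetrance: posterior-weighted conditional frequencies.

    ``entries[k][g] = sum_{i: y_i = k} p_i(g) / sum_{i phenotyped} p_i(g)``.
    A genotype column whose total posterior weight among phenotyped
    individuals falls below ``min_weight`` keeps its previous values
    (``prev`` required in that case).
    """
    y = phen.vector(probs.ids)
    observed = y >= 0
    if not observed.any():
        raise SegregationError("cannot estimate penetrance: all phenotypes missing")
    u = probs.unordered
    k = phen.n_classes
    num = np.zeros((k, 3))
    for cls in range(k):
        sel = observed & (y == cls)
        if sel.any():
            num[cls] = u[sel].sum(axis=0)
    denom = u[observed].sum(axis=0)
    entries = np.empty((k, 3))
    for g in range(3):
        if denom[g] < min_weight:
            if prev is None:
                raise SegregationError(
                    f"genotype class {g} has no posterior weight and no "
                    "previous penetrance column to retain")
            entries[:, g] = prev.entries[:, g]
        else:
            entries[:, g] = num[:, g] / denom[g]
    return PenetranceMatrix(entries, phen.labels)


def estimate_allele_frequency(probs: GenotypeProbabilities, ped: Pedigree) -> float:
    """M-step for q: mean founder EAC / 2, clamped inside (0, 1)."""
    founders = set(ped.founders)
    if not founders:
        raise SegregationError("pedigree has no founders")
    mask = np.array([ident in founders for ident in probs.ids])
    eac = probs.ordered @ EAC_WEIGHTS
    q = float(eac[mask].mean() / 2.0)
    return min(max(q, Q_MIN), Q_MAX)


def compute_eac(probs: GenotypeProbabilities) -> np.ndarray:
    """Expected allele count per individual: 0 p(aa)+1 p(aA)+1 p(Aa)+2 p(AA)."""
    return probs.ordered @ EAC_WEIGHTS


def compute_gpi(probs: GenotypeProbabilities, q: float) -> np.ndarray:
    """Genotype probability index, 0-100.

    ``GPI_i = 100 * sqrt(max(0, 1 - Var_i / Var_HW))`` where ``Var_i``
    is the posterior variance of individual i's allele count and
    ``Var_HW = 2 q (1 - q)`` the allele-count variance under the
    Hardy-Weinberg prior at the model allele frequency.

    A point mass scores 100; a distribution equal to the
    Hardy-Weinberg prior scores 0; distributions more dispersed than
    the prior are clamped to 0.  Because EAC is the posterior mean
    allele count, the population mean of ``sqrt(1 - Var_i/Var_HW)``
    approximates the correlation between EAC and the true allele count
    (law of total variance), making mean GPI approximately linear in
    that correlation -- the property the index is used for.
    """
    if not (0.0 < q < 1.0):
        raise SegregationError("q must lie strictly inside (0,1)")
    var_hw = 2.0 * q * (1.0 - q)
    u = probs.unordered
    eac = u @ np.array([0.0, 1.0, 2.0])
    var = u @ np.array([0.0, 1.0, 4.0]) - eac ** 2
    return 100.0 * np.sqrt(np.clip(1.0 - var / var_hw, 0.0, 1.0))


def mean_gpi(probs: GenotypeProbabilities, q: float,
             ids: Sequence[str] | None = None) -> float:
    """Mean GPI over a chosen id subset (all individuals by default)."""
    gpi = compute_gpi(probs, q)
    if ids is None:
        return float(gpi.mean())
    index = {ident: i for i, ident in enumerate(probs.ids)}
    return float(gpi[[index[i] for i in ids]].mean())


# --------------------------------------------------------------------------
# full EM fit
# --------------------------------------------------------------------------

@dataclass
class FittedSegregation:
    """Converged segregation model with per-individual EAC and GPI."""

    model: SegregationModel
    probs: GenotypeProbabilities
    eac: np.ndarray
    gpi: np.ndarray
    n_em_iterations: int
    converged: bool
    trace: list[float] = field(default_factory=list)     # max param change/iter
    history: list[SegregationModel] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return self.probs.ids

    def eac_series(self):
        import pandas as pd
        return pd.Series(self.eac, index=self.ids, name="eac")

    def mean_gpi(self, ids: Sequence[str] | None = None) -> float:
        return mean_gpi(self.probs, self.model.q, ids)


def fit_segregation_model(ped: Pedigree, phen: PhenotypeTable,
                          init: SegregationModel, *, em_tol: float = 1e-5,
                          max_em_iter: int = 500, peel_tol: float = 1e-8,
                          max_sweeps: int = 200) -> FittedSegregation:
    """EM fit of penetrance and allele frequency.

    E-step: iterative peeling under the current model.  M-step:
    posterior-weighted penetrance plus founder allele frequency.
    Convergence: max absolute change over all penetrance entries and q
    below ``em_tol``.  Non-convergence is flagged, not fatal.
    """
    engine = PeelingEngine(ped, phen)
    model = init
    trace: list[float] = []
    history: list[SegregationModel] = [model]
    converged = False
    iters = 0
    for iters in range(1, max_em_iter + 1):
        probs = engine.peel(model, tol=peel_tol, max_sweeps=max_sweeps,
                            warm=(iters > 1))
        new_pen = estimate_penetrance(probs, phen, prev=model.penetrance)
        new_q = estimate_allele_frequency(probs, ped)
        delta = max(new_pen.max_abs_diff(model.penetrance),
                    abs(new_q - model.q))
        model = SegregationModel(new_q, new_pen)
        trace.append(delta)
        history.append(model)
        if delta < em_tol:
            converged = True
            break
    probs = engine.peel(model, tol=peel_tol, max_sweeps=max_sweeps, warm=True)
    eac = compute_eac(probs)
    gpi = compute_gpi(probs, model.q)
    return FittedSegregation(model=model, probs=probs, eac=eac, gpi=gpi,
                             n_em_iterations=iters, converged=converged,
                             trace=trace, history=history)


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def write_eac_table(fit: FittedSegregation, path: str | Path) -> None:
    """Write `id p_aa p_het p_AA eac gpi` (6 decimals) plus a sidecar JSON."""
    path = Path(path)
    u = fit.probs.unordered
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\tp_aa\tp_het\tp_AA\teac\tgpi\n")
        for i, ident in enumerate(fit.ids):
            fh.write(f"{ident}\t{u[i, 0]:.6f}\t{u[i, 1]:.6f}\t{u[i, 2]:.6f}"
                     f"\t{fit.eac[i]:.6f}\t{fit.gpi[i]:.6f}\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    with sidecar.open("w", encoding="utf-8") as fh:
        json.dump({
            "q": fit.model.q,
            "penetrance": fit.model.penetrance.entries.tolist(),
            "phenotype_labels": list(fit.model.penetrance.labels),
            "n_em_iterations": fit.n_em_iterations,
            "converged": fit.converged,
            "mean_gpi": float(np.mean(fit.gpi)),
        }, fh, indent=1)
        fh.write("\n")


def read_eac_table(path: str | Path):
    """Read the EAC table back as a pandas DataFrame indexed by id."""
    import pandas as pd
    return pd.read_csv(path, sep="\t", index_col="id",
                       dtype={"id": str}, float_precision="round_trip")
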