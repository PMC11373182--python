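"""Compiled message-passing kernel for iterative peeling.

Genotypes are ordered four-state (0 = aa, 1 = aA, 2 = Aa, 3 = AA;
paternal allele first).  The pedigree is decomposed into nuclear
families (sire, dam, full-sib offspring).  Each sweep runs a forward
pass updating anterior distributions (information flowing from parents,
their other families and full sibs) in family topological order, then a
backward pass updating the posterior messages each family sends to its
two parents, and finally recomputes every individual's normalized
posterior.  On loop-free pedigrees the fixed point is reached within a
few sweeps and equals the exact marginals; marriage-graph loops are
handled by iterating the same updates to a fixed point.

Status codes returned by :func:`run_peeling`:
``1`` converged, ``0`` sweep limit reached, ``-1`` contradiction (an
individual's posterior, or a family message, vanished; the offending
individual index is reported).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _parent_excl(i, f_ex, anterior, penet, pf_start, pf_fam, pf_role, msg, out):
    """anterior x penetrance x posterior messages from all families but f_ex."""
    for g in range(4):
        out[g] = anterior[i, g] * penet[i, g]
    for k in range(pf_start[i], pf_start[i + 1]):
        f2 = pf_fam[k]
        if f2 != f_ex:
            r = pf_role[k]
            for g in range(4):
                out[g] *= msg[f2, r, g]


@njit(cache=True)
def _pen_post(i, penet, pf_start, pf_fam, pf_role, msg, out):
    """penetrance x posterior messages from all of i's own families."""
    for g in range(4):
        out[g] = penet[i, g]
    for k in range(pf_start[i], pf_start[i + 1]):
        f2 = pf_fam[k]
        r = pf_role[k]
        for g in range(4):
            out[g] *= msg[f2, r, g]


@njit(cache=True)
def _child_s_matrices(f, T, penet, off_start, off_idx, pf_start, pf_fam,
                      pf_role, msg, S, tmp):
    """S[j][a,b] = sum_g T[a,b,g] * pen*_child_j(g) for family f's children."""
    k = off_start[f + 1] - off_start[f]
    for j in range(k):
        c = off_idx[off_start[f] + j]
        _pen_post(c, penet, pf_start, pf_fam, pf_role, msg, tmp)
        for a in range(4):
            for b in range(4):
                acc = 0.0
                for g in range(4):
                    acc += T[a, b, g] * tmp[g]
                S[j, a, b] = acc
    return k


@njit(cache=True)
def run_peeling(T, penet, anterior, msg, posterior,
                fam_sire, fam_dam, off_start, off_idx,
                pf_start, pf_fam, pf_role, fam_order,
                tol, max_sweeps):
    n = penet.shape[0]
    F = fam_sire.shape[0]
    kmax = 0
    for f in range(F):
        k = off_start[f + 1] - off_start[f]
        if k > kmax:
            kmax = k
    S = np.empty((kmax, 4, 4))
    pre = np.empty((kmax + 1, 4, 4))
    suf = np.empty((kmax + 1, 4, 4))
    ps = np.empty(4)
    pd_ = np.empty(4)
    tmp = np.empty(4)
    anew = np.empty(4)

    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1

        # ---- forward: anterior of every non-founder ----------------------
        for oi in range(F):
            f = fam_order[oi]
            s = fam_sire[f]
            d = fam_dam[f]
            _parent_excl(s, f, anterior, penet, pf_start, pf_fam, pf_role, msg, ps)
            _parent_excl(d, f, anterior, penet, pf_start, pf_fam, pf_role, msg, pd_)
            k = _child_s_matrices(f, T, penet, off_start, off_idx,
                                  pf_start, pf_fam, pf_role, msg, S, tmp)
            for a in range(4):
                for b in range(4):
                    pre[0, a, b] = 1.0
                    suf[k, a, b] = 1.0
            for j in range(k):
                for a in range(4):
                    for b in range(4):
                        pre[j + 1, a, b] = pre[j, a, b] * S[j, a, b]
            for j in range(k - 1, -1, -1):
                for a in range(4):
                    for b in range(4):
                        suf[j, a, b] = suf[j + 1, a, b] * S[j, a, b]
            for j in range(k):
                c = off_idx[off_start[f] + j]
                tot = 0.0
                for g in range(4):
                    acc = 0.0
                    for a in range(4):
                        wa = ps[a]
                        for b in range(4):
                            acc += T[a, b, g] * wa * pd_[b] * \
                                pre[j, a, b] * suf[j + 1, a, b]
                    anew[g] = acc
                    tot += acc
                if tot <= 0.0:
                    return sweeps, -1, c
                for g in range(4):
                    anterior[c, g] = anew[g] / tot

        # ---- backward: messages to both parents of every family ----------
        for oi in range(F - 1, -1, -1):
            f = fam_order[oi]
            s = fam_sire[f]
            d = fam_dam[f]
            _parent_excl(s, f, anterior, penet, pf_start, pf_fam, pf_role, msg, ps)
            _parent_excl(d, f, anterior, penet, pf_start, pf_fam, pf_role, msg, pd_)
            k = _child_s_matrices(f, T, penet, off_start, off_idx,
                                  pf_start, pf_fam, pf_role, msg, S, tmp)
            for a in range(4):
                for b in range(4):
                    full = 1.0
                    for j in range(k):
                        full *= S[j, a, b]
                    pre[0, a, b] = full  # reuse pre[0] as the full product
            tot = 0.0
            for a in range(4):
                acc = 0.0
                for b in range(4):
                    acc += pd_[b] * pre[0, a, b]
                anew[a] = acc
                tot += acc
            if tot <= 0.0:
                return sweeps, -1, s
            for a in range(4):
                msg[f, 0, a] = anew[a] / tot
            tot = 0.0
            for b in range(4):
                acc = 0.0
                for a in range(4):
                    acc += ps[a] * pre[0, a, b]
                anew[b] = acc
                tot += acc
            if tot <= 0.0:
                return sweeps, -1, d
            for b in range(4):
                msg[f, 1, b] = anew[b] / tot

        # ---- posteriors and convergence check ----------------------------
        delta = 0.0
        for i in range(n):
            _pen_post(i, penet, pf_start, pf_fam, pf_role, msg, tmp)
            tot = 0.0
            for g in range(4):
                tmp[g] *= anterior[i, g]
                tot += tmp[g]
            if tot <= 0.0:
                return sweeps, -1, i
            for g in range(4):
                p = tmp[g] / tot
                dd = abs(p - posterior[i, g])
                if dd > delta:
                    delta = dd
                posterior[i, g] = p
        if delta < tol:
            return sweeps, 1, -1

    return max_sweeps, 0, -1
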