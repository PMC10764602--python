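"""Compiled kernels for the sum-of-trees sampler.

Trees live in fixed-size heap arrays: root at index 0, children of node k at
2k+1 / 2k+2, depth capped at ``MAX_DEPTH``.  Node states are UNUSED,
INTERNAL (holds a split rule) or LEAF (holds a terminal-node mean).  All
kernels mutate preallocated arrays in place and draw from numba's
per-thread RNG, which must be seeded explicitly through :func:`seed_rng`
before any stochastic kernel is used.

Split rule convention: observations with ``x[var] <= cut`` go left;
proposals that would create an empty child are rejected outright, so every
reachable leaf always holds at least one training observation.
"""

import math

import numpy as np
from numba import njit

MAX_DEPTH = 6
N_NODES = 2 ** (MAX_DEPTH + 1) - 1  # 127

UNUSED = 0
INTERNAL = 1
LEAF = 2

_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def node_depth(k):
    d = 0
    while k > 0:
        k = (k - 1) >> 1
        d += 1
    return d


@njit(cache=True)
def ndtri(p):
    # Acklam's rational approximation to the standard normal quantile,
    # |relative error| < 1.15e-9 over (0, 1); adequate deep into the tails.
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    plow = 0.02425
    if p < plow:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
              + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    elif p > 1.0 - plow:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                 - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
               + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    else:
        q = p - 0.5
        r = q * q
        x = (((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
                - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
              - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / \
            (((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
                - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
              - 1.328068155288572e+01) * r + 1.0)
    if -8.0 < x < 8.0:
        # one Newton polish using the accurate erfc-based CDF
        e = 0.5 * math.erfc(-x / _SQRT2) - p
        u = e * math.sqrt(2.0 * math.pi) * math.exp(x * x / 2.0)
        x = x - u / (1.0 + x * u / 2.0)
    return x


@njit(cache=True)
def rtnorm_upper(a):
    """Standard normal draw conditioned on Z > a (inverse-CDF, tail-stable)."""
    u = np.random.random()
    if u < 1e-16:
        u = 1e-16
    if a > 8.0:
        # exponential tail approximation; relative error negligible here
        return a - math.log(1.0 - u) / a
    p_tail = 0.5 * math.erfc(a / _SQRT2)
    x = -ndtri(u * p_tail)
    if x <= a:
        x = a + 1e-10 * (1.0 + abs(a))
    return x


@njit(cache=True)
def _psplit(d, alpha, gamma):
    return alpha * (1.0 + d) ** (-gamma)


@njit(cache=True)
def _leaf_lml(nk, sk, sigma2, tau2r):
    # Per-leaf log marginal likelihood terms that do not cancel between a
    # parent leaf and the two children partitioning the same residuals.
    denom = sigma2 + nk * tau2r
    return 0.5 * math.log(sigma2 / denom) + tau2r * sk * sk / (2.0 * sigma2 * denom)


@njit(cache=True)
def _count_leaves(tntype):
    b = 0
    for k in range(N_NODES):
        if tntype[k] == LEAF:
            b += 1
    return b


@njit(cache=True)
def _count_prunable(tntype):
    c = 0
    for k in range((N_NODES - 1) // 2):
        if tntype[k] == INTERNAL and tntype[2 * k + 1] == LEAF and tntype[2 * k + 2] == LEAF:
            c += 1
    return c


@njit(cache=True)
def _try_grow(X, y, fit, tntype, tvar, tcut, tleaf_of,
              sigma2, tau2r, alpha, gamma, p_grow, p_prune):
    n, p = X.shape
    b = _count_leaves(tntype)
    pick = np.random.randint(b)
    L = -1
    c2 = 0
    for k in range(N_NODES):
        if tntype[k] == LEAF:
            if c2 == pick:
                L = k
                break
            c2 += 1
    dL = node_depth(L)
    if dL >= MAX_DEPTH:
        return
    v = np.random.randint(p)
    m = 0
    xmax = -1.0e300
    for i in range(n):
        if tleaf_of[i] == L:
            m += 1
            xv = X[i, v]
            if xv > xmax:
                xmax = xv
    if m < 2:
        return
    t_ord = np.random.randint(m)
    cthr = 0.0
    c3 = 0
    for i in range(n):
        if tleaf_of[i] == L:
            if c3 == t_ord:
                cthr = X[i, v]
                break
            c3 += 1
    if cthr >= xmax:
        return
    nl = 0
    nr = 0
    sl = 0.0
    sr = 0.0
    for i in range(n):
        if tleaf_of[i] == L:
            ri = y[i] - fit[i]
            if X[i, v] <= cthr:
                nl += 1
                sl += ri
            else:
                nr += 1
                sr += ri
    llr = (_leaf_lml(nl, sl, sigma2, tau2r) + _leaf_lml(nr, sr, sigma2, tau2r)
           - _leaf_lml(nl + nr, sl + sr, sigma2, tau2r))
    ps_d = _psplit(dL, alpha, gamma)
    ps_c = _psplit(dL + 1.0, alpha, gamma)
    lprior = math.log(ps_d) + 2.0 * math.log(1.0 - ps_c) - math.log(1.0 - ps_d)
    npr_new = _count_prunable(tntype) + 1
    if L > 0:
        sib = L - 1 if L % 2 == 0 else L + 1
        if tntype[sib] == LEAF:
            npr_new -= 1  # parent was prunable before the grow, not after
    if p_prune <= 0.0:
        return
    lprop = math.log(p_prune / p_grow) + math.log(b / float(npr_new))
    if math.log(np.random.random() + 1e-300) < llr + lprior + lprop:
        tntype[L] = INTERNAL
        tvar[L] = v
        tcut[L] = cthr
        tntype[2 * L + 1] = LEAF
        tntype[2 * L + 2] = LEAF
        for i in range(n):
            if tleaf_of[i] == L:
                tleaf_of[i] = 2 * L + 1 if X[i, v] <= cthr else 2 * L + 2


@njit(cache=True)
def _try_prune(X, y, fit, tntype, tvar, tcut, tleaf_of,
               sigma2, tau2r, alpha, gamma, p_grow, p_prune):
    n = X.shape[0]
    npr = _count_prunable(tntype)
    if npr == 0:
        return
    pick = np.random.randint(npr)
    P = -1
    c = 0
    for k in range((N_NODES - 1) // 2):
        if tntype[k] == INTERNAL and tntype[2 * k + 1] == LEAF and tntype[2 * k + 2] == LEAF:
            if c == pick:
                P = k
                break
            c += 1
    kl = 2 * P + 1
    kr = 2 * P + 2
    nl = 0
    nr = 0
    sl = 0.0
    sr = 0.0
    for i in range(n):
        if tleaf_of[i] == kl:
            nl += 1
            sl += y[i] - fit[i]
        elif tleaf_of[i] == kr:
            nr += 1
            sr += y[i] - fit[i]
    llr = (_leaf_lml(nl + nr, sl + sr, sigma2, tau2r)
           - _leaf_lml(nl, sl, sigma2, tau2r) - _leaf_lml(nr, sr, sigma2, tau2r))
    d = node_depth(P)
    ps_d = _psplit(d, alpha, gamma)
    ps_c = _psplit(d + 1.0, alpha, gamma)
    lprior = math.log(1.0 - ps_d) - math.log(ps_d) - 2.0 * math.log(1.0 - ps_c)
    b_new = _count_leaves(tntype) - 1
    if p_grow <= 0.0:
        return
    lprop = math.log(p_grow / p_prune) + math.log(npr / float(b_new))
    if math.log(np.random.random() + 1e-300) < llr + lprior + lprop:
        tntype[kl] = UNUSED
        tntype[kr] = UNUSED
        tntype[P] = LEAF
        tvar[P] = -1
        for i in range(n):
            if tleaf_of[i] == kl or tleaf_of[i] == kr:
                tleaf_of[i] = P


@njit(cache=True)
def _try_change(X, y, fit, tntype, tvar, tcut, tleaf_of, sigma2, tau2r):
    n, p = X.shape
    npr = _count_prunable(tntype)
    if npr == 0:
        return
    pick = np.random.randint(npr)
    Q = -1
    c = 0
    for k in range((N_NODES - 1) // 2):
        if tntype[k] == INTERNAL and tntype[2 * k + 1] == LEAF and tntype[2 * k + 2] == LEAF:
            if c == pick:
                Q = k
                break
            c += 1
    kl = 2 * Q + 1
    kr = 2 * Q + 2
    v = np.random.randint(p)
    m = 0
    xmax = -1.0e300
    for i in range(n):
        ko = tleaf_of[i]
        if ko == kl or ko == kr:
            m += 1
            if X[i, v] > xmax:
                xmax = X[i, v]
    if m < 2:
        return
    t_ord = np.random.randint(m)
    cthr = 0.0
    c3 = 0
    for i in range(n):
        ko = tleaf_of[i]
        if ko == kl or ko == kr:
            if c3 == t_ord:
                cthr = X[i, v]
                break
            c3 += 1
    if cthr >= xmax:
        return
    onl = 0
    onr = 0
    osl = 0.0
    osr = 0.0
    nnl = 0
    nnr = 0
    nsl = 0.0
    nsr = 0.0
    for i in range(n):
        ko = tleaf_of[i]
        if ko == kl or ko == kr:
            ri = y[i] - fit[i]
            if ko == kl:
                onl += 1
                osl += ri
            else:
                onr += 1
                osr += ri
            if X[i, v] <= cthr:
                nnl += 1
                nsl += ri
            else:
                nnr += 1
                nsr += ri
    # symmetric rule proposal from the node prior: acceptance is the
    # likelihood ratio of the two child partitions
    llr = (_leaf_lml(nnl, nsl, sigma2, tau2r) + _leaf_lml(nnr, nsr, sigma2, tau2r)
           - _leaf_lml(onl, osl, sigma2, tau2r) - _leaf_lml(onr, osr, sigma2, tau2r))
    if math.log(np.random.random() + 1e-300) < llr:
        tvar[Q] = v
        tcut[Q] = cthr
        for i in range(n):
            ko = tleaf_of[i]
            if ko == kl or ko == kr:
                tleaf_of[i] = kl if X[i, v] <= cthr else kr


@njit(cache=True)
def one_sweep(X, y, ntype, tvar, tcut, tleaf, leaf_of, fit,
              sigma2, tau2r, alpha, gamma, p_grow, p_prune):
    """One full backfitting sweep: per tree, one structural MH move with
    leaf means marginalized, then conjugate leaf-mean draws."""
    n = X.shape[0]
    r = ntype.shape[0]
    cnt = np.empty(N_NODES, np.int64)
    ssum = np.empty(N_NODES, np.float64)
    for j in range(r):
        ntj = ntype[j]
        vj = tvar[j]
        cj = tcut[j]
        lj = tleaf[j]
        oj = leaf_of[j]
        for i in range(n):
            fit[i] -= lj[oj[i]]
        u_move = np.random.random()
        if u_move < p_grow:
            _try_grow(X, y, fit, ntj, vj, cj, oj, sigma2, tau2r,
                      alpha, gamma, p_grow, p_prune)
        elif u_move < p_grow + p_prune:
            _try_prune(X, y, fit, ntj, vj, cj, oj, sigma2, tau2r,
                       alpha, gamma, p_grow, p_prune)
        else:
            _try_change(X, y, fit, ntj, vj, cj, oj, sigma2, tau2r)
        for k in range(N_NODES):
            cnt[k] = 0
            ssum[k] = 0.0
        for i in range(n):
            k = oj[i]
            cnt[k] += 1
            ssum[k] += y[i] - fit[i]
        for k in range(N_NODES):
            if ntj[k] == LEAF:
                pv = 1.0 / (1.0 / tau2r + cnt[k] / sigma2)
                pm = pv * ssum[k] / sigma2
                lj[k] = pm + math.sqrt(pv) * np.random.normal()
        for i in range(n):
            fit[i] += lj[oj[i]]


@njit(cache=True)
def forest_predict(tntype, tvar, tcut, tleaf, Xe):
    """Prediction of a single forest (r, N_NODES arrays) at rows of Xe."""
    r = tntype.shape[0]
    ne = Xe.shape[0]
    out = np.zeros(ne)
    for j in range(r):
        for i in range(ne):
            k = 0
            while tntype[j, k] == INTERNAL:
                if Xe[i, tvar[j, k]] <= tcut[j, k]:
                    k = 2 * k + 1
                else:
                    k = 2 * k + 2
            out[i] += tleaf[j, k]
    return out


@njit(cache=True)
def draws_predict(ntype_d, var_d, cut_d, leaf_d, Xe):
    """Predictions for M retained forests: returns an (M, ne) matrix."""
    M = ntype_d.shape[0]
    r = ntype_d.shape[1]
    ne = Xe.shape[0]
    out = np.zeros((M, ne))
    for m in range(M):
        for j in range(r):
            for i in range(ne):
                k = 0
                while ntype_d[m, j, k] == INTERNAL:
                    if Xe[i, var_d[m, j, k]] <= cut_d[m, j, k]:
                        k = 2 * k + 1
                    else:
                        k = 2 * k + 2
                out[m, i] += leaf_d[m, j, k]
    return out


@njit(cache=True)
def run_chain(X, y0, cens_idx, lower, seed, r, n_burn, n_keep, thin,
              alpha, gamma, tau2r, nu, lam, sigma2_init, p_grow, p_prune):
    """Full Gibbs chain: truncated-normal imputation of censored responses,
    one backfitting sweep, then the scaled-inverse-chi-square variance draw,
    retaining ``n_keep`` post-burn-in states (forest copies + sigma2).

    ``y0`` is the centered response; censored entries (listed in
    ``cens_idx`` with truncation bounds ``lower`` on the same centered
    scale) are overwritten by imputation each iteration.
    """
    np.random.seed(seed)
    n = X.shape[0]
    ntype = np.zeros((r, N_NODES), np.int8)
    tvar = np.full((r, N_NODES), -1, np.int32)
    tcut = np.zeros((r, N_NODES))
    tleaf = np.zeros((r, N_NODES))
    leaf_of = np.zeros((r, n), np.int32)
    for j in range(r):
        ntype[j, 0] = LEAF
    fit = np.zeros(n)
    y = y0.copy()
    sigma2 = sigma2_init
    out_ntype = np.zeros((n_keep, r, N_NODES), np.int8)
    out_var = np.zeros((n_keep, r, N_NODES), np.int32)
    out_cut = np.zeros((n_keep, r, N_NODES))
    out_leaf = np.zeros((n_keep, r, N_NODES))
    out_sigma2 = np.zeros(n_keep)
    total = n_burn + n_keep * thin
    sig = math.sqrt(sigma2)
    for it in range(total):
        for ii in range(cens_idx.shape[0]):
            i = cens_idx[ii]
            a = (lower[ii] - fit[i]) / sig
            y[i] = fit[i] + sig * rtnorm_upper(a)
        one_sweep(X, y, ntype, tvar, tcut, tleaf, leaf_of, fit,
                  sigma2, tau2r, alpha, gamma, p_grow, p_prune)
        sse = 0.0
        for i in range(n):
            d = y[i] - fit[i]
            sse += d * d
        sigma2 = (nu * lam + sse) / np.random.chisquare(nu + n)
        sig = math.sqrt(sigma2)
        if it >= n_burn and (it - n_burn) % thin == 0:
            m = (it - n_burn) // thin
            out_sigma2[m] = sigma2
            for j in range(r):
                for k in range(N_NODES):
                    out_ntype[m, j, k] = ntype[j, k]
                    out_var[m, j, k] = tvar[j, k]
                    out_cut[m, j, k] = tcut[j, k]
                    out_leaf[m, j, k] = tleaf[j, k]
    return out_ntype, out_var, out_cut, out_leaf, out_sigma2
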