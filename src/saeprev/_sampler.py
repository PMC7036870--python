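"""Metropolis-within-Gibbs kernel for the hierarchical smoothing models.

One compiled kernel serves all four likelihood families and all four
structural variants.  The latent state is

    theta_cell = beta0 + beta_g[group(cell)] + u[area(cell)] + v[area(cell)]

with u_k iid N(0, 1/tau_u), v an intrinsic CAR field with precision
tau_v (Q = diag(m) - A), flat priors on the fixed effects and Gamma
(shape, rate) hyperpriors on the two precisions (conjugate Gibbs
updates).  Updates:

* v_k: single-site random-walk Metropolis for in-sample areas; exact
  Gibbs draw from the ICAR full conditional (which has no likelihood
  term) for off-sample areas.  After the sweep v is recentred within
  each connected component and the mean shift is absorbed into beta0.
  Areas without neighbours keep v_k = 0.
* u_k: single-site Metropolis in-sample; fresh N(0, 1/tau_u) draw
  off-sample (the exact full conditional).
* beta0 and each group offset: scalar random-walk Metropolis.
* a joint "shift" move (beta0 + d, u - d) that leaves the likelihood
  invariant and decorrelates the intercept from the unstructured field.

Proposal scales adapt toward ~44% acceptance during burn-in only.

Likelihood codes: 0 = binomial counts (NB), 1 = Gaussian on the
empirical logit (LN), 2 = Gaussian on the arcsine root (AS, where theta
lives on the arcsine scale), 3 = continuous binomial on effective counts
(ES).  The continuous-binomial normalizing constant is free of the
prevalence, so it drops out of every Metropolis ratio.
"""

import math

import numpy as np
from numba import njit

FAMILY_NB = 0
FAMILY_LN = 1
FAMILY_AS = 2
FAMILY_ES = 3


@njit(inline="always")
def _cell_ll(family, theta, a, b):
    """Log-likelihood kernel of one data cell at linear predictor theta.

    (a, b) = (y, n) for binomial-type families, (z, sigma2) for the
    Gaussian ones.  Constant terms are omitted.
    """
    if family == FAMILY_NB or family == FAMILY_ES:
        if theta > 0.0:
            sp = theta + math.log1p(math.exp(-theta))
        else:
            sp = math.log1p(math.exp(theta))
        return a * theta - b * sp
    d = a - theta
    return -0.5 * d * d / b


@njit(inline="always")
def _invlink(family, theta):
    """Prevalence from the linear predictor (clamped sine-square for AS)."""
    if family == FAMILY_AS:
        t = min(max(theta, 0.0), 1.5707963267948966)
        s = math.sin(t)
        return s * s
    if theta > 0.0:
        return 1.0 / (1.0 + math.exp(-theta))
    e = math.exp(theta)
    return e / (1.0 + e)


@njit(inline="always")
def _area_ll(family, k, off, beta0, betag, cell_group, d1, d2, area_ptr):
    s = 0.0
    for c in range(area_ptr[k], area_ptr[k + 1]):
        s += _cell_ll(family, beta0 + betag[cell_group[c]] + off, d1[c], d2[c])
    return s


@njit(inline="always")
def _total_ll(family, beta0, betag, u, v, cell_area, cell_group, d1, d2):
    s = 0.0
    for c in range(d1.shape[0]):
        a = cell_area[c]
        s += _cell_ll(
            family, beta0 + betag[cell_group[c]] + u[a] + v[a], d1[c], d2[c]
        )
    return s


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    burn,
    thin,
    family,
    has_u,
    has_v,
    has_cov,
    K,
    G,
    cell_area,
    cell_group,
    d1,
    d2,
    area_ptr,
    group_ptr,
    group_cells,
    in_sample,
    nbr_ptr,
    nbr_idx,
    m,
    comp,
    edges,
    n_comp,
    rank_v,
    a_prec,
    b_prec,
    fix_u,
    tau_u0,
    fix_v,
    tau_v0,
    pi,
    beta0_init,
    p_out,
    pg_out,
    store_pg,
    u_out,
    v_out,
    beta_out,
    hyper_out,
    acc_out,
):
    np.random.seed(seed)
    n_cells = d1.shape[0]
    u = np.zeros(K)
    v = np.zeros(K)
    betag = np.zeros(G)
    beta0 = beta0_init
    tau_u = tau_u0 if fix_u else 10.0
    tau_v = tau_v0 if fix_v else 10.0

    sv = np.full(K, 0.5)
    su = np.full(K, 0.5)
    sb0 = 0.1
    sbg = np.full(G, 0.2)
    ssh = 0.3
    acc_v = np.zeros(K)
    acc_u = np.zeros(K)
    acc_b0 = 0.0
    acc_bg = np.zeros(G)
    acc_sh = 0.0
    tot_acc_v = 0.0
    tot_acc_u = 0.0
    tot_acc_b0 = 0.0
    batch = 0
    n_ret = 0

    for it in range(n_iter):
        # ---- structured field v -------------------------------------
        if has_v:
            for k in range(K):
                if m[k] == 0:
                    continue
                nsum = 0.0
                for jj in range(nbr_ptr[k], nbr_ptr[k + 1]):
                    nsum += v[nbr_idx[jj]]
                if in_sample[k]:
                    prop = v[k] + sv[k] * np.random.normal()
                    dpri = -0.5 * tau_v * (
                        (m[k] * prop * prop - 2.0 * prop * nsum)
                        - (m[k] * v[k] * v[k] - 2.0 * v[k] * nsum)
                    )
                    dll = _area_ll(family, k, u[k] + prop, beta0, betag,
                                   cell_group, d1, d2, area_ptr) - _area_ll(
                        family, k, u[k] + v[k], beta0, betag,
                        cell_group, d1, d2, area_ptr)
                    if math.log(np.random.rand()) < dpri + dll:
                        v[k] = prop
                        acc_v[k] += 1.0
                else:
                    v[k] = nsum / m[k] + np.random.normal() / math.sqrt(tau_v * m[k])
            # sum-to-zero per component; absorb mean shift into beta0
            csum = np.zeros(n_comp)
            ccnt = np.zeros(n_comp)
            for k in range(K):
                if m[k] > 0:
                    csum[comp[k]] += v[k]
                    ccnt[comp[k]] += 1.0
            shift_total = 0.0
            for k in range(K):
                if m[k] > 0:
                    mu = csum[comp[k]] / ccnt[comp[k]]
                    v[k] -= mu
                    shift_total += mu
            beta0 += shift_total / K

        # ---- unstructured field u -----------------------------------
        if has_u:
            sd_u = 1.0 / math.sqrt(tau_u)
            for k in range(K):
                if in_sample[k]:
                    prop = u[k] + su[k] * np.random.normal()
                    dpri = -0.5 * tau_u * (prop * prop - u[k] * u[k])
                    dll = _area_ll(family, k, prop + v[k], beta0, betag,
                                   cell_group, d1, d2, area_ptr) - _area_ll(
                        family, k, u[k] + v[k], beta0, betag,
                        cell_group, d1, d2, area_ptr)
                    if math.log(np.random.rand()) < dpri + dll:
                        u[k] = prop
                        acc_u[k] += 1.0
                else:
                    u[k] = sd_u * np.random.normal()

        # ---- intercept ----------------------------------------------
        prop = beta0 + sb0 * np.random.normal()
        dll = 0.0
        for c in range(n_cells):
            a_ = cell_area[c]
            base = betag[cell_group[c]] + u[a_] + v[a_]
            dll += _cell_ll(family, prop + base, d1[c], d2[c]) - _cell_ll(
                family, beta0 + base, d1[c], d2[c])
        if math.log(np.random.rand()) < dll:
            beta0 = prop
            acc_b0 += 1.0

        # ---- covariate offsets --------------------------------------
        if has_cov:
            for g in range(1, G):
                propg = betag[g] + sbg[g] * np.random.normal()
                dll = 0.0
                for ii in range(group_ptr[g], group_ptr[g + 1]):
                    c = group_cells[ii]
                    a_ = cell_area[c]
                    base = beta0 + u[a_] + v[a_]
                    dll += _cell_ll(family, base + propg, d1[c], d2[c]) - _cell_ll(
                        family, base + betag[g], d1[c], d2[c])
                if math.log(np.random.rand()) < dll:
                    betag[g] = propg
                    acc_bg[g] += 1.0

        # ---- intercept/field shift move -----------------------------
        if has_u:
            delta = ssh * np.random.normal()
            usum = 0.0
            for k in range(K):
                usum += u[k]
            dpri = -0.5 * tau_u * (K * delta * delta - 2.0 * delta * usum)
            if math.log(np.random.rand()) < dpri:
                beta0 += delta
                for k in range(K):
                    u[k] -= delta
                acc_sh += 1.0

        # ---- variance components ------------------------------------
        if has_u and not fix_u:
            ssq = 0.0
            for k in range(K):
                ssq += u[k] * u[k]
            tau_u = np.random.gamma(a_prec + 0.5 * K, 1.0 / (b_prec + 0.5 * ssq))
        if has_v and not fix_v and rank_v > 0:
            ssq = 0.0
            for e in range(edges.shape[0]):
                d_ = v[edges[e, 0]] - v[edges[e, 1]]
                ssq += d_ * d_
            tau_v = np.random.gamma(a_prec + 0.5 * rank_v, 1.0 / (b_prec + 0.5 * ssq))

        # ---- joint scale moves (field, precision) -------------------
        # (u, tau_u) -> (c u, tau_u / c^2) keeps u/sigma_u fixed, which
        # decorrelates the field from its variance when sigma_u ~ 0;
        # same for (v, tau_v).  log-accept = dloglik - 2a ln c
        # - b tau (c^-2 - 1) after the prior and Jacobian terms cancel.
        if has_u and not fix_u:
            lc = 0.4 * np.random.normal()
            c_ = math.exp(lc)
            ll0 = _total_ll(family, beta0, betag, u, v, cell_area, cell_group, d1, d2)
            for k in range(K):
                u[k] *= c_
            ll1 = _total_ll(family, beta0, betag, u, v, cell_area, cell_group, d1, d2)
            lacc = ll1 - ll0 - 2.0 * a_prec * lc - b_prec * tau_u * (1.0 / (c_ * c_) - 1.0)
            if math.log(np.random.rand()) < lacc:
                tau_u = tau_u / (c_ * c_)
            else:
                for k in range(K):
                    u[k] /= c_
        if has_v and not fix_v and rank_v > 0:
            lc = 0.4 * np.random.normal()
            c_ = math.exp(lc)
            ll0 = _total_ll(family, beta0, betag, u, v, cell_area, cell_group, d1, d2)
            for k in range(K):
                v[k] *= c_
            ll1 = _total_ll(family, beta0, betag, u, v, cell_area, cell_group, d1, d2)
            lacc = ll1 - ll0 - 2.0 * a_prec * lc - b_prec * tau_v * (1.0 / (c_ * c_) - 1.0)
            if math.log(np.random.rand()) < lacc:
                tau_v = tau_v / (c_ * c_)
            else:
                for k in range(K):
                    v[k] /= c_

        # ---- burn-in adaptation -------------------------------------
        batch += 1
        if batch == 50:
            if it < burn:
                for k in range(K):
                    sv[k] *= math.exp(min(max(acc_v[k] / 50.0 - 0.44, -0.5), 0.5))
                    su[k] *= math.exp(min(max(acc_u[k] / 50.0 - 0.44, -0.5), 0.5))
                sb0 *= math.exp(min(max(acc_b0 / 50.0 - 0.44, -0.5), 0.5))
                ssh *= math.exp(min(max(acc_sh / 50.0 - 0.44, -0.5), 0.5))
                for g in range(G):
                    sbg[g] *= math.exp(min(max(acc_bg[g] / 50.0 - 0.44, -0.5), 0.5))
            else:
                for k in range(K):
                    tot_acc_v += acc_v[k]
                    tot_acc_u += acc_u[k]
                tot_acc_b0 += acc_b0
            for k in range(K):
                acc_v[k] = 0.0
                acc_u[k] = 0.0
            acc_b0 = 0.0
            acc_sh = 0.0
            for g in range(G):
                acc_bg[g] = 0.0
            batch = 0

        # ---- record --------------------------------------------------
        if it >= burn and (it - burn) % thin == 0:
            t = n_ret
            for k in range(K):
                acc = 0.0
                for g in range(G):
                    acc += pi[g, k] * _invlink(family, beta0 + betag[g] + u[k] + v[k])
                p_out[t, k] = acc
                u_out[t, k] = u[k]
                v_out[t, k] = v[k]
            if store_pg:
                for g in range(G):
                    for k in range(K):
                        pg_out[t, g, k] = _invlink(
                            family, beta0 + betag[g] + u[k] + v[k])
            for g in range(G):
                beta_out[t, g] = betag[g]
            hyper_out[t, 0] = beta0
            hyper_out[t, 1] = 1.0 / tau_u if has_u else np.nan
            hyper_out[t, 2] = 1.0 / tau_v if has_v else np.nan
            n_ret += 1

    denom = max(n_iter - burn, 1) * max(K, 1)
    acc_out[0] = tot_acc_v / denom
    acc_out[1] = tot_acc_u / denom
    acc_out[2] = tot_acc_b0 / max(n_iter - burn, 1)
    return n_ret
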