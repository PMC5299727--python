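"""Numba inner loops for the Metropolis-within-Gibbs sampler.

The sampler's cost is dominated by single-column likelihood deltas: a
proposal for alpha_j or beta_pj perturbs one column of the concentration
matrix, and the change in DM log-likelihood involves only the taxon-j
terms and the row-total terms, each O(n).  These loops are compiled with
numba; all randomness is pre-generated by the caller (numpy Generator) so
that chains are bit-reproducible given a seed.

Cached quantities carried between sweeps (kept exactly in sync by the
accept branches):

* ``Z``       n x J linear predictors zeta_ij
* ``G``       n x J concentrations exp(clip(zeta))
* ``rowsum``  per-sample gamma totals
* ``colterm`` per-taxon sums of lgamma(y_ij + g_ij) - lgamma(g_ij)
* ``S1``      sum_i [lgamma(rowsum_i) - lgamma(y_i+ + rowsum_i)]
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: lower bound on the adapted proposal variance sigma-hat^2
VAR_FLOOR = 1e-6

#: clip bound on linear predictors (mirrors model.Z_MAX)
Z_MAX = 50.0

LOG_SQRT_2PI = 0.9189385332046727


@njit(cache=True)
def _norm_logpdf(x: float, var: float) -> float:
    return -LOG_SQRT_2PI - 0.5 * math.log(var) - x * x / (2.0 * var)


@njit(cache=True)
def _mix_logpdf(x: float, v_adapt: float, v_fixed: float, mix_w: float) -> float:
    """Log density of the two-component normal proposal mixture at x."""
    la = _norm_logpdf(x, v_adapt) + math.log(mix_w)
    lf = _norm_logpdf(x, v_fixed) + math.log(1.0 - mix_w)
    hi = la if la > lf else lf
    return hi + math.log(math.exp(la - hi) + math.exp(lf - hi))


@njit(cache=True)
def _column_delta(
    Z, G, rowsum, colterm, S1, Yf, ysum, j, dz_col, use_likelihood,
    new_g, new_rs,
):
    """Log-likelihood change for zeta[:, j] += dz_col.

    Fills ``new_g`` and ``new_rs`` with the proposed column of G and the
    proposed row sums, and returns (delta_ll, S1_new, colterm_j_new).
    """
    n = Z.shape[0]
    if not use_likelihood:
        for i in range(n):
            z_new = Z[i, j] + dz_col[i]
            if z_new > Z_MAX:
                z_new = Z_MAX
            elif z_new < -Z_MAX:
                z_new = -Z_MAX
            g_new = math.exp(z_new)
            new_g[i] = g_new
            new_rs[i] = rowsum[i] - G[i, j] + g_new
        return 0.0, S1, colterm[j]
    s1_new = 0.0
    ct_new = 0.0
    for i in range(n):
        z_new = Z[i, j] + dz_col[i]
        if z_new > Z_MAX:
            z_new = Z_MAX
        elif z_new < -Z_MAX:
            z_new = -Z_MAX
        g_new = math.exp(z_new)
        new_g[i] = g_new
        rs = rowsum[i] - G[i, j] + g_new
        new_rs[i] = rs
        s1_new += math.lgamma(rs) - math.lgamma(ysum[i] + rs)
        y = Yf[i, j]
        if y > 0.0:
            ct_new += math.lgamma(y + g_new) - math.lgamma(g_new)
    delta = (s1_new - S1) + (ct_new - colterm[j])
    return delta, s1_new, ct_new


@njit(cache=True)
def alpha_sweep(
    alpha, Z, G, rowsum, colterm, S1, Yf, ysum, s2,
    z_prop, log_u, t_alpha, use_likelihood,
):
    """One random-walk Metropolis sweep over the intercepts.

    Returns (S1, n_accept).  Mutates alpha and the likelihood caches in
    place.
    """
    n, J = G.shape
    new_g = np.empty(n)
    new_rs = np.empty(n)
    dz = np.empty(n)
    n_acc = 0
    for j in range(J):
        da = t_alpha * z_prop[j]
        if da == 0.0:
            n_acc += 1
            continue
        for i in range(n):
            dz[i] = da
        delta_ll, s1_new, ct_new = _column_delta(
            Z, G, rowsum, colterm, S1, Yf, ysum, j, dz, use_likelihood,
            new_g, new_rs,
        )
        a_new = alpha[j] + da
        delta_prior = (alpha[j] * alpha[j] - a_new * a_new) / (2.0 * s2[j])
        log_r = delta_ll + delta_prior
        if not math.isfinite(log_r):
            continue
        if log_u[j] < log_r:
            alpha[j] = a_new
            for i in range(n):
                Z[i, j] += da
                G[i, j] = new_g[i]
                rowsum[i] = new_rs[i]
            S1 = s1_new
            colterm[j] = ct_new
            n_acc += 1
    return S1, n_acc


@njit(cache=True)
def beta_xi_sweep(
    beta, xi, Z, G, rowsum, colterm, S1, Yf, ysum, X, r2,
    log_m_ratio, v_adapt_eff, v_fixed, mix_w,
    scan_p, scan_j, z_prop, log_u, mix_u, use_likelihood,
):
    """One joint (xi, beta) Gibbs scan with add/delete Metropolis moves.

    The scan visits the (p, j) pairs in the order given by ``scan_p`` /
    ``scan_j`` (default: for each taxon j, covariates p = 1..P in turn).
    An included coefficient receives a delete proposal (xi, beta) ->
    (0, 0); an excluded one an add proposal with beta' drawn from the
    adaptive two-component normal mixture centred at zero.
    ``v_adapt_eff`` holds the per-coefficient adapted proposal variances
    (already scaled and floored by the caller).

    Returns (S1, n_add_acc, n_add_prop, n_del_acc, n_del_prop,
    n_nonfinite).  Mutates beta, xi and the caches in place.
    """
    n = G.shape[0]
    new_g = np.empty(n)
    new_rs = np.empty(n)
    dz = np.empty(n)
    n_add_acc = 0
    n_add_prop = 0
    n_del_acc = 0
    n_del_prop = 0
    n_nonfin = 0
    for k in range(scan_p.shape[0]):
        p = scan_p[k]
        j = scan_j[k]
        v_adapt = v_adapt_eff[p, j]
        if xi[p, j] == 1:
            # delete move: propose (0, 0)
            n_del_prop += 1
            b_cur = beta[p, j]
            dbeta = -b_cur
            for i in range(n):
                dz[i] = dbeta * X[i, p]
            delta_ll, s1_new, ct_new = _column_delta(
                Z, G, rowsum, colterm, S1, Yf, ysum, j, dz,
                use_likelihood, new_g, new_rs,
            )
            log_r = (
                delta_ll
                - _norm_logpdf(b_cur, r2[j])
                - log_m_ratio
                + _mix_logpdf(b_cur, v_adapt, v_fixed, mix_w)
            )
            if not math.isfinite(log_r):
                n_nonfin += 1
                continue
            if log_u[p, j] < log_r:
                beta[p, j] = 0.0
                xi[p, j] = 0
                for i in range(n):
                    Z[i, j] += dz[i]
                    G[i, j] = new_g[i]
                    rowsum[i] = new_rs[i]
                S1 = s1_new
                colterm[j] = ct_new
                n_del_acc += 1
        else:
            # add move: propose xi' = 1 with beta' from the mixture
            n_add_prop += 1
            if mix_u[p, j] < mix_w:
                sd = math.sqrt(v_adapt)
            else:
                sd = math.sqrt(v_fixed)
            b_new = sd * z_prop[p, j]
            for i in range(n):
                dz[i] = b_new * X[i, p]
            delta_ll, s1_new, ct_new = _column_delta(
                Z, G, rowsum, colterm, S1, Yf, ysum, j, dz,
                use_likelihood, new_g, new_rs,
            )
            log_r = (
                delta_ll
                + _norm_logpdf(b_new, r2[j])
                + log_m_ratio
                - _mix_logpdf(b_new, v_adapt, v_fixed, mix_w)
            )
            if not math.isfinite(log_r):
                n_nonfin += 1
                continue
            if log_u[p, j] < log_r:
                beta[p, j] = b_new
                xi[p, j] = 1
                for i in range(n):
                    Z[i, j] += dz[i]
                    G[i, j] = new_g[i]
                    rowsum[i] = new_rs[i]
                S1 = s1_new
                colterm[j] = ct_new
                n_add_acc += 1
    return S1, n_add_acc, n_add_prop, n_del_acc, n_del_prop, n_nonfin


@njit(cache=True)
def refresh_sweep(
    beta, xi, Z, G, rowsum, colterm, S1, Yf, ysum, X, r2,
    v_adapt_eff, v_fixed, mix_w, z_prop, log_u, mix_u, use_likelihood,
):
    """Within-model Metropolis refresh of the included coefficients.

    For each (p, j) with xi = 1, proposes beta' = beta + e with e drawn
    from the zero-centred two-component normal mixture; the mixture is
    an even function of the step, so the proposal is symmetric and the
    acceptance ratio involves only the likelihood and slab-prior change.
    Excluded coefficients are untouched, so the scan leaves the model
    (xi) invariant.

    Returns (S1, n_acc, n_prop).  Mutates beta and the caches in place.
    """
    n, J = G.shape
    P = beta.shape[0]
    new_g = np.empty(n)
    new_rs = np.empty(n)
    dz = np.empty(n)
    n_acc = 0
    n_prop = 0
    for j in range(J):
        for p in range(P):
            if xi[p, j] == 0:
                continue
            n_prop += 1
            if mix_u[p, j] < mix_w:
                sd = math.sqrt(v_adapt_eff[p, j])
            else:
                sd = math.sqrt(v_fixed)
            step = sd * z_prop[p, j]
            b_cur = beta[p, j]
            b_new = b_cur + step
            for i in range(n):
                dz[i] = step * X[i, p]
            delta_ll, s1_new, ct_new = _column_delta(
                Z, G, rowsum, colterm, S1, Yf, ysum, j, dz,
                use_likelihood, new_g, new_rs,
            )
            log_r = delta_ll + (b_cur * b_cur - b_new * b_new) / (2.0 * r2[j])
            if not math.isfinite(log_r):
                continue
            if log_u[p, j] < log_r:
                beta[p, j] = b_new
                for i in range(n):
                    Z[i, j] += dz[i]
                    G[i, j] = new_g[i]
                    rowsum[i] = new_rs[i]
                S1 = s1_new
                colterm[j] = ct_new
                n_acc += 1
    return S1, n_acc, n_prop


@njit(cache=True)
def welford_update(mean, m2, count, beta, xi):
    """Recursive mean/variance update with the post-scan included values.

    Only coefficients currently in the model (xi = 1) contribute: the
    estimate targets the slab-conditional variance of beta_pj, which is
    the scale an add proposal must cover.  Folding in the zeros of
    excluded sweeps would drive the estimate to zero for rarely included
    coefficients and freeze their add moves.
    """
    P, J = beta.shape
    for j in range(J):
        for p in range(P):
            if xi[p, j] == 1:
                count[p, j] += 1
                d = beta[p, j] - mean[p, j]
                mean[p, j] += d / count[p, j]
                m2[p, j] += d * (beta[p, j] - mean[p, j])
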