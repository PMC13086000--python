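"""Numba-compiled block-wise NUTS / MMNUTS sampler for the 4PNO model.

Same algorithm as :mod:`nuts4pno.nuts`, specialized to the item-response
posterior so that a full-size fit (thousands of examinees, K = 2000
iterations, several chains) runs in minutes on one core.  Each sweep
updates every examinee's ability as a 1-D NUTS block and every item's
unconstrained parameter vector (alpha*, beta, gamma, varsigma) as an
npar-D block, with per-block dual-averaged step sizes.

The ``mm`` flag switches the gradient route: 0 uses the direct
observed-data score, 1 the mixture-model expected score with the
responsibility z^E recomputed at every gradient evaluation.  The two are
equal by the Fisher identity, so both samplers target the same posterior;
the test suite checks their agreement explicitly.

The recursive tree functions mirror the reference implementation but are
cross-checked statistically rather than stream-for-stream (numba's RNG
stream differs from numpy Generators).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_INVSQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)
_FLOOR = 1e-12


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _ncdf(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True, inline="always")
def _npdf(x):
    return math.exp(-0.5 * x * x) * _INVSQRT2PI


@njit(cache=True, inline="always")
def _clamp(p):
    if p < _FLOOR:
        return _FLOOR
    if p > 1.0 - _FLOOR:
        return 1.0 - _FLOOR
    return p


@njit(cache=True, inline="always")
def _invlogit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# --------------------------------------------------------------------------
# log posterior + gradient, item block
# --------------------------------------------------------------------------

@njit(cache=True)
def _item_lp_grad(w, theta, y, mu, var, npar, mm):
    alpha = math.exp(w[0])
    beta = w[1]
    g = _invlogit(w[2]) if npar >= 3 else 0.0
    s = _invlogit(w[3]) if npar >= 4 else 0.0
    span = 1.0 - s - g
    lp = 0.0
    g0 = 0.0
    g1 = 0.0
    g2 = 0.0
    g3 = 0.0
    for i in range(theta.shape[0]):
        eta = alpha * theta[i] - beta
        ps = _ncdf(eta)
        p = _clamp(g + span * ps)
        yi = y[i]
        lp += yi * math.log(p) + (1.0 - yi) * math.log(1.0 - p)
        dens = _npdf(eta)
        if mm == 1:
            ze = yi * (1.0 - s) * ps / p + (1.0 - yi) * s * ps / (1.0 - p)
            psc = _clamp(ps)
            ratio = (ze - ps) / (psc * (1.0 - psc))
            g0 += ratio * alpha * theta[i] * dens
            g1 -= ratio * dens
            if npar >= 3:
                g2 += (yi - g) * (1.0 - ze)
            if npar >= 4:
                g3 += (1.0 - yi - s) * ze
        else:
            resid = (yi - p) / (p * (1.0 - p))
            g0 += resid * span * theta[i] * alpha * dens
            g1 -= resid * span * dens
            if npar >= 3:
                g2 += resid * (1.0 - ps) * g * (1.0 - g)
            if npar >= 4:
                g3 -= resid * ps * s * (1.0 - s)
    grad = np.zeros(4)
    grad[0] = g0
    grad[1] = g1
    if npar >= 3:
        grad[2] = g2
    if npar >= 4:
        grad[3] = g3
    for d in range(npar):
        lp += -0.5 * math.log(2.0 * math.pi * var[d]) \
              - 0.5 * (w[d] - mu[d]) ** 2 / var[d]
        grad[d] -= (w[d] - mu[d]) / var[d]
    return lp, grad


# --------------------------------------------------------------------------
# log posterior + gradient, one ability
# --------------------------------------------------------------------------

@njit(cache=True)
def _ability_lp_grad(th, a, b, g, s, y, mu_th, var_th, mm):
    lp = 0.0
    gr = 0.0
    for j in range(a.shape[0]):
        eta = a[j] * th - b[j]
        ps = _ncdf(eta)
        span = 1.0 - s[j] - g[j]
        p = _clamp(g[j] + span * ps)
        yj = y[j]
        lp += yj * math.log(p) + (1.0 - yj) * math.log(1.0 - p)
        dens = _npdf(eta)
        if mm == 1:
            ze = yj * (1.0 - s[j]) * ps / p + (1.0 - yj) * s[j] * ps / (1.0 - p)
            psc = _clamp(ps)
            gr += (ze - ps) / (psc * (1.0 - psc)) * a[j] * dens
        else:
            gr += (yj - p) / (p * (1.0 - p)) * span * a[j] * dens
    lp += -0.5 * math.log(2.0 * math.pi * var_th) - 0.5 * (th - mu_th) ** 2 / var_th
    gr -= (th - mu_th) / var_th
    return lp, gr


# --------------------------------------------------------------------------
# item-block NUTS
# --------------------------------------------------------------------------

@njit(cache=True)
def _leap_item(pos, r, grad, eps, dirn, theta, y, mu, var, npar, mm):
    h = dirn * eps
    r1 = r + 0.5 * h * grad
    p1 = pos + h * r1
    lp, g1 = _item_lp_grad(p1, theta, y, mu, var, npar, mm)
    r2 = r1 + 0.5 * h * g1
    return p1, r2, g1, lp


@njit(cache=True)
def _xi(lp, r):
    k = 0.0
    for d in range(r.shape[0]):
        k += r[d] * r[d]
    return lp - 0.5 * k


@njit(cache=True)
def _find_eps_item(pos, theta, y, mu, var, npar, mm):
    lp0, gr0 = _item_lp_grad(pos, theta, y, mu, var, npar, mm)
    r = np.zeros(4)
    for d in range(npar):
        r[d] = np.random.normal()
    xi0 = _xi(lp0, r)
    eps = 1.0
    _, r1, _, lp1 = _leap_item(pos, r, gr0, eps, 1.0, theta, y, mu, var, npar, mm)
    dxi = _xi(lp1, r1) - xi0
    rho = 1.0 if dxi > math.log(0.5) else -1.0
    for _ in range(50):
        # continue while Omega^rho > 2^-rho, i.e. rho*dxi > -rho*ln 2
        if not rho * dxi > -rho * math.log(2.0):
            break
        eps *= 2.0 ** rho
        _, r1, _, lp1 = _leap_item(pos, r, gr0, eps, 1.0, theta, y, mu, var, npar, mm)
        dxi = _xi(lp1, r1) - xi0
    return eps


@njit(cache=True)
def _bt_item(dirn, pos, r, grad, u0, xi0, depth, eps, theta, y, mu, var,
             npar, mm, delta_max):
    if depth == 0:
        p1, r1, g1, lp1 = _leap_item(pos, r, grad, eps, dirn, theta, y, mu,
                                     var, npar, mm)
        xi1 = _xi(lp1, r1)
        n_b = 1 if u0 < xi1 else 0
        div = 1 if (u0 - delta_max) >= xi1 else 0
        d = xi1 - xi0
        lam_a = 1.0 if d >= 0.0 else math.exp(d)
        return (p1, r1, g1, p1, r1, g1, p1, g1, lp1, n_b, div, lam_a, 1.0, div)

    res = _bt_item(dirn, pos, r, grad, u0, xi0, depth - 1, eps, theta, y,
                   mu, var, npar, mm, delta_max)
    (mp, mr, mg, pp, pr, pg, prop, propg, proplp, n_b, stop, lam_a, lam_b,
     div) = res
    if stop == 1:
        return res
    if dirn < 0.0:
        res2 = _bt_item(dirn, mp, mr, mg, u0, xi0, depth - 1, eps, theta, y,
                        mu, var, npar, mm, delta_max)
        mp, mr, mg = res2[0], res2[1], res2[2]
    else:
        res2 = _bt_item(dirn, pp, pr, pg, u0, xi0, depth - 1, eps, theta, y,
                        mu, var, npar, mm, delta_max)
        pp, pr, pg = res2[3], res2[4], res2[5]
    n_b2 = res2[9]
    total = n_b + n_b2
    x = np.random.random()
    if total > 0 and x < n_b2 / total:
        prop, propg, proplp = res2[6], res2[7], res2[8]
    sm = 0.0
    sp = 0.0
    for d in range(4):
        span = pp[d] - mp[d]
        sm += span * mr[d]
        sp += span * pr[d]
    uturn = 1 if (sm < 0.0 or sp < 0.0) else 0
    stop2 = 1 if (res2[10] == 1 or uturn == 1) else 0
    return (mp, mr, mg, pp, pr, pg, prop, propg, proplp,
            total, stop2, lam_a + res2[11], lam_b + res2[12],
            1 if (div == 1 or res2[13] == 1) else 0)


@njit(cache=True)
def _nuts_item(pos, eps, theta, y, mu, var, npar, mm, max_depth, delta_max):
    lp0, gr0 = _item_lp_grad(pos, theta, y, mu, var, npar, mm)
    r0 = np.zeros(4)
    for d in range(npar):
        r0[d] = np.random.normal()
    xi0 = _xi(lp0, r0)
    u0 = xi0 - np.random.exponential()

    mp = pos.copy()
    mr = r0.copy()
    mg = gr0.copy()
    pp = pos.copy()
    pr = r0.copy()
    pg = gr0.copy()
    prop = pos.copy()
    n_a = 1
    lam_a = 0.0
    lam_b = 0.0
    depth = 0
    diverged = 0
    while depth < max_depth:
        dirn = -1.0 if np.random.random() < 0.5 else 1.0
        if dirn < 0.0:
            res = _bt_item(dirn, mp, mr, mg, u0, xi0, depth, eps, theta, y,
                           mu, var, npar, mm, delta_max)
            mp, mr, mg = res[0], res[1], res[2]
        else:
            res = _bt_item(dirn, pp, pr, pg, u0, xi0, depth, eps, theta, y,
                           mu, var, npar, mm, delta_max)
            pp, pr, pg = res[3], res[4], res[5]
        x = np.random.random()
        if res[10] == 0 and x < res[9] / n_a:
            prop = res[6]
        n_a += res[9]
        lam_a += res[11]
        lam_b += res[12]
        depth += 1
        sm = 0.0
        sp = 0.0
        for d in range(4):
            span = pp[d] - mp[d]
            sm += span * mr[d]
            sp += span * pr[d]
        if res[10] == 1 or sm < 0.0 or sp < 0.0:
            diverged = res[13]
            break
    lam_c = lam_a / lam_b if lam_b > 0.0 else 0.0
    return prop, lam_c, diverged


# --------------------------------------------------------------------------
# ability-block NUTS (scalar state)
# --------------------------------------------------------------------------

@njit(cache=True)
def _leap_th(th, r, grad, eps, dirn, a, b, g, s, y, mu_th, var_th, mm):
    h = dirn * eps
    r1 = r + 0.5 * h * grad
    t1 = th + h * r1
    lp, g1 = _ability_lp_grad(t1, a, b, g, s, y, mu_th, var_th, mm)
    r2 = r1 + 0.5 * h * g1
    return t1, r2, g1, lp


@njit(cache=True)
def _find_eps_th(th, a, b, g, s, y, mu_th, var_th, mm):
    lp0, gr0 = _ability_lp_grad(th, a, b, g, s, y, mu_th, var_th, mm)
    r = np.random.normal()
    xi0 = lp0 - 0.5 * r * r
    eps = 1.0
    t1, r1, _, lp1 = _leap_th(th, r, gr0, eps, 1.0, a, b, g, s, y, mu_th, var_th, mm)
    dxi = (lp1 - 0.5 * r1 * r1) - xi0
    rho = 1.0 if dxi > math.log(0.5) else -1.0
    for _ in range(50):
        if not rho * dxi > -rho * math.log(2.0):
            break
        eps *= 2.0 ** rho
        t1, r1, _, lp1 = _leap_th(th, r, gr0, eps, 1.0, a, b, g, s, y, mu_th, var_th, mm)
        dxi = (lp1 - 0.5 * r1 * r1) - xi0
    return eps


@njit(cache=True)
def _bt_th(dirn, th, r, grad, u0, xi0, depth, eps, a, b, g, s, y,
           mu_th, var_th, mm, delta_max):
    if depth == 0:
        t1, r1, g1, lp1 = _leap_th(th, r, grad, eps, dirn, a, b, g, s, y,
                                   mu_th, var_th, mm)
        xi1 = lp1 - 0.5 * r1 * r1
        n_b = 1 if u0 < xi1 else 0
        div = 1 if (u0 - delta_max) >= xi1 else 0
        d = xi1 - xi0
        lam_a = 1.0 if d >= 0.0 else math.exp(d)
        return (t1, r1, g1, t1, r1, g1, t1, n_b, div, lam_a, 1.0, div)

    res = _bt_th(dirn, th, r, grad, u0, xi0, depth - 1, eps, a, b, g, s, y,
                 mu_th, var_th, mm, delta_max)
    (mt, mr, mg, pt, pr, pg, prop, n_b, stop, lam_a, lam_b, div) = res
    if stop == 1:
        return res
    if dirn < 0.0:
        res2 = _bt_th(dirn, mt, mr, mg, u0, xi0, depth - 1, eps, a, b, g, s,
                      y, mu_th, var_th, mm, delta_max)
        mt, mr, mg = res2[0], res2[1], res2[2]
    else:
        res2 = _bt_th(dirn, pt, pr, pg, u0, xi0, depth - 1, eps, a, b, g, s,
                      y, mu_th, var_th, mm, delta_max)
        pt, pr, pg = res2[3], res2[4], res2[5]
    n_b2 = res2[7]
    total = n_b + n_b2
    x = np.random.random()
    if total > 0 and x < n_b2 / total:
        prop = res2[6]
    span = pt - mt
    uturn = 1 if (span * mr < 0.0 or span * pr < 0.0) else 0
    stop2 = 1 if (res2[8] == 1 or uturn == 1) else 0
    return (mt, mr, mg, pt, pr, pg, prop,
            total, stop2, lam_a + res2[9], lam_b + res2[10],
            1 if (div == 1 or res2[11] == 1) else 0)


@njit(cache=True)
def _nuts_th(th, eps, a, b, g, s, y, mu_th, var_th, mm, max_depth, delta_max):
    lp0, gr0 = _ability_lp_grad(th, a, b, g, s, y, mu_th, var_th, mm)
    r0 = np.random.normal()
    xi0 = lp0 - 0.5 * r0 * r0
    u0 = xi0 - np.random.exponential()

    mt = th
    mr = r0
    mg = gr0
    pt = th
    pr = r0
    pg = gr0
    prop = th
    n_a = 1
    lam_a = 0.0
    lam_b = 0.0
    depth = 0
    while depth < max_depth:
        dirn = -1.0 if np.random.random() < 0.5 else 1.0
        if dirn < 0.0:
            res = _bt_th(dirn, mt, mr, mg, u0, xi0, depth, eps, a, b, g, s,
                         y, mu_th, var_th, mm, delta_max)
            mt, mr, mg = res[0], res[1], res[2]
        else:
            res = _bt_th(dirn, pt, pr, pg, u0, xi0, depth, eps, a, b, g, s,
                         y, mu_th, var_th, mm, delta_max)
            pt, pr, pg = res[3], res[4], res[5]
        x = np.random.random()
        if res[8] == 0 and x < res[7] / n_a:
            prop = res[6]
        n_a += res[7]
        lam_a += res[9]
        lam_b += res[10]
        depth += 1
        span = pt - mt
        if res[8] == 1 or span * mr < 0.0 or span * pr < 0.0:
            break
    lam_c = lam_a / lam_b if lam_b > 0.0 else 0.0
    return prop, lam_c


# --------------------------------------------------------------------------
# full chain
# --------------------------------------------------------------------------

@njit(cache=True)
def _dual_update(H, iota, ln_ebar, k, lam_c, target, sqrt_k):
    lam = lam_c
    if lam < 0.0:
        lam = 0.0
    if lam > 1.0:
        lam = 1.0
    eta_a = 1.0 / (k + 10.0)
    eta_b = k ** -0.75
    H = (1.0 - eta_a) * H + eta_a * (target - lam)
    scale = (math.sqrt(k) if sqrt_k == 1 else k) / 0.05
    ln_eps = iota - scale * H
    ln_ebar = (1.0 - eta_b) * ln_ebar + eta_b * ln_eps
    return H, ln_ebar, math.exp(ln_eps)


@njit(cache=True)
def run_chain(Y, YT, theta0, w0, mu_item, var_item, mu_th, var_th,
              npar, mm, K, warmup, max_depth, delta_max, target, sqrt_k,
              seed):
    """One MCMC chain of the alternating block sampler.

    Y is (I, J) float64, YT its (J, I) transpose.  Returns post-warm-up
    item draws (kept, J, 4) on the unconstrained scale, running mean and
    M2 of theta, the final step sizes, and the post-warm-up divergence
    count.
    """
    np.random.seed(seed)
    I = Y.shape[0]
    J = Y.shape[1]
    theta = theta0.copy()
    w = w0.copy()

    a = np.empty(J)
    b = np.empty(J)
    gv = np.zeros(J)
    sv = np.zeros(J)
    for j in range(J):
        a[j] = math.exp(w[j, 0])
        b[j] = w[j, 1]
        if npar >= 3:
            gv[j] = _invlogit(w[j, 2])
        if npar >= 4:
            sv[j] = _invlogit(w[j, 3])

    # Part B: initial step sizes and dual-averaging state per block
    eps_th = np.empty(I)
    iota_th = np.empty(I)
    H_th = np.zeros(I)
    lnB_th = np.zeros(I)
    for i in range(I):
        eps_th[i] = _find_eps_th(theta[i], a, b, gv, sv, Y[i], mu_th, var_th, mm)
        iota_th[i] = math.log(10.0 * eps_th[i])
    eps_it = np.empty(J)
    iota_it = np.empty(J)
    H_it = np.zeros(J)
    lnB_it = np.zeros(J)
    for j in range(J):
        eps_it[j] = _find_eps_item(w[j], theta, YT[j], mu_item, var_item,
                                   npar, mm)
        iota_it[j] = math.log(10.0 * eps_it[j])

    kept = K - warmup
    draws_w = np.empty((kept, J, 4))
    th_mean = np.zeros(I)
    th_m2 = np.zeros(I)
    n_div = 0

    for k in range(1, K + 1):
        # ability sweep (item parameters fixed)
        for i in range(I):
            th_new, lam_c = _nuts_th(theta[i], eps_th[i], a, b, gv, sv,
                                     Y[i], mu_th, var_th, mm,
                                     max_depth, delta_max)
            theta[i] = th_new
            if k <= warmup:
                H_th[i], lnB_th[i], eps_new = _dual_update(
                    H_th[i], iota_th[i], lnB_th[i], k, lam_c, target, sqrt_k)
                eps_th[i] = math.exp(lnB_th[i]) if k == warmup else eps_new
        # item sweep (abilities fixed)
        for j in range(J):
            w_new, lam_c, div = _nuts_item(w[j], eps_it[j], theta, YT[j],
                                           mu_item, var_item, npar, mm,
                                           max_depth, delta_max)
            w[j] = w_new
            a[j] = math.exp(w[j, 0])
            b[j] = w[j, 1]
            if npar >= 3:
                gv[j] = _invlogit(w[j, 2])
            if npar >= 4:
                sv[j] = _invlogit(w[j, 3])
            if k <= warmup:
                H_it[j], lnB_it[j], eps_new = _dual_update(
                    H_it[j], iota_it[j], lnB_it[j], k, lam_c, target, sqrt_k)
                eps_it[j] = math.exp(lnB_it[j]) if k == warmup else eps_new
            elif div == 1:
                n_div += 1
        if k > warmup:
            idx = k - warmup - 1
            for j in range(J):
                for d in range(4):
                    draws_w[idx, j, d] = w[j, d]
            m = idx + 1.0
            for i in range(I):
                delta = theta[i] - th_mean[i]
                th_mean[i] += delta / m
                th_m2[i] += delta * (theta[i] - th_mean[i])
    return draws_w, th_mean, th_m2, eps_it, eps_th, n_div
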