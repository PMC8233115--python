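"""Numba-compiled NUTS kernel for the hierarchical outcome model.

Same algorithm as :mod:`lesionatoms.nuts` (multinomial NUTS, dual-averaging
step size, windowed diagonal mass adaptation) and same model density as
``LesionOutcomeModel.logp_and_grad``, fused into one compiled chain loop.
The recursive tree doubling is replaced by the equivalent iterative form:
within a subtree of 2**depth leapfrog steps, the U-turn checks of the
recursion correspond exactly to checks on the dyadic step intervals, which
are tracked with per-level checkpoints of the momentum and summed momentum.

The model is passed as a flat tuple so the whole chain compiles to one
nopython call:
``(Z, Zt, y, k, p_cov, clamped, s_l, s_r, s_e, inv_cov_sd2, inv_hyper2,
inv_noise2)`` — with ``clamped`` nonzero, the trailing scale block is fixed
at (s_l, s_r, s_e) and only the Gaussian location block is sampled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DIVERGENCE_THRESHOLD = 1000.0


@njit(cache=True)
def _logp_grad(q, mdl):
    Z, Zt, y, k, p_cov, clamped, c_sl, c_sr, c_se, inv_cov_sd2, inv_hyper2, inv_noise2 = mdl
    n = Z.shape[0]
    d = q.shape[0]
    m = 1 + 2 * k + p_cov
    alpha = q[0]
    tau = 0.0
    e_l = 0.0
    e_r = 0.0
    if clamped:
        s_l, s_r, s_e = c_sl, c_sr, c_se
    else:
        tau = np.exp(q[d - 4])
        e_l = np.exp(q[d - 3])
        e_r = np.exp(q[d - 2])
        s_l = tau * e_l
        s_r = tau * e_r
        s_e = np.exp(q[d - 1])

    theta = np.empty(m)
    theta[0] = alpha
    sumsq_b = 0.0
    for j in range(k):
        b = q[1 + j]
        theta[1 + j] = b * s_l
        sumsq_b += b * b
    for j in range(k):
        b = q[1 + k + j]
        theta[1 + k + j] = b * s_r
        sumsq_b += b * b
    sumsq_g = 0.0
    for j in range(p_cov):
        g = q[1 + 2 * k + j]
        theta[1 + 2 * k + j] = g
        sumsq_g += g * g

    r = y - np.dot(Z, theta)
    zr = np.dot(Zt, r)
    rss = np.dot(r, r)
    inv_se2 = 1.0 / (s_e * s_e)

    logp = (
        -0.5 * alpha * alpha
        - 0.5 * sumsq_b
        - 0.5 * sumsq_g * inv_cov_sd2
        - n * np.log(s_e)
        - 0.5 * rss * inv_se2
    )
    grad = np.empty(d)
    grad[0] = -alpha + zr[0] * inv_se2
    dot_bl = 0.0
    dot_br = 0.0
    for j in range(k):
        grad[1 + j] = -q[1 + j] + (s_l * inv_se2) * zr[1 + j]
        dot_bl += q[1 + j] * zr[1 + j]
    for j in range(k):
        grad[1 + k + j] = -q[1 + k + j] + (s_r * inv_se2) * zr[1 + k + j]
        dot_br += q[1 + k + j] * zr[1 + k + j]
    for j in range(p_cov):
        grad[1 + 2 * k + j] = (
            -q[1 + 2 * k + j] * inv_cov_sd2 + zr[1 + 2 * k + j] * inv_se2
        )
    if not clamped:
        lt = q[d - 4]
        ll = q[d - 3]
        lr = q[d - 2]
        le = q[d - 1]
        logp += (
            -0.5 * tau * tau * inv_hyper2
            + lt
            - 0.5 * (e_l * e_l + e_r * e_r)
            + ll
            + lr
            - 0.5 * s_e * s_e * inv_noise2
            + le
        )
        pull_l = (s_l * inv_se2) * dot_bl
        pull_r = (s_r * inv_se2) * dot_br
        grad[d - 4] = -tau * tau * inv_hyper2 + 1.0 + pull_l + pull_r
        grad[d - 3] = -e_l * e_l + 1.0 + pull_l
        grad[d - 2] = -e_r * e_r + 1.0 + pull_r
        grad[d - 1] = -s_e * s_e * inv_noise2 + 1.0 - n + rss * inv_se2
    return logp, grad


@njit(cache=True)
def _logaddexp(a, b):
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = a if a > b else b
    return m + np.log(np.exp(a - m) + np.exp(b - m))


@njit(cache=True)
def _kinetic(p, inv_mass):
    s = 0.0
    for i in range(p.shape[0]):
        s += p[i] * p[i] * inv_mass[i]
    return 0.5 * s


@njit(cache=True)
def _leapfrog(q, p, grad, eps, inv_mass, mdl):
    d = q.shape[0]
    p_half = np.empty(d)
    q1 = np.empty(d)
    for i in range(d):
        p_half[i] = p[i] + 0.5 * eps * grad[i]
        q1[i] = q[i] + eps * inv_mass[i] * p_half[i]
    logp1, grad1 = _logp_grad(q1, mdl)
    if np.isfinite(logp1):
        for i in range(d):
            p_half[i] += 0.5 * eps * grad1[i]
        h_new = -logp1 + _kinetic(p_half, inv_mass)
    else:
        logp1 = -np.inf
        h_new = np.inf
    return q1, p_half, grad1, logp1, h_new


@njit(cache=True)
def _uturn(rho, p_first, p_last, inv_mass):
    a = 0.0
    b = 0.0
    for i in range(rho.shape[0]):
        v = inv_mass[i] * rho[i]
        a += v * p_first[i]
        b += v * p_last[i]
    return a <= 0.0 or b <= 0.0


@njit(cache=True)
def _build_subtree(depth, q, p, grad, eps, inv_mass, h0, mdl, rng, max_depth):
    """Iterative subtree of 2**depth leapfrog steps from (q, p).

    Returns (status, edge state, subtree rho / weight / proposal,
    accept-stat sum, leaves evaluated); status 0 = ok, 1 = turning,
    2 = divergent.
    """
    d = q.shape[0]
    p_first = np.zeros((max_depth + 1, d))
    rho_ckpt = np.zeros((max_depth + 1, d))
    rho = np.zeros(d)
    log_sum_w = -np.inf
    sum_accept = 0.0
    leaves = 0
    logp = 0.0
    prop_q = q.copy()
    prop_logp = 0.0
    status = 0
    n_leaf = 1 << depth
    for i in range(n_leaf):
        q, p, grad, logp, h_new = _leapfrog(q, p, grad, eps, inv_mass, mdl)
        leaves += 1
        energy_error = h_new - h0
        if not np.isfinite(energy_error) or energy_error > _DIVERGENCE_THRESHOLD:
            status = 2
            break
        w = -energy_error
        sum_accept += np.exp(w) if w < 0.0 else 1.0
        if log_sum_w == -np.inf:
            log_sum_w = w
            prop_q = q.copy()
            prop_logp = logp
        else:
            log_sum_w = _logaddexp(log_sum_w, w)
            if np.log(rng.random()) < w - log_sum_w:
                prop_q = q.copy()
                prop_logp = logp
        # dyadic bookkeeping: level-l intervals start where i % 2**l == 0
        for level in range(1, depth + 1):
            if i % (1 << level) == 0:
                for j in range(d):
                    p_first[level, j] = p[j]
                    rho_ckpt[level, j] = rho[j]
        for j in range(d):
            rho[j] += p[j]
        turning = False
        for level in range(1, depth + 1):
            if (i + 1) % (1 << level) == 0:
                rho_int = np.empty(d)
                for j in range(d):
                    rho_int[j] = rho[j] - rho_ckpt[level, j]
                if _uturn(rho_int, p_first[level], p, inv_mass):
                    turning = True
                    break
        if turning:
            status = 1
            break
    return status, q, p, grad, logp, rho, log_sum_w, prop_q, prop_logp, sum_accept, leaves


@njit(cache=True)
def _find_initial_step(q, logp, grad, inv_mass, mdl, rng):
    d = q.shape[0]
    eps = 1.0
    p = np.empty(d)
    for i in range(d):
        p[i] = rng.standard_normal() / np.sqrt(inv_mass[i])
    h0 = -logp + _kinetic(p, inv_mass)
    _, _, _, _, h1 = _leapfrog(q, p, grad, eps, inv_mass, mdl)
    accept = np.exp(min(0.0, h0 - h1))
    direction = 1 if accept > 0.5 else -1
    for _ in range(60):
        eps *= 2.0**direction
        _, _, _, _, h1 = _leapfrog(q, p, grad, eps, inv_mass, mdl)
        accept = np.exp(min(0.0, h0 - h1))
        if (direction == 1 and accept <= 0.5) or (direction == -1 and accept >= 0.5):
            break
    if eps < 1e-8:
        eps = 1e-8
    if eps > 10.0:
        eps = 10.0
    return eps


@njit(cache=True)
def run_chain(mdl, q0, n_draws, n_warmup, window_ends, target_accept,
              max_treedepth, rng):
    """One NUTS chain; returns (draws, n_divergent, mean_accept, eps, mean_depth)."""
    q = q0.copy()
    logp, grad = _logp_grad(q, mdl)
    d = q.shape[0]
    inv_mass = np.ones(d)

    eps = _find_initial_step(q, logp, grad, inv_mass, mdl, rng)
    da_gamma, da_t0, da_kappa = 0.05, 10.0, 0.75
    mu = np.log(10.0 * eps)
    log_eps_bar = np.log(eps)
    h_bar = 0.0
    da_count = 0

    window_idx = 0
    init_buffer = 75
    w_n = 0
    w_mean = np.zeros(d)
    w_m2 = np.zeros(d)

    draws = np.empty((n_draws, d))
    n_divergent = 0
    sum_accept_stat = 0.0
    sum_depth = 0.0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p0 = np.empty(d)
        for i in range(d):
            p0[i] = rng.standard_normal() / np.sqrt(inv_mass[i])
        h0 = -logp + _kinetic(p0, inv_mass)

        q_left = q.copy()
        q_right = q.copy()
        p_left = p0.copy()
        p_right = p0.copy()
        g_left = grad.copy()
        g_right = grad.copy()
        q_prop = q.copy()
        logp_prop = logp
        log_sum_w = 0.0
        rho = p0.copy()
        sum_accept = 0.0
        n_leaves = 0
        divergent = False
        depth = 0
        while depth < max_treedepth:
            go_right = rng.random() < 0.5
            if go_right:
                (status, eq, ep, eg, elogp, s_rho, s_lsw, s_pq, s_plogp,
                 s_acc, s_leaves) = _build_subtree(
                    depth, q_right, p_right, g_right, eps, inv_mass, h0, mdl,
                    rng, max_treedepth,
                )
            else:
                (status, eq, ep, eg, elogp, s_rho, s_lsw, s_pq, s_plogp,
                 s_acc, s_leaves) = _build_subtree(
                    depth, q_left, p_left, g_left, -eps, inv_mass, h0, mdl,
                    rng, max_treedepth,
                )
            sum_accept += s_acc
            n_leaves += s_leaves
            if status == 2:
                divergent = True
                break
            if status == 1:
                break
            if np.log(rng.random()) < s_lsw - log_sum_w:
                q_prop = s_pq
                logp_prop = s_plogp
            log_sum_w = _logaddexp(log_sum_w, s_lsw)
            if go_right:
                q_right, p_right, g_right = eq, ep, eg
            else:
                q_left, p_left, g_left = eq, ep, eg
            for j in range(d):
                rho[j] += s_rho[j]
            depth += 1
            if _uturn(rho, p_left, p_right, inv_mass):
                break

        q = q_prop
        logp, grad = _logp_grad(q, mdl)
        accept_stat = sum_accept / max(n_leaves, 1)
        sum_depth += depth

        if warming:
            da_count += 1
            h_bar += (target_accept - accept_stat - h_bar) / (da_count + da_t0)
            log_eps = mu - np.sqrt(da_count) / da_gamma * h_bar
            eta = da_count**-da_kappa
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = np.exp(log_eps)

            if window_ends.shape[0] > 0 and it >= init_buffer and window_idx < window_ends.shape[0]:
                w_n += 1
                for j in range(d):
                    delta = q[j] - w_mean[j]
                    w_mean[j] += delta / w_n
                    w_m2[j] += delta * (q[j] - w_mean[j])
                if it + 1 == window_ends[window_idx]:
                    if w_n >= 10:
                        for j in range(d):
                            var = w_m2[j] / max(w_n - 1, 1)
                            im = var * (w_n / (w_n + 5.0)) + 1e-3 * (5.0 / (w_n + 5.0))
                            inv_mass[j] = im if im > 1e-10 else 1e-10
                    w_n = 0
                    for j in range(d):
                        w_mean[j] = 0.0
                        w_m2[j] = 0.0
                    eps = _find_initial_step(q, logp, grad, inv_mass, mdl, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar = np.log(eps)
                    h_bar = 0.0
                    da_count = 0
                    window_idx += 1
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = q
            if divergent:
                n_divergent += 1
            sum_accept_stat += accept_stat

    mean_accept = sum_accept_stat / max(n_draws, 1)
    mean_depth = sum_depth / (n_warmup + n_draws)
    return draws, n_divergent, mean_accept, eps, mean_depth


def make_model_tuple(model) -> tuple:
    """Flatten a LesionOutcomeModel into the kernel's model tuple."""
    clamp = model.clamp or {}
    return (
        model._Z,
        model._Zt,
        np.ascontiguousarray(model.y, dtype=np.float64),
        model.k,
        model.p,
        1 if model.clamp else 0,
        float(clamp.get("sigma_left", 0.0)),
        float(clamp.get("sigma_right", 0.0)),
        float(clamp.get("sigma_eps", 0.0)),
        model._inv_cov_sd2,
        model._inv_hyper2,
        model._inv_noise2,
    )
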