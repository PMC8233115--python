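"""No-U-Turn sampler with dual-averaging step size and windowed mass adaptation.

A self-contained gradient-based MCMC engine for the fixed-structure
hierarchical model in :mod:`lesionatoms.model`: multinomial NUTS (progressive
biased sampling over the doubling trajectory), Nesterov dual averaging toward
a target acceptance statistic, and Stan-style expanding adaptation windows
for the mass matrix — diagonal by default, optionally dense
(``dense_mass=True``), which pays off on near-Gaussian targets with strong
linear correlations such as the scale-clamped model variant. The target
density is supplied as a callable returning the log density and its gradient
on the unconstrained scale.
This is the readable reference engine; :mod:`lesionatoms._kernel` holds a
numba-compiled equivalent specialized to the hierarchical outcome model.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log, sqrt
from typing import Callable

import numpy as np
from scipy.linalg import cholesky

__all__ = ["sample_chain", "ChainResult"]

#: energy error above which a leapfrog trajectory is declared divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim)
    n_divergent: int
    mean_accept: float
    step_size: float
    mean_tree_depth: float


class _Metric:
    """Diagonal kinetic-energy metric: momenta p ~ N(0, diag(1/inv_mass)),
    velocity inv_mass * p (inv_mass is the running posterior-variance estimate)."""

    def __init__(self, inv_mass: np.ndarray):
        self.inv_mass = inv_mass
        self._mom_scale = 1.0 / np.sqrt(inv_mass)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.inv_mass * p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ (self.inv_mass * p))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.inv_mass.shape[0]) * self._mom_scale


class _DenseMetric:
    """Dense metric: inv_mass is a full covariance estimate Sigma;
    momenta p ~ N(0, Sigma^-1), velocity Sigma @ p."""

    def __init__(self, sigma: np.ndarray):
        self.sigma = sigma
        self._chol_upper = cholesky(sigma, lower=False)  # Sigma = U' U

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.sigma @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ (self.sigma @ p))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        # p = U^-1 z has covariance (U' U)^-1 = Sigma^-1
        z = rng.standard_normal(self.sigma.shape[0])
        return np.linalg.solve(self._chol_upper, z)


class _Tree:
    __slots__ = (
        "q_left", "p_left", "g_left",
        "q_right", "p_right", "g_right",
        "q_prop", "logp_prop",
        "log_sum_w", "rho", "sum_accept", "n_leaves",
        "divergent", "turning",
    )


def _logaddexp(a: float, b: float) -> float:
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = a if a > b else b
    return m + log(exp(a - m) + exp(b - m))


def _uturn(rho: np.ndarray, p_first: np.ndarray, p_last: np.ndarray,
           metric: _Metric) -> bool:
    # the trajectory starts doubling back when the summed momentum no longer
    # points along the momenta at either end (symmetric in the two ends)
    v = metric.velocity(rho)
    return (v @ p_first) <= 0 or (v @ p_last) <= 0


def _leaf(logp_and_grad, q, p, grad, eps, metric, h0):
    """One leapfrog step from (q, p); eps carries the direction sign."""
    p_half = p + (0.5 * eps) * grad
    q1 = q + eps * metric.velocity(p_half)
    logp1, grad1 = logp_and_grad(q1)
    tree = _Tree()
    if np.isfinite(logp1):
        p1 = p_half + (0.5 * eps) * grad1
        energy_error = (-logp1 + metric.kinetic(p1)) - h0
    else:
        logp1, grad1, p1 = -np.inf, np.zeros_like(q1), p_half
        energy_error = np.inf
    tree.q_left = tree.q_right = tree.q_prop = q1
    tree.p_left = tree.p_right = p1
    tree.g_left = tree.g_right = grad1
    tree.logp_prop = logp1
    if np.isfinite(energy_error):
        tree.log_sum_w = -energy_error
        tree.sum_accept = exp(-energy_error) if energy_error > 0 else 1.0
        tree.divergent = energy_error > DIVERGENCE_THRESHOLD
    else:
        tree.log_sum_w = -np.inf
        tree.sum_accept = 0.0
        tree.divergent = True
    tree.rho = p1
    tree.n_leaves = 1
    tree.turning = False
    return tree


def _build(logp_and_grad, depth, q, p, grad, eps, metric, h0, rng):
    """Balanced subtree of 2**depth leapfrog steps starting at (q, p)."""
    if depth == 0:
        return _leaf(logp_and_grad, q, p, grad, eps, metric, h0)
    first = _build(logp_and_grad, depth - 1, q, p, grad, eps, metric, h0, rng)
    if first.divergent or first.turning:
        return first
    second = _build(
        logp_and_grad, depth - 1, first.q_right, first.p_right, first.g_right,
        eps, metric, h0, rng,
    )
    tree = _Tree()
    tree.q_left, tree.p_left, tree.g_left = first.q_left, first.p_left, first.g_left
    tree.q_right, tree.p_right, tree.g_right = (
        second.q_right, second.p_right, second.g_right,
    )
    log_sum_w = _logaddexp(first.log_sum_w, second.log_sum_w)
    # multinomial choice between subtrees, proportional to their weights
    if second.log_sum_w > -np.inf and log(rng.random()) < second.log_sum_w - log_sum_w:
        tree.q_prop, tree.logp_prop = second.q_prop, second.logp_prop
    else:
        tree.q_prop, tree.logp_prop = first.q_prop, first.logp_prop
    tree.log_sum_w = log_sum_w
    tree.rho = first.rho + second.rho
    tree.sum_accept = first.sum_accept + second.sum_accept
    tree.n_leaves = first.n_leaves + second.n_leaves
    tree.divergent = second.divergent
    tree.turning = second.turning or _uturn(
        tree.rho, tree.p_left, tree.p_right, metric
    )
    return tree


def _find_initial_step(logp_and_grad, q, logp, grad, metric, rng):
    """Double/halve the step until one leapfrog step crosses 50% acceptance."""
    eps = 1.0
    p = metric.sample_momentum(rng)
    h0 = -logp + metric.kinetic(p)

    def accept_of(e):
        leaf = _leaf(logp_and_grad, q, p, grad, e, metric, h0)
        return exp(min(0.0, leaf.log_sum_w))

    direction = 1 if accept_of(eps) > 0.5 else -1
    for _ in range(60):
        eps *= 2.0**direction
        a = accept_of(eps)
        if (direction == 1 and a <= 0.5) or (direction == -1 and a >= 0.5):
            break
    return float(np.clip(eps, 1e-8, 10.0))


def _adaptation_windows(n_warmup: int) -> list[int]:
    """End iterations of the expanding mass-adaptation windows."""
    init_buffer, term_buffer, base = 75, 50, 25
    if n_warmup < init_buffer + term_buffer + 2 * base:
        return []
    ends, pos, width = [], init_buffer, base
    while True:
        if pos + width + 2 * width + term_buffer > n_warmup:
            ends.append(n_warmup - term_buffer)
            break
        pos += width
        ends.append(pos)
        width *= 2
    return ends


def sample_chain(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    n_draws: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_treedepth: int = 10,
    dense_mass: bool = False,
) -> ChainResult:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics."""
    q = np.asarray(q0, dtype=float).copy()
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise RuntimeError("non-finite log density at the initial point")
    dim = q.size
    metric = _DenseMetric(np.eye(dim)) if dense_mass else _Metric(np.ones(dim))

    eps = _find_initial_step(logp_and_grad, q, logp, grad, metric, rng)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    mu = log(10.0 * eps)
    log_eps_bar, h_bar, da_count = log(eps), 0.0, 0

    windows = _adaptation_windows(n_warmup)
    window_idx = 0
    init_buffer = 75
    w_n, w_mean = 0, np.zeros(dim)
    w_m2 = np.zeros((dim, dim)) if dense_mass else np.zeros(dim)

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    sum_accept_stat = 0.0
    sum_depth = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p0 = metric.sample_momentum(rng)
        h0 = -logp + metric.kinetic(p0)

        q_left = q_right = q
        p_left = p_right = p0
        g_left = g_right = grad
        q_prop, logp_prop = q, logp
        log_sum_w = 0.0
        rho = p0.copy()
        sum_accept, n_leaves = 0.0, 0
        divergent = False
        depth = 0
        while depth < max_treedepth:
            if rng.random() < 0.5:
                sub = _build(
                    logp_and_grad, depth, q_right, p_right, g_right,
                    eps, metric, h0, rng,
                )
                edge = "right"
            else:
                sub = _build(
                    logp_and_grad, depth, q_left, p_left, g_left,
                    -eps, metric, h0, rng,
                )
                edge = "left"
            sum_accept += sub.sum_accept
            n_leaves += sub.n_leaves
            if sub.divergent:
                divergent = True
                break
            if sub.turning:
                break
            # biased progressive sampling: favour the newly built half
            if log(rng.random()) < sub.log_sum_w - log_sum_w:
                q_prop, logp_prop = sub.q_prop, sub.logp_prop
            log_sum_w = _logaddexp(log_sum_w, sub.log_sum_w)
            if edge == "right":
                q_right, p_right, g_right = sub.q_right, sub.p_right, sub.g_right
            else:
                q_left, p_left, g_left = sub.q_right, sub.p_right, sub.g_right
            rho = rho + sub.rho
            depth += 1
            if _uturn(rho, p_left, p_right, metric):
                break

        q = q_prop
        logp, grad = logp_and_grad(q)
        accept_stat = sum_accept / max(n_leaves, 1)
        sum_depth += depth

        if warming:
            da_count += 1
            h_bar += (target_accept - accept_stat - h_bar) / (da_count + t0)
            log_eps = mu - sqrt(da_count) / gamma * h_bar
            eta = da_count**-kappa
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = exp(log_eps)

            if windows and it >= init_buffer and window_idx < len(windows):
                w_n += 1
                delta = q - w_mean
                w_mean += delta / w_n
                if dense_mass:
                    w_m2 += np.outer(delta, q - w_mean)
                else:
                    w_m2 += delta * (q - w_mean)
                if it + 1 == windows[window_idx]:
                    if w_n >= 10:
                        shrink = w_n / (w_n + 5.0)
                        reg = 1e-3 * (5.0 / (w_n + 5.0))
                        est = w_m2 / max(w_n - 1, 1)
                        if dense_mass:
                            sigma = shrink * est + (reg + 1e-8) * np.eye(dim)
                            metric = _DenseMetric(sigma)
                        else:
                            inv_mass = shrink * est + reg
                            metric = _Metric(np.clip(inv_mass, 1e-10, None))
                    w_n, w_mean = 0, np.zeros(dim)
                    w_m2 = np.zeros((dim, dim)) if dense_mass else np.zeros(dim)
                    eps = _find_initial_step(logp_and_grad, q, logp, grad, metric, rng)
                    mu = log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = log(eps), 0.0, 0
                    window_idx += 1
            if it == n_warmup - 1:
                eps = exp(log_eps_bar)
        else:
            draws[it - n_warmup] = q
            n_divergent += int(divergent)
            sum_accept_stat += accept_stat

    return ChainResult(
        draws=draws,
        n_divergent=n_divergent,
        mean_accept=sum_accept_stat / max(n_draws, 1),
        step_size=eps,
        mean_tree_depth=sum_depth / (n_warmup + n_draws),
    )
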