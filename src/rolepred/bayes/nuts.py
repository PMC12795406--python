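"""No-U-Turn sampler with dual-averaging step-size and diagonal metric
adaptation (Hoffman & Gelman 2014, efficient variant; Stan-style warmup
windows).  Self-contained so the regression model can run where no
probabilistic-programming backend is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "run_chains", "ChainResult"]

_DELTA_MAX = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray       # (n_draws, dim)
    diverging: np.ndarray   # (n_draws,)
    accept_stat: np.ndarray
    step_size: float
    tree_depth: np.ndarray
    m_inv: np.ndarray | None = None


def _leapfrog(logp_grad, theta, r, grad, eps, m_inv):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * m_inv * r1
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, logp1, grad1


def _kinetic(r, m_inv):
    return 0.5 * np.dot(m_inv * r, r)


def _find_initial_step(logp_grad, theta, rng, m_inv):
    eps = 1.0
    logp, grad = logp_grad(theta)
    r = rng.standard_normal(theta.shape) / np.sqrt(m_inv)
    h0 = logp - _kinetic(r, m_inv)
    _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, m_inv)
    h1 = logp1 - _kinetic(r1, m_inv)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(64):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, m_inv)
        h1 = logp1 - _kinetic(r1, m_inv) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def _build_tree(logp_grad, state, logu, v, j, eps, h0, m_inv, rng):
    """Recursive doubling; state = (theta, r, logp, grad)."""
    theta, r, logp, grad = state
    if j == 0:
        theta1, r1, logp1, grad1 = _leapfrog(logp_grad, theta, r, grad, v * eps, m_inv)
        h1 = logp1 - _kinetic(r1, m_inv)
        if not np.isfinite(h1):
            h1 = -np.inf
        n1 = int(logu <= h1)
        s1 = int(logu < h1 + _DELTA_MAX)
        alpha = min(1.0, np.exp(min(0.0, h1 - h0)))
        st = (theta1, r1, logp1, grad1)
        return st, st, st, n1, s1, alpha, 1, s1 == 0
    st_m, st_p, st1, n1, s1, alpha, n_alpha, div = _build_tree(
        logp_grad, state, logu, v, j - 1, eps, h0, m_inv, rng
    )
    if s1 == 1:
        if v == -1:
            st_m, _, st2, n2, s2, a2, na2, div2 = _build_tree(
                logp_grad, st_m, logu, v, j - 1, eps, h0, m_inv, rng
            )
        else:
            _, st_p, st2, n2, s2, a2, na2, div2 = _build_tree(
                logp_grad, st_p, logu, v, j - 1, eps, h0, m_inv, rng
            )
        if n2 > 0 and rng.random() < n2 / max(n1 + n2, 1):
            st1 = st2
        alpha += a2
        n_alpha += na2
        div = div or div2
        dtheta = st_p[0] - st_m[0]
        s1 = s2 * int(np.dot(dtheta, m_inv * st_m[1]) >= 0) * int(np.dot(dtheta, m_inv * st_p[1]) >= 0)
        n1 += n2
    return st_m, st_p, st1, n1, s1, alpha, n_alpha, div


def _nuts_step(logp_grad, theta, logp, grad, eps, m_inv, rng, max_depth):
    r0 = rng.standard_normal(theta.shape) / np.sqrt(m_inv)
    h0 = logp - _kinetic(r0, m_inv)
    logu = h0 - rng.exponential()
    state = (theta, r0, logp, grad)
    st_m = st_p = st1 = state
    j, n, s = 0, 1, 1
    alpha_sum, n_alpha_sum, diverged = 0.0, 0, False
    while s == 1 and j < max_depth:
        v = 1 if rng.random() < 0.5 else -1
        if v == -1:
            st_m, _, st2, n2, s2, alpha, n_alpha, div = _build_tree(
                logp_grad, st_m, logu, v, j, eps, h0, m_inv, rng
            )
        else:
            _, st_p, st2, n2, s2, alpha, n_alpha, div = _build_tree(
                logp_grad, st_p, logu, v, j, eps, h0, m_inv, rng
            )
        if s2 == 1 and n2 > 0 and rng.random() < min(1.0, n2 / n):
            st1 = st2
        n += n2
        alpha_sum += alpha
        n_alpha_sum += n_alpha
        diverged = diverged or div
        dtheta = st_p[0] - st_m[0]
        s = s2 * int(np.dot(dtheta, m_inv * st_m[1]) >= 0) * int(np.dot(dtheta, m_inv * st_p[1]) >= 0)
        j += 1
    accept_stat = alpha_sum / max(n_alpha_sum, 1)
    return st1[0], st1[2], st1[3], accept_stat, diverged, j


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_depth: int = 10,
    eps: float | None = None,
    m_inv: np.ndarray | None = None,
    adapt: bool = True,
) -> ChainResult:
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.shape[0]
    m_inv = np.ones(dim) if m_inv is None else np.asarray(m_inv, dtype=float)
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    if not adapt:
        if eps is None:
            raise ValueError("adapt=False requires an explicit step size")
        # fixed-tuning burn-in, then sampling
        for _ in range(n_warmup):
            theta, logp, grad, _, _, _ = _nuts_step(
                logp_grad, theta, logp, grad, eps, m_inv, rng, max_depth
            )
        draws = np.empty((n_draws, dim))
        diverging = np.zeros(n_draws, dtype=bool)
        accept_stat = np.empty(n_draws)
        depth = np.empty(n_draws, dtype=int)
        for i in range(n_draws):
            theta, logp, grad, a_stat, div, j = _nuts_step(
                logp_grad, theta, logp, grad, eps, m_inv, rng, max_depth
            )
            draws[i] = theta
            diverging[i] = div
            accept_stat[i] = a_stat
            depth[i] = j
        return ChainResult(draws=draws, diverging=diverging, accept_stat=accept_stat,
                           step_size=eps, tree_depth=depth, m_inv=m_inv)

    eps = _find_initial_step(logp_grad, theta, rng, m_inv)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # Stan-like warmup windows: fast, expanding slow, fast
    init_buf = min(75, max(1, int(0.15 * n_warmup)))
    term_buf = min(50, max(1, int(0.1 * n_warmup)))
    slow_start, slow_end = init_buf, max(init_buf, n_warmup - term_buf)
    window_ends: list[int] = []
    w = 25
    pos = slow_start
    while pos < slow_end:
        end = min(pos + w, slow_end)
        if slow_end - end < w:  # absorb the remainder into the last window
            end = slow_end
        window_ends.append(end)
        pos = end
        w *= 2
    window_samples: list[np.ndarray] = []

    adapt_count = 0
    for i in range(n_warmup):
        theta, logp, grad, a_stat, _, _ = _nuts_step(
            logp_grad, theta, logp, grad, eps, m_inv, rng, max_depth
        )
        adapt_count += 1
        frac = 1.0 / (adapt_count + t0)
        h_bar = (1 - frac) * h_bar + frac * (target_accept - a_stat)
        log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
        eta = adapt_count ** (-kappa)
        log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
        eps = float(np.exp(log_eps))
        if slow_start <= i < slow_end:
            window_samples.append(theta.copy())
            if (i + 1) in window_ends:
                samp = np.asarray(window_samples)
                nw = samp.shape[0]
                var = samp.var(axis=0, ddof=1) if nw > 1 else np.ones(dim)
                m_inv = (nw / (nw + 5.0)) * var + (5.0 / (nw + 5.0)) * 1e-3
                window_samples = []
                eps = _find_initial_step(logp_grad, theta, rng, m_inv)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0

    eps = float(np.exp(log_eps_bar)) if n_warmup > 0 else eps
    draws = np.empty((n_draws, dim))
    diverging = np.zeros(n_draws, dtype=bool)
    accept_stat = np.empty(n_draws)
    depth = np.empty(n_draws, dtype=int)
    for i in range(n_draws):
        theta, logp, grad, a_stat, div, j = _nuts_step(
            logp_grad, theta, logp, grad, eps, m_inv, rng, max_depth
        )
        draws[i] = theta
        diverging[i] = div
        accept_stat[i] = a_stat
        depth[i] = j
    return ChainResult(draws=draws, diverging=diverging, accept_stat=accept_stat,
                       step_size=eps, tree_depth=depth, m_inv=m_inv)


def run_chains(
    logp_grad, init: Callable[[np.random.Generator], np.ndarray], dim: int,
    chains: int, n_warmup: int, n_draws: int, seed: int,
    target_accept: float = 0.8, max_depth: int = 10,
    shared_warmup: bool = False, burnin: int = 75,
) -> list[ChainResult]:
    """Run independent chains.

    With ``shared_warmup`` the step size and metric are adapted on the first
    chain only; the remaining chains reuse that tuning after a short
    fixed-tuning burn-in.  Chains stay independent given the tuning, so
    split-R-hat remains valid.
    """
    results = []
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101, c]))
        theta0 = init(rng)
        assert theta0.shape == (dim,)
        if shared_warmup and c > 0:
            first = results[0]
            res = sample_nuts(
                logp_grad, theta0, burnin, n_draws, rng, target_accept, max_depth,
                eps=first.step_size, m_inv=first.m_inv, adapt=False,
            )
        else:
            res = sample_nuts(logp_grad, theta0, n_warmup, n_draws, rng, target_accept, max_depth)
        results.append(res)
    return results
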