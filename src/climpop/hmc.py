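"""A compact Hamiltonian Monte Carlo sampler with warmup adaptation.

Static HMC with jittered trajectory lengths, dual-averaging step-size
adaptation (target acceptance 0.8) and diagonal mass-matrix estimation over
expanding warmup windows — the standard recipe for hierarchical regression
posteriors expressed with analytic gradients and non-centered random effects.
Models supply a single ``logp_and_grad(theta) -> (float, ndarray)`` callable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_hmc", "HMCDraws"]


class HMCDraws:
    """Posterior draws as (n_chains, n_draws, dim) with sampler diagnostics."""

    def __init__(self, draws, accept_rate, step_sizes, divergences):
        self.draws = draws
        self.accept_rate = accept_rate
        self.step_sizes = step_sizes
        self.divergences = divergences

    @property
    def stacked(self):
        return self.draws.reshape(-1, self.draws.shape[-1])


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass, n_steps):
    q = q.copy()
    p = p.copy()
    p += 0.5 * eps * grad
    for i in range(n_steps):
        q += eps * inv_mass * p
        lp, grad = logp_and_grad(q)
        if not np.isfinite(lp):
            return q, p, lp, grad
        p += (eps if i < n_steps - 1 else 0.5 * eps) * grad
    return q, p, lp, grad


def _find_initial_step(logp_and_grad, q0, inv_mass, rng):
    """Stan-style heuristic: double/halve eps until accept prob crosses 0.5."""
    eps = 0.1 / max(1.0, q0.size ** 0.25)
    lp0, grad0 = logp_and_grad(q0)
    for _ in range(50):
        p = rng.standard_normal(q0.size) / np.sqrt(inv_mass)
        h0 = lp0 - 0.5 * np.sum(inv_mass * p * p)
        q1, p1, lp1, _ = _leapfrog(logp_and_grad, q0, p, grad0, eps,
                                   inv_mass, 1)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(lp1) else -np.inf
        ratio = np.exp(min(0.0, h1 - h0))
        if ratio > 0.5:
            eps *= 2.0
            if eps > 10:
                break
        else:
            eps *= 0.5
            if eps < 1e-8:
                break
            if ratio > 0.25:
                break
    return eps


def _one_chain(logp_and_grad, q0, n_warmup, n_draws, rng, target_accept,
               traj_length, max_steps):
    dim = q0.size
    inv_mass = np.ones(dim)
    q = q0.copy()
    lp, grad = logp_and_grad(q)
    if not np.isfinite(lp):
        raise ValueError("non-finite log-density at the initial point")
    eps = _find_initial_step(logp_and_grad, q, inv_mass, rng)
    # dual averaging state
    mu = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    # warmup windows for mass adaptation (Stan-like: 75 | 25,50,100,... | 50)
    init_buf = min(75, max(10, int(0.15 * n_warmup)))
    term_buf = min(50, max(10, int(0.1 * n_warmup)))
    windows = []
    w, pos = 25, init_buf
    while pos + w < n_warmup - term_buf:
        nxt = pos + w
        if nxt + 2 * w >= n_warmup - term_buf:
            nxt = n_warmup - term_buf
        windows.append(nxt)
        pos, w = nxt, 2 * w
    window_draws = []
    draws = np.empty((n_draws, dim))
    n_accept, n_div, da_iter = 0, 0, 0
    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p * p)
        L = max(1, min(max_steps, int(np.ceil(traj_length / eps))))
        L = int(rng.integers(max(1, L // 2), L + 1))
        q1, p1, lp1, grad1 = _leapfrog(logp_and_grad, q, p, grad, eps,
                                       inv_mass, L)
        if np.isfinite(lp1):
            h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
            dh = h1 - h0
        else:
            dh = -np.inf
        if dh < -1000 and not warm:
            n_div += 1
        alpha = min(1.0, np.exp(min(0.0, dh)))
        if rng.random() < alpha:
            q, lp, grad = q1, lp1, grad1
            if not warm:
                n_accept += 1
        if warm:
            da_iter += 1
            h_bar = ((1 - 1 / (da_iter + t0)) * h_bar
                     + (target_accept - alpha) / (da_iter + t0))
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            wgt = da_iter ** (-kappa)
            log_eps_bar = wgt * log_eps + (1 - wgt) * log_eps_bar
            eps = np.exp(log_eps)
            window_draws.append(q.copy())
            if it + 1 in windows:
                arr = np.asarray(window_draws)
                var = arr.var(axis=0)
                n = arr.shape[0]
                inv_mass = (n * var + 1e-3 * 5.0) / (n + 5.0)
                inv_mass = np.clip(inv_mass, 1e-8, 1e8)
                window_draws = []
                eps = _find_initial_step(logp_and_grad, q, inv_mass, rng)
                mu = np.log(10 * eps)
                log_eps_bar, h_bar, da_iter = np.log(eps), 0.0, 0
            if it + 1 == n_warmup:
                eps = np.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = q
    return draws, n_accept / max(n_draws, 1), eps, n_div


def sample_hmc(logp_and_grad, init, n_chains=3, n_warmup=500, n_draws=500,
               seed=0, target_accept=0.8, traj_length=1.0, max_steps=48,
               init_jitter=0.5):
    """Run ``n_chains`` independent HMC chains.

    ``init`` is either one vector (jittered per chain) or an (n_chains, dim)
    array.  Returns an :class:`HMCDraws`.
    """
    init = np.atleast_2d(np.asarray(init, dtype=float))
    dim = init.shape[1]
    rng = np.random.default_rng(seed)
    all_draws = np.empty((n_chains, n_draws, dim))
    accepts, epss, divs = [], [], []
    for c in range(n_chains):
        q0 = init[c % init.shape[0]].copy()
        if init.shape[0] == 1 and c > 0:
            q0 = q0 + init_jitter * rng.standard_normal(dim)
        crng = np.random.default_rng(rng.integers(2 ** 31))
        d, acc, eps, ndiv = _one_chain(
            logp_and_grad, q0, n_warmup, n_draws, crng, target_accept,
            traj_length, max_steps)
        all_draws[c] = d
        accepts.append(acc)
        epss.append(eps)
        divs.append(ndiv)
    return HMCDraws(all_draws, float(np.mean(accepts)), epss, int(sum(divs)))
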