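"""A compact Hamiltonian Monte Carlo engine with warm-up adaptation.

Leapfrog integration with a jittered number of steps, dual-averaging step
size adaptation toward a target acceptance rate, and two diagonal mass
matrix updates during warm-up from the empirical draw variance.  The
target is supplied as a callable returning (log density, gradient).
"""

from __future__ import annotations

import numpy as np


def _leapfrog(logp_grad, x, p, eps, n_steps, minv):
    lp, g = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        x = x + eps * minv * p
        lp, g = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, -np.inf, g
        p = p + 0.5 * eps * g
    return x, p, lp, g


def _find_reasonable_eps(logp_grad, x, minv, rng):
    eps = 0.1
    lp0, g0 = logp_grad(x)
    p = rng.standard_normal(x.size) / np.sqrt(minv)
    h0 = lp0 - 0.5 * np.sum(minv * p * p)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, eps, 1, minv)
    h1 = lp1 - 0.5 * np.sum(minv * p1 * p1)
    diff = h1 - h0 if np.isfinite(h1) else -np.inf
    direction = 1.0 if diff > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, eps, 1, minv)
        h1 = lp1 - 0.5 * np.sum(minv * p1 * p1) if np.isfinite(lp1) else -np.inf
        diff = h1 - h0
        if (direction == 1.0 and diff <= np.log(0.5)) or (
            direction == -1.0 and diff >= np.log(0.5)
        ):
            break
    return max(eps, 1e-8)


class _DualAveraging:
    """Nesterov dual averaging of log step size (standard constants)."""

    def __init__(self, eps0, target=0.8):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob):
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


def hmc_chain(
    logp_grad,
    x0,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    leapfrog_range=(8, 48),
):
    """Run one HMC chain; returns (draws after warmup, diagnostics dict).

    The number of leapfrog steps is drawn uniformly from
    ``leapfrog_range`` each iteration to break periodicity.
    """
    x = np.asarray(x0, float).copy()
    dim = x.size
    minv = np.ones(dim)  # inverse diagonal mass
    eps0 = _find_reasonable_eps(logp_grad, x, minv, rng)
    da = _DualAveraging(eps0, target_accept)

    mass_updates = [int(0.3 * warmup), int(0.7 * warmup)]
    window_buf = []
    draws = np.empty((n_iter - warmup, dim))
    n_accept = 0
    n_total = 0
    lmin, lmax = leapfrog_range

    lp, _ = logp_grad(x)
    for it in range(n_iter):
        adapting = it < warmup
        eps = da.eps if adapting else da.eps_final
        L = int(rng.integers(lmin, lmax + 1))
        p0 = rng.standard_normal(dim) / np.sqrt(minv)
        h0 = lp - 0.5 * np.sum(minv * p0 * p0)
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, eps, L, minv)
        h1 = lp1 - 0.5 * np.sum(minv * p1 * p1) if np.isfinite(lp1) else -np.inf
        log_alpha = min(0.0, h1 - h0)
        accept = np.log(rng.random()) < log_alpha
        if accept:
            x, lp = x1, lp1
        if adapting:
            da.update(np.exp(log_alpha))
            window_buf.append(x.copy())
            if it + 1 in mass_updates:
                recent = np.asarray(window_buf[len(window_buf) // 2:])
                var = recent.var(axis=0)
                minv = np.clip(var, 1e-6, None)
                window_buf = []
                eps0 = _find_reasonable_eps(logp_grad, x, minv, rng)
                da = _DualAveraging(eps0, target_accept)
        else:
            draws[it - warmup] = x
            n_accept += accept
            n_total += 1
    info = {
        "accept_rate": n_accept / max(n_total, 1),
        "step_size": da.eps_final,
        "mass_inv": minv,
    }
    return draws, info
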