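"""Hamiltonian Monte Carlo with dual-averaging step-size adaptation and a
structured mass matrix, for models that supply an analytic gradient.

A deliberately compact sampler: static trajectories with a randomized
number of leapfrog steps (which breaks periodicity) and a warmup that
alternates step-size adaptation with (re-)estimation of the mass matrix
from accumulated warmup positions. The mass matrix is diagonal by default;
the caller may designate a sub-block of coordinates that receives a dense
(shrunken full-covariance) mass, which is what removes the random-walk
behavior along correlated directions such as a fixed effect versus the
mean of its group effects. Sufficient for the smooth posteriors this
package fits; not a general replacement for adaptive tree samplers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular

_DIVERGENCE_THRESHOLD = 1000.0


class _Mass:
    """Kinetic-energy operator: diagonal with an optional dense sub-block.

    The inverse mass approximates the posterior covariance: dense block
    ``cov`` on the coordinates in ``dense_idx``, variances elsewhere.
    """

    def __init__(self, dim: int, var: np.ndarray | None = None,
                 dense_idx: np.ndarray | None = None, cov: np.ndarray | None = None):
        self.dim = dim
        self.var = np.ones(dim) if var is None else var
        self.dense_idx = dense_idx
        if dense_idx is not None:
            self.chol = cholesky(cov, lower=True)  # cov = L L^T
        else:
            self.chol = None

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        p = rng.normal(size=self.dim) / np.sqrt(self.var)
        if self.dense_idx is not None:
            z = rng.normal(size=len(self.dense_idx))
            # cov(p_S) = (L L^T)^{-1}: p_S = L^{-T} z
            p[self.dense_idx] = solve_triangular(self.chol, z, lower=True, trans="T")
        return p

    def apply_inv(self, p: np.ndarray) -> np.ndarray:
        v = self.var * p
        if self.dense_idx is not None:
            pS = p[self.dense_idx]
            v[self.dense_idx] = self.chol @ (self.chol.T @ pS)
        return v

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.apply_inv(p))


@dataclass
class HMCResult:
    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    divergences: int
    step_size: float


def _estimate_mass(window: np.ndarray, dense_idx: np.ndarray | None,
                   var_floor: np.ndarray | None = None) -> _Mass:
    n, dim = window.shape
    var = np.var(window, axis=0)
    var = np.where(var > 1e-12, var, 1.0)
    if var_floor is not None:
        # a floor keeps weakly-explored coordinates (e.g. log hyper-SDs whose
        # posterior range exceeds a short warmup window) from getting an
        # over-heavy mass
        var = np.maximum(var, var_floor)
    if dense_idx is None or n < 25:
        return _Mass(dim, var=var)
    sub = window[:, dense_idx]
    c = np.cov(sub.T)
    # shrink towards the diagonal: keeps the estimate well conditioned when
    # the window is short relative to the block size
    lam = float(np.clip(0.3 * len(dense_idx) / n, 0.05, 0.7))
    c = (1.0 - lam) * c + lam * np.diag(np.diag(c))
    c += 1e-10 * np.eye(len(dense_idx))
    return _Mass(dim, var=var, dense_idx=dense_idx, cov=c)


def _leapfrog(logp_grad, x, p, g, eps, n_steps, mass: _Mass):
    lp = None
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        x = x + eps * mass.apply_inv(p)
        lp, g = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, lp, g
        p = p + 0.5 * eps * g
    return x, p, lp, g


def sample_hmc(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_leapfrog: int = 32,
    target_accept: float = 0.8,
    init_step: float = 0.1,
    dense_idx: np.ndarray | None = None,
    var_floor: np.ndarray | None = None,
) -> HMCResult:
    """One chain; ``logp_grad(x) -> (logp, grad)``."""
    x = np.asarray(x0, dtype=float).copy()
    dim = len(x)
    mass = _Mass(dim)

    def fresh_da(eps):
        return {"mu": np.log(10.0 * eps), "log_eps_bar": np.log(eps), "h_bar": 0.0, "t": 0}

    gamma, t0, kappa = 0.05, 10.0, 0.75
    eps = init_step / dim**0.25
    da = fresh_da(eps)
    # warmup phases: eps only | window 1 -> mass | window 2 -> mass | eps only
    w1 = (max(int(0.10 * n_warmup), 1), max(int(0.35 * n_warmup), 2))
    w2 = (max(int(0.40 * n_warmup), 3), max(int(0.85 * n_warmup), 4))
    window: list[np.ndarray] = []

    lp, g = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    draws = np.empty((n_draws, dim))
    n_accept = 0
    n_div = 0
    for it in range(n_warmup + n_draws):
        p0 = mass.sample_momentum(rng)
        # upper-half jitter: breaks periodicity without wasting short paths
        n_steps = int(rng.integers(max(max_leapfrog // 2, 1), max_leapfrog + 1))
        h0 = -lp + mass.kinetic(p0)
        x_new, p_new, lp_new, g_new = _leapfrog(logp_grad, x, p0, g, eps, n_steps, mass)
        if lp_new is not None and np.isfinite(lp_new):
            delta = h0 - (-lp_new + mass.kinetic(p_new))
        else:
            delta = -np.inf
        accept_prob = min(1.0, np.exp(min(delta, 0.0)))
        diverged = (not np.isfinite(delta)) or (-delta > _DIVERGENCE_THRESHOLD)
        if (not diverged) and rng.uniform() < accept_prob:
            x, lp, g = x_new, lp_new, g_new
            if it >= n_warmup:
                n_accept += 1
        if diverged and it >= n_warmup:
            n_div += 1

        if it < n_warmup:
            da["t"] += 1
            w = 1.0 / (da["t"] + t0)
            da["h_bar"] = (1 - w) * da["h_bar"] + w * (target_accept - accept_prob)
            log_eps = da["mu"] - np.sqrt(da["t"]) / gamma * da["h_bar"]
            step_w = da["t"] ** (-kappa)
            da["log_eps_bar"] = step_w * log_eps + (1 - step_w) * da["log_eps_bar"]
            eps = float(np.exp(log_eps))
            if w1[0] <= it < w1[1] or w2[0] <= it < w2[1]:
                window.append(x.copy())
            if it == w1[1] - 1 and len(window) >= 10:
                # first update: diagonal only (the window still carries the
                # initial transient, which would corrupt a dense estimate)
                mass = _estimate_mass(np.asarray(window), None, var_floor)
                window = []
                eps = float(np.exp(da["log_eps_bar"]))
                da = fresh_da(eps)
            elif it == w2[1] - 1 and len(window) >= 10:
                mass = _estimate_mass(np.asarray(window), dense_idx, var_floor)
                window = []
                eps = float(np.exp(da["log_eps_bar"]))
                da = fresh_da(eps)
            if it == n_warmup - 1:
                eps = float(np.exp(da["log_eps_bar"]))
        else:
            draws[it - n_warmup] = x
    return HMCResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        divergences=n_div,
        step_size=eps,
    )
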