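"""Vectorized profile-likelihood engine for segmented AR(1) models.

Computes, for a batch of series, the maximized log-likelihood of the full
model and of each constrained model (equal means / equal variances / equal
autocorrelations), profiling the change point over its candidate window in
every case. Autocorrelations are maximized on a fixed rho grid, with the
regression coefficients and innovation variances concentrated out in closed
form, so a whole parametric-bootstrap batch is handled with array
operations. The observed series is always evaluated through the same code
path as its bootstrap replicates, which is what makes the Monte-Carlo
p-values exchangeable.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))
_S2_FLOOR = 1e-12  # matches the exact-fit variance floor


def _design(m: int) -> np.ndarray:
    return np.column_stack([np.ones(m), np.arange(1.0, m + 1.0)])


class ProfileEngine:
    """Batch evaluator tied to one series length and candidate window.

    ``cands`` holds 1-based change points (first month of the post regime);
    the pre segment is months ``1..tau-1`` and the post segment is
    re-anchored to start at 1.
    """

    def __init__(self, n: int, cands, n_rho: int = 61, rho_bound: float = 0.98):
        self.n = int(n)
        self.cands = list(cands)
        self.rho = np.linspace(-rho_bound, rho_bound, n_rho)
        self._fine_rho = np.linspace(-rho_bound, rho_bound, 201)
        # transformed designs + projectors per (segment length, rho)
        self._dcache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for tau in self.cands:
            for m in (tau - 1, self.n - tau + 1):
                if m not in self._dcache:
                    self._dcache[m] = self._build_design(m)

    def _build_design(self, m: int):
        X = _design(m)
        G = len(self.rho)
        Xs = np.empty((G, m, 2))
        P = np.empty((G, 2, m))
        for g, r in enumerate(self.rho):
            Xs[g, 0] = X[0] * np.sqrt(1.0 - r * r)
            Xs[g, 1:] = X[1:] - r * X[:-1]
            P[g] = np.linalg.pinv(Xs[g])
        return Xs, P

    def _transform_y(self, Yseg: np.ndarray) -> np.ndarray:
        """(G, B, m) Prais-Winsten transform of a (B, m) segment batch."""
        r = self.rho[:, None, None]
        ys = np.empty((len(self.rho),) + Yseg.shape)
        ys[:, :, 0] = np.sqrt(1.0 - self.rho[:, None] ** 2) * Yseg[None, :, 0]
        ys[:, :, 1:] = Yseg[None, :, 1:] - r * Yseg[None, :, :-1]
        return ys

    def _segment_Q(self, Yseg: np.ndarray) -> np.ndarray:
        """Concentrated residual sum of squares per rho: (G, B).

        Q = ||ys||^2 - beta . (Xs^T ys) with beta the least-squares fit,
        avoiding an explicit residual array.
        """
        m = Yseg.shape[1]
        Xs, P = self._dcache[m]
        ys = self._transform_y(Yseg)
        Xty = np.einsum("gmk,gbm->gbk", Xs, ys)
        beta = np.einsum("gkm,gbm->gbk", P, ys)
        yy = np.einsum("gbm,gbm->gb", ys, ys)
        return np.maximum(yy - np.einsum("gbk,gbk->gb", beta, Xty), 0.0)

    @staticmethod
    def _seg_ll(Q: np.ndarray, m: int, rho: np.ndarray) -> np.ndarray:
        s2 = np.maximum(Q / m, _S2_FLOOR)
        return (
            -0.5 * m * (_LOG2PI + 1.0)
            - 0.5 * m * np.log(s2)
            + 0.5 * np.log(1.0 - rho * rho)[:, None]
        )

    def q_tables(self, Y: np.ndarray):
        """Per-candidate (Q_pre, Q_post) concentrated RSS grids, (G, B)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        tables = []
        for tau in self.cands:
            tables.append((self._segment_Q(Y[:, : tau - 1]), self._segment_Q(Y[:, tau - 1 :])))
        return tables

    # ----- model log-likelihoods (each maximized over the candidate window)

    def full_ll(self, Y, q_tables=None, reduce=True):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        qt = self.q_tables(Y) if q_tables is None else q_tables
        per_tau = []
        for tau, (Q1, Q2) in zip(self.cands, qt):
            m1, m2 = tau - 1, self.n - tau + 1
            per_tau.append(
                self._seg_ll(Q1, m1, self.rho).max(axis=0)
                + self._seg_ll(Q2, m2, self.rho).max(axis=0)
            )
        out = np.stack(per_tau, axis=1)  # (B, T)
        return out.max(axis=1) if reduce else out

    def eqrho_ll(self, Y, q_tables=None, reduce=True):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        qt = self.q_tables(Y) if q_tables is None else q_tables
        per_tau = []
        for tau, (Q1, Q2) in zip(self.cands, qt):
            m1, m2 = tau - 1, self.n - tau + 1
            per_tau.append(
                (self._seg_ll(Q1, m1, self.rho) + self._seg_ll(Q2, m2, self.rho)).max(axis=0)
            )
        out = np.stack(per_tau, axis=1)
        return out.max(axis=1) if reduce else out

    def eqvar_ll(self, Y, q_tables=None, reduce=True):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        qt = self.q_tables(Y) if q_tables is None else q_tables
        n = self.n
        logterm = 0.5 * np.log(1.0 - self.rho * self.rho)
        per_tau = []
        for tau, (Q1, Q2) in zip(self.cands, qt):
            # shared sigma: s2 = (Q1(rho1) + Q2(rho2)) / n over the rho x rho grid
            s2 = np.maximum((Q1[:, None, :] + Q2[None, :, :]) / n, _S2_FLOOR)
            ll = (
                -0.5 * n * (_LOG2PI + 1.0)
                - 0.5 * n * np.log(s2)
                + logterm[:, None, None]
                + logterm[None, :, None]
            )
            per_tau.append(ll.max(axis=(0, 1)))
        out = np.stack(per_tau, axis=1)
        return out.max(axis=1) if reduce else out

    def eqmean_ll(self, Y, n_iter: int = 12, tol: float = 1e-7, reduce=True):
        """Single global trend line, regime-specific (sigma, rho): blockwise
        coordinate ascent (GLS for the line given the error parameters, exact
        per-segment AR(1) maximization given the line), vectorized over the
        batch. The ascent is monotone; a handful of sweeps suffices."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        X = _design(self.n)
        out = np.stack(
            [self._eqmean_at(Y, X, tau, n_iter, tol) for tau in self.cands], axis=1
        )
        return out.max(axis=1) if reduce else out

    def _eqmean_at(self, Y, X, tau, n_iter, tol):
        n = self.n
        m1, m2 = tau - 1, n - tau + 1
        B = Y.shape[0]
        X1, X2 = X[:m1], X[m1:]
        Y1, Y2 = Y[:, :m1], Y[:, m1:]
        rho1 = np.zeros(B)
        rho2 = np.zeros(B)
        s1 = np.full(B, max(float(np.var(Y)), 1e-12))
        s2 = s1.copy()
        ll = np.full(B, -np.inf)
        for _ in range(n_iter):
            X1s, y1s = _batch_pw(X1, Y1, rho1)
            X2s, y2s = _batch_pw(X2, Y2, rho2)
            A = (
                np.einsum("bmi,bmj->bij", X1s, X1s) / s1[:, None, None]
                + np.einsum("bmi,bmj->bij", X2s, X2s) / s2[:, None, None]
            )
            v = (
                np.einsum("bmi,bm->bi", X1s, y1s) / s1[:, None]
                + np.einsum("bmi,bm->bi", X2s, y2s) / s2[:, None]
            )
            beta = np.linalg.solve(A, v[..., None])[..., 0]
            e1 = Y1 - beta @ X1.T
            e2 = Y2 - beta @ X2.T
            rho1, s1, l1 = _ar1_mle_batch(e1, self._fine_rho)
            rho2, s2, l2 = _ar1_mle_batch(e2, self._fine_rho)
            new = l1 + l2
            if np.max(np.abs(new - ll)) < tol:
                ll = new
                break
            ll = new
        return ll


def _batch_pw(Xseg, Yseg, rho):
    """Per-batch-element Prais-Winsten transform (rho varies along the batch)."""
    f = np.sqrt(1.0 - rho * rho)
    Xs = Xseg[None, :, :] - rho[:, None, None] * np.concatenate(
        [np.zeros((1, Xseg.shape[1])), Xseg[:-1]], axis=0
    )[None, :, :]
    Xs[:, 0, :] = Xseg[0][None, :] * f[:, None]
    ys = Yseg - rho[:, None] * np.concatenate(
        [np.zeros((Yseg.shape[0], 1)), Yseg[:, :-1]], axis=1
    )
    ys[:, 0] = Yseg[:, 0] * f
    return Xs, ys


def _ar1_mle_batch(e, rho_grid):
    """Exact stationary AR(1) MLE on a batch of residual series.

    The concentrated RSS is quadratic in rho: Q(rho) = S0(1 - rho^2) + SA
    - 2 rho SB + rho^2 SC, so the grid evaluation needs only four
    sufficient statistics per series. Returns (rho, sigma2, loglik).
    """
    m = e.shape[1]
    S0 = e[:, 0] ** 2
    SA = np.einsum("bm,bm->b", e[:, 1:], e[:, 1:])
    SB = np.einsum("bm,bm->b", e[:, 1:], e[:, :-1])
    SC = np.einsum("bm,bm->b", e[:, :-1], e[:, :-1])
    r = rho_grid[None, :]
    Q = S0[:, None] * (1.0 - r * r) + SA[:, None] - 2.0 * r * SB[:, None] + r * r * SC[:, None]
    s2 = np.maximum(Q / m, _S2_FLOOR)
    ll = -0.5 * m * (_LOG2PI + 1.0) - 0.5 * m * np.log(s2) + 0.5 * np.log(1.0 - r * r)
    g = np.argmax(ll, axis=1)
    idx = np.arange(e.shape[0])
    return rho_grid[g], s2[idx, g], ll[idx, g]


@lru_cache(maxsize=64)
def get_engine(n: int, cands: tuple, n_rho: int = 61) -> ProfileEngine:
    """Cached engine per (series length, candidate window): the transformed
    designs and projectors are reused across series and bootstrap batches."""
    return ProfileEngine(n, list(cands), n_rho=n_rho)
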