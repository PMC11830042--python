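"""Robust interrupted time series: estimated change point, and inference on
pre/post changes in mean, innovation variance and lag-1 autocorrelation.

Model
-----
A monthly outcome series switches regime at an unknown change point tau
(the first month of the new regime). Within each regime the mean is linear
in time — the post-regime clock restarts at 1, so the post intercept is the
post level — and the errors are a stationary Gaussian AR(1) with
regime-specific innovation SD and lag-1 autocorrelation. The change point
is treated as fixed but unknown and estimated by profile likelihood over a
candidate window around the nominal intervention month, which is how the
model captures the lag between an intervention's introduction and its
effect in practice.

Inference on the three kinds of change compares the full model against the
constrained model (equal mean line / equal variances / equal
autocorrelations across regimes) by likelihood ratio, with the change point
re-profiled under both hypotheses. Because change-point estimation inflates
the likelihood-ratio statistic well beyond its asymptotic chi-square
reference, the default inference is a parametric bootstrap that simulates
from the constrained fit and re-profiles the change point in every
replicate; the asymptotic reference is available but anti-conservative.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from ._engine import ProfileEngine, get_engine
from .datasets import TimeSeriesPanel
from .errors import (
    ConfigurationError,
    DataError,
    DegenerateFitError,
    InferenceError,
    StructuralError,
)

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
_S2_FLOOR = 1e-12  # variance floor: keeps the profile finite and
# comparable when a segment fits exactly (degenerate, zero residuals)
_RHO_BOUND = 0.99
_DEGENERATE_S2 = 1e-12


@dataclass
class ITSModelConfig:
    """Estimation settings for the robust-ITS fit.

    ``candidate_window`` is an inclusive 1-based month range searched for
    the change point; if None it defaults to ``[nominal - 3, nominal + 12]``
    (clipped so each regime keeps ``min_segment`` months), allowing a small
    anticipation and up to a year of implementation lag.
    """

    min_segment: int = 3
    candidate_window: tuple[int, int] | None = None
    ar_order: int = 1
    inference: str = "parametric_bootstrap"
    n_boot: int = 199
    alpha_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.min_segment < 3:
            raise ConfigurationError("min_segment must be >= 3")
        if self.ar_order != 1:
            raise ConfigurationError("only ar_order=1 is supported")
        if self.inference not in ("asymptotic_lrt", "parametric_bootstrap"):
            raise ConfigurationError(f"unknown inference mode {self.inference!r}")
        if not (0 < self.alpha_level < 0.5):
            raise ConfigurationError("alpha_level must lie in (0, 0.5)")
        if self.n_boot < 19:
            raise ConfigurationError("n_boot must be >= 19")

    def resolve_window(self, n: int, nominal: int | None) -> list[int]:
        lo_valid, hi_valid = self.min_segment + 1, n - self.min_segment + 1
        if lo_valid > hi_valid:
            raise DataError(f"series of length {n} is too short for min_segment={self.min_segment}")
        if self.candidate_window is not None:
            lo, hi = self.candidate_window
        elif nominal is not None:
            lo, hi = nominal - 3, nominal + 12
        else:
            lo, hi = lo_valid, hi_valid
        lo, hi = max(lo, lo_valid), min(hi, hi_valid)
        if lo > hi:
            raise ConfigurationError(
                f"candidate window [{lo}, {hi}] leaves no admissible change point "
                f"for a series of length {n}"
            )
        return list(range(lo, hi + 1))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    estimate: float
    ci: tuple[float, float]
    method: str

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value)) and self.p_value < 0.05


@dataclass
class ITSFit:
    """Fitted robust-ITS model for a single series."""

    series: np.ndarray
    changepoint_hat: int
    beta_hat: np.ndarray  # (pre_intercept, pre_slope, post_intercept, post_slope)
    sd_hat_pre: float
    sd_hat_post: float
    ac_hat_pre: float
    ac_hat_post: float
    loglik: float
    profile: pd.Series  # log-likelihood per candidate change point
    config: ITSModelConfig
    candidates: list[int]
    nominal_intervention: int | None = None
    degenerate: bool = False
    tests: dict[str, TestResult] = field(default_factory=dict)

    @property
    def marginal_sd_pre(self) -> float:
        return self.sd_hat_pre / np.sqrt(1.0 - self.ac_hat_pre**2)

    @property
    def marginal_sd_post(self) -> float:
        return self.sd_hat_post / np.sqrt(1.0 - self.ac_hat_post**2)

    @property
    def mean_change_estimate(self) -> float:
        """Level change at the change point: post level at its first month
        minus the pre trend extrapolated to that month."""
        b0, b1, b2, b3 = self.beta_hat
        return (b2 + b3 * 1.0) - (b0 + b1 * self.changepoint_hat)

    @property
    def variance_ratio(self) -> float:
        """Post/pre innovation variance ratio (nan if the pre fit is degenerate)."""
        if self.sd_hat_pre**2 <= _DEGENERATE_S2:
            return float("nan")
        return self.sd_hat_post**2 / self.sd_hat_pre**2

    def mean_path(self) -> np.ndarray:
        n = len(self.series)
        t = np.arange(1, n + 1, dtype=float)
        b0, b1, b2, b3 = self.beta_hat
        tau = self.changepoint_hat
        return np.where(t < tau, b0 + b1 * t, b2 + b3 * (t - tau + 1))


# ---------------------------------------------------------------------------
# exact single-series segment fits
# ---------------------------------------------------------------------------

def _pw(X, y, rho):
    f = np.sqrt(1.0 - rho * rho)
    Xs = np.empty_like(X)
    ys = np.empty_like(y)
    Xs[0], ys[0] = X[0] * f, y[0] * f
    Xs[1:] = X[1:] - rho * X[:-1]
    ys[1:] = y[1:] - rho * y[:-1]
    return Xs, ys


def _segment_concentrated(t, y, rho):
    """Loglik with beta and sigma concentrated out at fixed rho."""
    m = len(y)
    X = np.column_stack([np.ones(m), t])
    Xs, ys = _pw(X, y, rho)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    r = ys - Xs @ beta
    Q = float(r @ r)
    s2 = max(Q / m, _S2_FLOOR)
    ll = -0.5 * m * (_LOG2PI + 1.0) - 0.5 * m * np.log(s2) + 0.5 * np.log(1.0 - rho * rho)
    return ll, beta, Q / m, Xs


def _fit_segment(t, y):
    res = minimize_scalar(
        lambda r: -_segment_concentrated(t, y, r)[0],
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    ll, beta, s2, Xs = _segment_concentrated(t, y, rho)
    if s2 <= _DEGENERATE_S2:
        rho = 0.0  # autocorrelation of an exact fit is unidentified
        ll, beta, s2, Xs = _segment_concentrated(t, y, rho)
    return {"rho": rho, "beta": beta, "s2": s2, "ll": ll, "Xs": Xs, "m": len(y)}


def _full_fit_at(y, tau):
    n = len(y)
    pre = _fit_segment(np.arange(1.0, tau), y[: tau - 1])
    post = _fit_segment(np.arange(1.0, n - tau + 2), y[tau - 1 :])
    return pre, post, pre["ll"] + post["ll"]


def fit_robust_its(
    series,
    config: ITSModelConfig | None = None,
    nominal_intervention: int | None = None,
    months=None,
    with_tests: bool = True,
) -> ITSFit:
    """Profile-likelihood fit of the segmented AR(1) model.

    For each candidate change point the two segments are fitted exactly by
    maximum likelihood (regression line and innovation variance concentrated
    out, autocorrelation optimized numerically); the candidate maximizing
    the summed log-likelihood wins, ties broken toward the earliest.
    """
    config = config or ITSModelConfig()
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise DataError("series must be one-dimensional")
    if np.isnan(y).any():
        raise DataError("series contains missing values; gaps are not supported")
    if months is not None:
        months = np.asarray(months)
        if not np.array_equal(months, np.arange(months[0], months[0] + len(months))):
            raise DataError("months are not contiguous; gapped series are not supported")
    n = len(y)
    if n < 2 * config.min_segment:
        raise DataError(f"series length {n} < 2 * min_segment = {2 * config.min_segment}")
    if np.ptp(y) == 0:
        raise DegenerateFitError(
            "series is constant over the whole range (flat segment: months "
            f"1..{n}); the model is unidentified"
        )
    cands = config.resolve_window(n, nominal_intervention)

    lls = np.empty(len(cands))
    fits = []
    for i, tau in enumerate(cands):
        pre, post, ll = _full_fit_at(y, tau)
        lls[i] = ll
        fits.append((pre, post))
    best = int(np.argmax(lls))  # argmax returns the first (earliest) maximizer
    pre, post = fits[best]
    tau_hat = cands[best]
    degenerate = pre["s2"] <= _DEGENERATE_S2 or post["s2"] <= _DEGENERATE_S2
    fit = ITSFit(
        series=y,
        changepoint_hat=tau_hat,
        beta_hat=np.concatenate([pre["beta"], post["beta"]]),
        sd_hat_pre=float(np.sqrt(pre["s2"])),
        sd_hat_post=float(np.sqrt(post["s2"])),
        ac_hat_pre=pre["rho"],
        ac_hat_post=post["rho"],
        loglik=float(lls[best]),
        profile=pd.Series(lls, index=pd.Index(cands, name="changepoint")),
        config=config,
        candidates=cands,
        nominal_intervention=nominal_intervention,
        degenerate=degenerate,
    )
    if with_tests:
        fit.tests = test_changes(fit, config)
    return fit


# ---------------------------------------------------------------------------
# constrained fits (exact, profiled over the candidate window)
# ---------------------------------------------------------------------------

def _eqrho_fit_at(y, tau):
    n = len(y)
    t1, y1 = np.arange(1.0, tau), y[: tau - 1]
    t2, y2 = np.arange(1.0, n - tau + 2), y[tau - 1 :]

    def nll(rho):
        return -(
            _segment_concentrated(t1, y1, rho)[0] + _segment_concentrated(t2, y2, rho)[0]
        )

    res = minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded", options={"xatol": 1e-8}
    )
    rho = float(res.x)
    _, b1, s1, _ = _segment_concentrated(t1, y1, rho)
    _, b2, s2, _ = _segment_concentrated(t2, y2, rho)
    return -res.fun, {"tau": tau, "beta_pre": b1, "beta_post": b2, "rho_pre": rho,
                      "rho_post": rho, "s2_pre": s1, "s2_post": s2, "kind": "eqrho"}


def _eqvar_fit_at(y, tau):
    n = len(y)
    t1, y1 = np.arange(1.0, tau), y[: tau - 1]
    t2, y2 = np.arange(1.0, n - tau + 2), y[tau - 1 :]
    m1, m2 = len(y1), len(y2)

    def parts(rho1, rho2):
        _, b1, s1, _ = _segment_concentrated(t1, y1, rho1)
        _, b2, s2, _ = _segment_concentrated(t2, y2, rho2)
        Q = s1 * m1 + s2 * m2
        s_common = max(Q / n, _S2_FLOOR)
        ll = (
            -0.5 * n * (_LOG2PI + 1.0)
            - 0.5 * n * np.log(s_common)
            + 0.5 * np.log(1.0 - rho1**2)
            + 0.5 * np.log(1.0 - rho2**2)
        )
        return ll, b1, b2, s_common

    r1 = r2 = 0.0
    ll_prev = -np.inf
    for _ in range(30):
        res = minimize_scalar(
            lambda r: -parts(r, r2)[0],
            bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded", options={"xatol": 1e-8},
        )
        r1 = float(res.x)
        res = minimize_scalar(
            lambda r: -parts(r1, r)[0],
            bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded", options={"xatol": 1e-8},
        )
        r2 = float(res.x)
        ll, b1, b2, s_common = parts(r1, r2)
        if ll - ll_prev < 1e-9:
            break
        ll_prev = ll
    return ll, {"tau": tau, "beta_pre": b1, "beta_post": b2, "rho_pre": r1,
                "rho_post": r2, "s2_pre": s_common, "s2_post": s_common, "kind": "eqvar"}


def _eqmean_fit_at(y, tau):
    """Single global line, regime-specific (sigma, rho)."""
    n = len(y)
    X = np.column_stack([np.ones(n), np.arange(1.0, n + 1.0)])
    i2 = tau - 1
    X1, X2 = X[:i2], X[i2:]
    y1, y2 = y[:i2], y[i2:]
    m1, m2 = i2, n - i2

    def ar_mle(e):
        m = len(e)
        S0, SA = e[0] ** 2, float(e[1:] @ e[1:])
        SB, SC = float(e[1:] @ e[:-1]), float(e[:-1] @ e[:-1])

        def nll(rho):
            Q = S0 * (1 - rho * rho) + SA - 2 * rho * SB + rho * rho * SC
            s2 = max(Q / m, _S2_FLOOR)
            return 0.5 * m * np.log(s2) - 0.5 * np.log(1 - rho * rho)

        res = minimize_scalar(nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
                              options={"xatol": 1e-8})
        rho = float(res.x)
        Q = S0 * (1 - rho * rho) + SA - 2 * rho * SB + rho * rho * SC
        s2 = max(Q / m, _S2_FLOOR)
        ll = -0.5 * m * (_LOG2PI + 1.0) - 0.5 * m * np.log(s2) + 0.5 * np.log(1 - rho * rho)
        return rho, s2, ll

    rho1 = rho2 = 0.0
    s1 = s2 = max(float(np.var(y)), _S2_FLOOR)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    ll_prev = -np.inf
    for _ in range(60):
        X1s, y1s = _pw(X1, y1, rho1)
        X2s, y2s = _pw(X2, y2, rho2)
        A = X1s.T @ X1s / s1 + X2s.T @ X2s / s2
        v = X1s.T @ y1s / s1 + X2s.T @ y2s / s2
        beta = np.linalg.solve(A, v)
        rho1, s1, l1 = ar_mle(y1 - X1 @ beta)
        rho2, s2, l2 = ar_mle(y2 - X2 @ beta)
        ll = l1 + l2
        if ll - ll_prev < 1e-9:
            break
        ll_prev = ll
    return ll, {"tau": tau, "beta": beta, "rho_pre": rho1, "rho_post": rho2,
                "s2_pre": s1, "s2_post": s2, "kind": "eqmean"}


_CONSTRAINED = {"mean": _eqmean_fit_at, "variance": _eqvar_fit_at,
                "autocorrelation": _eqrho_fit_at}
_DF = {"mean": 2, "variance": 1, "autocorrelation": 1}


def _profile_constrained(y, cands, kind):
    best_ll, best_params = -np.inf, None
    for tau in cands:
        ll, params = _CONSTRAINED[kind](y, tau)
        if ll > best_ll + 1e-12:
            best_ll, best_params = ll, params
    return best_ll, best_params


def _debias(s2, rho, m, n_trend):
    """Small-sample corrections for the simulation parameters.

    The constrained MLEs understate the innovation variance (residual
    Q/m after fitting ``n_trend`` trend parameters plus the AR
    coefficient) and the autocorrelation (the AR(1) MLE bias is
    ~ -(1+3 rho)/m around a fitted mean and grows by ~(1+rho)/m per
    additional trend regressor); simulating from the raw plug-ins makes
    the bootstrap tests anti-conservative on short segments.
    """
    s2_adj = s2 * m / max(m - n_trend - 1, 1)
    bias = (1.0 + 3.0 * rho + n_trend * (1.0 + rho) / 2.0) / m
    rho_adj = float(np.clip(rho + bias, -_RHO_BOUND, _RHO_BOUND))
    return s2_adj, rho_adj


def _simulate_constrained(params, n, B, rng):
    """Parametric-bootstrap replicates from a constrained fit."""
    tau = params["tau"]
    m1, m2 = tau - 1, n - tau + 1
    t = np.arange(1.0, n + 1.0)
    if params["kind"] == "eqmean":
        mean = params["beta"][0] + params["beta"][1] * t
        # two trend parameters shared across segments: one per segment
        s2_1, rho_1 = _debias(params["s2_pre"], params["rho_pre"], m1, 1)
        s2_2, rho_2 = _debias(params["s2_post"], params["rho_post"], m2, 1)
    else:
        mean = np.where(
            t < tau,
            params["beta_pre"][0] + params["beta_pre"][1] * t,
            params["beta_post"][0] + params["beta_post"][1] * (t - tau + 1),
        )
        s2_1, rho_1 = _debias(params["s2_pre"], params["rho_pre"], m1, 2)
        s2_2, rho_2 = _debias(params["s2_post"], params["rho_post"], m2, 2)
    out = np.empty((B, n))
    for seg, (m, s2, rho) in enumerate([(m1, s2_1, rho_1), (m2, s2_2, rho_2)]):
        sd = np.sqrt(s2)
        z = rng.normal(size=(B, m))
        e = np.empty((B, m))
        e[:, 0] = z[:, 0] * sd / np.sqrt(1.0 - rho * rho)
        for k in range(1, m):
            e[:, k] = rho * e[:, k - 1] + sd * z[:, k]
        sl = slice(0, m1) if seg == 0 else slice(m1, n)
        out[:, sl] = e
    return out + mean


def _point_estimates(fit: ITSFit):
    """Effect estimates and conditional asymptotic CIs (given tau, rho)."""
    z = norm.ppf(1.0 - fit.config.alpha_level / 2.0)
    tau = fit.changepoint_hat
    n = len(fit.series)
    m1, m2 = tau - 1, n - tau + 1
    pre, post, _ = _full_fit_at(fit.series, tau)

    # mean: level change at the change point
    est_mean = fit.mean_change_estimate
    var = 0.0
    for seg, x in ((pre, np.array([1.0, tau])), (post, np.array([1.0, 1.0]))):
        XtX = seg["Xs"].T @ seg["Xs"]
        var += seg["s2"] * float(x @ np.linalg.solve(XtX, x))
    se_mean = float(np.sqrt(var))
    ci_mean = (est_mean - z * se_mean, est_mean + z * se_mean)

    # variance ratio (log-normal approximation; df adjusted for the trend fit)
    ratio = fit.variance_ratio
    if np.isfinite(ratio) and ratio > 0:
        se_log = np.sqrt(2.0 / max(m1 - 2, 1) + 2.0 / max(m2 - 2, 1))
        ci_var = (ratio * np.exp(-z * se_log), ratio * np.exp(z * se_log))
    else:
        ci_var = (float("nan"), float("nan"))

    # autocorrelation difference
    est_ac = fit.ac_hat_post - fit.ac_hat_pre
    se_ac = np.sqrt(
        (1.0 - fit.ac_hat_pre**2) / m1 + (1.0 - fit.ac_hat_post**2) / m2
    )
    ci_ac = (est_ac - z * se_ac, est_ac + z * se_ac)
    return {
        "mean": (est_mean, ci_mean),
        "variance": (ratio, ci_var),
        "autocorrelation": (est_ac, ci_ac),
    }


def test_changes(
    fit: ITSFit,
    config: ITSModelConfig | None = None,
    which: tuple[str, ...] = ("mean", "variance", "autocorrelation"),
) -> dict[str, TestResult]:
    """Likelihood-ratio tests of mean, variance and autocorrelation change.

    Both the full and the constrained model re-profile the change point.
    In ``parametric_bootstrap`` mode the null distribution of the statistic
    is obtained by simulating from the constrained fit and re-running the
    whole profiling on each replicate via the vectorized engine (the
    observed statistic is computed through the identical engine so observed
    and replicate values are exchangeable under the null).
    """
    config = config or fit.config
    y = fit.series
    n = len(y)
    cands = fit.candidates
    estimates = _point_estimates(fit)
    results: dict[str, TestResult] = {}

    if fit.degenerate:
        # an exactly-fitting segment: the LRT scale is unbounded
        for name in which:
            est, ci = estimates[name]
            undefined = name == "variance" and not np.isfinite(est)
            results[name] = TestResult(
                statistic=float("inf") if not undefined else float("nan"),
                p_value=0.0 if not undefined else float("nan"),
                estimate=est,
                ci=ci,
                method="degenerate (zero residual variance)"
                + (", ratio undefined" if undefined else ""),
            )
        return results

    if config.inference == "asymptotic_lrt":
        constrained = {k: _profile_constrained(y, cands, k) for k in which}
        for name, (ll_c, _) in constrained.items():
            stat = max(2.0 * (fit.loglik - ll_c), 0.0)
            p = float(chi2.sf(stat, _DF[name]))
            est, ci = estimates[name]
            results[name] = TestResult(
                statistic=stat, p_value=p, estimate=est, ci=ci,
                method=f"asymptotic LRT, df={_DF[name]} (anti-conservative with "
                       "estimated change point)",
            )
        return results

    engine = get_engine(n, tuple(cands))
    rng = np.random.default_rng(config.seed)
    B = config.n_boot
    con_fun = {"mean": engine.eqmean_ll, "variance": engine.eqvar_ll,
               "autocorrelation": engine.eqrho_ll}
    # constrained change point selected on the engine grid, exact fit there
    qt_obs = engine.q_tables(y)
    per_tau_funs = {
        "mean": lambda: engine.eqmean_ll(y, reduce=False),
        "variance": lambda: engine.eqvar_ll(y, q_tables=qt_obs, reduce=False),
        "autocorrelation": lambda: engine.eqrho_ll(y, q_tables=qt_obs, reduce=False),
    }
    # simulation parameters come from the constrained fit at the nominal
    # intervention month (or the window midpoint): fitting them at the
    # profiled change point would inherit its selection bias and make the
    # bootstrap anti-conservative. The test statistic itself still
    # re-profiles the change point under both hypotheses.
    nominal = fit.nominal_intervention
    tau_sim = nominal if nominal in cands else cands[len(cands) // 2]
    constrained = {}
    for name in which:
        per_tau = per_tau_funs[name]()
        tau_c = cands[int(np.argmax(per_tau[0]))]
        constrained[name] = (_CONSTRAINED[name](y, tau_c)[0],
                             _CONSTRAINED[name](y, tau_sim)[1])
    for name, (ll_c, params) in constrained.items():
        boots = _simulate_constrained(params, n, B, rng)
        batch = np.vstack([y[None, :], boots])
        qt = engine.q_tables(batch)
        ll_full_b = engine.full_ll(batch, q_tables=qt)
        if name == "mean":
            ll_con_b = con_fun[name](batch)
        else:
            ll_con_b = con_fun[name](batch, q_tables=qt)
        T = 2.0 * (ll_full_b - ll_con_b)
        bad = ~np.isfinite(T)
        if bad.mean() > 0.05:
            raise InferenceError(
                f"{int(bad.sum())} of {B + 1} bootstrap refits failed for the "
                f"{name}-change test"
            )
        T = np.where(bad, -np.inf, T)
        p = float((1 + np.sum(T[1:] >= T[0])) / (B + 1))
        stat = max(2.0 * (fit.loglik - constrained[name][0]), 0.0)
        est, ci = estimates[name]
        results[name] = TestResult(
            statistic=stat, p_value=p, estimate=est, ci=ci,
            method=f"parametric bootstrap, B={B}, change point re-profiled",
        )
    return results


# ---------------------------------------------------------------------------
# panel analysis: consistency-in-outcome
# ---------------------------------------------------------------------------

def holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@dataclass
class ConsistencyReport:
    """Per-unit and pooled decisions for every metric in a panel.

    ``per_unit`` has one row per unit x metric with the variance ratio
    (post/pre innovation variance), its CI and the "variability reduced"
    flag (CI entirely below 1), plus the mean-change estimate with raw and
    Holm-adjusted (across units within metric) p-values. ``pooled`` holds
    the same quantities for the across-unit mean series of each metric,
    with mean-change p-values Holm-adjusted across metrics.
    """

    per_unit: pd.DataFrame
    pooled: pd.DataFrame
    failures: pd.DataFrame
    alpha_level: float

    @property
    def all_units_variability_reduced(self) -> bool:
        return bool(self.per_unit["variability_reduced"].all())

    @property
    def pooled_mean_change_any(self) -> bool:
        return bool(self.pooled["mean_flag"].any())


def _no_mean_test(fit: ITSFit) -> TestResult:
    est, ci = _point_estimates(fit)["mean"]
    return TestResult(statistic=float("nan"), p_value=float("nan"),
                      estimate=est, ci=ci, method="not tested")


def _series_record(fit: ITSFit, mean_test: TestResult) -> dict:
    est_var, ci_var = _point_estimates(fit)["variance"]
    return {
        "changepoint": fit.changepoint_hat,
        "variance_ratio": est_var,
        "variance_ci_low": ci_var[0],
        "variance_ci_high": ci_var[1],
        "variability_reduced": bool(np.isfinite(ci_var[1]) and ci_var[1] < 1.0),
        "mean_change": mean_test.estimate,
        "mean_p": mean_test.p_value,
    }


def analyze_panel(
    panel: TimeSeriesPanel,
    config: ITSModelConfig | None = None,
    mean_tests: bool = True,
) -> ConsistencyReport:
    """Fit every unit x metric series plus each metric's pooled
    (across-unit average) series, and report variance-reduction and
    mean-change decisions.

    Unit-level mean-change p-values are Holm-corrected across units within
    a metric; pooled mean-change p-values are Holm-corrected across metrics
    (the family of hospital-level claims). Variance decisions use the
    variance-ratio CI at the configured level. Units that fail to fit are
    reported in ``failures`` and excluded, never silently dropped.
    ``mean_tests=False`` skips the (bootstrap) mean-change inference and
    reports only the variance decisions, which need no resampling.
    """
    config = config or ITSModelConfig()
    units, metrics = panel.units, panel.metrics
    if not units or not metrics:
        raise StructuralError("panel has no units or no metrics")
    nominal = panel.nominal_intervention
    unit_rows, fail_rows = [], []
    for metric in metrics:
        for unit in units:
            try:
                y = panel.series(unit, metric)
                fit = fit_robust_its(y, config, nominal_intervention=nominal,
                                     with_tests=False)
                tm = (test_changes(fit, config, which=("mean",))["mean"]
                      if mean_tests else _no_mean_test(fit))
                rec = {"unit": unit, "metric": metric, **_series_record(fit, tm)}
                unit_rows.append(rec)
            except Exception as exc:  # reported, not swallowed
                logger.warning("unit %r metric %r failed to fit: %s", unit, metric, exc)
                fail_rows.append({"unit": unit, "metric": metric, "error": str(exc)})
    if not unit_rows:
        raise StructuralError("no unit series could be fitted")
    per_unit = pd.DataFrame(unit_rows)
    per_unit["mean_p_holm"] = np.nan
    for metric in metrics:
        mask = per_unit["metric"] == metric
        if mask.any():
            per_unit.loc[mask, "mean_p_holm"] = holm(per_unit.loc[mask, "mean_p"].to_numpy())
    per_unit["mean_flag"] = per_unit["mean_p_holm"] <= config.alpha_level

    pooled_rows = []
    for metric in metrics:
        y = panel.pooled_series(metric)
        fit = fit_robust_its(y, config, nominal_intervention=nominal, with_tests=False)
        tm = (test_changes(fit, config, which=("mean",))["mean"]
              if mean_tests else _no_mean_test(fit))
        pooled_rows.append({"metric": metric, **_series_record(fit, tm)})
    pooled = pd.DataFrame(pooled_rows)
    pooled["mean_p_holm"] = holm(pooled["mean_p"].to_numpy())
    pooled["mean_flag"] = pooled["mean_p_holm"] <= config.alpha_level
    return ConsistencyReport(
        per_unit=per_unit,
        pooled=pooled,
        failures=pd.DataFrame(fail_rows, columns=["unit", "metric", "error"]),
        alpha_level=config.alpha_level,
    )
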