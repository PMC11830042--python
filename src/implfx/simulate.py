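"""Ground-truth-known synthetic data for the three analytic stages.

Three generators emulate the statistical structure the analyses assume:

* monthly outcome series with a lagged regime change in mean, innovation
  variance and lag-1 autocorrelation (AR(1) errors per regime);
* nested survey ratings (domain -> component -> item -> participant) drawn
  from a zero-one-inflated beta process on the proportion scale;
* case x condition membership matrices with planted sufficiency and
  necessity subset relations, crisp or fuzzy.

Every generator is fully determined by its parameter object (including the
seed) and returns its ground truth in the container's ``truth`` sidecar.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .datasets import QCADataset, SurveyTable, TimeSeriesPanel
from .errors import ConfigurationError, ParameterError, StructuralError
from .qca import evaluate_expression, parse_expression


# ---------------------------------------------------------------------------
# interrupted time series
# ---------------------------------------------------------------------------

@dataclass
class ITSSimParams:
    """Parameters of one simulated monthly outcome series.

    The regime actually switches at ``true_changepoint`` (the first month of
    the new regime, always ``n_pre + 1``); ``nominal_intervention`` is the
    month the intervention was introduced, which may precede the switch —
    the difference is the implementation lag. The post-regime trend is
    re-anchored: its time index restarts at 1 at the change point, so
    ``post_intercept`` is interpretable as the post level.
    """

    n_pre: int
    n_post: int
    pre_intercept: float = 0.0
    pre_slope: float = 0.0
    post_intercept: float = 0.0
    post_slope: float = 0.0
    pre_sd: float = 1.0
    post_sd: float = 1.0
    pre_ac: float = 0.0
    post_ac: float = 0.0
    nominal_intervention: int | None = None
    true_changepoint: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.true_changepoint is None:
            self.true_changepoint = self.n_pre + 1
        if self.nominal_intervention is None:
            self.nominal_intervention = self.true_changepoint
        if self.n_pre < 3 or self.n_post < 3:
            raise ParameterError("n_pre >= 3 and n_post >= 3 required")
        if self.true_changepoint != self.n_pre + 1:
            raise ParameterError(
                "true_changepoint must equal n_pre + 1 (first post-regime month); "
                f"got {self.true_changepoint} with n_pre={self.n_pre}"
            )
        n = self.n_pre + self.n_post
        if not (1 <= self.nominal_intervention <= self.true_changepoint <= n):
            raise ParameterError(
                "nominal_intervention <= true_changepoint <= n_pre + n_post violated"
            )
        if self.pre_sd < 0 or self.post_sd < 0:
            raise ParameterError("innovation SDs must be >= 0")
        if not (abs(self.pre_ac) < 1 and abs(self.post_ac) < 1):
            raise ParameterError("|pre_ac| and |post_ac| must be < 1")

    @property
    def n_total(self) -> int:
        return self.n_pre + self.n_post


def _ar1(rng: np.random.Generator, n: int, sd: float, ac: float) -> np.ndarray:
    """AR(1) innovations initialized from the stationary distribution."""
    if n == 0:
        return np.empty(0)
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    z = rng.normal(size=n)
    e[0] = z[0] * sd / np.sqrt(1.0 - ac * ac)
    for t in range(1, n):
        e[t] = ac * e[t - 1] + sd * z[t]
    return e


def its_mean_path(params: ITSSimParams) -> np.ndarray:
    """Noise-free mean of the series at months 1..n_pre+n_post."""
    t = np.arange(1, params.n_total + 1, dtype=float)
    tau = params.true_changepoint
    pre = params.pre_intercept + params.pre_slope * t
    post = params.post_intercept + params.post_slope * (t - tau + 1)
    return np.where(t < tau, pre, post)


def simulate_its(params: ITSSimParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """One series of length ``n_pre + n_post`` with a regime change at
    ``true_changepoint``; the AR(1) error process restarts (stationary init)
    at the change point."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mean = its_mean_path(params)
    e_pre = _ar1(rng, params.n_pre, params.pre_sd, params.pre_ac)
    e_post = _ar1(rng, params.n_post, params.post_sd, params.post_ac)
    return mean + np.concatenate([e_pre, e_post])


def _metric_seed(base_seed: int, metric_index: int) -> int:
    # metric 0 must reproduce simulate_its(params) exactly
    return int(base_seed) + 100003 * metric_index


def simulate_panel(
    params_per_unit: list[ITSSimParams],
    n_metrics: int = 1,
    unit_ids: list | None = None,
    metric_ids: list | None = None,
    shared_pre_sd: float = 0.0,
    shared_post_sd: float = 0.0,
    shared_ac: float = 0.0,
    shared_seed: int | None = None,
) -> TimeSeriesPanel:
    """One series per unit x metric.

    ``shared_*`` optionally add a hospital-level AR(1) month effect, drawn
    once per metric and added to every unit's series: real satisfaction
    metrics share hospital-wide temporal shocks, which is what keeps a
    pooled (across-unit average) series noisy even when idiosyncratic unit
    noise averages out. The shared process switches its SD at the (common)
    true change point.
    """
    if len(params_per_unit) < 1:
        raise StructuralError("need at least one unit")
    if n_metrics < 1:
        raise StructuralError("need at least one metric")
    n_tot = params_per_unit[0].n_total
    tau = params_per_unit[0].true_changepoint
    nominal = params_per_unit[0].nominal_intervention
    for p in params_per_unit:
        if p.n_total != n_tot or p.true_changepoint != tau:
            raise StructuralError("all units must share the same month range")
    if unit_ids is None:
        unit_ids = [f"unit{i + 1:02d}" for i in range(len(params_per_unit))]
    if metric_ids is None:
        metric_ids = [f"metric{j + 1}" for j in range(n_metrics)]
    if len(set(unit_ids)) != len(params_per_unit) or len(set(metric_ids)) != n_metrics:
        raise StructuralError("unit/metric ids must be unique")

    shared = np.zeros((n_metrics, n_tot))
    if shared_pre_sd > 0 or shared_post_sd > 0:
        srng = np.random.default_rng(
            shared_seed if shared_seed is not None else params_per_unit[0].seed + 777
        )
        for j in range(n_metrics):
            shared[j, : tau - 1] = _ar1(srng, tau - 1, shared_pre_sd, shared_ac)
            shared[j, tau - 1 :] = _ar1(srng, n_tot - tau + 1, shared_post_sd, shared_ac)

    months = np.arange(1, n_tot + 1)
    rows = []
    for uid, p in zip(unit_ids, params_per_unit):
        for j, mid in enumerate(metric_ids):
            rng = np.random.default_rng(_metric_seed(p.seed, j))
            y = simulate_its(p, rng=rng) + shared[j]
            rows.append(
                pd.DataFrame({"unit": uid, "metric": mid, "month": months, "value": y})
            )
    data = pd.concat(rows, ignore_index=True)
    truth = {
        "true_changepoint": tau,
        "nominal_intervention": nominal,
        "units": {uid: asdict(p) for uid, p in zip(unit_ids, params_per_unit)},
        "shared": {
            "pre_sd": shared_pre_sd,
            "post_sd": shared_post_sd,
            "ac": shared_ac,
        },
    }
    return TimeSeriesPanel(data=data, nominal_intervention=nominal, truth=truth)


# ---------------------------------------------------------------------------
# study-shaped panel scenarios (10 units x 7 satisfaction metrics)
# ---------------------------------------------------------------------------

def consistency_scenario(
    seed: int = 0,
    n_units: int = 10,
    n_metrics: int = 7,
    n_pre: int = 72,
    n_post: int = 72,
    unit_sd: float = 1.0,
    shared_sd: float = 2.0,
    variance_ratio: float = 0.5,
    ac: float = 0.3,
    n_gain_units: int = 3,
    gain: float = 0.3,
    lag: int = 3,
) -> TimeSeriesPanel:
    """Panel emulating the observed unit-versus-hospital effect pattern.

    Every unit's innovation SD (idiosyncratic and shared) is multiplied by
    ``variance_ratio`` after the change point; only the ``n_gain_units``
    lowest-baseline units receive a mean gain of ``gain`` outcome units.
    The dominant shared month effect means the hospital-level (pooled)
    series does not reliably show the diluted mean gain, while unit-level
    variance reduction is strong everywhere.
    """
    rng = np.random.default_rng(seed)
    baselines = np.sort(rng.uniform(70.0, 90.0, size=n_units))[::-1]  # descending
    order = np.argsort(baselines)  # lowest-baseline units
    gain_units = set(order[:n_gain_units].tolist())
    params = []
    for i in range(n_units):
        delta = gain if i in gain_units else 0.0
        params.append(
            ITSSimParams(
                n_pre=n_pre,
                n_post=n_post,
                pre_intercept=baselines[i],
                pre_slope=0.0,
                post_intercept=baselines[i] + delta,
                post_slope=0.0,
                pre_sd=unit_sd,
                post_sd=unit_sd * variance_ratio,
                pre_ac=ac,
                post_ac=ac,
                nominal_intervention=n_pre + 1 - lag,
                true_changepoint=n_pre + 1,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    panel = simulate_panel(
        params,
        n_metrics=n_metrics,
        shared_pre_sd=shared_sd,
        shared_post_sd=shared_sd * variance_ratio,
        shared_ac=ac,
        shared_seed=int(rng.integers(0, 2**31 - 1)),
    )
    panel.truth["gain_units"] = sorted(f"unit{i + 1:02d}" for i in gain_units)
    panel.truth["variance_ratio"] = variance_ratio**2
    return panel


def unit_gain_scenario(
    seed: int = 0,
    n_units: int = 10,
    n_pre: int = 72,
    n_post: int = 72,
    unit_sd: float = 1.0,
    ac: float = 0.3,
    n_gain_units: int = 3,
    gain: float = 4.0,
    lag: int = 3,
) -> TimeSeriesPanel:
    """Single-metric panel with a strong mean gain planted in the
    ``n_gain_units`` lowest-baseline units only (no shared month effect),
    for unit-level mean-change detection checks."""
    return consistency_scenario(
        seed=seed,
        n_units=n_units,
        n_metrics=1,
        n_pre=n_pre,
        n_post=n_post,
        unit_sd=unit_sd,
        shared_sd=0.0,
        variance_ratio=1.0,
        ac=ac,
        n_gain_units=n_gain_units,
        gain=gain,
        lag=lag,
    )


# ---------------------------------------------------------------------------
# nested survey ratings (zero-one-inflated beta)
# ---------------------------------------------------------------------------

@dataclass
class SurveySimParams:
    """Parameters of the nested-survey generator.

    Ratings live on [0, 1] (already converted to proportions). Hierarchy:
    ``n_domains`` domains, each with ``n_components_per_domain`` components,
    each with ``n_items_per_component`` items; every participant rates every
    item once. Logit-scale varying intercepts and success slopes are drawn
    per domain/component/item; participants get varying intercepts.
    """

    n_domains: int = 5
    n_components_per_domain: int = 3
    n_items_per_component: int = 2
    n_participants: int = 100
    base_intercept: float = 0.0
    base_slope: float = 1.0
    sd_domain_int: float = 0.3
    sd_domain_slope: float = 0.16
    sd_component_int: float = 0.3
    sd_component_slope: float = 0.29
    sd_item_int: float = 0.2
    sd_item_slope: float = 0.09
    sd_participant: float = 0.5
    inflate_alpha: float = 0.1
    inflate_gamma: float = 0.5
    precision_phi: float = 10.0
    success_dist: str | tuple = "grid"
    seed: int = 0

    def __post_init__(self):
        for name in (
            "sd_domain_int",
            "sd_domain_slope",
            "sd_component_int",
            "sd_component_slope",
            "sd_item_int",
            "sd_item_slope",
            "sd_participant",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0 <= self.inflate_alpha <= 1 and 0 <= self.inflate_gamma <= 1):
            raise ParameterError("inflate_alpha and inflate_gamma must lie in [0, 1]")
        if self.precision_phi <= 0:
            raise ParameterError("precision_phi must be > 0")
        for name in ("n_domains", "n_components_per_domain", "n_items_per_component",
                     "n_participants"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


def _draw_success(params: SurveySimParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_participants
    dist = params.success_dist
    if dist == "grid":
        # evenly spaced over [0, 1]: maximizes slope identifiability
        return np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    if dist == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if isinstance(dist, tuple) and len(dist) == 3 and dist[0] == "beta":
        return rng.beta(dist[1], dist[2], size=n)
    raise ParameterError(f"unknown success_dist {dist!r}")


def simulate_survey(params: SurveySimParams, rng: np.random.Generator | None = None) -> SurveyTable:
    """One row per participant x item, drawn from the zero-one-inflated beta
    process; ground-truth effects are in the ``truth`` sidecar."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    nd, nc, ni = (
        params.n_domains,
        params.n_components_per_domain,
        params.n_items_per_component,
    )
    n_comp, n_item = nd * nc, nd * nc * ni
    domains = [f"D{d + 1}" for d in range(nd)]
    components = [f"D{d + 1}_C{c + 1}" for d in range(nd) for c in range(nc)]
    items = [
        f"D{d + 1}_C{c + 1}_I{i + 1}"
        for d in range(nd)
        for c in range(nc)
        for i in range(ni)
    ]
    item_domain = np.repeat(np.arange(nd), nc * ni)
    item_comp = np.repeat(np.arange(n_comp), ni)

    eff = {
        "domain_int": rng.normal(0.0, params.sd_domain_int, nd),
        "domain_slope": rng.normal(0.0, params.sd_domain_slope, nd),
        "component_int": rng.normal(0.0, params.sd_component_int, n_comp),
        "component_slope": rng.normal(0.0, params.sd_component_slope, n_comp),
        "item_int": rng.normal(0.0, params.sd_item_int, n_item),
        "item_slope": rng.normal(0.0, params.sd_item_slope, n_item),
        "participant_int": rng.normal(0.0, params.sd_participant, params.n_participants),
    }
    success = _draw_success(params, rng)

    part_idx = np.repeat(np.arange(params.n_participants), n_item)
    item_idx = np.tile(np.arange(n_item), params.n_participants)
    d_idx = item_domain[item_idx]
    c_idx = item_comp[item_idx]
    s = success[part_idx]

    eta = (
        params.base_intercept
        + eff["domain_int"][d_idx]
        + eff["component_int"][c_idx]
        + eff["item_int"][item_idx]
        + (
            params.base_slope
            + eff["domain_slope"][d_idx]
            + eff["component_slope"][c_idx]
            + eff["item_slope"][item_idx]
        )
        * s
        + eff["participant_int"][part_idx]
    )
    mu = 1.0 / (1.0 + np.exp(-eta))
    n_rows = len(eta)
    interior = np.clip(
        rng.beta(mu * params.precision_phi, (1.0 - mu) * params.precision_phi),
        1e-9,
        1.0 - 1e-9,
    )
    is_endpoint = rng.uniform(size=n_rows) < params.inflate_alpha
    is_one = rng.uniform(size=n_rows) < params.inflate_gamma
    rating = np.where(is_endpoint, np.where(is_one, 1.0, 0.0), interior)

    data = pd.DataFrame(
        {
            "participant": [f"P{p + 1:03d}" for p in part_idx],
            "domain": [domains[d] for d in d_idx],
            "component": [components[c] for c in c_idx],
            "item": [items[i] for i in item_idx],
            "rating": rating,
            "success": s,
        }
    )
    truth = {
        "params": asdict(params),
        "effects": {k: v.tolist() for k, v in eff.items()},
        "success": success.tolist(),
        "hyper_sd": {
            "domain_int": params.sd_domain_int,
            "domain_slope": params.sd_domain_slope,
            "component_int": params.sd_component_int,
            "component_slope": params.sd_component_slope,
            "item_int": params.sd_item_int,
            "item_slope": params.sd_item_slope,
            "participant_int": params.sd_participant,
        },
    }
    return SurveyTable(data=data, truth=truth)


# ---------------------------------------------------------------------------
# QCA configurations with planted subset relations
# ---------------------------------------------------------------------------

@dataclass
class QCASimParams:
    """Case x condition generator with a planted sufficient configuration
    (a Boolean expression such as ``"A*B + ~C"``) and an optional condition
    forced to be necessary for the outcome."""

    n_cases: int = 50
    condition_names: tuple = ("A", "B", "C")
    planted_solution: str = "A*B"
    necessity_condition: str | None = None
    noise_rate: float = 0.0
    crisp: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ParameterError("n_cases must be >= 1")
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ParameterError("condition names must be unique")
        if not (0 <= self.noise_rate < 0.5):
            raise ParameterError("noise_rate must lie in [0, 0.5)")


def simulate_qca(params: QCASimParams, rng: np.random.Generator | None = None) -> QCADataset:
    """Membership matrix plus outcome with the planted relations holding
    exactly at ``noise_rate=0``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    names = list(params.condition_names)
    expr = parse_expression(params.planted_solution, names)
    nec = params.necessity_condition
    if nec is not None:
        if nec not in names:
            raise ConfigurationError(f"necessity condition {nec!r} not among conditions")
        if f"~{nec}" in params.planted_solution.replace(" ", ""):
            raise ConfigurationError(
                f"necessity condition {nec!r} appears negated in the planted solution"
            )

    n = params.n_cases
    if params.crisp:
        m = rng.integers(0, 2, size=(n, len(names))).astype(float)
    else:
        m = rng.uniform(0.0, 1.0, size=(n, len(names)))
        m[np.isclose(m, 0.5)] += 1e-3
    cols = {name: m[:, j] for j, name in enumerate(names)}

    # fixpoint: outcome = planted expression; necessity forces P >= outcome
    y = evaluate_expression(expr, cols)
    if nec is not None:
        for _ in range(10):
            cols[nec] = np.maximum(cols[nec], y)
            y_new = evaluate_expression(expr, cols)
            if np.allclose(y_new, y):
                break
            y = y_new

    flip = rng.uniform(size=n) < params.noise_rate
    y = np.where(flip, 1.0 - y, y)

    case_ids = [f"case{i + 1:03d}" for i in range(n)]
    memberships = pd.DataFrame(
        {name: cols[name] for name in names}, index=pd.Index(case_ids, name="case")
    )
    outcome = pd.Series(y, index=memberships.index, name="outcome")
    truth = {
        "params": asdict(params),
        "planted_solution": params.planted_solution,
        "necessity_condition": nec,
        "n_flipped": int(flip.sum()),
    }
    return QCADataset(memberships=memberships, outcome=outcome, truth=truth)
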