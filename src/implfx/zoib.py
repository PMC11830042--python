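"""Bayesian multilevel zero-one-inflated beta (ZOIB) regression of item
ratings on implementation-success scores.

Ratings on [0, 1] are modelled as a mixture: with probability ``alpha`` the
response is an endpoint (1 with conditional probability ``gamma``, else 0);
otherwise it follows a beta distribution parameterized by mean ``mu``
(logit link) and precision ``phi``. The linear predictor for ``mu`` carries
a fixed intercept and success slope, varying intercepts and success slopes
for domains, components and items (items nested in components nested in
domains), and varying intercepts per participant. The posterior standard
deviations of the varying success slopes at each level measure how much
that level of the instrument discriminates between lower and higher
implementation success.

``alpha`` and ``gamma`` are population constants; varying effects use the
non-centered parameterization; priors are weakly informative (normal for
fixed effects, half-normal for hyper-SDs, gamma for ``phi``, beta for the
inflation probabilities). Sampling is Hamiltonian Monte Carlo with analytic
gradients; diagnostics (split-chain R-hat, effective sample size,
divergences) are attached before any summary and a fit that misses the
configured thresholds raises instead of silently returning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, expit, gammaln, logit

from ._hmc import sample_hmc
from .datasets import SurveyTable
from .errors import ConvergenceError, DataError, ParameterError

logger = logging.getLogger(__name__)

LEVELS = ("domain", "component", "item")

try:  # jit-compiled likelihood kernel: ~3x faster gradient evaluations
    from ._zoib_kernel import beta_lik_kernel as _beta_lik_kernel
except Exception:  # pragma: no cover - numba missing or compilation failure
    _beta_lik_kernel = None


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def to_proportion(score: float, max_score: float):
    """Convert a raw score to a proportion by dividing by its maximum."""
    if max_score <= 0:
        raise ParameterError("max_score must be > 0")
    arr = np.asarray(score, dtype=float)
    if (arr < 0).any() or (arr > max_score).any():
        raise ParameterError(f"score outside [0, {max_score}]")
    out = arr / max_score
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


@dataclass
class ZOIBParams:
    """Parameters of a single zero-one-inflated beta distribution."""

    alpha: float
    gamma: float
    mu: float
    phi: float

    def __post_init__(self):
        if not (0 <= self.alpha <= 1 and 0 <= self.gamma <= 1):
            raise ParameterError("alpha and gamma must lie in [0, 1]")
        if not (0 < self.mu < 1):
            raise ParameterError("mu must lie in (0, 1)")
        if self.phi <= 0:
            raise ParameterError("phi must be > 0")


def zoib_logdensity(y: float, params: ZOIBParams) -> float:
    """Log density of the ZOIB mixture at ``y`` in [0, 1].

    Point masses: alpha*(1-gamma) at 0 and alpha*gamma at 1; the interior
    carries (1-alpha) times a Beta(mu*phi, (1-mu)*phi) density.
    """
    if not 0 <= y <= 1:
        raise ParameterError("y must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        if y == 0.0:
            return float(np.log(params.alpha) + np.log1p(-params.gamma))
        if y == 1.0:
            return float(np.log(params.alpha) + np.log(params.gamma))
        a = params.mu * params.phi
        b = (1.0 - params.mu) * params.phi
        return float(
            np.log1p(-params.alpha)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
            - betaln(a, b)
        )


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class PriorSettings:
    fixed_scale: float = 2.0  # N(0, scale) on intercept and slope
    sd_scale: float = 1.0  # half-normal scale on every hyper-SD
    phi_shape: float = 2.0  # gamma prior on the beta precision
    phi_rate: float = 0.1
    inflate_a: float = 2.0  # beta prior on alpha and gamma
    inflate_b: float = 2.0


@dataclass
class MultilevelSpec:
    """Hierarchy, priors and sampler settings for the multilevel ZOIB fit.

    ``grouping`` (item -> component -> domain map) defaults to the one
    implied by the survey table; supplying it explicitly lets a caller
    assert the intended nesting. A level with a single observed group
    cannot support a hyper-SD and is dropped with a warning.
    """

    grouping: pd.DataFrame | None = None
    include_participant_intercepts: bool = True
    center_success: bool = False
    priors: PriorSettings = field(default_factory=PriorSettings)
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    max_leapfrog: int = 32
    seed: int = 0
    rhat_threshold: float = 1.01
    min_ess: float = 400.0

    def __post_init__(self):
        if self.chains < 2:
            raise ParameterError("need >= 2 chains for split-chain diagnostics")
        if self.warmup < 50 or self.draws < 50:
            raise ParameterError("warmup and draws must each be >= 50")


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class ZOIBPosterior:
    """Posterior draws plus diagnostics for the multilevel ZOIB model.

    ``draws`` maps parameter names to arrays of shape (chains, draws) or
    (chains, draws, n_groups). Hyper-SD names follow
    ``sd_<level>_<int|slope>`` plus ``sd_participant``; per-group effects
    are ``<level>_int`` / ``<level>_slope`` with ``groups[level]`` labels.
    """

    draws: dict[str, np.ndarray]
    groups: dict[str, list[str]]
    diagnostics: pd.DataFrame  # per monitored parameter: rhat, ess
    divergences: int
    dropped_levels: list[str]
    spec: MultilevelSpec

    def stacked(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def hyper_sd_summary(self, ci: float = 0.90) -> pd.DataFrame:
        lo, hi = 50 * (1 - ci), 50 * (1 + ci)
        rows = []
        for name in sorted(self.draws):
            if not name.startswith("sd_"):
                continue
            x = self.stacked(name)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(x)),
                    f"q{lo:g}": float(np.percentile(x, lo)),
                    f"q{hi:g}": float(np.percentile(x, hi)),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PredictorRanking:
    """Levels ordered by posterior median slope SD; groups by |median slope|."""

    levels: pd.DataFrame  # level, median_sd, ci_low, ci_high (ordered)
    best_level: str
    group_slopes: dict[str, pd.DataFrame]  # per level, ordered by |median|


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _mean_first_rotation(k: int) -> np.ndarray:
    """Orthonormal K x K matrix whose first column is 1/sqrt(K)."""
    base = np.column_stack([np.full(k, 1.0 / np.sqrt(k)), np.eye(k)[:, : k - 1]])
    q, r = np.linalg.qr(base)
    # fix signs so the first column is +1/sqrt(K)
    return q * np.sign(np.diag(r))


class _ZOIBModel:
    """Packed-parameter log posterior with analytic gradient."""

    def __init__(self, table: SurveyTable, spec: MultilevelSpec):
        df = table.data
        y = df["rating"].to_numpy(dtype=float)
        s = df["success"].to_numpy(dtype=float)
        if (y < 0).any() or (y > 1).any() or (s < 0).any() or (s > 1).any():
            raise DataError("ratings and success scores must lie in [0, 1]")
        nest = df[["domain", "component", "item"]].drop_duplicates()
        if (nest.groupby("item")["component"].nunique() > 1).any():
            raise DataError("an item maps to more than one component")
        if (nest.groupby("component")["domain"].nunique() > 1).any():
            raise DataError("a component maps to more than one domain")
        if spec.grouping is not None:
            given = spec.grouping[["domain", "component", "item"]].drop_duplicates()
            merged = nest.merge(given, on=["domain", "component", "item"])
            if len(merged) != len(nest):
                raise DataError("supplied grouping map conflicts with the table")
        if spec.center_success:
            s = s - s.mean()

        self.spec = spec
        self.s = s
        self.interior = (y > 0.0) & (y < 1.0)
        self.n0 = int((y == 0.0).sum())
        self.n1 = int((y == 1.0).sum())
        yi = y[self.interior]
        self.log_y = np.log(yi)
        self.log_1my = np.log1p(-yi)
        self.si = s[self.interior]

        self.groups: dict[str, list[str]] = {}
        self.dropped: list[str] = []
        # the item (cell) determines its component and domain, so the row-level
        # gather/scatter runs over cells and is then aggregated per level
        cell_codes, cell_labels = pd.factorize(df["item"], sort=True)
        self.n_cells = len(cell_labels)
        self.cell_ix = cell_codes[self.interior]
        cell_map = (
            df[["item", "component", "domain"]]
            .drop_duplicates()
            .set_index("item")
            .loc[list(cell_labels)]
        )
        self.cell_to: dict[str, np.ndarray] = {}
        for level in LEVELS:
            codes, labels = pd.factorize(df[level], sort=True)
            if len(labels) < 2:
                logger.warning(
                    "level %r has a single group; its varying effects are dropped", level
                )
                self.dropped.append(level)
                continue
            self.groups[level] = list(labels)
            if level == "item":
                self.cell_to[level] = np.arange(self.n_cells)
            else:
                lookup = {lab: k for k, lab in enumerate(labels)}
                self.cell_to[level] = np.array(
                    [lookup[v] for v in cell_map[level]], dtype=int
                )
        if spec.include_participant_intercepts:
            codes, labels = pd.factorize(df["participant"], sort=True)
            if len(labels) < 2:
                logger.warning("single participant; participant intercepts dropped")
                self.dropped.append("participant")
                spec_participant = False
            else:
                self.groups["participant"] = list(labels)
                self.part_ix = codes[self.interior]
                spec_participant = True
        else:
            spec_participant = False
        self.with_participant = spec_participant
        self.hier_levels = [lv for lv in LEVELS if lv in self.groups]

        # parameter layout
        self.blocks: list[tuple[str, int]] = [
            ("b0", 1), ("b1", 1), ("logit_alpha", 1), ("logit_gamma", 1), ("log_phi", 1)
        ]
        for level in self.groups:
            if level == "participant":
                self.blocks.append(("log_sd_participant", 1))
                self.blocks.append(("raw_participant", len(self.groups[level])))
            else:
                k = len(self.groups[level])
                self.blocks.append((f"log_sd_{level}_int", 1))
                self.blocks.append((f"raw_{level}_int", k))
                self.blocks.append((f"log_sd_{level}_slope", 1))
                self.blocks.append((f"raw_{level}_slope", k))
        self.slices: dict[str, slice] = {}
        off = 0
        for name, size in self.blocks:
            self.slices[name] = slice(off, off + size)
            off += size
        self.dim = off
        # Each raw block is sampled in rotated coordinates w with raw = H w,
        # H orthonormal with first column 1/sqrt(K): the standard-normal
        # prior is rotation invariant, and w[0] isolates the group-mean
        # direction whose trade-off with the fixed effects is the slowest
        # posterior direction — the sampler gives those coordinates a dense
        # mass block.
        self.rot: dict[str, np.ndarray] = {}
        for name, size in self.blocks:
            if name.startswith("raw_"):
                self.rot[name] = _mean_first_rotation(size)
        # The fixed effects are sampled as TOTALS (fixed effect plus the
        # group-mean components of every varying-effect block): in a balanced
        # design the likelihood identifies only the totals, so sampling them
        # directly removes the slow fixed-vs-group-mean posterior direction.
        self.int_mean_blocks = [
            (f"raw_{lv}_int", f"log_sd_{lv}_int", len(self.groups[lv]))
            for lv in self.hier_levels
        ]
        if self.with_participant:
            self.int_mean_blocks.append(
                ("raw_participant", "log_sd_participant", len(self.groups["participant"]))
            )
        self.slope_mean_blocks = [
            (f"raw_{lv}_slope", f"log_sd_{lv}_slope", len(self.groups[lv]))
            for lv in self.hier_levels
        ]
        self.dense_idx = np.array(
            [
                self.slices[name].start
                for name, size in self.blocks  # scalars and each block's w[0]
            ],
            dtype=int,
        )

    # -- packing helpers ----------------------------------------------------

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = 0.01 * rng.normal(size=self.dim)
        n_int = len(self.log_y)
        n = n_int + self.n0 + self.n1
        mean_i = float(np.exp(self.log_y).mean()) if n_int else 0.5
        x[self.slices["b0"]] = logit(np.clip(mean_i, 0.05, 0.95))
        x[self.slices["logit_alpha"]] = logit(np.clip((self.n0 + self.n1 + 1) / (n + 2), 0.02, 0.98))
        x[self.slices["logit_gamma"]] = logit(np.clip((self.n1 + 1) / (self.n0 + self.n1 + 2), 0.02, 0.98))
        x[self.slices["log_phi"]] = np.log(10.0)
        for name, _ in self.blocks:
            if name.startswith("log_sd"):
                x[self.slices[name]] = np.log(0.1)
        return x

    def logp_grad(self, x: np.ndarray):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(x)

    def _mean_adjustment(self, x, blocks):
        sl = self.slices
        return sum(
            np.exp(x[sl[sd_name]][0]) * x[sl[raw_name]][0] / np.sqrt(k)
            for raw_name, sd_name, k in blocks
        )

    def _logp_grad(self, x: np.ndarray):
        pr = self.spec.priors
        g = np.zeros_like(x)
        sl = self.slices
        adj0 = self._mean_adjustment(x, self.int_mean_blocks)
        adj1 = self._mean_adjustment(x, self.slope_mean_blocks)
        b0 = x[sl["b0"]][0] - adj0  # x holds the totals
        b1 = x[sl["b1"]][0] - adj1
        la = x[sl["logit_alpha"]][0]
        lg = x[sl["logit_gamma"]][0]
        lphi = x[sl["log_phi"]][0]
        alpha, gamma_p, phi = expit(la), expit(lg), np.exp(lphi)
        gb0 = 0.0  # accumulated d logp / d b0 (chained to totals at the end)
        gb1 = 0.0

        n_int = len(self.log_y)
        logp = 0.0

        # endpoint masses (counts only)
        n01 = self.n0 + self.n1
        with np.errstate(divide="ignore"):
            logp += n01 * np.log(alpha) if n01 else 0.0
            logp += n_int * np.log1p(-alpha) if n_int else 0.0
            logp += self.n1 * np.log(gamma_p) if self.n1 else 0.0
            logp += self.n0 * np.log1p(-gamma_p) if self.n0 else 0.0
        g[sl["logit_alpha"]] += n01 * (1 - alpha) - n_int * alpha
        g[sl["logit_gamma"]] += self.n1 * (1 - gamma_p) - self.n0 * gamma_p

        # interior beta likelihood
        if n_int:
            if abs(lphi) > 15.0:  # precision out of floating range: reject state
                return -np.inf, g
            cell_int = np.zeros(self.n_cells)
            cell_slope = np.zeros(self.n_cells)
            int_effects = {}
            for level in self.hier_levels:
                sd_i = np.exp(x[sl[f"log_sd_{level}_int"]][0])
                sd_s = np.exp(x[sl[f"log_sd_{level}_slope"]][0])
                eff_i = sd_i * (self.rot[f"raw_{level}_int"] @ x[sl[f"raw_{level}_int"]])
                eff_s = sd_s * (self.rot[f"raw_{level}_slope"] @ x[sl[f"raw_{level}_slope"]])
                amap = self.cell_to[level]
                cell_int += eff_i[amap]
                cell_slope += eff_s[amap]
                int_effects[level] = (sd_i, eff_i, sd_s, eff_s)
            if self.with_participant:
                sd_p = np.exp(x[sl["log_sd_participant"]][0])
                eff_p = sd_p * (self.rot["raw_participant"] @ x[sl["raw_participant"]])
                n_part = len(eff_p)
            else:
                sd_p, eff_p, n_part = 0.0, np.empty(0), 0

            if _beta_lik_kernel is not None:
                ll_beta, gg_cell, gg_cell_s, gg_p, dphi = _beta_lik_kernel(
                    self.log_y, self.log_1my, self.si, self.cell_ix,
                    self.part_ix, self.with_participant,
                    cell_int, cell_slope, eff_p, b0, b1, phi,
                    self.n_cells, n_part,
                )
                logp += ll_beta
            else:
                eta = (
                    b0 + cell_int[self.cell_ix] + (b1 + cell_slope[self.cell_ix]) * self.si
                )
                if self.with_participant:
                    eta = eta + eff_p[self.part_ix]
                # saturated logits are kept just inside (0, 1); the likelihood
                # gradient there is ~0 so the tiny inconsistency is harmless
                mu = expit(np.clip(eta, -30.0, 30.0))
                a = mu * phi
                b = (1.0 - mu) * phi
                logp += float(
                    np.sum((a - 1.0) * self.log_y + (b - 1.0) * self.log_1my)
                    + n_int * gammaln(phi)
                    - np.sum(gammaln(a))
                    - np.sum(gammaln(b))
                )
                dig_a = digamma(a)
                dig_b = digamma(b)
                # d logp / d eta, scattered to cells once and then per level
                grow = mu * (1.0 - mu) * phi * (self.log_y - self.log_1my - dig_a + dig_b)
                gg_cell = np.bincount(self.cell_ix, weights=grow, minlength=self.n_cells)
                gg_cell_s = np.bincount(
                    self.cell_ix, weights=grow * self.si, minlength=self.n_cells
                )
                if self.with_participant:
                    gg_p = np.bincount(self.part_ix, weights=grow, minlength=n_part)
                dphi = float(
                    np.sum(mu * self.log_y + (1.0 - mu) * self.log_1my)
                    + n_int * digamma(phi)
                    - np.sum(mu * dig_a)
                    - np.sum((1.0 - mu) * dig_b)
                )

            gb0 += gg_cell.sum()
            gb1 += gg_cell_s.sum()
            for level in self.hier_levels:
                k = len(self.groups[level])
                amap = self.cell_to[level]
                sd_i, eff_i, sd_s, eff_s = int_effects[level]
                gg_i = np.bincount(amap, weights=gg_cell, minlength=k)
                gg_s = np.bincount(amap, weights=gg_cell_s, minlength=k)
                g[sl[f"raw_{level}_int"]] += sd_i * (gg_i @ self.rot[f"raw_{level}_int"])
                g[sl[f"log_sd_{level}_int"]] += float(eff_i @ gg_i)
                g[sl[f"raw_{level}_slope"]] += sd_s * (gg_s @ self.rot[f"raw_{level}_slope"])
                g[sl[f"log_sd_{level}_slope"]] += float(eff_s @ gg_s)
            if self.with_participant:
                g[sl["raw_participant"]] += sd_p * (gg_p @ self.rot["raw_participant"])
                g[sl["log_sd_participant"]] += float(eff_p @ gg_p)
            g[sl["log_phi"]] += phi * dphi

        # priors (the normal prior sits on the fixed effects, not the totals)
        logp += -0.5 * (b0**2 + b1**2) / pr.fixed_scale**2
        gb0 += -b0 / pr.fixed_scale**2
        gb1 += -b1 / pr.fixed_scale**2
        # chain d/d b0 to the sampled totals and mean coordinates
        g[sl["b0"]] += gb0
        g[sl["b1"]] += gb1
        for blocks, gb in ((self.int_mean_blocks, gb0), (self.slope_mean_blocks, gb1)):
            for raw_name, sd_name, k in blocks:
                sd = np.exp(x[sl[sd_name]][0])
                w0 = x[sl[raw_name]][0]
                g[sl[raw_name].start] += -sd / np.sqrt(k) * gb
                g[sl[sd_name]] += -sd * w0 / np.sqrt(k) * gb
        # beta priors on alpha, gamma with the logit Jacobian folded in
        logp += pr.inflate_a * np.log(alpha) + pr.inflate_b * np.log1p(-alpha)
        logp += pr.inflate_a * np.log(gamma_p) + pr.inflate_b * np.log1p(-gamma_p)
        g[sl["logit_alpha"]] += pr.inflate_a * (1 - alpha) - pr.inflate_b * alpha
        g[sl["logit_gamma"]] += pr.inflate_a * (1 - gamma_p) - pr.inflate_b * gamma_p
        # gamma prior on phi with the log Jacobian
        logp += pr.phi_shape * lphi - pr.phi_rate * phi
        g[sl["log_phi"]] += pr.phi_shape - pr.phi_rate * phi
        # half-normal hyper-SD priors (log parameterization) and N(0,1) raws
        for name, _ in self.blocks:
            if name.startswith("log_sd"):
                sd = np.exp(x[sl[name]][0])
                logp += -0.5 * sd**2 / pr.sd_scale**2 + x[sl[name]][0]
                g[sl[name]] += 1.0 - sd**2 / pr.sd_scale**2
            elif name.startswith("raw_"):
                raw = x[sl[name]]
                logp += -0.5 * float(raw @ raw)
                g[sl[name]] += -raw
        if not np.isfinite(logp) or not np.all(np.isfinite(g)):
            return -np.inf, np.zeros_like(g)
        return logp, g


_MONITOR_PREFIXES = ("b0", "b1", "logit_alpha", "logit_gamma", "log_phi", "log_sd")


def fit_zoib_multilevel(table: SurveyTable, spec: MultilevelSpec | None = None) -> ZOIBPosterior:
    """Sample the posterior of the multilevel ZOIB model.

    Raises :class:`ConvergenceError` (naming the offending parameters) if
    any monitored hyper-parameter misses the split-chain R-hat or effective
    sample size thresholds in ``spec``.
    """
    import arviz as az

    spec = spec or MultilevelSpec()
    model = _ZOIBModel(table, spec)
    root = np.random.default_rng(spec.seed)
    chains = []
    divergences = 0
    for c in range(spec.chains):
        rng = np.random.default_rng(root.integers(2**31))
        res = sample_hmc(
            model.logp_grad,
            model.initial_point(rng),
            n_warmup=spec.warmup,
            n_draws=spec.draws,
            rng=rng,
            max_leapfrog=spec.max_leapfrog,
        )
        chains.append(res.draws)
        divergences += res.divergences
    raw = np.stack(chains)  # (chains, draws, dim)

    draws: dict[str, np.ndarray] = {}
    sl = model.slices
    for name, size in model.blocks:
        block = raw[:, :, sl[name]]
        if name.startswith("log_sd"):
            draws[name.replace("log_sd", "sd")] = np.exp(block[:, :, 0])
        elif name == "logit_alpha":
            draws["alpha"] = expit(block[:, :, 0])
        elif name == "logit_gamma":
            draws["gamma"] = expit(block[:, :, 0])
        elif name == "log_phi":
            draws["phi"] = np.exp(block[:, :, 0])
        elif name in ("b0", "b1"):
            mean_blocks = (
                model.int_mean_blocks if name == "b0" else model.slope_mean_blocks
            )
            adj = sum(
                np.exp(raw[:, :, sl[sd_name].start]) * raw[:, :, sl[rn].start] / np.sqrt(k)
                for rn, sd_name, k in mean_blocks
            )
            draws[name] = block[:, :, 0] - adj  # fixed effect, not the total
    # per-group effects on the natural (sd * raw) scale
    for level in model.groups:
        if level == "participant":
            draws["participant_int"] = np.exp(raw[:, :, sl["log_sd_participant"]]) * (
                raw[:, :, sl["raw_participant"]] @ model.rot["raw_participant"].T
            )
        else:
            for kind in ("int", "slope"):
                draws[f"{level}_{kind}"] = np.exp(
                    raw[:, :, sl[f"log_sd_{level}_{kind}"]]
                ) * (raw[:, :, sl[f"raw_{level}_{kind}"]] @ model.rot[f"raw_{level}_{kind}"].T)

    monitored = {
        k: v for k, v in draws.items()
        if k in ("b0", "b1", "alpha", "gamma", "phi") or k.startswith("sd_")
    }
    idata = az.from_dict(posterior=monitored)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    diag = pd.DataFrame(
        {
            "parameter": list(monitored),
            "rhat": [float(rhat[k].values) for k in monitored],
            "ess": [float(ess[k].values) for k in monitored],
        }
    )
    offenders = diag[
        (diag["rhat"] > spec.rhat_threshold) | (diag["ess"] < spec.min_ess)
    ]["parameter"].tolist()
    post = ZOIBPosterior(
        draws=draws,
        groups=dict(model.groups),
        diagnostics=diag,
        divergences=divergences,
        dropped_levels=list(model.dropped),
        spec=spec,
    )
    if offenders:
        raise ConvergenceError(
            "MCMC did not meet diagnostics (rhat <= "
            f"{spec.rhat_threshold}, ess >= {spec.min_ess:g}) for: "
            + ", ".join(offenders),
            offenders=offenders,
        )
    return post


def rank_predictors(posterior: ZOIBPosterior, ci: float = 0.90) -> PredictorRanking:
    """Order hierarchy levels by posterior median slope SD and groups within
    levels by absolute posterior median slope (fixed + varying part); ties
    break lexicographically by label. Deterministic given the draws."""
    lo, hi = 50 * (1 - ci), 50 * (1 + ci)
    rows = []
    for level in LEVELS:
        name = f"sd_{level}_slope"
        if name not in posterior.draws:
            continue
        x = posterior.stacked(name)
        rows.append(
            {
                "level": level,
                "median_sd": float(np.median(x)),
                "ci_low": float(np.percentile(x, lo)),
                "ci_high": float(np.percentile(x, hi)),
            }
        )
    if not rows:
        raise DataError("posterior has no slope hyper-SDs to rank")
    levels = (
        pd.DataFrame(rows)
        .sort_values(["median_sd", "level"], ascending=[False, True])
        .reset_index(drop=True)
    )
    b1 = posterior.stacked("b1")
    group_slopes = {}
    for level in LEVELS:
        key = f"{level}_slope"
        if key not in posterior.draws:
            continue
        eff = posterior.stacked(key) + b1[:, None]
        med = np.median(eff, axis=0)
        df = pd.DataFrame(
            {
                "group": posterior.groups[level],
                "median_slope": med,
                "ci_low": np.percentile(eff, lo, axis=0),
                "ci_high": np.percentile(eff, hi, axis=0),
            }
        )
        df["abs_median"] = df["median_slope"].abs()
        df = df.sort_values(["abs_median", "group"], ascending=[False, True]).reset_index(
            drop=True
        )
        group_slopes[level] = df.drop(columns="abs_median")
    return PredictorRanking(
        levels=levels,
        best_level=str(levels.iloc[0]["level"]),
        group_slopes=group_slopes,
    )
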