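# Methods

`implfx` implements three analytic engines used in implementation-
effectiveness research on nursing care-delivery models — a robust
interrupted time series (ITS) with an estimated change point, a Bayesian
multilevel zero–one-inflated beta (ZOIB) regression of survey ratings, and
set-theoretic configurational analysis (QCA) — together with synthetic-data
generators that emulate the statistical structure each engine assumes. The
real survey and patient-satisfaction data behind this line of research are
proprietary, so every engine is validated against simulated data whose
ground truth is known and returned alongside the dataset.

## Robust interrupted time series

**Model.** A monthly outcome series $y_t$, $t = 1..n$, switches regime at an
unknown change point $\tau$ (the first month of the new regime):

$$
y_t = \begin{cases}
\beta_0 + \beta_1 t + e_t, & t < \tau\\
\beta_2 + \beta_3 (t - \tau + 1) + e_t, & t \ge \tau
\end{cases}
$$

with $e_t$ a stationary Gaussian AR(1) whose innovation SD and lag-1
autocorrelation are regime-specific ($\sigma_1, \rho_1$ pre, $\sigma_2,
\rho_2$ post) and which restarts from its stationary distribution at
$\tau$. The post-regime clock restarts at 1, so $\beta_2$ is the post
level. The change point is treated as fixed but unknown: for each candidate
$\tau$ in a window around the nominal intervention month (default
$[\text{nominal}-3,\ \text{nominal}+12]$, clipped so each regime keeps
`min_segment` = 3 months) both segments are fitted by exact maximum
likelihood — the regression line by Prais–Winsten GLS and the innovation
variance in closed form at fixed $\rho$, with $\rho$ optimized numerically —
and the candidate with the largest summed log-likelihood wins, ties broken
toward the earliest. This is how the model captures the lag between an
intervention's introduction and its effect. Whether "variance" means the
innovation or the marginal series variance is ambiguous in verbal accounts
of such models; the innovation variance is tested, and the implied marginal
SD $\sigma/\sqrt{1-\rho^2}$ is reported alongside.

**Inference.** Mean, variance and autocorrelation changes are each tested
by a likelihood ratio against the constrained model (single global trend
line / common innovation variance / common autocorrelation), with the
change point re-profiled under *both* hypotheses. The asymptotic
chi-square reference (df 2/1/1) is available but anti-conservative —
estimating the change point inflates the statistic; a calibration run
during development measured type-I rates of roughly 0.31/0.13/0.08 at
$\alpha = 0.05$ for the three tests. The default is therefore a parametric
bootstrap: simulate from the constrained fit, re-run the full double
profiling on every replicate through a vectorized evaluator (regression
and variance concentrated out in closed form on a fixed autocorrelation
grid), and compare the observed statistic — computed through the identical
evaluator, which makes observed and replicate values exchangeable under
the null — via the Monte-Carlo p-value $(1 + \#\{T_b \ge T_0\})/(B+1)$.

The simulation parameters deserve care on short segments. They are
extracted from the constrained fit at the *nominal* intervention month,
not at the profiled change point: profiling selects the lowest-variance
configuration and would hand the bootstrap systematically deflated
innovation variances and autocorrelations. On top of that, two standard
small-sample corrections are applied to the plug-ins: the innovation
variance is inflated by $m/(m - p - 1)$ for the $p$ trend parameters fitted
per segment, and the AR coefficient by its estimation bias
$\approx (1 + 3\rho + p(1+\rho)/2)/m$. With these, 500 null simulations
put all three tests' rejection rates at 5.0–6.4% at $\alpha = 0.05$,
inside the exact binomial band around the nominal level.

Two numerical details. A variance floor of $10^{-12}$ keeps the profile
finite and comparable when a segment fits exactly (a noiseless series);
such fits are flagged degenerate, the mean change is still recovered
exactly and the variance ratio is reported as undefined. Second,
Monte-Carlo p-values have a granularity floor of $1/(B+1)$, so
multiple-testing decisions use $p_{\text{adj}} \le \alpha$ (not $<$);
with $B = 199$ a Holm-corrected decision over 10 units is otherwise
logically impossible.

**Known power limitation.** Because the constrained (equal-means) model
keeps a free post-regime autocorrelation, an AR coefficient near 1 can
absorb a level shift; at 48 months the mean-change test's power is
non-monotone in the step size and genuinely modest. This is the honest
price of not assuming the error structure fixed under the null. Variance
and autocorrelation changes do not suffer from this.

**Panel analysis ("consistency in outcome").** Every unit × metric series
is fitted; the per-unit decision "variability reduced" is the two-sided
$(1-\alpha)$ CI of the innovation-variance ratio lying entirely below 1
(log-normal CI, df adjusted for the trend fit). Mean-change p-values are
Holm-corrected across units within a metric; the pooled (across-unit
average) series per metric is analyzed the same way with Holm correction
across metrics, since the hospital-level claims form their own family.
Pooling by averaging is exact here: AR(1) components with a common
$\rho$ sum to an AR(1) with that $\rho$.

## Synthetic panels

`simulate_its`/`simulate_panel` generate the model above; AR errors start
from the stationary distribution (no burn-in artifacts), and the lag is
encoded solely as `nominal_intervention < true_changepoint` with an abrupt
regime switch — no ramp, since the shape of a gradual transition is an
open question for this design. `simulate_panel` optionally adds a
hospital-level AR(1) month effect shared by all units of a metric, which
is what keeps a pooled series noisy when idiosyncratic unit noise averages
out — the mechanism behind units improving significantly while the
hospital aggregate does not.

Two documented scenario builders fix the study-shaped conditions:

* `consistency_scenario`: 10 units × 7 metrics, 144 months (72 per
  regime), unit innovation SD 1.0 and shared-effect SD 2.0 both halved
  after the change point (variance ratio 0.25), lag 3, autocorrelation
  0.3, and a mean gain of 0.3 points planted only in the 3 lowest-baseline
  units. The length is chosen so that the per-series sampling SD of the
  log variance ratio (≈ 0.24 at 72+72 months) leaves all 70 simultaneous
  variance-reduction flags with a comfortable margin; at 24+24 months that
  SD is ≈ 0.43 and a simultaneous-flag requirement would fail almost
  surely even though every series' variance truly halves.
* `unit_gain_scenario`: single metric, no shared effect, gain 4.0 in the
  3 lowest-baseline units — sized for unit-level mean-change detection.

## Multilevel zero–one-inflated beta regression

**Model.** Ratings and success scores are proportions in $[0,1]$ (raw
scores divided by their maximum; `to_proportion`). A rating is an endpoint
with probability $\alpha$ (then 1 with conditional probability $\gamma$,
else 0) and otherwise beta-distributed with mean $\mu$ (logit link) and
precision $\phi$:

$$\operatorname{logit}(\mu_{pi}) = b_0 + b_1 s_p
 + u^{dom}_{d(i)} + u^{comp}_{c(i)} + u^{item}_i
 + (v^{dom}_{d(i)} + v^{comp}_{c(i)} + v^{item}_i)\, s_p + w_p,$$

with varying intercepts $u$ and success slopes $v$ for domains, components
and items (items nested in components nested in domains) and participant
intercepts $w_p$. $\alpha$ and $\gamma$ are population constants — they are
two extra mixture parameters, not regressed on success. The posterior SDs
of the $v$'s at each level measure how much that level discriminates
implementation success; groups within a level are ranked by the absolute
posterior median of $b_1 + v_g$, ties broken lexicographically.

**Priors** (weakly informative): $b_0, b_1 \sim N(0, 2^2)$; all hyper-SDs
half-normal(1); $\phi \sim$ Gamma(2, 0.1); $\alpha, \gamma \sim$
Beta(2, 2). Success enters raw (proportion scale); centering is available
via `center_success`.

**Computation.** The posterior is sampled with the package's Hamiltonian
Monte Carlo sampler: analytic gradients (the interior beta likelihood and
its gradient accumulators are JIT-compiled), static trajectories with the
number of leapfrog steps drawn uniformly from the upper half of
`max_leapfrog`, dual-averaging step-size adaptation, and a diagonal mass
matrix re-estimated twice during warmup. Two parameterization choices
matter for geometry: varying effects are non-centered, sampled in rotated
coordinates whose first component is the group mean; and the fixed effects
are sampled as *totals* (fixed effect plus the group-mean components of
every block), because in a balanced design the likelihood identifies only
those totals — sampling them directly removes the slowest posterior
direction. Split-chain R-hat and effective sample size (via arviz) are
attached to every fit; a fit that misses the configured thresholds raises
`ConvergenceError` naming the offenders rather than returning silently.
Defaults (4 chains, 1000 warmup + 1000 draws, R-hat ≤ 1.01, ESS ≥ 400)
suit production use; the test suite runs 2 chains with a 400+500 first
attempt and a retry ladder, declaring R-hat ≤ 1.1 and ESS ≥ 25 — adequate
for medians and 90% intervals, stated openly as short-MCMC settings.

**What recovery simulations can and cannot show.** With the study-shaped
hierarchy (5 domains × 3 components × 2 items, 100 participants) and
planted slope SDs 0.16/0.29/0.09, 90% credible intervals cover the true
hyper-SDs at close to nominal rates (≈ 0.95 measured over 140
parameter–replicate pairs; slightly above 0.90 because few-group hyper-SD
posteriors are wide). Ranking the *component* level first by posterior
median, however, succeeds in only ≈ two-thirds of replicates: the realized
SD of five simulated domain slopes rarely flips above the component
level's (≈ 1 replicate in 20), but the posterior median of a 5-group
hyper-SD is noisy and prior-influenced enough to flip the ranking in
roughly a third of replicates. That is an identification limit of the
design, not a defect a longer chain fixes; single-dataset rankings at
these sizes should be read together with their credible intervals. The
generator draws effects normally at every level, participants rate every
item, and success scores are spread over a grid — real surveys have
missing cells, response styles and ceiling effects the generator does not
emulate.

## Qualitative comparative analysis

Necessity and sufficiency of condition $X$ for outcome $Y$ are measured on
fuzzy memberships by the min-sum formulas
$\text{cons}_{nec} = \sum\min(x,y)/\sum y$,
$\text{cons}_{suf} = \sum\min(x,y)/\sum x$, each with the mirrored
coverage; crisp data reduce these to 2×2-table proportions. Raw scores are
calibrated to memberships with the direct method: a piecewise-logistic map
sending the three anchors (full non-membership, crossover, full
membership) to 0.05 / 0.5 / 0.95, strictly monotone, with decreasing
anchors supported for negated conditions.

Truth tables assign each case to the configuration of its strongest
memberships (per-condition membership > 0.5; cases at exactly 0.5 are
excluded with a warning), code rows positive when the configuration's
sufficiency consistency reaches `cons_cutoff` (default 0.8; frequency
cutoff 1), and flag crisp rows with disagreeing outcomes as contradictory.
Minimization is Quine–McCluskey over the positive rows only — the
conservative solution; remainders are never used as counterfactuals —
followed by an essential-then-greedy irredundant cover. The solution is
logically equivalent to the disjunction of positive rows by construction,
which the tests verify exhaustively for every outcome coding of a
3-condition table. Consistency and coverage of the solution and its terms
are computed against the original (fuzzy) memberships.

The QCA generator plants a sufficient Boolean expression and, optionally,
a necessary condition (enforced as a fixpoint $P \ge Y$); with
`noise_rate` $r$, a Bernoulli($r$) subset of cases has its outcome
complemented, so planted-solution consistency degrades to ≈ $1-r$.

## Reproducibility and problem sizes

All randomness is seeded: generators take explicit seeds, the pipeline
derives per-stage substreams from one root seed by hashing, and bootstrap
and MCMC seeds live in the model configs, so identical configurations
reproduce identical outputs bit for bit. The shipped test suite and
`scripts/acceptance.py` use study-shaped but desk-scale problem sizes —
500 null simulations for test calibration, 200 series for change-point
oracle agreement, 20 survey replicates for hyper-SD recovery, the full
256-coding sweep for minimization — chosen so a complete run stays within
tens of minutes on one CPU.

## Known limitations

* Missing months are an error, never imputed; the AR likelihood on gapped
  series is out of scope, as are seasonality, higher-order AR and
  comparative (control-series) ITS designs.
* The mean-change bootstrap test is conservative for large level shifts on
  short series (free null autocorrelation; see above).
* The HMC sampler is static-trajectory; posteriors far harder than the
  ZOIB class (heavy funnels, multimodality) would need an adaptive
  trajectory sampler.
* Only the conservative QCA solution is produced; intermediate and
  parsimonious solutions, multi-value QCA and panel QCA are out of scope.
* Whether the original robust-ITS treats the change point as fixed
  (profiled) or random (Bayesian) is not documented in the sources this
  package follows; the profile treatment here is an interpretation.
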