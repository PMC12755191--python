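# Methods

`pulsediv` studies whether *response diversity* — variation among species in
how they respond to an environmental change — stabilises aggregate community
biomass under a *pulse* disturbance (an abrupt, temporary temperature drop),
and how interspecific competition modulates that relationship. It combines a
mechanistic simulation arm with a meta-analysis-style statistical arm, tied
together by shared response and stability metrics.

## Community model

Each community holds `S` species (default 10). Species `i` has a Gaussian
thermal performance curve for its birth rate and carrying capacity, both
centred on its temperature optimum `bopt_i`:

    b_i(T) = bmax * exp(-(T - bopt_i)^2 / (2 sigma_b^2))
    K_i(T) = Kmax * exp(-(T - bopt_i)^2 / (2 sigma_K^2))
    r_i(T) = b_i(T) - d0

Defaults: `bmax = 1`, `sigma_b = 5 °C`, `d0 = 0.05`, `Kmax = 1`,
`sigma_K = 10 °C` (all per-species-configurable). The Gaussian form is the
minimal thermal performance curve with a single optimum; real curves are
typically left-skewed, and this symmetry matters for what the simulations
show (see *Limitations*). The death rate is deliberately small: the Ricker
update below becomes dynamically unstable whenever `r_i(T) < 0` while
`N > K_i(T)` (declining species above their thermal carrying capacity enter
a positive feedback with finite-time divergence). `d0 = 0.05` keeps
`r_i(T) > 0` for thermal offsets up to ~12 °C, which covers every
temperature–optimum combination reachable in the default design, so all
14,175 default-grid communities integrate stably.

Dynamics are the discrete-time (Ricker) competitive Lotka–Volterra map

    N_i(t+1) = N_i(t) * exp( r_i(T) * (1 - sum_j alpha_ij N_j(t) / K_i(T)) )

which preserves non-negativity with zero absorbing. Intraspecific
coefficients are fixed at `alpha_ii = 1`; interspecific `alpha_ij` are drawn
from a left-skewed normal (shape −4, location/scale chosen in closed form so
the untruncated mean and sd both equal `alpha_sd`), clipped to [0, 1] so
interactions are purely competitive and their average strength rises with
`alpha_sd`. Dynamics are deterministic; all randomness is in community
assembly (optima uniform on `bopt_mean ± bopt_range/2`, then the interaction
matrix), driven by one seed per community.

## Disturbance protocol

Two runs per community from identical initial abundances
(`K_i(T_control)/S`): a control at 22 °C for 750 steps, and a disturbed run
identical until step 500, then at 15 °C for 50 steps, then back at 22 °C.
The first 500 steps are an equilibration period; only steps ≥ 500 enter the
analysis window, whose time axis is affinely rescaled to [0, 1].

Following the source protocol, species with fewer than 10 analysis-window
time points above abundance 10⁻³ are dropped from *species-level realised*
calculations (counting a time point if either arm is above threshold;
configurable to a single arm). Community totals are never filtered.

## Response metrics

*Fundamental response* (species in isolation): the IGR effect
`r_i(T_pulse) − r_i(T_control)`; negative for warm-adapted species under the
cold pulse, positive for cold-adapted ones, zero at the 18.5 °C midpoint.
Note the death rate cancels in this difference.

*Realised response* (species in community): with the per-time-point response
ratio `RR = (treat − con)/(treat + con)` (0 where both are 0; bounded in
[−1, 1]), the realised response is the trapezoidal AUC of `RR` over
normalized time — hence also in [−1, 1].

Community summaries over a response vector `x`:

- **mean** — arithmetic mean; 0 indicates balance of declines and gains.
- **dissimilarity** — Leinster–Cobbold similarity-sensitive diversity at
  sensitivity `q = 0` (exposed for general `q`): pairwise distances
  `|x_i − x_j|` rescaled by their maximum, similarity `Z = 1 − d`, uniform
  weights `p_i = 1/S`, ordinariness `(Zp)_i`, diversity
  `(Σ p_i (Zp)_i^{q−1})^{1/(1−q)}` (at `q = 0`: `Σ p_i/(Zp)_i`). Ranges over
  [1, 2] for scalar responses; exactly 1 iff all responses are equal
  (defined as 1 for the degenerate all-equal case, where the rescaling step
  would divide by zero). Uniform weights are used because in this framework
  `p` is a weight vector, with the responses entering through `Z`; this is
  what makes the [1, 2] bounds attainable.
- **divergence** — with `a = max(x)`, `b = min(x)`:
  `((a − b) − ||a| − |b||)/(a − b)` (0 if `a = b`). Zero when all responses
  share one sign, 1 iff `a = −b`; invariant under negation and positive
  scaling. **This formula is a reconstruction**: the printed source formula
  is degenerate (identically zero), so the implementation uses the unique
  simple range-comparison satisfying all three stated boundary behaviours.
  A consequence worth knowing: divergence has a point mass at exactly 0
  for every one-signed response vector.

## Stability metrics

Community instability is Overall Ecological Vulnerability: the *signed*
trapezoidal AUC of the total-biomass response ratio
`tot.RR = (Treat.Tot − Con.Tot)/(Treat.Tot + Con.Tot)` over normalized time
(`oev`), keeping negative and positive deviations distinct; `oev_abs`
integrates the magnitude of the interpolated curve (zero crossings inserted,
so opposite-sign deviations accumulate rather than cancel). The
decomposition: resistance = `tot.RR` at the first window sample;
recovery = `tot.RR` at the last; resilience = OLS slope of `tot.RR` against
normalized time over the recovery phase (from the pulse end for simulated
data; from the window start for empirical series, where the pulse precedes
the first sample — configurable via `recovery_from`); temporal stability =
inverse CV (mean/sd, sample sd) of disturbed total biomass. Undefined cases
(zero-variance biomass, < 2 recovery samples) are reported as NaN, never 0.

## Factorial design

The default grid crosses 7 `alpha_sd` levels (0, 0.05, 0.1, 0.15, 0.25,
0.35, 0.5) × 27 `bopt_mean` levels (15–21.5 °C, step 0.25) × 15 `bopt_range`
levels (0–7 °C, step 0.5) × 5 replicates = 14,175 communities (2,025 per
interaction-strength level), matching the source study's printed totals; the
exact level values are otherwise a reconstruction and the design is fully
config-driven. Per-run seeds derive deterministically from a base seed and
the grid coordinates (`numpy.random.SeedSequence`), so any subset is
reproducible in isolation; per-run failures are logged with coordinates and
skipped rather than aborting a grid. Tests and the acceptance script use a
reduced grid (3 × 5 × 5 × 5 = 375 communities at the full 750-step
protocol, ~10 s on one CPU) chosen as a subsample of the default levels.

## Synthetic empirical generator

Emulates a pulse-disturbance meta-analysis database (default 134
experiments): per experiment, 3–12 species, 3–12 sampling times on [0, 1]
(endpoints always included), paired control/disturbed series, multiplicative
lognormal noise (sd 0.1) applied independently per arm. Treatment series are
built by *inverting* the response-ratio formula from a known profile
`RR_i(t) = delta_i exp(−rho_i t)`, so each species' true response is exact
by construction and |RR| < 1 guarantees positive treatment abundances.

`generate_dataset` additionally embeds a linear instability–mean-response
relation with coefficients `beta0 = 0`, `beta1 = 0.97` (the scale of the
source study's empirical slope) plus experiment-level noise (sd 0.08): the
per-experiment mean response is drawn uniform on [−0.55, 0.25] (mostly
negative, as pulse disturbances produce), species responses are paired
jittered deviations around that mean (time-constant, so the community
response ratio is a closed-form weighted mean of the species values), and
control abundances are solved so the measured OEV equals the target exactly
in the noise-free limit. What this generator does *not* emulate: taxonomic
composition, disturbance-type covariates, publication structure,
within-series autocorrelated dynamics, or unequal arm noise — so passing
recovery tests demonstrate the pipeline's correctness, not robustness to
those real-data features.

## Meta-regression

The headline model is an *unweighted mixed-effects meta-analysis*:
`OEV ~ mean + dissimilarity + divergence` with a random intercept per
experiment and sampling variances fixed at 1 (the standard reading of
"unweighted"; equivalently metafor's `rma.mv(yi, V = 1, mods,
random = ~1|id)`). Fixing the sampling variance keeps the between-experiment
variance τ² identifiable even with one observation per experiment. τ² is
estimated by a REML profile (ML optional) using per-group Sherman–Morrison
inverses; fixed effects by GLS at τ̂²; moderator tests are raw normal-theory
z-tests (no multiplicity correction, matching the source's reporting).
Moderators enter on their raw scale. This model is implemented directly
because general mixed-model software estimates the residual scale rather
than fixing it; tests cross-check it against R's metafor to ~1e-5 and
against OLS in the τ² = 0 limit. Note the unit-variance z-tests are
calibrated for response values on a meta-analysis scale; for simulation-grid
OEV values (magnitude ~10⁻²) they are extremely conservative, so
grid-level relationships are asserted via sign and rank statistics instead.

## Numerical choices

- Trapezoidal integration everywhere an AUC is taken; time normalized per
  experiment/window before integration so areas are comparable across
  experiments of different duration.
- `response_ratio(0, 0) = 0`: species absent from both arms are "unaffected"
  and generate no spurious signal.
- Rare-filter boundary: exactly 10 qualifying entries is *included*
  ("fewer than 10" are removed).
- The bounded REML optimizer never evaluates τ² = 0 exactly; the boundary is
  checked explicitly and snapped when it is no worse.
- Pre-onset segments of the paired runs are simulated once and shared — the
  schedules are identical there, so this is exact, not an approximation.
- No extinction floor: abundances may become arbitrarily small; the rare
  filter handles them at analysis time.

## Known limitations

- The Gaussian thermal performance curve is symmetric, so cold-adapted
  communities gain roughly what warm-adapted communities lose under the
  pulse; grid-mean OEV is consequently near zero and ratio-type summaries of
  it (percent change across competition levels) are ill-conditioned.
  Asymmetric curves would break this cancellation.
- The divergence metric's point mass at zero for one-signed communities
  caps its rank correlation with dissimilarity on grids where many
  communities respond one-signedly.
- The resistance convention (first post-onset sample) gives ~0 for
  simulated trajectories, where the first window sample precedes any
  divergence between arms; the maximal-deviation alternative is not
  implemented, but `decompose` accepts any window.
- Press disturbances, fluctuating regimes, stochastic dynamics,
  facilitation (negative interactions), and evolutionary change are out of
  scope.
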