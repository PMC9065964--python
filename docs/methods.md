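# Methods

`woo` models the establishment of a young organism with stage-dependent
tolerance in a temporally variable environment, and the statistics of the
*windows of opportunity* (WoO) — benign intervals long enough for the
organism to outgrow the returning harsh conditions.

## Model and assumptions

The environment is a scalar stressor `E(t)`; the organism's state is its
tolerance `T(t)`.  From inception (birth, germination, attachment) at a
benign moment (`E < T0`), tolerance grows deterministically from `T0`,
either linearly (`T = T0 + λt`) or exponentially (`T = T0·exp(λt)`).  The
organism dies instantaneously the first time `T < E` and establishes
irreversibly once its tolerance can no longer be exceeded by the
environment.  All stochasticity lives in the environment; there is no
demographic noise, density dependence or tolerance decay.

Three environment classes are implemented:

1. **Regular dichotomous**: a square wave alternating between `E_low`
   (benign, duration `τ_low`) and `E_high` (harsh, duration `τ_high`).
2. **Dichotomous Markov noise (DMN)**: a random telegraph signal with
   transition rates `k_low`, `k_high`; residence times are exponential
   with means `⟨τ_low⟩ = 1/k_low`, `⟨τ_high⟩ = 1/k_high`.
3. **Ornstein–Uhlenbeck-type (OUN) red noise**: the discrete recursion
   `E ← E + c·(μ − E)·dt + ε·R`, `R ~ N(0,1)` per step.

### Closed-form theory

With a tolerance gap `δ = E_high − T0` (floored at 0), a linear grower
needs the critical window `τ_crit = δ/λ`; equivalently a window of length
`τ_low` demands the critical rate `λ_crit = δ/τ_low`.  Exponential growth
uses the corresponding inverse `τ_crit = ln(E_high/T0)/λ`.  For DMN, the
benign-window length density is `P(τ_low) = k_low·exp(−k_low·τ_low)`, so
the probability that a window is a WoO is the survival function at the
critical length,

    P_WoO = exp(−k_low · τ_crit).

On the regular-dichotomous critical boundary — where the critical window
equals the mean window, `k_low·τ_crit = 1` — this is `1/e ≈ 0.368`
regardless of the other parameters.

Each `(T0, E_low, E_avg, E_high)` configuration falls into exactly one of
four regimes: (i) `T0 ≥ E_high`, always establishable; (ii)
`E_high > T0 ≥ E_avg`, benign on average but variance destroys
opportunity; (iii) `E_avg > T0 > E_low`, harsh on average but variance
creates windows; (iv) `T0 ≤ E_low`, never establishable.  Ties follow the
printed inequality pattern (`T0 = E_high → i`, `T0 = E_avg → ii`,
`T0 = E_low → iv`).  Establishment succeeds at equality `T = E_high` and
death requires strictly `T < E`, so the marginal organism with
`λ = λ_crit` exactly is successful.

`p_establishment` compounds `P_WoO` over the expected number of windows
in a horizon, `N = horizon/(1/k_low + 1/k_high)`, as
`P_est = 1 − (1 − P_WoO)^N`.  This expected-window-count model is a
documented reconstruction, not a derived result; treat it as indicative.

Similarly, the occurrence diagram maps a `(E_avg, σ²(E))` cell to a
symmetric two-point envelope `E_low/E_high = E_avg ∓ σ` (equal residence,
so `σ = (E_high − E_low)/2`) with mean benign window `⟨τ⟩/2`.  This
envelope convention is the simplest mapping consistent with the two-point
moments and is likewise a design choice of this package.

## Numerical design

- **DMN generation** draws per-state geometric run lengths with success
  probability `k·dt` — the exact law of per-step Bernoulli switching —
  and starts from the stationary state distribution
  `p_low = k_high/(k_low+k_high)`.  `k·dt ≥ 1` is an error; `k·dt ≥ 0.1`
  warns, since the discretised waiting times then deviate visibly from
  exponential.
- **OUN drift convention.**  Two autoregressive coefficients are
  offered: the *printed* form `a = 1 − (1 − 1/⟨τ⟩)·dt` and the standard
  mean-*reverting* form `a = 1 − dt/⟨τ⟩`.  The printed form is the
  package default for the raw generator, but it is non-stationary for
  `⟨τ⟩ ≤ 1` and its correlation time is `≈ 1/(1 − 1/⟨τ⟩)`, i.e. nearly
  independent of `⟨τ⟩` when `⟨τ⟩` is large — it cannot express a
  tenfold change of period.  The experiment presets and the f_WoO
  studies therefore use the reverting form, whose correlation time is
  `≈ ⟨τ⟩`, keeping all study periods `⟨τ⟩ ∈ {0.1, 1, 10}` stationary.
- **Variance scaling.**  Both forms are AR(1) in the deviation from the
  mean, with stationary variance `ε²/(1 − a²)`; `scale_epsilon` inverts
  this (`ε = sqrt(σ²·(1 − a²))`) so runs with different `⟨τ⟩` share the
  same stationary variance.  This is validated against simulated sample
  variances, not assumed.
- **Windows** are maximal runs of samples with `E < T0`, half-open in
  continuous time (sample `i` covers `[t0+i·dt, t0+(i+1)·dt)`), so a run
  of `m` samples has duration `m·dt`.  Windows touching either series
  boundary are flagged censored and excluded from duration statistics by
  default — boundary truncation biases the exponential fit.
- **Attempts** incept at each window's opening sample only: the
  from-inception clock starts when conditions first permit, and windows
  are the unit of analysis throughout.  An attempt establishes once
  tolerance reaches the maximum of the remaining series (death is then
  impossible), except at the final sample, whose suffix maximum is
  trivially itself; surviving to the end without establishing is a
  *censored* outcome, counted as not attainable (conservative) and
  tallied separately.
- **Tie tolerance.**  Survival/establishment comparisons carry an
  absolute+relative slack of 1e-9 so that float round-trips such as
  `(δ/τ)·τ ≠ δ` cannot kill the analytically marginal organism.
- **Autocorrelation** uses the biased (1/N) normalisation; the reported
  correlation time is the smallest positive lag with normalised
  autocorrelation ≤ 1/e (series length if never reached; 0 with a
  warning for a constant series).
- **Seeding.**  Every stochastic entry point takes an integer seed;
  replicated experiments derive child seeds as
  `SeedSequence(master, spawn_key=(replicate,))`, so results are
  independent of execution order and common random numbers across
  parameter values come for free by sharing the master seed.  f_WoO
  curves over a λ grid reuse the same trajectories for every λ, which
  makes monotonicity in λ exact rather than statistical.

## Synthetic data and what the tests show

All inputs are generated internally; there is no empirical forcing data.
The generators emulate stationary two-level switching and stationary
Gaussian red noise with chosen mean, variance and correlation time.
They do not emulate trends, seasonality/phase structure (tidal or annual
cycles), heavy-tailed or skewed stressors, or multiple interacting
stressors — passing tests therefore demonstrate internal consistency of
the framework and its statistics under idealised noise, not predictive
skill on field series.

Default study conditions: DMN experiments use `E_low = 0`, `E_high = 1`,
`k_low = 0.1`, `k_high = 0.2`, `dt = 0.01`, organism `T0 = 1/6`
(`δ = 5/6`), linear growth; OUN experiments use `μ = 1`, `⟨τ⟩ = 1`,
`σ²(E) = 0.5`, `dt = 0.01`, series of 1000 steps replicated 1000 times
(presets) — the same `T0 = 1/6` is used for the OUN threshold, which
reproduces the episodic, high-spread emergence at `σ² = 0.25`.  The
occurrence diagram defaults to `⟨τ⟩ = 10`, `λ = 0.05`.  Tests and the
acceptance checks run the OUN orderings at 200 replicates and the
Monte-Carlo equivalence checks on ~10⁴ windows, sizes at which the
relevant standard errors are a few times smaller than the asserted
tolerances.

## Known limitations

- Only the emergence transition is modelled; extinction/collapse
  dynamics and flickering between states are out of scope.
- `P_est` and the occurrence-diagram envelope are reconstructions (see
  above); quantities derived from them carry that caveat.
- The per-step switching scheme is first-order accurate in `k·dt`;
  rates near the `0.1` warning threshold shorten apparent waiting times
  by O(k·dt).
- The printed OUN drift degenerates at `⟨τ⟩ = 1` (random walk) and is
  explosive for `⟨τ⟩ < 1`; it is retained for fidelity but guarded by
  explicit stationarity errors.
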