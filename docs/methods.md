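# Methods

This note documents the model, the numerical choices, and the design
decisions behind `deltapoint`, in the spirit of a model reference rather
than a tutorial.

## Model and assumptions

The input is a univariate, regularly sampled, piecewise locally stationary
series: stationary stretches separated by abrupt changes in mean, variance,
dependence structure or trend. The method is explicitly *not* designed for
periodic signals (the kernel has no periodic component by design), and it
assumes a single change point is of primary interest to the user.

Three layers:

1. **GP time-series predictive (gp module).** `y_t = f(t) + ε_t`,
   `f ~ GP(0, k)`, `ε_t ~ N(0, σ²)`, with the rational quadratic kernel on
   time indices: `k(t,t') = s²(1 + d²/(2αℓ²))^(−α)`, `d = |t − t'|`. The RQ
   kernel is a scale mixture of squared exponentials; small `α` gives heavy
   tails over length scales (in practice the fitted `α` on the synthetic
   series is ≪ 1, i.e. strongly mixed), and `α → ∞` recovers the squared
   exponential — computed stably as `s² exp(−α log1p(d²/2αℓ²))`. The
   one-step-ahead predictive includes the observation-noise term `+σ²` so
   that the recursion scores the noisy observation, not the latent function.
2. **BOCPD recursion (bocpd module).** Constant hazard parameterised through
   a logit, `h = σ(θ_h)`; default `θ_h = −3.982` (h ≈ 0.0183, one prior
   change per ~55 steps). The run-length posterior is propagated in log
   space with log-sum-exp accumulation; masses below `log(1e-6)` are pruned
   (the MAP entry is always kept) and support above `max_runlength` (default
   500) is merged into the cap rather than dropped, so no posterior mass is
   ever discarded wholesale.
3. **Delta point layer (delta module).** Declared change points are treated
   as a doubly stochastic Poisson process. The intensity surrogate is the
   change-point mass `Λ(t) = p(r_t = 0 | y_1:t)` per step and intervals
   integrate it by summation. Note an identity worth knowing: with a
   constant hazard the *filtered* change mass equals `h` at every step
   (both branches of the recursion score `y_t` identically), so `m_i = h·|I|`
   and the Poisson layer's count probability is a diagnostic of count
   anomalousness, not an evidence term. Evidence about changes lives in the
   *retrospective* reshaping of the run-length posterior, which is what the
   declaration rule reads.

## Detection pipeline

`standardize → fit → sweep → declare → select`:

* **Standardization.** The series is z-scored with the mean/sd of the
  training prefix; detected times are reported on the input time axis.
* **Fitting.** Type-II maximum likelihood on the training prefix (default
  200 points), multi-start (default 3 restarts in the pipeline, seeded
  log-normal perturbations of the init) L-BFGS-B in log-parameter space with
  analytic gradients; box bounds `e^±9.2` keep every hyperparameter finite
  and the Gram matrix well conditioned. The fit never returns parameters
  scoring below the init. Hyperparameters are frozen during monitoring.
* **Monitoring span.** The sweep runs over the whole series from the delta
  state `p(r=0)=1`: the training prefix informs the hyperparameters and the
  standardization but is also monitored, since changes of interest may
  pre-date the end of the training window. (`monitor_from_start=False`
  restricts monitoring to the post-training suffix.)
* **Sweep cost.** For a stationary kernel on contiguous integer times the
  predictive for run length `r` depends on times only through `r`, so the
  solve `(K_r + σ²I)⁻¹k*` is precomputed once per `r` (bordered Cholesky,
  `O(r²)` per extension); each step of the sweep is then one dot product
  per retained run length. A 500-point series sweeps in well under a second.

### Declaration rule

How suspected change points are read off the run-length posterior is a
genuine design choice; the recursion itself does not define one. The
default (`map_surge`) declares a change at step `t` when

1. the MAP run length drops by more than one (a reset), **and**
2. the new MAP hypothesis holds at least `2×` the fresh-change mass
   `p(r_t = 0 | y_1:t)`.

Condition 2 exists because a constant hazard makes the MAP flip *without
evidence* in long homogeneous stretches: the continuation hypothesis loses
prior mass at rate `(1−h)` per step, so after roughly `log h / log(1−h)`
(≈ 215 steps at the default hazard) the argmax drifts onto a young run even
when nothing changed. At such a flip the posterior is flat near the hazard
baseline; at a real change, mass concentrates far above it (measured on the
synthetic series: flat flips peak at ≈ 1.1–1.3 h, real resets at 4–50 h, so
any factor in ~[1.5, 3] separates them; 2 is the default). A refractory
window (pipeline default: half the interval length `j`) suppresses
"aftershock" re-declarations fired while the GP re-adapts to the new
regime. The declared run length is the amount of history the posterior
discarded at the reset — the distance from the pre-drop run's birth to the
new run's origin (equivalently, the MAP drop size plus one). This estimate
of the completed segment is robust in two directions the raw pre-drop MAP
run length is not: a change detected late does not credit the completed
segment with the detection lag (the new run's origin reaches back to the
change), and a segment truncated by an earlier *false* reset is recovered
whenever the posterior re-adopts the full-history hypothesis before the
real change arrives. The raw pre-drop MAP attachment (`attachment="map"`),
a posterior-tail attachment (`"tail"`; rejected as default because
long-dead "no change yet" hypotheses stay marginally alive for hundreds of
steps on weak-evidence changes and corrupt it), the unguarded rule
(`map_reset`) and a mass-threshold rule (`threshold`) remain available as
switches.

### Selection rule

Among intervals holding at least one suspected change point, the selected
interval maximises the average attached run length, with fewest count and
then earliest start as tie-breakers; the Delta point is its longest-run
member (earliest on ties). The fewest-count/longest-average criterion is a
joint verbal rule; run length leads the ordering here because a long
completed run is direct evidence of a stable preceding regime, whereas a
small count alone is satisfied by any lone noise blip that happens to be
isolated in its interval — count-first selection measurably doubles the
mean detection error on the level-shift and dependence-change benchmarks.
The per-interval conditioned score `log P(C_i; m_i) + log r̄_i` is reported
as a diagnostic but does not drive selection. Empty intervals are excluded;
a final remainder interval shorter than `j` participates normally.

## Synthetic data

The generators emulate three change types at fixed, realistic noise
(`ε_t ~ N(0,1)` throughout, `X_0 = 0`, `ε_0 = 0` for the MA lag):

* **Series 1** — scaled noise `ε_t/3` switching to AR(1) (`ρ₁`, default
  0.7) on `t ∈ [150, 350]` and back: a dependence/variance change.
* **Series 2** — AR(1) (`ρ₂`, default 0.4) with a +3 level shift on
  `t ∈ [175, 325]`: an abrupt mean jump.
* **Series 3** — ARMA(1,1) (`ρ₃`, default 0.5, MA weight 0.5) with the
  trend `0.02t − 4` added on `t ∈ [225, 375)` and a `+4` plateau after: a
  noise-obscured trend onset. The overlapping boundary at `t = 375` is
  resolved as trend before, plateau from 375 on — the trend reaches 3.5
  there, so the series stays continuous.

The ρ defaults are the values the study reports results for; uniform
resampling of ρ per replicate is available (`resample_rho`). The noisy
Donoho–Johnstone Blocks/Bumps fixtures use the standard 2,048-point
construction plus i.i.d. Gaussian noise of configurable sd (no canonical
noise level exists for them; the Blocks label is the 0.65 breakpoint, 1331,
and the Bumps label the 0.23 breakpoint, 471, the construction point
nearest the conventional label).

What the generators do *not* emulate: artifacts with temporal structure
(sensor dropouts, baseline wander), heteroscedastic or heavy-tailed noise,
and periodic physiology. Passing the simulation tests therefore shows
correct recovery of the three modeled change types under Gaussian noise,
not robustness to everything real recordings contain.

## Evaluation harness

Per replicate the harness records the Delta point and aggregates
`|detected − true|` (mean, sample sd) and `MSE/10³`, the study table's
layout; `mean² + population variance = MSE·10³` holds by construction.
Two-sided Welch t-tests compare two methods' absolute differences. The
simulation study at desk scale uses 100 replicates per series (the original
uses 1,000); with the observed sds this puts ~1–4 step standard errors on
the means, and hyperparameters are re-fitted per replicate since each
replicate is an independent series. Replicates with no suspected change
point at all would be excluded and counted (`n_missed`); at the study's
noise levels none occur.

## Numerical choices and degenerate inputs

* All probability arithmetic in log space; states renormalize to 1 ± 1e-8
  over full runs (tested).
* Predictive variances are floored at σ² against round-off; Gram matrices
  are PD by construction for σ² > 0.
* A constant training prefix standardizes with sd 1 instead of dividing by
  zero; a predictive failure for one run length falls back to the prior
  predictive with a logged warning rather than poisoning the state.
* Tie-breaks: interval selection prefers fewest count then earliest start;
  within-interval selection prefers the earliest among equally long runs.
* Determinism: every stochastic component (generators, restarts, replicate
  scheduling) is a pure function of its seed; replicate seeds are spawned
  from a `SeedSequence` of the study seed and kept below 2³¹.

## Known limitations

* The filtered change mass being constant (= h) means intensity-based
  interval diagnostics cannot distinguish intervals; they are reported for
  interpretability, and selection rests on counts and run lengths.
* Weak-evidence changes (variance drops; slow trends as in Series 3) are
  detected late or attributed to nearby spurious resets; the dependence
  change of Series 1 occasionally (~5–10% of replicates) breaks the first
  run early, which no declaration rule we evaluated fully removes.
* The interval length `j` is user-set; no optimal choice is attempted.
* Hyperparameters are frozen after the prefix fit; regime-dependent noise
  within the monitored span is absorbed by the run-length posterior, not
  the GP.
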