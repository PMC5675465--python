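# Methods

## Model

Two slow state variables are integrated through a sleep/wake history:
total adenosine concentration `A_tot` (nM) and total A1 receptor
concentration `R1_tot` (nM). All concentrations are in nM and all times in
hours throughout the package; clock time is `t mod 24` with 0 = midnight.

**Adenosine kinetics.** `chi dA_tot/dt = mu − A_tot`, with
`(mu_wake, chi_wake)` in waking and `(mu_sleep, chi_sleep)` in sleep and
`A_tot` continuous across transitions. Production is higher and clearance
slower in waking, so `A_tot` relaxes upward toward `mu_wake` (time constant
18.18 h) when awake and downward toward `mu_sleep` (4.20 h) when asleep —
the same time constants classically used for the fast sleep homeostat,
which this variable reproduces on sub-day timescales.

**Quasistatic binding.** Binding/unbinding at A1 and A2A receptors is
orders of magnitude faster than the pool dynamics, so the mass-action
kinetics are taken to be at equilibrium at every instant. With the unbound
A2A pool held at its total (`R2_tot = 300` nM; A2A affinity is ~100-fold
weaker than A1, so A2A receptors are mostly unoccupied at physiological
free adenosine), the A2A pathway reduces to a constant partition fraction
`beta = R2_tot/(R2_tot + Kd2)` and the bound A1 pool is the smaller root of
a quadratic in `(A_tot, R1_tot, Kd1/(1−beta))`. The smaller root is the
physical one (`0 ≤ A1_b ≤ min(A_tot, R1_tot)`); it is evaluated in the
rationalized form `2AR/(b + sqrt(b² − 4AR))`, which is exact algebraically
and avoids catastrophic cancellation at high concentrations. The explicit
mass-action ODE system is retained in the package only as a brute-force
cross-check (`kinetic_oracle`), with the same frozen-A2A assumption so the
two routes describe the same chemistry; equilibrium depends only on the
dissociation constants, not on the individual rate magnitudes.

**Receptor homeostasis.** `lambda dR1_tot/dt = R1_b − gamma R1_tot`: the
pool up-regulates when occupancy `R1_b/R1_tot` exceeds the target `gamma`
and down-regulates below it, with `lambda ≈ 291 h` setting the weeks-long
timescale of chronic sleep-restriction effects. An exact consequence is
that on any periodic steady state the time-average bound pool equals
`gamma` times the time-average total pool; this integral identity is used
as an acceptance check on the integrator.

**Sleep drive and performance.** `D = R1_b + a cos(omega (t − phi))`
(`omega = 2*pi/24 h⁻¹`; `phi = 7.95` h, early-morning maximum of circadian
sleep promotion). Predicted PVT lapses are
`P = p_max/(1 + exp((D_mid − D)/D_s))`, a bounded, strictly increasing
sigmoid; `p_max = 60` reflects the trial-count ceiling of a 10-minute test
at the ~4 s response times seen under severe impairment (a subject lapsing
on every trial at exactly 500 ms would score 92). `P` is sampled
instantaneously at test times; the 10-minute test duration is not
integrated over. Sleep-inertia exclusion is honored by the sampling
schedule (first test 4 h after waking), not by modifying `P`.

**Two-threshold switching.** In free-sleep windows the model transitions
to sleep when `D` rises through `D_sleep` and to wake when it falls through
`D_wake < D_sleep`; between the thresholds the current state persists (the
standard hysteresis reading of two-process thresholds — the rule fires on
crossings only). Later in a sleep bout the drive may legitimately re-exceed
`D_sleep` through the circadian rise; the model stays asleep until the wake
threshold is reached. Forced-wake boundaries truncate open bouts.

## Numerics

* `A_tot` advances by its exact exponential solution within each
  constant-vigilance span; no discretization error.
* `R1_tot` advances by fixed-step classical RK4 (default `dt = 0.01` h),
  recomputing the bound pool at every stage with `A_tot` evaluated from its
  closed form at the stage time. The equation is slow and non-stiff;
  fixed-step keeps runs bit-reproducible. Halving the step changes a 24 h
  endpoint by < 1e-8 relative.
* Threshold crossings are located by bisection on `D` within the
  integration step that brackets the crossing (one RK4 sub-step per
  candidate), to a time tolerance of 1e-6 h. If a threshold is already met
  at window entry, the transition occurs at the window start.
* Limit-cycle initialization iterates the 24 h day map until the boundary
  state changes by < 1e-8 relative, with Aitken extrapolation every third
  iterate (the day map contracts at only ~exp(−24/lambda) ≈ 0.92/day); the
  convergence test is always on the plain day map, so the accelerated
  result satisfies the same fixed-point contract. The receptor pool is
  seeded at the level in equilibrium with the schedule-average adenosine
  (solved by bisection on occupancy), avoiding multi-week burn-in.
* The inner loops are numba-compiled (`_kernels.py`); the staged fits
  evaluate tens of thousands of multi-week simulations.
* Bouts separated by < 5 min are merged before scoring (polysomnographic
  scoring ignores momentary arousals); nights are classified by merged
  bout count (monophasic/biphasic/polyphasic). Nightly scoring windows run
  18:00–08:00.

## Parameters

Defaults are the full calibration. Units: concentrations nM, times h.

| name | default | meaning | constraint |
|---|---|---|---|
| `Kd1` | 1 | A1 dissociation constant | 1–10 (physiological) |
| `Kd2` | 100 | A2A dissociation constant | 100–10 000 |
| `chi_wake`, `chi_sleep` | 18.18, 4.20 | adenosine time constants | fixed |
| `mu_wake`, `mu_sleep` | 869.5, 596.4 | adenosine asymptotes | `mu_wake > mu_sleep > 0` |
| `lambda_` | 291 | receptor regulation time constant | > 100 |
| `gamma` | 0.9677 | target occupancy fraction | 0.75–0.97 |
| `R2_tot` | 300 | total A2A receptors | fixed |
| `a`, `phi` | 3.25, 7.95 | circadian amplitude, acrophase | `a ≥ 0`, `phi ∈ [0, 24)` |
| `p_max` | 60 | lapse ceiling | fixed |
| `D_mid`, `D_s` | 583.2, 5.872 | sigmoid midpoint, width | `D_s > 0` |
| `D_sleep`, `D_wake` | 572.7, 555.4 | switching thresholds | `D_wake < D_sleep` |

`ModelParameters.pvt_fit()` gives the PVT-only calibration (nominal
`lambda_ = 300`, `D_mid = 579.3`, `D_s = 5.603`).

Useful steady-state identities: `gamma ≈ <A_u>/(<A_u> + Kd1)` (≈ 0.9677 at
the typical 30 nM free adenosine and `Kd1 = 1`); the typical total
concentration on a regular 8 h-sleep day is `0.3583 mu_wake +
0.6417 mu_sleep` (plain average of the periodic sleep-onset and wake-onset
boundary values; the coefficients are exact functions of `T` and the chi's
and sum to exactly 1, so the wake coefficient rounds to 0.36).

## Protocols

* **Forced-schedule presets** (`build_exp1`): 88 h acute deprivation, or
  13 nights of restricted sleep (achieved sleep 3.7 h or 5.5 h for the 4 h
  and 6 h time-in-bed groups) followed by two 7.0 h recovery nights, or 15
  nights of 6.8 h (8 h time-in-bed group). All conditions share three
  7.0 h baseline nights and limit-cycle initialization on a 7.8 h-sleep
  pre-study day; every sleep episode is anchored to end at 08:00 (wake
  time was the experimentally fixed anchor; within-night placement of
  achieved sleep is otherwise unreported, so the end-anchored convention
  is used and is config-overridable via inline schedules). PVT samples run
  every 2 h from wake + 4 h, stopping at the last gridpoint strictly
  before the next sleep onset (no evening cutoff is imposed).
* **Long-night preset** (`build_exp2`): limit-cycle initialization on a
  7 h-sleep-from-midnight day, then 50 days of forced wake 08:00–18:00
  with a free 14 h window 18:00–08:00.

## Staged calibration

1. **PVT stage** (`PVTStage1Estimator`): all adenosine/performance
   parameters fit to lapse counts on the forced protocols with `lambda_`
   at its nominal 300 h (forced-schedule predictions are insensitive to
   it). Physiological box constraints are enforced by smooth logistic
   reparameterization so the Levenberg–Marquardt machinery runs
   unconstrained. Three identification devices matter:
   `gamma` is tied to the occupancy relation at 30 nM free adenosine
   (flag `tie_gamma`); `mu_sleep` is tied to `mu_wake` through the
   typical-concentration identity evaluated at `A_u = 30` nM and
   `R1_tot = 600` nM (flag `tie_mu`; with both mus free the objective is
   degenerate — the concentration scale trades off against `D_mid`); and
   `D_mid` is parameterized as an offset from the baseline drive implied
   by the physiological parameters, since a fixed absolute midpoint
   leaves the sigmoid saturated (objective flat) over most of the search
   space. The optimizer is an in-package damped LM with Marquardt
   scaling, a step-norm cap, and monotone acceptance: the objective has
   large saturated-sigmoid plateaus, and an unrestrained Gauss–Newton
   step can vault onto one and stall, which is exactly how the stock
   MINPACK implementation fails here. Accepted-iteration costs are
   recorded (`cost_trace_`) and are strictly decreasing.
2. **Sleep-timing stage** (`SleepTimingStage2Estimator`): `lambda_`,
   `D_sleep`, `D_wake` fit to daily total sleep durations of the
   long-night protocol by exhaustive grid search (the least-squares
   landscape is far too flat and multimodal for LM). The thresholds are
   gridded as midpoint and hysteresis gap — the SSE valley runs along
   nearly constant midpoint — and the search proceeds digit-by-digit on
   decimal-aligned grids (the resolution the procedure certifies, at
   least 3 significant figures per parameter: final steps 1 h in
   `lambda_`, 0.05 nM in midpoint, 0.1 nM in gap). Because daily
   durations are piecewise smooth with bout-structure knife edges, the
   surface is multimodal across regimes organized by the gap: an anchor
   survey refines the thresholds within every gap band at a few anchor
   `lambda_` values, then the thresholds are profiled out near the
   winning basin at each candidate `lambda_` while `lambda_` itself is
   refined. Gaps below 2 nM are excluded from the default domain (they
   produce threshold chatter — hundreds of sub-minute bouts per night
   that scoring merges away). Ties break toward the smallest `lambda_`,
   then the smallest midpoint, then the smallest gap. Limit-cycle
   initializations are cached per `lambda_` (thresholds do not affect
   forced-schedule initialization).
3. **Recalibration** (`SigmoidRecalibrationEstimator`): `D_mid` and `D_s`
   refit to the PVT data with everything else fixed. The drive
   trajectory is independent of the sigmoid, so this is a two-parameter
   logistic fit on precomputed drives; sleep/wake outputs are bit-wise
   untouched by construction.

Model evaluations inside the fits default to `dt = 0.02` h (RK4 error at
this step is ~1e-10 relative, far below observation noise); simulation
elsewhere defaults to 0.01 h. Adjusted R² uses the Wherry/Ezekiel form
with the stage's free-parameter count.

## Synthetic observations

The group-average observation series the model was originally calibrated
against are not redistributable, so `fixtures.py` generates synthetic
ones: the named protocol is simulated at known parameters and i.i.d.
Gaussian noise is added (default sd 2 lapses for PVT counts, truncated to
`[0, p_max]`; durations truncated to `[0, 14]` h), with a JSON sidecar
recording the generating truth. The noise model is a test convention —
the originals are group means with unknown error structure — so passing
recovery tests demonstrates that the staged workflow identifies the
parameters it claims to identify under the stated protocols and noise,
not that the model fits any particular empirical data set. Generating
truths for stage-1 recovery are first projected onto the stage-1
constraint surface (`stage1_consistent_params`), since a truth outside
the fitted model class would conflate recovery error with deliberate
model restriction. Published goodness-of-fit statistics for the original
data cannot be recomputed without those series; the package reports the
same metrics (SSE, RMSE, adjusted R²) on the synthetic surface instead.

## Known limitations

* The circadian process is a fixed 24 h sinusoid: protocols involving
  re-entrainment (jet lag, shift work) need a dynamic circadian model.
* No regional adenosine heterogeneity; A2A receptor regulation, caffeine,
  cytokines, and allostatic set-point changes are out of scope; the
  A2A unbound pool is frozen at its total.
* Circadian–homeostatic interaction is linear by design.
* Group-average behavior only; no individual-differences machinery.
* The sleep-timing objective (daily totals) identifies the receptor time
  constant only weakly away from exact data; on noisy data many
  parameter-space points fit comparably well, which is why the fine-grid
  stage reports its full refinement trail for diagnostics.
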