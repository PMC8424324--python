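# Methods

This note documents the model implemented by `beeodom`, the parameter
choices, the numerical decisions, and what the simulations do and do not
show.

## Plant model

The simulated bee has two decoupled first-order dynamics, identified in prior
behavioural work on honeybee flight:

- vertical: `V_z(s)/u_dPhi(s) = K_z / (1 + tau_z s)` with `K_z = 0.11`
  m s⁻¹ per degree of wing-stroke-amplitude delta and `tau_z = 0.22` s;
- forward: `V_air(s)/u_theta(s) = K_surge / (1 + tau_surge s)` with
  `K_surge = 0.10` m s⁻¹ per degree of pitch and `tau_surge = 0.22` s.

Ground speed is `V_x = V_air + v_wind(h)`, with the logarithmic wind profile
`v_wind = k_wind · v0 · ln(h/h0)` (`v0 = 0.2` m/s, roughness height
`h0 = 0.05` m), clamped to zero at or below `h0` so that take-off from the
ground is well-posed.  Positive `k_wind` is tail wind.  Clearance is
`h = z − elevation(x)` and the clearance rate seen by the ventral sensor is
`V_h = V_z − slope(x)·V_x`, so the optic-flow cues reflect motion relative to
the local ground — this slope term is what lets the clearance filter track
`h` over relief.

Terrain is either flat or three raised-cosine hills,
`elev(x) = s_i · h_peak/2 · (1 − cos(2π(x − x_i + w/2)/w))` on each hill
footprint, width `w = 20` m, centres 25/50/75 m on the 100 m course.  Peak
heights are only characterised in the original SOFIa study as small hills
with gentle slopes of 0/1/2 m peaks, so the geometry above is this package's declared choice, exposed in
the configuration.  The "irregular course" preset scales the three hills by
(0.5, 1.0, 0.75) — hills of 1, 2 and 1.5 m — to exercise varied heights and
slopes in the single-flight demonstrations; the parametric sweep uses uniform
hills so its relief factor has exactly one free level.

## Autopilot

The ventral optic-flow regulator is a PD controller on the error
`e = omega_T_meas − omega_T_set` with `k_P = 15`, `k_D = 0.3`.  The sign
closes a negative feedback loop through the plant's inverse nonlinearity:
extra flow (too low or too fast) commands a larger stroke amplitude, the bee
climbs, and the flow falls.  The derivative acts on a first-order low-pass
filtered error (`tau_d = 20` ms) to avoid step-level derivative noise; the
original model is described only as a PD controller, so the filter is our choice and its
time constant is configurable.

The self-oscillation `A_osc · sin(2π f_osc t)` (18°, 1 Hz) is added to the
regulator output whenever `h ≥ 5` cm; the gate keeps take-off and landing
smooth.  Missions impose pitch over along-track position: a linear ramp from
0 to the cruise pitch over 0–1 m, a plateau, and a descending ramp from
5.5 m (8 m course) or 95.5 m (100 m course) to the course end.  Because the
ramp is a function of position, pitch at `x = 0` would be exactly zero and
the bee would never start moving; a small bootstrap offset (`x_boot = 0.05`
m inside the ramp argument, ≈2° initial pitch) resolves the deadlock.  A run
terminates when the bee crosses the course end or touches down (clearance at
the sensor floor) after the landing ramp has begun; odometers accumulate from
lift-off to termination.

## Sensing

The two observables are pure ratios: `omega_T = V_x/h` and
`omega_div = V_h/h`.  Both are computed noise-free (the original study shows
smooth simulated measurements and reports no noise parameters); optional Gaussian noise
hooks exist for robustness experiments and are the only source of randomness
in the package.  A sensor floor of `h_min = 0.01` m keeps the ratios finite
through touchdown.

## Clearance EKF

State `[h, v_h]` follows the linear vertical model driven by the commanded
stroke amplitude (the efference copy, PD output plus oscillation); the
measurement `omega_div = v_h/h` is nonlinear.  The filter uses the exact
discrete transition of the linear model at the simulation step, a
Joseph-form covariance update, and — a documented adaptation of the SOFIa
model — replaces the clearance estimate by its absolute value after
every step, since clearance is physically positive.  Initial state is 0.5 m
and 1 m s⁻¹ with unit initial covariance.

The original SOFIa study does not disclose its noise covariances.  Defaults
here are
continuous `Q = diag(1e-4, 1e-2)` discretized as `Q·dt`, and `R = 1e-2`
(rad/s)²; a sensitivity test verifies that scaling Q and R by ten in either
direction, independently, keeps the cruise estimation error below 10 %.
With noise-free measurements this tuning yields a near-ideal filter (cruise
tracking error ~0.1–3 %), noticeably tighter than the endpoint errors the
original SOFIa study reports (3.67 % / 5.18 %); consequently the self-scaled
odometer's dispersion over the sweep (MAD ≈ 0.3 m) is about ten times
smaller than the originally reported 3.09 m.  The direction of every
qualitative comparison is unchanged.

Observability: stacking the measurement and its Lie derivative along the
dynamics gives a Jacobian with determinant `u/h³` — the state is locally
observable exactly while the stroke command is non-zero, which the 1 Hz
oscillation guarantees in flight.  The classical statement also requires
`V_h ≠ 0`; the diagnostic reports both conditions.

A consequence of the exact-discretization design worth noting: over flat
ground the filter's internal model matches the simulated plant *exactly*, so
once converged it can dead-reckon `h` without observability and switching the
oscillation off barely degrades it there.  Over relief the slope term makes
`V_h ≠ V_z` and the mismatch accumulates: on the irregular 100 m course the
cruise estimation error grows from 2.6 % (oscillation on) to 18.5 %
(oscillation off), and the distance estimate degrades from −0.5 % to +17.7 %.
The oscillation-necessity property is therefore asserted on the irregular
course, where the claim is physically meaningful.

## Odometers and comparison statistics

`X_sofia = ∫ omega_T_meas · h_hat dt` (metres);
`OFacc = ∫ omega_T_meas dt` (radians).  After a sweep, the raw accumulator's
distribution is mapped to metres with `k_comparisons = 100/median(OFacc)`,
computed from that sweep's own finals — its calibrated median is 100 m by
construction, and the factor exists only so the two distributions can be
compared.  The flight-distance error is `(X_hat − X)/X × 100` with `X` the
ground-truth distance at termination.

The sweep crosses relief peak (0/1/2 m) × wind coefficient (−1.5…1.5, step
0.5) × optic-flow setpoint (2.0…3.5 rad/s, step 0.3 — six levels, the only
count of setpoints in that range and step compatible with a 630-condition
total) × cruise pitch (30°…50°, step 5°).
Dispersion uses the unscaled MAD, `median(|v − median v|)`, and
`rMAD = MAD/median`.  The Brown–Forsythe test is implemented as Levene's
test centred on the median; "Wilcoxon" comparisons between the two models
within a wind class are two-sample rank-sum tests; wind classes are the sign
of `k_wind`.

## Numerical choices

- Fixed step `dt = 1` ms with exact exponential discretization of both
  first-order systems; the 0.22 s time constants and ≤4 Hz oscillations are
  fully resolved, and a convergence test shows <0.1 % endpoint change at
  `dt = 0.1` ms.  The EKF runs at the same rate.
- All conditions of a batch advance in lock-step as NumPy array lanes; lanes
  snapshot their finals when they terminate.  Records are bit-identical
  across re-runs and independent of batch composition.
- A 300 s safety cap flags (never drops) any non-terminating run; no sweep
  condition comes near it (slowest ≈ 59 s of simulated flight).
- Reduced-grid robustness experiments (e.g. the 1–4 Hz oscillation
  comparison) use a fixed 24-condition subgrid: relief {0, 2} m × wind
  {−1, 0, 1} × setpoint {2.3, 3.2} rad/s × pitch {35°, 45°}.

## Limitations

- The simulation is a model of a model: no image formation, no
  elementary-motion-detector noise, no attitude or lateral dynamics, no
  aerodynamics beyond the two identified transfer functions.  Passing tests
  say nothing about real bees' sensory noise or about textured-ground optic
  flow density.
- The originally reported kinematic envelope quotes a maximum ground speed of
  4.95 m s⁻¹, which equals 99 % of the maximum *air* speed
  (`K_surge · 50°`); with the stated wind added to the air speed, tail-wind
  conditions necessarily exceed it (our sweep maximum is 6.34 m s⁻¹, while
  the clearance maximum, 4.32 m, matches the originally reported 4.35 m).  We report
  ground speed as defined and flag the discrepancy rather than redefining
  the quantity.
- Endpoint estimation errors depend on the EKF tuning, whose original
  values are unavailable; with the defaults here they are smaller than the
  originally reported ones, so dispersion-ratio results should be read as "at least as
  strong as" the original contrast, not as an exact reproduction.
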