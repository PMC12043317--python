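# Methods

## Model

`epvsom` analyses a three-population firing-rate circuit of excitatory (E),
parvalbumin (PV) and somatostatin (SOM) neurons,

    tau_X dr_X/dt = -r_X + f_X(q_X),      q_X = [ sum_Y (+/-) w_XY r_Y + I_X ]_+

with a rectified power-law transfer `f_X(q) = alpha_X [q]_+^beta_X`.
Population order is always (E, P, S).  Synaptic weights are stored as
nonnegative magnitudes `w[post, pre]`; the sign of a column follows the
identity of the presynaptic population (E excitatory; PV, SOM inhibitory).
Defaults: `alpha = 1/4`, `beta = 2`, `tau = 10 ms` for all populations;
`wSS = 0` (SOM cells do not inhibit each other in sensory neocortex) except
in the weight-sweep experiments, where it is a sweep axis.

Key assumptions: no transmission delays, no synaptic dynamics, a single
(point-neuron) compartment per population, and modulatory input targeting
only SOM while sensory stimuli target E and PV.

## Operating points and linearization

A state is parameterized *by its rates*: `inputs_for_rates` inverts the
steady-state condition in closed form, `I = f^{-1}(r) - W r`, so gain and
stability are defined at every point of an (rE, rP) grid, including points
whose dynamics are unstable.  The forward solver (`fixed_point`) uses damped
Picard iteration (damping 0.5, tolerance 1e-10, at most 1e5 iterations).
The damped map need not contract even at dynamically stable states (large
PV gain), so a stalled iteration hands over to integrating the rate
dynamics in 0.5 s chunks until the state stops moving; divergence (any rate
beyond 1e6 Hz) or a persistent residual raises `NonConvergenceError`.  That
error is the package's operational definition of "no stable fixed point
reachable from here" and is what masks cells in the vector-field
experiments.

Linearization at an operating point with all net currents positive defines
cellular gains `b_X = f'(q_X)` (for the defaults, `b = sqrt(r)`), the
response matrix

    L = (B^{-1} - W)^{-1} = (1 - BW)^{-1} B,

and the synaptic-pathway series `L = sum_i (BW)^i B`, which converges iff
the spectral radius of `BW` is below one.  Operating points with a
rectified population (q <= 0) refuse to linearize and report the population.

## Stability convention

Stability is measured by the largest real part `lambda_max` of the
eigenvalues of the rate-dynamics Jacobian in units of the common time
constant,

    J = B W - 1,        L = (-J)^{-1} B.

We deliberately do not use the superficially similar matrix `W - B^{-1} =
B^{-1} J`: multiplying by the positive diagonal `B^{-1}` preserves the
determinant-sign (saddle-node) boundary but not Hopf boundaries, and there
are states inside the default rate grid that `W - B^{-1}` calls stable
while the simulated dynamics leave them (oscillatory instability).  With
equal `tau` the chosen convention reproduces exactly the states where
forward simulation diverges or departs.  A flag folds in `T^{-1}` when time
constants differ.  A decoupled population contributes a pure leak
eigenvalue of -1 in these units.  The oscillatory flag (complex leading
eigenvalue) is always reported: leading-eigenvalue switches and
real<->complex collisions are what make `lambda_max` kink along rate or
weight sweeps.

Modulation outcomes report `delta_g = gE_mod - gE` and `delta_lambda =
lambda_max - lambda_max_mod`, both positive when the modulation improves
the quantity; the modulated state is re-solved nonlinearly by default (a
`linear` mode applies `L` directly; the two agree to second order in the
modulation amplitude).

## Reconstructed protocol constants

The weight table and the transfer/noise constants are printed; the
operating points, modulation amplitudes and stimulus probes behind the
summary numbers are not.  They were reconstructed once, by calibrating
round-valued states against the reported numbers, and are frozen in
`epvsom.fixtures` with provenance tags:

* Blank cells of the printed weight table inherit from the row above; the
  resolution is encoded fixture by fixture.  Two rows are not uniquely
  resolvable from the extracted table; they were chosen so that the
  documented qualitative results of those experiments hold (see the
  `fixtures` module docstring).
* Motivating-example circuits: operating rates (3.5, 1.5, 1.5) Hz with SOM
  modulation +0.25 (disinhibitory circuit) and (4, 3, 1) Hz with -0.3
  (PV->SOM feedback), stimulus probe (10, 5) onto (E, PV).  These reproduce
  the reported delta-gain/delta-stability pairs (0.12, -0.03) and
  (0.35, 0.04) to within ~6%.
* Rate-grid vector fields: SOM modulation +/-0.2 and an E-dominant probe
  (10, 0).  An equal-component probe makes the E-gain
  `psi_g (bP^{-1} + wPP - wEP)` change sign inside the grid for the
  resolved weights and scrambles the modulation statistics; the E-dominant
  probe keeps the gain map positive over the stable region and is the
  regime in which all documented sign/structure claims hold simultaneously.
  Probe amplitudes of order 10 are also what make the inclusion thresholds
  |delta_g| > 0.1, |delta_lambda| > 0.01 meaningful.
* Stochastic runs: smoothed noise `tau_xi dxi/dt = -xi + I + sigma*zeta`
  onto E and PV with `tau_xi = 50 ms`, `sigma = 6`, run for 1000 s.  The
  per-step discretization draws a unit normal per Euler step, so the
  stationary input variance `a sigma^2 / (2 - a)` (with `a = dt/tau_xi`)
  depends on the step; at the default `dt = 1 ms` the input s.d. is 0.6,
  which reproduces the order of the reported E-rate variances (10 ms would
  give ~300, 0.1 ms ~0.08).  An `euler-maruyama` mode (zeta scaled by
  `1/sqrt(dt)`) provides the step-independent continuum limit.  Mean
  operating points (1.5, 2.5, 2) Hz with modulation +0.8 and
  (2.5, 2.5, 1.5) Hz with -1.0 reproduce the reported variance pairs
  0.7->1.3 and 1.1->0.8.  Network gain is probed with a unit-amplitude
  (1, 0.5) stimulus on a frozen noise realization; large probes leave the
  near-linear regime and bias the gain distribution downward.
* Tuning experiments: background input (1, 1, 1.5), Gaussian stimulus of
  height 2 and width 20 degrees centred at 90 degrees onto E and PV, SOM
  modulation -0.1, theta sampled every 1 degree (the regression is
  insensitive to the grid).  The additive component is normalized by the
  maximum of the *unmodulated* curve of each population.

## Numerical choices

* Deterministic integration: forward Euler, default `dt = tau/100 =
  0.1 ms`; fixed-point results are insensitive to `dt` once converged
  (halving `dt` moves terminal states by < 1e-6).
* Divergence guard at 1e6 Hz makes unstable runs terminate deterministically.
* Quadrant statistics exclude cells below the thresholds and report
  percentages over included cells; the Q1..Q4 labels follow the package
  convention Q1 = (gain up, stability up), Q2 = (down, up), Q3 = (down,
  down), Q4 = (up, down) — tests and docs refer to sign patterns, not
  labels.
* Heatmap normalization: gain is divided by its maximum absolute finite
  value over the grid; `lambda_max` by |min lambda| (most stable cell maps
  to -1).
* Grid sizes: library default 50x50 over [0.5, 10] Hz; the test suite and
  acceptance checks use 21x21 — every cell is closed-form, so density only
  affects the resolution of summary statistics.
* Stochastic test runs use 300 s (batch-means s.e. of the variance ~2-3%);
  the acceptance script uses the full 1000 s.

## What the tests do and do not show

The analytic layer (response matrix, pathway series, transfer
factorizations, paradoxical threshold) is verified against independent
oracles: Richardson-extrapolated numerical differentiation of the nonlinear
fixed-point map solved by a finite-difference Newton method, and closed
forms on decoupled circuits.  The experiment layer is verified against the
reported summary quantities *under the reconstructed protocols above*; it
shows the circuit mechanisms (gain/stability tangling, disentangling by
SOM feedback, paradoxical onset at the ISN boundary, tuning-curve
arithmetic), not a parameter-free reproduction, since the original
operating points are unpublished.  The model itself idealizes cortical
circuits: three homogeneous populations, deterministic rates plus one
smoothed noise source, no delays or plasticity — agreement here says
nothing about spiking, conductance-based or multi-compartment variants.

## Known limitations

* Multistability is out of scope: `fixed_point` returns the attractor it
  reaches; basins are not mapped.
* `lambda_max` of the modulated state can jump (eigenvalue switches), so
  `delta_lambda` near those switches is sensitive to the modulation
  amplitude; the included-cell statistics inherit that sensitivity.
* The closed-form gain expansion (`network_gain_expanded`) assumes
  `wSS = 0`; the matrix route has no such restriction.
* The stochastic integrator hard-rectifies rates at zero, which slightly
  skews fluctuation statistics at low rates.
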