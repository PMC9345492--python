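# Methods

`astroud` implements two formulations of the same three-population circuit —
excitatory neurons (E), inhibitory neurons (I) and astrocytes (A) — built to
study how gliotransmission moves a cortical network in and out of the
Up-Down switching regime, together with the analyses used to explain the
simulations: piecewise-linear fixed-point theory for the rate model,
self-consistent first-passage theory for the spiking network, and the
threshold segmentation that turns simulations into phase-duration
statistics.

## 1. Rate model

State: population rates `r_E, r_I, r_A` (Hz), adaptation current `a`.
Dynamics

    tau_E dr_E/dt = -r_E + phi_E(I_E - a + sigma*xi_E)
    tau_I dr_I/dt = -r_I + phi_I(I_I + sigma*xi_I)
    tau_A dr_A/dt = -r_A + phi_A(I_A + sigma*xi_A)
    tau_a da/dt   = -a + beta * r_E

with `phi_X(x) = g_X [x - theta_X]_+`, recurrent input
`I_X = J_XE r_E + J_XI r_I + J_XA r_A`, and an independent
Ornstein-Uhlenbeck process `xi_X` per population.  `r_A` is the rate of
gliotransmitter release events, not a firing rate; its negative threshold
`theta_A = -3.5` encodes spontaneous astrocytic activity.  Units: rates Hz,
couplings and `beta` in seconds (so `J*r` is a dimensionless input), time
in ms.

Numerics: forward Euler–Maruyama at `dt = 0.1 ms` (guard `dt <=
min(tau)/4`), with the OU states advanced by their exact discretization
(decay `exp(-dt/tau_ou)`, stationary std `sigma`), so the noise process is
step-size free.  Noise enters inside the transfer argument, not as an
additive term on `dr/dt`.  One master seed spawns three independent
innovation streams (NumPy `SeedSequence`).  Initial conditions default to
the origin.  The scheme is first order; the test suite checks the error
halves with `dt`.

**OU correlation time.** Only the stationary std `sigma = 3.52` is fixed by
the reference parameter set; the correlation time is not.  We default to
`tau_ou = 1 ms` (fast, nearly-white drive) and expose it as a parameter.
Phase-duration statistics of the rate model are insensitive to `tau_ou` well
below `tau_E`; slow drives (tens of ms and beyond) lengthen both phases.

**Operating point.** `theta_E` and `beta` select the regime.  The defaults
`(beta, theta_E) = (3 s, 8)` were chosen, once, as a point where (i) with
all four neuron–astrocyte couplings set to zero the network is silent
(zero segmented Up phases), and (ii) with the couplings at their defaults
(`J_EA = 1`, `J_IA = J_AI = J_AE = 0.5 s`) the network switches
spontaneously between Up and Down phases, with `r_I ~ 10 Hz` during Up
states.  These are the defining features of the reference scenario.  Note a
structural property of this model worth stating explicitly: on the fully
active branch the equilibrium satisfies
`r_E = (25.588 - theta_E - a)/5.118` (reference couplings), so wherever the
no-coupling network is silent the Up-state excitatory rate is necessarily
~2.5–3 Hz — an order of magnitude below the inhibitory rate, which carries
most of the Up-state activity.

## 2. Rate-model fixed points and phase diagram

The model is piecewise linear, so equilibria are solved per rectification
configuration:

* **Down state**: E and I silent, astrocytes on their linear branch at
  `r_A0 = -g_A theta_A / (1 - g_A J_AA)` (3.889 Hz at defaults; requires
  `g_A J_AA < 1`).  It exists iff the silent populations stay subthreshold:
  `theta_E >= J_EA r_A0` and `theta_I >= J_IA r_A0` — in the
  `(beta, theta_E)` plane a vertical line at `theta_E = J_EA r_A0`
  (3.889 with coupling, 0 without).  The Jacobian is triangular and the
  point is stable whenever it exists.
* **Up state**: all transfers active; the equilibrium solves
  `(I - G J_eff) r = -G theta` with the adaptation nullcline `a0 = beta
  r_E0` folded into the E self-coupling, and exists iff all rates are
  positive.  Existence is lost along a downward line in `(beta, theta_E)`
  (at defaults `theta_E ≈ 14.11 - 2.24 beta` with astrocytic coupling,
  `10 - 2.5 beta` without), computed by bisection rather than transcribed
  algebra, and verified in the tests against a two-initial-condition
  simulation oracle on a 20x20 grid.

Labels: `U` (only Up exists), `D` (only Down), `Bist` (both), `Osc`
(neither; the non-smooth oscillation regime).  Boundary cases are decided
with a 1e-9 tolerance on the existence inequalities.

**Noise frontiers.** With noise, switching occurs beyond the noiseless
multistable band.  The package provides first-order escape estimates: the
effective noise seen by the E transfer argument has std `sigma_eff = sigma
sqrt(1 + (J_EA g_A/(1 - g_A J_AA))^2)` (direct drive plus the component
transmitted quasi-statically through the astrocyte), and the two frontiers
are the outermost/innermost existence lines shifted by one `sigma_eff`.
They collapse onto the noiseless lines at `sigma = 0` and shift to larger
`theta_E` when astrocytic coupling is on; they are order-of-magnitude
estimates (the simulated switching region is larger), used as overlays on
the simulated diagram, which is the authoritative object: per grid cell the
fraction of time the smoothed `r_E` spends above 1 Hz, labelled `U`
(> 0.95), `D` (< 0.05) or `U<->D`.

## 3. Spiking network

Leaky integrate-and-fire neurons (`V_th = 20 mV`, reset `V_r = 14 mV`) and
integrate-and-release astrocytes (dimensionless `G`, threshold 13, reset
9).  Each population has ONE pair of synaptic variables: `tau_r du/dt = -u
+ tau_bar * sum_events delta(t - t_spike - d)` and `tau_d ds/dt = -s + u`;
each matured event bumps `u` by `tau_bar/tau_r` (the exact integral of the
printed impulse), and stationarily `s = N r tau_bar` (rates per ms) — the
drives are extensive in population size.  Per-event transmission delays are
uniform in `[d_min, d_max]`: 0–1 ms for neurons, 0.5–1.5 s for astrocytes
(calcium signalling is slow).  Excitatory cells carry an AHP current with
per-spike increment `beta/tau_a` and strength `K_a`, i.e. a stationary
hyperpolarization `0.6 mV` per Hz of the cell's own rate at defaults.
External white noise enters as an increment `sigma_X sqrt(dt/tau_X) N(0,1)`
per step (stationary voltage variance `sigma_X^2/2`); the astrocyte noise
uses the same form.  Connectivity: neuron-neuron and astro-astro channels
all-to-all; exactly `round(0.10 N)` E and I cells receive gliotransmission
and `round(0.50 N_A)` astrocytes receive neuronal input, sampled uniformly.

Numerics: Euler at `dt = 0.1 ms` default; threshold tested after the
update, reset the same step, spike time = end-of-step; delays are rounded
to the nearest step and queued in a per-population ring buffer (one bucket
per step), so event bookkeeping is exact — the tests assert one matured
`u`-increment per threshold crossing and delay bounds.  A cell may fire on
consecutive steps (no refractory period is part of the model).  Gaussian
noise comes from an inlined 128-layer ziggurat over xorshift128+ (the
built-in generator dominated runtime at ~3.5e8 draws per 20 s run); the
sampler's moments and tail mass are validated in the test suite.  The
kernel seed, initial conditions and connectivity all derive from one
master seed.

**Integration step for duration statistics.**  First-passage times of
noise-driven threshold crossings converge slowly in `dt`: at `dt = 0.1 ms`
the pooled mean Down duration is biased upward by roughly 15% relative to
`dt = 0.05 ms`, while halving again to 0.025 ms changes the statistics by
less than the sampling error.  The phase-duration statistics in
`scripts/acceptance.py` therefore run at `dt = 0.05 ms`; the simulator
default stays at 0.1 ms.

## 4. Spiking mean-field

Stationary population rates solve a self-consistency problem: candidate
rates fix the drives `s_X0 = N_X r_X tau_bar_X`, each cell then fires at
the diffusion-approximation (first-passage) rate

    r = [ tau_m sqrt(pi) * int_{(V_r-mu)/sigma}^{(V_th-mu)/sigma} erfcx(-u) du ]^{-1}

(and the astrocytes release at the same formula with their constants).
Because of the partial contact rules the system splits into six
subpopulations (contacted/non-contacted E, I, A), and the E subpopulations
include their own stationary AHP current `K_a beta r / 1000` — solved as a
6-dimensional root-finding problem (`scipy.optimize.root`, hybr) from a
multi-start grid `r_E, r_I in {0, 1, 2, 5, 10, 20} Hz` (plus asymmetric
starts with the contacted subpopulations elevated, which is where the
intermediate saddle lives), astrocyte rates seeded from their scalar
self-consistency.  Accepted points satisfy a population-rate residual
below 1e-6 Hz and are deduplicated at 1e-3 Hz.  The integral uses
`erfcx`, which is numerically stable on both tails.

Stability: Jacobian (central differences, step 1e-5) of the relaxation
flow `tau_X dr/dt = -r + F(r)` extended with the two AHP currents as slow
variables (`tau_a = 500 ms`).  Delays and the synaptic rise/decay filters
do not move fixed points and are treated quasi-statically; they could only
add oscillatory instabilities not captured here.  Treating the AHP as a
dynamical variable has a visible consequence: near the lower fold the
active branch is oscillatory-unstable through the slow adaptation loop —
the same mechanism that makes simulated Up states transient — and
stabilizes deeper into the branch.

Sweeps along `sigma_X` (with `sigma_A` held fixed) warm-start each grid
point from the previous solutions and bisect fold locations to 1e-3 mV
where the fixed-point count changes.  With the reference parameters this
yields: without astrocytes a narrow bistable window at `sigma_X ≈
[4.64, 4.87] mV`; with astrocytes a much wider window reaching below
2.6 mV and containing the reference `sigma_X = 3 mV`.  The corresponding
reference analysis reports `[4.4, 4.5] mV` for the no-astro window — same
structure and width, displaced by ~0.25 mV (about 5%).  We derived the
stationary map independently (standard diffusion approximation, AHP
self-consistent, subpopulation-resolved), so quantitative displacement of
this size is expected; the direct simulations, which are the ground truth
for both analyses, agree with our map in placing noise-induced switching
without astrocytes near `sigma_X ≈ 5 mV`.

## 5. Up/Down segmentation

From a raster: mean population rate over a 10 ms sliding window counting E
and I spikes only (astrocyte events excluded), divided by `window *
(N_E + N_I)`, sampled every 1 ms.  The series is smoothed by a centered
running median over +/-50 points (windows truncated at the edges — no
fabricated data), and thresholded at 1.0 Hz: a sample `>= threshold` is Up
(tie counts as Up), phase boundaries sit at the first sample of the new
state, and the first and last phases are discarded from statistics.
Duration statistics use the population std (divisor n).  For rate-model
trajectories the same smoothing and threshold are applied to `r_E`
decimated to a 1 ms step.

The sampling step of the series is not part of the printed procedure; it
is exposed as a parameter (default 1 ms, so +/-50 points = +/-50 ms of
median smoothing).  The recovered statistics are insensitive to the step
between 1 and 5 ms at fixed 50-point half-width.

## 6. Synthetic fixtures

Square-wave traces (known phase boundaries), homogeneous Poisson rasters
(known per-neuron rate) and single-event rasters back the segmentation and
I/O tests; each generator returns its ground truth and is deterministic
given a seed.  They emulate only the structure the segmentation consumes
(uniformly sampled rates, timed events) — none of the temporal correlation,
phase-duration dispersion or population heterogeneity of real recordings —
so passing them certifies the *bookkeeping* (crossing detection, duration
arithmetic, discard rules), not performance on physiological data.

## 7. Known limitations and open points

* The Up-state excitatory level of the rate model at any silent-without-
  coupling operating point is ~2.6 Hz (Section 1); the reference text's
  "around 10 Hz" for `r_E` is only consistent with the inhibitory trace.
* The Down-duration distribution of the spiking network has a heavy right
  tail (rare multi-second silent episodes: 99th percentile ~1.3 s in a
  48-run batch), so its mean and CV converge slowly with replication.  At
  48 x 20 s runs we obtain Down mean ~567 ms and CV ~0.58, versus the
  reference 459 ms and 0.73: our Down phases are ~20% longer and somewhat
  more regular.  Down->Up ignition here is paced by AHP decay under a
  nearly stationary gliotransmission background; every parameter is fixed
  by the reference table, so the discrepancy is reported as is.  The other
  phase statistics (Up mean ~1003 ms vs 1031, Up CV ~0.54 vs 0.56, ~2440
  Up phases per 200 runs vs 2273) match within a few percent.
* The mean-field stability classification includes the slow AHP loop; a
  frozen-adaptation analysis would label parts of the active branch stable
  where we report oscillatory instability.
* No spatial structure, no per-synapse state, no sparse neuron-neuron
  connectivity, no calcium dynamics: the astrocyte is a threshold-release
  unit by design.
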