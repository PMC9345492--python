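# astroud

Simulators and analysis tools for **astrocyte-modulated Up-Down dynamics**
in cortical networks.

Cortical circuits spontaneously alternate between epochs of high collective
firing (Up states) and near-silence (Down states).  Recent experiments show
that astrocytes — glial cells that ensheath synapses and release
gliotransmitters on a seconds timescale — can switch a network in and out of
this regime.  `astroud` implements a three-population model of the
phenomenon (excitatory neurons E, inhibitory neurons I, astrocytes A) in two
complementary formulations, plus the analyses that explain them:

* **`rate_model`** — population rates with rectified-linear transfer
  `phi_X(x) = g_X [x - theta_X]_+`, slow spike-frequency adaptation
  `tau_a da/dt = -a + beta r_E` on the excitatory population, and
  Ornstein-Uhlenbeck external drive:

      tau_E dr_E/dt = -r_E + phi_E(J_EE r_E + J_EI r_I + J_EA r_A - a + sigma xi_E)

  (analogous equations for I and A; `r_A` is the gliotransmitter release
  rate, with a negative threshold for spontaneous astrocytic activity).
* **`rate_meanfield`** — closed-form Down/Up fixed points of the piecewise
  linear system, their stability, the (beta, theta_E) regime diagram
  (U / D / Bist / Osc without noise; U, D, U<->D with noise) and one-sigma
  escape estimates of the noisy frontiers.
* **`spiking_model`** — a stochastic network of leaky integrate-and-fire
  neurons (N_E = 4000, N_I = 1000) and integrate-and-release astrocytes
  (N_A = 2000) coupled through population synaptic variables
  `tau_r du/dt = -u + tau_bar sum delta(t - t_spike - d)`,
  `tau_d ds/dt = -s + u`, with per-event delays (milliseconds for neurons,
  0.5-1.5 **seconds** for astrocytes), spike-triggered AHP adaptation on E
  cells, and partial gliotransmission contact (10% of neurons, 50% of
  astrocytes).
* **`spiking_meanfield`** — self-consistent stationary rates from the LIF
  first-passage (diffusion approximation) formula, resolved into
  contacted/non-contacted subpopulations, with stability and saddle-node
  (fold) sweeps along the external-noise amplitude sigma_X.
* **`segmentation`** — the standard Up/Down segmentation: population rate
  in a 10 ms sliding window, +/-50-point running median, 1.0 Hz threshold,
  first/last phases discarded, duration statistics (mean, std, CV).

The central scientific result the package reproduces: switching
gliotransmission on moves the bistable region of the dynamics so that a
previously silent network (at its reference noise level) lands inside the
Up-Down switching regime, while the astrocytes themselves release at a
nearly constant rate across the phases — their second-scale transmission
delays decouple them from the fast neuronal alternation.

## Worked example

Simulate the rate model for 20 s with the default parameters
(gliotransmission on) and segment the excitatory rate into phases:

```
$ astroud simulate-rate --duration 20 --seed 2 --out traj.csv
wrote traj.csv
$ astroud segment --trace traj.csv --out intervals.csv --stats-out stats.json
Up: n=23 mean=399.5 ms CV=0.51 | Down: n=23 mean=461.4 ms CV=0.55
```

The network alternates spontaneously: 23 retained Up phases averaging
~0.4 s separated by Down phases of ~0.46 s.  Re-running with `--no-astro`
(all four neuron-astrocyte couplings zeroed, nothing else changed) yields
**zero** Up phases — the same network is silent without gliotransmission.

The same pipeline applies to the spiking network
(`astroud simulate-spiking ... `, then `segment --raster`), and

```
$ astroud bifurcation --from 4.2 --to 5.0 --step 0.05 --no-astro --out branches.csv
folds: [4.6449, 4.8996]; bistable window: (4.6449, 4.8996)
```

computes the mean-field fixed-point branches and the noise window in which
silent and active states coexist.  In the library the same calls are
`simulate_rate`, `simulate_spiking`, `segment_series`, `sweep_bifurcation`,
etc.; see `docs/methods.md` for the model definitions, parameter meanings
and numerical choices.

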