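"""Stochastic spiking network: LIF neurons plus threshold-release astrocytes.

Excitatory and inhibitory neurons are leaky integrate-and-fire units
(threshold V_th, reset V_r); astrocytes follow the same integrate-and-release
principle on a dimensionless variable G (threshold G_th, reset G_r) whose
crossings are gliotransmitter release events.  Spikes and release events of
each population X feed a single pair of population synaptic variables
(u_X, s_X) through per-event transmission delays (uniform in
[d_min_X, d_max_X]; milliseconds for neurons, seconds for astrocytes), and
s_X is broadcast back through the couplings J_XY.  Excitatory cells carry a
spike-triggered after-hyperpolarization (AHP) current I_a with per-spike
increment beta/tau_a and strength K_a.

Connectivity: neuron-neuron and astrocyte-astrocyte channels are all-to-all;
only a fraction (default 10%) of E and of I cells receive gliotransmission,
and only a fraction (default 50%) of the astrocytes receive neuronal input.

Units: potentials in mV, time in ms; G and its couplings are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .utils import derive_seeds

__all__ = [
    "SpikingParams",
    "Connectivity",
    "NetworkState",
    "SpikeRaster",
    "PopulationTraces",
    "build_connectivity",
    "init_state",
    "network_step",
    "simulate_spiking",
]

POP_CODES = {"E": 0, "I": 1, "A": 2}


@dataclass
class SpikingParams:
    """Spiking-network parameters; defaults are the reference set."""

    tau_E: float = 20.0  # ms, membrane
    tau_I: float = 10.0
    tau_A: float = 160.0
    tau_a: float = 500.0  # ms, AHP
    tau_bar_E: float = 1.0  # ms, u-variable drive scale
    tau_bar_I: float = 1.0
    tau_bar_A: float = 1.0
    J_EE: float = 1.4  # mV
    J_EI: float = -1.4
    J_IE: float = 1.25
    J_II: float = -1.0
    J_AA: float = 0.16  # dimensionless (inputs to A)
    J_AE: float = 0.053
    J_AI: float = 0.058
    J_EA: float = 22.0  # mV (gliotransmission onto neurons)
    J_IA: float = 4.4
    beta: float = 1.0  # ms, per-spike AHP increment scale
    K_a: float = 600.0  # AHP strength
    sigma_E: float = 3.0  # mV
    sigma_I: float = 3.0
    sigma_A: float = 3.0  # dimensionless
    V_r: float = 14.0  # mV
    V_th: float = 20.0
    V_L_E: float = 7.6
    V_L_I: float = 6.5
    G_r: float = 9.0
    G_th: float = 13.0
    G_L: float = 7.0
    tau_r_E: float = 8.0  # ms, synaptic rise
    tau_r_I: float = 1.0
    tau_r_A: float = 8.0
    tau_d_E: float = 23.0  # ms, synaptic decay
    tau_d_I: float = 1.0
    tau_d_A: float = 2.0
    d_min_E: float = 0.0  # ms, transmission delays
    d_max_E: float = 1.0
    d_min_I: float = 0.0
    d_max_I: float = 0.5
    d_min_A: float = 500.0
    d_max_A: float = 1500.0
    N_E: int = 4000
    N_I: int = 1000
    N_A: int = 2000
    frac_glio_targets: float = 0.10
    frac_astro_receivers: float = 0.50

    def __post_init__(self) -> None:
        if not self.V_r < self.V_th:
            raise ValueError("V_r must be below V_th")
        if not self.G_r < self.G_th:
            raise ValueError("G_r must be below G_th")
        for pop in "EIA":
            if getattr(self, f"d_min_{pop}") > getattr(self, f"d_max_{pop}"):
                raise ValueError(f"d_min_{pop} must not exceed d_max_{pop}")
        for name in (
            "tau_E", "tau_I", "tau_A", "tau_a",
            "tau_r_E", "tau_r_I", "tau_r_A", "tau_d_E", "tau_d_I", "tau_d_A",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_glio_targets", "frac_astro_receivers"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def without_astro(self) -> "SpikingParams":
        """Copy with all neuron-astrocyte couplings zeroed (astro network intact)."""
        return replace(self, J_AE=0.0, J_AI=0.0, J_EA=0.0, J_IA=0.0)

    def replace(self, **kw) -> "SpikingParams":
        return replace(self, **kw)


@dataclass
class Connectivity:
    """Boolean contact indicators of the sparse neuron-astrocyte channels."""

    glio_E: np.ndarray  # C_i^{EA}: E cells receiving gliotransmission
    glio_I: np.ndarray  # C_i^{IA}
    astro_in: np.ndarray  # C_i^{AE} = C_i^{AI}: astrocytes receiving neuronal input

    @property
    def n_glio_E(self) -> int:
        return int(self.glio_E.sum())

    @property
    def n_glio_I(self) -> int:
        return int(self.glio_I.sum())

    @property
    def n_astro_in(self) -> int:
        return int(self.astro_in.sum())


def _exact_subset(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    k = int(round(frac * n))
    if n == 0 and frac > 0:
        raise ValueError("cannot contact a fraction of an empty population")
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def build_connectivity(params: SpikingParams, seed: int = 0) -> Connectivity:
    """Uniformly sampled index subsets with exact counts round(frac * N)."""
    rngs = [np.random.default_rng(s) for s in derive_seeds(seed, 3)]
    return Connectivity(
        glio_E=_exact_subset(params.N_E, params.frac_glio_targets, rngs[0]),
        glio_I=_exact_subset(params.N_I, params.frac_glio_targets, rngs[1]),
        astro_in=_exact_subset(params.N_A, params.frac_astro_receivers, rngs[2]),
    )


def _queue_len(d_max: float, dt: float) -> int:
    return int(round(d_max / dt)) + 2


@dataclass
class NetworkState:
    V_E: np.ndarray
    V_I: np.ndarray
    G: np.ndarray
    I_a: np.ndarray
    u_E: float = 0.0
    s_E: float = 0.0
    u_I: float = 0.0
    s_I: float = 0.0
    u_A: float = 0.0
    s_A: float = 0.0
    queue_E: np.ndarray = None  # time-bucketed pending events, index 0 matures next
    queue_I: np.ndarray = None
    queue_A: np.ndarray = None
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            V_E=self.V_E.copy(),
            V_I=self.V_I.copy(),
            G=self.G.copy(),
            I_a=self.I_a.copy(),
            u_E=self.u_E,
            s_E=self.s_E,
            u_I=self.u_I,
            s_I=self.s_I,
            u_A=self.u_A,
            s_A=self.s_A,
            queue_E=self.queue_E.copy(),
            queue_I=self.queue_I.copy(),
            queue_A=self.queue_A.copy(),
            t=self.t,
        )


@dataclass
class SpikeRaster:
    """Timed spike / release events: population code (0=E,1=I,2=A), cell, t (ms)."""

    population: np.ndarray
    cell: np.ndarray
    t_ms: np.ndarray
    n_E: int
    n_I: int
    n_A: int
    duration: float

    def events_of(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """(cell, t_ms) of one population ('E', 'I' or 'A')."""
        m = self.population == POP_CODES[pop]
        return self.cell[m], self.t_ms[m]

    def count(self, pop: str) -> int:
        return int(np.sum(self.population == POP_CODES[pop]))

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass
class PopulationTraces:
    t_ms: np.ndarray
    u_E: np.ndarray
    s_E: np.ndarray
    u_I: np.ndarray
    s_I: np.ndarray
    u_A: np.ndarray
    s_A: np.ndarray
    mean_ahp: np.ndarray  # mean over E cells of K_a * I_a
    v_example_E: np.ndarray
    v_example_I: np.ndarray
    g_example_A: np.ndarray
    v_example_E_glio: np.ndarray


def init_state(
    params: SpikingParams,
    connectivity: Connectivity,
    seed: int = 0,
    dt: float = 0.1,
) -> NetworkState:
    """Random initial conditions: V, G uniform between reset and threshold.

    Synaptic variables, AHP currents and the delay queues start at zero.
    """
    rng_V, rng_G = [np.random.default_rng(s) for s in derive_seeds(seed, 2)]
    p = params
    V_E = p.V_r + (p.V_th - p.V_r) * rng_V.random(p.N_E)
    V_I = p.V_r + (p.V_th - p.V_r) * rng_V.random(p.N_I)
    G = p.G_r + (p.G_th - p.G_r) * rng_G.random(p.N_A)
    return NetworkState(
        V_E=V_E,
        V_I=V_I,
        G=G,
        I_a=np.zeros(p.N_E),
        queue_E=np.zeros(_queue_len(p.d_max_E, dt)),
        queue_I=np.zeros(_queue_len(p.d_max_I, dt)),
        queue_A=np.zeros(_queue_len(p.d_max_A, dt)),
    )


def _run_kernel(
    state: NetworkState,
    params: SpikingParams,
    connectivity: Connectivity,
    n_steps: int,
    dt: float,
    kernel_seed: int,
    record_every: int,
    max_events: int | None = None,
):
    p = params
    if dt > 0.1 + 1e-12:
        raise ValueError("dt must be <= 0.1 ms for the spiking integrator")
    if max_events is None:
        n_cells = p.N_E + p.N_I + p.N_A
        max_events = int(n_cells * (n_steps * dt / 1000.0) * 60) + 1_000_000
    ex_E_glio = int(np.argmax(connectivity.glio_E)) if connectivity.n_glio_E else 0
    out = _kernels.spiking_kernel(
        state.V_E,
        state.V_I,
        state.G,
        state.I_a,
        connectivity.glio_E.astype(np.float64),
        connectivity.glio_I.astype(np.float64),
        n_steps,
        dt,
        kernel_seed,
        record_every,
        p.tau_E,
        p.tau_I,
        p.tau_A,
        p.tau_a,
        p.tau_bar_E,
        p.tau_bar_I,
        p.tau_bar_A,
        p.tau_r_E,
        p.tau_r_I,
        p.tau_r_A,
        p.tau_d_E,
        p.tau_d_I,
        p.tau_d_A,
        p.J_EE,
        p.J_EI,
        p.J_EA,
        p.J_IE,
        p.J_II,
        p.J_IA,
        p.beta,
        p.K_a,
        p.sigma_E,
        p.sigma_I,
        p.sigma_A,
        p.V_r,
        p.V_th,
        p.V_L_E,
        p.V_L_I,
        p.G_r,
        p.G_th,
        p.G_L,
        p.d_min_E,
        p.d_max_E,
        p.d_min_I,
        p.d_max_I,
        p.d_min_A,
        p.d_max_A,
        p.J_AE,
        p.J_AI,
        p.J_AA,
        connectivity.astro_in.astype(np.float64),
        state.queue_E,
        state.queue_I,
        state.queue_A,
        np.array([state.u_E, state.s_E, state.u_I, state.s_I, state.u_A, state.s_A]),
        max_events,
        0,
        0,
        0,
        ex_E_glio,
    )
    (pop, cell, t, n_ev, traces, syn, matured, overflow) = out
    if overflow:
        raise RuntimeError("spike storage overflow: raise max_events")
    for name, val in zip(("V_E", "V_I", "G"), (state.V_E, state.V_I, state.G)):
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"numerical blow-up: non-finite {name}")
    state.u_E, state.s_E = syn[0], syn[1]
    state.u_I, state.s_I = syn[2], syn[3]
    state.u_A, state.s_A = syn[4], syn[5]
    t_offset = state.t
    state.t += n_steps * dt
    return pop, cell, t + t_offset, traces, matured


def network_step(
    state: NetworkState,
    params: SpikingParams,
    connectivity: Connectivity,
    dt: float = 0.1,
    kernel_seed: int = 0,
) -> tuple[NetworkState, SpikeRaster]:
    """Advance the network by a single Euler step (returns new state + events).

    Convenience wrapper around the same compiled kernel used by
    :func:`simulate_spiking`, so single-step semantics and full runs agree
    exactly.
    """
    new = state.copy()
    pop, cell, t, _, _ = _run_kernel(
        new, params, connectivity, 1, dt, kernel_seed, record_every=1,
        max_events=params.N_E + params.N_I + params.N_A,
    )
    raster = SpikeRaster(
        population=pop.copy(),
        cell=cell.copy(),
        t_ms=t.copy(),
        n_E=params.N_E,
        n_I=params.N_I,
        n_A=params.N_A,
        duration=new.t,
    )
    return new, raster


def simulate_spiking(
    params: SpikingParams,
    connectivity: Connectivity | None = None,
    duration: float = 20_000.0,
    dt: float = 0.1,
    seed: int = 0,
    record_every: int = 10,
    init: NetworkState | None = None,
) -> tuple[SpikeRaster, PopulationTraces]:
    """Simulate the network for ``duration`` ms; reproducible from ``seed``.

    The master seed spawns sub-seeds for connectivity (when not supplied),
    initial conditions and the integration noise.  ``record_every``
    subsamples the stored population traces (default every 1 ms at
    dt = 0.1 ms).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    conn_seed, init_seed, kernel_seed = derive_seeds(seed, 3)
    if connectivity is None:
        connectivity = build_connectivity(params, conn_seed)
    state = init if init is not None else init_state(params, connectivity, init_seed, dt)
    n_steps = int(round(duration / dt))
    pop, cell, t, traces, _ = _run_kernel(
        state, params, connectivity, n_steps, dt, kernel_seed, record_every
    )
    raster = SpikeRaster(
        population=pop.copy(),
        cell=cell.copy(),
        t_ms=t.copy(),
        n_E=params.N_E,
        n_I=params.N_I,
        n_A=params.N_A,
        duration=duration,
    )
    tr = PopulationTraces(
        t_ms=traces[:, 0].copy(),
        u_E=traces[:, 1].copy(),
        s_E=traces[:, 2].copy(),
        u_I=traces[:, 3].copy(),
        s_I=traces[:, 4].copy(),
        u_A=traces[:, 5].copy(),
        s_A=traces[:, 6].copy(),
        mean_ahp=traces[:, 7].copy(),
        v_example_E=traces[:, 8].copy(),
        v_example_I=traces[:, 9].copy(),
        g_example_A=traces[:, 10].copy(),
        v_example_E_glio=traces[:, 11].copy(),
    )
    return raster, tr
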