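"""Three-population firing-rate model of neuron-astrocyte Up-Down switching.

The network couples an excitatory (E) and an inhibitory (I) neuronal
population with a population of astrocytes (A) whose "rate" r_A is the rate
of gliotransmitter release events.  Each population obeys

    tau_X dr_X/dt = -r_X + phi_X(I_X [+ extras] + sigma * xi_X)

with a rectified-linear transfer phi_X(x) = g_X * [x - theta_X]_+, recurrent
input I_X = J_XE r_E + J_XI r_I + J_XA r_A, and an independent
Ornstein-Uhlenbeck drive xi_X per population.  The E population additionally
carries a slow adaptation current ``a`` (subtracted inside phi_E) that obeys
tau_a da/dt = -a + beta * r_E and provides the intrinsic negative feedback
terminating Up states.

Units: rates in Hz, couplings J and adaptation strength beta in seconds (so
J*r is a dimensionless input), time constants and time in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .utils import check_finite, spawn_generators

__all__ = [
    "RateParams",
    "RateState",
    "OUConfig",
    "RateTrajectory",
    "transfer",
    "recurrent_inputs",
    "ou_step",
    "rate_step",
    "simulate_rate",
]

# population order used for J matrices everywhere: rows/cols = (E, I, A)
_POPS = ("E", "I", "A")


@dataclass
class RateParams:
    """Parameters of the rate model; defaults are the reference set.

    ``theta_E`` and ``beta`` select the operating point in the
    (adaptation strength, excitatory threshold) plane; the defaults place
    the model where switching astrocytic coupling on moves it from the
    silent (Down) regime into the noise-driven Up-Down regime.
    """

    tau_E: float = 10.0  # ms
    tau_I: float = 2.0  # ms
    tau_A: float = 20.0  # ms
    tau_a: float = 500.0  # ms
    theta_E: float = 8.0
    theta_I: float = 25.0
    theta_A: float = -3.5
    g_E: float = 1.0  # Hz per input unit
    g_I: float = 4.0
    g_A: float = 1.0
    sigma: float = 3.52  # OU stationary std, input units
    tau_ou: float = 1.0  # ms, OU correlation time
    beta: float = 3.0  # s, adaptation strength
    J_EE: float = 5.0  # s
    J_EI: float = -1.0
    J_EA: float = 1.0
    J_IE: float = 10.0
    J_II: float = -0.5
    J_IA: float = 0.5
    J_AE: float = 0.5
    J_AI: float = 0.5
    J_AA: float = 0.1

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I", "tau_A", "tau_a", "tau_ou"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_E", "g_I", "g_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.J_EE < 0 or self.J_IE < 0:
            raise ValueError("J_EE and J_IE must be nonnegative (excitatory)")
        if self.J_EI > 0 or self.J_II > 0:
            raise ValueError("J_EI and J_II must be nonpositive (inhibitory)")
        for name in ("J_AE", "J_AI", "J_AA", "J_EA", "J_IA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def J(self) -> np.ndarray:
        """3x3 coupling matrix, J[X, Y] = strength of Y -> X, order (E, I, A)."""
        return np.array(
            [
                [self.J_EE, self.J_EI, self.J_EA],
                [self.J_IE, self.J_II, self.J_IA],
                [self.J_AE, self.J_AI, self.J_AA],
            ]
        )

    def without_astro(self) -> "RateParams":
        """Copy with all neuron-astrocyte couplings set to zero."""
        return replace(self, J_EA=0.0, J_IA=0.0, J_AE=0.0, J_AI=0.0)

    def replace(self, **kw) -> "RateParams":
        return replace(self, **kw)


@dataclass
class OUConfig:
    """Ornstein-Uhlenbeck drive: correlation time (ms) and stationary std."""

    tau_ou: float = 1.0
    sigma: float = 3.52

    def __post_init__(self) -> None:
        if self.tau_ou <= 0:
            raise ValueError("tau_ou must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class RateState:
    r_E: float = 0.0
    r_I: float = 0.0
    r_A: float = 0.0
    a: float = 0.0
    xi_E: float = 0.0
    xi_I: float = 0.0
    xi_A: float = 0.0
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.r_E, self.r_I, self.r_A, self.a, self.xi_E, self.xi_I, self.xi_A]
        )


@dataclass
class RateTrajectory:
    """Uniformly sampled trajectory of the rate model."""

    dt: float  # sampling step, ms
    t: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    r_A: np.ndarray
    a: np.ndarray
    xi: np.ndarray  # (n, 3) OU states
    params: RateParams = field(repr=False, default=None)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int) -> RateState:
        return RateState(
            r_E=self.r_E[i],
            r_I=self.r_I[i],
            r_A=self.r_A[i],
            a=self.a[i],
            xi_E=self.xi[i, 0],
            xi_I=self.xi[i, 1],
            xi_A=self.xi[i, 2],
            t=self.t[i],
        )


def transfer(x, g: float, theta: float):
    """Rectified-linear transfer: ``g * max(x - theta, 0)``.

    Accepts scalars or arrays; rejects non-finite inputs.
    """
    if g < 0:
        raise ValueError("gain g must be nonnegative")
    check_finite("transfer input x", x)
    return g * np.maximum(np.asarray(x, dtype=float) - theta, 0.0)


def recurrent_inputs(state: RateState, J: np.ndarray) -> tuple[float, float, float]:
    """Recurrent inputs (I_E, I_I, I_A) = J @ (r_E, r_I, r_A)."""
    r = np.array([state.r_E, state.r_I, state.r_A])
    check_finite("rates", r)
    I = np.asarray(J, dtype=float) @ r
    return float(I[0]), float(I[1]), float(I[2])


def ou_step(xi: float, cfg: OUConfig, dt: float, rng: np.random.Generator) -> float:
    """Exact one-step update of a unit-variance-scaled OU process.

    The state ``xi`` is kept on the unit-variance scale (the model multiplies
    by ``cfg.sigma`` where the noise enters the transfer argument), so the
    update is xi' = f*xi + sqrt(1-f^2)*N(0,1) with f = exp(-dt/tau_ou);
    its stationary distribution is N(0, 1).  With ``cfg.sigma == 0`` the
    deterministic decay is returned.
    """
    if cfg.sigma < 0:
        raise ValueError("sigma must be nonnegative")
    f = math.exp(-dt / cfg.tau_ou)
    if cfg.sigma == 0.0:
        return f * xi
    return f * xi + math.sqrt(1.0 - f * f) * rng.standard_normal()


def rate_rhs(state: RateState, params: RateParams) -> np.ndarray:
    """Deterministic right-hand side d/dt (r_E, r_I, r_A, a), noise at its current value."""
    p = params
    I_E, I_I, I_A = recurrent_inputs(state, p.J)
    phiE = transfer(I_E - state.a + p.sigma * state.xi_E, p.g_E, p.theta_E)
    phiI = transfer(I_I + p.sigma * state.xi_I, p.g_I, p.theta_I)
    phiA = transfer(I_A + p.sigma * state.xi_A, p.g_A, p.theta_A)
    return np.array(
        [
            (-state.r_E + phiE) / p.tau_E,
            (-state.r_I + phiI) / p.tau_I,
            (-state.r_A + phiA) / p.tau_A,
            (-state.a + p.beta * state.r_E) / p.tau_a,
        ]
    )


def _check_dt(params: RateParams, dt: float) -> None:
    guard = min(params.tau_E, params.tau_I, params.tau_A) / 4.0
    if dt > guard:
        raise ValueError(
            f"dt={dt} ms violates the stability guard dt <= min(tau)/4 = {guard} ms"
        )


def rate_step(
    state: RateState,
    params: RateParams,
    dt: float,
    rng: np.random.Generator | None = None,
) -> RateState:
    """One forward Euler step; OU states advanced with their exact update."""
    _check_dt(params, dt)
    if rng is None:
        rng = np.random.default_rng()
    d = rate_rhs(state, params)
    cfg = OUConfig(tau_ou=params.tau_ou, sigma=params.sigma)
    return RateState(
        r_E=state.r_E + dt * d[0],
        r_I=state.r_I + dt * d[1],
        r_A=state.r_A + dt * d[2],
        a=state.a + dt * d[3],
        xi_E=ou_step(state.xi_E, cfg, dt, rng),
        xi_I=ou_step(state.xi_I, cfg, dt, rng),
        xi_A=ou_step(state.xi_A, cfg, dt, rng),
        t=state.t + dt,
    )


def simulate_rate(
    params: RateParams,
    duration: float,
    dt: float = 0.1,
    seed: int | None = 0,
    init: RateState | None = None,
    record_every: int = 1,
) -> RateTrajectory:
    """Simulate the rate model for ``duration`` ms.

    The master ``seed`` spawns three independent innovation streams, one per
    OU process, so trajectories are bit-reproducible.  ``record_every``
    subsamples the stored trajectory (sampling step ``dt * record_every``);
    the integration step is always ``dt``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    _check_dt(params, dt)
    n_steps = int(round(duration / dt))
    if init is None:
        init = RateState()

    if params.sigma > 0 and seed is not None:
        gens = spawn_generators(seed, 3)
        innovations = np.column_stack([g.standard_normal(n_steps) for g in gens])
    else:
        innovations = np.zeros((n_steps, 3))

    out = _kernels.rate_kernel(
        init.as_array(),
        n_steps,
        dt,
        record_every,
        params.tau_E,
        params.tau_I,
        params.tau_A,
        params.tau_a,
        params.g_E,
        params.g_I,
        params.g_A,
        params.theta_E,
        params.theta_I,
        params.theta_A,
        params.beta,
        params.sigma,
        params.tau_ou,
        params.J,
        innovations,
    )
    sample_dt = dt * record_every
    t = init.t + sample_dt * np.arange(out.shape[0])
    return RateTrajectory(
        dt=sample_dt,
        t=t,
        r_E=out[:, 0].copy(),
        r_I=out[:, 1].copy(),
        r_A=out[:, 2].copy(),
        a=out[:, 3].copy(),
        xi=out[:, 4:7].copy(),
        params=params,
        seed=seed,
    )
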