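"""Fixed points, stability and phase diagram of the rate model.

Because the transfer functions are rectified-linear, the model is piecewise
linear: every fixed point lives in a "rectification configuration" (each
population either silent or on its linear branch), where equilibria and
Jacobians are available in closed form.

* Down state: both neuronal populations silent, astrocytes on their linear
  branch at r_A0 = -g_A*theta_A / (1 - g_A*J_AA).  It exists when the silent
  populations indeed stay below threshold, which for the E population reads
  theta_E >= J_EA*r_A0 - a line in the (beta, theta_E) plane independent of
  beta.
* Up state: all three populations on the linear branch; the equilibrium
  solves a 3x3 linear system (adaptation eliminated through a0 = beta*r_E0)
  and exists when the solution is self-consistent (all rates positive).

With the Ornstein-Uhlenbeck drive the noiseless regions blur into three
noisy regimes - persistent Up (U), persistent Down (D) and spontaneous
switching (U<->D).  ``noise_frontiers`` returns one-sigma escape estimates
of the two frontiers: the noiseless existence boundaries shifted by the
effective noise amplitude seen by the E population (direct drive plus the
component transmitted through the astrocytes).  They collapse onto the
noiseless lines as sigma -> 0 and shift to larger theta_E when astrocytic
coupling is switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rate_model import RateParams, RateState, rate_rhs, simulate_rate
from .segmentation import median_smooth, phase_statistics, segment_phases, series_from_trajectory
from .utils import derive_seeds

__all__ = [
    "FixedPoint",
    "RegionLabel",
    "PhaseDiagramGrid",
    "down_fixed_point",
    "up_fixed_point",
    "classify_noiseless",
    "down_existence_line",
    "up_existence_line",
    "noise_frontiers",
    "simulate_phase_diagram",
]

_EXIST_TOL = 1e-9


@dataclass
class FixedPoint:
    r_E0: float
    r_I0: float
    r_A0: float
    a0: float
    exists: bool
    stable: bool
    eigenvalues: np.ndarray = field(default=None, repr=False)
    residual: float = np.nan

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.r_E0, self.r_I0, self.r_A0])


@dataclass
class RegionLabel:
    label: str  # noiseless: U, D, Bist, Osc; noisy: U, D, U<->D
    frac_up: float = np.nan


@dataclass
class PhaseDiagramGrid:
    beta_values: np.ndarray
    thetaE_values: np.ndarray
    frac_up: np.ndarray  # (len(beta), len(thetaE))
    labels: np.ndarray  # same shape, dtype=object of str
    frontiers: dict = field(default_factory=dict)


def _residual(params: RateParams, rates: np.ndarray, a: float) -> float:
    st = RateState(r_E=rates[0], r_I=rates[1], r_A=rates[2], a=a)
    return float(np.max(np.abs(rate_rhs(st, params))))


def down_fixed_point(params: RateParams) -> FixedPoint:
    """Down state: silent neurons, astrocytes at their spontaneous level.

    Raises if g_A*J_AA >= 1 (the astrocyte self-excitation diverges).
    """
    p = params
    if p.g_A * p.J_AA >= 1.0:
        raise ValueError("astrocyte self-consistency requires g_A * J_AA < 1")
    r_A0 = -p.g_A * p.theta_A / (1.0 - p.g_A * p.J_AA)
    if r_A0 <= 0.0:
        # positive astrocyte threshold: the spontaneous branch is off too
        r_A0 = 0.0
    # silence of E and I is self-consistent when their inputs stay subthreshold
    arg_E = p.J_EA * r_A0  # a0 = 0 at the Down point
    arg_I = p.J_IA * r_A0
    exists = (arg_E <= p.theta_E + _EXIST_TOL) and (arg_I <= p.theta_I + _EXIST_TOL)
    if r_A0 > 0.0:
        eig_A = (p.g_A * p.J_AA - 1.0) / p.tau_A
    else:
        eig_A = -1.0 / p.tau_A
    eigs = np.array([-1.0 / p.tau_E, -1.0 / p.tau_I, eig_A, -1.0 / p.tau_a])
    fp = FixedPoint(
        r_E0=0.0,
        r_I0=0.0,
        r_A0=r_A0,
        a0=0.0,
        exists=bool(exists),
        stable=bool(np.all(eigs.real < 0)),
        eigenvalues=eigs,
    )
    fp.residual = _residual(params, fp.rates, fp.a0) if exists else np.nan
    return fp


def _active_jacobian(params: RateParams) -> np.ndarray:
    """Jacobian of (r_E, r_I, r_A, a) dynamics with all rectifications active."""
    p = params
    J = p.J
    g = np.array([p.g_E, p.g_I, p.g_A])
    tau = np.array([p.tau_E, p.tau_I, p.tau_A])
    M = np.zeros((4, 4))
    for x in range(3):
        for y in range(3):
            M[x, y] = g[x] * J[x, y] / tau[x]
        M[x, x] -= 1.0 / tau[x]
    M[0, 3] = -p.g_E / p.tau_E  # adaptation enters phi_E's argument
    M[3, 0] = p.beta / p.tau_a
    M[3, 3] = -1.0 / p.tau_a
    return M


def up_fixed_point(params: RateParams) -> FixedPoint:
    """Up state: all populations on the linear branch of their transfer.

    Solves (I - G*J_eff) r = -G*theta with the adaptation nullcline
    a0 = beta*r_E0 folded into the E self-coupling.  The point exists when
    the linear solution is self-consistent, i.e. all rates are positive
    (equivalently, every transfer argument exceeds its threshold).
    """
    p = params
    G = np.diag([p.g_E, p.g_I, p.g_A])
    J_eff = p.J.copy()
    J_eff[0, 0] -= p.beta
    M = np.eye(3) - G @ J_eff
    theta = np.array([p.theta_E, p.theta_I, p.theta_A])
    try:
        r = np.linalg.solve(M, -G @ theta)
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate parameters: singular Up-state system") from err
    exists = bool(np.all(r > _EXIST_TOL))
    a0 = p.beta * r[0]
    eigs = np.linalg.eigvals(_active_jacobian(params))
    fp = FixedPoint(
        r_E0=float(r[0]),
        r_I0=float(r[1]),
        r_A0=float(r[2]),
        a0=float(a0),
        exists=exists,
        stable=bool(np.all(eigs.real < 0)),
        eigenvalues=eigs,
    )
    fp.residual = _residual(params, fp.rates, fp.a0) if exists else np.nan
    return fp


def classify_noiseless(beta: float, theta_E: float, params: RateParams) -> RegionLabel:
    """Noiseless regime at one point of the (beta, theta_E) plane.

    U: only the Up fixed point exists; D: only the Down one; Bist: both;
    Osc: neither (rectification arguments keep switching sign, the
    non-smooth oscillation regime).
    """
    p = params.replace(beta=beta, theta_E=theta_E)
    down = down_fixed_point(p)
    up = up_fixed_point(p)
    if up.exists and down.exists:
        return RegionLabel("Bist")
    if up.exists:
        return RegionLabel("U")
    if down.exists:
        return RegionLabel("D")
    return RegionLabel("Osc")


def down_existence_line(params: RateParams) -> float:
    """theta_E of the Down-existence boundary (independent of beta)."""
    fp = down_fixed_point(params.replace(theta_E=np.inf))
    return params.J_EA * fp.r_A0


def up_existence_line(params: RateParams, beta: float) -> float:
    """theta_E above which the Up fixed point no longer exists, at given beta."""
    lo, hi = -200.0, 200.0
    p_lo = params.replace(beta=beta, theta_E=lo)
    p_hi = params.replace(beta=beta, theta_E=hi)
    if not up_fixed_point(p_lo).exists:
        return -np.inf
    if up_fixed_point(p_hi).exists:
        return np.inf
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if up_fixed_point(params.replace(beta=beta, theta_E=mid)).exists:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sigma_eff(params: RateParams) -> float:
    """Effective noise std seen by the E transfer argument.

    Direct OU drive plus the component transmitted quasi-statically through
    the astrocyte population (gain J_EA * g_A / (1 - g_A*J_AA)).
    """
    p = params
    gain_A = p.J_EA * p.g_A / (1.0 - p.g_A * p.J_AA)
    return p.sigma * np.sqrt(1.0 + gain_A**2)


def noise_frontiers(params: RateParams, beta_grid: np.ndarray) -> dict:
    """One-sigma estimates of the noisy-regime frontiers theta_E*(beta).

    ``d_frontier``: between U<->D and pure D - the largest noiseless
    existence boundary shifted up by one effective noise std (above it, noise
    can no longer ignite Up states).  ``u_frontier``: between pure U and
    U<->D - the smallest existence boundary shifted down by the same amount
    (below it, noise can no longer interrupt the Up state).  Both collapse
    onto the noiseless existence lines at sigma = 0.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    th_down = down_existence_line(params)
    th_up = np.array([up_existence_line(params, b) for b in beta_grid])
    s = _sigma_eff(params)
    return {
        "beta": beta_grid,
        "down_line": np.full_like(beta_grid, th_down),
        "up_line": th_up,
        "d_frontier": np.maximum(th_down, th_up) + s,
        "u_frontier": np.minimum(th_down, th_up) - s,
    }


def simulate_phase_diagram(
    beta_values: np.ndarray,
    thetaE_values: np.ndarray,
    params: RateParams,
    duration: float = 100_000.0,
    dt: float = 0.1,
    seed: int = 0,
    n_reps: int = 1,
    record_every: int = 10,
    frac_up_hi: float = 0.95,
    frac_up_lo: float = 0.05,
) -> PhaseDiagramGrid:
    """Simulated (beta, theta_E) diagram: fraction of time in the Up state.

    Each cell runs ``n_reps`` simulations of ``duration`` ms, segments the
    r_E series with the standard smoothing + 1 Hz threshold procedure, and
    reports the fraction of (retained + discarded) time with the smoothed
    rate above threshold.  Labels: U if frac_up > ``frac_up_hi``, D if
    < ``frac_up_lo``, else U<->D.
    """
    beta_values = np.asarray(beta_values, dtype=float)
    thetaE_values = np.asarray(thetaE_values, dtype=float)
    frac = np.zeros((len(beta_values), len(thetaE_values)))
    labels = np.empty(frac.shape, dtype=object)
    seeds = derive_seeds(seed, frac.size * n_reps)
    k = 0
    for i, beta in enumerate(beta_values):
        for j, th in enumerate(thetaE_values):
            p = params.replace(beta=beta, theta_E=th)
            tot = 0.0
            for _ in range(n_reps):
                traj = simulate_rate(
                    p, duration, dt=dt, seed=seeds[k], record_every=record_every
                )
                k += 1
                series = series_from_trajectory(traj)
                smooth = median_smooth(series)
                tot += float(np.mean(smooth.values >= 1.0))
            frac[i, j] = tot / n_reps
            if frac[i, j] > frac_up_hi:
                labels[i, j] = "U"
            elif frac[i, j] < frac_up_lo:
                labels[i, j] = "D"
            else:
                labels[i, j] = "U<->D"
    frontiers = noise_frontiers(params, beta_values)
    return PhaseDiagramGrid(
        beta_values=beta_values,
        thetaE_values=thetaE_values,
        frac_up=frac,
        labels=labels,
        frontiers=frontiers,
    )
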