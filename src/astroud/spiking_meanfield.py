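"""Mean-field fixed points and bifurcation sweeps of the spiking network.

In the stationary state each population synaptic variable equals the total
event throughput, s_X0 = N_X * r_X * tau_bar_X (rates in events/ms), so the
mean input to every cell is a deterministic function of the three population
rates.  A LIF cell receiving mean input mu with white noise of amplitude
sigma fires at the first-passage (diffusion-approximation) rate

    r = [ tau_m * sqrt(pi) * int_{(V_r-mu)/sigma}^{(V_th-mu)/sigma}
              erfcx(-u) du ]^{-1}

and the astrocyte release rate follows the same formula with (G_r, G_th,
tau_A, sigma_A).  Because only a fraction of the neurons receive
gliotransmission and only a fraction of the astrocytes receive neuronal
input, each population splits into a contacted and a non-contacted
subpopulation; the excitatory subpopulations additionally carry their own
stationary AHP current I_a0 = beta * r / 1000.  Fixed points solve the
resulting six-dimensional self-consistency problem; population rates are the
contact-fraction-weighted mixtures.

Stability is classified from the Jacobian (central finite differences) of
the relaxation flow tau_X dr/dt = -r + F(r), with the two AHP currents kept
as slow dynamical variables (time constant tau_a).  Transmission delays and
the synaptic rise/decay filters do not move fixed points and are treated
quasi-statically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, root
from scipy.special import erfcx

from .spiking_model import SpikingParams

__all__ = [
    "SelfConsistentPoint",
    "BifurcationDiagram",
    "siegert_rate",
    "selfconsistent_residual",
    "find_fixed_points",
    "sweep_bifurcation",
    "simulated_updown_range",
    "bistable_window",
]

_RESIDUAL_TOL = 1e-6
_DEDUP_TOL = 1e-3
_Y_MAX = 24.0  # beyond this the rate underflows double precision


@dataclass
class SelfConsistentPoint:
    r_E0: float
    r_I0: float
    r_A0: float
    residual: float
    stable: bool
    eigenvalues: np.ndarray = field(default=None, repr=False)
    sub_rates: np.ndarray = field(default=None, repr=False)  # (rEc,rEnc,rIc,rInc,rAc,rAnc)

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.r_E0, self.r_I0, self.r_A0])


@dataclass
class BifurcationDiagram:
    parameter: str
    values: np.ndarray
    points: list  # list (per parameter value) of lists of SelfConsistentPoint
    folds: list  # fold (saddle-node) parameter locations
    with_astro: bool

    def counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.points])


def siegert_rate(mu: float, sigma: float, tau_m: float, v_reset: float, v_th: float) -> float:
    """Stationary LIF firing rate (Hz) under the diffusion approximation.

    ``tau_m`` in ms; no refractory period.  For ``sigma == 0`` the
    deterministic suprathreshold rate is returned.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0.0:
        if mu <= v_th:
            return 0.0
        return 1000.0 / (tau_m * np.log((mu - v_reset) / (mu - v_th)))
    y_th = (v_th - mu) / sigma
    y_r = (v_reset - mu) / sigma
    if y_th > _Y_MAX:
        return 0.0
    val, err = quad(lambda u: erfcx(-u), y_r, y_th, limit=200, epsabs=1e-12, epsrel=1e-11)
    if not np.isfinite(val) or val < 0:
        raise FloatingPointError(
            f"first-passage quadrature failed (mu={mu}, sigma={sigma}): value {val}"
        )
    return 1000.0 / (tau_m * np.sqrt(np.pi) * val)


def _couplings(params: SpikingParams, with_astro: bool):
    p = params
    if with_astro:
        return p.J_EA, p.J_IA, p.J_AE, p.J_AI
    return 0.0, 0.0, 0.0, 0.0


def _drives(params: SpikingParams, r_E: float, r_I: float, r_A: float):
    """Stationary synaptic variables from population rates (Hz)."""
    p = params
    s_E = p.N_E * r_E * 1e-3 * p.tau_bar_E
    s_I = p.N_I * r_I * 1e-3 * p.tau_bar_I
    s_A = p.N_A * r_A * 1e-3 * p.tau_bar_A
    return s_E, s_I, s_A


def _subpop_map(x: np.ndarray, sigma_X: float, params: SpikingParams, with_astro: bool) -> np.ndarray:
    """Stationary-rate map on the six subpopulation rates (Hz)."""
    p = params
    J_EA, J_IA, J_AE, J_AI = _couplings(p, with_astro)
    fg, fa = p.frac_glio_targets, p.frac_astro_receivers
    rEc, rEnc, rIc, rInc, rAc, rAnc = x
    r_E = fg * rEc + (1 - fg) * rEnc
    r_I = fg * rIc + (1 - fg) * rInc
    r_A = fa * rAc + (1 - fa) * rAnc
    s_E, s_I, s_A = _drives(p, r_E, r_I, r_A)

    base_E = p.V_L_E + p.J_EE * s_E + p.J_EI * s_I
    base_I = p.V_L_I + p.J_IE * s_E + p.J_II * s_I
    base_A = p.G_L + p.J_AA * s_A
    ahp = p.K_a * p.beta * 1e-3  # mV per Hz of the cell's own rate

    mu = np.array(
        [
            base_E + J_EA * s_A - ahp * rEc,
            base_E - ahp * rEnc,
            base_I + J_IA * s_A,
            base_I,
            base_A + J_AE * s_E + J_AI * s_I,
            base_A,
        ]
    )
    out = np.empty(6)
    out[0] = siegert_rate(mu[0], sigma_X, p.tau_E, p.V_r, p.V_th)
    out[1] = siegert_rate(mu[1], sigma_X, p.tau_E, p.V_r, p.V_th)
    out[2] = siegert_rate(mu[2], sigma_X, p.tau_I, p.V_r, p.V_th)
    out[3] = siegert_rate(mu[3], sigma_X, p.tau_I, p.V_r, p.V_th)
    out[4] = siegert_rate(mu[4], p.sigma_A, p.tau_A, p.G_r, p.G_th)
    out[5] = siegert_rate(mu[5], p.sigma_A, p.tau_A, p.G_r, p.G_th)
    return out


def _solve_ahp_rate(mu_free: float, sigma_X: float, params: SpikingParams) -> float:
    """Self-consistent rate of an E subpopulation: r = F(mu_free - ahp*r).

    F is decreasing in the AHP feedback, so the fixed point is unique;
    bracketed bisection via brentq.
    """
    p = params
    ahp = p.K_a * p.beta * 1e-3

    def g(r):
        return r - siegert_rate(mu_free - ahp * r, sigma_X, p.tau_E, p.V_r, p.V_th)

    hi = siegert_rate(mu_free, sigma_X, p.tau_E, p.V_r, p.V_th)
    if hi <= 0.0:
        return 0.0
    return brentq(g, 0.0, hi + 1e-9, xtol=1e-12)


def selfconsistent_residual(
    rates: np.ndarray,
    sigma_X: float,
    params: SpikingParams,
    with_astro: bool = True,
) -> np.ndarray:
    """Residual of the population-rate self-consistency at a candidate point.

    Given candidate population rates (r_E0, r_I0, r_A0) the stationary
    synaptic drives are fixed; each subpopulation rate is then determined
    (the E subpopulations through their own-AHP scalar self-consistency) and
    the residual is ``rates - recomposed population rates``.  Zero residual
    is equivalent to a mean-field fixed point.
    """
    p = params
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("candidate rates must be nonnegative")
    J_EA, J_IA, J_AE, J_AI = _couplings(p, with_astro)
    fg, fa = p.frac_glio_targets, p.frac_astro_receivers
    s_E, s_I, s_A = _drives(p, *rates)
    base_E = p.V_L_E + p.J_EE * s_E + p.J_EI * s_I
    base_I = p.V_L_I + p.J_IE * s_E + p.J_II * s_I
    base_A = p.G_L + p.J_AA * s_A
    rEc = _solve_ahp_rate(base_E + J_EA * s_A, sigma_X, p)
    rEnc = _solve_ahp_rate(base_E, sigma_X, p)
    rIc = siegert_rate(base_I + J_IA * s_A, sigma_X, p.tau_I, p.V_r, p.V_th)
    rInc = siegert_rate(base_I, sigma_X, p.tau_I, p.V_r, p.V_th)
    rAc = siegert_rate(base_A + J_AE * s_E + J_AI * s_I, p.sigma_A, p.tau_A, p.G_r, p.G_th)
    rAnc = siegert_rate(base_A, p.sigma_A, p.tau_A, p.G_r, p.G_th)
    new = np.array(
        [
            fg * rEc + (1 - fg) * rEnc,
            fg * rIc + (1 - fg) * rInc,
            fa * rAc + (1 - fa) * rAnc,
        ]
    )
    return rates - new


def _extended_flow(z: np.ndarray, sigma_X: float, params: SpikingParams, with_astro: bool) -> np.ndarray:
    """Relaxation flow on (6 subpop rates, 2 E-subpop AHP currents)."""
    p = params
    x = z[:6]
    ia_c, ia_nc = z[6], z[7]
    # rates the subpopulations would relax towards, at frozen AHP currents
    J_EA, J_IA, J_AE, J_AI = _couplings(p, with_astro)
    fg, fa = p.frac_glio_targets, p.frac_astro_receivers
    r_E = fg * x[0] + (1 - fg) * x[1]
    r_I = fg * x[2] + (1 - fg) * x[3]
    r_A = fa * x[4] + (1 - fa) * x[5]
    s_E, s_I, s_A = _drives(p, r_E, r_I, r_A)
    base_E = p.V_L_E + p.J_EE * s_E + p.J_EI * s_I
    base_I = p.V_L_I + p.J_IE * s_E + p.J_II * s_I
    base_A = p.G_L + p.J_AA * s_A
    F = np.array(
        [
            siegert_rate(base_E + J_EA * s_A - p.K_a * ia_c, sigma_X, p.tau_E, p.V_r, p.V_th),
            siegert_rate(base_E - p.K_a * ia_nc, sigma_X, p.tau_E, p.V_r, p.V_th),
            siegert_rate(base_I + J_IA * s_A, sigma_X, p.tau_I, p.V_r, p.V_th),
            siegert_rate(base_I, sigma_X, p.tau_I, p.V_r, p.V_th),
            siegert_rate(base_A + J_AE * s_E + J_AI * s_I, p.sigma_A, p.tau_A, p.G_r, p.G_th),
            siegert_rate(base_A, p.sigma_A, p.tau_A, p.G_r, p.G_th),
        ]
    )
    tau = np.array([p.tau_E, p.tau_E, p.tau_I, p.tau_I, p.tau_A, p.tau_A])
    dz = np.empty(8)
    dz[:6] = (-x + F) / tau
    dz[6] = (-ia_c + p.beta * 1e-3 * x[0]) / p.tau_a
    dz[7] = (-ia_nc + p.beta * 1e-3 * x[1]) / p.tau_a
    return dz


def _stability(sub: np.ndarray, sigma_X: float, params: SpikingParams, with_astro: bool):
    p = params
    z0 = np.concatenate([sub, [p.beta * 1e-3 * sub[0], p.beta * 1e-3 * sub[1]]])
    h = 1e-5
    J = np.empty((8, 8))
    for k in range(8):
        zp = z0.copy()
        zm = z0.copy()
        zp[k] += h
        zm[k] = max(zm[k] - h, 0.0) if k < 6 else zm[k] - h
        step = zp[k] - zm[k]
        J[:, k] = (_extended_flow(zp, sigma_X, p, with_astro) - _extended_flow(zm, sigma_X, p, with_astro)) / step
    eigs = np.linalg.eigvals(J)
    return bool(np.all(eigs.real < 0)), eigs


def _seed_astro_rate(r_E: float, r_I: float, sigma_X: float, params: SpikingParams, with_astro: bool) -> float:
    """Scalar self-consistent astrocyte rate at frozen neuronal rates."""
    p = params
    J_EA, J_IA, J_AE, J_AI = _couplings(p, with_astro)
    fa = p.frac_astro_receivers
    s_E = p.N_E * r_E * 1e-3 * p.tau_bar_E
    s_I = p.N_I * r_I * 1e-3 * p.tau_bar_I
    r_A = 0.0
    for _ in range(60):
        s_A = p.N_A * r_A * 1e-3 * p.tau_bar_A
        base_A = p.G_L + p.J_AA * s_A
        new = fa * siegert_rate(
            base_A + J_AE * s_E + J_AI * s_I, p.sigma_A, p.tau_A, p.G_r, p.G_th
        ) + (1 - fa) * siegert_rate(base_A, p.sigma_A, p.tau_A, p.G_r, p.G_th)
        if abs(new - r_A) < 1e-10:
            r_A = new
            break
        r_A = 0.5 * r_A + 0.5 * new
    return r_A


_START_RATES = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0)


def find_fixed_points(
    sigma_X: float,
    params: SpikingParams,
    with_astro: bool = True,
    extra_starts: list[np.ndarray] | None = None,
    start_rates: tuple = _START_RATES,
) -> list[SelfConsistentPoint]:
    """Multi-start root finding on the six-dimensional self-consistency map.

    Starts cross r_E, r_I over ``start_rates`` with the astrocyte rate seeded
    from its scalar self-consistency; ``extra_starts`` (subpopulation-rate
    vectors) are tried as well, which the sweep uses for warm starts.
    Solutions are certified by the population-rate residual (< 1e-6 Hz) and
    deduplicated at 1e-3 Hz.
    """
    p = params

    def fun(x):
        return x - _subpop_map(x, sigma_X, p, with_astro)

    starts: list[np.ndarray] = []
    for rE in start_rates:
        for rI in start_rates:
            rA = _seed_astro_rate(rE, rI, sigma_X, p, with_astro)
            starts.append(np.array([rE, rE, rI, rI, rA, rA]))
            if with_astro:
                # the gliotransmission-contacted subpopulations fire well above
                # the rest; seed asymmetric states so the intermediate branch
                # (high contacted, low background) is not missed
                starts.append(np.array([rE + 25.0, rE, rI + 8.0, rI, rA, rA]))
                starts.append(np.array([rE + 6.0, rE, rI + 1.0, rI, rA, rA]))
    if extra_starts:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    found: list[SelfConsistentPoint] = []
    fg, fa = p.frac_glio_targets, p.frac_astro_receivers
    for x0 in starts:
        sol = root(fun, x0, method="hybr", options={"xtol": 1e-13})
        x = sol.x
        if not sol.success or np.any(x < -1e-9):
            continue
        x = np.clip(x, 0.0, None)
        pop = np.array(
            [
                fg * x[0] + (1 - fg) * x[1],
                fg * x[2] + (1 - fg) * x[3],
                fa * x[4] + (1 - fa) * x[5],
            ]
        )
        res = float(np.max(np.abs(selfconsistent_residual(pop, sigma_X, p, with_astro))))
        if res >= _RESIDUAL_TOL:
            continue
        if any(np.max(np.abs(pop - q.rates)) <= _DEDUP_TOL for q in found):
            continue
        stable, eigs = _stability(x, sigma_X, p, with_astro)
        found.append(
            SelfConsistentPoint(
                r_E0=pop[0],
                r_I0=pop[1],
                r_A0=pop[2],
                residual=res,
                stable=stable,
                eigenvalues=eigs,
                sub_rates=x,
            )
        )
    found.sort(key=lambda q: q.r_E0)
    return found


def _count(sigma, params, with_astro, warm):
    return len(find_fixed_points(sigma, params, with_astro, extra_starts=warm))


def sweep_bifurcation(
    sigma_values: np.ndarray,
    params: SpikingParams,
    with_astro: bool = True,
    fold_tol: float = 1e-3,
    refine_folds: bool = True,
) -> BifurcationDiagram:
    """Sweep the external-noise amplitude sigma_X and track the fixed points.

    ``sigma_A`` is held at its default while sigma_X sets the noise to the E
    and I populations.  Where the number of fixed points changes between
    consecutive grid values, the fold (saddle-node) location is bisected to
    ``fold_tol`` (mV).
    """
    sigma_values = np.asarray(sigma_values, dtype=float)
    points: list[list[SelfConsistentPoint]] = []
    warm: list[np.ndarray] = []
    for s in sigma_values:
        pts = find_fixed_points(s, params, with_astro, extra_starts=warm)
        points.append(pts)
        warm = [q.sub_rates for q in pts]
    folds: list[float] = []
    if refine_folds:
        for i in range(len(sigma_values) - 1):
            n_lo, n_hi = len(points[i]), len(points[i + 1])
            if n_lo == n_hi:
                continue
            lo, hi = sigma_values[i], sigma_values[i + 1]
            warm = [q.sub_rates for q in points[i] + points[i + 1]]
            while hi - lo > fold_tol:
                mid = 0.5 * (lo + hi)
                if _count(mid, params, with_astro, warm) == n_lo:
                    lo = mid
                else:
                    hi = mid
            folds.append(0.5 * (lo + hi))
    return BifurcationDiagram(
        parameter="sigma_X",
        values=sigma_values,
        points=points,
        folds=folds,
        with_astro=with_astro,
    )


def simulated_updown_range(
    sigma_values: np.ndarray,
    params: SpikingParams,
    with_astro: bool = True,
    duration: float = 20_000.0,
    seed: int = 0,
    dt: float = 0.1,
    min_up_phases: int = 2,
) -> dict:
    """Companion to the analytic sweep: where do simulations actually switch?

    Runs the full spiking network at each sigma_X and tests whether the
    segmentation finds at least ``min_up_phases`` retained Up phases — the
    simulated counterpart of the bistable window (the shaded band usually
    drawn next to mean-field branches).  Returns ``{"sigma": ..., "updown":
    boolean array}``.
    """
    from .segmentation import median_smooth, raster_to_rate, segment_phases
    from .spiking_model import simulate_spiking
    from .utils import derive_seeds

    sigma_values = np.asarray(sigma_values, dtype=float)
    p0 = params if with_astro else params.without_astro()
    flags = np.zeros(len(sigma_values), dtype=bool)
    for i, (s, run_seed) in enumerate(zip(sigma_values, derive_seeds(seed, len(sigma_values)))):
        p = p0.replace(sigma_E=float(s), sigma_I=float(s))
        raster, _ = simulate_spiking(p, duration=duration, dt=dt, seed=run_seed)
        seg = segment_phases(median_smooth(raster_to_rate(raster)))
        flags[i] = len(seg.retained("Up")) >= min_up_phases
    return {"sigma": sigma_values, "updown": flags}


def bistable_window(diagram: BifurcationDiagram) -> tuple[float, float] | None:
    """(lower, upper) edge of the range with three coexisting fixed points.

    Fold locations are used when the sweep refined them; otherwise the first
    and last grid values with three points.
    """
    counts = diagram.counts()
    idx = np.flatnonzero(counts >= 3)
    if len(idx) == 0:
        return None
    lo_grid = diagram.values[idx[0]]
    hi_grid = diagram.values[idx[-1]]
    lo = max([f for f in diagram.folds if f <= lo_grid], default=lo_grid)
    hi = min([f for f in diagram.folds if f >= hi_grid], default=hi_grid)
    return float(lo), float(hi)
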