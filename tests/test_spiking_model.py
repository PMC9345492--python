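"""Spiking-network tests: connectivity, event bookkeeping, single-event and
AHP oracles, the silent-network null, and the noise generator itself."""

import numpy as np
import pytest

import astroud as au
from astroud._kernels import sample_normals
from astroud.spiking_model import _run_kernel, build_connectivity, init_state


class TestConnectivity:
    def test_exact_counts_reference_network(self, spiking_params):
        conn = build_connectivity(spiking_params, seed=0)
        assert conn.n_glio_E == 400  # 10% of 4000
        assert conn.n_glio_I == 100  # 10% of 1000
        assert conn.n_astro_in == 1000  # 50% of 2000

    def test_zero_fraction_gives_zero_contacts(self, spiking_params):
        p = spiking_params.replace(frac_glio_targets=0.0)
        conn = build_connectivity(p, seed=1)
        assert conn.n_glio_E == 0 and conn.n_glio_I == 0

    def test_empty_population_with_positive_fraction_rejected(self, spiking_params):
        with pytest.raises(ValueError):
            build_connectivity(spiking_params.replace(N_A=0), seed=0)

    def test_subsets_are_seeded_and_uniform(self, spiking_params):
        c1 = build_connectivity(spiking_params, seed=5)
        c2 = build_connectivity(spiking_params, seed=5)
        c3 = build_connectivity(spiking_params, seed=6)
        assert np.array_equal(c1.glio_E, c2.glio_E)
        assert not np.array_equal(c1.glio_E, c3.glio_E)


class TestInitState:
    def test_initial_ranges(self, spiking_params):
        conn = build_connectivity(spiking_params, seed=0)
        st = init_state(spiking_params, conn, seed=0)
        assert st.V_E.min() >= 14.0 and st.V_E.max() < 20.0
        assert st.G.min() >= 9.0 and st.G.max() < 13.0
        assert st.u_E == 0.0 and st.s_A == 0.0
        assert np.all(st.I_a == 0.0)

    def test_deterministic(self, spiking_params):
        conn = build_connectivity(spiking_params, seed=0)
        a = init_state(spiking_params, conn, seed=3)
        b = init_state(spiking_params, conn, seed=3)
        assert np.array_equal(a.V_E, b.V_E) and np.array_equal(a.G, b.G)


def _quiet_params(**kw):
    """Small noiseless network with all couplings removed unless overridden."""
    base = dict(
        N_E=20, N_I=10, N_A=10, sigma_E=0.0, sigma_I=0.0, sigma_A=0.0,
        J_EE=0.0, J_EI=0.0, J_IE=0.0, J_II=0.0, J_EA=0.0, J_IA=0.0,
        J_AE=0.0, J_AI=0.0, J_AA=0.0,
    )
    base.update(kw)
    return au.SpikingParams(**base)


def _subthreshold_state(params, conn, dt=0.1):
    st = init_state(params, conn, seed=0, dt=dt)
    st.V_E[:] = params.V_L_E
    st.V_I[:] = params.V_L_I
    st.G[:] = params.G_L
    return st


class TestNetworkDynamics:
    def test_silent_network_null(self):
        """Zero noise + subthreshold init => no events over any horizon."""
        p = _quiet_params()
        conn = build_connectivity(p, seed=0)
        st = _subthreshold_state(p, conn)
        raster, traces = au.simulate_spiking(p, conn, duration=2_000.0, seed=0, init=st)
        assert len(raster) == 0
        assert traces.u_E.max() == 0.0 and traces.s_A.max() == 0.0

    def test_voltage_decays_to_leak(self):
        p = _quiet_params()
        conn = build_connectivity(p, seed=0)
        st = init_state(p, conn, seed=0)
        st.V_E[:] = 18.0  # subthreshold, above leak
        st.V_I[:] = p.V_L_I
        st.G[:] = p.G_L
        raster, traces = au.simulate_spiking(p, conn, duration=300.0, seed=0, init=st)
        assert len(raster) == 0
        expected = p.V_L_E + (18.0 - p.V_L_E) * np.exp(-300.0 / p.tau_E)
        assert traces.v_example_E[-1] == pytest.approx(expected, abs=0.02)

    def test_single_event_matures_at_exact_delay(self):
        """One E spike with a fixed 5 ms delay bumps u_E by tau_bar/tau_r at t0+d."""
        p = _quiet_params(d_min_E=5.0, d_max_E=5.0)
        conn = build_connectivity(p, seed=0)
        st = _subthreshold_state(p, conn)
        st.V_E[0] = 25.0  # fires on the first step
        raster, traces = au.simulate_spiking(
            p, conn, duration=20.0, seed=0, init=st, record_every=1
        )
        assert raster.count("E") == 1
        assert raster.t_ms[0] == pytest.approx(0.1)
        jump = p.tau_bar_E / p.tau_r_E
        first_nonzero = np.argmax(traces.u_E > 0)
        # spike at 0.1 ms + 5 ms delay: u jumps during the step ending at 5.2 ms
        assert traces.t_ms[first_nonzero] == pytest.approx(5.2, abs=0.05)
        assert traces.u_E[first_nonzero] == pytest.approx(jump, rel=1e-9)

    def test_astro_release_and_delay_bounds(self):
        """A release event matures within [d_min_A, d_max_A]."""
        p = _quiet_params()
        conn = build_connectivity(p, seed=0)
        st = _subthreshold_state(p, conn)
        st.G[0] = 14.0  # above release threshold
        raster, traces = au.simulate_spiking(
            p, conn, duration=2_000.0, seed=0, init=st, record_every=1
        )
        assert raster.count("A") == 1
        t_jump = traces.t_ms[np.argmax(traces.u_A > 0)]
        assert 500.0 <= t_jump <= 1500.0 + 0.2

    def test_reset_after_spike(self):
        p = _quiet_params()
        conn = build_connectivity(p, seed=0)
        st = _subthreshold_state(p, conn)
        st.V_E[0] = 30.0
        new, raster = au.network_step(st, p, conn, dt=0.1)
        assert raster.count("E") == 1
        assert new.V_E[0] == pytest.approx(p.V_r)

    def test_ahp_impulse_response(self):
        """A regularly firing cell accumulates I_a as a sum of beta/tau_a jumps."""
        p = _quiet_params(N_E=1, N_I=1, N_A=1, V_L_E=25.0)  # suprathreshold drive
        conn = build_connectivity(p, seed=0)
        st = _subthreshold_state(p, conn)
        st.V_E[0] = p.V_r
        raster, traces = au.simulate_spiking(
            p, conn, duration=200.0, seed=0, init=st, record_every=1
        )
        spikes = raster.t_ms[raster.population == 0]
        assert len(spikes) >= 3
        t_end = traces.t_ms[-1]
        expected = (p.beta / p.tau_a) * np.sum(np.exp(-(t_end - spikes) / p.tau_a))
        assert traces.mean_ahp[-1] == pytest.approx(p.K_a * expected, rel=1e-2)

    def test_event_conservation(self, small_spiking_params):
        """Every spike enqueues exactly one delayed event: matured + pending == spikes."""
        p = small_spiking_params
        conn = build_connectivity(p, seed=2)
        st = init_state(p, conn, seed=2)
        n_steps = 20_000  # 2 s
        pop, cell, t, traces, matured = _run_kernel(st, p, conn, n_steps, 0.1, 77, 10)
        for code, queue in ((0, st.queue_E), (1, st.queue_I), (2, st.queue_A)):
            n_spikes = int(np.sum(pop == code))
            assert matured[code] + queue.sum() == n_spikes

    def test_determinism_and_seed_sensitivity(self, small_spiking_params):
        r1, _ = au.simulate_spiking(small_spiking_params, duration=1_000.0, seed=10)
        r2, _ = au.simulate_spiking(small_spiking_params, duration=1_000.0, seed=10)
        r3, _ = au.simulate_spiking(small_spiking_params, duration=1_000.0, seed=11)
        assert np.array_equal(r1.t_ms, r2.t_ms) and np.array_equal(r1.cell, r2.cell)
        assert not np.array_equal(r1.t_ms, r3.t_ms)

    def test_numerical_blowup_reported(self, small_spiking_params):
        conn = build_connectivity(small_spiking_params, seed=0)
        st = init_state(small_spiking_params, conn, seed=0)
        st.V_E[0] = np.nan
        with pytest.raises(FloatingPointError, match="V_E"):
            au.network_step(st, small_spiking_params, conn)

    def test_astro_synaptic_variable_steadier_than_neuronal(self, spiking_run_astro):
        """Release events spread by second-scale delays keep s_A nearly
        stationary across Up/Down phases while s_E follows them."""
        _, traces = spiking_run_astro
        sel = traces.t_ms > 2_000.0  # drop the initial transient
        cv = lambda x: x.std() / x.mean()
        assert cv(traces.s_A[sel]) / cv(traces.s_E[sel]) < 0.5

    def test_up_states_initiated_by_contacted_subset(self, spiking_params, spiking_run_astro):
        """Around Down->Up transitions the astrocyte-contacted E cells fire first."""
        raster, traces = spiking_run_astro
        from astroud.segmentation import raster_to_rate, median_smooth, segment_phases

        conn = build_connectivity(
            spiking_params, au.utils.derive_seeds(1234, 3)[0]
        )
        seg = segment_phases(median_smooth(raster_to_rate(raster)))
        cells, times = raster.events_of("E")
        contacted = conn.glio_E[cells]
        frac_contact = []
        for iv in seg.retained("Up"):
            pre = (times >= iv.start - 60.0) & (times < iv.start + 10)
            if pre.sum() >= 5:
                frac_contact.append(contacted[pre].mean())
        assert len(frac_contact) >= 3
        # contacted cells are 10% of the population but dominate ignition windows
        assert np.median(frac_contact) > 0.3


class TestNoiseGenerator:
    def test_moments_and_tails(self):
        x = sample_normals(2024, 4_000_000)
        n = len(x)
        assert abs(x.mean()) < 3.5 / np.sqrt(n)
        assert x.std() == pytest.approx(1.0, abs=3.5 / np.sqrt(2 * n))
        assert np.mean(x**3) == pytest.approx(0.0, abs=5 * np.sqrt(15 / n))
        assert np.mean(x**4) == pytest.approx(3.0, abs=5 * np.sqrt(96 / n))
        for z, pz in ((1.0, 0.3173), (2.0, 0.0455), (3.0, 0.0027)):
            frac = np.mean(np.abs(x) > z)
            se = np.sqrt(pz * (1 - pz) / n)
            assert frac == pytest.approx(pz, abs=5 * se)

    def test_deterministic_stream(self):
        assert np.array_equal(sample_normals(7, 1000), sample_normals(7, 1000))
        assert not np.array_equal(sample_normals(7, 1000), sample_normals(8, 1000))
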