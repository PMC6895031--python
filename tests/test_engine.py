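"""LIF and alpha-synapse numerics against closed-form oracles."""

import math

import numpy as np
import pytest

from tilespike.builder import ConnectionBatch, TilePopulation
from tilespike.config import (
    NeuronModelParams,
    SystemSpec,
)
from tilespike.engine import (
    SchedulingError,
    TileSimulator,
    simulate_tile,
    step_membrane,
    step_synapse,
    synaptic_current,
)
from tilespike.store import build_store

from conftest import make_single_type_region

DT = 0.1
TAU_S = 2.0


def _alpha_closed_form(t, tau):
    """Conductance of a unit-weight spike at t=0: (t/τ)·e^{1-t/τ}."""
    return (t / tau) * math.exp(1.0 - t / tau)


class TestAlphaSynapse:
    def test_exact_update_matches_closed_form_on_grid(self):
        z = np.array([math.e])  # unit-weight impulse at t=0
        g = np.array([0.0])
        for k in range(1, 501):
            z, g = step_synapse(z, g, DT, TAU_S)
            t = k * DT
            assert g[0] == pytest.approx(_alpha_closed_form(t, TAU_S),
                                         abs=1e-12)
        # the peak: g(τ) == 1 exactly (within 1e-12), at t = 2 ms

    def test_unit_peak_at_tau(self):
        z, g = np.array([math.e]), np.array([0.0])
        for _ in range(int(TAU_S / DT)):
            z, g = step_synapse(z, g, DT, TAU_S)
        assert abs(g[0] - 1.0) <= 1e-12

    def test_decays_to_zero_without_input(self):
        z, g = np.array([math.e]), np.array([0.0])
        for _ in range(int(50 * TAU_S / DT)):
            z, g = step_synapse(z, g, DT, TAU_S)
        assert 0 <= g[0] < 1e-10 and 0 <= z[0] < 1e-10

    def test_two_spikes_superpose_linearly(self):
        def response(impulses, n_steps):
            z, g = np.array([0.0]), np.array([0.0])
            out = []
            for k in range(n_steps):
                z = z + impulses.get(k, 0.0) * math.e
                z, g = step_synapse(z, g, DT, TAU_S)
                out.append(g[0])
            return np.array(out)

        a = response({3: 1.0}, 200)
        b = response({40: 0.5}, 200)
        both = response({3: 1.0, 40: 0.5}, 200)
        np.testing.assert_allclose(both, a + b, atol=1e-14)


class TestSynapticCurrent:
    def test_unit_conductance_driving_force(self):
        i = synaptic_current(np.array([[1.0], [0.0]]), np.array([-70.0]),
                            np.array([0.0, -70.0]))
        assert i[0] == pytest.approx(70.0)

    def test_zero_at_reversal(self):
        i = synaptic_current(np.array([[1.0], [2.0]]), np.array([0.0]),
                            np.array([0.0, 0.0]))
        assert i[0] == 0.0

    def test_inhibitory_drives_negative(self):
        i = synaptic_current(np.array([[0.0], [2.0]]), np.array([-50.0]),
                            np.array([0.0, -70.0]))
        assert i[0] == pytest.approx(-40.0)


class TestMembrane:
    def test_euler_decay_tracks_exponential(self):
        """Free decay toward rest matches the exponential within O(dt)."""
        p = NeuronModelParams()
        tau = np.array([20.0])
        u = np.array([p.u_rest + 10.0])
        zero = np.array([0.0])
        for k in range(1, int(20.0 / DT) + 1):
            u, spiked = step_membrane(u, zero, zero, tau, p, DT)
            assert not spiked.any()
        exact = p.u_rest + 10.0 * math.exp(-1.0)  # at t = τ_m
        assert abs(u[0] - exact) < 0.005 * 10.0

    def test_subthreshold_fixed_point(self):
        p = NeuronModelParams()
        tau = np.array([20.0])
        u = np.array([p.u_rest])
        bias = np.array([15.0])  # u_rest + 15 < θ
        zero = np.array([0.0])
        for _ in range(20_000):
            u, spiked = step_membrane(u, bias, zero, tau, p, DT)
            assert not spiked.any()
        assert u[0] == pytest.approx(p.u_rest + 15.0, abs=1e-9)

    def test_tonic_isi_matches_closed_form(self):
        """bias 25 over a 20 mV gap fires with ISI ≈ -τ ln(1-20/25)."""
        p = NeuronModelParams()
        tau_m = 20.0
        tau = np.array([tau_m])
        u = np.array([p.u_reset])
        bias = np.array([25.0])
        zero = np.array([0.0])
        spike_steps = []
        for k in range(1, 20_000):
            u, spiked = step_membrane(u, bias, zero, tau, p, DT)
            if spiked[0]:
                spike_steps.append(k)
        isis = np.diff(spike_steps)
        assert len(isis) > 10 and np.all(isis == isis[0])
        # Euler-exact ISI: smallest k with (1-a)^k <= 1 - gap/drive
        a = DT / tau_m
        k_exact = math.ceil(math.log(1 - 20.0 / 25.0) / math.log(1 - a))
        assert isis[0] == k_exact
        continuous = -tau_m * math.log(1 - 20.0 / 25.0)
        assert abs(isis[0] * DT - continuous) <= max(2 * DT, 0.01 * continuous)


def _manual_pop(n, bias, gid_start=0):
    return TilePopulation(
        tile_id=0, x0=0.0, y0=0.0, tile_len=100.0, gid_start=gid_start,
        type_index=np.zeros(n, dtype=np.uint16),
        x=np.full(n, 50.0), y=np.full(n, 50.0), z=np.zeros(n),
        bias=np.asarray(bias, dtype=float),
    )


def _system(t_ms=100.0, seed=3):
    return SystemSpec(biological_time_ms=t_ms, dt_ms=DT, seed=seed)


class TestSimulateTile:
    def test_zero_neurons(self):
        region = make_single_type_region()
        res = simulate_tile(_manual_pop(0, []), build_store(ConnectionBatch.empty()),
                            region, _system())
        assert len(res.spike_ticks) == 0

    def test_subthreshold_neuron_stays_silent(self):
        region = make_single_type_region()
        res = simulate_tile(_manual_pop(1, [15.0]),
                            build_store(ConnectionBatch.empty()),
                            region, _system(t_ms=1000.0))
        assert len(res.spike_ticks) == 0

    def test_bias_only_rates_match_isi_prediction(self):
        """With no synapses, per-neuron spike counts follow the Euler ISI."""
        region = make_single_type_region()
        biases = [22.0, 25.0, 30.0, 50.0]
        res = simulate_tile(_manual_pop(4, biases),
                            build_store(ConnectionBatch.empty()),
                            region, _system(t_ms=1000.0))
        a = DT / 20.0
        for i, b in enumerate(biases):
            k_isi = math.ceil(math.log(1 - 20.0 / b) / math.log(1 - a))
            expect = (int(round(1000.0 / DT))) // k_isi
            got = int((res.spike_gids == i).sum())
            assert abs(got - expect) <= 1

    def test_excitation_chain_fires_follower_on_schedule(self):
        """A drives B: B's first spike follows A's by delay plus the
        hand-stepped conductance rise time."""
        region = make_single_type_region(delay_ms=2.0)
        pop = _manual_pop(2, [25.0, 0.0])
        delay_ticks = 20
        batch = ConnectionBatch(
            pre_gid=np.array([0]), post_gid=np.array([1]),
            weight=np.array([5.0], dtype=np.float32),
            delay_ticks=np.array([delay_ticks], dtype=np.uint16),
            syn_type=np.array([0], dtype=np.uint16),
        )
        res = simulate_tile(pop, build_store(batch), region, _system(t_ms=100.0))
        a_spikes = res.spike_ticks[res.spike_gids == 0]
        b_spikes = res.spike_ticks[res.spike_gids == 1]
        assert len(a_spikes) > 0 and len(b_spikes) > 0

        # hand-stepped scalar oracle for B
        p = region.model_params
        z = g = u_b = 0.0
        u = p.u_rest
        due = {int(t) + delay_ticks: 5.0 * math.e for t in a_spikes}
        first_b = None
        for k in range(int(round(100.0 / DT))):
            z += due.get(k, 0.0)
            i_syn = g * (0.0 - u)
            decay = math.exp(-DT / 2.0)
            g = decay * (g + (DT / 2.0) * z)
            z = decay * z
            u = u + (DT / 20.0) * (-u + p.u_rest + i_syn)
            if u >= p.theta:
                first_b = k + 1
                break
        assert first_b is not None
        assert b_spikes[0] == first_b

    def test_inbox_gap_raises_scheduling_error(self):
        region = make_single_type_region()
        pop = _manual_pop(1, [25.0])
        with pytest.raises(SchedulingError):
            simulate_tile(pop, build_store(ConnectionBatch.empty()), region,
                          _system(t_ms=20.0), inbox={0: []}, interval_ticks=10)

    def test_remote_spike_changes_conductance_after_exact_delay(self):
        """An inbox spike first perturbs the follower's synaptic state at
        spike tick + delay, i.e. 1 ms = 10 steps for the minimum delay."""
        region = make_single_type_region(delay_ms=1.0)
        pop = _manual_pop(1, [0.0], gid_start=1)
        batch = ConnectionBatch(
            pre_gid=np.array([0]), post_gid=np.array([1]),
            weight=np.array([1.0], dtype=np.float32),
            delay_ticks=np.array([10], dtype=np.uint16),
            syn_type=np.array([0], dtype=np.uint16),
        )
        sim = TileSimulator(pop, build_store(batch), region,
                            _system(t_ms=10.0), interval_ticks=5)
        spike_tick = 3  # remote spike in interval 0
        sim.schedule_spike(0, spike_tick)
        changed_at = None
        for k in range(100):
            sim.step()
            if changed_at is None and (sim.z != 0).any():
                changed_at = k  # z receives the impulse at step start
        assert changed_at == spike_tick + 10

    def test_bitwise_reproducibility_same_seed(self):
        from tilespike import build_sheet, plan_grid, run
        from conftest import make_toy_region
        region = make_toy_region()
        system = _system(t_ms=200.0, seed=11)
        grid = plan_grid(1, 1, 600.0)
        r1 = run(build_sheet(region, system, grid), "serial")
        r2 = run(build_sheet(region, system, grid), "serial")
        np.testing.assert_array_equal(r1.spikes, r2.spikes)
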