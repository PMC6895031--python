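"""Placement, kernel calibration and connection-draw correctness."""

import math
import warnings

import numpy as np
import pytest
from scipy import integrate

from tilespike.builder import (
    CalibrationError,
    PeakCapWarning,
    TilePopulation,
    calibrate_peaks,
    expected_counts,
    expected_in_degree,
    generate_connections,
    place_neurons,
    sample_weight,
)
from tilespike.config import KernelSpec, NeuronTypeSpec
from tilespike.m1 import builtin_m1_region
from tilespike.rng import Xorshift32

from conftest import make_single_type_region, make_toy_region


def _point_population(tile_id, xy_points, gid_start=0, type_idx=0,
                      tile_len=1000.0):
    """Hand-built population with explicit positions (zero bias)."""
    n = len(xy_points)
    return TilePopulation(
        tile_id=tile_id, x0=0.0, y0=0.0, tile_len=tile_len,
        gid_start=gid_start,
        type_index=np.full(n, type_idx, dtype=np.uint16),
        x=np.array([p[0] for p in xy_points], dtype=float),
        y=np.array([p[1] for p in xy_points], dtype=float),
        z=np.zeros(n), bias=np.zeros(n),
    )


class TestExpectedInDegree:
    def test_matches_radial_quadrature(self):
        """Closed form equals direct numerical integration of the kernel disc."""
        k = KernelSpec(pre_type="a", post_type="b", peak=0.25, sigma=650.0,
                       cutoff=1300.0)
        density = 56291.0  # per mm^2
        integrand = lambda r_mm: (0.25 * math.exp(-r_mm**2 / (2 * 0.65**2))
                                  * density * 2 * math.pi * r_mm)
        oracle, _ = integrate.quad(integrand, 0.0, 1.3)
        got = expected_in_degree(k, density)
        assert got == pytest.approx(oracle, rel=1e-10)
        assert got == pytest.approx(3.230e4, rel=1e-3)

    def test_zero_peak_gives_zero(self):
        k = KernelSpec(pre_type="a", post_type="b", peak=0.0, sigma=100.0,
                       cutoff=400.0)
        assert expected_in_degree(k, 1000.0) == 0.0

    def test_large_cutoff_approaches_full_gaussian_mass(self):
        k = KernelSpec(pre_type="a", post_type="b", peak=0.2, sigma=100.0,
                       cutoff=5000.0)
        full = 1000.0 * 0.2 * 2 * math.pi * 0.1**2
        assert expected_in_degree(k, 1000.0) == pytest.approx(full, rel=1e-9)


class TestCalibration:
    def test_single_pair_scales_linearly(self):
        region = make_single_type_region(density=1000.0, in_degree=100.0)
        base = expected_in_degree(region.kernels[0], 1000.0)
        plan = calibrate_peaks(region)
        peak = plan.kernels[("exc", "exc")].peak
        assert peak == pytest.approx(0.1 * (100.0 / base), rel=1e-12)

    def test_m1_plan_hits_every_target(self):
        region = builtin_m1_region()
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # M1 calibration stays under caps
            plan = calibrate_peaks(region)
        plan.check_in_degrees(rtol=1e-3)
        assert plan.in_degree_of("L2/3 IT") == pytest.approx(3178, rel=1e-3)

    def test_cap_violation_warns_but_builds(self):
        region = make_single_type_region(density=100.0, in_degree=10.0)
        with pytest.warns(PeakCapWarning):
            plan = calibrate_peaks(region)
        plan.check_in_degrees()

    def test_unreachable_target_raises(self):
        region = make_single_type_region(density=1.0, in_degree=1000.0)
        with pytest.raises(CalibrationError):
            calibrate_peaks(region)

    def test_density_invariance_of_connection_budget(self):
        """Scaling densities by f scales connections/mm² by f, peaks by 1/f."""
        base = make_toy_region(in_degree=2.0)  # headroom: peaks stay <= 1 at f=0.01
        plan0 = calibrate_peaks(base)
        c0 = expected_counts(base, 1000.0).connections_per_mm2
        for f in (0.01, 0.1):
            scaled = make_toy_region(in_degree=2.0)
            scaled.neuron_types = [
                NeuronTypeSpec(**{**t.__dict__, "density": t.density * f})
                for t in base.neuron_types]
            plan_f = calibrate_peaks(scaled)
            cf = expected_counts(scaled, 1000.0).connections_per_mm2
            assert cf == pytest.approx(f * c0, rel=1e-12)
            for key in plan0.kernels:
                assert plan_f.kernels[key].peak == pytest.approx(
                    plan0.kernels[key].peak / f, rel=1e-9)


class TestExpectedCounts:
    def test_m1_tile_census(self):
        c = expected_counts(builtin_m1_region(), 1300.0)
        assert c.neurons_per_tile == pytest.approx(95_131.79, abs=0.01)
        assert c.connections_per_tile == pytest.approx(3.5966e8, rel=1e-3)
        assert round(c.mean_in_degree) == 3781
        assert c.bytes_per_tile == pytest.approx(14 * c.connections_per_tile)

    def test_zero_tile(self):
        c = expected_counts(builtin_m1_region(), 0.0)
        assert (c.neurons_per_tile, c.connections_per_tile,
                c.bytes_per_tile) == (0.0, 0.0, 0.0)


class TestPlacement:
    def test_positions_respect_tile_and_layer(self):
        region = make_toy_region()
        pop = place_neurons(0, 1000.0, 2000.0, 500.0, region,
                            Xorshift32(3), gid_start=10)
        assert np.all((pop.x >= 1000.0) & (pop.x < 1500.0))
        assert np.all((pop.y >= 2000.0) & (pop.y < 2500.0))
        assert np.all((pop.z >= 0.0) & (pop.z <= 200.0))
        assert pop.gids[0] == 10 and pop.gids[-1] == 10 + pop.n - 1

    def test_zero_density_type_places_nothing(self):
        region = make_single_type_region(density=0.0, in_degree=0.0)
        pop = place_neurons(0, 0, 0, 1000.0, region, Xorshift32(3))
        assert pop.n == 0

    def test_fixed_mode_is_deterministic_expectation(self):
        region = make_toy_region()
        pop = place_neurons(0, 0, 0, 1000.0, region, Xorshift32(3),
                            count_mode="fixed")
        assert pop.n == 500  # 400 + 100 per mm^2 on a 1 mm^2 tile

    def test_poisson_counts_follow_poisson_law(self):
        """Sample mean of a density-100, 1 mm² tile count is within 3 SE of 100."""
        rng = Xorshift32(11)
        draws = np.array([rng.poisson(100.0) for _ in range(10_000)])
        se = math.sqrt(100.0 / len(draws))
        assert abs(draws.mean() - 100.0) < 3 * se

    def test_bias_distribution(self):
        region = make_toy_region()
        pop = place_neurons(0, 0, 0, 2000.0, region, Xorshift32(5))
        exc = pop.bias[pop.type_index == 0]
        assert abs(exc.mean() - 16.0) < 4 * 4.0 / math.sqrt(len(exc))


class TestGenerateConnections:
    def test_coincident_points_connect_with_certainty(self):
        """peak=1 at distance 0 ⇒ every ordered non-self pair connects."""
        region = make_single_type_region(density=100.0, in_degree=1.0)
        region.kernels = [KernelSpec(pre_type="exc", post_type="exc",
                                     peak=1.0, sigma=200.0, cutoff=400.0)]
        plan = calibrate_peaks(region)
        plan.kernels[("exc", "exc")] = region.kernels[0]
        pre = _point_population(0, [(50.0, 50.0)] * 4)
        batch = generate_connections([pre], pre, plan, Xorshift32(2),
                                     Xorshift32(3))
        assert batch.n == 4 * 3  # all ordered pairs except self-pairs
        assert np.all(batch.pre_gid != batch.post_gid)

    def test_zero_peak_yields_empty(self):
        region = make_single_type_region()
        plan = calibrate_peaks(region)
        plan.kernels[("exc", "exc")] = KernelSpec(
            pre_type="exc", post_type="exc", peak=0.0, sigma=150.0,
            cutoff=450.0)
        pop = place_neurons(0, 0, 0, 400.0, region, Xorshift32(4))
        batch = generate_connections([pop], pop, plan, Xorshift32(2),
                                     Xorshift32(3))
        assert batch.n == 0

    def test_count_within_binomial_band_of_pair_probabilities(self):
        """Realized count sits in the 99% band of Σ p(d_ij) over all pairs."""
        region = make_toy_region()
        plan = calibrate_peaks(region)
        pop = place_neurons(0, 0, 0, 500.0, region, Xorshift32.substream(6, 0))
        batch = generate_connections([pop], pop, plan,
                                     Xorshift32.substream(8, 0),
                                     Xorshift32.substream(9, 0))
        # enumerate all ordered pairs by hand
        names = [t.name for t in region.neuron_types]
        mu = 0.0
        var = 0.0
        for j in range(pop.n):
            for i in range(pop.n):
                if i == j:
                    continue
                pre_t, post_t = names[pop.type_index[i]], names[pop.type_index[j]]
                if (pre_t, post_t) not in plan.kernels:
                    continue
                k = plan.kernels[(pre_t, post_t)]
                d2 = (pop.x[i] - pop.x[j])**2 + (pop.y[i] - pop.y[j])**2
                if d2 > k.cutoff**2:
                    continue
                p = k.peak * math.exp(-d2 / (2 * k.sigma**2))
                mu += p
                var += p * (1 - p)
        assert abs(batch.n - mu) < 3.0 * math.sqrt(var)

    def test_agrees_with_bruteforce_oracle_on_shared_variates(self):
        """A naive all-pairs Bernoulli loop consuming the same stream
        reproduces the exact same edge set."""
        region = make_toy_region()
        plan = calibrate_peaks(region)
        rng = Xorshift32(31)
        pop = place_neurons(0, 0, 0, 300.0, region, rng)
        assert pop.n <= 60
        batch = generate_connections([pop], pop, plan, Xorshift32(13),
                                     Xorshift32(14))
        got = set(zip(batch.pre_gid.tolist(), batch.post_gid.tolist()))

        names = [t.name for t in region.neuron_types]
        oracle_rng = Xorshift32(13)
        expect = set()
        for j in range(pop.n):  # post gids ascending
            for i in range(pop.n):  # pre gids ascending
                pre_t, post_t = names[pop.type_index[i]], names[pop.type_index[j]]
                if (pre_t, post_t) not in plan.kernels or i == j:
                    continue
                k = plan.kernels[(pre_t, post_t)]
                d2 = (pop.x[i] - pop.x[j])**2 + (pop.y[i] - pop.y[j])**2
                if d2 > k.cutoff**2:
                    continue
                p = k.peak * math.exp(-d2 / (2 * k.sigma**2))
                if oracle_rng.uniform() < p:
                    expect.add((i, j))
        assert got == expect

    def test_no_connection_beyond_cutoff(self):
        region = make_toy_region()
        plan = calibrate_peaks(region)
        pops = [place_neurons(t, 700.0 * t, 0, 700.0, region,
                              Xorshift32(40 + t), gid_start=0 if t == 0 else None)
                for t in range(2)]
        pops[1].gid_start = pops[0].n
        batch = generate_connections(pops, pops[0], plan, Xorshift32(50),
                                     Xorshift32(51))
        all_x = np.concatenate([p.x for p in pops])
        all_y = np.concatenate([p.y for p in pops])
        d = np.hypot(all_x[batch.pre_gid] - all_x[batch.post_gid],
                     all_y[batch.pre_gid] - all_y[batch.post_gid])
        assert np.all(d <= 600.0)

    def test_interior_in_degree_recovers_target_at_reduced_density(self):
        """Periodic sheet at half density realizes half the in-degree target."""
        region = make_single_type_region(density=2000.0, in_degree=30.0,
                                         sigma=150.0, cutoff=450.0)
        plan = calibrate_peaks(region)
        pop = place_neurons(0, 0, 0, 1000.0, region,
                            Xorshift32.substream(3, 0), density_scale=0.5)
        batch = generate_connections([pop], pop, plan,
                                     Xorshift32.substream(4, 0),
                                     Xorshift32.substream(5, 0),
                                     periodic_extent=(1000.0, 1000.0))
        mean_k = batch.n / pop.n
        # conditional on the realized count n, each neuron expects
        # (n-1) * target / (full density * area) incoming connections
        expect_cond = (pop.n - 1) * 30.0 / 2000.0
        se = math.sqrt(expect_cond / pop.n)
        assert abs(mean_k - expect_cond) < 4 * se
        # and unconditionally the Poisson spread of n dominates: 3σ band
        sd_n = math.sqrt(1000.0)
        assert abs(mean_k - 15.0) < 4 * se + 3 * sd_n * 30.0 / 2000.0


class TestWeights:
    def test_printed_constants(self):
        region = builtin_m1_region()
        rng = Xorshift32(2)
        assert sample_weight("L2/3 PV", "L2/3 IT", region, rng) == 2.00
        assert sample_weight("L6 IT", "L6 SST", region, rng) == 0.19

    def test_lognormal_law(self):
        region = builtin_m1_region()
        rng = Xorshift32(6)
        w = np.array([sample_weight("L2/3 IT", "L5A IT", region, rng)
                      for _ in range(2000)])
        assert np.all(w > 0)
        lw = np.log(w)
        assert abs(lw.mean() + 0.72) < 3 * 1.0 / math.sqrt(len(lw))

    def test_batch_weights_follow_rules(self):
        region = make_toy_region()
        plan = calibrate_peaks(region)
        pop = place_neurons(0, 0, 0, 600.0, region, Xorshift32(8))
        batch = generate_connections([pop], pop, plan, Xorshift32(9),
                                     Xorshift32(10))
        names = [t.name for t in region.neuron_types]
        pre_t = pop.type_index[batch.pre_gid]
        post_t = pop.type_index[batch.post_gid]
        w = batch.weight
        assert np.allclose(w[(pre_t == 0) & (post_t == 1)], 0.03)
        assert np.allclose(w[pre_t == 1], 0.15)
        ee = w[(pre_t == 0) & (post_t == 0)]
        assert len(ee) > 100 and np.all(ee > 0)
        assert abs(np.log(ee.astype(float)).mean() + 3.5) \
            < 4 * 0.5 / math.sqrt(len(ee))

    def test_unresolved_pair_is_lookup_error(self):
        region = make_toy_region()
        region.weight_rules = region.weight_rules[:2]  # drop the I rule
        with pytest.raises(Exception):
            sample_weight("inh", "exc", region, Xorshift32(2))
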