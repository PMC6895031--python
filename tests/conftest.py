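"""Shared fixtures: small two-type sheet models with sparse, stable firing."""

from __future__ import annotations

import numpy as np
import pytest

from tilespike.config import (
    KernelSpec,
    LayerSpec,
    NeuronTypeSpec,
    RegionSpec,
    SynapseClassSpec,
    SystemSpec,
    WeightRuleSpec,
)


def make_toy_region(delay_ms: float = 2.0, peak: float = 0.1,
                    sigma: float = 300.0, cutoff: float = 600.0,
                    in_degree: float = 20.0) -> RegionSpec:
    """Two-type (E/I) single-layer sheet that fires at a few Hz.

    Weights are weak enough that recurrent input perturbs spike times
    without causing runaway excitation; the inhibitory bias N(18, 4)
    drives a tonically active tail as in the full model.
    """
    types = [
        NeuronTypeSpec(name="exc", layer="a", ei_class="excitatory",
                       density=400.0, tau_m=20.0, target_in_degree=in_degree,
                       bias_mean=16.0, bias_sd=4.0),
        NeuronTypeSpec(name="inh", layer="a", ei_class="inhibitory",
                       density=100.0, tau_m=10.0, target_in_degree=in_degree,
                       bias_mean=18.0, bias_sd=4.0),
    ]
    mask = [(a, b) for a in ("exc", "inh") for b in ("exc", "inh")]
    kernels = [KernelSpec(pre_type=a, post_type=b, peak=peak, sigma=sigma,
                          cutoff=cutoff) for a, b in mask]
    rules = [
        WeightRuleSpec("E", "E", rule="lognormal", mu_ln=-3.5, sigma_ln=0.5),
        WeightRuleSpec("E", "I", rule="constant", value=0.03),
        WeightRuleSpec("I", "*", rule="constant", value=0.15),
    ]
    return RegionSpec(
        name="toy", layers=[LayerSpec("a", 200.0)], neuron_types=types,
        synapse_classes=[SynapseClassSpec("excitatory", 2.0, 0.0),
                         SynapseClassSpec("inhibitory", 2.0, -70.0)],
        kernels=kernels, weight_rules=rules, connectivity_mask=mask,
        delay_ms=delay_ms, total_depth_um=200.0,
    )


def make_single_type_region(density: float = 2000.0, in_degree: float = 30.0,
                            sigma: float = 150.0, cutoff: float = 450.0,
                            delay_ms: float = 2.0) -> RegionSpec:
    """One excitatory type; handy for parameter-recovery and analytics tests."""
    t = NeuronTypeSpec(name="exc", layer="a", ei_class="excitatory",
                       density=density, tau_m=20.0, target_in_degree=in_degree,
                       bias_mean=10.0, bias_sd=5.0)
    return RegionSpec(
        name="mono", layers=[LayerSpec("a", 100.0)], neuron_types=[t],
        synapse_classes=[SynapseClassSpec("excitatory", 2.0, 0.0),
                         SynapseClassSpec("inhibitory", 2.0, -70.0)],
        kernels=[KernelSpec(pre_type="exc", post_type="exc", peak=0.1,
                            sigma=sigma, cutoff=cutoff)],
        weight_rules=[WeightRuleSpec("E", "E", rule="constant", value=0.01)],
        connectivity_mask=[("exc", "exc")],
        delay_ms=delay_ms, total_depth_um=100.0,
    )


@pytest.fixture
def toy_region() -> RegionSpec:
    return make_toy_region()


@pytest.fixture
def toy_system() -> SystemSpec:
    return SystemSpec(biological_time_ms=300.0, dt_ms=0.1, seed=7)


@pytest.fixture
def rng_seed() -> int:
    return 20260923
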