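"""Built-in mouse primary motor cortex (M1) region.

A layered cortical sheet with five layers (1, 2/3, 5A, 5B, 6) and fifteen
neuron types: layer 1 holds two interneuron types (single-bouquet cells,
SBC, and elongated neurogliaform cells, ENGC); every deeper layer holds an
intratelencephalic excitatory type (IT) plus parvalbumin (PV) and
somatostatin (SST) interneurons, and layer 5B adds pyramidal-tract (PT)
excitatory neurons.

Per-type areal densities, membrane time constants, mean in-degrees and
reference firing rates follow the published M1 census for this model
family; summed over types they give 56,291 neurons and ≈212.8 million
connections per mm² of sheet (mean in-degree 3780.65, i.e. 3781 to the
printed precision).

Connectivity mask:

* excitatory → excitatory and excitatory → PV/SST everywhere;
* PV/SST → excitatory everywhere;
* among layer 2/3–6 interneurons only PV→PV and SST→PV connect;
* layer-1 SBC project to inhibitory targets only, ENGC to every type.

Weights: E→E log-normal (ln W ~ N(-0.72, 1)); E→PV 0.42; E→SST 0.19;
PV/SST→E 2.00; PV→PV 1.12; SST→PV 0.74; SBC→(inhibitory) 0.80;
ENGC→(all) 1.00.  Bias currents are N(10, 5) for layer-1 and excitatory
types and N(18, 5) for the deeper-layer interneurons (mV scale with
R_m = 1), giving the interneurons a tonically firing tail.

Per-pair Gaussian widths are not part of the public census; the built-in
spec therefore assigns every kernel σ = 650 μm (half the 1300 μm cutoff,
which corresponds to two standard deviations of the widest kernel) and
relative peaks at the class caps (0.12 E→E, 0.25 otherwise); kernel
calibration (`tilespike.builder.calibrate_peaks`) then rescales them so
each type's expected in-degree matches the census exactly.
"""

from __future__ import annotations

from .config import (
    DEFAULT_CUTOFF_UM,
    KernelSpec,
    LayerSpec,
    NeuronModelParams,
    NeuronTypeSpec,
    RegionSpec,
    SynapseClassSpec,
    WeightRuleSpec,
)

__all__ = ["builtin_m1_region", "M1_TABLE"]

# (layer, type name, E/I, density /mm^2, tau_m ms, in-degree, rate Hz)
M1_TABLE = [
    ("1",   "L1 SBC",    "I", 1259,  10, 15,   0.03),
    ("1",   "L1 ENGC",   "I", 540,   10, 21,   0.02),
    ("2/3", "L2/3 IT",   "E", 14659, 20, 3178, 0.06),
    ("2/3", "L2/3 PV",   "I", 2290,  10, 8105, 14.7),
    ("2/3", "L2/3 SST",  "I", 1374,  20, 3040, 30.7),
    ("5A",  "L5A IT",    "E", 5106,  20, 3952, 0.01),
    ("5A",  "L5A PV",    "I", 774,   10, 4549, 11.5),
    ("5A",  "L5A SST",   "I", 516,   20, 4215, 31.6),
    ("5B",  "L5B IT",    "E", 6072,  20, 4248, 0.0),
    ("5B",  "L5B PT",    "E", 3036,  20, 4673, 0.0),
    ("5B",  "L5B PV",    "I", 1822,  10, 6440, 0.05),
    ("5B",  "L5B SST",   "I", 1215,  20, 5283, 58.58),
    ("6",   "L6 IT",     "E", 14102, 20, 2279, 0.01),
    ("6",   "L6 PV",     "I", 1763,  10, 9908, 1.7),
    ("6",   "L6 SST",    "I", 1763,  20, 5586, 16.6),
]

# Layer thicknesses partitioning the 1400 μm depth.  Vertical position
# never affects connectivity (kernels use horizontal distance only).
M1_LAYERS = [
    ("1", 100.0),
    ("2/3", 400.0),
    ("5A", 200.0),
    ("5B", 400.0),
    ("6", 300.0),
]

_SIGMA_UM = 650.0


def _weight_class(name: str, ei: str) -> str:
    if "SBC" in name:
        return "SBC"
    if "ENGC" in name:
        return "ENGC"
    if "PV" in name:
        return "PV"
    if "SST" in name:
        return "SST"
    return "E"


def builtin_m1_region(delay_ms: float = 1.0,
                      sigma_um: float = _SIGMA_UM,
                      sigma_ln: float = 1.0) -> RegionSpec:
    """The built-in M1 layered-sheet model.

    Parameters
    ----------
    delay_ms:
        Constant signal-transmission delay applied to every connection.
    sigma_um:
        Gaussian width assigned to every kernel (per-pair widths are not
        part of the census; override via the returned spec if needed).
    sigma_ln:
        Log-space SD of the E→E log-normal weight distribution.
    """
    types = []
    for layer, name, ei, density, tau_m, in_deg, rate in M1_TABLE:
        ei_class = "excitatory" if ei == "E" else "inhibitory"
        is_l1 = layer == "1"
        bias_mean = 10.0 if (ei == "E" or is_l1) else 18.0
        types.append(NeuronTypeSpec(
            name=name, layer=layer, ei_class=ei_class,
            density=float(density), tau_m=float(tau_m),
            target_in_degree=float(in_deg),
            bias_mean=bias_mean, bias_sd=5.0,
            weight_class=_weight_class(name, ei_class),
            reference_rate_hz=rate,
        ))

    exc = [t.name for t in types if t.ei_class == "excitatory"]
    inh = [t.name for t in types if t.ei_class == "inhibitory"]
    pv = [t.name for t in types if t.weight_class == "PV"]
    sst = [t.name for t in types if t.weight_class == "SST"]

    mask: list[tuple[str, str]] = []
    mask += [(a, b) for a in exc for b in exc]            # E -> E
    mask += [(a, b) for a in exc for b in pv + sst]       # E -> PV/SST
    mask += [(a, b) for a in pv + sst for b in exc]       # PV/SST -> E
    mask += [(a, b) for a in pv for b in pv]              # PV -> PV
    mask += [(a, b) for a in sst for b in pv]             # SST -> PV
    mask += [("L1 SBC", b) for b in inh]                  # SBC -> inhibitory
    mask += [("L1 ENGC", b) for b in [t.name for t in types]]  # ENGC -> all

    def _cap(pre: str, post: str) -> float:
        pre_e = pre in exc
        post_e = post in exc
        return 0.12 if (pre_e and post_e) else 0.25

    kernels = [
        KernelSpec(pre_type=a, post_type=b, peak=_cap(a, b),
                   sigma=sigma_um, cutoff=DEFAULT_CUTOFF_UM)
        for a, b in mask
    ]

    weight_rules = [
        WeightRuleSpec("SBC", "*", rule="constant", value=0.80),
        WeightRuleSpec("ENGC", "*", rule="constant", value=1.00),
        WeightRuleSpec("E", "E", rule="lognormal", mu_ln=-0.72, sigma_ln=sigma_ln),
        WeightRuleSpec("E", "PV", rule="constant", value=0.42),
        WeightRuleSpec("E", "SST", rule="constant", value=0.19),
        WeightRuleSpec("PV", "E", rule="constant", value=2.00),
        WeightRuleSpec("SST", "E", rule="constant", value=2.00),
        WeightRuleSpec("PV", "PV", rule="constant", value=1.12),
        WeightRuleSpec("SST", "PV", rule="constant", value=0.74),
    ]

    return RegionSpec(
        name="M1",
        layers=[LayerSpec(n, t) for n, t in M1_LAYERS],
        neuron_types=types,
        synapse_classes=[
            SynapseClassSpec(name="excitatory", tau_syn=2.0, e_rev=0.0),
            SynapseClassSpec(name="inhibitory", tau_syn=2.0, e_rev=-70.0),
        ],
        kernels=kernels,
        weight_rules=weight_rules,
        connectivity_mask=mask,
        delay_ms=delay_ms,
        model_params=NeuronModelParams(),
    )
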