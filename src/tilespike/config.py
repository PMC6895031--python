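"""Model and run configuration.

Two JSON documents drive a simulation, mirroring the two-file layout used
by tile-partitioning cortical simulators:

* a *region* file — the declarative network model: layers, neuron types
  with areal densities and in-degree targets, synapse classes, Gaussian
  connection kernels, weight rules, the connectivity mask and the delay
  rule;
* a *system* file — run settings: biological time, integration step,
  worker count, seed, memory budget, recording switches.

Both are strict: unknown keys are rejected (typos fail fast), every kernel
and mask entry must reference a declared neuron type, and every allowed
(pre, post) pair must resolve to exactly one kernel and one weight rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

__all__ = [
    "ConfigError",
    "MissingFieldError",
    "UnknownKeyError",
    "UnknownReferenceError",
    "LayerSpec",
    "NeuronTypeSpec",
    "SynapseClassSpec",
    "KernelSpec",
    "WeightRuleSpec",
    "NeuronModelParams",
    "RegionSpec",
    "SystemSpec",
    "load_region_config",
    "write_region_config",
    "load_system_config",
    "write_system_config",
    "total_density",
]

DEFAULT_CUTOFF_UM = 1300.0
DEFAULT_DEPTH_UM = 1400.0
EE_PEAK_CAP = 0.12
OTHER_PEAK_CAP = 0.25


class ConfigError(ValueError):
    """Base class for configuration validation failures."""


class MissingFieldError(ConfigError):
    """A required field is absent from a configuration document."""


class UnknownKeyError(ConfigError):
    """A configuration document contains a key the schema does not define."""


class UnknownReferenceError(ConfigError):
    """A kernel, rule or mask entry references an undeclared name."""


@dataclass(frozen=True)
class LayerSpec:
    name: str
    thickness_um: float


@dataclass(frozen=True)
class NeuronTypeSpec:
    """One neuron population: where it lives and how it is parameterized.

    ``density`` is neurons per mm² of sheet; ``target_in_degree`` is the
    expected number of incoming connections per neuron that kernel
    calibration must reproduce.  ``weight_class`` groups types for weight
    rule lookup (e.g. all excitatory types share class "E").
    ``reference_rate_hz`` is descriptive metadata only and never enters
    construction.
    """

    name: str
    layer: str
    ei_class: str  # "excitatory" | "inhibitory"
    density: float  # neurons / mm^2
    tau_m: float  # ms
    target_in_degree: float
    bias_mean: float = 0.0
    bias_sd: float = 0.0
    weight_class: str = ""
    reference_rate_hz: float = 0.0

    def __post_init__(self):
        if self.ei_class not in ("excitatory", "inhibitory"):
            raise ConfigError(f"{self.name}: ei_class must be excitatory|inhibitory")
        if self.density < 0:
            raise ConfigError(f"{self.name}: density must be >= 0")
        if self.tau_m <= 0:
            raise ConfigError(f"{self.name}: tau_m must be > 0")
        if self.target_in_degree < 0:
            raise ConfigError(f"{self.name}: target_in_degree must be >= 0")
        if self.bias_sd < 0:
            raise ConfigError(f"{self.name}: bias_sd must be >= 0")
        if not self.weight_class:
            object.__setattr__(
                self, "weight_class", "E" if self.ei_class == "excitatory" else "I"
            )


@dataclass(frozen=True)
class SynapseClassSpec:
    """A conductance class: alpha-function time constant and reversal potential."""

    name: str  # "excitatory" | "inhibitory"
    tau_syn: float = 2.0  # ms
    e_rev: float = 0.0  # mV

    def __post_init__(self):
        if self.tau_syn <= 0:
            raise ConfigError(f"synapse class {self.name}: tau_syn must be > 0")


@dataclass(frozen=True)
class KernelSpec:
    """Distance-dependent connection probability p(d) = peak * exp(-d²/2σ²).

    Distances are horizontal (within-sheet) in μm; probability is zero
    beyond ``cutoff``.  Before calibration ``peak`` is a *relative*
    magnitude; calibration rescales it per postsynaptic type.
    """

    pre_type: str
    post_type: str
    peak: float
    sigma: float  # um
    cutoff: float = DEFAULT_CUTOFF_UM  # um

    def __post_init__(self):
        if not 0.0 <= self.peak <= 1.0:
            raise ConfigError(
                f"kernel {self.pre_type}->{self.post_type}: peak must lie in [0,1]"
            )
        if self.cutoff <= 0:
            raise ConfigError(
                f"kernel {self.pre_type}->{self.post_type}: cutoff must be > 0"
            )
        if not 0 < self.sigma <= self.cutoff / 2:
            raise ConfigError(
                f"kernel {self.pre_type}->{self.post_type}: need 0 < sigma <= cutoff/2"
            )


@dataclass(frozen=True)
class WeightRuleSpec:
    """Synaptic weight rule for a (pre weight-class, post weight-class) pair.

    ``rule`` is "constant" (fixed positive ``value``) or "lognormal"
    (ln W ~ Normal(mu_ln, sigma_ln)).  Selectors may be "*" wildcards;
    rules are matched in declaration order, first match wins.
    """

    pre_class: str
    post_class: str
    rule: str = "constant"
    value: float = 1.0
    mu_ln: float = -0.72
    sigma_ln: float = 1.0

    def __post_init__(self):
        if self.rule not in ("constant", "lognormal"):
            raise ConfigError(f"weight rule {self.pre_class}->{self.post_class}: "
                              f"rule must be constant|lognormal")
        if self.rule == "constant" and self.value <= 0:
            raise ConfigError(
                f"weight rule {self.pre_class}->{self.post_class}: value must be > 0"
            )
        if self.sigma_ln < 0:
            raise ConfigError(
                f"weight rule {self.pre_class}->{self.post_class}: sigma_ln >= 0"
            )

    def matches(self, pre_class: str, post_class: str) -> bool:
        return (self.pre_class in ("*", pre_class)
                and self.post_class in ("*", post_class))


@dataclass(frozen=True)
class NeuronModelParams:
    """Global leaky integrate-and-fire constants (mV scale, R_m in mV/unit current)."""

    u_rest: float = -70.0
    theta: float = -50.0
    u_reset: float = -70.0
    r_m: float = 1.0

    def __post_init__(self):
        if self.u_reset > self.theta:
            raise ConfigError("u_reset must not exceed theta")


@dataclass
class RegionSpec:
    """Full declarative description of one layered-sheet region."""

    name: str
    layers: list[LayerSpec]
    neuron_types: list[NeuronTypeSpec]
    synapse_classes: list[SynapseClassSpec]
    kernels: list[KernelSpec]
    weight_rules: list[WeightRuleSpec]
    connectivity_mask: list[tuple[str, str]]
    delay_ms: float = 1.0
    total_depth_um: float = DEFAULT_DEPTH_UM
    model_params: NeuronModelParams = field(default_factory=NeuronModelParams)

    def __post_init__(self):
        self.validate()

    # -- lookups -------------------------------------------------------

    def type_by_name(self, name: str) -> NeuronTypeSpec:
        for t in self.neuron_types:
            if t.name == name:
                return t
        raise UnknownReferenceError(f"unknown neuron type {name!r}")

    def kernel_for(self, pre: str, post: str) -> KernelSpec:
        hits = [k for k in self.kernels if k.pre_type == pre and k.post_type == post]
        if len(hits) != 1:
            raise UnknownReferenceError(
                f"pair ({pre}->{post}) resolves to {len(hits)} kernels, expected 1"
            )
        return hits[0]

    def weight_rule_for(self, pre: str, post: str) -> WeightRuleSpec:
        pre_c = self.type_by_name(pre).weight_class
        post_c = self.type_by_name(post).weight_class
        for r in self.weight_rules:
            if r.matches(pre_c, post_c):
                return r
        raise UnknownReferenceError(
            f"no weight rule matches ({pre}->{post}) classes ({pre_c}->{post_c})"
        )

    def layer_depth_range(self, layer: str) -> tuple[float, float]:
        """(z_top, z_bottom) of a layer in μm, measured down from the surface."""
        z = 0.0
        for ly in self.layers:
            if ly.name == layer:
                return z, z + ly.thickness_um
            z += ly.thickness_um
        raise UnknownReferenceError(f"unknown layer {layer!r}")

    def synapse_class_index(self, name: str) -> int:
        for i, c in enumerate(self.synapse_classes):
            if c.name == name:
                return i
        raise UnknownReferenceError(f"unknown synapse class {name!r}")

    def min_delay_ms(self) -> float:
        return self.delay_ms

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        names = [t.name for t in self.neuron_types]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate neuron type names")
        declared = set(names)
        layer_names = {ly.name for ly in self.layers}
        for t in self.neuron_types:
            if t.layer not in layer_names:
                raise UnknownReferenceError(
                    f"type {t.name!r} references undeclared layer {t.layer!r}"
                )
        for k in self.kernels:
            for end in (k.pre_type, k.post_type):
                if end not in declared:
                    raise UnknownReferenceError(
                        f"kernel references undeclared type {end!r}"
                    )
        for pre, post in self.connectivity_mask:
            if pre not in declared or post not in declared:
                raise UnknownReferenceError(
                    f"mask pair ({pre!r}, {post!r}) references undeclared type"
                )
            self.kernel_for(pre, post)  # raises unless exactly one
            self.weight_rule_for(pre, post)
        thick = sum(ly.thickness_um for ly in self.layers)
        if abs(thick - self.total_depth_um) > 1e-6:
            raise ConfigError(
                f"layer thicknesses sum to {thick} μm, expected {self.total_depth_um}"
            )
        if self.delay_ms <= 0:
            raise ConfigError("delay_ms must be > 0")

    def peak_cap(self, pre: str, post: str) -> float:
        pre_e = self.type_by_name(pre).ei_class == "excitatory"
        post_e = self.type_by_name(post).ei_class == "excitatory"
        return EE_PEAK_CAP if (pre_e and post_e) else OTHER_PEAK_CAP


@dataclass
class SystemSpec:
    """Run settings: what to simulate, with what resolution, on how many workers."""

    biological_time_ms: float = 1000.0
    dt_ms: float = 0.1
    n_workers: int = 1
    seed: int = 1
    memory_limit_bytes: int = 8 * 10**9
    record_spikes: bool = True
    record_positions: bool = True
    record_timing: bool = True

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ConfigError("dt_ms must be > 0")
        if self.biological_time_ms < self.dt_ms:
            raise ConfigError("biological_time_ms must be >= dt_ms")
        if self.n_workers < 1:
            raise ConfigError("n_workers must be >= 1")
        if self.seed == 0:
            raise ConfigError("seed must be nonzero (xorshift)")


def total_density(region: RegionSpec) -> float:
    """Total neuron density of the region, neurons per mm² of sheet."""
    return float(sum(t.density for t in region.neuron_types))


# ---------------------------------------------------------------------------
# JSON (de)serialization.  Documents are strict: unknown keys are rejected.
# ---------------------------------------------------------------------------

def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise MissingFieldError(f"{where}: missing required field {key!r}")
    return obj[key]

def _check_keys(obj: dict, allowed: set[str], where: str):
    extra = set(obj) - allowed
    if extra:
        raise UnknownKeyError(f"{where}: unknown key(s) {sorted(extra)}")


def region_to_dict(region: RegionSpec) -> dict:
    d = {
        "name": region.name,
        "structure": {
            "total_depth_um": region.total_depth_um,
            "layers": [asdict(ly) for ly in region.layers],
        },
        "neuron_properties": {
            "types": [asdict(t) for t in region.neuron_types],
            "model_params": asdict(region.model_params),
        },
        "connections": {
            "synapse_classes": [asdict(c) for c in region.synapse_classes],
            "kernels": [asdict(k) for k in region.kernels],
            "weight_rules": [asdict(r) for r in region.weight_rules],
            "mask": [list(p) for p in region.connectivity_mask],
            "delay_ms": region.delay_ms,
        },
    }
    return d


def region_from_dict(doc: dict, where: str = "region") -> RegionSpec:
    _check_keys(doc, {"name", "structure", "neuron_properties", "connections"}, where)
    structure = _require(doc, "structure", where)
    _check_keys(structure, {"total_depth_um", "layers"}, f"{where}.structure")
    props = _require(doc, "neuron_properties", where)
    _check_keys(props, {"types", "model_params"}, f"{where}.neuron_properties")
    conns = _require(doc, "connections", where)
    _check_keys(
        conns,
        {"synapse_classes", "kernels", "weight_rules", "mask", "delay_ms"},
        f"{where}.connections",
    )

    layer_keys = {"name", "thickness_um"}
    layers = []
    for i, ly in enumerate(_require(structure, "layers", f"{where}.structure")):
        _check_keys(ly, layer_keys, f"{where}.structure.layers[{i}]")
        layers.append(LayerSpec(name=str(_require(ly, "name", "layer")),
                                thickness_um=float(_require(ly, "thickness_um", "layer"))))

    type_keys = {"name", "layer", "ei_class", "density", "tau_m", "target_in_degree",
                 "bias_mean", "bias_sd", "weight_class", "reference_rate_hz"}
    types = []
    for i, t in enumerate(_require(props, "types", f"{where}.neuron_properties")):
        loc = f"{where}.neuron_properties.types[{i}]"
        _check_keys(t, type_keys, loc)
        types.append(NeuronTypeSpec(
            name=str(_require(t, "name", loc)),
            layer=str(_require(t, "layer", loc)),
            ei_class=str(_require(t, "ei_class", loc)),
            density=float(_require(t, "density", loc)),
            tau_m=float(_require(t, "tau_m", loc)),
            target_in_degree=float(_require(t, "target_in_degree", loc)),
            bias_mean=float(t.get("bias_mean", 0.0)),
            bias_sd=float(t.get("bias_sd", 0.0)),
            weight_class=str(t.get("weight_class", "")),
            reference_rate_hz=float(t.get("reference_rate_hz", 0.0)),
        ))

    mp = props.get("model_params", {})
    _check_keys(mp, {"u_rest", "theta", "u_reset", "r_m"}, f"{where}.model_params")
    model_params = NeuronModelParams(**{k: float(v) for k, v in mp.items()})

    cls_keys = {"name", "tau_syn", "e_rev"}
    classes = []
    for i, c in enumerate(_require(conns, "synapse_classes", f"{where}.connections")):
        _check_keys(c, cls_keys, f"{where}.connections.synapse_classes[{i}]")
        classes.append(SynapseClassSpec(
            name=str(_require(c, "name", "synapse class")),
            tau_syn=float(c.get("tau_syn", 2.0)),
            e_rev=float(c.get("e_rev", 0.0)),
        ))

    kern_keys = {"pre_type", "post_type", "peak", "sigma", "cutoff"}
    kernels = []
    for i, k in enumerate(_require(conns, "kernels", f"{where}.connections")):
        loc = f"{where}.connections.kernels[{i}]"
        _check_keys(k, kern_keys, loc)
        kernels.append(KernelSpec(
            pre_type=str(_require(k, "pre_type", loc)),
            post_type=str(_require(k, "post_type", loc)),
            peak=float(_require(k, "peak", loc)),
            sigma=float(_require(k, "sigma", loc)),
            cutoff=float(k.get("cutoff", DEFAULT_CUTOFF_UM)),
        ))

    rule_keys = {"pre_class", "post_class", "rule", "value", "mu_ln", "sigma_ln"}
    rules = []
    for i, r in enumerate(_require(conns, "weight_rules", f"{where}.connections")):
        loc = f"{where}.connections.weight_rules[{i}]"
        _check_keys(r, rule_keys, loc)
        rules.append(WeightRuleSpec(
            pre_class=str(_require(r, "pre_class", loc)),
            post_class=str(_require(r, "post_class", loc)),
            rule=str(r.get("rule", "constant")),
            value=float(r.get("value", 1.0)),
            mu_ln=float(r.get("mu_ln", -0.72)),
            sigma_ln=float(r.get("sigma_ln", 1.0)),
        ))

    mask = [(str(p[0]), str(p[1])) for p in _require(conns, "mask", f"{where}.connections")]

    return RegionSpec(
        name=str(_require(doc, "name", where)),
        layers=layers,
        neuron_types=types,
        synapse_classes=classes,
        kernels=kernels,
        weight_rules=rules,
        connectivity_mask=mask,
        delay_ms=float(conns.get("delay_ms", 1.0)),
        total_depth_um=float(structure.get("total_depth_um", DEFAULT_DEPTH_UM)),
        model_params=model_params,
    )


def load_region_config(path: str | Path) -> RegionSpec:
    """Read and fully validate a region JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return region_from_dict(doc, where=str(path))


def write_region_config(region: RegionSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(region_to_dict(region), fh, indent=1)
        fh.write("\n")


_SYSTEM_KEYS = {
    "simulation": {"biological_time_ms", "dt_ms", "seed"},
    "parallelization": {"n_workers", "memory_limit_bytes"},
    "recording": {"spikes", "positions", "timing"},
}


def system_to_dict(system: SystemSpec) -> dict:
    return {
        "simulation": {
            "biological_time_ms": system.biological_time_ms,
            "dt_ms": system.dt_ms,
            "seed": system.seed,
        },
        "parallelization": {
            "n_workers": system.n_workers,
            "memory_limit_bytes": system.memory_limit_bytes,
        },
        "recording": {
            "spikes": system.record_spikes,
            "positions": system.record_positions,
            "timing": system.record_timing,
        },
    }


def system_from_dict(doc: dict, where: str = "system") -> SystemSpec:
    _check_keys(doc, set(_SYSTEM_KEYS), where)
    for section, keys in _SYSTEM_KEYS.items():
        _check_keys(doc.get(section, {}), keys, f"{where}.{section}")
    sim = _require(doc, "simulation", where)
    par = doc.get("parallelization", {})
    rec = doc.get("recording", {})
    return SystemSpec(
        biological_time_ms=float(_require(sim, "biological_time_ms", f"{where}.simulation")),
        dt_ms=float(sim.get("dt_ms", 0.1)),
        seed=int(_require(sim, "seed", f"{where}.simulation")),
        n_workers=int(par.get("n_workers", 1)),
        memory_limit_bytes=int(par.get("memory_limit_bytes", 8 * 10**9)),
        record_spikes=bool(rec.get("spikes", True)),
        record_positions=bool(rec.get("positions", True)),
        record_timing=bool(rec.get("timing", True)),
    )


def load_system_config(path: str | Path) -> SystemSpec:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return system_from_dict(doc, where=str(path))


def write_system_config(system: SystemSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(system_to_dict(system), fh, indent=1)
        fh.write("\n")
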