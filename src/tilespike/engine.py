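"""Single-tile numerics: LIF membranes, alpha-conductance synapses, spikes.

Membrane potentials follow the leaky integrate-and-fire equation

    τ_m du/dt = -u + u_rest + R_m (I_syn + I_ext),    u ≥ θ ⇒ spike, u → u_reset,

integrated with forward Euler at a fixed step (0.1 ms by default).  The
synaptic current is conductance-based, I_syn = Σ_c g_c (E_c - u), summed
over synapse classes (excitatory E = 0 mV, inhibitory E = -70 mV); this is
the standard depolarizing-for-E>u sign convention.

Each (neuron, synapse class) carries an alpha-function conductance: the
two-state linear system

    z' = -z/τ_s + impulses,      g' = (z - g)/τ_s,

whose per-step propagator is the exact 2×2 matrix exponential
e^{-dt/τ_s} [[1, 0], [dt/τ_s, 1]] — the update is exact on the grid for
impulsive input, not an Euler approximation.  A spike of total weight w
raises z by w·e, normalized so a unit-weight spike peaks at g = 1 exactly
one τ_s after arrival: g(t) = w · (t/τ_s) e^{1 - t/τ_s}.

Spikes due in a step are applied at the start of that step; weights of
simultaneous arrivals sum before the impulse.  Deliveries are processed in
(presynaptic gid, spike tick) order so that tiled and monolithic runs
accumulate floating-point sums in the identical order.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .builder import TilePopulation
from .config import NeuronModelParams, RegionSpec, SystemSpec
from .store import ConnectionStore

__all__ = [
    "SchedulingError",
    "NumericalError",
    "alpha_propagator",
    "step_synapse",
    "synaptic_current",
    "step_membrane",
    "TileSimulator",
    "TileResult",
    "simulate_tile",
    "interval_of_tick",
]

_E = math.e  # impulse normalization: unit weight -> unit peak conductance


class SchedulingError(RuntimeError):
    """The inbox is missing an interval the schedule requires."""


class NumericalError(FloatingPointError):
    """A membrane potential became non-finite."""


def alpha_propagator(dt: float, tau_syn: float) -> tuple[float, float]:
    """(decay, drive) of the exact per-step update: g' = decay·(g + drive·z)."""
    a = dt / tau_syn
    return math.exp(-a), a


def step_synapse(z: np.ndarray, g: np.ndarray, dt: float, tau_syn: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Advance the alpha-conductance pair (z, g) by one step, exactly."""
    decay, a = alpha_propagator(dt, tau_syn)
    return decay * z, decay * (g + a * z)


def synaptic_current(g_by_class: np.ndarray, u: np.ndarray,
                     e_rev: np.ndarray) -> np.ndarray:
    """I_syn = Σ_c g_c (E_c - u); g_by_class has shape (n_classes, n)."""
    i_syn = np.zeros_like(u)
    for c in range(g_by_class.shape[0]):
        i_syn += g_by_class[c] * (e_rev[c] - u)
    return i_syn


def step_membrane(u: np.ndarray, bias: np.ndarray, i_syn: np.ndarray,
                  tau_m: np.ndarray, params: NeuronModelParams, dt: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """One forward-Euler membrane step; returns (u_next, spiked mask)."""
    u = u + (dt / tau_m) * (-u + params.u_rest + params.r_m * (i_syn + bias))
    spiked = u >= params.theta
    if spiked.any():
        u = np.where(spiked, params.u_reset, u)
    return u, spiked


def interval_of_tick(tick: int, interval_ticks: int) -> int:
    """Communication interval containing a spike tick.

    Spikes are stamped at the *end* of the step that produced them, so
    interval m owns ticks m·I+1 .. (m+1)·I.
    """
    return (tick - 1) // interval_ticks


@dataclass
class TileResult:
    """Spikes and bookkeeping from one tile's run."""

    spike_ticks: np.ndarray
    spike_gids: np.ndarray
    outbound: dict[int, list[tuple[int, int]]]  # interval -> [(gid, tick)]
    timing: dict[str, float] = field(default_factory=dict)


class TileSimulator:
    """Stepwise simulator for one tile's neurons and incoming synapses.

    Drives the membrane and conductance state of the tile's own neurons;
    the `ConnectionStore` holds every connection terminating here, keyed
    by presynaptic gid (which may belong to a neighboring tile).  Spikes
    from other tiles enter through `schedule_spike`.
    """

    def __init__(self, pop: TilePopulation, store: ConnectionStore,
                 region: RegionSpec, system: SystemSpec,
                 interval_ticks: int | None = None):
        self.pop = pop
        self.store = store
        self.region = region
        self.system = system
        self.dt = system.dt_ms
        self.n_steps = int(round(system.biological_time_ms / self.dt))
        self.interval_ticks = interval_ticks or self.n_steps
        self.params = region.model_params

        n = pop.n
        tau_by_type = np.array([t.tau_m for t in region.neuron_types])
        self.tau_m = tau_by_type[pop.type_index] if n else np.empty(0)
        self.u = np.full(n, self.params.u_rest, dtype=np.float64)
        self.bias = pop.bias.astype(np.float64)

        n_cls = len(region.synapse_classes)
        self.e_rev = np.array([c.e_rev for c in region.synapse_classes])
        self._decay = np.array([alpha_propagator(self.dt, c.tau_syn)[0]
                                for c in region.synapse_classes])
        self._drive = np.array([alpha_propagator(self.dt, c.tau_syn)[1]
                                for c in region.synapse_classes])
        self.z = np.zeros((n_cls, n))
        self.g = np.zeros((n_cls, n))

        # tick -> list of (pre_gid, spike_tick, post_idx, weights, syn_type)
        self._pending: dict[int, list] = {}
        self._spike_ticks: list[int] = []
        self._spike_gids: list[int] = []
        self.outbound: dict[int, list[tuple[int, int]]] = {}
        self.timing = {"synapse_s": 0.0, "neuron_s": 0.0, "comm_s": 0.0,
                       "total_s": 0.0}
        self._step = 0

    # -- spike scheduling ---------------------------------------------

    def schedule_spike(self, pre_gid: int, spike_tick: int) -> None:
        """Register one presynaptic spike; its records fan out by delay."""
        post, w, delay, syn = self.store.targets_of(pre_gid)
        if len(post) == 0:
            return
        idx = post.astype(np.int64) - self.pop.gid_start
        for d in np.unique(delay):
            due = int(spike_tick + d)
            sel = delay == d
            self._pending.setdefault(due, []).append(
                (int(pre_gid), int(spike_tick), idx[sel], w[sel], syn[sel]))

    # -- stepping ------------------------------------------------------

    def _apply_due(self, tick: int) -> None:
        entries = self._pending.pop(tick, None)
        if not entries:
            return
        entries.sort(key=lambda e: (e[0], e[1]))
        for _pre, _tk, idx, w, syn in entries:
            for c in np.unique(syn):
                sel = syn == c
                np.add.at(self.z[int(c)], idx[sel],
                          w[sel].astype(np.float64) * _E)

    def step(self) -> np.ndarray:
        """Advance one dt; returns the local indices that spiked."""
        k = self._step
        t0 = time.perf_counter()
        self._apply_due(k)
        i_syn = synaptic_current(self.g, self.u, self.e_rev)
        # exact propagation of (z, g) from tick k to k+1
        for c in range(len(self._decay)):
            self.g[c] = self._decay[c] * (self.g[c] + self._drive[c] * self.z[c])
            self.z[c] *= self._decay[c]
        t1 = time.perf_counter()
        self.u, spiked = step_membrane(self.u, self.bias, i_syn, self.tau_m,
                                       self.params, self.dt)
        if not np.all(np.isfinite(self.u)):
            bad = int(self.pop.gid_start + np.flatnonzero(~np.isfinite(self.u))[0])
            raise NumericalError(f"membrane potential diverged at gid {bad}")
        t2 = time.perf_counter()
        self._step = k + 1
        idx = np.flatnonzero(spiked)
        if idx.size:
            tick = k + 1
            m = interval_of_tick(tick, self.interval_ticks)
            out = self.outbound.setdefault(m, [])
            for li in idx:
                gid = int(self.pop.gid_start + li)
                self._spike_ticks.append(tick)
                self._spike_gids.append(gid)
                out.append((gid, tick))
                self.schedule_spike(gid, tick)
        self.timing["synapse_s"] += t1 - t0
        self.timing["neuron_s"] += t2 - t1
        return idx

    def run_interval(self, m: int) -> list[tuple[int, int]]:
        """Run all steps of communication interval ``m``; returns its spikes."""
        first = m * self.interval_ticks
        last = min((m + 1) * self.interval_ticks, self.n_steps)
        for _ in range(first, last):
            self.step()
        return self.outbound.get(m, [])

    def result(self) -> TileResult:
        self.timing["total_s"] = (self.timing["synapse_s"]
                                  + self.timing["neuron_s"]
                                  + self.timing["comm_s"])
        return TileResult(
            spike_ticks=np.asarray(self._spike_ticks, dtype=np.int64),
            spike_gids=np.asarray(self._spike_gids, dtype=np.int64),
            outbound=self.outbound,
            timing=dict(self.timing),
        )


def simulate_tile(pop: TilePopulation, store: ConnectionStore,
                  region: RegionSpec, system: SystemSpec,
                  inbox: dict[int, list[tuple[int, int]]] | None = None,
                  interval_ticks: int | None = None) -> TileResult:
    """Simulate one tile for the full biological time.

    ``inbox`` maps a communication-interval index to the remote spikes
    generated in that interval (``(pre_gid, tick)`` pairs); interval-m
    spikes are injected before interval m+2 is computed, matching the
    half-minimum-delay exchange schedule.  ``inbox=None`` means the tile
    is isolated.  A missing interval raises `SchedulingError`.
    """
    sim = TileSimulator(pop, store, region, system, interval_ticks)
    n_intervals = -(-sim.n_steps // sim.interval_ticks)
    t0 = time.perf_counter()
    for m in range(n_intervals):
        if inbox is not None and m >= 2:
            src = m - 2
            if src not in inbox:
                raise SchedulingError(f"inbox missing interval {src}")
            for gid, tick in inbox[src]:
                sim.schedule_spike(gid, tick)
        sim.run_interval(m)
    res = sim.result()
    res.timing["total_s"] = time.perf_counter() - t0
    return res
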