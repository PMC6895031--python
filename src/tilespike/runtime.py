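"""Tile partitioning runtime: grid geometry, spike exchange, run modes.

The sheet is cut into a regular grid of square tiles (half-open
footprints, so tiles partition the sheet exactly).  Each tile holds its
neurons and every connection terminating on them; two tiles are
*neighbors* — and exchange spike messages — iff the distance between
their footprints is strictly below the connection cutoff.

Spikes are exchanged at an interval of half the minimum transmission
delay: spikes generated in communication interval m are delivered to
postsynaptic conductance computation in interval m+2, which is what lets
a worker overlap interval m+1's computation with the transfer.  Because
every connection delay is at least the minimum delay (= two intervals),
the two-interval message latency never violates causality; a model whose
delays undercut the configured minimum is rejected at load time.

Three run modes produce byte-identical spike trains on the same built
sheet: ``serial`` (tiles round-robin in one process, same message
schedule), ``parallel`` (one worker process per tile, queues between
neighbors only), and ``monolithic`` (the union of all tiles stepped as
one population, no exchange) — the partition-correctness oracle.
"""

from __future__ import annotations

import hashlib
import json
import math
import multiprocessing as mp
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .builder import (
    ConnectionBatch,
    ConnectivityPlan,
    TilePopulation,
    calibrate_peaks,
    expected_counts,
    generate_connections,
    place_neurons,
)
from .config import RegionSpec, SystemSpec, region_to_dict, system_to_dict
from .engine import TileResult, TileSimulator
from .rng import Xorshift32
from .store import ConnectionStore, build_store, read_tile_file, write_tile_file

__all__ = [
    "ConfigurationError",
    "ScheduleViolationError",
    "TileGrid",
    "plan_grid",
    "grid_expected_totals",
    "neighbor_tiles",
    "comm_interval",
    "BuiltSheet",
    "build_sheet",
    "load_sheet",
    "RunResult",
    "run",
    "timing_log",
    "write_timing_log",
    "read_timing_log",
    "write_spikes_tsv",
    "write_positions_csv",
]

# substream purposes
_PLACE, _CONN, _WEIGHT = 1, 2, 3


class ConfigurationError(ValueError):
    """A schedule or grid setting is inconsistent (e.g. off the dt grid)."""


class ScheduleViolationError(ValueError):
    """A connection's delay is shorter than the configured minimum delay."""


@dataclass(frozen=True)
class TileGrid:
    """An nx × ny grid of square tiles of side ``tile_len_um``.

    Tile ids are row-major: ``tile_id = iy * nx + ix``; footprints are the
    half-open squares [ix·L, (ix+1)·L) × [iy·L, (iy+1)·L).
    """

    nx: int
    ny: int
    tile_len_um: float

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ConfigurationError("grid needs nx, ny >= 1")
        if self.tile_len_um <= 0:
            raise ConfigurationError("tile_len_um must be > 0")

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny

    @property
    def area_mm2(self) -> float:
        return self.n_tiles * (self.tile_len_um / 1000.0) ** 2

    @property
    def area_cm2(self) -> float:
        return self.area_mm2 / 100.0

    def coords(self, tile_id: int) -> tuple[int, int]:
        if not 0 <= tile_id < self.n_tiles:
            raise LookupError(f"unknown tile id {tile_id}")
        return tile_id % self.nx, tile_id // self.nx

    def tile_id(self, ix: int, iy: int) -> int:
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise LookupError(f"tile coords ({ix}, {iy}) outside grid")
        return iy * self.nx + ix

    def footprint(self, tile_id: int) -> tuple[float, float]:
        ix, iy = self.coords(tile_id)
        return ix * self.tile_len_um, iy * self.tile_len_um


def plan_grid(nx: int, ny: int, tile_len_um: float) -> TileGrid:
    """Construct a grid with exact area bookkeeping."""
    return TileGrid(nx=nx, ny=ny, tile_len_um=tile_len_um)


def grid_expected_totals(grid: TileGrid, region: RegionSpec) -> dict[str, float]:
    """Expected whole-sheet census for a grid of a given region."""
    counts = expected_counts(region, grid.tile_len_um)
    return {
        "n_tiles": grid.n_tiles,
        "area_mm2": grid.area_mm2,
        "area_cm2": grid.area_cm2,
        "neurons": counts.neurons_per_tile * grid.n_tiles,
        "connections": counts.connections_per_tile * grid.n_tiles,
        "bytes": counts.bytes_per_tile * grid.n_tiles,
    }


def neighbor_tiles(grid: TileGrid, tile_id: int, cutoff_um: float) -> list[int]:
    """Tiles whose footprint lies within the cutoff of the given tile's.

    The footprint-to-footprint distance must be *strictly* below the
    cutoff: tiles whose closest approach equals the cutoff exactly carry
    zero connection probability mass (footprints are half-open sets).
    For an interior tile this yields (2⌈cutoff/L⌉+1)² − 1 neighbors.
    """
    if cutoff_um < 0:
        raise ValueError("cutoff_um must be >= 0")
    ix, iy = grid.coords(tile_id)
    if cutoff_um == 0:
        return []
    L = grid.tile_len_um
    reach = math.ceil(cutoff_um / L)
    out = []
    for dy in range(-reach, reach + 1):
        for dx in range(-reach, reach + 1):
            if dx == 0 and dy == 0:
                continue
            jx, jy = ix + dx, iy + dy
            if not (0 <= jx < grid.nx and 0 <= jy < grid.ny):
                continue
            gap_x = max(0, abs(dx) - 1) * L
            gap_y = max(0, abs(dy) - 1) * L
            if math.hypot(gap_x, gap_y) < cutoff_um:
                out.append(grid.tile_id(jx, jy))
    return sorted(out)


def comm_interval(min_delay_ms: float, dt_ms: float = 0.1) -> float:
    """Spike-exchange interval: half the minimum transmission delay.

    The minimum delay must be a positive, *even* number of dt steps so
    the interval lands on the integration grid.
    """
    if min_delay_ms <= 0:
        raise ConfigurationError("min_delay must be > 0")
    ticks = min_delay_ms / dt_ms
    if abs(ticks - round(ticks)) > 1e-9:
        raise ConfigurationError(
            f"min_delay {min_delay_ms} ms is not an integer number of "
            f"dt={dt_ms} ms steps")
    ticks = int(round(ticks))
    if ticks % 2:
        raise ConfigurationError(
            f"min_delay of {ticks} steps is odd; the half-delay exchange "
            f"interval would fall off the dt grid")
    return min_delay_ms / 2.0


# ---------------------------------------------------------------------------
# Building a sheet
# ---------------------------------------------------------------------------

@dataclass
class BuiltSheet:
    """A fully constructed sheet: populations and stores for every tile."""

    grid: TileGrid
    region: RegionSpec
    system: SystemSpec
    plan: ConnectivityPlan
    pops: list[TilePopulation]
    stores: list[ConnectionStore]
    density_scale: float = 1.0
    config_digest: str = ""

    @property
    def n_neurons(self) -> int:
        return sum(p.n for p in self.pops)

    @property
    def n_records(self) -> int:
        return sum(s.n_records for s in self.stores)

    def neighbor_map(self) -> dict[int, list[int]]:
        cut = self.plan.max_cutoff_um
        return {t: neighbor_tiles(self.grid, t, cut)
                for t in range(self.grid.n_tiles)}


def _sheet_digest(region: RegionSpec, system: SystemSpec, grid: TileGrid,
                  density_scale: float, count_mode: str) -> str:
    doc = {
        "region": region_to_dict(region),
        "system": system_to_dict(system),
        "grid": [grid.nx, grid.ny, grid.tile_len_um],
        "density_scale": density_scale,
        "count_mode": count_mode,
    }
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode("utf-8")).hexdigest()


def build_sheet(region: RegionSpec, system: SystemSpec, grid: TileGrid,
                density_scale: float = 1.0, count_mode: str = "poisson",
                out_dir: str | Path | None = None) -> BuiltSheet:
    """Place every tile's neurons and draw every connection.

    Deterministic in ``system.seed``: placement, connectivity and weight
    draws each use a substream keyed by (seed, purpose, tile id), and
    global ids run row-major over tiles then insertion order within a
    tile — so any run mode consuming the result sees the same network.

    With ``out_dir`` set, one binary tile file per tile plus a JSON
    manifest are written (the intermediate-file workflow).
    """
    plan = calibrate_peaks(region)
    digest = _sheet_digest(region, system, grid, density_scale, count_mode)
    seed = system.seed

    pops: list[TilePopulation] = []
    gid_start = 0
    for tid in range(grid.n_tiles):
        x0, y0 = grid.footprint(tid)
        rng = Xorshift32.substream(seed, _PLACE, tid)
        pop = place_neurons(tid, x0, y0, grid.tile_len_um, region, rng,
                            gid_start=gid_start, density_scale=density_scale,
                            count_mode=count_mode)
        pops.append(pop)
        gid_start += pop.n

    nmap = {t: neighbor_tiles(grid, t, plan.max_cutoff_um)
            for t in range(grid.n_tiles)}
    stores: list[ConnectionStore] = []
    for tid in range(grid.n_tiles):
        pres = [pops[j] for j in sorted([tid] + nmap[tid])]
        rng = Xorshift32.substream(seed, _CONN, tid)
        wrng = Xorshift32.substream(seed, _WEIGHT, tid)
        batch = generate_connections(pres, pops[tid], plan, rng, wrng,
                                     dt_ms=system.dt_ms)
        stores.append(build_store(batch))

    sheet = BuiltSheet(grid=grid, region=region, system=system, plan=plan,
                       pops=pops, stores=stores, density_scale=density_scale,
                       config_digest=digest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for tid in range(grid.n_tiles):
            write_tile_file(stores[tid], pops[tid], digest,
                            out / f"tile_{tid:05d}.bin")
        manifest = {
            "grid": [grid.nx, grid.ny, grid.tile_len_um],
            "region": region_to_dict(region),
            "system": system_to_dict(system),
            "density_scale": density_scale,
            "count_mode": count_mode,
            "config_digest": digest,
            "n_neurons": sheet.n_neurons,
            "n_records": sheet.n_records,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
    return sheet


def load_sheet(in_dir: str | Path) -> BuiltSheet:
    """Reload a built sheet from its tile files and manifest."""
    from .config import region_from_dict, system_from_dict

    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    region = region_from_dict(manifest["region"])
    system = system_from_dict(manifest["system"])
    nx, ny, L = manifest["grid"]
    grid = plan_grid(int(nx), int(ny), float(L))
    pops, stores = [], []
    for tid in range(grid.n_tiles):
        path = in_dir / f"tile_{tid:05d}.bin"
        if not path.exists():
            raise FileNotFoundError(f"missing tile file {path}")
        store, pop, digest = read_tile_file(path)
        if digest != manifest["config_digest"]:
            raise ValueError(f"{path}: config digest does not match manifest")
        pops.append(pop)
        stores.append(store)
    return BuiltSheet(grid=grid, region=region, system=system,
                      plan=calibrate_peaks(region), pops=pops, stores=stores,
                      density_scale=float(manifest["density_scale"]),
                      config_digest=manifest["config_digest"])


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Spike output of a run, identical across modes for the same sheet."""

    spikes: np.ndarray  # shape (n, 2): [tick, gid], sorted by (tick, gid)
    dt_ms: float
    mode: str
    timing: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)

    def spike_times_ms(self) -> np.ndarray:
        return self.spikes[:, 0] * self.dt_ms


def _interval_ticks(sheet: BuiltSheet) -> int:
    dt = sheet.system.dt_ms
    half_ms = comm_interval(sheet.region.min_delay_ms(), dt)
    return int(round(half_ms / dt))


def _check_delays(sheet: BuiltSheet, min_delay_ticks: int) -> None:
    for tid, store in enumerate(sheet.stores):
        lo = store.min_delay_ticks()
        if lo is not None and lo < min_delay_ticks:
            raise ScheduleViolationError(
                f"tile {tid}: connection delay {lo} ticks < minimum delay "
                f"{min_delay_ticks} ticks")


def _sorted_spikes(ticks: np.ndarray, gids: np.ndarray) -> np.ndarray:
    order = np.lexsort((gids, ticks))
    return np.column_stack([ticks[order], gids[order]]).astype(np.int64)


def _merge_populations(sheet: BuiltSheet) -> TilePopulation:
    pops = sheet.pops
    return TilePopulation(
        tile_id=-1, x0=0.0, y0=0.0,
        tile_len=sheet.grid.nx * sheet.grid.tile_len_um,
        gid_start=0,
        type_index=np.concatenate([p.type_index for p in pops]),
        x=np.concatenate([p.x for p in pops]),
        y=np.concatenate([p.y for p in pops]),
        z=np.concatenate([p.z for p in pops]),
        bias=np.concatenate([p.bias for p in pops]),
    )


def _merge_stores(sheet: BuiltSheet) -> ConnectionStore:
    batches = []
    for s in sheet.stores:
        counts = np.diff(s._offsets)
        batches.append(ConnectionBatch(
            pre_gid=np.repeat(s.pre_gids, counts).astype(np.int64),
            post_gid=s.post_gid.astype(np.int64),
            weight=s.weight, delay_ticks=s.delay, syn_type=s.syn_type,
        ))
    merged = ConnectionBatch(
        pre_gid=np.concatenate([b.pre_gid for b in batches]),
        post_gid=np.concatenate([b.post_gid for b in batches]),
        weight=np.concatenate([b.weight for b in batches]),
        delay_ticks=np.concatenate([b.delay_ticks for b in batches]),
        syn_type=np.concatenate([b.syn_type for b in batches]),
    ) if batches else ConnectionBatch.empty()
    return build_store(merged)


def _run_monolithic(sheet: BuiltSheet) -> RunResult:
    from .engine import simulate_tile

    pop = _merge_populations(sheet)
    store = _merge_stores(sheet)
    res = simulate_tile(pop, store, sheet.region, sheet.system, inbox=None,
                        interval_ticks=_interval_ticks(sheet))
    return RunResult(
        spikes=_sorted_spikes(res.spike_ticks, res.spike_gids),
        dt_ms=sheet.system.dt_ms, mode="monolithic",
        timing={"tiles": {"-1": res.timing}},
    )


def _run_serial(sheet: BuiltSheet) -> RunResult:
    interval_ticks = _interval_ticks(sheet)
    nmap = sheet.neighbor_map()
    sims = [TileSimulator(sheet.pops[t], sheet.stores[t], sheet.region,
                          sheet.system, interval_ticks)
            for t in range(sheet.grid.n_tiles)]
    n_steps = int(round(sheet.system.biological_time_ms / sheet.system.dt_ms))
    n_intervals = -(-n_steps // interval_ticks)
    history: dict[int, dict[int, list]] = {}
    for m in range(n_intervals):
        if m >= 2:
            src = m - 2
            for t, sim in enumerate(sims):
                t0 = time.perf_counter()
                for nb in nmap[t]:
                    for gid, tick in history[src].get(nb, []):
                        sim.schedule_spike(gid, tick)
                sim.timing["comm_s"] += time.perf_counter() - t0
        history[m] = {}
        for t, sim in enumerate(sims):
            history[m][t] = sim.run_interval(m)
        history.pop(m - 3, None)
    ticks = np.concatenate([np.asarray(s._spike_ticks, dtype=np.int64)
                            for s in sims]) if sims else np.empty(0, np.int64)
    gids = np.concatenate([np.asarray(s._spike_gids, dtype=np.int64)
                           for s in sims]) if sims else np.empty(0, np.int64)
    timing = {"tiles": {str(t): s.result().timing for t, s in enumerate(sims)}}
    return RunResult(spikes=_sorted_spikes(ticks, gids),
                     dt_ms=sheet.system.dt_ms, mode="serial", timing=timing)


def _parallel_worker(tid, pop, store, region, system, interval_ticks,
                     neighbors, inq, outqs, result_q):
    sim = TileSimulator(pop, store, region, system, interval_ticks)
    n_steps = int(round(system.biological_time_ms / system.dt_ms))
    n_intervals = -(-n_steps // interval_ticks)
    buffered: dict[tuple[int, int], list] = {}
    neighbor_set = set(neighbors)
    for m in range(n_intervals):
        if m >= 2 and neighbors:
            src_iv = m - 2
            t0 = time.perf_counter()
            while any((nb, src_iv) not in buffered for nb in neighbors):
                src, iv, spikes = inq.get()
                if src not in neighbor_set:
                    raise RuntimeError(
                        f"tile {tid} got message from non-neighbor {src}")
                buffered[(src, iv)] = spikes
            for nb in sorted(neighbors):
                for gid, tick in buffered.pop((nb, src_iv)):
                    sim.schedule_spike(gid, tick)
            sim.timing["comm_s"] += time.perf_counter() - t0
        spikes = sim.run_interval(m)
        t0 = time.perf_counter()
        for nb in neighbors:
            outqs[nb].put((tid, m, spikes))
        sim.timing["comm_s"] += time.perf_counter() - t0
    res = sim.result()
    result_q.put((tid, res.spike_ticks, res.spike_gids, res.timing))
    # drain leftovers so sender feeder threads can flush and exit
    try:
        while True:
            inq.get_nowait()
    except Exception:
        pass


def _run_parallel(sheet: BuiltSheet) -> RunResult:
    interval_ticks = _interval_ticks(sheet)
    nmap = sheet.neighbor_map()
    n_tiles = sheet.grid.n_tiles
    ctx = mp.get_context("fork")
    inqs = {t: ctx.Queue() for t in range(n_tiles)}
    result_q = ctx.Queue()
    procs = []
    for t in range(n_tiles):
        outqs = {nb: inqs[nb] for nb in nmap[t]}  # neighbor queues only
        p = ctx.Process(
            target=_parallel_worker,
            args=(t, sheet.pops[t], sheet.stores[t], sheet.region,
                  sheet.system, interval_ticks, nmap[t], inqs[t], outqs,
                  result_q),
        )
        p.daemon = True
        p.start()
        procs.append(p)
    results = {}
    for _ in range(n_tiles):
        tid, ticks, gids, timing = result_q.get()
        results[tid] = (ticks, gids, timing)
    for p in procs:
        p.join(timeout=60)
    ticks = np.concatenate([results[t][0] for t in range(n_tiles)]) \
        if n_tiles else np.empty(0, np.int64)
    gids = np.concatenate([results[t][1] for t in range(n_tiles)]) \
        if n_tiles else np.empty(0, np.int64)
    timing = {"tiles": {str(t): results[t][2] for t in range(n_tiles)}}
    return RunResult(spikes=_sorted_spikes(ticks.astype(np.int64),
                                           gids.astype(np.int64)),
                     dt_ms=sheet.system.dt_ms, mode="parallel", timing=timing)


def run(sheet: BuiltSheet, mode: str = "serial") -> RunResult:
    """Simulate a built sheet.  ``mode`` is serial | parallel | monolithic."""
    min_delay_ticks = int(round(sheet.region.min_delay_ms()
                                / sheet.system.dt_ms))
    _check_delays(sheet, min_delay_ticks)
    _interval_ticks(sheet)  # validates schedule alignment
    t0 = time.perf_counter()
    if mode == "serial":
        res = _run_serial(sheet)
    elif mode == "parallel":
        res = _run_parallel(sheet)
    elif mode == "monolithic":
        res = _run_monolithic(sheet)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res.timing["wall_s"] = time.perf_counter() - t0
    res.timing["aggregate"] = timing_log(res)["aggregate"]
    return res


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

def timing_log(result: RunResult) -> dict:
    """Per-tile and aggregate elapsed times per phase."""
    tiles = result.timing.get("tiles", {})
    agg = {"synapse_s": 0.0, "neuron_s": 0.0, "comm_s": 0.0, "total_s": 0.0}
    for t in tiles.values():
        for k in agg:
            agg[k] += t.get(k, 0.0)
    return {"mode": result.mode, "tiles": tiles, "aggregate": agg,
            "wall_s": result.timing.get("wall_s", 0.0)}


def write_timing_log(result: RunResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(timing_log(result), fh, indent=1)


def read_timing_log(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_spikes_tsv(result: RunResult, path: str | Path) -> None:
    """Spike raster: one "time_ms<TAB>gid" line per spike, (time, gid) sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for tick, gid in result.spikes:
            fh.write(f"{tick * result.dt_ms:.3f}\t{gid}\n")


def write_positions_csv(sheet: BuiltSheet, path: str | Path) -> None:
    """Neuron positions: gid,type,layer,x_um,y_um,z_um."""
    types = sheet.region.neuron_types
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gid,type,layer,x_um,y_um,z_um\n")
        for pop in sheet.pops:
            gids = pop.gids
            for i in range(pop.n):
                t = types[pop.type_index[i]]
                fh.write(f"{gids[i]},{t.name},{t.layer},"
                         f"{pop.x[i]:.3f},{pop.y[i]:.3f},{pop.z[i]:.3f}\n")
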