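"""Partitioning analytics: locality, shared input, communication, memory.

How good a tile partition is at keeping traffic off the network is a pure
function of connection geometry: the fraction of connections whose
presynaptic partner already lives in the postsynaptic tile, the number of
postsynaptic neurons that share one incoming remote spike, the number of
tiles a tile must talk to, and the bytes of connection storage per tile.

Because the Gaussian kernels factor out of the neuron density, the
intra-tile fraction depends only on kernel geometry and tile size — it is
density invariant — so it is estimated by Monte-Carlo integration over
positions (postsynaptic point uniform in the tile, presynaptic
displacement drawn from the cutoff-truncated Gaussian), not by building a
full-density sheet.  Shared-input multiplicity is measured on sheets
built at a reduced density and rescaled analytically: the expected number
of inter-tile connections scales with the density factor squared, while
the pool of contributing presynaptic neurons is integrated at full
density from the per-position Poisson non-emptiness probability
1 - exp(-λ(x)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .builder import (
    ConnectivityPlan,
    ExpectedCounts,
    RECORD_BYTES,
    expected_counts,
    generate_connections,
    place_neurons,
)
from .config import RegionSpec
from .rng import Xorshift32
from .runtime import neighbor_tiles, plan_grid

__all__ = [
    "PartitionStats",
    "intra_tile_fraction",
    "realized_intra_tile_fraction",
    "MultiplicityEstimate",
    "shared_input_multiplicity",
    "sweep_tile_sizes",
    "memory_per_tile",
    "plot_partition_curves",
]

# substream purposes (disjoint from the runtime's)
_FRACTION, _BUILD, _CONTRIB = 11, 12, 13


@dataclass(frozen=True)
class PartitionStats:
    """One row of the tile-size sweep."""

    tile_len_um: float
    intra_tile_fraction: float
    fraction_se: float
    mean_shared_multiplicity: float
    n_comm_partners: int
    neurons_per_tile: float
    connections_per_tile: float
    bytes_per_tile: float


def _truncated_gaussian_displacements(sigma: float, cutoff: float, n: int,
                                      rng: Xorshift32):
    """Radial displacements from the 2-D Gaussian truncated at the cutoff."""
    u = rng.uniforms(n)
    c = 1.0 - math.exp(-cutoff**2 / (2.0 * sigma**2))
    r = sigma * np.sqrt(-2.0 * np.log1p(-u * c))
    theta = 2.0 * math.pi * rng.uniforms(n)
    return r * np.cos(theta), r * np.sin(theta)


def _kernel_groups(plan: ConnectivityPlan):
    """Group allowed pairs by (σ, cutoff); weight = expected connection mass."""
    region = plan.region
    groups: dict[tuple[float, float], float] = {}
    for (pre, post), k in plan.kernels.items():
        d_pre = region.type_by_name(pre).density
        d_post = region.type_by_name(post).density
        mass = (2.0 * math.pi * (k.sigma / 1000.0) ** 2
                * (1.0 - math.exp(-k.cutoff**2 / (2.0 * k.sigma**2))))
        groups[(k.sigma, k.cutoff)] = groups.get((k.sigma, k.cutoff), 0.0) \
            + d_pre * d_post * k.peak * mass
    return groups


def intra_tile_fraction(plan: ConnectivityPlan, region: RegionSpec,
                        tile_len_um: float, n_samples: int,
                        rng: Xorshift32) -> tuple[float, float]:
    """Expected fraction of a tile's connections that are tile-internal.

    Monte-Carlo estimate ± standard error for an interior tile with a
    full neighborhood.  Density-invariant: postsynaptic positions are
    sampled uniformly in the tile and presynaptic partners from the
    connection-probability kernel itself, so neuron counts cancel.
    """
    if n_samples < 10**3:
        raise ValueError("n_samples must be >= 1000")
    if tile_len_um <= 0:
        return 0.0, 0.0
    groups = _kernel_groups(plan)
    total_w = sum(groups.values())
    if total_w <= 0:
        return 0.0, 0.0
    est = 0.0
    var = 0.0
    for (sigma, cutoff), w in sorted(groups.items()):
        px = rng.uniforms(n_samples) * tile_len_um
        py = rng.uniforms(n_samples) * tile_len_um
        dx, dy = _truncated_gaussian_displacements(sigma, cutoff, n_samples, rng)
        qx, qy = px + dx, py + dy
        inside = ((0 <= qx) & (qx < tile_len_um)
                  & (0 <= qy) & (qy < tile_len_um))
        f = float(inside.mean())
        est += (w / total_w) * f
        var += (w / total_w) ** 2 * f * (1.0 - f) / n_samples
    return est, math.sqrt(var)


def _build_neighborhood(plan: ConnectivityPlan, region: RegionSpec,
                        tile_len_um: float, density_scale: float,
                        seed: int, dt_ms: float = 0.1):
    """Center tile plus every tile within the cutoff, built at reduced density.

    Returns (center population, ring populations, connection batch into the
    center tile).
    """
    cutoff = plan.max_cutoff_um
    reach = max(1, math.ceil(cutoff / tile_len_um)) if cutoff > 0 else 0
    side = 2 * reach + 1
    grid = plan_grid(side, side, tile_len_um)
    center = grid.tile_id(reach, reach)
    ring_ids = neighbor_tiles(grid, center, cutoff)
    pops = {}
    gid_start = 0
    for tid in sorted(ring_ids + [center]):
        x0, y0 = grid.footprint(tid)
        rng = Xorshift32.substream(seed, _BUILD, tid)
        pop = place_neurons(tid, x0, y0, tile_len_um, region, rng,
                            gid_start=gid_start, density_scale=density_scale)
        pops[tid] = pop
        gid_start += pop.n
    center_pop = pops[center]
    ring_pops = [pops[t] for t in ring_ids]
    batch = generate_connections(
        list(pops.values()), center_pop, plan,
        Xorshift32.substream(seed, _BUILD, 10_000),
        Xorshift32.substream(seed, _BUILD, 10_001), dt_ms=dt_ms)
    return center_pop, ring_pops, batch


def realized_intra_tile_fraction(plan: ConnectivityPlan, region: RegionSpec,
                                 tile_len_um: float, density_scale: float,
                                 seed: int) -> tuple[float, float, int]:
    """Intra-tile fraction measured on an actually built neighborhood.

    Returns (fraction, binomial SE, number of connections).  Used to
    check density invariance against the position-sampling estimate.
    """
    center, _ring, batch = _build_neighborhood(plan, region, tile_len_um,
                                               density_scale, seed)
    n = batch.n
    if n == 0:
        return float("nan"), float("nan"), 0
    lo = center.gid_start
    hi = lo + center.n
    inside = (batch.pre_gid >= lo) & (batch.pre_gid < hi)
    f = float(inside.mean())
    return f, math.sqrt(f * (1.0 - f) / n), n


@dataclass(frozen=True)
class MultiplicityEstimate:
    """Shared-input multiplicity of one tile size, raw and rescaled."""

    raw_mean: float  # mean targets per contributing remote presynaptic neuron
    raw_se: float
    n_contributing: int  # remote pres with >=1 target (at the build density)
    inter_connections: int  # realized inter-tile connections (build density)
    density_scale: float
    rescaled_mean: float  # estimate at full density
    n_contributing_full: float  # full-density contributing-pre pool (MC)


def shared_input_multiplicity(plan: ConnectivityPlan, region: RegionSpec,
                              tile_len_um: float, density_scale: float,
                              seed: int, n_position_samples: int = 2000,
                              n_landing_samples: int = 128
                              ) -> MultiplicityEstimate:
    """Average number of center-tile targets per remote presynaptic neuron.

    Built at ``density_scale``; contributing neurons are those in the
    neighbor tiles with at least one target in the center tile.  The
    full-density rescaling divides the scaled-up inter-tile connection
    count (∝ scale²) by the full-density contributing pool, integrated by
    Monte Carlo from the per-position Poisson non-emptiness probability.
    """
    center, ring_pops, batch = _build_neighborhood(plan, region, tile_len_um,
                                                   density_scale, seed)
    lo, hi = center.gid_start, center.gid_start + center.n
    remote = (batch.pre_gid < lo) | (batch.pre_gid >= hi)
    remote_pre = batch.pre_gid[remote]
    n_inter = int(remote.sum()) if batch.n else 0
    if n_inter == 0:
        return MultiplicityEstimate(float("nan"), float("nan"), 0, 0,
                                    density_scale, float("nan"), 0.0)
    pres, counts = np.unique(remote_pre, return_counts=True)
    raw_mean = float(counts.mean())
    raw_se = float(counts.std(ddof=1) / math.sqrt(len(counts))) \
        if len(counts) > 1 else float("nan")

    # full-density contributing pool: A_ring * E_x[ Σ_T density_T (1-e^{-λ_T(x)}) ]
    rng = Xorshift32.substream(seed, _CONTRIB, 0)
    region_types = region.neuron_types
    tidx = {t.name: i for i, t in enumerate(region_types)}
    # per (pre type, σ, cutoff): Σ_post density_post * peak * mass
    per_pre: dict[int, dict[tuple[float, float], float]] = {}
    for (pre, post), k in plan.kernels.items():
        mass = (2.0 * math.pi * (k.sigma / 1000.0) ** 2
                * (1.0 - math.exp(-k.cutoff**2 / (2.0 * k.sigma**2))))
        lam = region.type_by_name(post).density * k.peak * mass
        per_pre.setdefault(tidx[pre], {})
        key = (k.sigma, k.cutoff)
        per_pre[tidx[pre]][key] = per_pre[tidx[pre]].get(key, 0.0) + lam

    ring_area_mm2 = len(ring_pops) * (tile_len_um / 1000.0) ** 2
    n_ring = len(ring_pops)
    # sample positions uniformly over the union of ring tiles
    tile_pick = (rng.uniforms(n_position_samples) * n_ring).astype(int)
    tile_pick = np.minimum(tile_pick, n_ring - 1)
    xs = np.empty(n_position_samples)
    ys = np.empty(n_position_samples)
    ux = rng.uniforms(n_position_samples)
    uy = rng.uniforms(n_position_samples)
    for i, t in enumerate(tile_pick):
        pop = ring_pops[t]
        xs[i] = pop.x0 + ux[i] * tile_len_um
        ys[i] = pop.y0 + uy[i] * tile_len_um
    cx0, cy0 = center.x0, center.y0

    sigma_keys = sorted({key for d in per_pre.values() for key in d})
    landing = {}
    for key in sigma_keys:
        sigma, cutoff = key
        dx, dy = _truncated_gaussian_displacements(
            sigma, cutoff, n_position_samples * n_landing_samples, rng)
        dx = dx.reshape(n_position_samples, n_landing_samples)
        dy = dy.reshape(n_position_samples, n_landing_samples)
        tx = xs[:, None] + dx
        ty = ys[:, None] + dy
        inside = ((cx0 <= tx) & (tx < cx0 + tile_len_um)
                  & (cy0 <= ty) & (ty < cy0 + tile_len_um))
        landing[key] = inside.mean(axis=1)  # P(land in center | position)

    contrib_density = np.zeros(n_position_samples)
    for ti, lam_by_key in per_pre.items():
        lam = np.zeros(n_position_samples)
        for key, l0 in lam_by_key.items():
            lam += l0 * landing[key]
        contrib_density += region_types[ti].density * (1.0 - np.exp(-lam))
    n_contrib_full = float(ring_area_mm2 * contrib_density.mean())

    inter_full = n_inter / density_scale**2
    rescaled = inter_full / n_contrib_full if n_contrib_full > 0 else float("nan")
    return MultiplicityEstimate(
        raw_mean=raw_mean, raw_se=raw_se, n_contributing=int(len(pres)),
        inter_connections=n_inter, density_scale=density_scale,
        rescaled_mean=rescaled, n_contributing_full=n_contrib_full,
    )


def interior_comm_partners(tile_len_um: float, cutoff_um: float) -> int:
    """Communication partners of an interior tile (grid large enough)."""
    if cutoff_um <= 0:
        return 0
    reach = math.ceil(cutoff_um / tile_len_um)
    side = 2 * reach + 3
    grid = plan_grid(side, side, tile_len_um)
    center = grid.tile_id(side // 2, side // 2)
    return len(neighbor_tiles(grid, center, cutoff_um))


def memory_per_tile(counts: ExpectedCounts) -> float:
    """Connection-storage bytes for one tile: 14 B per record (decimal GB = 1e9 B)."""
    return counts.connections_per_tile * RECORD_BYTES


def sweep_tile_sizes(plan: ConnectivityPlan, region: RegionSpec,
                     tile_sizes_um: list[float], n_samples: int = 20_000,
                     seed: int = 1) -> pd.DataFrame:
    """Partition statistics as a function of tile size.

    The shared-input multiplicity column is the full-density analytic
    estimate (1 - intra fraction) × connections per tile ÷ contributing
    pool; it requires no sheet construction, so the sweep runs in
    seconds.  The result carries monotonicity flags in ``df.attrs``:
    the intra-tile fraction must be nondecreasing and the partner count
    nonincreasing in the tile size.
    """
    rows = []
    for i, L in enumerate(tile_sizes_um):
        if L <= 0:
            raise ValueError("tile sizes must be > 0")
        rng = Xorshift32.substream(seed, _FRACTION, i)
        frac, se = intra_tile_fraction(plan, region, L, n_samples, rng)
        counts = expected_counts(region, L)
        n_contrib = _contributing_pool_full(plan, region, L, seed=seed + i)
        inter = (1.0 - frac) * counts.connections_per_tile
        mult = inter / n_contrib if n_contrib > 0 else float("nan")
        rows.append(PartitionStats(
            tile_len_um=L, intra_tile_fraction=frac, fraction_se=se,
            mean_shared_multiplicity=mult,
            n_comm_partners=interior_comm_partners(L, plan.max_cutoff_um),
            neurons_per_tile=counts.neurons_per_tile,
            connections_per_tile=counts.connections_per_tile,
            bytes_per_tile=memory_per_tile(counts),
        ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    frac_mono = bool(np.all(np.diff(df.sort_values("tile_len_um")
                                    ["intra_tile_fraction"]) >= -3e-2))
    partners_mono = bool(np.all(np.diff(df.sort_values("tile_len_um")
                                        ["n_comm_partners"]) <= 0))
    df.attrs["fraction_nondecreasing"] = frac_mono
    df.attrs["partners_nonincreasing"] = partners_mono
    return df


def _contributing_pool_full(plan: ConnectivityPlan, region: RegionSpec,
                            tile_len_um: float, seed: int,
                            n_position_samples: int = 2000,
                            n_landing_samples: int = 64) -> float:
    """Full-density count of remote pres with ≥1 center-tile target (MC)."""
    cutoff = plan.max_cutoff_um
    if cutoff <= 0:
        return 0.0
    reach = max(1, math.ceil(cutoff / tile_len_um))
    side = 2 * reach + 1
    grid = plan_grid(side, side, tile_len_um)
    center = grid.tile_id(reach, reach)
    ring_ids = neighbor_tiles(grid, center, cutoff)
    if not ring_ids:
        return 0.0
    rng = Xorshift32.substream(seed, _CONTRIB, 1)
    tidx = {t.name: i for i, t in enumerate(region.neuron_types)}
    per_pre: dict[int, dict[tuple[float, float], float]] = {}
    for (pre, post), k in plan.kernels.items():
        mass = (2.0 * math.pi * (k.sigma / 1000.0) ** 2
                * (1.0 - math.exp(-k.cutoff**2 / (2.0 * k.sigma**2))))
        lam = region.type_by_name(post).density * k.peak * mass
        per_pre.setdefault(tidx[pre], {})
        key = (k.sigma, k.cutoff)
        per_pre[tidx[pre]][key] = per_pre[tidx[pre]].get(key, 0.0) + lam

    n_ring = len(ring_ids)
    tile_pick = np.minimum((rng.uniforms(n_position_samples) * n_ring)
                           .astype(int), n_ring - 1)
    ux = rng.uniforms(n_position_samples)
    uy = rng.uniforms(n_position_samples)
    xs = np.empty(n_position_samples)
    ys = np.empty(n_position_samples)
    for i, t in enumerate(tile_pick):
        x0, y0 = grid.footprint(ring_ids[t])
        xs[i] = x0 + ux[i] * tile_len_um
        ys[i] = y0 + uy[i] * tile_len_um
    cx0, cy0 = grid.footprint(center)

    sigma_keys = sorted({key for d in per_pre.values() for key in d})
    landing = {}
    for key in sigma_keys:
        sigma, cut = key
        dx, dy = _truncated_gaussian_displacements(
            sigma, cut, n_position_samples * n_landing_samples, rng)
        dx = dx.reshape(n_position_samples, n_landing_samples)
        dy = dy.reshape(n_position_samples, n_landing_samples)
        tx = xs[:, None] + dx
        ty = ys[:, None] + dy
        inside = ((cx0 <= tx) & (tx < cx0 + tile_len_um)
                  & (cy0 <= ty) & (ty < cy0 + tile_len_um))
        landing[key] = inside.mean(axis=1)

    contrib_density = np.zeros(n_position_samples)
    for ti, lam_by_key in per_pre.items():
        lam = np.zeros(n_position_samples)
        for key, l0 in lam_by_key.items():
            lam += l0 * landing[key]
        contrib_density += region.neuron_types[ti].density * (1.0 - np.exp(-lam))
    ring_area_mm2 = n_ring * (tile_len_um / 1000.0) ** 2
    return float(ring_area_mm2 * contrib_density.mean())


def plot_partition_curves(df: pd.DataFrame, path: str) -> None:
    """Four-panel summary: census, fraction, multiplicity, partners vs tile area."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    area = (df["tile_len_um"] / 1000.0) ** 2
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    ax = axes[0, 0]
    ax.plot(area, df["neurons_per_tile"], "o-", color="tab:red", label="neurons")
    ax.plot(area, df["connections_per_tile"], "s-", color="tab:blue",
            label="connections")
    ax.set_yscale("log")
    ax.set_xlabel("tile area (mm²)")
    ax.set_ylabel("count per tile")
    ax.legend()
    ax = axes[0, 1]
    ax.errorbar(area, df["intra_tile_fraction"], yerr=df["fraction_se"],
                fmt="ko-")
    ax.set_xlabel("tile area (mm²)")
    ax.set_ylabel("intra-tile connection fraction")
    ax.set_ylim(0, 1)
    ax = axes[1, 0]
    ax.plot(area, df["mean_shared_multiplicity"], "o-", color="tab:green")
    ax.set_xlabel("tile area (mm²)")
    ax.set_ylabel("shared-input multiplicity")
    ax = axes[1, 1]
    ax.plot(area, df["n_comm_partners"], "o-", color="tab:orange")
    ax.set_xlabel("tile area (mm²)")
    ax.set_ylabel("communication partners")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
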