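"""Sheet construction: neuron placement, kernel calibration, connection draws.

Connectivity is distance-dependent: a presynaptic neuron at horizontal
distance ``d`` from a postsynaptic neuron connects with probability
``peak * exp(-d²/2σ²)`` up to a hard cutoff (1300 μm by default).  The
expected in-degree of an interior neuron with a full neighborhood has the
closed form

    density_pre * peak * 2πσ² * (1 - exp(-R²/2σ²)),

the disc integral of the truncated Gaussian.  `calibrate_peaks` uses this
to rescale all relative peaks incoming to each postsynaptic type by one
factor so the summed expectation matches the type's in-degree target.

Connection generation draws one Bernoulli per candidate pair.  The draw
order is a contract: pairs are visited in (post gid, pre gid) lexicographic
order and one uniform variate is consumed per visited pair, where a pair is
"visited" iff its type pair is allowed, it is not a self-pair, and the
horizontal distance is within the pair's cutoff.  Any enumeration strategy
honoring the contract (naive double loop, k-d tree, spatial grid)
reproduces the same network draw for draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import KernelSpec, NeuronTypeSpec, RegionSpec, WeightRuleSpec
from .rng import Xorshift32

__all__ = [
    "PeakCapWarning",
    "CalibrationError",
    "expected_in_degree",
    "ConnectivityPlan",
    "calibrate_peaks",
    "ExpectedCounts",
    "expected_counts",
    "TilePopulation",
    "place_neurons",
    "ConnectionBatch",
    "generate_connections",
    "sample_weight",
    "RECORD_BYTES",
]

RECORD_BYTES = 14  # serialized size of one connection record


class PeakCapWarning(UserWarning):
    """A calibrated kernel peak exceeds its class cap (model still built)."""


class CalibrationError(ValueError):
    """A postsynaptic type's in-degree target cannot be met."""


def expected_in_degree(kernel: KernelSpec, pre_density: float) -> float:
    """Expected connections onto one interior neuron from one presynaptic type.

    ``pre_density`` is neurons per mm²; ``kernel`` distances are in μm.
    Closed form of ∫ p(d) · density over the cutoff disc.
    """
    sigma_mm = kernel.sigma / 1000.0
    r_mm = kernel.cutoff / 1000.0
    mass = 2.0 * math.pi * sigma_mm**2 * (1.0 - math.exp(-r_mm**2 / (2.0 * sigma_mm**2)))
    return pre_density * kernel.peak * mass


@dataclass
class ConnectivityPlan:
    """Calibrated kernels plus weight and delay rules, ready for generation."""

    region: RegionSpec
    kernels: dict[tuple[str, str], KernelSpec]
    delay_ms: float
    scale_factors: dict[str, float] = field(default_factory=dict)

    @property
    def max_cutoff_um(self) -> float:
        return max((k.cutoff for k in self.kernels.values()), default=0.0)

    def in_degree_of(self, post_type: str) -> float:
        """Analytic expected in-degree of an interior neuron of ``post_type``."""
        total = 0.0
        for (pre, post), k in self.kernels.items():
            if post == post_type:
                total += expected_in_degree(k, self.region.type_by_name(pre).density)
        return total

    def check_in_degrees(self, rtol: float = 1e-3) -> None:
        for t in self.region.neuron_types:
            if t.target_in_degree == 0:
                continue
            got = self.in_degree_of(t.name)
            if abs(got - t.target_in_degree) > rtol * t.target_in_degree:
                raise CalibrationError(
                    f"{t.name}: calibrated in-degree {got:.4f} misses target "
                    f"{t.target_in_degree}"
                )


def calibrate_peaks(region: RegionSpec) -> ConnectivityPlan:
    """Rescale relative kernel peaks so expected in-degrees hit their targets.

    For each postsynaptic type one scale factor multiplies every incoming
    relative peak; the relative mix across presynaptic types (set by the
    declared peaks, equal class caps by default ⇒ mix proportional to
    presynaptic density) is preserved.  A calibrated peak above its class
    cap raises `PeakCapWarning`, not an error.
    """
    incoming: dict[str, list[KernelSpec]] = {t.name: [] for t in region.neuron_types}
    for pre, post in region.connectivity_mask:
        incoming[post].append(region.kernel_for(pre, post))

    kernels: dict[tuple[str, str], KernelSpec] = {}
    scales: dict[str, float] = {}
    for t in region.neuron_types:
        kerns = incoming[t.name]
        base = sum(expected_in_degree(k, region.type_by_name(k.pre_type).density)
                   for k in kerns)
        if t.target_in_degree > 0 and base <= 0:
            raise CalibrationError(
                f"{t.name}: in-degree target {t.target_in_degree} but no incoming "
                f"pairs with positive relative peak"
            )
        scale = (t.target_in_degree / base) if base > 0 else 0.0
        scales[t.name] = scale
        for k in kerns:
            peak = k.peak * scale
            cap = region.peak_cap(k.pre_type, k.post_type)
            if peak > cap + 1e-12:
                warnings.warn(
                    f"calibrated peak {peak:.4f} for {k.pre_type}->{k.post_type} "
                    f"exceeds class cap {cap}",
                    PeakCapWarning,
                    stacklevel=2,
                )
            if peak > 1.0:
                raise CalibrationError(
                    f"{k.pre_type}->{k.post_type}: calibrated peak {peak:.4f} > 1; "
                    f"target in-degree unreachable under this kernel geometry"
                )
            kernels[(k.pre_type, k.post_type)] = KernelSpec(
                pre_type=k.pre_type, post_type=k.post_type,
                peak=peak, sigma=k.sigma, cutoff=k.cutoff,
            )
    return ConnectivityPlan(region=region, kernels=kernels,
                            delay_ms=region.delay_ms, scale_factors=scales)


@dataclass(frozen=True)
class ExpectedCounts:
    """Analytic neuron/connection/memory expectations per mm² and per tile."""

    neurons_per_mm2: float
    connections_per_mm2: float
    mean_in_degree: float
    neurons_per_tile: float
    connections_per_tile: float
    bytes_per_tile: float


def expected_counts(region: RegionSpec, tile_len_um: float) -> ExpectedCounts:
    """Expected census of one square tile of side ``tile_len_um``.

    Connection expectations take each type's in-degree target at face
    value (interior tile, full neighborhood); memory is 14 bytes per
    stored connection record.
    """
    if tile_len_um < 0:
        raise ValueError("tile_len_um must be >= 0")
    n_mm2 = float(sum(t.density for t in region.neuron_types))
    c_mm2 = float(sum(t.density * t.target_in_degree for t in region.neuron_types))
    mean_k = c_mm2 / n_mm2 if n_mm2 > 0 else 0.0
    area = (tile_len_um / 1000.0) ** 2
    n_tile = n_mm2 * area
    c_tile = n_tile * mean_k
    return ExpectedCounts(
        neurons_per_mm2=n_mm2,
        connections_per_mm2=c_mm2,
        mean_in_degree=mean_k,
        neurons_per_tile=n_tile,
        connections_per_tile=c_tile,
        bytes_per_tile=c_tile * RECORD_BYTES,
    )


@dataclass
class TilePopulation:
    """Neurons of one tile: identities, positions, per-neuron bias currents.

    ``gid_start`` is the first global id; gids are contiguous
    ``gid_start .. gid_start+n-1`` in insertion order (types in declaration
    order, neurons within a type in draw order).  Positions are sheet
    coordinates in μm (x, y horizontal; z depth below the surface).
    """

    tile_id: int
    x0: float
    y0: float
    tile_len: float
    gid_start: int
    type_index: np.ndarray  # uint16, index into region.neuron_types
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    bias: np.ndarray

    @property
    def n(self) -> int:
        return len(self.type_index)

    @property
    def gids(self) -> np.ndarray:
        return np.arange(self.gid_start, self.gid_start + self.n, dtype=np.int64)

    def local_index(self, gid: np.ndarray | int):
        return gid - self.gid_start


def place_neurons(
    tile_id: int,
    x0: float,
    y0: float,
    tile_len: float,
    region: RegionSpec,
    rng: Xorshift32,
    gid_start: int = 0,
    density_scale: float = 1.0,
    count_mode: str = "poisson",
) -> TilePopulation:
    """Populate one tile footprint with neurons.

    Per type the count is Poisson(density × scale × area) in "poisson"
    mode or the rounded expectation in "fixed" mode; positions are uniform
    in the tile footprint and the type's layer slab; bias currents are
    drawn Normal(bias_mean, bias_sd) per neuron.
    """
    if count_mode not in ("poisson", "fixed"):
        raise ValueError("count_mode must be 'poisson' or 'fixed'")
    if not 0 < density_scale <= 1.0 + 1e-12:
        raise ValueError("density_scale must lie in (0, 1]")
    area_mm2 = (tile_len / 1000.0) ** 2
    counts = []
    for t in region.neuron_types:
        lam = t.density * density_scale * area_mm2
        counts.append(rng.poisson(lam) if count_mode == "poisson" else int(round(lam)))
    n = int(sum(counts))
    type_index = np.empty(n, dtype=np.uint16)
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    bias = np.empty(n)
    pos = 0
    for ti, (t, c) in enumerate(zip(region.neuron_types, counts)):
        if c == 0:
            continue
        sl = slice(pos, pos + c)
        type_index[sl] = ti
        x[sl] = x0 + rng.uniforms(c) * tile_len
        y[sl] = y0 + rng.uniforms(c) * tile_len
        z_top, z_bot = region.layer_depth_range(t.layer)
        z[sl] = z_top + rng.uniforms(c) * (z_bot - z_top)
        bias[sl] = rng.normals(c, t.bias_mean, t.bias_sd)
        pos += c
    return TilePopulation(
        tile_id=tile_id, x0=x0, y0=y0, tile_len=tile_len, gid_start=gid_start,
        type_index=type_index, x=x, y=y, z=z, bias=bias,
    )


@dataclass
class ConnectionBatch:
    """Struct-of-arrays batch of connections stored on the postsynaptic side."""

    pre_gid: np.ndarray  # int64
    post_gid: np.ndarray  # int64
    weight: np.ndarray  # float32
    delay_ticks: np.ndarray  # uint16
    syn_type: np.ndarray  # uint16, index into region.synapse_classes

    @property
    def n(self) -> int:
        return len(self.pre_gid)

    @classmethod
    def empty(cls) -> "ConnectionBatch":
        return cls(
            pre_gid=np.empty(0, np.int64), post_gid=np.empty(0, np.int64),
            weight=np.empty(0, np.float32), delay_ticks=np.empty(0, np.uint16),
            syn_type=np.empty(0, np.uint16),
        )


def sample_weight(pre_type: str, post_type: str, region: RegionSpec,
                  rng: Xorshift32) -> float:
    """One synaptic weight for a (pre, post) type pair under the region's rules."""
    rule = region.weight_rule_for(pre_type, post_type)
    if rule.rule == "constant":
        return rule.value
    return float(np.exp(rng.normal(rule.mu_ln, rule.sigma_ln)))


def _pair_tables(plan: ConnectivityPlan, dt_ms: float):
    """Dense per-(pre type, post type) lookup tables for vectorized draws."""
    region = plan.region
    nt = len(region.neuron_types)
    allowed = np.zeros((nt, nt), dtype=bool)
    peak = np.zeros((nt, nt))
    inv2sig2 = np.zeros((nt, nt))
    cutoff2 = np.zeros((nt, nt))
    lognormal = np.zeros((nt, nt), dtype=bool)
    const_w = np.zeros((nt, nt))
    mu_ln = np.zeros((nt, nt))
    sd_ln = np.zeros((nt, nt))
    idx = {t.name: i for i, t in enumerate(region.neuron_types)}
    for (pre, post), k in plan.kernels.items():
        i, j = idx[pre], idx[post]
        allowed[i, j] = True
        peak[i, j] = k.peak
        inv2sig2[i, j] = 1.0 / (2.0 * k.sigma**2)
        cutoff2[i, j] = k.cutoff**2
        rule = region.weight_rule_for(pre, post)
        if rule.rule == "lognormal":
            lognormal[i, j] = True
            mu_ln[i, j], sd_ln[i, j] = rule.mu_ln, rule.sigma_ln
        else:
            const_w[i, j] = rule.value
    delay_ticks = int(round(plan.delay_ms / dt_ms))
    if abs(delay_ticks * dt_ms - plan.delay_ms) > 1e-9:
        raise ValueError(f"delay {plan.delay_ms} ms is not a multiple of dt {dt_ms} ms")
    syn_class = np.array(
        [region.synapse_class_index(
            "excitatory" if t.ei_class == "excitatory" else "inhibitory")
         for t in region.neuron_types],
        dtype=np.uint16,
    )
    return allowed, peak, inv2sig2, cutoff2, lognormal, const_w, mu_ln, sd_ln, \
        delay_ticks, syn_class


def generate_connections(
    pre_pops: list[TilePopulation],
    post_pop: TilePopulation,
    plan: ConnectivityPlan,
    rng: Xorshift32,
    weight_rng: Xorshift32,
    dt_ms: float = 0.1,
    periodic_extent: tuple[float, float] | None = None,
) -> ConnectionBatch:
    """Draw all connections terminating on ``post_pop``.

    ``pre_pops`` should cover the post tile's full neighborhood (every tile
    within the cutoff); with open boundaries the caller accepts edge
    truncation.  ``rng`` supplies the per-pair Bernoulli uniforms under the
    iteration-order contract; ``weight_rng`` supplies weight draws (one
    log-normal deviate per accepted connection of a log-normal pair, in
    acceptance order), so the connectivity draw is independent of the
    weight rule.

    With ``periodic_extent=(W, H)`` distances wrap (minimum image); the
    extent must be at least twice every cutoff so the nearest image is
    unique.
    """
    tables = _pair_tables(plan, dt_ms)
    (allowed, peak, inv2sig2, cutoff2, lognormal, const_w, mu_ln, sd_ln,
     delay_ticks, syn_class) = tables
    max_cut = plan.max_cutoff_um
    if max_cut <= 0 or post_pop.n == 0 or not pre_pops:
        return ConnectionBatch.empty()

    pre_gid = np.concatenate([p.gids for p in pre_pops])
    pre_x = np.concatenate([p.x for p in pre_pops])
    pre_y = np.concatenate([p.y for p in pre_pops])
    pre_t = np.concatenate([p.type_index for p in pre_pops]).astype(np.int64)
    order = np.argsort(pre_gid, kind="stable")
    pre_gid, pre_x, pre_y, pre_t = (a[order] for a in (pre_gid, pre_x, pre_y, pre_t))
    if len(pre_gid) == 0:
        return ConnectionBatch.empty()

    if periodic_extent is not None:
        w, h = periodic_extent
        if max_cut > min(w, h) / 2:
            raise ValueError("periodic extent must be >= 2x cutoff in each direction")
        tree = cKDTree(np.column_stack([pre_x % w, pre_y % h]), boxsize=(w, h))
        query_xy = np.column_stack([post_pop.x % w, post_pop.y % h])
    else:
        tree = cKDTree(np.column_stack([pre_x, pre_y]))
        query_xy = np.column_stack([post_pop.x, post_pop.y])

    neighbor_lists = tree.query_ball_point(query_xy, r=max_cut)

    post_t = post_pop.type_index.astype(np.int64)
    cand_pre_idx: list[np.ndarray] = []
    cand_p: list[np.ndarray] = []
    cand_post: list[np.ndarray] = []
    for li in range(post_pop.n):
        idxs = np.sort(np.asarray(neighbor_lists[li], dtype=np.int64))
        if idxs.size == 0:
            continue
        tj = post_t[li]
        ok = allowed[pre_t[idxs], tj]
        idxs = idxs[ok]
        if idxs.size == 0:
            continue
        dx = pre_x[idxs] - post_pop.x[li]
        dy = pre_y[idxs] - post_pop.y[li]
        if periodic_extent is not None:
            w, h = periodic_extent
            dx -= w * np.round(dx / w)
            dy -= h * np.round(dy / h)
        d2 = dx * dx + dy * dy
        ti = pre_t[idxs]
        in_range = d2 <= cutoff2[ti, tj]
        not_self = pre_gid[idxs] != post_pop.gid_start + li
        keep = in_range & not_self
        idxs, d2, ti = idxs[keep], d2[keep], ti[keep]
        if idxs.size == 0:
            continue
        p = peak[ti, tj] * np.exp(-d2 * inv2sig2[ti, tj])
        cand_pre_idx.append(idxs)
        cand_p.append(p)
        cand_post.append(np.full(idxs.size, li, dtype=np.int64))

    if not cand_pre_idx:
        return ConnectionBatch.empty()
    cand_pre_idx = np.concatenate(cand_pre_idx)
    cand_p = np.concatenate(cand_p)
    cand_post = np.concatenate(cand_post)

    u = rng.uniforms(cand_pre_idx.size)
    hit = u < cand_p
    sel_pre = cand_pre_idx[hit]
    sel_post = cand_post[hit]

    ti = pre_t[sel_pre]
    tj = post_t[sel_post]
    weights = const_w[ti, tj].copy()
    ln_mask = lognormal[ti, tj]
    n_ln = int(ln_mask.sum())
    if n_ln:
        z = weight_rng.normals(n_ln)
        weights[ln_mask] = np.exp(mu_ln[ti, tj][ln_mask] + sd_ln[ti, tj][ln_mask] * z)

    return ConnectionBatch(
        pre_gid=pre_gid[sel_pre].astype(np.int64),
        post_gid=(post_pop.gid_start + sel_post).astype(np.int64),
        weight=weights.astype(np.float32),
        delay_ticks=np.full(sel_pre.size, delay_ticks, dtype=np.uint16),
        syn_type=syn_class[ti],
    )
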