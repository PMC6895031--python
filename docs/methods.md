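# Methods

## Model

**Neurons.** Single-compartment leaky integrate-and-fire:
τ_m du/dt = −u + u_rest + R_m (I_syn + I_ext), with spike-and-reset at
threshold.  The voltage scale is not part of the published census, so the
package fixes the canonical values u_rest = u_reset = −70 mV, θ = −50 mV
and R_m = 1 (currents thereby expressed in mV).  With that scale the
per-type bias currents — N(10, 5) for layer-1 and excitatory types,
N(18, 5) for deeper-layer interneurons — put ≈34 % of the interneurons
above the 20 mV tonic-firing threshold and almost no excitatory cells,
reproducing the qualitative rate pattern of the census (interneurons
active, excitatory cells nearly silent at rest).  The threshold test is
`u ≥ θ` (an equality test is measure-zero under Euler).  No refractory
period is modeled.

**Synapses.** Conductance-based, one alpha-function state pair (z, g) per
neuron and synapse class (excitatory E = 0 mV, inhibitory E = −70 mV,
τ_s = 2 ms).  The per-step update is the exact matrix exponential
e^{−dt/τ}[[1,0],[dt/τ,1]] of the linear system z′ = −z/τ,
g′ = (z − g)/τ; integration error on the grid is zero (machine epsilon),
which the tests assert at 1e−12.  A spike of total weight w raises z by
w·e, normalizing a unit-weight spike to unit peak conductance at lag τ_s;
all published weight constants are interpreted on that scale (the source
census does not state a normalization).  Simultaneous arrivals sum
before the impulse; impulses are applied at the start of the step in
which they are due.

**Sign convention.** The synaptic current is I_syn = Σ g·(E_syn − u).
Written with (u − E_syn), a positive-conductance excitatory input would
hyperpolarize; the standard conductance-based convention is used
deliberately and this deviation is intentional.

**Connectivity.** Distance-dependent Bernoulli wiring,
p(d) = peak·exp(−d²/2σ²) for horizontal distance d up to a hard cutoff
(default 1300 μm, two standard deviations of the widest kernel).
Per-pair σ values come from photostimulation mapping data that are not
part of the census this package transcribes; the default assigns every
kernel σ = cutoff/2 = 650 μm, overridable per pair in the region file.
Relative peaks default to the patch-clamp class caps (0.12 E→E, 0.25
otherwise), making the presynaptic mix of each type's in-degree
proportional to presynaptic density; **calibration** then multiplies all
peaks incoming to a postsynaptic type by one factor so the analytic
expected in-degree (disc integral of the truncated Gaussian times
density) matches the census target to better than 0.1 %.  A calibrated
peak above its class cap warns; above 1 it is an error (the target is
unreachable).  Because in-degree targets are held fixed, scaling all
densities by f rescales peaks by 1/f and connections per area by f — the
density-invariance property the analytics rely on.

Weights: E→E log-normal (ln W ~ N(−0.72, σ_ln), σ_ln = 1 by default —
only the log-mean is published); other class pairs constant (E→PV 0.42,
E→SST 0.19, PV/SST→E 2.00, PV→PV 1.12, SBC→inhibitory 0.80, ENGC→all
1.00).  Among deep-layer interneurons only PV→PV and SST→PV connect; the
SST→PV weight is not published and is set to 0.74, the one published
cross-type interneuron constant.  Delays are constant 1 ms by default
(configurable); they are stored in integer dt ticks so the exchange
schedule is integer arithmetic.

**Placement.** Per tile and type, the neuron count is
Poisson(density × area): a deterministic rounded-expectation mode exists
for tests, but stochastic counts are the default because realized tile
censuses should scatter around the expectation.  Positions are uniform in
the tile footprint and the type's layer slab (layer thicknesses 100/400/
200/400/300 μm over a 1400 μm depth; the vertical coordinate never enters
connectivity, only visualization).  Biases are drawn once per neuron.

## Randomness

All draws come from Marsaglia xorshift32 (shift triplet 13, 17, 5);
normals via Box–Muller, Poisson counts by Knuth's product method below
λ = 50 and a rounded normal approximation above (relative error is
negligible at the λ ~ 10³–10⁴ of per-type tile counts).  Substreams are
keyed by (master seed, purpose, tile id) through a SplitMix64 hash: raw
consecutive seeds of a xorshift cycle can produce extreme early
deviates, and hashing decorrelates them.  Connection generation consumes
exactly one uniform per *visited* pair — pairs enumerated in
(postsynaptic gid, presynaptic gid) lexicographic order, a pair being
visited iff its type pair is allowed, it is not a self-pair and its
distance is within the pair cutoff — so any enumeration strategy (naive
loop, k-d tree) reproduces the same network.  Weights use a separate
substream, one deviate per accepted log-normal connection, keeping the
topology independent of the weight rule.

## Tiling and spike exchange

Tiles are half-open squares partitioning the sheet exactly; global ids
run row-major over tiles, then insertion order within a tile, so tiled
and untiled runs number neurons identically.  Two tiles are neighbors iff
the distance between their footprints is *strictly* less than the cutoff
— at distance exactly equal to the cutoff the connection mass is zero, so
a closed comparison would add a spurious second ring; the strict rule
yields 8 partners when tile length equals the cutoff and 24 at half that
tile length.  Edge tiles simply have fewer neighbors (open boundary).  An
optional periodic-boundary mode (minimum-image distances, valid for
extents ≥ 2 × cutoff) lets in-degree recovery tests run without halo
tiles.

Spikes are exchanged at half the minimum delay: with min delay 2I ticks,
interval m's spikes are delivered before interval m+2 is computed.  Since
every connection delay is ≥ 2I (models violating this are rejected at
load), the two-interval latency is exact, not approximate — a remote
spike's impulse lands at precisely spike tick + delay, the same tick as
in an untiled run.  The minimum delay must be an even number of dt steps
so the interval lies on the integration grid.  Float summation order is
pinned by sorting each step's due deliveries by (presynaptic gid, spike
tick); with that, serial, parallel and monolithic modes are
bit-identical, which the suite asserts on 2×2 and 3×3 toy sheets over 1 s
of biological time.  The parallel backend is one process per tile with
queues between neighbor tiles only (oversubscription of physical cores is
accepted; the message contract — send interval k, proceed to k+1 without
acknowledgment — is what the half-delay schedule licenses).

## Connection storage

One connection record is 14 bytes, little-endian, no padding:
postsynaptic gid (u32), weight (IEEE-754 single), delay in dt ticks
(u16), synapse type (u16), a reserved plasticity byte, and a local
synapse id byte.  Records are grouped by presynaptic gid in a
struct-of-arrays store with an offset table — delivering one spike is a
contiguous scan.  The byte footprint is exactly 14 × record count (5.03–
5.04 GB for a full-density 1.3 mm M1 tile; decimal GB).  The per-tile
intermediate file carries a magic/version header, a JSON metadata block,
the neuron arrays, the packed record block and a SHA-256 payload digest;
weight encoding and endianness are fixed by the format so files are
bit-portable.

## Partition analytics

The intra-tile connection fraction is estimated by Monte-Carlo over
geometry: postsynaptic point uniform in the tile, presynaptic
displacement drawn from the truncated kernel by inverse CDF — densities
cancel, so the estimate is density invariant, and kernels are grouped by
(σ, cutoff) with connection-mass weights.  A second, empirical estimator
builds an actual neighborhood at reduced density and counts; the suite
checks the two agree and that the fraction is invariant across build
densities.  Shared-input multiplicity (mean center-tile targets per
contributing remote presynaptic neuron) is measured on built
neighborhoods at reduced density and rescaled: inter-tile connection
counts scale with density², while the full-density contributing pool is
integrated by Monte Carlo from the per-position Poisson non-emptiness
probability 1 − e^{−λ(x)}.  The absolute published values of these two
statistics depend on the unpublished per-pair σ table, so they are not
point targets; what is asserted instead is density invariance, monotone
growth of the fraction with tile size, multiplicity saturation once the
tile side reaches twice the cutoff, and the internal-consistency identity
multiplicity = (1 − fraction) × connections per tile ÷ contributing pool.

## Problem sizes

Tests and examples run two-type toy sheets (≈180 neurons per 0.36 mm²
tile, weights weakened to keep recurrent activity near 5 Hz and stable)
and reduced-density single-type sheets (1–20 % of nominal density) for
the analytics; the full-density M1 model is exercised analytically
(census, calibration integrals, memory model) and through single-tile
placement (~95 k neurons).  Full-density connection construction
(≈3.6 × 10⁸ records per tile) is represented by the exact byte-count
model rather than allocated.  These sizes are the package's chosen study
conditions; the rescaling laws that connect them to full density are
themselves asserted as tests.

## Known limitations

- No synaptic plasticity (the record layout reserves a byte for it), no
  refractory period, no multi-compartment morphology, no conductance
  noise.
- Single region only: no inter-regional (long-range) projections.
- The default σ = 650 μm for every kernel flattens genuine per-pair
  differences in spatial extent; per-pair overrides exist but no
  published table ships with the package.
- Wall-clock performance of a real distributed run (elapsed-time
  breakdowns, wire-format message volumes) is out of scope; the timing
  log measures this implementation, and message payload is counted in
  spikes, not wire bytes.
- The toy fixtures' weight scales are chosen for stable sparse firing;
  they are not a calibrated activity model of cortex.
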