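"""Expected and realized census of one compute tile of the M1 sheet.

Builds the analytic expectations for a 1.3 × 1.3 mm tile of the built-in
mouse M1 layered sheet (15 neuron types, 5 layers), then places one
actual tile population with Poisson per-type counts and compares.
"""

from tilespike import builtin_m1_region, expected_counts, place_neurons, total_density
from tilespike.rng import Xorshift32

region = builtin_m1_region()
counts = expected_counts(region, tile_len_um=1300.0)

print(f"total density          : {total_density(region):,.0f} neurons/mm^2")
print(f"connections per mm^2   : {counts.connections_per_mm2:,.0f}")
print(f"mean in-degree         : {counts.mean_in_degree:,.1f} connections/neuron")
print(f"expected neurons/tile  : {counts.neurons_per_tile:,.1f}")
print(f"expected conns/tile    : {counts.connections_per_tile:.4g}")
print(f"connection memory/tile : {counts.bytes_per_tile/1e9:.2f} GB (14 B/record)")

pop = place_neurons(0, 0.0, 0.0, 1300.0, region, Xorshift32.substream(1, 0))
print(f"one Poisson realization: {pop.n:,} neurons "
      f"({pop.n - counts.neurons_per_tile:+,.0f} vs expectation)")
# The expectation is ~95,132 neurons and ~3.6e8 connections: a tile this
# size fills roughly 5 GB of packed 14-byte connection records, which is
# what makes it the natural per-worker unit.
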