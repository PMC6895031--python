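"""Whole-sheet bookkeeping for weak-scaling-style tile grids.

Shows how sheet area, neuron and connection totals grow when the same
1.3 mm tile is replicated onto larger and larger grids, and how many
neighbors a tile exchanges spikes with.
"""

from tilespike import builtin_m1_region, grid_expected_totals, neighbor_tiles, plan_grid

region = builtin_m1_region()
for n in (1, 24, 252):
    grid = plan_grid(n, n, 1300.0)
    t = grid_expected_totals(grid, region)
    print(f"{n:>3d} x {n:<3d}: {t['n_tiles']:>6,} tiles  "
          f"{t['area_cm2']:>8.2f} cm^2  "
          f"{t['neurons']:.3g} neurons  {t['connections']:.3g} connections")

grid = plan_grid(5, 5, 1300.0)
center = grid.tile_id(2, 2)
print(f"\ninterior tile partners at the 1300 um cutoff: "
      f"{len(neighbor_tiles(grid, center, 1300.0))}")
print(f"corner tile partners                        : "
      f"{len(neighbor_tiles(grid, 0, 1300.0))}")
# Communication is strictly nearest-neighbor for tiles at least as large
# as the connection cutoff, so the per-tile message volume does not grow
# with the sheet.
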