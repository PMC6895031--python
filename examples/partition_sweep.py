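"""How tile size trades locality against communication for the M1 sheet.

Sweeps tile sizes for the built-in M1 region and prints, per size, the
expected per-tile census, the fraction of connections that stay inside
one tile (Monte-Carlo over kernel geometry — density invariant), the
estimated shared-input multiplicity, and the number of communication
partners of an interior tile.
"""

from tilespike import builtin_m1_region, calibrate_peaks
from tilespike.analytics import sweep_tile_sizes

region = builtin_m1_region()
plan = calibrate_peaks(region)

df = sweep_tile_sizes(plan, region, [650.0, 1300.0, 2600.0],
                      n_samples=20_000, seed=1)
cols = ["tile_len_um", "neurons_per_tile", "connections_per_tile",
        "intra_tile_fraction", "mean_shared_multiplicity", "n_comm_partners"]
print(df[cols].to_string(index=False,
                         float_format=lambda v: f"{v:,.3g}"))
print(f"\nfraction nondecreasing with tile size: "
      f"{df.attrs['fraction_nondecreasing']}")
print(f"partner count nonincreasing          : "
      f"{df.attrs['partners_nonincreasing']}")
# Larger tiles keep more connections in local memory (higher fraction)
# and talk to fewer neighbors, at the price of more memory per worker:
# the 1.3 mm tile is the point where partners bottom out at 8.
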