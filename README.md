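# tilespike

Desk-scale simulator for **layered cortical sheets of spiking neurons
executed as a grid of square tiles**.  The cortex is, computationally, a
thin laminar sheet with locally dense, distance-dependent wiring; cutting
it into equal square tiles — one worker per tile — keeps most synapses
inside a worker's own memory and restricts spike traffic to nearest
neighbors.  `tilespike` implements that partitioning end to end for
point-neuron models: model description in JSON, deterministic sheet
construction, a packed per-tile connection store, exact synapse numerics,
and a spike-exchange schedule that lets communication overlap computation
— small enough to study on a workstation, with the bookkeeping needed to
reason about supercomputer-scale grids.

## The model

Neurons are leaky integrate-and-fire units,

    τ_m du/dt = −u + u_rest + R_m (I_syn + I_ext),     u ≥ θ ⇒ u → u_reset,

integrated with forward Euler at dt = 0.1 ms.  Synapses are
conductance-based with alpha-function kernels
g(t) = w·(t/τ_s)·e^{1−t/τ_s} (τ_s = 2 ms; reversal potentials 0 mV
excitatory, −70 mV inhibitory), advanced by the exact 2×2 matrix
exponential of the underlying linear system, so the conductance is exact
on the grid.  All randomness flows through a xorshift32 PRNG with
per-purpose substreams, which makes every build and run bit-reproducible.

Connectivity is distance dependent: a pair at horizontal distance d
connects with probability `peak · exp(−d²/2σ²)` up to a hard cutoff
(1300 μm by default).  Kernel peaks are *calibrated*: one scale factor
per postsynaptic type makes the analytic expected in-degree
`Σ_pre density_pre · peak · 2πσ²(1 − e^{−R²/2σ²})` match the type's
target exactly.

The built-in region transcribes a mouse primary motor cortex (M1) census:
5 layers, 15 neuron types (layer-1 SBC/ENGC interneurons; IT/PT
excitatory classes; PV/SST interneurons), per-type densities, membrane
time constants, in-degrees, log-normal E→E weights (ln W ~ N(−0.72, 1))
and constant weights for the other classes.  Summed over types it gives
56,291 neurons and 212,816,704 connections per mm² (mean in-degree 3781).

The sheet runs as square tiles that exchange spikes **at half the minimum
transmission delay**: spikes generated in exchange interval k are applied
to postsynaptic conductances in interval k+2, so a worker can compute
interval k+1 while interval k's messages are in flight.  Serial,
parallel (one process per tile) and monolithic (untiled) execution of
the same built sheet produce byte-identical spike trains — the partition
is an execution detail, not a model change.

## Worked example

```sh
python examples/tile_census.py
```

prints

```
total density          : 56,291 neurons/mm^2
connections per mm^2   : 212,816,704
mean in-degree         : 3,780.7 connections/neuron
expected neurons/tile  : 95,131.8
expected conns/tile    : 3.597e+08
connection memory/tile : 5.04 GB (14 B/record)
one Poisson realization: 95,208 neurons (+76 vs expectation)
```

i.e. one 1.3 × 1.3 mm tile of the M1 sheet holds ≈95 k neurons and
≈3.6 × 10⁸ connections, whose packed 14-byte records occupy ≈5 GB — the
natural per-worker unit.  `examples/toy_run_modes.py` builds a small
two-type sheet on a 2 × 2 grid and shows the three run modes emitting
identical spike trains; `examples/grid_bookkeeping.py` scales the tile to
252 × 252 grids (63,504 tiles, 1,073 cm², 6.04 billion neurons expected);
`examples/partition_sweep.py` sweeps tile sizes and prints the intra-tile
connection fraction, shared-input multiplicity and communication-partner
counts.

The same workflow is available from the shell:

```sh
tilespike build --system system.json --grid 2 2 --tile-len 600 --out built/
tilespike run --dir built/ --mode parallel --out out/
tilespike analyze --tile-sizes 650,1300,2600 --out sweep.csv
```

(`--region region_X.json` selects a user model; omitting it uses the
built-in M1 region.)

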