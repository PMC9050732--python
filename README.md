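# nanosynapse

Quantification of synaptic protein nanoclusters in 3D single-molecule
localization microscopy (dSTORM) point clouds.

Super-resolution imaging shows that synaptic adhesion proteins such as
teneurin-3 (Tenm3) are not spread across the synaptic junction but
concentrate in small, dense **nanoclusters** (~80 nm radius of gyration)
that sit in the synaptic cleft, 20–30 nm from the much larger
**macroclusters** formed by active-zone and postsynaptic-density markers
(Bassoon, Homer1; ~300 nm radius). `nanosynapse` is the analysis pipeline
for this kind of question, aimed at microscopists working from localization
tables (one row per detected molecule: x, y, z, frame, channel):

- read/write localization tables and apply per-channel acquisition
  frame windows (e.g. drop the first 3,000 of 10,000 frames);
- density-based denoising and 3D **DBSCAN** clustering with per-channel
  parameters (nanoclusters: ≥ 10 localizations within a 100 nm search
  radius; macroclusters: ≥ 50 within 300 nm);
- cluster metrics: radius of gyration
  `Rg = sqrt(mean_i ||r_i − r̄||²)` and nearest-pair ("edge") distances
  between clusters;
- **synaptic classification**: a nanocluster is synaptic iff its edge
  distance to the nearest macrocluster is ≤ 80 nm (">80 nm separated"
  defines non-synaptic); per-synapse counts, % synaptic, occupancy
  `mean count × (Rg_nano/Rg_macro)² × 100 %`, and control-vs-knockout
  contrasts (fold change + Welch t-test across fields);
- two-component Gaussian histogram fits,
  `f(x) = a1·exp(−((x−b1)/c1)²) + a2·exp(−((x−b2)/c2)²)` (note: c = σ√2);
- image rendering (Gaussian points, default σ = 50 nm) and **Fourier ring
  correlation** resolution estimates with the 1/7 threshold;
- a ground-truth-annotated synthetic two-channel field generator used by
  the whole validation suite (no raw STORM data are publicly deposited).

See `docs/methods.md` for the models, parameter defaults, and numerical
conventions.

## Worked example

Simulate a control field and run the full chain from the shell (the same
operations are available as library functions):

```bash
nanosynapse simulate --preset control --seed 7 --out field.csv --truth truth.json
# wrote 75839 localizations to field.csv

nanosynapse filter --channel Tenm3   --exclude-first 3000 --total 10000 field.csv f1.csv
# Tenm3: kept 18541/26391 localizations
nanosynapse filter --channel Bassoon --exclude-first 2000 --total 7000  f1.csv  f2.csv
# Bassoon: kept 35357/49448 localizations

nanosynapse cluster --channel Tenm3   f2.csv nanos.json
# Tenm3: 126 clusters, 2748 noise localizations
nanosynapse cluster --channel Bassoon f2.csv macros.json
# Bassoon: 50 clusters, 5159 noise localizations

nanosynapse associate --table f2.csv --out assoc.json nanos.json macros.json
# 61/126 nanoclusters synaptic (48.4%)
nanosynapse stats --table f2.csv --out stats.json nanos.json macros.json
# mean 1.22 nanoclusters/synapse, 48.4% synaptic
```

Reading the output: the frame filter removed the unusable early-acquisition
localizations per channel; DBSCAN recovered 126 Tenm3 nanoclusters and all
50 simulated synaptic specializations; 61 nanoclusters lie within 80 nm of
a macrocluster edge (48.4% synaptic — the rest are the simulated
extrasynaptic pool), and the average Bassoon-positive synapse carries 1.22
Tenm3 nanoclusters. `stats.json` additionally reports the per-synapse count
distribution and the ~8.6% area occupancy estimate for this field.

`nanosynapse run --config pipeline.yaml` executes the same chain (including
multi-field simulation) into a run directory with a machine-readable
manifest; `fitgauss` and `frc` expose the histogram fitter and the
resolution estimator.

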