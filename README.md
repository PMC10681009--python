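# spatialith

Agent-based lattice simulation of tumour expansion under variable spatial
constraint, with the measurement stack used to study how **intra-tumour
heterogeneity (ITH)** and **mutation-rate inference** depend on growth mode,
sampling distance and sampling size.

## The problem

Multi-region sequencing shows that mutation composition diverges between
biopsies of one tumour, and that the divergence grows with the physical
distance between samples. How fast it grows — and whether evolutionary
parameters such as the mutation rate can be recovered from a biopsy at all —
depends on how the tumour expanded. `spatialith` provides a controlled
in-silico laboratory for these questions, for modellers and for anyone
planning or interpreting multi-region sampling.

## The model

A tumour grows from one cell seeded at the centre of a 2D (8-neighbour) or
3D (26-neighbour) lattice, in synchronous generations. A dividing cell keeps
one daughter in place; the other occupies a uniformly chosen empty
neighbour. A fully enclosed cell divides with probability *p* — the **push
rate** — by displacing neighbours outward, either along a random lattice ray
or along the shortest path to the nearest empty site:

* *p* = 0 — **surface growth**: only rim cells divide;
* *p* = 1 — **exponential growth**: every cell divides every generation,
  so N(g) = 2^g exactly.

Each daughter independently acquires *k* ~ Poisson(λ) neutral mutations
(default λ = 10 per daughter per division). Genotypes are stored as ancestry
deltas, so whole-tumour and per-sample site-frequency spectra are exact.

On top of the simulator:

* **Spatial sampling** — fully occupied square/cubic samples of exactly S
  cells around random occupied sites, optionally restricted to the central
  disc (within ⅔ of the tumour radius) or the outer margin ring.
* **ITH metrics** — pairwise Jaccard index J(A,B) = |A∩B|/|A∪B| of sample
  mutation sets versus the Euclidean distance between sample centres, with
  clonal-mutation filters, and the same analysis for generic multi-region
  biopsy presence tables (plus a synthetic biopsy-table generator).
* **VAF inference** — under neutral exponential growth the cumulative
  spectrum is linear in inverse frequency, M(f) = (μ/β)(1/f − 1/f_max); an
  OLS fit of M against 1/f (diploid VAF convention, f_max = ½) estimates the
  effective mutation rate μ/β, and a normalised Kolmogorov–Smirnov-style
  distance quantifies how far the observed curve is from linear (large D =
  the estimate should not be trusted).

## Worked example

```python
import numpy as np
import spatialith as sl

cfg = sl.SimulationConfig(push_rate=1.0, mutation_rate=10.0, target_size=2**12, seed=7)
tumour = sl.grow_tumour(cfg)
print(f"{tumour.n_cells} cells in {tumour.generation} generations; "
      f"{tumour.n_mutations} mutations")

fit = sl.CumulativeVAFModel.from_spectrum(sl.mutation_frequencies(tumour)).fit()
print(fit.summary())

rng = np.random.default_rng(0)
samples = sl.random_square_samples(tumour, 100, 500, rng)
records = sl.jaccard_distance_table(samples, tumour=tumour, pairing="ordered")
binned, trend = sl.distance_trend_summary(records)
print(f"{len(records)} ordered Jaccard records; "
      f"Pearson r = {trend.pearson_r:.3f} (p = {trend.p_value:.1e})")
```

prints

```
4096 cells in 12 generations; 82285 mutations
Neutral cumulative-VAF linear fit
==============================================
frequency convention               diploid_vaf
f_max                                    0.500
points fitted                                3
----------------------------------------------
effective mutation rate                10.2857
slope std. error                        0.1856
intercept                             -21.0000
R                                       0.9998
KS distance                             0.0089
==============================================
249500 ordered Jaccard records; Pearson r = -0.864 (p = 0.0e+00)
```

Reading the numbers: at push rate 1 a 2^12-cell tumour takes exactly 12
generations. The fitted effective mutation rate 10.29 recovers the true
λ = 10 from the cumulative VAF curve (KS distance ≈ 0.01: essentially
linear, as neutral exponential growth predicts). The 500 samples of 100
cells yield 500·499 = 249,500 ordered pairwise Jaccard records whose strong
negative distance correlation quantifies how heterogeneity accumulates over
space. Rerunning at `push_rate=0` makes the curve strongly non-linear (large
KS distance) and drives Jaccard to 0 at large distances.

The same analyses are available from the shell:

```bash
spatialith grow -p 1 --lambda 10 --size 16384 --seed 1 -o out/growth
spatialith ith  -p 0 --size 16384 -S 100 -n 500 --seed 1 -o out/ith
spatialith vaf  -p 1 --size 16384 --seed 1 -o out/vaf
spatialith fixture --n-samples 23 -o out/biopsy
spatialith run --push-rates 0,0.125,1 --sample-sizes 100,400 --replicates 3 -o out/sweep
```

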