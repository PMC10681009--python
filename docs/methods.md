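# Methods

## Growth model

Tumours grow from a single cell seeded at the centre of a square (2D) or
cubic (3D) lattice. Time advances in **synchronous generations**: every cell
alive at the start of a generation attempts one division, in uniformly
shuffled order, and daughters born within a generation first act in the
next one. A cell with at least one empty Moore neighbour (8 sites in 2D,
26 in 3D) always divides: one daughter keeps the site, the other occupies a
uniformly chosen empty neighbour. A fully enclosed cell divides with
probability *p* (the push rate) by creating space:

* **random-direction push** — a uniformly chosen Moore direction; the
  contiguous run of cells along that ray shifts outward one site, up to the
  first empty site on the ray;
* **shortest-path push** — the empty site nearest in Euclidean distance
  (ties uniform) is located by expanding Chebyshev rings; cells along a
  greedy sign-stepped Moore path (a discretised straight segment) shift one
  step toward it. A breadth-first-search path would conserve occupancy
  equally well; the straight-line discretisation is the choice made here.

Both products of a division are new genotype records with fresh ids (the
parent record is retired), so cell ids strictly encode birth order. There is
no cell death, migration or selection. Growth stops at the end of the first
generation in which the population reaches `target_size`, or at
`max_generations` (not an error — fixed-duration surface-growth runs are
expressed this way).

The lattice side is `4 * ceil(target_size**(1/dim)) + 3` with a sentinel
border ring; a push reaching the border raises an error rather than
clamping. A single seeded `numpy` generator drives all stochastic choices in
a documented order (per generation: shuffle, per-cell placement/push-gate/
push-direction uniforms, batched Poisson draws), so a configuration replays
bit-identically.

**Update-order caveat.** Within-generation ordering is not an innocuous
detail: with everything else fixed, the mean population after 100
surface-growth generations ranges from ≈21,000 (simultaneous intents,
conflicts fail) through ≈31,000 (uniformly shuffled, the convention here) to
≈37,000 (oldest first). Published figures from models of this family can
therefore differ by ±20% in absolute cell counts while agreeing in every
qualitative pattern. The shuffled convention is kept because it is the
least-structured reading and reproduces exponential doubling exactly.

## Mutations

Each daughter draws k ~ Poisson(λ) new neutral mutations; λ defaults to 10,
the conventional order of magnitude for point mutations per division in
tumours. Mutation ids are sequential, so a cell's private mutations are a
contiguous range stored as `(start, count)`; genotypes are resolved through
the ancestry chain and never materialised per cell. The seed cell carries no
recorded mutations: truncal mutations would be clonal everywhere and are
excluded from all sub-clonal analyses anyway. Carrier counts are computed by
accumulating subtree sizes level-by-level over birth generations (vectorised
per level), giving exact spectra for any cell universe — the whole tumour or
one sample. Frequencies are **cell fractions** natively; the diploid VAF of
a heterozygous mutation is half the cell fraction.

## Sampling

Samples are axis-aligned boxes of side `s = round(S**(1/dim))` anchored on
uniformly drawn occupied sites and accepted only when fully occupied, so
every sample holds exactly `s**dim` cells (the standard sizes 100, 196, 400,
3600 are perfect squares). Boxes span `[c - s//2, c - s//2 + s)` per axis.
Samples may overlap at draw time; pair analyses filter to non-overlapping
pairs (box disjointness). Centre/margin classification puts a sample in the
central region when its centre lies within two-thirds of the tumour radius
R (max Euclidean distance from seed to any occupied site), boundary
inclusive. Note that Moore-neighbourhood surface growth yields squarish
clusters whose max-radius exceeds the disc-equivalent radius by ~13%, so the
central region holds ≈55% of cells rather than the 4/9 a perfect disc would
give.

## Jaccard ITH analysis

Sample mutation sets are presence-based (any carrier among member cells; an
optional within-sample frequency cut exists but is off by default, since the
index is defined on sets). Pairwise J = |A∩B|/|A∪B| is computed via a sparse
presence matrix product; J(∅,∅) = 0 by convention — after sub-clonal
filtering, two samples sharing nothing informative are maximally dissimilar,
not identical. Ordered pairing (n(n−1) records, e.g. 249,500 for 500
samples) is the default convention; the unordered option halves the table.
Trend summaries bin non-overlapping pairs into 20 equal-width distance bins
and report the Pearson correlation of J against distance.

Clonality filters: `whole_tumour_clonal` drops mutations at cell fraction
exactly 1; for biopsy tables, where purity rarely lets a clonal mutation
appear in literally every sample, `present_in_all_samples` and
`present_in_more_than_half_of_samples` drop columns by sample-presence
counts (strictly more than half excluded in the latter). Biopsy distances
can be normalised so the largest pairwise distance is 100 (the tissue
diameter), the convention of multi-region hepatocellular studies.

## Cumulative VAF inference

Under neutral exponential growth, M(f) — the number of mutations at
frequency ≥ f — is linear in 1/f with slope equal to the effective mutation
rate μ/β. The pipeline: (1) detection filter, dropping cell fractions below
0.01 (inclusive retention at the limit), mirroring realistic sequencing
sensitivity; (2) conversion to diploid VAF v = f_c/2 with f_max = 0.5 —
chosen because with per-daughter Poisson(λ) draws the generation-g daughters
contribute λ·2^g mutations at v = 2^−(g+1), making the expected curve
M(v) = λ(1/v − 2) and the slope exactly λ (the cell-fraction convention,
slope 2λ, remains available); (3) truncation of the 3 lowest-frequency
points, which are dominated by the detection limit; (4) OLS with a **free
intercept** — the theoretical intercept −(μ/β)/f_max is not imposed, so
truncation effects load on the intercept and not the rate estimate.

The linearity diagnostic normalises both the observed counts and the fitted
line by the maximum observed count over the fitted points and takes the
maximum absolute difference, clipped to [0, 1]. Only orderings of this
distance across push rates and sampling sizes are meaningful; its absolute
scale depends on the normalisation.

On a perfect binary tree with deterministic k = λ per daughter the fitted
slope is λ exactly and the distance is 0 — the closed-form oracle used in
the tests. At p = 1 with 2^14 cells the post-filter curve has six points
(cell fractions 2^−1 … 2^−6) and the fit uses the top three.

## Synthetic biopsy tables

The generator emulates a ~23-sample whole-exome multi-region study: samples
uniform in a disc, each sub-clonal mutation with a uniform origin point,
base prevalence q ~ U(0.2, 0.8), and presence probability
q·exp(−decay·distance); a configurable fraction of mutations is clonal.
`decay = 0` removes spatial structure (a null for the correlation
machinery); large decay makes sharing strictly local. It reproduces the
*sign* and *null* behaviour of real biopsy correlations, not sequencing
noise, copy-number effects, purity variation or realistic mutation counts —
passing tests on it validate the analysis plumbing, not biological claims.

## Experiment scale and defaults

Defaults are the standard study conditions: λ = 10, 2D, final size 2^14
cells, 500 sample locations, detection limit 0.01, 3-point truncation.
Validation suites run replicate counts of 20–100 and tumour sizes 2^10–2^14,
sizes at which every qualitative pattern (frequency halving per generation,
Jaccard decay and its ordering in p, KS-distance ordering, small-sample rate
overestimation) is already stable; the acceptance script uses the full 2^14
conditions. Per-run seeds derive from a single base seed (plan runs use
`base_seed + run_index`), and identical plans reproduce output tables byte
for byte.

## Known limitations

* No cell death or turnover: μ/β equals the per-division rate; spectra lack
  the drift-induced smearing death would add.
* No selection, no micro-environment, no sequencing noise or depth model.
* Absolute cell counts at fixed generation depend on the within-generation
  update order (see the caveat above); cross-implementation comparisons
  should match growth curves, not assume them.
* Shortest-path pushing searches Chebyshev rings exhaustively; it is
  markedly slower than random-direction pushing at high push rates and large
  sizes, and is intended for comparison studies at moderate scale.
* 3D runs are supported throughout but memory/time grow with the cube of
  the linear size; the 10^5-cell scale is practical, whole-organ scales are
  not.
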