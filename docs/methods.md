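# Methods

This note records the statistical procedure the package implements, the
choices made where the procedure was genuinely open, and what the
synthetic data can and cannot show.

## Design and estimands

The design is six single-channel oligoarrays: two biological replicates
each of a vector-control genotype (VC) and two transgenic genotypes
(PhaC, PhaBC) that both express the *phaC* transgene. The two transgenic
genotypes are pooled into one four-array treatment group for the primary
analysis (per-genotype runs are available through
`fold_change(..., treatment_lines=...)`).

**Gene expression.** Each gene is printed as several duplicate spots per
array. The gene's expression on an array is the arithmetic mean of its
passing spots; spots flagged failed and probes without a gene assignment
are excluded first, and a gene lacking a passing spot on any array is
dropped entirely (count logged). The mean is computed as an explicit
sequential sum divided by the count, so results are bit-reproducible.

**Fold change.** For gene *g* and treatment array *s*,
ratio(g, s) = x(g, s) / mean_c x(g, c) over the control arrays; the
gene's fold change is the arithmetic mean of its four ratios. Reading
"mean" as arithmetic (not geometric) and referencing a pooled control
mean (not per-replicate pairing) are deliberate choices; both are the
plainest readings of the procedure and are what the synthetic ground
truth encodes. Genes with non-positive control mean are dropped and
listed rather than assigned infinite ratios.

**Normalisation.** The array normalisation behind "normalized signal
values" is not specified anywhere upstream, so the package offers
`median-scale` (each array rescaled so its median equals the global
matrix median — monotone, scale-only, idempotent) and `none`. The
pipeline default is median-scale. Recovery experiments in the tests use
`none`, because the simulation plants no array-scale artifacts and
median scaling would only perturb a planted multiplier by the small
random shift of the treatment-array medians.

**GO-term expression score.** score(t) is the arithmetic mean fold
change over the measured genes carrying term *t*; a gene carrying k
terms contributes to all k. Consequence (used as a test invariant):
Σ_t score(t)·n_measured(t) = Σ_(g,t) FC(g) over gene–term incidences.
Scores are computed on the ratio scale (the literal "mean of the fold
changes"), not on a log scale. No hierarchy propagation and no
enrichment statistics: the score is descriptive. An optional seeded
permutation p-value (gene-label shuffling) exists but is off by default.
Classification is strict: up iff score > 2, down iff score < 0.5.

**Co-occurrence network.** count(a, b) = number of genes annotated with
both terms; by default over all annotated genes (a `measured` universe
is selectable). Each term selects its top-3 partners by count, ties
broken by descending count then ascending term identifier — the tie
rule is an implementation choice that makes outputs deterministic.
Edges are directed selections; the drawn graph is their undirected
union (a reciprocal selection draws one edge). Terms with exactly one
distinct co-occurrence partner move to a secondary "singleton" graph;
by default the rule is applied when building the BP map (it was
introduced for readability of that category) and can be extended to all
aspects. Node colour interpolates linearly in log2(score) between white
at score 1 and saturated red/blue; the saturation points 4 and 0.25 are
symmetric in log2 around 1 and sit one doubling beyond the 2 / 0.5
classification thresholds (configurable). Layout is Fruchterman–
Reingold with an explicit seed; coordinates are presentation only.

**Clustering.** Samples are compared by Euclidean distance over all
genes. The pipeline clusters log2-transformed normalised intensities:
on the raw scale a handful of bright genes dominates the 2,000–44,000
dimensional distance, and whether the original analysis used raw or
transformed values is unknowable — log2 is recorded here as the
package's default and is exposed as a flag. Agglomeration is Ward's
minimum-variance method in its squared-distance ("D2") form via the
Lance–Williams recurrence; the recorded merge height is the unsquared
merge distance, which equals sqrt(2·ΔESS) for the merged pair. Merge
ties are broken by the smallest pair of cluster indices. The
implementation is a direct O(n³) recurrence — n is the number of
arrays, at most a handful — and is cross-checked in the tests against
scipy's Ward linkage and against a naive oracle that re-computes
cluster variances from raw coordinates at every step.

**Newick serialisation** places each cluster at half its merge height,
so a child branch is (parent height − child height)/2 relative to merge
heights; a single merge of A, B at height 2 renders as `(A:1,B:1):0;`.
Parsing (via dendropy) inverts the convention and requires an
ultrametric, strictly binary tree.

**Volcano plot.** x = log2 of the fold change (the mean ratio);
y = −log10 p from a two-sided one-sample t-test of the four per-array
log2 ratios against 0 (df = 3). The upstream procedure names no test,
so this minimal choice is recorded in the plot metadata as a pipeline
default. Zero-variance genes get p = 1 when the mean log ratio is 0 and
the smallest positive double otherwise, flagged in the output.

## Synthetic data

The generator emulates the study inputs, not real array physics:

- **Annotation**: term counts per aspect (defaults 80 BP / 40 MF /
  30 CC), term sizes from a shaped log-uniform on [5, 60], rescaled so
  total incidences hit `terms_per_gene_mean` (default 3) × n_genes;
  members drawn uniformly without replacement, which produces the term
  overlap the co-occurrence network requires.
- **Intensities**: log2 intensity = baseline(g) + N(0, noise_sd_log2)
  per spot, with baseline ~ N(10, 1.5) in log2 fluorescence units and
  noise default 0.25; two duplicate spots per gene per array. The
  planted effect multiplies intensities on the linear scale, so
  noise-free runs recover planted multipliers *exactly* through the
  whole pipeline (a deliberate property used by the tests).
- **Signature**: `de_spec` plants per-term multipliers; a DE gene is
  shared between PhaC and PhaBC with probability `shared_fraction`
  (default 0.95, mirroring the observation that fewer than 5% of
  changed genes were PhaBC-specific) and is PhaBC-only otherwise.
  The default emulated study plants multipliers 4 and 3 (up) and 0.25
  and 0.4 (down) on four BP terms. Ground truth records every gene's
  per-line multiplier; the expected pooled score of a term is the mean
  over members of (mult_PhaC + mult_PhaBC)/2, since the pooled fold
  change averages equally many arrays of each line.
- **Scale**: defaults use 2,000 genes rather than the ~44k probes of
  the real arrays; the generator is configurable up to full size. All
  simulation-based checks in the tests and in `scripts/acceptance.py`
  use 1,000–2,000 genes, 20–200 repetitions per property.

Not modelled: spatial artifacts, dye effects, background, cross-
hybridisation, correlated noise between duplicate spots, or realistic
GO-term hierarchy. Passing tests therefore demonstrate correctness of
the *computations* and recoverability of planted signals under
log-normal noise — not robustness to real microarray artifacts.

## Numerical and degenerate-input conventions

- Spot averaging: sequential sum / count (bit-reproducible; matches an
  independent oracle exactly).
- Median scaling tolerance: column medians equal the global median to
  1e-9 relative; idempotent to 1e-12 relative.
- All random draws use `numpy.random.default_rng` seeded from the run
  configuration; set iteration never feeds a floating-point reduction
  (members are sorted first), so repeated runs are byte-identical
  across processes.
- Duplicate (probe, sample) pairs, missing columns, empty tables,
  non-positive values under median scaling, overlapping scatter groups
  and unknown GO terms (with near-match suggestions) all raise typed
  errors (`FormatError` / `ConfigError`).
- Regeneration efficiencies are rounded to three significant figures,
  the printed precision of the source counts. The packaged table
  includes the published efficiency columns; recomputation flags the
  two rows whose printed values disagree with their own counts
  (2/527 = 0.3795% prints as 0.379 instead of 0.380; 10/33 = 30.3%
  prints as 30.0) and never silently corrects them.

## Known limitations

- The co-occurrence count is O(genes × terms-per-gene²) and the
  brute-force checks are only feasible at test scale; at 44k genes the
  pair counting is still fast but the oracle comparison is not run.
- The Ward implementation targets sample clustering (few leaves); it is
  not meant for clustering thousands of genes.
- The permutation p-value is provided for exploration only and is not
  calibrated for multiple testing.
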