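# Methods

## Evaluation model

A bicluster is a pair of id sets `(genes, samples)`; a method's output is
an ordered list of biclusters.  Evaluation is split into a sample-based
view (does the method separate known sample types?) and a gene-based view
(do the gene sets recover externally annotated gene lists?).

### Sample differentiation

All set comparisons use the Dice/Sørensen coefficient
`s(A,B) = 2|A∩B|/(|A|+|B|)`.  It is symmetric, lies in `[0,1]`, and equals
1 only for exact set equality — note this is stricter than "the bicluster
contains the whole type": a bicluster strictly containing a type's samples
scores below 1 because the denominator counts its extra samples.  The
`k × t` matrix of bicluster-vs-type overlaps is reduced by greedy
matching: extract the global maximum, delete its row and column, repeat
until a dimension is exhausted.  The extracted values form a non-increasing
vector `V` of length `min(k,t)` and SampleDif is their mean.  Two
consequences are inherited from this literal definition: the matching is
greedy, not an optimal assignment (ties are broken deterministically by
lowest row index then lowest column index), and a method returning fewer
than `t` biclusters is averaged over only `min(k,t)` entries, which is
lenient toward small `k`; `sample_dif` logs a warning only for the
degenerate `k = 0` case, which is scored 0.

### Resampling significance of gene-set overlap

The observed Dice overlap between a bicluster's genes and a target set
(the union of the per-type tissue-specific lists) is compared against
`B = 1000` random gene sets of the same size drawn uniformly without
replacement from the expression universe (the genes of the preprocessed
matrix).  The p-value is `(1 + #{draws with overlap ≥ observed})/(B + 1)`:
the add-one correction keeps p in `[1/(B+1), 1]` and is conservative; a
strict-inequality variant (`strict=True`) implements the literal
"strictly higher overlaps" reading.  The per-method score is the fraction
of biclusters with `p < α`.

### Annotation enrichment with family-wise error control

Per category, enrichment is the upper hypergeometric tail
`P(X ≥ x)` for `X ~ Hypergeom(N, K, n)` with `N` the universe size, `K`
the category size and `n` the bicluster size (Fisher's exact one-sided
test).  Multiplicity over categories is handled by Westfall–Young minP
resampling: for each of `B` resamples a random gene set of the bicluster's
size is drawn and the minimum Fisher p over all categories recorded; the
adjusted p of a category is the (add-one-corrected) proportion of resample
minima at or below its raw p, followed by step-down monotonicity
enforcement in raw-p order.  The resample unit is a redrawn gene set (not
a permutation of gene labels), mirroring the Fisher null itself; since
category membership is fixed and only the drawn set varies, the two
formulations coincide here.  A bicluster counts as significant if its
minimum adjusted p is below α.

Defaults: `α = 0.05`, `B = 1000`.  Per-bicluster resampling seeds are
spawned from the benchmark seed via `numpy.random.SeedSequence`, so
results are reproducible and independent of evaluation order.

## Reference methods

**Cheng–Church.**  Mean squared residue of a submatrix:
`MSR = mean((e_ij − rowmean_i − colmean_j + mean)²)`.  One round runs
multiple node deletion (drop all rows/columns whose mean residue exceeds
`alpha_rate × MSR`, default 1.5), falling back to single deletion of the
worst row/column, until `MSR ≤ delta`; then node addition admits
rows/columns whose residue does not exceed the current MSR.  Discovered
cells are masked with Uniform(min, max) noise before the next round (the
original scheme's choice).  Because masking noise can leak into later
discoveries, a found submatrix whose MSR *on the original values* exceeds
delta is suppressed rather than returned — every emitted bicluster
therefore honours the delta ceiling under independent recomputation.  A
`1e-12` absolute slack on delta guards the `delta = 0` limit against
floating-point residue of exactly-additive matrices.  Known limitation
(inherent to the published greedy scheme, observed here on planted data):
a small high-signal block inside a large noise background has
*above*-average residue w.r.t. the full-matrix fit, so deletion removes
its rows first and the search settles on an overfitted noise submatrix;
the algorithm is faithful, not repaired.

**Bimax-style enumeration.**  Inclusion-maximal all-ones submatrices of a
binarized matrix are exactly the closed pairs (rows whose support covers
the column set; column set equal to the intersection of those supports).
Enumeration walks the lattice of row-support intersections with pruning
below the minimum column count and a cap on explored column sets
(`50 × max_results`, at least 5000) to bound the exponential worst case;
results are ordered by area, then lexicographically, for determinism.
Binarization is per-gene z-scoring (`1` iff `z > threshold`); a zero-SD
gene becomes an all-zero row with a logged warning.

**Constant-interval search (xMOTIF-flavoured).**  Each of `n_seeds` trials
draws a small discriminating sample set, keeps genes whose value range
over it is within `interval_width`, then greedily adds samples that keep
every kept gene inside a width-`interval_width` window.  Every returned
pair satisfies the window condition by construction; results are
de-duplicated and size-filtered.

**One-way adapters.**  k-means (scikit-learn, Euclidean, seeded, 10
restarts) or agglomerative clustering (scipy, correlation distance
`1 − r`, complete linkage, cut at `k`) partitions one axis; each cluster
becomes a bicluster spanning the full other axis.  Gene-based benchmarks
are uninformative for sample partitions (their gene set is the whole
universe) — the gene-overlap diagnostic flags this as 1.0.

**Result filtering.**  Biclusters under `min_genes × min_samples`
(default 10 × 10) are dropped; survivors are stably sorted by sample count
descending and truncated to `top_n` (default 40).  Idempotent.

## Synthetic data generator

`generate_multitissue_dataset` emulates a five-tissue bulk compendium:
group sizes default to 59/95/13/41/20 (228 samples; `desk_config()` scales
to 15/24/3/10/5 with 1000 genes for quick runs), background expression is
Normal(0, `noise_sd`²), and each type owns a signature module of
`signature_size` genes expressed with one of two planted archetypes:

- `constant_shift`: signature entries shifted by `effect_size` in that
  type's samples (a limited-variance block);
- `correlated`: entries `effect_size · a_g · p_s + b_g + noise` with a
  shared latent per-sample profile `p_s ~ N(0,1)`, loadings
  `a_g ~ U(0.5, 2)` and offsets `b_g ~ N(0,1)` — co-varying genes with
  heterogeneous amplitude.

The first `round(correlated_fraction · t)` types (declaration order) use
the correlated archetype.  Defaults: `signature_size = 100`,
`effect_size = 2`, `noise_sd = 1`, `correlated_fraction = 0.4` — a
signal-to-noise regime in which transcriptionally distinct tissues are
clearly recoverable but not trivial.  `overlap_fraction` re-uses that
fraction of a previous block's genes (and samples, for extra biclusters)
to emulate homogeneous-cohort data with overlapping programs; extra
non-type biclusters, uniform missing-value injection (after ground truth
is recorded), and annotation corruption (member dropout / spurious
additions) are available.  All randomness flows from a single
`numpy.random.default_rng(seed)` (PCG64), so outputs are bit-reproducible
for a given generator algorithm.

What the generator does *not* emulate: probe-level artifacts, cross-study
batch effects, heavy-tailed or count-distributed expression, structured
missingness, or correlated background genes.  Passing calibration tests
on this data therefore shows the statistics and bookkeeping are correct —
not that any method will perform comparably on real compendia.

## Pipeline and numerical conventions

The pipeline runs: drop genes with missing values (never impute) → discard
genes with across-sample variance below 1 (sample variance, `ddof = 1`;
"variance ≥ threshold keeps") → run/import methods → filter → benchmark →
report (TSV + JSON, with per-bicluster p-value tables).  Wall-clock
runtime per method is recorded as metadata only and is the single
non-deterministic report field.  The gene universe for all gene-based
statistics is the preprocessed matrix's gene list; bicluster gene sets are
intersected with it before testing.

Other conventions: empirical p-values never return 0; greedy ties break
lowest-index-first; filtering sorts are stable; identifiers are opaque
case-sensitive strings; the missing-value token defaults to `NA`.

## Problem sizes

Default test and acceptance runs use the quarter-scaled design (57
samples, 1000 genes, 50-gene signatures), 1000 resamples for calibration
checks, 500 random biclusters for null rejection and 200 for family-wise
error estimation — sizes chosen so Monte-Carlo error is well inside the
asserted binomial confidence bands while a full run stays in the
minutes range.
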