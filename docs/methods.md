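# Methods

This note records the models, conventions and numerical choices behind
`shapescreen`, in the spirit of a methods appendix: what is computed,
under which assumptions, and where the design was genuinely open.

## Shape distance and Z-score

Per-well distributions are normalized by subtracting the mean and
dividing by the **population** standard deviation (ddof = 0). The
population convention makes normalization exactly idempotent and makes
the normalize→moments identities exact; with ≥ 200 cells per well the
n vs n−1 distinction is immaterial. Constant (zero-variance) wells
cannot be normalized; they are excluded from scoring, reported in the
`excluded` field, and carry NaN scores.

The two-sample KS distance is evaluated exactly: both ECDFs are
right-continuous and the supremum is taken over every pooled data
point, so ties and discrete features need no approximation and no
asymptotic correction. The scaled statistic D* = √Nₑ·D with
1/Nₑ = 1/N₁ + 1/N₂ puts wells of different population sizes on a
common scale; it is used purely as a distance, never as a significance
test.

Slide scoring is a two-pass procedure. Pass 1: every designated
negative's D* vector against all wells is standardized (mean 0, sd 1
per row) and the preliminary Z is the column mean over all negative
rows. Pass 2: the `n_holdout` (default 10) negatives with the highest
preliminary Z — the "worst-scoring" negatives — are removed, the
matrix is re-formed from the retained negatives, rows re-standardized,
and the final Z is the column mean. The removal criterion (highest
preliminary column-mean Z over all 30 rows) is the most direct reading
of "worst-scoring"; it makes the held-out negatives an approximately
unbiased false-positive set, which is exactly what they are used for
downstream. A negative's row includes its own column (its D* against
itself is 0); the subsequent row standardization absorbs this, and the
choice is recorded here rather than made configurable-by-default.

Z-scores of typical wells concentrate well inside ±1 (a column mean of
~20 correlated standardized rows has sd < 1), so false-positive rates
of ~0.1 correspond to thresholds near 0, not near 1; TP/FP curves are
therefore fitted over threshold grids that extend below the hit-calling
threshold.

## Artifact diagnostics

Per-well moments use the standard central-moment definitions; skewness
is m₃/m₂^{3/2} and kurtosis is the **non-excess** Pearson form m₄/m₂²
(a normal has kurtosis 3). Both are affine-invariant, so the choice of
convention cannot change any diagnostic conclusion; it is recorded in
output metadata. The one-way ANOVA F comparing between- vs within-row
(or column, or slide) variability of a moment is reported
descriptively, without a p-value: the diagnostic contrast of interest
is that F for means/variances of intensity features is inflated by
positional artifacts while F for skewness/kurtosis is not.

The nonlinear-rescale check compares replicate negative wells after a
log or power pre-transform. If wells differ by affine maps with
nonzero offsets, plain normalization aligns them but log-then-normalize
does not; if they differ by a pure scale, log converts it to a shift
that normalization removes. Numerically, wells that are *identical* up
to an affine map collapse to a KS distance of at most a few ECDF steps
(O(1/n) from float rounding), not to exactly zero.

Partial normalization (mode `P`) rescales a well to the average mean
and average variance of its Chebyshev-ring-1 neighbors (the 8
surrounding wells; edge and corner wells use their existing 5 or 3).

## Triplicate mixture model

At threshold t a gene lands in bin k ∈ {0..3} by how many of its three
replicate Z-scores exceed t (strictly: z > t). The model: a fraction h
of genes are hits; hit g misses threshold per replicate with
probability β_g drawn from a normal(β₀, σ) truncated to [0, 1];
negatives exceed threshold independently with probability α. The
bracketed averages ⟨(1−β)^k β^{3−k}⟩ are cubic polynomials in β, so
they are computed **exactly** from the first three raw moments of the
truncated normal via the standard moment recurrence (no quadrature, no
Monte Carlo; smooth in the parameters, which the optimizer needs).
σ < 1e−10, or a truncation interval with underflowing mass, degrades
gracefully to a point mass at clip(β₀, 0, 1).

Fitting minimizes the summed squared difference between observed and
model bin *fractions* jointly across thresholds, with (α, β₀, σ) free
per threshold and h shared. h is profiled: for each candidate h the
per-threshold parameters are fitted by bounded least squares
(multi-start; heuristic starts from the per-replicate above-threshold
fraction plus seeded random restarts), and h minimizes the total
residual over a coarse grid (0 to 0.6 in 13 steps) refined by bounded
scalar minimization. Convergence is flagged on the profile optimizer;
fits from fewer than 3 thresholds are flagged under-determined (4 bins
are 3 degrees of freedom against 4 unknowns).

**Identifiability.** With data generated exactly from the model the
joint problem has a *continuum* of exact least-squares optima: at fixed
h the map (α, β₀, σ) → bin fractions is locally onto, so an interval
of h values around the truth attains zero residual, with the
per-threshold parameters compensating. The estimator therefore breaks
exact ties toward the smallest h (a parsimony convention: the fewest
hits that explain the data), and its guarantee on noise-free data is
*functional* recovery — the fitted model reproduces the generating bin
probabilities — not parameter identity. On sampled data (10⁴ genes)
the degeneracy disappears in practice and h, α, β₀, σ are recovered
within a few percent; the package's validation relies on that noisy
regime, which is also the only regime real screens occupy.

The TP/FP curve reports FP = α(t) and the true-positive band
1 − β₀(t) ± σ(t) clipped to [0, 1]; the band width is a genuine claim
of the model — hits have a *distribution* of detectabilities — not a
confidence interval. TP at a requested FP (e.g. 0.1) is linear
interpolation along the fitted curve and is refused outside the fitted
α range.

## Hit calling and permutation band

A gene is a hit if ≥ 2 of 3 replicate Z-scores exceed the threshold
(strict inequality). Genes with fewer than 2 usable replicate scores
are excluded and logged. Under the null with per-replicate exceedance
α the rule's hit rate is 3α²(1−α) + α³ — the false-positive
suppression that motivates triplicates. The permutation band shuffles
gene labels independently *within each replicate*: this preserves each
replicate's Z-score multiset exactly while destroying gene-level
coherence, which is precisely what the band is meant to test. The band
is the per-threshold min/max hit count over 1000 permutations.

The reporting helpers follow the field's conventions: overlap of two
hit sets is compared with the independence expectation |A||B|/|U| (the
hypergeometric mean), and term enrichment uses the one-tailed Fisher
exact test (upper hypergeometric tail) with a permutation correction.
The correction is family-wise by default: term labels are permuted over
genes and a term's corrected p is the fraction of permutations whose
*minimum* raw p beats its observed raw p (add-one convention); a
per-term calibration is available behind a flag.

## Cell-state (classifier/output) analysis

Within each well, cells are ranked by the classifier feature and three
percentile windows are formed (A: 5–15%, B: 45–55%, C: 85–95%); the
score is y = (m_A − m_B)/(m_B − m_C) on the mean output per window.
Percentiles are computed per well (pooled percentiles are available for
the binned-response profile, whose 5 bins are plain quintiles with
per-bin counts reported). y is invariant under affine maps of the
output and under strictly monotone transforms of the classifier. When
the output is unrelated to the classifier, y is a ratio of two
near-zero noise terms — effectively heavy-tailed — so wells failing the
denominator guard (|m_B − m_C| ≤ 1e−6 × output sd) or with under 30
cells are dropped, summaries are medians over wells, and Δy (positive
median minus negative median) is always read against a label-shuffling
permutation null rather than an absolute scale.

## Synthetic screens

The simulator emulates the study design end-to-end: slides of 10 × 30
wells with 30 negative and 8 positive controls, 200–500 cells per
well, every slide design assayed in triplicate with an independently
scrambled (uniform random) well-to-gene assignment per replicate.

* **Families.** Intensity-like features are right-skewed continuous
  (gamma(2, 1) baseline). Geometry-like features are narrow/discrete:
  Poisson(4) counts plus an additive normal jitter (sd 0.3) standing
  for sub-resolution measurement noise — pure integer counts would
  make per-well normalization misalign the discrete atoms and place
  even baseline wells far apart in exact-ties KS distance, which real
  (jittered) geometric measurements do not do.
* **Perturbations are shape-only.** Responding cells are redrawn from
  a distribution matching the baseline mean and variance but differing
  in shape: a bimodal normal (modes 2 ± 1.35, sd 0.4) for the
  intensity feature and a two-point {2, 6} mixture (variance 4,
  matching Poisson(4)) for the count feature. Matching the first two
  moments makes the normalized-shape distance grow essentially
  linearly with penetrance; a location-shift perturbation would make
  post-normalization detectability non-monotone in penetrance, which
  contradicts the intended dose-response structure.
* **Penetrance.** Hit genes draw a responding-cell fraction from a
  normal(0.5, 0.2) truncated to [0, 1]; positives come in three tiers
  (0.95 / 0.60 / 0.30). This induces a spectrum of per-gene TP rates
  for the power module to recover. At these settings a penetrance-0.5
  hit scores Z ≈ 2 and the single-replicate TP at Z = 3 is ≈ 0.3 — a
  deliberately conservative operating point.
* **Artifacts.** Affine per well: offset = row + column + slide
  effects (normal, sds 0.5/0.3/0.5), scale = product of log-normal
  effects (log-sds 0.15/0.10/0.15), applied to intensity features
  only. Artifact effect draws are unconditional, so artifact-on and
  artifact-off screens at the same seed contain identical cells.
* **Cell-state coupling.** Optionally, responding cells are the top
  penetrance-fraction by an (unperturbed) classifier feature instead
  of a uniform random subset, giving the Δy analysis a recoverable
  ground truth.

What the simulator does **not** emulate: image formation and
segmentation errors, cell-density/proliferation effects, spatial
correlation of cells within a well beyond the well-level artifact,
non-affine (e.g. saturating) measurement distortions, and any real
gene network structure. Passing tests therefore demonstrate
correctness and statistical behavior of the *method*, not biological
fidelity of any particular screen.

## Problem sizes and determinism

The validation suite runs at the study's design scale where the
property lives at that scale (full 300-well slides in triplicate for
band signatures and power comparisons; score-level simulations with
10⁴ genes for mixture-model recovery; 20 seeds wherever a rate over
screens is asserted) and at reduced scale (4 × 10-well slides, 80–120
cells) for orchestration and unit tests. The cell-state acceptance
uses two slide designs (48 positive / 180 negative wells) so the
median-based Δy statistic has adequate well counts. All randomness
flows through `numpy.random.default_rng` seeds; the pipeline derives
independent per-stage seeds by hashing the stage name, so stages can
be re-run alone and reproduce the full-pipeline output bit for bit.

## Known limitations

* The shape Z-score's scale depends on the negative-control count and
  inter-row correlation; thresholds are comparable within a screen,
  not across screens with different designs.
* The mixture model assumes replicate exchangeability and
  gene-independent α; plate-level batch structure that survives
  scoring would violate both.
* h is only partially identified from noise-free bin data (see
  Identifiability); reported h on small screens inherits a downward
  parsimony bias within the exact-fit interval.
* The Δy statistic is a ratio and is meaningless well-by-well; only
  its medians over ≥ dozens of wells, read against the permutation
  null, carry signal.
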