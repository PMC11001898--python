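# Methods

This note records the models, parameter choices and numerical conventions
behind `lungspan`, and what the synthetic-data tests do and do not
establish about real data.

## Data model and preprocessing

The pipeline operates on a genes×cells UMI count matrix with per-cell
sample, ordered life-stage group (T1 < T2 < T3 < T4 < T5) and cell-type
labels. Mitochondrial genes are recognised by a configurable symbol prefix
(default `MT-`; the mitochondrial gene list is a convention, not data, so
it is never inferred). Gene symbols match case-sensitively: silent case
folding hides data errors.

QC removes cells first, then genes: a cell is dropped when it has fewer
than 200 detected genes **or** more than 10% mitochondrial UMIs (the 10%
boundary itself is kept, reading "max" as an allowed maximum); afterwards
genes with total UMI ≤ 5 are dropped (strictly more than 5 retained).
Normalization is CP10K + natural log, with cell totals computed on the
post-filter gene universe, so downstream values always refer to the
retained transcriptome. The de-logged values of each cell sum to 10,000
by construction, which the tests assert to 1e-6.

## Transcriptional noise

Noise is the per-cell Euclidean distance to a reference profile in
log-normalized space. Two estimators:

* **Centroid variant** — distance to the arithmetic-mean vector of the
  cell's stratum over all genes. The stratum is either the cell type
  pooled over age groups, or cell type × group (default for the group
  summaries): with pooled centroids, age-dependent *mean shifts* leak into
  the distance, whereas per-group centroids isolate within-group
  dispersion. Both modes are exposed because either reading is defensible;
  strata with fewer than two cells are excluded with a warning (their
  distance is identically zero).
* **Invariant-gene variant** — genes with nonzero mean are ranked by mean
  abundance and split into 10 equally sized bins (any remainder going to
  the highest-abundance bins — an arbitrary but fixed convention); within
  each bin the genes with the lowest coefficient of variation (sample
  sd/mean, at least one per bin, default the lowest 10%) form the
  invariant set, and each cell's distance to the all-cell mean profile is
  computed over that set. "Invariant" is operationalised as lowest
  within-bin CV: CV is the standard scale-aware stability criterion.

Distances are computed on log-normalized values without per-gene scaling
or centering; no z-scoring is applied because the statistic is meant to
reflect the expression scale of the transcriptome.

An identifiability caveat that shapes the tests: for a gene with mean
count μ and NB dispersion φ, CV² ≈ 1/μ + φ. Below roughly one count per
cell the Poisson term dominates and *no* estimator can distinguish a
low-dispersion gene from its neighbours. The invariant-gene recovery test
therefore simulates deep coverage (~20k UMI/cell over 1,000 genes) so even
bottom-decile genes average a few counts; at shallow depth the recovery
ceiling is ~85% for structural, not algorithmic, reasons.

## Functional-module scores

`SC_j(i) = avg(Er(G_j, i)) − avg(Er(G_j^cont, i))` with `Er` the
log-normalized value. All matrix genes are placed into 25 equally sized
mean-expression bins; for each target gene, 100 control genes are drawn
uniformly without replacement from its bin (with replacement only when
the bin is smaller than the draw), excluding members of `G_j`; a bin
emptied by the exclusion falls back to the nearest non-empty bin with a
logged warning. The pooled draws (with multiplicity) form the control
average. Bin count 25 and 100 controls per gene are the conventional
defaults of this scoring scheme and are exposed as parameters. Because
both averages shift equally, adding a constant to a cell's expression
vector leaves the score unchanged — asserted as a property test. Er is
taken as the log-normalized value without further per-gene centering
(the formula-exact reading).

## Time-course modules

The clustering input is the per-group pseudobulk trajectory: the mean
log-normalized expression of each gene over the selected cells of each
group, z-scored per gene (constant trajectories are dropped with a
warning). Pseudobulk-then-z-score is the conventional time-course input
and makes patterns comparable across expression magnitudes.

Fuzzy c-means uses the standard alternating updates with fuzzifier
m = 2.0 and k = 6 modules by default, tolerance 1e-6 on the relative
objective change, at most 500 iterations, and 20 seeded restarts keeping
the lowest objective. Initial centroids are drawn by k-means++-style D²
sampling from the data rows: flat random memberships collapse every
centroid onto the grand mean, and uniform row picks frequently miss one
of several planted patterns. Exact centroid hits (zero distance) receive
membership one. The objective is non-increasing across iterations and
membership rows sum to one; both are asserted in tests.

Centroid trend labels use thresholded consecutive steps (ε = 0.1 on
z-scores): development_up = non-negative steps T1→T3 with at least one
positive; t3_peak = development_up plus non-positive steps T3→T5 with at
least one negative; aging_down = negative step T4→T5. Labels are
non-exclusive flags with primary precedence
t3_peak > development_up > aging_down > flat. The rule is a repository
convention for reading centroids, not a fitted model.

## Differential expression

Genes detected in ≥10% of cells in at least one group and with
|log₂FC| ≥ 0.25 are tested with the Welch (unequal-variance) two-sample
t-test on log-normalized values; Welch is the robust default when group
sizes differ. The fold change de-logs the group means first:
`log₂[(mean(expm1 x) + 1)/(mean(expm1 y) + 1)]`, the common single-cell
convention with a pseudocount of 1 guarding against empty means; the
pseudocount is a parameter. BH adjustment is applied over the tested
genes only. The disease-overlap filter selects genes with p < 0.05 and
log₂FC > 0.25 (one-sided on the fold change) and intersects them with
user-supplied gene lists.

The null-FDR calibration runs with both pre-filters disabled
(`min_pct=0, logfc_threshold=0`): selecting on the observed fold change
under a global null enriches for small p-values before BH sees them,
which makes the procedure anticonservative by construction; the
calibration is about the test + BH chain itself.

## Cohort statistics

Two-group comparisons follow the decision tree: Shapiro–Wilk per sample
(α = 0.05) and, when both samples pass, the variance-ratio test
F = s²_max/s²_min with a two-sided F p-value choose between the pooled t
(df = n₁+n₂−2), Welch t (Satterthwaite df) and Mann–Whitney
(exact enumeration when both n ≤ 20 and no ties, otherwise the
tie-corrected normal approximation). Summary-based t-tests computed from
(mean, SD, n) are algebraically identical to the raw-data pooled test,
which the suite verifies. The 2×2 chi-square uses the Yates continuity
correction, χ² = n(|ad−bc|−n/2)²/[(a+b)(c+d)(a+c)(b+d)], with any zero
marginal yielding p = 1 and a warning; it is cross-checked against the
cell-wise (|O−E|−0.5)²/E formulation and an independent library
implementation.

Dunnett many-to-one adjusted p-values are computed by seeded Monte Carlo:
the null maximum of the absolute correlated t statistics is sampled
(default 10⁵ replicates sharing one variance draw per replicate, which
reproduces the comparisons' correlation), the adjusted p is the
exceedance fraction with its Monte-Carlo standard error reported, and it
is floored at the unadjusted two-sided p, which it cannot undercut
analytically. Monte Carlo was chosen over multivariate-t quadrature for
simplicity with controlled, reported accuracy; agreement with an
independent quadrature implementation is asserted in tests to ±0.01.

## Score-gated correlation

The gated subset is the conjunction: cells in the requested groups
(default T4 and T5) whose **every** supplied score is strictly greater
than 0.01 ("upper than" read as strictly greater; boundary excluded).
Pearson r over that subset, with the two-sided p from
t = r√((n−2)/(1−r²)); fewer than three gated cells is an explicit error,
never a NaN.

## Synthetic data generator

Counts are Gamma–Poisson: gene g in cell c has mean
`base_g · pattern_g(rank) · marker_g(type) · s_c` and dispersion
`φ_g · κ_group`, with lognormal size factors s_c (σ = 0.35), Gamma base
means (shape 0.5, scale 2 by default), φ = 0.2, and κ = 2 for T5 only.
Defaults: 2,000 genes, 200 cells per group, three cell types (AT1/AT2/FB)
with 20 marker genes at 4-fold, 13 mitochondrial genes sized so the
expected mitochondrial share is 5% *after* accounting for program and
marker inflation of cell totals, three 100-gene temporal programs
(dev_up, t3_peak, aging_down; log-amplitude 2 on group rank), and an
FTL-like focal gene following dev_up-then-aging_down. Temporal patterns
are parameterized on group rank 1..5, not gestational weeks, because the
analysis itself only uses the five ordered groups.

Three deliberate design choices:

* **Dispersion inflation, not mean shift, implements aging noise** — it
  raises distance-to-centroid without moving centroids, isolating the
  noise statistic from differential expression.
* **Planted signals live in expressed genes.** Program genes, the focal
  gene, and two-group DE genes draw their base means from the
  above-median part of the base distribution: a fold change or trajectory
  planted on a gene with ~0 counts is not a recoverable signal, and
  uniform planting makes recovery tests measure the fixture rather than
  the method. Relatedly, recovery fixtures keep programs below ~5% of the
  transcriptome: a dominant rising program inflates cell totals enough
  that per-cell normalization visibly flattens its own trajectory
  (a compositional effect worth knowing about in real data too).
* **Planted score–gene correlations are exact on the gated cells.** The
  planted score is `loc + scale·(r₀·z(expr) + √(1−r₀²)·ε)`, affinely
  shifted so no cell falls below the 0.01 gate: gating on the score
  selects against low noise draws and would otherwise attenuate the
  gated-subset correlation below the nominal r₀ (Pearson r is invariant
  to the shift). Gate behaviour itself is tested separately with
  deliberately sub-gate scores.

Time-course module recovery uses profile-level planting (six z-scored
patterns plus N(0, σ=0.3) noise, flat genes scattered around the origin)
rather than the full count model, so the clustering test isolates the
solver from pseudobulk estimation error; pseudobulk correctness is tested
separately against the count-level generator.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, cell-type abundance shifts across groups, gene–gene correlation
beyond the planted programs, or the scale of a real atlas. Passing tests
therefore establish that the estimators recover what they claim under a
well-specified NB world at desk scale — not that real lungs behave this
way.

## Problem sizes and determinism

Monte-Carlo checks run at sizes chosen to make their conclusions stable:
100 seeds × (300 genes, 1,000 cells) for the noise ordering, 100
simulations of 2,000 genes × 400 cells for the null FDR, 100 datasets of
~1,040 gated cells for correlation recovery, 2,000 replicates against a
200,000-draw null for the Dunnett FWER. Every stochastic routine takes an
explicit integer seed (the pipeline treats a missing seed as a
configuration error), fixed seeds give bit-identical outputs, and the
run manifest records sha256 hashes of every stage output so reruns can be
verified byte-for-byte.

## Known limitations

* The noise estimators inherit CP10K/log geometry; distances are not
  variance-stabilised, so highly expressed genes dominate d(i).
* Invariant-gene selection cannot identify stable genes in the
  shot-noise regime (see above); on shallow data the invariant set is
  effectively "least-noisy given depth".
* Fuzzy c-means with m = 2 merges clusters separated by less than roughly
  their within-cluster spread; k is fixed by the user, and no model
  selection over k is attempted.
* Mann–Whitney p-values from printed medians/IQRs are not reconstructible;
  the raw-data routine exists for pipeline use only.
* Dunnett adjusted p-values carry Monte-Carlo error (reported per
  comparison); quadrature-exact values are out of scope.
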