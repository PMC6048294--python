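# Methods

## The ordination model

The package analyzes a nonnegative gene-by-sample abundance table
`X ∈ R^{p×m}` (counts, or log2 intensities floored at a detection
threshold) as a two-way contingency table. With grand total `n`, row masses
`r` and column masses `c`, the chi-square standardized residuals are

    P = X/n − r cᵀ,        S = Dr^{−1/2} P Dc^{−1/2},

and `‖S‖²_F` is the **total inertia** — the chi-square statistic of the
table divided by `n`. Plain correspondence analysis (CA) is the SVD of `S`.

**Canonically constrained CA (CCA)** restricts the analysis to the part of
`S` explained by per-row covariates `Z ∈ R^{p×k}` (each column standardized
to mean 0, variance 1). The projector is built from an orthonormal basis of

    B = Dr^{1/2} [1  Z],

i.e. a weighted least-squares regression of each column of `S` on `Z`
*with an intercept*. The intercept matters: the rows of `S` are centered in
the `Dr^{1/2}` metric (S ⊥ Dr^{1/2}1), not in the unweighted metric, so
without the intercept a full-rank standardized `Z` would *not* reproduce
plain CA. With it, the implementation agrees with the direct SVD of `S` to
machine precision and matches scikit-bio's (vegan-style) constrained CA
exactly (both checked in the test suite). Rank-deficient `Z` falls back to
the pseudo-inverse (a rank-revealing SVD of `B` with tolerance
`1e−10 · σ_max`) with a logged warning.

The SVD `S* = U Dα Vᵀ` retains `J = min(p−1, m−1, k)` axes with
eigenvalues `λ_j = α_j²`. Scores:

* **column (sample) scores** `Dc^{−1/2} V Dα` — principal coordinates, so
  Euclidean distances between them equal chi-square distances between
  column profiles (asserted against a brute-force computation);
* **row WA scores** `Gwa = Dr^{−1} P V Dα^{−1}` (and `Dr^{−1} P V` for
  `k = 1`), the weighted-average projection of the residual table onto the
  axes;
* **principal row scores** `Dr^{−1} P V`, the α-weighted form used wherever
  geometry (angles, centroids) matters — see below.

Sample scores are sometimes written with a `Dr^{−1/2}` factor, which is
not conformable (`V` has `m` rows while `Dr` is `p×p`); the `Dc` form
above is the standard CA column scaling and is the one whose distances
reproduce chi-square distances.

**Biplot values** are Dr-weighted Pearson correlations between each
covariate and the linear-combination row scores `Dr^{−1/2} u_j`,
equivalently the cosine of `u_j` with `d = Dr^{1/2}(z − mean_r(z))`. With a
single covariate this is exactly ±1, because the single constrained axis
*is* the covariate direction; the unweighted correlation of `Dr·z` with
`u_j` does not have this property under nonuniform row masses, which is why
the weighted form is used.

**Axis signs** are fixed deterministically (largest-magnitude entry of each
`u_j` made positive), so repeated runs are bit-identical. Consequently the
1D **activation score** — Axis-1 sample score times the sign of the single
biplot value — is *equivariant*: negating the covariate negates the score.
A high score always means positive correlation with the covariate as given.

**Gene-space partition.** With ≥2 axes, genes in the lowest quartile
(configurable) of Axis-1 WA scores form the activation-correlated set;
Axis-2 sign splits it into the Treg-shared (Axis 2 ≥ 0) and
Tmem/effector-associated (Axis 2 < 0) modules. Quantile-boundary ties stay
in the set; Axis-2 zeros go to the positive side.

## Explanatory variables from contrasts

A contrast of two sample groups on the log2 scale yields per-gene log2 fold
changes and t-type p-values: Welch's unequal-variance t, or a **moderated
t** in which gene-wise pooled variances are shrunk toward their mean with a
prior df `d0` solved by method of moments from the excess dispersion of the
variances (`Var(s²) = s0⁴(2/d + 2/d0)`; observed dispersion at or below the
chi-square expectation means complete shrinkage). This is an approximation
to full empirical-Bayes moderation — the prior scale is the mean variance
rather than a fitted scaled-inverse-chi-square — and is the default for the
recovery experiments; Welch is the assumption-light alternative. P-values
are BH-adjusted (statsmodels), and the suite checks BH against an
independent step-up computation exactly.

The explanatory variable keeps the log2FC of genes passing `FDR < 0.01`
and `|log2FC| > 1` (strict inequalities), zero elsewhere, then standardizes
the full-length column — so `Z` stays row-aligned with the main matrix. An
option restricts the analysis to the passing genes instead; `top_n` caps
the set by p-value rank (all passing genes by default, since no cutoff
count is canonical).

## Single-cell preprocessing

Cells are rows. Gene filtering removes genes that fail **both** a variance
and a maximal-value threshold (defaults: the 10th percentile of each
distribution — the data sets them, and the attrition report records the
outcome). In-silico gating keeps cells positive for every marker
(conjunction; default threshold 0, strict). Outlier removal embeds cells by
PCA (centered, unscaled), k-means clusters them (fixed seed, `n_init`
restarts), and drops the smallest cluster (or the farthest-centroid
cluster); removing more than 20% of cells is an error, never silent, and
equidistant-centroid ties keep everything. The "PCA plot" is read as the
cell-score space because the operation's purpose is excluding cells.

## Combinatorial selection of explanatory genes

When covariates are genes from the table itself, their columns are removed
from the main matrix (`X′`) and their expression becomes `Z` — the guard
against a covariate "explaining" its own column is an error, not a warning.
Cells whose remaining row sum is zero are dropped from both sides.

The tournament enumerates all unordered pairs of candidate genes (≤25 —
beyond that the exhaustive search is refused). Each pair defines one
two-covariate CCA, evaluated against every population one-vs-rest:

* the pair's **winner** for a population is the gene whose biplot arrow
  subtends the smaller angle to the population centroid;
* each gene's **F1** comes from a nearest-arrow classifier: predict a cell
  into the target population iff its score vector is closer in angle to the
  gene's arrow than to the competitor's *and* its projection on that arrow
  is positive.

Angles, centroids and classifications are computed in **principal
scaling** — cell scores `Dr^{−1} P V` and arrows `ρ_j·α_j` — restricted to
the first two axes. WA scores carry a `1/α_j` factor that gives a
near-degenerate axis (λ ≈ 0) the same visual spread as the dominant axis,
which makes angle comparisons meaningless; weighting by `α` restores each
axis's actual share of the dispersion, and in the noise-free limit a marker
expressed in exactly its population then classifies it with F1 = 1.0.

Per population, genes are ranked two ways: by mean F1 (ties → smaller mean
angle → lexicographic) and by mean angle. The angle ("most correlated")
ranking is the primary tournament statistic; when the two rankings
disagree the tool reports both and requires an explicit preference or a
manual choice — it never guesses. Candidate auto-selection ranks genes by
the projection of their score vector onto the population-centroid direction
(cosine alone is degenerate: near-zero noise genes pointing along the
centroid would outrank strongly loaded genes).

The final solution re-runs CCA with the selected genes (deduplicated, with
a warning) as covariates.

## Lineages and pseudotime

Cell scores are clustered by a Gaussian-mixture EM (scikit-learn, fixed
seed, `n_init` restarts; BIC selects K when a range is given). A Euclidean
minimum spanning tree over cluster centroids (Kruskal, lexicographic tie
break) gives the skeleton; the root is fixed by the user or chosen as the
centroid best cosine-aligned with a named covariate arrow (the
resting/naive pole). Lineages are root-to-leaf paths; clusters of degree ≥3
shared by ≥2 lineages are bifurcation points. A cell on a lineage (by
cluster membership, shared trunk clusters belonging to every lineage
through them) is orthogonally projected onto the piecewise-linear curve
through the lineage's ordered centroids; pseudotime is arc length from the
root, rescaled to [0, 1] per lineage (units are arbitrary). This is a
deliberate simplification of simultaneous principal curves: it is fully
specifiable and deterministic, at the cost of curvature smoothing —
piecewise-linear curves slightly distort pseudotime near sharp cluster
turns, and there is no shrinkage of branches toward each other near the
split.

Module trajectories z-score each member gene across cells (zero-variance
genes contribute 0), sum the z-scores per cell, and average within
equal-width pseudotime bins. Quadrant gates and Venn-region cardinalities
(≤5 sets) are exact tallies.

## Synthetic data: what it emulates and what it does not

The generators define the package's study conditions; their defaults are
fixed and all are pure functions of the seed.

**Bulk contrast** (microarray-like): 500 genes, 3 vs 3 replicates, log2
intensities with baseline ~ N(6, 1.5²), replicate noise SD 0.7, and 100
induced genes shifted by 4 noise-SDs (2.8 log2 units). The sizing comes
from a power analysis done before the tests were written: with 3 replicates
a 4-SD shift survives BH at 0.01 *and* the fold-change filter with ≥95%
mean sensitivity only when the affected fraction is substantial (~20%,
realistic for a strong activation response); at a 5% DEG fraction the same
effect yields ~92% and the stated sensitivity would be unattainable.
Genes undetected (all-zero after clipping) in either group are dropped from
both, keeping the universes aligned.

**Single cells**: negative-binomial counts (gamma-Poisson, dispersion 0.3 —
typical droplet-data overdispersion; `dispersion=None` is the noise-free
limit used for exactness checks), 500 cells in 4 equal populations, 300
genes. Each population carries one exclusive marker (mean 30 in its cells,
0 elsewhere), 4 decoys (3-fold elevated but expressed everywhere), and a
10-gene 3-fold signature; everything else is shared noise. The decoy fold
is deliberately below the point where decoys tie the exclusive marker —
decoys are meant to be plausible-but-inferior candidates.

**Branching scores**: cells uniform along a Y-shaped (or chain) polyline in
a 2D score space with isotropic Gaussian noise (SD 0.25 against arm
lengths of ~2–2.5), shared trunk between branches.

What the generators do *not* emulate: batch effects, doublets, ambient
RNA, library-size gradients, gene-gene correlation beyond the planted
blocks, and cross-platform variation. Passing tests therefore demonstrate
that the algorithms recover structure they are designed for under clean,
calibrated noise — not that any particular real dataset will behave as
well.

## Numerical choices

* Validation drops all-zero rows/columns iteratively (a dropped column can
  zero a row) with a logged count; negatives and duplicate ids are errors.
* Floor-to-zero semantics for the log2 detection threshold (default
  log2(10)): entries below the floor become 0, genes losing all entries are
  dropped. The alternative reading (gene-level max filter) is available
  through the single-cell gene filter.
* The constrained SVD is computed on the small matrix `TᵀS` (rank of the
  projector), which is exact and makes the pairwise tournament ~p/k times
  cheaper than a full SVD per pair.
* Tie rules: tournament angle ties break lexicographically by gene id;
  quantile-boundary genes stay in the activation set; Axis-2 zeros go to
  the positive module; activation-score boundary cells (score exactly 0)
  are labeled resting; marker positivity is strict (> 0).
* TSV I/O round-trips floats exactly (`float_precision="round_trip"` on
  read).
* All stochastic stages (k-means, EM, generators) require an explicit seed;
  there are no random defaults.

## Problem sizes in the checks

The suite and the acceptance script run desk-scale problems chosen to
exercise every code path while staying well-calibrated: 50–100 random
tables up to 20×10 for the algebraic identities, 20 seeded runs of the
500×300 four-population tournament (190 pairwise CCAs each), 20 seeded
branching-trajectory runs of 600 cells, and 50+50 contrast simulations for
the null/power calibration. The whole suite runs in well under a minute of
compute for the algebra and a few tens of seconds for the simulations.

## Known limitations

* The moderated t is a method-of-moments approximation, not a limma
  replacement; borderline genes near the FDR cutoff can differ from limma.
* The F1 classification rule inside the tournament is one defensible
  reading of "top-ranked by F1"; it is isolated behind the tournament
  interface so alternatives can be swapped.
* MST + piecewise-linear projection approximates smooth lineage curves;
  pseudotime near bifurcations inherits the skeleton's angularity.
* Probe-to-gene collapsing, CEL-file normalization, pathway enrichment and
  cross-species mapping beyond case-folding are out of scope; inputs are
  assumed to be gene-level tables.
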