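# Methods

## Model

Cells are modeled as Pareto-optimal mixtures of k archetypal phenotypes.
In a d-dimensional PC embedding, the data matrix X (d × n) is factored as

    X ≈ X · C · S,

with C (n × k) and S (k × n) nonnegative and column-stochastic.  The
archetypes Z = X·C are then convex combinations of cells — vertices of a
polytope inside the data's convex hull — and column i of S gives cell i's
mixture weights over archetypes.  The fit minimizes ‖X − XCS‖²_F by
alternating projected-gradient descent: each block update takes a gradient
step followed by Euclidean projection of every column onto the probability
simplex, with the step size halved until the residual does not increase, so
the SSE is non-increasing by construction.  Convergence is declared when
the relative SSE change drops below `tol` (default 1e-6); a `max_iter`
(default 500) stop sets a non-convergence flag.  Each fit is restarted from
several FurthestSum-seeded anchor sets (default 10; ties broken at the
lowest cell index) and the best final SSE wins.  Explained variance is
ev = 1 − SSE/SST with SST the mean-centered total variation, so the trivial
k = 1 fit (the centroid) has ev = 0.

The vertex-relaxation parameter δ (allowing column sums of C in
[1−δ, 1+δ], i.e. archetypes slightly outside the hull) defaults to 0, the
conservative choice; δ > 0 is available and solved by an exact per-column
scale step clipped to the allowed interval.

## Choosing k

k is scanned over 3–8.  Each k beyond the first also receives a nested
initialization built from the previous k's solution (previous vertices plus
the cell farthest from them), which makes the best-fit SSE non-increasing
in k and the EV curve non-decreasing.  The elbow rule picks the smallest k
whose EV gain at k+1 falls below an absolute threshold (default 0.02); if
no gain is small, k_max is returned with a flag.

Polytope significance uses the t-ratio: the volume of the archetype
polytope divided by the volume of the data's convex hull, both in the first
(k−1) coordinates (a k-vertex polytope has zero volume in ≥ k dimensions,
so the leading k−1 PCs are the natural space; polytope volume is the exact
simplex determinant, the data hull comes from Qhull).  Null datasets
permute each coordinate column independently across cells, preserving
marginals while destroying the joint simplex geometry.  Because archetypes
are constrained inside the hull (δ = 0), a tight simplex fit has t-ratio
near 1 while an elliptical null can only inscribe a relatively small
polytope, so significance is the upper tail: p = (1 + #{null t ≥ observed})
/ (1 + n_shuffles), with the add-one estimator avoiding p = 0.  Vertex
stability is quantified by bootstrap resampling of cells, refitting, and
optimal-assignment matching to the reference fit; the statistic is the
per-vertex mean displacement in PC units.

## Scores and specialists

For each archetype a, the score of cell i is 1 − (d_ia − min_i d_ia) /
(max_i d_ia − min_i d_ia), the per-archetype min–max standardized, inverted
Euclidean distance.  Min–max (rather than a z-score) keeps scores in
[0, 1], which is what makes an absolute enrichment cutoff such as
score > 0.8 meaningful; a z-score variant would not support that usage.
Specialists are cells whose score strictly exceeds that archetype's
percentile threshold (default 80th; 95th is sometimes used for stricter
display cuts and is exposed as the same parameter).  A cell passing several
thresholds is labeled with its highest-scoring archetype (ties → lowest
index) so labels partition the cells — proportion bookkeeping and fishplot
exports need a partition.

## Task annotation

Predictors are per-cell single-sample gene-set enrichment scores: genes are
ranked per cell by descending expression (average ranks on ties; running-sum
positions tie-broken by gene id), in-set mass accrues with rank weight
(N − position + 1)^α (α = 0.25) and out-of-set mass uniformly, and the
enrichment score is the summed difference of the two running fractions.
The statistic is rank-based and therefore invariant to monotone transforms
of a cell's expression.  This is the ssGSEA running-sum form, chosen over a
KS/ECDF kernel variant because it is a single fully specified formula and
the downstream regression only needs a monotone per-set score.

The multitask model regresses all k archetype-score columns jointly on the
z-scored enrichment matrix with a group-lasso penalty λΣⱼ‖Bⱼ·‖₂, so a
pathway is active in all responses or none.  Block coordinate descent with
the group soft-threshold runs down a 100-point log-spaced λ path from
λ_max = maxⱼ‖xⱼᵀY/n‖₂ with warm starts; 10-fold cross-validation selects
λ_1se, the largest λ whose mean held-out Frobenius MSE is within one
standard error of the minimum.  Active coefficient rows are clustered
(correlation distance 1 − r, average linkage; default 3 clusters — only
active rows are clustered, since zeroed pathways carry no signal) and each
cluster is assigned to the archetype with the largest mean coefficient.
The univariate pass fits a simple regression per pathway–archetype pair and
applies Benjamini–Hochberg FDR across all pairs (the procedure is BH
because only "FDR" is specified by convention).

## Subclones

Copy-number surrogates: per gene, log expression minus the mean over a
reference cell population; values clipped to ±3; a centered moving average
over 101 genes along each chromosome's gene order (window truncated at
chromosome ends); finally each cell is re-centered on its median.  Window,
cap and linkage follow common InferCNV practice and are configurable; no
numeric parity with any specific InferCNV release is claimed.  Cells are
grouped by Ward clustering of the profiles into a user-chosen number of
subclones m (cluster counts are a display/interpretation choice, not
inferred), labeled by decreasing size.  Archetype–subclone association is a
per-archetype one-way ANOVA of scores by cluster with Tukey HSD
(studentized-range) pairwise adjusted p-values.

## Dynamics and WGS table rules

Specialist proportions are per-sample fractions of each archetype label
plus non-specialists (summing to 1).  Cohort comparisons use the
pooled-variance two-sample Student's t test (pooled, not Welch, matching
the named test).  Mutation-group contrasts compute, per archetype, the
wild-type vs mutated difference with a Tukey adjustment whose family is the
full archetype × status set of cells, using the pooled within-cell mean
square — the contrast-extraction reading of "post hoc analysis of the ANOVA
model with mutation status as an interaction term".  "Single-sided" is
implemented as half the studentized-range tail when the difference is in
the alternative's direction (mutated > wild-type), 1 − tail/2 otherwise;
two-sided is available.  Copy-number z-scores are rounded half away from
zero, then ≥ 2 is a gain and ≤ −2 a loss.  Variant consensus keeps variants
seen by at least two callers with maximum VAF across callers ≥ 0.05 (the
maximum governs because no single caller's VAF is canonical).

## Synthetic data

The generator emulates the study's inputs: k disjoint 50-gene signature
sets elevated 4-fold in their archetype's program over a shared
gamma-distributed baseline; cell mixture weights Dirichlet(α·1) (α = 0.3
default — strongly vertex-concentrated populations); per-cell rates
library-factor × depth × mixture, with log-normal(0, 0.3²) library factors;
negative-binomial counts parameterized by mean and inverse-dispersion
(variance μ + μ²/dispersion, Poisson as dispersion → ∞); independent
dropout.  Longitudinal sampling draws a configurable specialist fraction
(default 80%) as Dirichlet draws conditioned on max weight > 0.8 (the
enrichment convention for specialist cells), assigned to archetypes at the
stated per-time frequencies, plus unconditioned interior cells.  CNV
subclones are planted by rescaling counts in contiguous gene blocks of
carrier cells — Poisson top-up for gains, binomial thinning for losses —
so the block mean scales exactly by the fold change.

What the generator does not emulate: batch effects and cross-sample
integration (multi-sample runs simply concatenate normalized matrices),
doublets, ambient RNA, cell-cycle structure, or realistic gene–gene
correlation beyond the archetype programs.  Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not robustness to those artifacts in real data.

## Normalization and preprocessing choices

QC keeps cells with ≥ 1000 expressed genes, ≥ 2000 UMIs and mitochondrial
percentage strictly below 25 (prefix-configurable, default `MT-`); the
tests at desk scale lower the two count thresholds to match simulated
depths.  Normalization scales each cell to the median library size and
applies log1p (a CPM-10k variant is available); the originally cited
normalization method could not be identified from its description, and the
downstream geometry depends only weakly on the variant.  Variable genes
are the top-n by raw variance of normalized values (simple and
reproducible; variance-stabilized residual ranking is deliberately not
implemented).  PCA is gene-centered with a deterministic sign convention
(largest-magnitude loading positive); archetype fitting uses the first
five PCs by default.

## Numerical notes and limitations

- Simplex projection is the exact sort-based algorithm, vectorized over
  columns.
- The t-ratio test refits each null with fewer restarts (3) and iterations
  (300) than the observed fit; nulls only need a representative best fit,
  and the add-one p keeps the test valid regardless.
- At count-matrix scale with strong negative-binomial noise and dropout,
  the EV elbow at threshold 0.02 may not trigger before k_max (each extra
  vertex keeps absorbing noise variance); the k-recovery guarantees in the
  test suite are stated for the latent-coordinate conditions (1,000 cells,
  2% noise), where selection is reliable.  On noisy small runs the scan
  reports the k_max flag and the t-ratio curve is the better guide.
- Specialist label invariance holds under affine rescaling of distances;
  general monotone transforms can reorder cross-archetype score
  comparisons and are not claimed.
- Problem sizes in the test suite and acceptance script (1,000-cell
  simplex scans, 200-shuffle randomization, 40-run calibration loops,
  600-cell subclone recovery) were chosen as the smallest sizes at which
  the corresponding statistics are stable.
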