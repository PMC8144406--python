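# scpareto

Pareto task inference for single-cell transcriptomes.

Tumor cell populations facing trade-offs between biological tasks are
expected to occupy low-dimensional polytopes in expression space: each
vertex (an *archetype*) is the phenotype optimal at one task, and every cell
is a mixture of archetypes. `scpareto` implements the full analysis around
this idea for scRNA-seq count data — as used, for example, to track how
specialist populations in high-grade serous ovarian cancer shift across
lines of therapy:

- **Archetypal analysis** by the principal convex hull algorithm (PCHA):
  factor the cell × PC matrix as X ≈ X·C·S with column-stochastic C, S, so
  the archetypes Z = X·C are vertices of a polytope inside the data's
  convex hull.
- **Model selection**: scan k = 3…8 vertices, pick the elbow of the
  explained-variance curve, and test polytope significance with the
  *t-ratio* (volume of the polytope over the volume of the data's convex
  hull) against column-shuffled nulls; bootstrap vertex uncertainty.
- **Archetype scores**: per archetype, the min–max standardized, inverted
  Euclidean distance of each cell to the vertex (1 = at the vertex);
  *specialists* are cells above a percentile threshold (default 80th).
- **Task annotation**: a multitask group lasso, (1/2n)‖Y − 1bᵀ − XB‖²_F +
  λΣⱼ‖Bⱼ·‖₂, regressing all archetype scores jointly on single-sample
  gene-set enrichment scores, with 10-fold CV and the one-standard-error
  rule; active coefficient rows are hierarchically clustered into task
  groups, plus a univariate pathway–archetype association table with BH FDR.
- **Subclones**: InferCNV-style expression-derived copy-number profiles
  (reference-centered, clipped, smoothed along the genome), Ward clustering
  into subclones, and ANOVA + Tukey HSD archetype–subclone association.
- **Dynamics**: specialist proportions per sample/time (fishplot-ready),
  cohort-shift Student's t tests, proportion and survival correlations,
  mutation-group Tukey contrasts, and tabular WGS filters (copy-number
  z classification, multi-caller variant consensus).
- **Synthetic data**: a generator with known ground truth — Dirichlet
  mixtures of archetypal expression programs, negative-binomial counts with
  library-size variation and dropout, drifting longitudinal proportions,
  and planted CNV subclones — so every stage is testable without downloads.

## Worked example

Recover a planted 3-archetype structure from 1,000 cells simulated as
Dirichlet(0.3) mixtures of 3 vertices in 5 dimensions with 2% noise:

```python
import numpy as np
from scpareto import (make_truth, simulate_latent, pca_project, scan_k,
                      select_k_elbow, t_ratio_test, score_cells,
                      classify_specialists)

truth = make_truth(k=3, n_genes=1000, d=5, alpha=0.3, seed=1)
X, W = simulate_latent(truth.vertex_coords, n_cells=1000, alpha=0.3,
                       noise_frac=0.02, seed=1)
pcs = pca_project(X.T, d=5)

scan = scan_k(pcs, k_min=3, k_max=8, restarts=5, seed=7)
k = select_k_elbow(scan, gain_threshold=0.02)
print("EV(k):", {r["k"]: round(r["ev"], 4) for r in scan.records})
print("chosen k =", k)

t, p = t_ratio_test(pcs, k, n_shuffles=200, seed=3)
print(f"t-ratio = {t:.3f}, randomization p = {p:.4f}")

table = classify_specialists(score_cells(pcs, scan.fits[k]), percentile=80)
print("specialists:", table.specialist_label.value_counts().to_dict())
```

prints

```
EV(k): {3: 0.9935, 4: 0.9945, 5: 0.9955, 6: 0.9963, 7: 0.9968, 8: 0.9969}
chosen k = 3
t-ratio = 0.805, randomization p = 0.0050
specialists: {'non-specialist': 400, 2: 200, 1: 200, 0: 200}
```

The explained-variance curve saturates at 3 vertices (the first gain below
0.02 is at k=3, so the elbow rule stops there), the fitted triangle covers
80% of the area of the data's convex hull in the leading two PCs — far more
than any of 200 column-shuffled nulls achieve, hence the minimal possible
p of 1/201 — and the 80th-percentile rule marks 200 of 1,000 cells as
candidate specialists per archetype.

A command-line interface mirrors the library
(`archetype simulate|qc|pca|select-k|fit|score|enrich|annotate|cnv|dynamics|run`);
`archetype run --config cfg.yaml --out rundir` executes the whole pipeline
from a YAML config and writes a manifest with parameters, seeds and
checksums.

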