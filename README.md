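# transst

Transfer-learning factor models with Potts-MRF spatial clustering for
spatial transcriptomics.

## The problem

Spatial transcriptomics measures, at each spot on a tissue section, an
expression vector over thousands of genes together with the spot's 2-D
coordinates — but sequencing depth per spot is shallow and the signal
noisy, so clustering spots into cell types from the target slide alone
is hard. Meanwhile, labeled external data (annotated scRNA-seq or
previously analyzed spatial sections) often exists for related tissue.
This package transfers what the labeled source knows about cell-type
structure into the clustering of an unlabeled spatial target.

It is aimed at computational biologists who have (a) a source
expression matrix with cell-type labels and (b) a target spot × gene
matrix with coordinates, and want spatially coherent cluster labels,
marker genes, and an estimate of the number of cell types.

## The model

Three stages, exposed as scikit-learn-style estimators and chained by
`TransST`:

1. **Supervised factor model** (`PLDR`). For source cell *i* with known
   label *z_i = k*:
   `x_i = W₀ u_i + ε_i`, `ε_i ~ N(0, Λ)` (Λ diagonal), and
   `u_i | z_i = k ~ N(μ_k, Σ_k)`. Fit by EM; because labels are known,
   the loading **W₀** (p × q) is learned in a supervised way and
   captures the directions that separate cell types.

2. **Penalized transfer** (`TransferFactorization`). The target
   embedding V and loading W minimize
   `Σ_i ‖x_tgt,i − W v_i‖² + λ‖W − Ŵ₀‖_F²`,
   by alternating least squares; λ is chosen by a two-fold
   reconstruction scheme (fit a loading on one half, score the held-out
   half by least squares, sum both directions).

3. **Spatial Gaussian mixture** (`SpatialGMM`). With
   `v_i | z_i = k ~ N(μ_k, Σ_k)` and a Potts Markov-random-field prior
   over labels on the 5-nearest-neighbor spot graph,
   `f(z) ∝ exp{−½ Σ_i Σ_{i'∈N_i} β (1 − I[z_i = z_{i'}])}`,
   fit by ICM-EM. β = 0 recovers the plain Gaussian mixture; β ∈ [0, 1]
   is chosen by a pseudo-likelihood line search, and the number of
   clusters by a modified BIC.

A Potts-field simulation engine (`transst.simulate`) generates matched
source/target benchmarks with planted marker genes, so the whole
pipeline can be validated end to end without external downloads.

## Worked example

```python
from transst import SimConfig, TransST, adjusted_rand_index, find_markers, simulate_dataset

cfg = SimConfig(grid_height=20, grid_width=20, p=60, n_source=600, seed=21,
                beta_true=1.2, marker_scale=3.0, noise_e=0.25)
data = simulate_dataset(cfg)

est = TransST(n_components=5, n_clusters=4, random_state=21)
est.fit(data.target_expr, coords=data.coords,
        source_X=data.source.expr, source_y=data.source.labels)

print(f"selected lambda: {est.lambda_:g}")
print(f"selected beta:   {est.beta_:g}")
print(f"ARI vs truth:    {adjusted_rand_index(est.labels_, data.true_labels):.3f}")
```

Output:

```
selected lambda: 100
selected beta:   0.8
ARI vs truth:    0.958
```

The two-fold scheme picks the strongest penalty (λ = 100): the target
is generated from the same loading as the source, so pulling W all the
way to Ŵ₀ reconstructs held-out spots best. The line search picks
β = 0.8 — the simulated label field is spatially smooth, and the
adjusted Rand index of 0.958 against the true labels means near-perfect
recovery up to label permutation. Marker detection on the inferred
labels then recovers the planted markers (cluster ids are arbitrary,
so each estimated cluster's top marker is one of its true cluster's
planted genes):

```python
markers = find_markers(data.target_expr, est.labels_)
```

```
top marker per cluster:
  cluster 1: gene3  (lfc=8.88, adj. p=6.03e-59)
  cluster 2: gene5  (lfc=10.10, adj. p=1.25e-19)
  cluster 3: gene2  (lfc=9.06, adj. p=1.22e-49)
  cluster 4: gene1  (lfc=10.20, adj. p=2.92e-15)
```

A command-line interface mirrors the library:
`transst simulate`, `transst run`, `transst evaluate`, `transst markers`.

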