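# hyperjnmf

Hypergraph-regularized joint non-negative matrix factorization for fusing
two feature matrices measured on the same samples — e.g. radiomic texture
features from abdominal radiographs and routine clinical laboratory values
in neonates evaluated for necrotizing enterocolitis (NEC), where the goal
is to find cross-modality feature modules that separate surgical from
non-surgical patients.

## The model

Given non-negative matrices `X1 (n × p1)` and `X2 (n × p2)` over the same
`n` samples, the package factorizes both against one shared basis,

    X1 ≈ W H1,   X2 ≈ W H2,      W ≥ 0 (n × K),  Hi ≥ 0 (K × pi),

by minimizing

    F(W, H1, H2) = Σᵢ ‖Xᵢ − W Hᵢ‖²_Ω                 diagnosis-weighted fit
                 − α · tr(H1 A H2ᵀ)                   cross-modality adjacency reward
                 + Σᵢ λᵢ · tr(Hᵢ Bᵢ Hᵢᵀ)              hypergraph smoothness
                 + Σᵢ βᵢ · ‖Hᵢ Hᵢᵀ − I_K‖²_F          soft orthogonality
                 + γ₁‖W‖₁ + γ₂(‖H1‖₁ + ‖H2‖₁)         sparsity

where `Ω = diag(d²)` up-weights surgical samples (diagnosis code `d ∈ {1, 2}`),
`A` links cross-modality feature pairs with high absolute Pearson
correlation, and `Bᵢ = D_v − H W_e D_e⁻¹ Hᵀ` is the (simple) Laplacian of a
k-nearest-neighbor feature hypergraph, which smooths coefficients over
whole feature neighborhoods rather than pairwise edges. Optimization uses
multiplicative Karush–Kuhn–Tucker updates — each factor is multiplied
elementwise by the ratio of the negative to the positive part of its
gradient — which preserve non-negativity exactly and decrease `F`
monotonically. Setting every constraint weight to zero recovers plain
joint NMF (`jnmf_fit`), the published baseline.

Each factorization dimension defines a *coexpression module*: features
whose row-wise z-scored coefficient exceeds a threshold `T` are its
members, modules are ranked by the Pearson correlation between their
member submatrix and its rank-1 reconstruction, and the top module feeds
a random-forest / SVM / logistic-regression surgery classifier evaluated
by ROC/AUC on a stratified 75/25 split.

## Worked example

Plant one correlated cross-modality feature block in synthetic data, fit
the constrained model, and mine it back:

```python
import hyperjnmf as hj

cfg = hj.SyntheticConfig(n_samples=60, p1=40, p2=40, K=5, noise_level=1.0, seed=0,
                         planted=hj.PlantedSpec(n_blocks=1, block_size1=10, block_size2=10))
ds = hj.generate_planted(cfg)
x1 = hj.standardize_columns(ds.x1)
x2 = hj.standardize_columns(ds.x2)
adj = hj.build_cross_adjacency(x1, x2, threshold=0.5)
lap1 = hj.hypergraph_laplacian(hj.build_knn_hypergraph(x1, k_neighbors=5))
lap2 = hj.hypergraph_laplacian(hj.build_knn_hypergraph(x2, k_neighbors=5))
params = hj.FactorizationParams(K=5, alpha=0.1, lambda1=0.001, lambda2=0.001,
                                beta1=0.1, beta2=0.1, gamma1=0.001, gamma2=0.1,
                                max_iter=300)
res = hj.fit(x1, x2, ds.labels, adj, lap1, lap2, params)
print(f"converged: {res.converged} after {res.n_iter} iterations")
print(f"relative reconstruction error: {res.relative_error_trace[-1]:.4f}")
modules = hj.rank_modules(x1, x2, res, T=1.0)
print(f"best module: {modules.best_module}, mean Pearson r = "
      f"{modules.scores['mean'][modules.best_module]:.4f}")
print(f"members (modality 1): {[int(j) for j in modules.members1[modules.best_module]]}")
print(f"planted block       : {[int(j) for j in ds.truth_members1[0]]}")
```

prints

```
converged: False after 300 iterations
relative reconstruction error: 0.0757
best module: 0, mean Pearson r = 0.9683
members (modality 1): [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
planted block       : [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
```

The fit exhausts its 300-iteration budget (the tolerance is strict), but
the residual 7.6% is dominated by the injected noise; the module ranked
best by mean reconstruction correlation recovers the planted 10-feature
block exactly in both modalities.

The same pipeline is available from the shell:

```sh
hyperjnmf synth --out data --n-samples 60 --p1 40 --p2 40 --k 5 --noise-level 1 --seed 0
hyperjnmf fit --x1 data/x1.csv --x2 data/x2.csv --labels data/labels.csv \
              --config cfg.json --out result
hyperjnmf modules --x1 data/x1.csv --x2 data/x2.csv --result result --T 1.0 --out modules
hyperjnmf grid --x1 data/x1.csv --x2 data/x2.csv --out grid.csv        # 243 combinations
hyperjnmf classify --features feats.csv --labels data/labels.csv
```

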