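# Methods

## Model

Two non-negative sample-by-feature matrices `X1 (n × p1)`, `X2 (n × p2)`
over the same cohort are jointly factorized as `Xi ≈ W Hi` with a shared
basis `W ≥ 0 (n × K)` and modality-specific coefficients `Hi ≥ 0 (K × pi)`.
Columns of each input are first scaled to unit Euclidean norm
(`standardize_columns`) so that the regularizers act on comparable feature
scales; all-zero columns are left at zero and reported.

The full objective is

    F = Σᵢ tr((Xᵢ − W Hᵢ)ᵀ Ω (Xᵢ − W Hᵢ))
      − α tr(H1 A H2ᵀ)
      + Σᵢ λᵢ tr(Hᵢ Bᵢ Hᵢᵀ)
      + Σᵢ βᵢ ‖Hᵢ Hᵢᵀ − I_K‖²_F
      + γ₁‖W‖₁ + γ₂(‖H1‖₁ + ‖H2‖₁)

with the following ingredients.

**Diagnosis weighting Ω.** Surgery status is coded 1 (non-surgical) /
2 (surgical). The code enters as a per-sample weight in the quadratic
reconstruction form, `Ω = diag(d²)` by default, so surgical patients count
4:1; `sample_weighting="linear"` gives `diag(d)` (2:1). The weighting
steers the shared basis toward features that reconstruct the surgical
group well, i.e. toward diagnostically differential structure. With all
labels equal the weighting is inert.

**Cross-modality adjacency A.** `build_cross_adjacency` links feature
pair (j, k) across modalities when |Pearson r| ≥ 0.5 (binary by default;
thresholded |r| optionally). The `−α tr(H1 A H2ᵀ)` term *rewards* linked
pairs for loading on the same components, the standard network
regularization in joint-NMF pipelines. Constant features correlate 0 by
convention, keeping A finite and non-negative. Note the term is unbounded
below on its own: α > 0 with every other penalty at zero lets the
coefficients grow without limit. The grid search records such diverged
cells as non-converged rather than failing.

**Hypergraph smoothness Bᵢ.** Features are vertices described by their
n-dimensional sample profiles. Each feature seeds one hyperedge containing
itself and its k = 5 nearest neighbors (Euclidean; ties broken by
ascending index), weighted by the heat kernel
`a(e_v) = Σ_{u∈e_v} exp(−dist(v,u)²/σ²)` with σ = mean pairwise distance
("auto"). The regularizer is the simple hypergraph Laplacian
`L = D_v − H W_e D_e⁻¹ Hᵀ`; it is symmetric, positive semi-definite, has
zero row sums, scales linearly in the edge weights, and reduces to half
the ordinary graph Laplacian when every hyperedge has two vertices and
unit weight — all verified in the test suite. A degree-normalized variant
sits behind `normalized=True`. The construction details (k, weights) are
conventions of the hypergraph-NMF literature, not fixed by the source
method; they are exposed as configuration.

**Soft orthogonality.** `‖HᵢHᵢᵀ − I‖²_F` discourages redundant modules
without imposing a hard Stiefel constraint, keeping the problem compatible
with multiplicative updates.

**Sparsity.** γ₁ penalizes ‖W‖₁; γ₂ penalizes ‖H1‖₁ + ‖H2‖₁ jointly. This
assignment yields exactly three all-ones subgradient matrices in the
update rules (one for W, one per Hᵢ).

## Optimization

Updates are multiplicative KKT rules: each factor is multiplied
elementwise by (negative gradient part) / (positive gradient part + ε),
with ε = 1e-12 guarding the division. The Laplacian enters through its
split `B = B⁺ − B⁻` with `B⁺ = D_v` (diagonal) and `B⁻ = H W_e D_e⁻¹ Hᵀ`
(entrywise non-negative), so both ratio parts stay non-negative and
non-negativity of the factors is preserved exactly. W is updated first and
the fresh W feeds the H updates (Gauss–Seidel order); H2's cross term uses
the freshly updated H1.

The numerator/denominator split is derived term-by-term from the gradient
of the objective above, so the recorded objective trace is the quantity
the updates provably descend; the test suite asserts a non-increasing
trace (relative slack 1e-8) across 50 constrained runs, and approximate
KKT stationarity (`max min(factor, |grad|) < 1e-3`) at convergence on
small standardized instances. One subtlety: the L1 subgradient enters the
denominator at its full weight γ (not γ/2), matching the 2× factor the
smooth terms carry in the gradient; a formulation that halves the smooth
parts but keeps γ whole would silently optimize a doubled sparsity weight
and lose the monotonicity guarantee with respect to the reported
objective.

Iteration stops when the relative objective change drops below `tol`
(default 1e-6) or at `max_iter` (default 500; fixed-budget comparisons use
100 with tol disabled). Non-convergence returns a result flagged
`converged=False`; only non-finite blow-ups raise.

**Initialization.** Non-negative double SVD (NNDSVD) of the concatenated
matrix `[X1 | X2]`, splitting each of the leading K singular triplets into
its positive/negative parts and keeping the dominant pair. Zeros are then
filled with `sqrt(mean([X1|X2])/K)` — the magnitude of a well-scaled
factor entry — rather than the raw data mean: multiplicative updates can
never revive an exact zero, and a raw-mean fill inflates the initial
product by roughly K·mean when the data mean is large (the integer
benchmark has mean ≈ 30·K), which would start the optimization from a
reconstruction worse than random. A seeded uniform `random` strategy is
available; paired runs in the tests confirm the SVD start dominates it in
median final error.

## Model selection

The tuning grid takes every combination of (α, λ, β, γ₁, γ₂) over
{0.001, 0.01, 0.1} with λ₁=λ₂ and β₁=β₂ tied — 3⁵ = 243 combinations,
enumerated in odometer order with α slowest. Every cell is fitted from the
same SVD initialization at fixed K (default 15) and scored by relative
reconstruction error

    err = sqrt( Σᵢ ‖Xᵢ − W Hᵢ‖²_F / Σᵢ ‖Xᵢ‖²_F ).

Cells whose objective blows up are recorded as non-converged (error
missing; plotted as 0 in the grid figure, following the convention of
blanking non-convergent combinations) and excluded from the argmin. The K
sweep refits over K = 2..n with fresh initializations; raw error is
minimized at the largest K on real data, so `chosen_K` reproduces that
rule while `elbow_K` (largest second difference of the error curve) is
reported as a clearly-advisory extension.

## Module mining

For each coefficient row i, `z_ij = (h_ij − mean_i) / sd_i` with the
population (divide-by-p) standard deviation; feature j is a member of
module i iff `z_ij > T` (one-sided; default T = 1.0 — neither the sd
convention nor T is fixed by the source method). Constant rows yield empty
modules with a warning. Modules are ranked by the Pearson correlation
between the flattened member submatrix `X_i[:, members]` and its rank-1
reconstruction `W[:,m] · H_i[m, members]`, averaged over modalities;
one-sided-empty modules are scored on the populated side and flagged. The
best module's members feed a cross-modality correlation table and a
top-10-pairs list ranked by |r|.

## Synthetic benchmark

`generate` draws `W ~ U{1..10} (n × K)`, `Hi ~ U{1..10} (K × pi)` and
emits `Xi = W Hi + l·η` (η i.i.d. standard normal, level l), clipped at 0;
with factors ≥ 1 every noiseless entry is ≥ K, so clipping is negligible
at the default levels {0, 1, 2, 5, 10}. Defaults are n = 100, p1 = p2 =
100, K = 45. Labels are drawn 1/2 at 50% prevalence, independent of the
matrices — they deliberately carry no structure. `generate_planted` lays
disjoint feature blocks (coefficients U(5,10) against a U(0,1) background)
on dedicated components with ground-truth membership returned for Jaccard
scoring.

What the generator does *not* emulate: real radiomic/clinical marginals,
feature-scale heterogeneity, label-linked effect structure, or missing
data. Passing tests therefore establish algorithmic correctness and
recovery behaviour under the stated generative model, not clinical
performance.

## Evaluation

`compare_algorithms` runs the plain baseline and the constrained model for
exactly the same iteration budget (100) from the same SVD start and
reports relative error and the common l1 norm ‖W‖₁+‖H1‖₁+‖H2‖₁. On the
synthetic benchmark the comparison runs without diagnosis weighting, since
the generator's labels are structure-free by design. A negative finding,
reported as measured: with the selected weight combination the constrained
model's l1 norm is smaller than the baseline's in every seed at every
noise level, but its reconstruction error against the noisy input is
consistently *larger* — the unconstrained fit minimizes exactly that
error, and both algorithms effectively converge within the budget, so any
active penalty must measure worse on it. The win fractions for both
metrics are reported exactly as measured by the acceptance script.

`classify_patients` takes any sample-by-feature matrix (module-selected
raw features by default; W rows work too), makes a stratified seeded
75/25 split, grid-searches a small fixed hyperparameter set by 3-fold CV
on the training part (random forest: trees {100, 300}, depth {None, 3, 5};
RBF-SVM: C {0.1, 1, 10}, γ {scale, 0.1}; logistic: C {0.1, 1, 10}; all
behind a standardizing pipeline), and reports the test-set ROC and AUC
with label 2 (surgical) positive. Sanity anchors: perfectly separable
features reach AUC 1.0; permuted labels sit at chance in the median.

## Problem sizes and tolerances

The test and acceptance runs use scaled-down study conditions chosen once:
benchmark recovery and the noise comparison at n = 50, p = 50, K = 10
(10 and 20 seeds); monotonicity at 20×15 / 20×12, K = 5, 50 runs;
planted-module recovery at n = 60, pᵢ = 40, K = 5, one 10-feature block
per modality, l = 1, T = 1.0 (10 seeds). Monotonicity slack 1e-8
(relative), Laplacian PSD slack −1e-9, standardization tolerance 1e-9,
division guard 1e-12.

## Known limitations

- Exactly two modalities; the three-matrix generalization is out of scope.
- The adjacency construction, hypergraph recipe and NNDSVD zero-fill are
  literature conventions, configurable but not canonical.
- Multiplicative updates stall near zeros; final noiseless errors plateau
  around 1–3% rather than machine precision.
- Raw-error rank selection degenerates to K = n by construction; use the
  advisory elbow for an honest rank estimate.
- The adjacency reward makes the objective unbounded below for α > 0 when
  every balancing penalty is zero; such settings diverge and are reported,
  not repaired.
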