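# Methods

## Model and objective

Given responses `y ∈ R^n` and a design `X ∈ R^{n×m}` (no intercept), the
package estimates the sparse linear model `y = Xθ + ε`, `ε ~ N(0, σ²I)`, by
minimizing the L0-penalized least-squares objective

    E(θ) = ½‖y − Xθ‖² + (λ/2)‖θ‖₀ ,

where `‖θ‖₀` counts nonzero coefficients. This is best-subset selection:
minimizing E exactly is NP-hard, so the package uses a fixed-point (EM-style)
approximation. Writing the penalty as `(λ/2)Σ_{j∈R} θ_j²/η_j²` with an
auxiliary vector η and the support `R = {j : θ_j ≠ 0}`, the stationarity
conditions give the two-step iteration

    θ ← (D XᵀX + λI_m)⁻¹ D Xᵀy ,   D = diag(η²)      (M-step)
    η ← θ                                             (E-step)

Small coefficients are driven toward zero super-linearly (the effective
per-coefficient penalty is λ/(2η_j²), which diverges as η_j → 0); entries
whose magnitude falls below `zero_eps` are set to exact zero and the zero is
absorbing — the active set only shrinks. The converged θ satisfies
`x_jᵀ(y − Xθ) = λ/θ_j` on its support, so it is close to (but not exactly)
the least-squares refit on that support; the residual correlation λ/θ_j is
the price of the smooth surrogate.

For `n ≪ m` the algebraically identical dual iteration

    θ ← D Xᵀ (X D Xᵀ + λI_n)⁻¹ y

solves an n×n system instead (the push-through identity makes the two forms
equal; a property test checks agreement to 1e-8 across random sizes).

Both forms are implemented as a single loop that restricts each solve to the
current active columns: with `W = diag(|η|^{(2−p)/2})` the primal step solves
the symmetric positive-definite system `(W XᵀX W + λI)z = W Xᵀy`, `θ = Wz`,
via Cholesky; the dual step factors `X_A W² X_Aᵀ + λI_n`.

### What the iteration actually selects

Under an orthonormal design (`XᵀX = I`, `z = Xᵀy`) the coordinates decouple
and the scalar map `t ← t²z/(t² + λ)` has fixed points 0 and
`(z ± √(z² − 4λ))/2`. Started from the ridge solution, the iteration keeps
coordinate j iff `z_j² > 4λ` and converges to the larger root — a
hard-threshold-like rule at `2√λ` on the marginal score, with a mild
downward bias `≈ λ/z_j` on retained coefficients. This is why the null
threshold used for the grid is `λ_max = max_j (x_jᵀy)²/(4 x_jᵀx_j)`: above
it every coordinate collapses to zero.

### Lp generalization

The same loop with `D = diag(|η|^{2−p})` covers all p ∈ [0, 2]. p = 0 is the
L0 iteration above; p = 2 gives D = I, so the first step returns the ridge
solution and is already the fixed point; p = 1 has the stationarity
conditions of the lasso with penalty `λ‖θ‖₁` (verified in tests against an
independent coordinate-descent implementation at matching scaling,
`alpha = λ/n` in scikit-learn's parameterization). Intermediate p
interpolates. The weights are recomputed from the current iterate each step,
so no pre-estimated weights are needed.

### Convergence and diagnostics

The iteration map is not convex; it converges to the local solution nearest
its start whenever it is a local contraction. `check_contraction` evaluates
the sufficient bound `2λ‖(DXᵀX + λI)⁻²‖_∞‖DXᵀy‖_∞ < 1` at a given θ — a
conservative diagnostic only; the solvers run regardless and flag
non-convergence after `max_iter`. Stopping rule: max-abs coefficient change
below `tol = 1e-8` (the reference description gives none; fits typically
converge well under 100 iterations, with occasional slow boundary cases
where a coordinate sits near `z² = 4λ`). An all-zero start is a fixed point,
so user-supplied zero inits are rejected; the default start is the ridge
solution at the same λ (one free parameter total).

## Choosing λ

* **Grid**: `n_points` (default 100) log-equally spaced values from
  `lam_min = 1e-4` to `λ_max` above.
* **Cross-validation**: seeded k-fold (default 5, unstratified — the
  response is continuous); per λ and fold, the fit is trained on the
  training part (ridge-initialized at that λ) and scored by held-out
  `MSE = Σ(y_i − ŷ_i)²/n_test`. `λ_MSE` minimizes the mean test MSE, ties
  toward the larger (sparser) λ.
* **Stability selection**: `λ_SS` is the smallest λ at which all folds agree
  on the number of selected features (zero SD of support size). If no λ
  attains zero SD, the smallest-SD λ is used, ties toward larger λ. The
  combined rule `λ_opt = max(λ_MSE, λ_SS)` is the recommended CV-based
  choice. Caveat: on signal-free data with few features the dense end of
  the grid can saturate (every fold selecting every feature), which also
  has zero SD and pulls `λ_SS` to the bottom of the grid; realistic feature
  counts never saturate, so the rule is kept literal.
* **Information criteria**: because the penalty is exactly the support
  size, classical criteria fix λ directly with no resampling: AIC → 2,
  BIC → log n, RIC → 2 log m (natural logs). These are used verbatim,
  which implicitly assumes unit noise variance (true in all the synthetic
  protocols); for data with very different noise scale, pass an explicit
  numeric λ ≈ criterion × σ̂² instead.
* **Path**: `fit_path` fits each grid λ cold-started from its own ridge
  solution. Warm starts are opt-in only: exact zeros are absorbing, so
  carrying supports across λ would freeze the path; the opt-in mode
  re-inflates zeros to `zero_eps` before reuse.

CV prediction uses the EM coefficients directly (no post-selection
least-squares refit): the retained coefficients are already near-unbiased.

## Graphical model

The conditional distribution of a Gaussian variable given the rest is a
linear regression whose coefficients are proportional to the corresponding
precision-matrix entries, so the package estimates a network by m
neighborhood regressions: x_j on X_{−j}, each L0-penalized with λ from AIC
or BIC (no cross-validation: m fits total). Nonzero coefficients become
directed selections; the undirected edge set uses the OR rule by default (an
edge if either regression selects it; this is the most literal reading of
"collected nonzero coefficients are the edges"), with AND available. Pair
scores for ROC ranking are the symmetrized absolute coefficient magnitudes
from the single selected-λ fit, with all exact-zero pairs tied at score 0
(ties handled by grouped/trapezoidal AUC). `positive_only` clamps negative
coefficients to zero inside each M-step, restricting the graph to positive
partial dependencies (the usual convention for coexpression databases).
Edge metrics: FDR = false selected edges / selected edges (0 with a flag
when nothing is selected), FNR = missed true edges / true edges, both in
percent.

## Synthetic data

* **Regression scenarios**: rows of X are i.i.d. N(0, Σ) with AR(1)
  covariance `Σ_ij = r^{|i−j|}`, r ∈ {0, 0.3, 0.6, 0.8}, sampled through the
  Cholesky factor of the explicit Toeplitz matrix (cached per (m, r));
  response `y = 2x₁ − 3x₂ + 4x₅ + ε`, `ε ~ N(0, 1)`. Defaults follow the
  benchmark designs: n = 100 with m = 50 (low-dimensional) or m = 1000
  (high-dimensional).
* **Band networks**: band 1 draws from `Σ_ij = 0.6^{|i−j|}` (AR(1)), whose
  precision is exactly tridiagonal — true edges at lag 1 (99 edges at
  m = 100). Band 2 uses a precision matrix `Ω = I + 0.25·lag1 + 0.4·lag2`
  (true edges at lags 1–2, 197 edges at m = 100). The literal "negative
  off-diagonal, unit diagonal" reading of the band-2 construction is not
  positive definite (its spectral symbol `1 − 0.5cos ω − 0.8cos 2ω` is
  negative at ω = 0), so the positive-off-diagonal convention is used;
  edge-recovery scoring is sign-blind, so this only affects coefficient
  signs. Positive definiteness is asserted at construction and failure
  raises.

What the generators do **not** emulate: heavy-tailed or heteroscedastic
noise, non-Gaussian marginals typical of expression data, hub/scale-free
topologies, missing values, or batch structure. Passing benchmarks on this
synthetic family therefore demonstrates correctness of the algorithms under
their stated assumptions, not robustness on real omics matrices (for which
column standardization and the positive-dependency option are the usual
starting points).

## Replicate experiments and problem sizes

`run_experiment` regenerates fresh data per replicate from a single master
seed stream and aggregates support size, MSE, coefficient bias
`‖θ̂ − θ_true‖` (Euclidean over all m coordinates; an L1 option exists) and
the exact-support indicator as mean ± SD. For CV-based protocols the
reported MSE is the held-out CV mean at the selected λ; for
information-criterion protocols it is the in-sample MSE* of the single fit
(the two are not comparable and are labeled distinctly).

The bundled acceptance script runs the low-dimensional CV protocols and all
fixed-penalty protocols at 100 replicates, the high-dimensional CV
protocols at 20 replicates on the full 100-point grid, and the network
cells at 20 replicates; the test suite uses 5–50 replicates per protocol
(with a 40-point grid for the high-dimensional CV checks). These sizes
keep the whole reproduction at desk scale while staying within the
binomial/normal 3-SE tolerances used in the tests.

## Known limitations

* The objective is nonconvex: results depend on initialization (ridge by
  default), and an occasional coordinate near the selection boundary
  `z² ≈ 4λ` converges slowly enough to hit `max_iter` (flagged, not fatal).
* On pure-noise data the CV minimum occasionally lands at a small λ and
  fold support sizes never agree exactly near λ_max, so the combined rule
  picks a 2+-feature model in roughly 15% of null runs at small m.
* The band-network benchmarks reproduce at n ≥ 100 (band 1) and n = 200
  (band 2). At n = 50, m = 100 the per-direction partial-association
  z-statistic of a true band-1 edge is ≈ 0.44·√50 ≈ 3.1, so the published
  joint operating points (sub-0.3% edge FDR together with sub-10% FNR)
  lie outside the frontier attainable by any λ in per-variable L0
  neighborhood regression at that sample size; the λ-scan in the test suite
  documents the frontier actually achieved.
* Only Gaussian linear regression is covered (no GLMs, no survival models);
  comparison methods (lasso/SCAD/MC+) are not reimplemented — an external
  lasso serves as a test oracle for the p = 1 solver only.
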