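# Methods

`migsurf` estimates an *effective migration surface*: a field of relative
gene-flow rates, represented as edge weights on a triangular spatial lattice,
inferred from how allele-frequency covariance decays across geography. This
note records the model, its assumptions, the numerical choices, what the
synthetic-data generator does and does not emulate, and known limitations.

## Model

**Graph.** The habitat is discretized as a triangular lattice
G = (V, E) with |V| = d nodes (demes) clipped to a user-supplied outer
polygon. Each edge (k, l) carries a weight w_kl > 0 interpreted as the level
of gene flow between neighbouring demes. The weighted graph Laplacian is
L = diag(W1) − W.

**Observation model.** Diploid genotypes y ∈ {0, 1, 2} at SNP j for
individuals assigned to node k are modelled as Binomial(2, f_j(k)) draws
from a latent node frequency. Node frequencies are estimated by maximum
likelihood, f̂_j(k) = (allele count at k) / (2 n_k), giving an o × p matrix
F̂ over the o ≤ d observed nodes together with node sample sizes n.

**Spatial prior.** Latent frequencies follow a Gaussian Markov random field

    f_j ~ N_d( μ_j 1,  μ_j (1 − μ_j) L† ),

where L† is the Moore–Penrose pseudo-inverse and μ_j the SNP's mean
frequency. Under this prior the expected squared difference of latent
frequencies between two nodes, rescaled by μ_j(1 − μ_j), equals the
effective resistance r_kl = L†_kk − 2 L†_kl + L†_ll of the weighted graph —
the classic bridge between random-walk migration models and electrical
networks. The tests verify this identity both by covariance algebra (exact
to 1e−10) and by Monte Carlo over 5000 simulated SNPs (within 10%).

**Marginal likelihood.** Binomial sampling noise is approximated as
homoskedastic: ½ f(1 − f) ≈ σ² μ(1 − μ), one scalar σ² for all nodes and
SNPs. Marginalizing the latent field,

    f̂_j ~ N_o( μ_j 1,  μ_j (1 − μ_j) · V ),   V = A L† Aᵀ + σ² diag(n⁻¹),

with A the o × d one-hot assignment matrix. Projecting out the per-SNP mean
with an orthonormal contrast basis C (C1 = 0, CCᵀ = I) makes p·C Σ̂ Cᵀ a
Wishart-distributed summary of the rescaled sample covariance
Σ̂ = F̂_s F̂_sᵀ / p, and yields the negative log-likelihood (constants
dropped)

    nll(w, σ²) = p [ tr(M⁻¹ S) + log det M ],   M = C V Cᵀ,  S = C Σ̂ Cᵀ.

The printed source formula for this likelihood carries an ambiguous sign and
inverse placement; the convention above is the one consistent with a
Gaussian/Wishart negative log-likelihood and is used throughout. The same
quantity can be written in terms of the genetic-distance matrix D̂ through
the identity C D̂ Cᵀ = −2 C Σ̂ Cᵀ, which the tests check to 1e−10. The
likelihood value is invariant to the particular orthonormal contrast basis
(tested to 1e−8 relative); the implementation fixes a deterministic Helmert
basis with a sign convention so runs are reproducible.

**Penalty.** Edge weights are smoothed by penalizing differences between
edges that share a node:

    φ_{λ,α}(w) = (λ/2) ‖ Δ log(e^{αw} − 1) ‖²,

where Δ has one row per unordered pair of node-sharing edges (+1 on the
lexicographically smaller edge, −1 on the other). The map
g(w) = log(e^{αw} − 1) behaves like log(αw) for w ≪ 1/α and like αw for
w ≫ 1/α, so the surface is smoothed on a log scale where migration is weak
and on a linear scale where it is strong; the two asymptotic regimes are
verified numerically at 1% tolerance. φ is exactly zero for any constant
surface. g is evaluated as αw + log1p(−exp(−αw)), stable over the full
positive range.

## Estimation

**Null (constant-w) stage.** A homogeneous isolation-by-distance model with
a single shared weight w0 and the residual variance σ² is fitted first by
Nelder–Mead simplex search in (log w0, log σ²). The starting w0 matches the
mean unit-weight resistance among observed nodes to the mean genetic
distance; σ² starts at 0.5 (the value binomial sampling induces when latent
frequencies vary little within a SNP). The stage outputs ŵ0 and σ̂²; σ̂² is
frozen for all penalized fits, the penalty scale defaults to α = 1/ŵ0, and
the penalized fit initializes at the constant ŵ0 surface.

**Penalized fit.** ŵ = argmin_{l ≤ w ≤ u} nll(w, σ̂²) + φ_{λ,α}(w), solved
by L-BFGS-B on z = log w so positivity is structural. Default bounds are
l = 1e−6·ŵ0 (strictly positive — both the Laplacian solve and g(w) require
w > 0) and u = +∞. Defaults: gradient tolerance 1e−6·p (the objective and
its gradient scale linearly with the SNP count), ftol 1e−11, at most 1000
iterations; all configurable. Optimizer failure is reported on the results
object (`converged`, `message`), not raised, so regularization paths and
cross-validation can continue past a bad penalty value.

**Gradients.** The likelihood gradient is computed by the analytic adjoint
through the Laplacian solve: with U = L† (CA)ᵀ and
G = p (M⁻¹ − M⁻¹ S M⁻¹), the derivative with respect to edge (k, l) is
−(u_k − u_l)ᵀ G (u_k − u_l); the penalty contributes
λ g′(w) ∘ ΔᵀΔ g(w). Central finite differences confirm the gradient to
1e−5 relative tolerance on random instances.

**Complexity.** All pseudo-inverse actions go through a *grounded* Laplacian
factorization: node 0's row and column are removed, right-hand sides are
implicitly centered against the ones vector, and solutions re-centered,
which reproduces L† exactly on the relevant subspace (verified against a
dense eigendecomposition oracle to 1e−8 relative on graphs up to d = 50).
One objective/gradient evaluation costs O(d·o + o³). Graphs up to 800 nodes
use a dense Cholesky of the grounded Laplacian (faster at these sizes);
larger graphs switch to sparse LU. If the contrast-projected covariance
fails to factor, it is jittered once by 1e−12·trace/(o−1) with a logged
warning, and a structured error suggesting a larger residual-variance floor
is raised if that also fails.

**Regularization path.** Fits over a penalty grid run from the strongest λ
downward, each initialized at the previous solution (warm starts). Cold
starts restart every fit at the constant ŵ0 surface and are retained only
as a comparison mode; the tests check that warm-started objectives are never
worse and that fold-to-fold CV error spread does not increase.

## Penalty selection by cross-validation

One observed node is held out per fold. Everything the fold's fit touches is
recomputed from the training nodes alone — frequency summaries and their
mean frequencies μ̂, the fold's own constant-w stage (hence its own σ̂² and
α = 1/ŵ0), and the penalized path. This makes the leakage contract exact:
perturbing only the held-out node's genotypes leaves the fold's fitted
weights bit-identical (tested). The held-out node's frequencies are then
predicted per SNP by the Gaussian conditional mean

    f̂_pred = μ̂_j + V[val, tr] V[tr, tr]⁻¹ (f̂_tr − μ̂_j 1)

under the fitted covariance over all observed nodes; the SNP scale factor
μ_j(1 − μ_j) cancels between the covariance blocks. (The printed source
expression for this conditional mean carries a stray trailing term; the
standard Gaussian conditional mean is implemented.) The per-fold error is
the squared prediction error averaged over SNPs, then averaged over folds.

**Selection rule.** The winning λ minimizes the fold-averaged error. Mean
errors within 0.1% (relative) of the minimum are treated as ties and
resolved toward the larger λ. The tolerance reflects an empirical scale
separation: on the flat strong-penalty arm of the CV curve, fits differ only
by optimizer termination noise (~1e−6 relative in the mean error), while
genuine curvature — e.g. the interior minimum under a migration barrier —
shows up at ≥3e−3 relative. Anything in between is not resolvable from o
folds whose fold-to-fold standard error is two orders of magnitude larger.
α is not cross-validated (fixed at 1/ŵ0 per fold); a joint (λ, α) grid
search (`loocv_2d`) and a k-fold variant with k < o are available, but
leave-one-out with fold-wise α = 1/ŵ0 is the default and recommended mode.

## Synthetic data

The generator simulates from the estimator's own generative model so that
recovery targets are exactly defined: μ_j ~ Uniform(0.1, 0.9), latent
frequencies from the GMRF via the Laplacian eigendecomposition square root,
clipped to [0.01, 0.99] to stay valid as binomial probabilities, then
10 diploid individuals per observed node with Binomial(2, f) genotypes and
coordinates jittered around node positions (5% of the lattice spacing, far
too small to flip the nearest-node assignment). Three scenarios on an
8 × 12 rectangular lattice (96 nodes, 50 km spacing):

* **homogeneous** — every edge at the base weight;
* **barrier** — edges whose midpoint falls in the central longitude third
  down-weighted 10-fold;
* **anisotropic** — edges oriented within 30° of east–west up-weighted
  5-fold.

Sampling designs: *dense* (all nodes observed) and *random* (a 20% random
node subset). The base weight defaults to 10, chosen so pairwise resistance
distances fall in the ~0.01–0.1 range typical of continuous-range population
structure; this also keeps the latent Gaussian inside (0, 1) (about 1% of
values touch the clip bounds), so the binomial stage is faithful to the
observation model. A second generator emits observed frequencies directly
from the Gaussian observation model with an explicit σ², without any
clipping — this is the model-exact mode used for (w0, σ²) recovery checks.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (all SNPs independent), coalescent genealogical noise (the source
method was originally evaluated against out-of-model coalescent
simulations; a coalescent engine can be substituted by supplying genotypes
directly), ascertainment bias, genotyping error, and non-equilibrium
demography. Passing recovery tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to model
mis-specification.

## Problem sizes used in the checks

Numerical contracts (oracle equivalence, gradients, identities) run on
random lattices with d ≤ 50. Statistical checks use: d = 30, p = 2000,
σ² = 0.1 for constant-weight recovery (ŵ0 within 10% of truth, majority of
five seeds); the 96-node lattice with p = 1000 SNPs and 10 diploids per node
for barrier/anisotropy recovery and for penalty selection. For the
directional recovery checks the penalty is selected by cross-validation once
(first seed) and five independent datasets are refit at that value; the
headline penalty-selection computation in `scripts/acceptance.py` runs the
full leave-one-out cross-validation separately for every seed and both
sampling designs over an 11-point log-spaced grid with maximum 100.

## Known limitations

* The objective is non-convex; L-BFGS-B finds a local minimum. Across
  random initializations the barrier-vs-background weight ordering is
  stable (tested), but individual edge weights can differ between runs from
  different starts.
* Node placement is implementation-defined: the lattice is built in a local
  equirectangular projection and clipped to the polygon, not intersected
  with a precomputed global spherical grid, so grids on real datasets will
  not reproduce any particular published node layout (and selected λ values
  are not comparable across grids or datasets).
* The homoskedastic σ² approximation is coarse for SNPs with extreme
  frequencies; the QC default (MAF ≥ 5%) is partly motivated by this.
* Edge weights are relative; the likelihood constrains ratios across the
  surface far better than the absolute scale, which is why surfaces are
  reported as log10(w/ŵ0).
* Samples falling outside the habitat polygon are assigned to the nearest
  node with a warning rather than rejected; distant outliers can distort
  the local fit.
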