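# Methods

## Model

Let R ∈ {0,1}^(I×J) be the drug–target interaction matrix, U ∈ R^(L×I) and
V ∈ R^(L×J) latent factor matrices with columns u_i, v_j, and σ the
logistic function. The likelihood is an importance-weighted Bernoulli,

    p(R | U, V) ∝ ∏_ij [ σ(u_iᵀv_j)^(c R_ij) (1 − σ(u_iᵀv_j))^(1 − R_ij) ]^(m_i^u m_j^v),

with c ≥ 1 multiplying observed positives and masks m^u, m^v that are 0
exactly for empty rows/columns of the *training* matrix. Masked entities
receive no likelihood information; their posteriors are shaped by the
kernel prior alone. Unobserved pairs in non-empty rows enter as weight-1
negatives — the standard positive–unlabeled treatment.

The prior on U couples entities through similarity kernels K^u_n,

    p(U | γ^u, α_u) ∝ exp{ −½ Σ_n γ^u_n Σ_{i,k} K^u_{n,ik} ‖u_i − u_k‖² } ·
                       exp{ −(α_u/2) Σ_i ‖u_i‖² },

summing over ordered pairs (i,k). Expanding the double sum gives the
per-latent-dimension prior precision

    Q^u = 2 Σ_n γ^u_n (D_n − K^u_n) + α_u I,

with D_n the degree matrix. (A different printed constant convention for
Q^u circulates; the implementation fixes the constant from the density
itself, and a numeric quadratic-form identity test pins it to 10⁻¹⁰.) The
prior on V is symmetric in form. Kernel weights carry Gamma(a, b)
hyperpriors.

Before use, every kernel is sparsified to its N nearest neighbors per row
(default N = 3), symmetrized by the element-wise maximum so the retained
graph is undirected, with ties among equal similarities broken by ascending
index. Truncation is idempotent.

## Inference

The mean-field family is q(U) q(V) q(γ^u) q(γ^v) with *full* Gaussians over
vec(U) and vec(V) (the cross-entity covariance blocks are needed by the
Gamma update) and independent Gamma factors. Because the logistic
likelihood is not conjugate, each factor ln σ(z) is replaced by the
Jaakkola quadratic lower bound with a local parameter ξ_ij ≥ 0; the bounded
per-cell log-likelihood is

    R̂_ij (ln σ(ξ_ij) − ξ_ij/2 − ξ̂_ij ξ_ij²) + R′_ij z + R̂_ij ξ̂_ij z²,

with z = u_iᵀv_j, augmented count R̂_ij = m(c−1)R_ij + m, linear
coefficient R′_ij = m(c R_ij − R̂_ij/2) (= +c/2 at positives, −1/2 at
negatives; a finite-difference test on the bounded objective arbitrates the
sign), and curvature ξ̂ = −(σ(ξ)−½)/(2ξ) ∈ [−1/8, 0).

Closed-form coordinate updates:

* **q(vec(U))** is Gaussian with precision
  Λ = Q^u ⊗ I_L − 2·blkdiag_i(Σ_j R̂_ij ξ̂_ij E[v_j v_jᵀ]) and mean
  Λ⁻¹ vec_i(Σ_j R′_ij E[v_j]). Since ξ̂ ≤ 0 and R̂ ≥ 0 the likelihood term
  is PSD, so Λ stays positive definite. Solves use Cholesky with a
  symmetric-eigendecomposition fallback (eigenvalue floor 10⁻¹⁰).
* **ξ_ij² = E[(u_iᵀv_j)²] = tr(E[u_i u_iᵀ] E[v_j v_jᵀ])** — exact under
  mean-field independence; it reduces to the familiar
  marginal-variance expansion when within-column covariance is diagonal.
  A Monte-Carlo oracle validates the trace form.
* **q(γ_n) = Gamma(a + I²/2, b + ½ E[Σ_{i,k} K_{n,ik} ‖u_i − u_k‖²])**,
  using E[u_iᵀu_k] = tr Cov(u_i, u_k) + E[u_i]ᵀE[u_k]. The shape offset
  I²/2 corresponds to a γ^(1/2) pseudo-normalizer per ordered pair in the
  Laplacian prior; the bounded ELBO uses the same pseudo-normalized prior,
  which makes the Gamma step its exact coordinate maximizer.

A sweep runs ξ → q(U) → ξ → q(V) → q(γ^u) → q(γ^v); the default budget is
D = 20 sweeps (convergence is typically reached in 20–50). The bounded
ELBO — likelihood bound plus prior expectations plus Gaussian and Gamma
entropies — is recorded each sweep (or each update, for testing) and must
never decrease beyond a 10⁻⁶ relative tolerance; this monotonicity is the
central correctness oracle of the test suite, alongside a direct comparison
of the Gaussian update mean against a generic numeric maximizer of the
bounded objective on small instances.

Initialization: factor means are drawn N(0, 1/L) from the run seed (scale-
stable inner products at start), covariances start at the prior covariance,
Gamma factors at the prior, and ξ from the initial moments. Runs are
bitwise deterministic given the seed.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| L | 10 | latent dimension; small values (≈10–15) suffice and larger ones mostly cost time |
| c | 10 | importance weight on observed positives (dimensionless multiplicity) |
| α_u, α_v | 0.1 | ridge precision of the factor priors |
| a, b | 1, 10³ | Gamma hyperprior shape/rate; prior mean weight a/b = 10⁻³ keeps kernels weak until the data promotes them |
| neighbors | 3 | nearest-neighbor kernel truncation |
| iterations | 20 | variational sweeps |

Memory is O(L²I² + L²J²) for the two full covariances and time is dominated
by the O(L³·max(I,J)³) precision inversions — fine at the hundreds-of-
entities scale this package targets.

## Prediction

Default is the plug-in link P_ij = σ(E[u_i]ᵀE[v_j]). An optional
moment-corrected mode integrates the Gaussian uncertainty of z = u_iᵀv_j
through the probit approximation, P_ij = σ(μ_ij/√(1 + π s²_ij/8)); it
shrinks uncertain cells toward ½ and is labeled in the output. Expected
interaction counts (promiscuity per drug, druggability per target) are row
and column sums of P, valid under independence of cells — a raw but useful
estimate of undiscovered interactions. Novel-pair ranking sorts
zero-cells by probability with deterministic index tie-breaks.

## Evaluation

CVS1 partitions all I·J cells, CVS2 whole drug rows, CVS3 whole target
columns; blinded cells become unobserved zeros in training (blinded
rows/columns become empty and hence masked) and are scored against their
true values. AUROC is the tie-aware rank statistic; AUPRC is step-wise
average precision (trapezoidal interpolation overestimates PR area), both
delegated to scikit-learn and verified against exhaustive brute-force
oracles up to length 8. Summaries report means with normal-approximation
95% confidence intervals over per-fold values. The learning-curve
experiment holds out a fixed test fraction, trains on growing fractions of
the remaining cells, and contrasts the real kernels with identity kernels
(the Laplacian vanishes, leaving the α ridge) — the cleanest ablation of
side information.

## Synthetic data

The generator emulates the model's own generative process: block-membership
similarity kernels (1 within a block, 0 between, plus clipped symmetric
Gaussian noise, unit diagonal), latent factors drawn from the
Laplacian-Gaussian prior via a Cholesky of the precision (the same
decomposition path the inference engine uses), and Bernoulli interactions
through the logistic link with P\* = σ(UᵀV) exactly.

Two calibration constants are set per scenario and recorded in its
metadata. First, the factors are rescaled so the logit spread is 8.0 by
default, placing the Bayes-optimal AUROC of P\* near 0.99 — the
near-separable regime of the public DTI gold standards. Second, the factor
means are translated along the first latent axis (u_1 += t, v_1 += ±t, with
the signed offset found by root finding) until the mean of P\* hits the
target positive rate (default 0.20). A plain scalar rescaling cannot set
the rate (zero-mean factors give symmetric logits and a rate pinned near
½), and an additive intercept on the logits would add a rank-one component
*outside* the rank-L_true model family; the translation keeps the data
exactly representable and induces per-drug/per-target base-rate
heterogeneity like the degree spread of real DTI networks. A unit-diagonal
positive-definite random-valued kernel (normalized Gram matrix of uniform
factors, off-diagonals ≈ 0.75 — deliberately scale-matched to the block
kernels so weight comparisons reflect information content, not entry
magnitude) serves as the robustness control.

What the generator does **not** emulate: realistic fingerprint/sequence
feature distributions, dataset-specific ascertainment bias in which pairs
get assayed, inter-dataset heterogeneity, and the extreme sparsity
(1–4% positives) of some real gold standards. Passing tests therefore show
that the inference machinery is correct and that the model recovers its own
generative structure — not that real-data benchmark numbers are reproduced.

## Experiment scales

Recovery and kernel-weight robustness run on 40×30 scenarios with
L_true = 4 (γ_true = 1, α = 0.1, ≈20% positives): held-out AUROC is
averaged over 5 seeded CVS1 folds, and the informative-vs-random weight
comparison over 20 seeded fits. The prior-fading experiment uses 60×45
scenarios: at 40×30 even the full matrix sits inside the small-sample
region (the kernel advantage has not yet faded), while at 60×45 the
advantage at a 0.1 training fraction clearly exceeds the advantage at the
full size, reproducing the qualitative small-sample-gain signature.

## Numerical choices and degenerate inputs

ξ̂ is computed as −tanh(ξ/2)/(4ξ) with a Taylor series below 10⁻⁶ (exact
limit −1/8 at 0). Tanimoto similarity of two empty fingerprints is defined
as 0 off-diagonal (diagonal forced to 1). Kernels asymmetric beyond 10⁻⁸
on load are averaged with a logged warning; kernels are not forced PSD (the
Laplacian needs no PSD-ness) but negative eigenvalues are logged. Folds
with degenerate test labels are skipped with a warning and counted in the
summary. Negative computed second moments (numerics) clamp ξ at 0 with a
warning. α must be strictly positive; a disconnected graph with α = 0
would make the prior precision singular.

## Known limitations

The full-covariance posterior is exact for the bounded objective but
O(L²I²) in memory; no sparse or reduced-rank variant is provided. The
Jaakkola bound loosens for saturated logits (|z| ≳ 10), so on nearly
separable data the variational posterior under-spreads predicted
probabilities relative to a MAP fit — rankings remain strong but
probability calibration at the extremes is conservative. Kernel
combination is linear; strongly redundant kernels share weight rather than
being pruned. Binary interactions only: real-valued affinity regression is
out of scope.
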