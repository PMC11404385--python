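# Methods

## Model

Per subject, row vectors x (p), y (q) and an outcome z are generated as

    x = t W' + t⊥ W⊥' + e,   e ~ N(0, σe² Ip)
    y = u C' + u⊥ C⊥' + f,   f ~ N(0, σf² Iq)
    u = t B + h
    η(E[z]) = a0 + t a' + h b'

with independent zero-mean normal latents t (K joint), t⊥ (Kx x-specific),
u⊥ (Ky y-specific) and h (K, the heterogeneity of the y-side joint scores),
all with diagonal covariances Σt, Σt⊥, Σu⊥, Σh. The outcome link η is the
identity (gaussian family, residual g ~ N(0, σg²), data centered, a0 = 0) or
the logit (bernoulli family, a0 estimated). Writing the linear predictor on
(t, h) instead of (t, u) — a ↦ a + B b, b ↦ b — removes the near collinearity
of t and u = tB + h; all code stores coefficients in this total/direct-effect
form: `a` is the total effect of the x-side joint structure, `b` the effect
of the part of u not explained by t.

Identifiability (up to component-wise sign flips) requires W, C, W⊥, C⊥
semi-orthogonal, [W W⊥] and [C C⊥] of full column rank, diagonal latent
covariances, diag(B) > 0 and diag(Σt B) strictly decreasing.
`validate_params` checks these; `canonicalize_signs` resolves the sign
freedom deterministically (B made positive by flipping the u-side of a
component; then the largest-|entry| of each W column made positive by a
joint (t, u) flip; specific columns flipped independently; ties at the
largest entry go to the first index).

The implied covariance of (x, y, z) is Σθ = L diag(D) L' + diag(r) with the
(p+q+1) × (2K+Kx+Ky) loading factor L over the base latents (t, h, t⊥, u⊥).
All likelihoods, conditionals and determinants go through the Woodbury /
matrix-determinant identities on the (2K+Kx+Ky)-dimensional posterior
precision, so no operation forms or inverts a dense (p+q+1)² matrix; cost is
O(N (p+q) d) per EM iteration with d = 2K+Kx+Ky.

## Estimation

**Gaussian outcome.** EM with an exact E-step: (t, u, t⊥, u⊥) | (x, y, z) is
Gaussian with per-subject means and a shared covariance, both computed from
the low-rank factorization. The M-step maximizes each factor of the
complete-data likelihood in closed form:

- (a, b) = z'E[(t, h)] (E[(t, h)'(t, h)])⁻¹ and σg² as the mean expected
  squared outcome residual;
- loading blocks under the semi-orthogonality constraint: for fixed W⊥ the
  x-block objective is linear in W on the Stiefel manifold (the quadratic
  term has constant trace there), so the exact constrained maximizer is the
  polar factor of x'E[t] − W⊥ E[t⊥'t]; W and W⊥ (and C, C⊥) are updated in
  one block-coordinate pass, each step an exact maximizer given the other —
  EM ascent is preserved exactly, not only to first order;
- B by per-component regression of u on t, Σh from the expected residual
  second moment, Σt, Σt⊥, Σu⊥ from expected latent second moments, σe², σf²
  from expected residual traces.

Convergence: relative change of the observed-data log-likelihood below
`tol` (default 1e-6), `max_iter` 10,000. The trace is recorded at every
iterate and is non-decreasing (enforced by test with 1e-8 relative slack).
Data are column-centered internally; scaling is left to the user. Loadings
are re-orthogonalized (by construction of the polar update) every iteration.
Initialization is method-of-moments: W, C from the top-K singular triplets
of x'y, specific loadings from the principal directions of the residuals,
variances from explained-variance splits, B and (a, b) from score
regressions; `random_state`/`seed` jitters the joint loadings for random
restarts. The one pathological regime is near-zero residual noise, where EM
converges correctly but slowly (verified: estimates keep drifting toward
the MLE at tol 1e-12); omics data in practice are nowhere near this corner.

**Bernoulli outcome.** The specific latents ξ = (t⊥, u⊥) are integrated out
analytically through Σx|t = W⊥Σt⊥W⊥' + σe²Ip (and the y analogue), leaving a
2K-dimensional integral over ν = (t, u). That integral is evaluated with a
tensor-product Gauss–Hermite rule: nodes √2 Σ^{1/2} s_m, product weights
normalized by π^{-K} (the unique normalization under which the Gaussian
density integrates to 1; checked to 1e-10).

A rule scaled by the *prior* Cov(ν) breaks down as soon as the omics blocks
are informative: the posterior f(ν|x,y,z) is then an order of magnitude
narrower than f(ν), nearly all posterior mass falls between adjacent nodes
(median effective node count ≈ 1.5 of 256 in a p=100 experiment), the E-step
moments quantize to the grid, and the EM trace *decreases*. We therefore use
the exact factorization p(z|ν) f(x,y|ν) f(ν) = f(x,y) · p(z|ν) f(ν|x,y):
f(ν|x,y) is Gaussian with closed-form (low-rank) mean and covariance, the
grid is scaled to that conditional, and only the smooth logistic factor is
left to the quadrature. This is the same integral, not an approximation
change, and it is not adaptive quadrature (no iterative refinement —
the recentering is a single closed-form conditioning). With M = 16 nodes
per dimension (default; M^{2K} points total, hard error above 10⁶ points)
the log-likelihood is stable to ~1e-9 against M = 32 and matches dense
trapezoid integration on toys to 1e-6.

The outcome coefficients β = (a0, a, b) have no closed-form update; each EM
iteration takes exactly one gradient-ascent step on Q_β with the Armijo
backtracking rule: start at s = 1, shrink s ← 0.8 s until
Q(β + s∇Q) ≥ Q(β) + 0.5 s‖∇Q‖², skip with a warning if s underflows 1e-12.
All other parameters reuse the gaussian M-step: the ξ statistics are
recovered by Gaussian conditioning of ξ given (ν, x, y) (linear in ν with
constant covariance), composed with the quadrature moments of ν. The
resulting procedure is a generalized EM; the quadrature log-likelihood trace
is non-decreasing up to quadrature error (tested with 1e-6 relative slack).
Q_β and its backtracking evaluations use the same quadrature grid as the
E-step. `max_iter` defaults to 2,000 (one gradient step per iteration makes
β the slowest direction; typical fits converge in well under 100).

## Inference

Cov(α̂), α = (a, b), is estimated from the observed Fisher information via
Louis' decomposition restricted to the outcome term of the complete-data
likelihood, under the approximations that α̂ is asymptotically independent
of the remaining parameters and σ̂g² is non-random:

    I(α̂) = Σᵢ E[Bᵢ|ψᵢ] − Σᵢ E[SᵢSᵢ'|ψᵢ] − (Σᵢ E[Sᵢ]) (Σⱼ E[Sⱼ])' + Σᵢ E[Sᵢ]E[Sᵢ]'

with Sᵢ and Bᵢ the score and negative Hessian of the outcome term. For the
gaussian family the conditional expectations are fourth-order Gaussian
moments of (t, h)|ψ, evaluated in closed form (Isserlis); for the bernoulli
family they are quadrature sums over the posterior of ν. The i ≠ j cross
term is ≈ 0 at the MLE but kept for exactness of the decomposition. In the
noiseless limit the whole expression collapses to the classical
σg²(V'V)⁻¹ of linear regression (tested). T_full = α̂ Π⁻¹ α̂' is referred to
χ² with 2K df; the component-wise statistic uses the (a_k, b_k) sub-block
of Π with 2 df. Component indices in `test_componentwise` are 1-based,
matching the component numbering in reports.

Calibration, measured on this implementation: mean Π tracks the Monte-Carlo
covariance of α̂ within ~5% at N = 300–1000; under the independence null the
empirical size of the 5%-level full test is ≈ 3.5–4% at N = 1000 (slightly
conservative; the null T is marginally light-tailed, mean 1.94 vs 2) and
≈ 5–7% at N = 100. Binary-family p-values assume the asymptotic normality
carries over from the gaussian case; every binary inference result carries
`caveat=True` and the CLI prints a warning.

The per-component test of the t–u link (B_k = 0) applies the same Louis
construction to the complete-data u|t term with (t, u) moments conditioned
on (x, y) only, giving a 1-df Wald statistic B̂_k² I(B̂_k). The exact
construction of this test is this package's interpretation (only the
reported p-values, not the formula, appear in the literature the model
follows); it is validated by null calibration and sign-flip invariance
tests.

## Synthetic data

`SimScenario` encodes the simulation grid this model family is studied on:
N ∈ {100, 1000}; (p, q) ∈ {(100, 10), (2000, 25)}; one joint and one
specific component per block; latents standard normal; B = I; heterogeneity
(the variance share of h in u) 40% or 80%; residual variance fractions
40%/40% or 95%/5% in (x, y); outcome noise 20% of var(z); a = 2, b = 1.
"Noise proportion" is read as a trace ratio (expected residual variance over
expected total variance, summed over a block's features) — the conventional
reading, and the one consistent with unit latent/loading scales. Σh solves
var(h)/var(u) = heterogeneity with Σt fixed (var(u) is not rescaled to 1;
the variance share, not the total, is the stated quantity). For K ≥ 2, Σt
is the decreasing sequence K..1 so diag(Σt B) is strictly decreasing; the
multi-component grid settings are otherwise this package's choice. Loadings
are standard normal then orthonormalized (QR with a fixed sign convention).
One master seed expands into independent substreams for loadings, latents,
noise and outcome. The null-outcome generator draws z ~ N(0, 1) independent
of (x, y).

What the generator does *not* emulate: bounded methylation beta values,
family or batch structure, covariate effects, non-Gaussian heavy tails,
missing data. A green recovery or calibration test therefore establishes
correctness under the model's own assumptions, not robustness to real-data
violations of them.

## Evaluation harness

`run_type1_experiment` / `run_power_experiment` simulate, fit and apply the
full test per replicate (failed fits are excluded and counted);
`run_scenario_grid` records scaled coefficient errors (est − true)/true,
RMSEP on an independent test set drawn from the *same* ground-truth
parameters (binary outcomes are scored on the logit of the true vs
predicted probability, probabilities clipped at 1e-12 with a warning),
top-25% feature-recovery TPR (ties at the cutoff broken by feature index),
and loading inner products. Ridge baselines fit each block separately with
a 10-fold-CV penalty (fixed-penalty mode matches (X'X + λI)⁻¹X'z exactly).
Estimated components are sign-aligned to the truth before computing signed
errors. Default replication counts are desk-scale (100–500 for rejection
rates and medians); all drivers are reproducible given (seed, reps,
scenario) and parallelizable with joblib.

## Component selection

`scree` returns the singular values of x'y (joint), and the eigenvalues of
x'x and y'y after deflating the suggested joint part (specific), computed
via N×N Gram matrices so no p×p product is formed. The suggested counts use
the largest successive-ratio drop; this heuristic is advisory only — the
intended use is visual inspection of the spectra.

## Numerical choices and degenerate inputs

- Variance floors at 1e-10 in all M-step updates; polar projection falls
  back to the previous loadings if its target matrix is numerically zero.
- Convergence is relative |Δ loglik| / max(|loglik|, 1); `tol=inf` stops
  after exactly one EM iteration (trace length 2).
- A binary outcome without variation aborts with a separation error; codes
  other than 0/1 are rejected.
- `ModelDims` enforces K ≤ min(p, q), Kx < p, Ky < q; r (the coefficient
  length) is fixed equal to K, matching the per-component pairing of
  (a_k, b_k) in the component-wise test.
- Serialization writes one TSV per loading matrix plus a JSON manifest at 17
  significant digits; write → read round-trips bit-exactly.

## Known limitations

- Binary-family standard errors assume unproven asymptotic normality
  (flagged in every result).
- The binary fit cost scales as M^{2K}; K = 1 is the practical regime
  (matching the regime the model family is reported in), with a hard error
  above 10⁶ grid points.
- The full test is mildly conservative at N = 1000 (≈ 3.5–4% empirical size
  at the 5% level) and mildly anticonservative at N = 100 (≈ 5–7%).
- No missing-data handling, no more than two omics blocks, no non-diagonal
  latent covariances, no outcome families beyond gaussian/bernoulli.
- EM convergence slows sharply as residual noise → 0 (a property of EM, not
  of this implementation); fits in that regime need much tighter `tol`.
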