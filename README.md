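# glmpo2pls

One-stage probabilistic integration of two omics data blocks with an outcome
variable.

## The problem

Studies of complex traits increasingly measure several omics layers (say,
DNA methylation and plasma glycomics) on the same subjects together with a
phenotype. Analyzing each layer separately ignores the correlation between
layers; two-stage pipelines (reduce dimension first, regress the outcome on
the scores second) ignore the outcome during the reduction and carry
unquantified first-stage error into the second-stage inference. This package
fits a single latent-variable model for both blocks **and** the outcome, so
the dimension reduction is outcome-aware and the omics–outcome association
comes with likelihood-based tests.

It is aimed at statisticians and computational biologists who want an
interpretable joint/specific decomposition of two heterogeneous blocks plus
a formal test of whether the shared structure is associated with a
(continuous or binary) outcome.

## The model

For row vectors x (p features), y (q features) and outcome z per subject:

```
x = t W' + t⊥ W⊥' + e            t   ~ N(0, Σt)       K joint components
y = u C' + u⊥ C⊥' + f            t⊥  ~ N(0, Σt⊥)      Kx x-specific
u = t B + h                      u⊥  ~ N(0, Σu⊥)      Ky y-specific
η(E[z]) = a0 + t a' + h b'       h   ~ N(0, Σh)       joint heterogeneity
```

with e ~ N(0, σe²Ip), f ~ N(0, σf²Iq), semi-orthogonal loading matrices
W, C, W⊥, C⊥, and a positive diagonal B linking the two joint score sets.
The coefficients are stored in the total/direct-effect form: `a` is the
total effect of the x-side joint scores on z and `b` the direct effect of
the y-side heterogeneity h = u − tB. The link η is the identity for a
gaussian outcome (z = ta' + hb' + g, g ~ N(0, σg²)) and the logit for a
bernoulli outcome. Parameters are identifiable up to component-wise sign
flips; fits are returned in a deterministic canonical form.

Estimation is maximum likelihood by EM. For a gaussian outcome the E-step
is exact Gaussian conditioning (computed through low-rank Woodbury
identities, never a dense (p+q+1)² inverse). For a bernoulli outcome the
joint-score integral is evaluated by tensor-product Gauss–Hermite
quadrature and the outcome coefficients are updated by one Armijo
backtracking gradient step per EM iteration. The omics–outcome association
is tested with Wald chi-square statistics `T_full = α̂ Π⁻¹ α̂'` (df = 2K,
α = (a, b)) and per-component 2-df analogues, with Cov(α̂) estimated from
the Louis observed Fisher information.

## Worked example

```python
from glmpo2pls import GLMPO2PLS, SimScenario, simulate_dataset

x, y, z, latents, truth = simulate_dataset(SimScenario(N=500, p=100, q=10, seed=42))
model = GLMPO2PLS(n_joint=1, n_specific_x=1, n_specific_y=1).fit(x, y, z)
print("converged:", model.converged_, "after", model.n_iter_, "iterations")
print("a_hat:", model.coef_a_.round(3), " b_hat:", model.coef_b_.round(3))
res = model.test_association(x, y, z)
print("T_full = %.1f (df=%d), p = %.3g" % (res.T_full, res.df_full, res.p_full))
```

prints

```
converged: True after 37 iterations
a_hat: [1.96]  b_hat: [0.972]
T_full = 1520.4 (df=2), p = 0
```

The simulated truth is a = 2, b = 1: the fitted total x-effect (1.96) and
direct y-effect (0.972) recover it closely at N = 500, and the full test
overwhelmingly rejects "no omics–outcome association" (a chi-square of
1520 on 2 df). The t–u link itself can be tested per component:

```python
from glmpo2pls import test_omics_association
B, T, p = test_omics_association(model.fit_result_, x, y)
# B_hat = 1.016, T = 532.3, p = 9.09e-118   (truth B = 1)
```

and out-of-sample prediction uses the conditional mean of z given (x, y):

```python
from glmpo2pls import simulate_from_params, predict_outcome, rmsep
xt, yt, zt, _ = simulate_from_params(truth, 1000, seed=1)
rmsep(predict_outcome(model.fit_result_, xt, yt), zt)   # 1.129
```

close to the irreducible outcome noise (sd 1.080) and far below the
marginal outcome sd (2.393).

A command-line interface mirrors the library:

```
glmpo2pls simulate --n 100 --p 100 --q 10 --seed 3 --out sim/
glmpo2pls fit --x sim/x.tsv --y sim/y.tsv --z sim/z.tsv --k 1 --kx 1 --ky 1 --out fit/
glmpo2pls test --fit fit/ --x sim/x.tsv --y sim/y.tsv --z sim/z.tsv --out tests/
glmpo2pls scree --x sim/x.tsv --y sim/y.tsv --out scree/
glmpo2pls benchmark --grid grid.tsv --reps 100 --seed 1 --out bench/
```

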