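# Methods

## Model

PARAFAC2 decomposes a third-order array stored as K slabs `X_k` (each
`I × J_k`, the second mode may be ragged) into

```
X_k = A D_k Fᵀ P_kᵀ + E_k ,     P_kᵀ P_k = I_M ,
```

with shared first-mode loadings `A (I × M)`, per-slab diagonal scalings
`D_k = diag(c_k·)` collected in `C (K × M)`, a shared square matrix
`F (M × M)` and per-slab column-orthonormal projections `P_k (J_k × M)`.
The varying-mode loadings are `F_k = P_k F`; the orthonormality of `P_k`
forces all `F_kᵀF_k` to be equal, which is what gives the decomposition its
essential uniqueness — the property that makes it useful for, e.g.,
deconvolving GC-MS elution profiles under retention-time shifts or
fluorescence excitation–emission surfaces across samples.

### Direct fitting (maximum likelihood)

Alternating least squares: for fixed `(A, C, F)` each `P_k` solves an
orthogonal Procrustes problem, `P_k = V_k U_kᵀ` with
`U_k S_k V_kᵀ = F D_k Aᵀ X_k`; the slabs are then projected
(`Y_k = X_k P_k`) and one CP-ALS round updates `A`, `F`, `C` by exact least
squares on the `I × M × K` array `Y`. Every sub-step is an exact
least-squares solve, so the fit `R² = 1 − Σ_k‖X_k − X̂_k‖²/Σ_k‖X_k‖²` is
monotone over sweeps. Restarts perturb an SVD-based initialization
(`A` from left singular vectors of the column-concatenated slabs, `F = I`,
`C = 1`); the restart with the highest final `R²` is kept.

### Probabilistic model

Rows of `A` and `F` get standard-normal priors; rows of `C` get
`N(0, diag(α)⁻¹)` with per-component ARD precisions `α_m`; noise is Gaussian
with per-slab precision `τ_k` (heteroscedastic) or a single shared `τ`
(homoscedastic), with a shape–scale `Gamma(a_τ0, b_τ0)` prior. Two
treatments of the orthogonality constraint:

* **vMF** — `q(P_k)` is a matrix von Mises–Fisher distribution
  `∝ exp tr(B_kᵀP_k)` supported on the Stiefel manifold, so
  `E[P_kᵀP_k] = I` holds exactly for every realization; the posterior mean
  `E[P_k] = U Ψ Vᵀ` (from `B_k = U S Vᵀ`) has singular values `Ψ_m < 1`.
* **cMN** — `q(P_k)` is a matrix normal `MN(M_k, I_J, Σ_k)` whose *mean* is
  constrained to the Stiefel manifold. Maximizing the ELBO over the mean
  reduces to the same Procrustes SVD as direct fitting;
  `E[P_kᵀP_k] = I + J_k Σ_k` by the standard matrix-normal identity.

Mean-field coordinate ascent maximizes the ELBO in the fixed sweep order
`A → C → F → P → τ → α` (the problem is non-convex and sensitive to update
order; the order is a documented policy, configurable only in code). The `F`
update is a Gauss–Seidel sweep over component rows because the quadratic
term couples rows through `E[P_kᵀP_k]`; for the vMF variant that matrix is
the identity and the rows decouple. `α` is a MAP point update
`α_m = K / Σ_k E[c_km²]`, capped at `1e12`; a component at the cap is
reported as pruned. Component importance is the reconstruction share
(squared Frobenius norm of the componentwise reconstruction over the total),
and `effective_components` counts shares above `1e-3`.

### Derived choice: the cMN covariance update

Writing the `Σ_{P_k}`-dependent ELBO terms out gives

```
ELBO(Σ) = −(E[τ_k]/2)·J_k tr(ΣW) − (J_k/2) tr(Σ) + (J_k/2) log|Σ| + const,
W = E[F D_k AᵀA D_k Fᵀ],
```

whose exact maximizer is `Σ_{P_k} = (E[τ_k] W + I)⁻¹`. This τ-scaled form is
the default because it is the unique update consistent with coordinate
ascent (the ELBO is provably non-decreasing under it). An alternative
un-scaled form `(W + I)⁻¹` is available via `sigma_p_tau_scaled=False`; it
is not a coordinate-ascent optimum and can produce small ELBO decreases, so
the monotonicity guarantee is only stated for the default.

### Matrix ₀F₁ evaluation

The vMF normalizer is `κ(B) = ₀F₁(J/2; S²/4) · v_{J,M}` with `S` the
singular values of `B` and `v_{J,M} = 2^M π^{JM/2} / Γ_M(J/2)` the Stiefel
volume. `log ₀F₁` and its gradient `Ψ` are evaluated by three routes:

1. `M = 1`: exact, via `₀F₁(a; s²/4) = Γ(a)(s/2)^{1−a} I_{a−1}(s)` with
   exponentially scaled Bessel functions; a large-argument asymptotic
   series replaces `ive` beyond `s ≈ 1e8` where it loses accuracy.
2. `M = 2`, `max S ≤ 60`: exact deterministic quadrature. Conditioning the
   uniform Stiefel measure on the first column reduces the normalizer to a
   2-D integral of scalar-Bessel factors over the unit disk; a polar
   substitution removes the boundary singularity and Gauss–Legendre ×
   trapezoid rules give ~1e−10 accuracy (node count grows with `max S`).
3. otherwise: a sequential product of scalar Bessel factors
   `∏_i ₀F₁((J−i+1)/2; s_i²/4)` with `S` sorted descending. This is exact
   at `S = 0` and reproduces the leading-order Laplace (saddle-point)
   approximation of the Stiefel integral when the singular values are large
   and well separated — the regime a converging fit reaches, since
   `B_k = E[τ_k]·X_kᵀ E[A] E[D_k] E[F]ᵀ` scales with the data and the noise
   precision.

`Ψ_m = ∂ log ₀F₁ / ∂S_m` uses central differences (step
`1e−5·max(1, S_m)`), clipped to `[0, 1)`; an analytic Bessel-ratio backend
exists for the scalar/product paths and agrees to 1e−4 (tested). The
residual ₀F₁ approximation error for `M ≥ 3` is why the vMF variant's ELBO
monotonicity is guaranteed only to `1e−4` relative, versus `1e−8` for the
fully closed-form cMN variant.

### Fitting schedule

Initialization defaults to the direct-fit solution with component scales
balanced into `C` (unit-norm `A` columns) so that the ARD prior acts on a
common scale; `q(P)` is initialized from its own update and the initial
noise precision from the direct-fit residual variance. The precision update
is suspended for the first `noise_delay_iters` sweeps (default 50) while the
ARD scales adapt — updating τ immediately from a good initialization can
freeze the model before excess components are pruned. Convergence is
declared when `|ΔELBO| / (|ELBO| + 1e−12) < rel_tol` (default 1e−9) after
the delay window, or at `max_iter` (default 10⁴). Restarts perturb the
initialization; the highest *final* ELBO wins.

## Synthetic data generator

The generator reproduces the standard simulation protocol for this model
family: `A` with i.i.d. standard-normal entries; `F = Lᵀ` from the Cholesky
factor `G = LLᵀ` of the correlation matrix with unit diagonal and constant
off-diagonal 0.4 (so `FᵀF = G`, keeping components correlated but distinct);
`C` entries i.i.d. Uniform(0, 30); `P_k` by QR-orthonormalization of
Gaussian draws with a deterministic sign convention. The reference grid is
50×50×10 tensors with M = 4, SNR from −20 to 10 dB in 2 dB steps, both
noise modes, 10 replicates — 320 datasets.

Two choices the protocol leaves open are fixed here and documented:

* **SNR convention**: power ratio on Frobenius norms aggregated over slabs,
  `SNR_dB = 10 log₁₀(Σ_k‖signal_k‖² / Σ_k E‖E_k‖²)`.
* **Heteroscedastic scheme**: each slab's nominal SNR is jittered by
  Uniform(−6, +6) dB and the per-slab variances are rescaled by a common
  factor so the aggregate matches the target. This is an explicit stand-in
  policy (±6 dB spans a meaningful spread without drowning single slabs),
  not a reconstruction of any published scheme.

What the generator does *not* emulate: retention-time shifts or warped
elution profiles (the data are exactly PARAFAC2 plus white Gaussian noise),
non-negativity of real intensity data, correlated or non-Gaussian noise,
and missing values. Passing tests therefore demonstrate correct inference
under the model's own assumptions — robustness conclusions about real
chromatographic data require the real-data workflow, not the simulator.

## Diagnostics and model order

The ELBO serves as the probabilistic model-order criterion; the direct fit
reports `R²` (monotone in M, hence only a heuristic) and the core
consistency diagnostic `CCD = 100(1 − ‖G − I‖²_F/M)`, where `G` is the
least-squares Tucker core of the projected array with the CP loadings held
fixed (solved by mode products with pseudo-inverses, equivalent to the
`(C ⊗ F ⊗ A)` least-squares system). Scan output is normalized per criterion
to [0, 100] for display, pooling homo-/heteroscedastic variants of the same
model family onto one scale; the normalization is order preserving and
display-only. An advisory elbow locator (largest discrete second difference)
is reported but never used as a sole selector — CCD and ELBO should be read
together with the loadings and residuals.

Component matching uses uncentered cosine (Tucker congruence) between
vectorized componentwise reconstructions, maximized over one-to-one
assignments (Hungarian algorithm); Pearson correlation is available but
cosine is the default since reconstructions are non-centered intensity
surfaces.

## Numerical choices and degenerate inputs

* M×M normal equations get a `1e−10` ridge only when ill-conditioned
  (condition number > 1e12), with a logged warning.
* SVDs use a deterministic sign convention (largest-magnitude entry of each
  left singular vector made positive) so repeated runs are bit-stable.
* All-zero data tensors are rejected in `R²` (zero denominator), and
  all-zero models in component shares; a fit whose ARD prunes *every*
  component (possible at very low SNR) reports zero shares rather than
  failing.
* The rejection sampler for the vMF distribution uses the tight uniform
  envelope `exp(tr(BᵀP) − Σ_m S_m)`; it is an oracle for tests, and raises
  at concentrations where the acceptance rate collapses rather than
  stalling.
* Hyperprior default `(a_τ0, b_τ0) = (1, 10³)` — effectively uninformative
  at the simulated noise scales; configurable.

## Problem sizes in tests and the acceptance script

The bundled checks run on scaled-down instances chosen to exercise every
code path with comfortable statistical margins: 20×20×6 (M = 3) for exact
recovery, 30×30×8 (truth M = 4, fitted M = 6) for ARD pruning and parameter
recovery over 10 seeds, 24×24×6 for the noise-model ELBO comparison, and 20
small random datasets for the coordinate-ascent audit. These sizes are the
package's own test design; the full 50×50×10 × 320-dataset grid is
available through `generate_grid` / the `simulate` CLI command.

## Known limitations

* For `M ≥ 3` at moderate concentration the ₀F₁ product approximation can
  deviate at the percent level; vMF ELBO values across different `M` are
  comparable only to that accuracy.
* ARD is a MAP update, so the ELBO is not a bound on the evidence with
  respect to α (a Gamma variational factor would restore that, at the cost
  of the pruning sharpness this package prioritizes).
* No non-negativity or other constraints on `A`, `C`, `F`; no missing-data
  handling; inference is full-batch (no stochastic/minibatch VI).
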