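# probparafac2

Probabilistic PARAFAC2: variational Bayesian multiway decomposition with
orthogonality-constrained slab loadings, plus the classical direct-fitting
(alternating least squares) baseline.

## The problem

Multiway data with one *incomparable* mode are common in chemometrics and
metabolomics: GC-MS runs of different samples sampled at shifted retention
times, fluorescence excitation–emission surfaces across batches, process
data with unequal batch lengths. Such data form K slabs `X_k` of size
`I × J_k` where the second mode cannot be aligned across slabs. PARAFAC2
models every slab as

```
X_k = A D_k Fᵀ P_kᵀ + E_k ,     P_kᵀ P_k = I_M ,
```

with shared loadings `A` (I × M), per-slab component scalings
`D_k = diag(c_k·)` (rows of `C`, K × M), and per-slab varying-mode loadings
`F_k = P_k F` whose Gram matrix `F_kᵀF_k` is constant across slabs — the
constraint that makes the decomposition essentially unique.

This package fits that model two ways:

* **Direct fitting** — maximum-likelihood ALS alternating an orthogonal-
  Procrustes SVD update of each `P_k` with a CP round on the projected
  slabs; reports `R²` and the core consistency diagnostic (CCD).
* **Variational Bayes** — mean-field inference over all factors with
  automatic relevance determination (ARD) pruning excess components and
  either homoscedastic (shared τ) or heteroscedastic (per-slab τ_k) noise.
  Orthogonality of `P_k` is handled either by a matrix von Mises–Fisher
  factor on the Stiefel manifold (`variant="vmf"`, every realization is
  orthonormal) or by a Stiefel-constrained matrix-normal mean
  (`variant="cmn"`, closed-form updates mirroring the ALS projection).
  The ELBO doubles as a model-order criterion.

The probabilistic fits are more robust than ALS to noise and to
overspecifying the number of components: ARD turns surplus components off
instead of letting them absorb noise. See `docs/methods.md` for the model,
the update equations' structure, the matrix-₀F₁ numerics behind the vMF
factor, and the synthetic-data protocol.

## Worked example

```python
import numpy as np
from probparafac2 import (SimConfig, simulate, fit_direct, DirectFitOptions,
                          fit_vb, FitOptions, noiseless_r2)

# 30 x 30 x 8 tensor, 4 true components, 4 dB SNR — fitted with M = 6
ds = simulate(SimConfig(I=30, J=30, K=8, M=4, snr_db=4.0, seed=7))

fd, repd = fit_direct(ds.noisy, DirectFitOptions(M=6, max_iter=300, n_starts=2, seed=0))
state, f, rep = fit_vb(ds.noisy, FitOptions(M=6, variant="vmf",
                       noise_mode="heteroscedastic", max_iter=250, seed=0))

print("direct  R2 =", round(repd.final_r2, 4), " noiseless R2 =", round(noiseless_r2(ds.signal, fd), 4))
print("vb final ELBO =", round(rep.final_elbo, 1), " iterations =", rep.n_iter)
print("effective components =", rep.effective_components)
print("component shares =", np.round(rep.per_component_share, 4))
print("vb noiseless R2 =", round(noiseless_r2(ds.signal, f), 4))
```

Output:

```
direct  R2 = 0.7825  noiseless R2 = 0.9011
vb final ELBO = -21671.4  iterations = 250
effective components = 4
component shares = [0.2582 0.1965 0.3383 0.207  0.     0.    ]
vb noiseless R2 = 0.9515
```

Reading it: the direct fit explains 78% of the *noisy* data at M = 6 but
only 90% of the underlying noise-free signal — the two surplus components
fit noise. The variational fit prunes exactly those two components (their
reconstruction shares drop to zero), leaving four effective components and
a noiseless R² of 0.95: closer to the truth despite the misspecified model
order.

## Command line

```bash
probparafac2 simulate --out runs/sim --seed 1 --shape 50 50 10 4 --snr 4
probparafac2 fit runs/sim/dataset_0000.noisy.h5 --out runs/fit \
    --variant vmf --noise hetero -M 6 --seed 1
probparafac2 scan runs/sim/dataset_0000.noisy.h5 --out runs/scan --m-min 1 --m-max 8
probparafac2 diagnose runs/sim/dataset_0000.noisy.h5 runs/fit/factors.h5 --out runs/diag
```

`simulate --paper-grid` generates the full benchmark grid (SNR −20…10 dB in
2 dB steps, both noise modes, 10 replicates → 320 datasets). Every command
writes a resolved-config copy and records all seeds.

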