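"""Mean-field variational inference for probabilistic PARAFAC2.

Generative model (per slab k, M components):

    a_i.  ~ N(0, I_M)                       rows of A (I x M)
    f_m.  ~ N(0, I_M)                       rows of F (M x M)
    c_k.  ~ N(0, diag(alpha)^-1)            rows of C (K x M), ARD prior
    P_k   ~ uniform vMF / matrix normal     J_k x M, orthogonality handled
                                            by the chosen variant
    tau_k ~ Gamma(a_tau0, b_tau0)           noise precision (shape, scale)
    X_k   ~ N(A D_k F' P_k', tau_k^-1 I)    D_k = diag(c_k.)

Two variants differ in how the PARAFAC2 orthogonality constraint
P_k'P_k = I enters the variational factor q(P_k):

* ``vmf`` — q(P_k) is a matrix von Mises–Fisher distribution, supported on
  the Stiefel manifold, so E[P_k'P_k] = I holds for every realization;
* ``cmn`` — q(P_k) is a matrix normal MN(M_k, I_J, Sigma_k) whose MEAN is
  constrained to the Stiefel manifold; the mean update is the same
  orthogonal-Procrustes SVD as in direct fitting.

The noise is either homoscedastic (one shared precision) or heteroscedastic
(per-slab precisions).  The ARD scales alpha are MAP point estimates whose
update alpha_m = K / sum_k E[c_km^2] drives redundant components to zero.

Every update is exact coordinate ascent on the ELBO given the moments in
play, so the ELBO trace is non-decreasing (for the vMF variant, up to the
documented 0F1 approximation error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import digamma, gammaln

from .data_model import DataModelError, FactorSet, SlabTensor
from .direct_fit import DirectFitOptions, _signed_svd, fit_direct
from .vmf_distribution import (
    VmfMoments,
    VmfParam,
    stiefel_log_volume,
    vmf_entropy,
    vmf_mode,
    vmf_moments,
)

__all__ = [
    "FitOptions",
    "FitReport",
    "VariationalState",
    "fit_vb",
    "compute_elbo",
    "expect_outer_C_A",
    "expect_PtP",
    "expect_FtPtPF",
    "save_state",
    "load_state",
]

logger = logging.getLogger(__name__)

ALPHA_MAX = 1e12  # cap on ARD precisions; components at the cap are pruned
SHARE_THRESHOLD = 1e-3  # reconstruction share below which a component counts as dead


@dataclass
class FitOptions:
    M: int = 4
    variant: str = "vmf"  # 'vmf' or 'cmn'
    noise_mode: str = "heteroscedastic"  # or 'homoscedastic'
    a_tau0: float = 1.0
    b_tau0: float = 1e3
    max_iter: int = 10_000
    rel_tol: float = 1e-9
    noise_delay_iters: int = 50
    n_starts: int = 1
    seed: int = 0
    init: str = "direct_fit"  # or 'random'
    sigma_p_tau_scaled: bool = True  # exact coordinate-ascent Sigma_Pk update
    direct_fit_opts: DirectFitOptions | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("vmf", "cmn"):
            raise DataModelError(f"unknown variant {self.variant!r}")
        if self.noise_mode not in ("homoscedastic", "heteroscedastic"):
            raise DataModelError(f"unknown noise_mode {self.noise_mode!r}")
        if self.rel_tol <= 0 or self.max_iter < 1 or self.M < 1:
            raise DataModelError("rel_tol, max_iter and M must be positive")
        if self.a_tau0 <= 0 or self.b_tau0 <= 0:
            raise DataModelError("Gamma hyperparameters must be positive")
        if self.noise_delay_iters < 0 or self.n_starts < 1:
            raise DataModelError("noise_delay_iters >= 0 and n_starts >= 1 required")


@dataclass
class FitReport:
    elbo_trace: list[float]
    final_elbo: float
    n_iter: int
    converged: bool
    effective_components: int
    per_component_share: np.ndarray
    restart_elbo: list[float] = field(default_factory=list)


class _VmfFactor:
    """q(P_k) = vMF(B_k); caches the moments of the current parameter."""

    def __init__(self, B: np.ndarray):
        self.param = VmfParam(B)
        self.moments: VmfMoments = vmf_moments(self.param)

    @property
    def mean(self) -> np.ndarray:
        return self.moments.mean

    def EPtP(self) -> np.ndarray:
        return np.eye(self.param.M)

    def entropy(self) -> float:
        return vmf_entropy(self.param, self.moments)

    def expected_log_prior(self) -> float:
        # uniform prior on the Stiefel manifold
        return -stiefel_log_volume(self.param.J, self.param.M)


class _CmnFactor:
    """q(P_k) = MN(M_k, I_J, Sigma_k) with Stiefel-constrained mean."""

    def __init__(self, mean: np.ndarray, Sigma: np.ndarray):
        self.mean_mat = mean  # J x M, orthonormal columns
        self.Sigma = Sigma  # M x M

    @property
    def mean(self) -> np.ndarray:
        return self.mean_mat

    @property
    def J(self) -> int:
        return self.mean_mat.shape[0]

    def EPtP(self) -> np.ndarray:
        # MN(M, I_J, Sigma): E[P'P] = M'M + J Sigma = I + J Sigma
        return np.eye(self.Sigma.shape[0]) + self.J * self.Sigma

    def entropy(self) -> float:
        J, M = self.mean_mat.shape
        sign, logdet = np.linalg.slogdet(self.Sigma)
        return 0.5 * J * M * np.log(2 * np.pi * np.e) + 0.5 * J * logdet

    def expected_log_prior(self) -> float:
        # prior MN(0, I_J, I_M): -JM/2 log 2pi - 1/2 tr E[P'P]
        J, M = self.mean_mat.shape
        return -0.5 * J * M * np.log(2 * np.pi) - 0.5 * float(np.trace(self.EPtP()))


@dataclass
class VariationalState:
    """All variational parameters plus the MAP ARD scales."""

    mu_A: np.ndarray  # I x M
    Sigma_A: np.ndarray  # M x M shared across rows
    mu_C: np.ndarray  # K x M
    Sigma_C: np.ndarray  # K x M x M
    mu_F: np.ndarray  # M x M (rows f_m.)
    Sigma_F: np.ndarray  # M x M x M (one per row)
    qP: list  # per-slab _VmfFactor or _CmnFactor
    tau_shape: np.ndarray  # K (heteroscedastic) or length-1 (homoscedastic)
    tau_scale: np.ndarray
    alpha: np.ndarray  # M
    noise_mode: str = "heteroscedastic"
    variant: str = "vmf"
    sigma_p_tau_scaled_active: bool = True

    # -- moments -----------------------------------------------------------
    def E_tau(self) -> np.ndarray:
        """Per-slab E[tau_k] (broadcast for homoscedastic noise)."""
        e = self.tau_shape * self.tau_scale
        if self.noise_mode == "homoscedastic":
            return np.full(self.mu_C.shape[0], float(e[0]))
        return e

    def E_log_tau(self) -> np.ndarray:
        e = digamma(self.tau_shape) + np.log(self.tau_scale)
        if self.noise_mode == "homoscedastic":
            return np.full(self.mu_C.shape[0], float(e[0]))
        return e

    def E_AtA(self) -> np.ndarray:
        I = self.mu_A.shape[0]
        return self.mu_A.T @ self.mu_A + I * self.Sigma_A

    def E_ctc(self, k: int) -> np.ndarray:
        return np.outer(self.mu_C[k], self.mu_C[k]) + self.Sigma_C[k]

    def factor_set(self, orthogonal_summary: bool = False) -> FactorSet:
        """Point summary: variational means; for the vMF variant the mode
        U V' can be requested as an orthogonal summary of P_k."""
        P = []
        for q in self.qP:
            if orthogonal_summary and isinstance(q, _VmfFactor):
                P.append(vmf_mode(q.param))
            else:
                P.append(q.mean.copy())
        return FactorSet(self.mu_A.copy(), self.mu_C.copy(), self.mu_F.copy(), P)


# ---------------------------------------------------------------------------
# Non-trivial expectations
# ---------------------------------------------------------------------------


def expect_outer_C_A(E_ctc: np.ndarray, E_ata: np.ndarray) -> np.ndarray:
    """E[D_k a' a D_k] = E[c_k.' c_k.] o E[a' a] (Hadamard of second moments).

    The diagonal matrix D_k sandwiching an inner matrix turns, in
    expectation, into the elementwise product of the two M x M second-moment
    matrices."""
    return E_ctc * E_ata


def expect_PtP(q) -> np.ndarray:
    """E[P_k'P_k]: the identity for the vMF factor, I + J_k Sigma_Pk for the
    matrix-normal factor (standard MN second-moment identity)."""
    return q.EPtP()


def expect_FtPtPF(mu_F: np.ndarray, Sigma_F: np.ndarray, EPtP: np.ndarray) -> np.ndarray:
    """E[F' P'P F]_{ij} = sum_{m,m'} E[F_mi F_m'j] E[P'P]_{mm'}; the same-row
    covariance corrects the m = m' terms."""
    out = mu_F.T @ EPtP @ mu_F
    out = out + np.einsum("m,mij->ij", np.diag(EPtP), Sigma_F)
    return out


def _E_FDAADF(state: VariationalState, k: int) -> np.ndarray:
    """E[F D_k A'A D_k F'] (M x M), needed for the cMN Sigma_Pk update."""
    H = expect_outer_C_A(state.E_ctc(k), state.E_AtA())
    W = state.mu_F @ H @ state.mu_F.T
    W = W + np.diag([float(np.sum(H * state.Sigma_F[m])) for m in range(state.mu_F.shape[0])])
    return W


# ---------------------------------------------------------------------------
# Coordinate updates (Gaussian factors in-place on the state)
# ---------------------------------------------------------------------------


def update_A(state: VariationalState, x: SlabTensor) -> None:
    M = state.mu_F.shape[0]
    Etau = state.E_tau()
    prec = np.eye(M)
    lin = np.zeros((x.I, M))
    for k in range(x.K):
        EPtP = expect_PtP(state.qP[k])
        W = expect_FtPtPF(state.mu_F, state.Sigma_F, EPtP)
        prec = prec + Etau[k] * expect_outer_C_A(state.E_ctc(k), W)
        lin = lin + Etau[k] * (x[k] @ state.qP[k].mean @ state.mu_F * state.mu_C[k])
    Sigma = _sym_inv(prec)
    state.Sigma_A = Sigma
    state.mu_A = lin @ Sigma


def update_C(state: VariationalState, x: SlabTensor) -> None:
    Etau = state.E_tau()
    E_ata = state.E_AtA()
    for k in range(x.K):
        EPtP = expect_PtP(state.qP[k])
        W = expect_FtPtPF(state.mu_F, state.Sigma_F, EPtP)
        prec = np.diag(state.alpha) + Etau[k] * (W * E_ata)
        Sigma = _sym_inv(prec)
        lin = Etau[k] * np.diag(state.mu_F.T @ state.qP[k].mean.T @ x[k].T @ state.mu_A)
        state.Sigma_C[k] = Sigma
        state.mu_C[k] = Sigma @ lin


def update_F(state: VariationalState, x: SlabTensor) -> None:
    """Gauss–Seidel sweep over component rows f_m., using rows already
    refreshed within the sweep for the cross-component correction."""
    M = state.mu_F.shape[0]
    Etau = state.E_tau()
    E_ata = state.E_AtA()
    H = [expect_outer_C_A(state.E_ctc(k), E_ata) for k in range(x.K)]  # E[D A'A D]
    EPtP = [expect_PtP(state.qP[k]) for k in range(x.K)]
    lin_data = []  # per slab: E[P]' X' E[A] D  (M x M, row m belongs to f_m.)
    for k in range(x.K):
        lin_data.append((state.qP[k].mean.T @ x[k].T @ state.mu_A) * state.mu_C[k])
    for m in range(M):
        prec = np.eye(M)
        lin = np.zeros(M)
        for k in range(x.K):
            prec = prec + Etau[k] * H[k] * EPtP[k][m, m]
            cross = np.zeros(M)
            for mp in range(M):
                if mp != m and EPtP[k][m, mp] != 0.0:
                    cross += EPtP[k][m, mp] * state.mu_F[mp]
            lin = lin + Etau[k] * (lin_data[k][m] - H[k] @ cross)
        Sigma = _sym_inv(prec)
        state.Sigma_F[m] = Sigma
        state.mu_F[m] = Sigma @ lin


def update_P_vmf(state: VariationalState, x: SlabTensor, k: int) -> None:
    """Free-form vMF update: B_k = E[tau_k] X_k' E[A] E[D_k] E[F'] (J_k x M,
    the transpose of the Table-formula product)."""
    B = state.E_tau()[k] * (x[k].T @ (state.mu_A * state.mu_C[k]) @ state.mu_F.T)
    state.qP[k] = _VmfFactor(B)


def update_P_cmn(state: VariationalState, x: SlabTensor, k: int) -> None:
    """Stiefel-constrained mean by the direct-fit Procrustes SVD; Sigma from
    moment matching (tau-scaled exact coordinate-ascent form by default)."""
    T = (state.mu_F * state.mu_C[k]) @ (state.mu_A.T @ x[k])  # E[F]E[D]E[A']X_k, M x J
    U, _, Vt = _signed_svd(T)
    mean = Vt.T @ U.T
    W = _E_FDAADF(state, k)
    tau_w = state.E_tau()[k] if state.sigma_p_tau_scaled_active else 1.0
    Sigma = _sym_inv(tau_w * W + np.eye(W.shape[0]))
    state.qP[k] = _CmnFactor(mean, Sigma)


def _expected_slab_sse(state: VariationalState, x: SlabTensor, k: int) -> float:
    """E||X_k - A D_k F' P_k'||^2 under the current variational factors."""
    EPtP = expect_PtP(state.qP[k])
    W = expect_FtPtPF(state.mu_F, state.Sigma_F, EPtP)
    quad = float(np.sum(expect_outer_C_A(state.E_ctc(k), W) * state.E_AtA()))
    recon = (state.mu_A * state.mu_C[k]) @ state.mu_F.T @ state.qP[k].mean.T
    cross = float(np.sum(x[k] * recon))
    return float(np.sum(x[k] * x[k])) - 2.0 * cross + quad


def update_tau(state: VariationalState, x: SlabTensor, a0: float, b0: float) -> None:
    sse = np.array([_expected_slab_sse(state, x, k) for k in range(x.K)])
    n_k = np.array([x.I * j for j in x.J], dtype=float)
    if state.noise_mode == "heteroscedastic":
        state.tau_shape = a0 + n_k / 2.0
        state.tau_scale = 1.0 / (1.0 / b0 + sse / 2.0)
    else:
        state.tau_shape = np.array([a0 + n_k.sum() / 2.0])
        state.tau_scale = np.array([1.0 / (1.0 / b0 + sse.sum() / 2.0)])
    if np.any(state.tau_scale <= 0):
        raise FloatingPointError("negative Gamma scale in the tau update")


def update_alpha(state: VariationalState) -> None:
    """MAP ARD update alpha_m = K / sum_k E[c_km^2], capped at ALPHA_MAX."""
    K = state.mu_C.shape[0]
    Ec2 = np.sum(state.mu_C**2, axis=0) + np.einsum("kmm->m", state.Sigma_C)
    with np.errstate(divide="ignore"):
        state.alpha = np.where(Ec2 > 0, np.minimum(K / Ec2, ALPHA_MAX), ALPHA_MAX)


def _sym_inv(Mat: np.ndarray) -> np.ndarray:
    Sigma = np.linalg.inv(Mat)
    return 0.5 * (Sigma + Sigma.T)


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------


def _gamma_entropy(shape: np.ndarray, scale: np.ndarray) -> float:
    return float(
        np.sum(shape + np.log(scale) + gammaln(shape) + (1.0 - shape) * digamma(shape))
    )


def compute_elbo(state: VariationalState, x: SlabTensor, a0: float, b0: float) -> float:
    """Full evidence lower bound E[log p(X, theta)] - E[log q(theta)]."""
    I, K, M = x.I, x.K, state.mu_F.shape[0]
    Etau = state.E_tau()
    Elogtau = state.E_log_tau()
    terms = {}
    # likelihood
    lik = 0.0
    for k in range(K):
        n = I * x.J[k]
        lik += 0.5 * n * (Elogtau[k] - np.log(2 * np.pi)) - 0.5 * Etau[k] * _expected_slab_sse(
            state, x, k
        )
    terms["lik"] = lik
    # priors
    terms["pA"] = -0.5 * I * M * np.log(2 * np.pi) - 0.5 * float(np.trace(state.E_AtA()))
    Ec2 = np.sum(state.mu_C**2, axis=0) + np.einsum("kmm->m", state.Sigma_C)
    terms["pC"] = float(
        -0.5 * K * M * np.log(2 * np.pi)
        + 0.5 * K * np.sum(np.log(state.alpha))
        - 0.5 * np.sum(state.alpha * Ec2)
    )
    Ef2 = np.sum(state.mu_F**2) + float(np.einsum("mii->", state.Sigma_F))
    terms["pF"] = -0.5 * M * M * np.log(2 * np.pi) - 0.5 * Ef2
    terms["pP"] = float(sum(q.expected_log_prior() for q in state.qP))
    # tau prior (shape-scale Gamma)
    Et = state.tau_shape * state.tau_scale
    Elt = digamma(state.tau_shape) + np.log(state.tau_scale)
    terms["ptau"] = float(
        np.sum(-gammaln(a0) - a0 * np.log(b0) + (a0 - 1.0) * Elt - Et / b0)
    )
    # entropies
    sign, logdet_a = np.linalg.slogdet(state.Sigma_A)
    hA = I * (0.5 * M * np.log(2 * np.pi * np.e) + 0.5 * logdet_a)
    hC = sum(
        0.5 * M * np.log(2 * np.pi * np.e) + 0.5 * np.linalg.slogdet(state.Sigma_C[k])[1]
        for k in range(K)
    )
    hF = sum(
        0.5 * M * np.log(2 * np.pi * np.e) + 0.5 * np.linalg.slogdet(state.Sigma_F[m])[1]
        for m in range(M)
    )
    hP = float(sum(q.entropy() for q in state.qP))
    hTau = _gamma_entropy(state.tau_shape, state.tau_scale)
    terms["h"] = float(hA + hC + hF + hP + hTau)
    elbo = float(sum(terms.values()))
    if not np.isfinite(elbo):
        bad = {k: v for k, v in terms.items() if not np.isfinite(v)}
        raise FloatingPointError(f"non-finite ELBO terms: {bad}")
    return elbo


# ---------------------------------------------------------------------------
# Initialization and the fitting schedule
# ---------------------------------------------------------------------------


def _init_state(
    x: SlabTensor, opts: FitOptions, rng: np.random.Generator, perturb: bool
) -> VariationalState:
    M = opts.M
    if opts.init == "direct_fit":
        dopts = opts.direct_fit_opts or DirectFitOptions(
            M=M, max_iter=500, n_starts=1, seed=int(rng.integers(2**31))
        )
        if dopts.M != M:
            raise DataModelError("direct_fit_opts.M must match FitOptions.M")
        f, _ = fit_direct(x, dopts)
        A, C, F, P = f.A.copy(), f.C.copy(), f.F.copy(), [p.copy() for p in f.P]
    else:
        A = rng.standard_normal((x.I, M))
        C = np.abs(rng.standard_normal((x.K, M)))
        F = np.eye(M)
        P = [np.linalg.qr(rng.standard_normal((j, M)))[0] for j in x.J]
    if perturb:
        A = A + 0.1 * np.std(A) * rng.standard_normal(A.shape)
        C = C + 0.1 * (np.std(C) + 1e-12) * rng.standard_normal(C.shape)
    # scale balancing: unit-norm A columns, scale folded into C (ARD acts on C)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    A = A / norms
    C = C * norms
    # residual-based initial noise level
    recon_sse = sum(
        float(np.sum((x[k] - (A * C[k]) @ F.T @ P[k].T) ** 2)) for k in range(x.K)
    )
    n_tot = x.n_entries
    tau0 = n_tot / max(recon_sse, 1e-12 * x.squared_norm(), 1e-300)
    if opts.noise_mode == "heteroscedastic":
        tau_shape = np.full(x.K, opts.a_tau0 + 0.0)
        tau_scale = np.full(x.K, tau0 / tau_shape[0])
    else:
        tau_shape = np.array([opts.a_tau0 + 0.0])
        tau_scale = np.array([tau0 / tau_shape[0]])
    state = VariationalState(
        mu_A=A,
        Sigma_A=1e-6 * np.eye(M),
        mu_C=C,
        Sigma_C=np.stack([1e-6 * np.eye(M)] * x.K),
        mu_F=F,
        Sigma_F=np.stack([1e-6 * np.eye(M)] * M),
        qP=[None] * x.K,
        tau_shape=tau_shape,
        tau_scale=tau_scale,
        alpha=np.ones(M),
        noise_mode=opts.noise_mode,
        variant=opts.variant,
    )
    state.sigma_p_tau_scaled_active = opts.sigma_p_tau_scaled
    # q(P) from its own update so the state starts internally consistent
    for k in range(x.K):
        if opts.variant == "vmf":
            update_P_vmf(state, x, k)
        else:
            state.qP[k] = _CmnFactor(P[k], np.eye(M))  # placeholder mean
            update_P_cmn(state, x, k)
    return state


def _sweep(state: VariationalState, x: SlabTensor, opts: FitOptions, update_noise: bool) -> None:
    """One coordinate-ascent sweep in the fixed order A, C, F, P, tau, alpha."""
    update_A(state, x)
    update_C(state, x)
    update_F(state, x)
    for k in range(x.K):
        if opts.variant == "vmf":
            update_P_vmf(state, x, k)
        else:
            update_P_cmn(state, x, k)
    if update_noise:
        update_tau(state, x, opts.a_tau0, opts.b_tau0)
    update_alpha(state)


def _single_fit(
    x: SlabTensor, opts: FitOptions, rng: np.random.Generator, perturb: bool
) -> tuple[VariationalState, FitReport]:
    state = _init_state(x, opts, rng, perturb)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        _sweep(state, x, opts, update_noise=it > opts.noise_delay_iters)
        elbo = compute_elbo(state, x, opts.a_tau0, opts.b_tau0)
        trace.append(elbo)
        if len(trace) > 1 and it > opts.noise_delay_iters + 1:
            if abs(trace[-1] - trace[-2]) < opts.rel_tol * (abs(trace[-1]) + 1e-12):
                converged = True
                break
    from .diagnostics import component_shares

    try:
        shares = component_shares(state.factor_set())
    except DataModelError:  # fully pruned (all-zero) model at very low SNR
        shares = np.zeros(opts.M)
    report = FitReport(
        elbo_trace=trace,
        final_elbo=trace[-1],
        n_iter=it,
        converged=converged,
        effective_components=int(np.sum(shares > SHARE_THRESHOLD)),
        per_component_share=shares,
    )
    return state, report


def fit_vb(
    x: SlabTensor, opts: FitOptions
) -> tuple[VariationalState, FactorSet, FitReport]:
    """Fit the probabilistic PARAFAC2 by coordinate-ascent variational
    inference; among ``n_starts`` restarts the run with the highest final
    ELBO is returned.  The noise precision is held at its initial value for
    the first ``noise_delay_iters`` sweeps while the ARD scales adapt."""
    if opts.M > min(x.J):
        raise DataModelError(f"M={opts.M} exceeds the smallest slab width {min(x.J)}")
    rng = np.random.default_rng(opts.seed)
    best: tuple[VariationalState, FitReport] | None = None
    restart_elbo = []
    for start in range(opts.n_starts):
        state, rep = _single_fit(x, opts, rng, perturb=start > 0)
        restart_elbo.append(rep.final_elbo)
        if best is None or rep.final_elbo > best[1].final_elbo:
            best = (state, rep)
    best[1].restart_elbo = restart_elbo
    return best[0], best[0].factor_set(), best[1]


# ---------------------------------------------------------------------------
# State serialization
# ---------------------------------------------------------------------------


def save_state(state: VariationalState, path) -> None:
    with h5py.File(path, "w") as fh:
        q = fh.create_group("q")
        q.create_dataset("A/mu", data=state.mu_A)
        q.create_dataset("A/Sigma", data=state.Sigma_A)
        q.create_dataset("C/mu", data=state.mu_C)
        q.create_dataset("C/Sigma", data=state.Sigma_C)
        q.create_dataset("F/mu", data=state.mu_F)
        q.create_dataset("F/Sigma", data=state.Sigma_F)
        q.create_dataset("tau/shape", data=state.tau_shape)
        q.create_dataset("tau/scale", data=state.tau_scale)
        for k, qp in enumerate(state.qP):
            g = q.create_group(f"P/{k}")
            if isinstance(qp, _VmfFactor):
                g.attrs["kind"] = "vmf"
                g.create_dataset("B", data=qp.param.B)
            else:
                g.attrs["kind"] = "cmn"
                g.create_dataset("mean", data=qp.mean_mat)
                g.create_dataset("Sigma", data=qp.Sigma)
        fh.create_dataset("alpha", data=state.alpha)
        fh.attrs["noise_mode"] = state.noise_mode
        fh.attrs["variant"] = state.variant


def load_state(path) -> VariationalState:
    with h5py.File(path, "r") as fh:
        q = fh["q"]
        qP = []
        pg = q["P"]
        for k in sorted(pg.keys(), key=int):
            g = pg[k]
            if g.attrs["kind"] == "vmf":
                qP.append(_VmfFactor(g["B"][()]))
            else:
                qP.append(_CmnFactor(g["mean"][()], g["Sigma"][()]))
        state = VariationalState(
            mu_A=q["A/mu"][()],
            Sigma_A=q["A/Sigma"][()],
            mu_C=q["C/mu"][()],
            Sigma_C=q["C/Sigma"][()],
            mu_F=q["F/mu"][()],
            Sigma_F=q["F/Sigma"][()],
            qP=qP,
            tau_shape=q["tau/shape"][()],
            tau_scale=q["tau/scale"][()],
            alpha=fh["alpha"][()],
            noise_mode=str(fh.attrs["noise_mode"]),
            variant=str(fh.attrs["variant"]),
        )
    state.sigma_p_tau_scaled_active = True
    return state
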