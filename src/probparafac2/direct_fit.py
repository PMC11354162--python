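"""Direct-fitting PARAFAC2 by alternating least squares.

The classical maximum-likelihood algorithm minimizes

    Σ_k || X_k - A D_k F' P_k' ||²   s.t.  P_k' P_k = I_M

by alternating two steps: (1) for fixed A, D_k, F the optimal P_k solves an
orthogonal Procrustes problem, P_k = V_k U_k' from the SVD
U_k S_k V_k' = F D_k A' X_k; (2) the slabs are projected, Y_k = X_k P_k, and
one round of CP-ALS updates A, F and C on the I x M x K array Y.  Each
sub-step solves a least-squares problem exactly, so the objective (and hence
R²) is monotone over sweeps.

Also provides the core consistency diagnostic (CCD): with the CP loadings
held fixed on the projected array, the unconstrained Tucker core G is
re-estimated by least squares and compared with the superdiagonal array of
ones; CCD = 100 (1 - ||G - I||²_F / ||I||²_F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    DataModelError,
    FactorSet,
    SlabTensor,
    explained_variation,
)

__all__ = [
    "DirectFitOptions",
    "DirectFitReport",
    "update_projection",
    "cp_step",
    "fit_direct",
    "core_consistency",
]

logger = logging.getLogger(__name__)

RIDGE = 1e-10  # Tikhonov fallback for ill-conditioned normal equations


@dataclass
class DirectFitOptions:
    M: int = 4
    max_iter: int = 10_000
    rel_tol: float = 1e-9
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.max_iter < 1 or self.n_starts < 1:
            raise DataModelError("M, max_iter and n_starts must be positive")
        if self.rel_tol <= 0:
            raise DataModelError("rel_tol must be positive")


@dataclass
class DirectFitReport:
    r2_trace: list[float]
    final_r2: float
    n_iter: int
    converged: bool
    restart_r2: list[float] = field(default_factory=list)


def _signed_svd(M: np.ndarray):
    """Thin SVD with a deterministic sign convention on U's columns."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    for m in range(U.shape[1]):
        col = U[:, m]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            U[:, m] = -col
            Vt[m, :] = -Vt[m, :]
    return U, s, Vt


def update_projection(
    A: np.ndarray, c_k: np.ndarray, F: np.ndarray, X_k: np.ndarray
) -> np.ndarray:
    """Orthogonal-Procrustes update: P_k = V_k U_k' maximizing
    Tr(F D_k A' X_k P_k) over matrices with orthonormal columns."""
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(X_k))):
        raise DataModelError("non-finite input to update_projection")
    T = (F * c_k) @ (A.T @ X_k)  # F D_k A' X_k, shape M x J_k
    U, _, Vt = _signed_svd(T)
    return Vt.T @ U.T


def _solve_gram(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve G X = B for symmetric PSD G with a ridge fallback."""
    try:
        return np.linalg.solve(G, B)
    except np.linalg.LinAlgError:
        logger.warning("singular normal equations; adding ridge %.0e", RIDGE)
        return np.linalg.solve(G + RIDGE * np.eye(G.shape[0]), B)


def cp_step(
    Y: list[np.ndarray], A: np.ndarray, F: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One CP-ALS round on the projected slabs Y_k = X_k P_k (each I x M).

    Updates A, F, C in turn by exact least squares for
    Σ_k ||Y_k - A D_k F'||²; no sub-update increases the objective.
    """
    # A-update: A = (Σ_k Y_k F D_k) ((F'F) ∘ (C'C))^-1
    num = sum(Y[k] @ (F * C[k]) for k in range(len(Y)))
    A = num @ np.linalg.inv(_ridge_if_needed((F.T @ F) * (C.T @ C)))
    # F-update: F = (Σ_k Y_k' A D_k) ((A'A) ∘ (C'C))^-1
    num = sum(Y[k].T @ (A * C[k]) for k in range(len(Y)))
    F = num @ np.linalg.inv(_ridge_if_needed((A.T @ A) * (C.T @ C)))
    # C-update per slab: ((A'A) ∘ (F'F)) c_k = diag(A' Y_k F)
    G = _ridge_if_needed((A.T @ A) * (F.T @ F))
    C = np.stack(
        [_solve_gram(G, np.diag(A.T @ Y[k] @ F)) for k in range(len(Y))]
    )
    return A, F, C


def _ridge_if_needed(G: np.ndarray) -> np.ndarray:
    # cond check is cheap at M x M; ridge keeps degenerate components solvable
    if not np.all(np.isfinite(G)) or np.linalg.cond(G) > 1e12:
        logger.warning("ill-conditioned CP normal equations; adding ridge %.0e", RIDGE)
        return G + RIDGE * np.eye(G.shape[0])
    return G


def _svd_init(x: SlabTensor, M: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A from the leading left singular vectors of the column-concatenated
    slabs; F = I; C = ones."""
    concat = np.concatenate(x.slabs, axis=1)
    U, _, _ = np.linalg.svd(concat, full_matrices=False)
    A = U[:, :M].copy()
    if A.shape[1] < M:  # I < M corner: pad with unit columns
        pad = np.zeros((x.I, M - A.shape[1]))
        A = np.concatenate([A, pad], axis=1)
    return A, np.eye(M), np.ones((x.K, M))


def _als_run(
    x: SlabTensor, opts: DirectFitOptions, A: np.ndarray, F: np.ndarray, C: np.ndarray
) -> tuple[FactorSet, DirectFitReport]:
    tss = x.squared_norm()
    r2_trace: list[float] = []
    converged = False
    P = [None] * x.K
    it = 0
    for it in range(1, opts.max_iter + 1):
        P = [update_projection(A, C[k], F, x[k]) for k in range(x.K)]
        Y = [x[k] @ P[k] for k in range(x.K)]
        A, F, C = cp_step(Y, A, F, C)
        sse = sum(
            float(np.sum((x[k] - (A * C[k]) @ F.T @ P[k].T) ** 2)) for k in range(x.K)
        )
        r2 = 1.0 - sse / tss
        r2_trace.append(r2)
        if len(r2_trace) > 1:
            if abs(r2 - r2_trace[-2]) < opts.rel_tol * max(1.0, abs(r2)):
                converged = True
                break
    f = FactorSet(A=A, C=C, F=F, P=P)
    return f, DirectFitReport(r2_trace, r2_trace[-1], it, converged)


def fit_direct(x: SlabTensor, opts: DirectFitOptions) -> tuple[FactorSet, DirectFitReport]:
    """Multi-start ALS fit; returns the restart with the best final R².

    The first start uses an SVD-based initialization; later starts perturb it
    with seeded Gaussian noise.
    """
    if opts.M > min(x.J):
        raise DataModelError(
            f"M={opts.M} exceeds the smallest slab width {min(x.J)}"
        )
    rng = np.random.default_rng(opts.seed)
    A0, F0, C0 = _svd_init(x, opts.M)
    best: tuple[FactorSet, DirectFitReport] | None = None
    restart_r2 = []
    for start in range(opts.n_starts):
        if start == 0:
            A, F, C = A0.copy(), F0.copy(), C0.copy()
        else:
            A = A0 + 0.3 * rng.standard_normal(A0.shape)
            F = F0 + 0.3 * rng.standard_normal(F0.shape)
            C = np.abs(C0 + 0.3 * rng.standard_normal(C0.shape))
        f, rep = _als_run(x, opts, A, F, C)
        restart_r2.append(rep.final_r2)
        if best is None or rep.final_r2 > best[1].final_r2:
            best = (f, rep)
    best[1].restart_r2 = restart_r2
    return best


# ---------------------------------------------------------------------------
# Core consistency diagnostic
# ---------------------------------------------------------------------------


def _tucker_core(Y: np.ndarray, A: np.ndarray, F: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Least-squares M x M x M Tucker core of the I x M x K array Y with
    loadings (A, F, C) fixed: vec(Y) ≈ (C ⊗ F ⊗ A) vec(G).

    Solved through the factored pseudo-inverse (mode products with pinv of
    each loading), equivalent to the Kronecker least squares for full
    column-rank loadings.
    """
    Ap, Fp, Cp = (np.linalg.pinv(M) for M in (A, F, C))
    G = np.einsum("mi,ijk->mjk", Ap, Y)
    G = np.einsum("nj,mjk->mnk", Fp, G)
    G = np.einsum("ok,mnk->mno", Cp, G)
    return G


def core_consistency(x: SlabTensor, f: FactorSet) -> float:
    """CCD = 100 (1 - ||G - I||²_F / M) on the projected array Y_k = X_k P_k.

    100 means the least-squares Tucker core is exactly superdiagonal, i.e.
    the data (after projection) carry perfect CP structure at this M.
    """
    M = f.M
    Y = np.stack([x[k] @ f.P[k] for k in range(x.K)], axis=2)  # I x M x K
    G = _tucker_core(Y, f.A, f.F, f.C)
    sd = np.zeros((M, M, M))
    for m in range(M):
        sd[m, m, m] = 1.0
    return float(100.0 * (1.0 - np.sum((G - sd) ** 2) / M))
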