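"""Model-order scans and component-level diagnostics.

Component importance is summarized by reconstruction shares (the quantity a
Hinton diagram displays): the squared Frobenius norm of each component's
rank-one slab-wise reconstruction divided by the sum over components.
Recovered components are matched to a reference decomposition by maximizing
total congruence (uncentered cosine similarity of the vectorized
componentwise reconstructions) over one-to-one assignments.

The model-order scan fits the direct algorithm (reporting R² and core
consistency) and any requested probabilistic variants (reporting the ELBO)
over a range of M, with the display normalization to [0, 100] applied per
criterion across noise models, and an advisory elbow locator (largest
discrete second difference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .data_model import DataModelError, FactorSet, SlabTensor, explained_variation
from .direct_fit import DirectFitOptions, core_consistency, fit_direct

__all__ = [
    "ComponentMatch",
    "ScanResult",
    "component_shares",
    "component_reconstructions",
    "match_components",
    "congruence_matrix",
    "column_congruence",
    "model_order_scan",
    "elbow_m",
    "normalize_0_100",
]

logger = logging.getLogger(__name__)


def component_reconstructions(f: FactorSet) -> list[list[np.ndarray]]:
    """Per-component rank-one reconstructions; entry [m][k] is
    A_{.m} c_km (P_k F_{.m})'."""
    out = []
    for m in range(f.M):
        slabs = []
        for k in range(f.K):
            fk_col = f.P[k] @ f.F[:, m]
            slabs.append(np.outer(f.A[:, m] * f.C[k, m], fk_col))
        out.append(slabs)
    return out


def component_shares(f: FactorSet) -> np.ndarray:
    """share_m = Σ_k ||component-m reconstruction of slab k||²_F, normalized
    to sum to one over components."""
    recons = component_reconstructions(f)
    norms = np.array([sum(float(np.sum(s * s)) for s in slabs) for slabs in recons])
    total = norms.sum()
    if total == 0.0:
        raise DataModelError("all-zero model: component shares are undefined")
    return norms / total


@dataclass
class ComponentMatch:
    congruence: np.ndarray  # fit components x reference components
    assignment: np.ndarray  # assignment[i] = matched reference component of fit component i
    matched_congruence: np.ndarray  # congruence along the assignment


def _vectorized_components(f: FactorSet) -> np.ndarray:
    recons = component_reconstructions(f)
    return np.stack([np.concatenate([s.ravel() for s in slabs]) for slabs in recons])


def congruence_matrix(
    f: FactorSet, reference: FactorSet, kind: str = "cosine"
) -> np.ndarray:
    """Pairwise similarity of componentwise reconstructions.

    ``cosine`` (default) is the uncentered Tucker congruence, appropriate for
    non-centered intensity surfaces; ``pearson`` centers first."""
    U = _vectorized_components(f)
    V = _vectorized_components(reference)
    if kind == "pearson":
        U = U - U.mean(axis=1, keepdims=True)
        V = V - V.mean(axis=1, keepdims=True)
    elif kind != "cosine":
        raise DataModelError(f"unknown congruence kind {kind!r}")
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        logger.warning("zero-norm component: its congruences are set to 0")
    nu[nu == 0] = np.inf
    nv[nv == 0] = np.inf
    return (U / nu[:, None]) @ (V / nv[:, None]).T


def match_components(
    f: FactorSet, reference: FactorSet, kind: str = "cosine"
) -> ComponentMatch:
    """Optimal one-to-one matching (rectangular assignment) maximizing total
    congruence between fit and reference components."""
    C = congruence_matrix(f, reference, kind=kind)
    rows, cols = linear_sum_assignment(-C)
    assignment = np.full(f.M, -1)
    assignment[rows] = cols
    return ComponentMatch(
        congruence=C, assignment=assignment, matched_congruence=C[rows, cols]
    )


def column_congruence(X: np.ndarray, Y: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Uncentered cosine between columns of X and the perm-matched columns of
    Y (used to score recovery of A and C loadings against ground truth);
    sign-insensitive."""
    out = []
    for i, j in enumerate(perm):
        if j < 0 or j >= Y.shape[1]:
            out.append(0.0)
            continue
        nx, ny = np.linalg.norm(X[:, i]), np.linalg.norm(Y[:, j])
        out.append(abs(float(X[:, i] @ Y[:, j])) / (nx * ny) if nx > 0 and ny > 0 else 0.0)
    return np.array(out)


@dataclass
class ScanResult:
    table: pd.DataFrame  # columns: M, variant, criterion, value, normalized, seed

    def values(self, variant: str, criterion: str) -> pd.Series:
        t = self.table
        sel = t[(t.variant == variant) & (t.criterion == criterion)]
        return sel.set_index("M")["value"].sort_index()


def normalize_0_100(values: np.ndarray) -> np.ndarray:
    """Affine map of a criterion curve onto [0, 100] (display only; order
    preserving).  A constant curve maps to 100."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        return np.full_like(v, 100.0)
    return 100.0 * (v - lo) / (hi - lo)


def elbow_m(M_values, criterion_values) -> int:
    """Advisory elbow: M with the largest discrete second difference of the
    criterion curve.  Never a sole selector — combine with R²/CCD and
    inspection of loadings and residuals."""
    M_values = list(M_values)
    v = np.asarray(criterion_values, dtype=float)
    if len(M_values) < 3:
        return M_values[int(np.argmax(v))]
    d2 = v[:-2] - 2 * v[1:-1] + v[2:]
    return M_values[1 + int(np.argmin(d2))]


def model_order_scan(
    x: SlabTensor,
    M_values,
    variants=("vmf", "cmn"),
    noise_modes=("homoscedastic", "heteroscedastic"),
    direct_opts: DirectFitOptions | None = None,
    vb_opts=None,
    seed: int = 0,
) -> ScanResult:
    """Fit the direct algorithm and the requested probabilistic variants for
    every M; failures in a cell are logged and the scan continues."""
    from .vb_engine import FitOptions, fit_vb  # local import to avoid a cycle

    rows = []
    for M in M_values:
        base_direct = direct_opts or DirectFitOptions(M=M, max_iter=500, n_starts=2)
        dopt = DirectFitOptions(
            M=M,
            max_iter=base_direct.max_iter,
            rel_tol=base_direct.rel_tol,
            n_starts=base_direct.n_starts,
            seed=seed,
        )
        try:
            f, rep = fit_direct(x, dopt)
            rows.append(dict(M=M, variant="direct", criterion="r2", value=rep.final_r2, seed=seed))
            rows.append(
                dict(M=M, variant="direct", criterion="ccd", value=core_consistency(x, f), seed=seed)
            )
        except Exception as exc:  # cell failure: mark and continue
            logger.warning("direct fit failed at M=%d: %s", M, exc)
            rows.append(dict(M=M, variant="direct", criterion="failed", value=np.nan, seed=seed))
        for variant in variants:
            for noise in noise_modes:
                base = vb_opts or FitOptions(M=M, max_iter=200)
                vopt = FitOptions(
                    M=M,
                    variant=variant,
                    noise_mode=noise,
                    max_iter=base.max_iter,
                    rel_tol=base.rel_tol,
                    noise_delay_iters=min(base.noise_delay_iters, base.max_iter // 4),
                    n_starts=base.n_starts,
                    seed=seed,
                )
                label = f"{variant}-{'hetero' if noise == 'heteroscedastic' else 'homo'}"
                try:
                    _, _, vrep = fit_vb(x, vopt)
                    rows.append(
                        dict(M=M, variant=label, criterion="elbo", value=vrep.final_elbo, seed=seed)
                    )
                except Exception as exc:
                    logger.warning("VB fit (%s) failed at M=%d: %s", label, M, exc)
                    rows.append(dict(M=M, variant=label, criterion="failed", value=np.nan, seed=seed))
    table = pd.DataFrame(rows)
    # display normalization: per criterion and variant family, pooled across
    # noise models (homo/hetero share one scale)
    table["normalized"] = np.nan
    table["family"] = table.variant.str.replace("-homo|-hetero", "", regex=True)
    for (crit, fam), idx in table.groupby(["criterion", "family"]).groups.items():
        if crit == "failed":
            continue
        vals = table.loc[idx, "value"].to_numpy(dtype=float)
        if np.all(np.isfinite(vals)):
            table.loc[idx, "normalized"] = normalize_0_100(vals)
    return ScanResult(table=table.drop(columns="family"))
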