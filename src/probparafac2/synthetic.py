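"""Synthetic PARAFAC2 data with controlled signal-to-noise ratio.

The generator emulates the classical simulation protocol for PARAFAC2
benchmarks: first-mode loadings A with i.i.d. standard-normal entries, a
shared matrix F taken as the (transposed lower) Cholesky factor of a
correlation matrix with unit diagonal and a constant off-diagonal (0.4 by
default, keeping components from being too similar, F'F = G), third-mode
scalings C drawn Uniform(0, 30), and per-slab projections P_k obtained by
orthonormalizing standard-normal J x M draws.

Additive Gaussian noise is injected at a prescribed SNR.  The SNR convention
(the protocol leaves it implicit, so it is fixed here and documented
prominently) is a power ratio on Frobenius norms aggregated over slabs:

    SNR_dB = 10 log10( Σ_k ||signal_k||²_F / Σ_k E||E_k||²_F ).

Homoscedastic noise uses a single variance for all slabs.  Heteroscedastic
noise perturbs each slab's nominal SNR by Uniform(-6, +6) dB and then
rescales all per-slab variances by a common factor so the aggregate matches
the target — a named stand-in policy, since published simulations do not
state how per-slab variances were drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .data_model import FactorSet, SlabTensor, reconstruct

__all__ = [
    "SimConfig",
    "SimOutput",
    "SyntheticConfigError",
    "generate_truth",
    "add_noise",
    "simulate",
    "generate_grid",
]

HET_JITTER_DB = 6.0  # half-width of the per-slab SNR jitter, dB


class SyntheticConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the benchmark protocol: 50 x 50 x 10 tensors with M = 4
    components, off-diagonal component correlation 0.4 and C ~ Uniform(0, 30).
    """

    I: int = 50  # noqa: E741
    J: int = 50
    K: int = 10
    M: int = 4
    snr_db: float = 4.0
    noise_mode: str = "homoscedastic"
    off_diag: float = 0.4
    c_max: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("I", "J", "K", "M"):
            if getattr(self, name) < 1:
                raise SyntheticConfigError(f"{name} must be a positive integer")
        if self.M > self.J:
            raise SyntheticConfigError("M must not exceed J (P_k needs orthonormal columns)")
        if not (0.0 <= self.off_diag < 1.0):
            raise SyntheticConfigError("off_diag must lie in [0, 1)")
        if self.c_max < 0:
            raise SyntheticConfigError("c_max must be non-negative")
        if self.noise_mode not in ("homoscedastic", "heteroscedastic"):
            raise SyntheticConfigError(f"unknown noise_mode {self.noise_mode!r}")
        if np.isnan(self.snr_db) or np.isneginf(self.snr_db):
            raise SyntheticConfigError("snr_db must be a real number (or +inf for noise-free)")


@dataclass
class SimOutput:
    """A generated dataset: noise-free signal, noisy tensor, ground truth."""

    signal: SlabTensor
    noisy: SlabTensor
    truth: FactorSet | None
    noise_scales: list[float]  # per-slab noise standard deviations
    config: SimConfig | None = None


def _component_gram(M: int, off_diag: float) -> np.ndarray:
    G = np.full((M, M), off_diag)
    np.fill_diagonal(G, 1.0)
    return G


def _orthonormalize(Z: np.ndarray) -> np.ndarray:
    """Thin QR with a deterministic sign convention (first nonzero entry of
    each column made positive) for reproducibility."""
    Q, R = np.linalg.qr(Z)
    # standard Haar fix first, then the documented sign convention
    Q = Q * np.sign(np.where(np.diag(R) == 0, 1.0, np.diag(R)))
    for m in range(Q.shape[1]):
        col = Q[:, m]
        nz = np.flatnonzero(np.abs(col) > 1e-300)
        if nz.size and col[nz[0]] < 0:
            Q[:, m] = -col
    return Q


def generate_truth(cfg: SimConfig) -> FactorSet:
    """Draw a ground-truth factor set.

    F is built so that F'F equals the Gram matrix with unit diagonal and
    ``cfg.off_diag`` off-diagonal entries: G = L L' (lower Cholesky), F = L'.
    """
    rng = np.random.default_rng(cfg.seed)
    G = _component_gram(cfg.M, cfg.off_diag)
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError as exc:
        raise SyntheticConfigError(
            f"off_diag={cfg.off_diag} gives a non-positive-definite component Gram matrix"
        ) from exc
    A = rng.standard_normal((cfg.I, cfg.M))
    F = L.T
    C = rng.uniform(0.0, cfg.c_max, size=(cfg.K, cfg.M))
    P = [_orthonormalize(rng.standard_normal((cfg.J, cfg.M))) for _ in range(cfg.K)]
    return FactorSet(A=A, C=C, F=F, P=P)


def _per_slab_variances(
    signal: SlabTensor, snr_db: float, noise_mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Noise variances per slab realizing the aggregate SNR convention."""
    powers = np.array([np.sum(s * s) for s in signal.slabs])
    sizes = np.array([s.size for s in signal.slabs], dtype=float)
    total_noise_power = powers.sum() / 10.0 ** (snr_db / 10.0)
    if noise_mode == "homoscedastic":
        var = total_noise_power / sizes.sum()
        return np.full(signal.K, var)
    # heteroscedastic: jitter each slab's nominal SNR, then rescale the
    # aggregate expected noise power back onto the target
    delta = rng.uniform(-HET_JITTER_DB, HET_JITTER_DB, size=signal.K)
    var = powers / (sizes * 10.0 ** ((snr_db + delta) / 10.0))
    var *= total_noise_power / np.sum(sizes * var)
    return var


def add_noise(
    signal: SlabTensor,
    snr_db: float,
    noise_mode: str = "homoscedastic",
    seed: int = 0,
    truth: FactorSet | None = None,
    config: SimConfig | None = None,
) -> SimOutput:
    """Add Gaussian noise at the requested aggregate SNR (dB, power ratio).

    ``snr_db = inf`` is the noise-free limit and returns the signal unchanged.
    """
    if np.isnan(snr_db):
        raise SyntheticConfigError("snr_db must not be NaN")
    if noise_mode not in ("homoscedastic", "heteroscedastic"):
        raise SyntheticConfigError(f"unknown noise_mode {noise_mode!r}")
    if signal.squared_norm() == 0.0:
        raise SyntheticConfigError("degenerate all-zero signal: SNR is undefined")
    rng = np.random.default_rng(seed)
    if np.isposinf(snr_db):
        var = np.zeros(signal.K)
    else:
        var = _per_slab_variances(signal, snr_db, noise_mode, rng)
    noisy = [
        s + np.sqrt(v) * rng.standard_normal(s.shape) if v > 0 else s.copy()
        for s, v in zip(signal.slabs, var)
    ]
    return SimOutput(
        signal=signal,
        noisy=SlabTensor(noisy),
        truth=truth,
        noise_scales=[float(np.sqrt(v)) for v in var],
        config=config,
    )


def simulate(cfg: SimConfig) -> SimOutput:
    """Ground truth + noise-free signal + noisy tensor for one configuration.

    The truth draw and the noise draw use independent streams spawned from
    ``cfg.seed`` so the same truth can be re-noised reproducibly.
    """
    truth_seed, noise_seed = _spawn_seeds(cfg.seed, 2)
    truth = generate_truth(replace(cfg, seed=truth_seed))
    signal = reconstruct(truth)
    return add_noise(
        signal, cfg.snr_db, cfg.noise_mode, seed=noise_seed, truth=truth, config=cfg
    )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_grid(
    snr_list: Sequence[float],
    noise_modes: Sequence[str],
    replicates: int,
    base: SimConfig,
) -> list[SimOutput]:
    """The full benchmark grid: every SNR x noise-mode x replicate cell.

    The reference protocol — SNR from -20 to 10 dB in 2 dB steps (16 values),
    both noise modes, 10 replicates — yields 320 datasets.  Per-dataset seeds
    are derived deterministically from ``base.seed`` and recorded in each
    dataset's config.
    """
    if not snr_list or not noise_modes:
        raise SyntheticConfigError("snr_list and noise_modes must be non-empty")
    if replicates < 1:
        raise SyntheticConfigError("replicates must be >= 1")
    n = len(snr_list) * len(noise_modes) * replicates
    seeds = _spawn_seeds(base.seed, n)
    out = []
    i = 0
    for snr in snr_list:
        for mode in noise_modes:
            for _ in range(replicates):
                cfg = replace(base, snr_db=float(snr), noise_mode=mode, seed=seeds[i])
                out.append(simulate(cfg))
                i += 1
    return out


def paper_grid_snrs() -> list[float]:
    """SNR grid -20..10 dB in steps of 2 (16 values)."""
    return [float(s) for s in range(-20, 12, 2)]
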