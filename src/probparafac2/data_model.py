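"""Core data structures for ragged slab tensors and PARAFAC2 factor sets.

A third-order array with a ragged mode is stored as K "slabs": real matrices
``X_k`` of shape ``I x J_k`` sharing the first dimension.  The PARAFAC2 model
decomposes every slab as

    X_k = A D_k F' P_k' + E_k,      P_k' P_k = I_M,

with shared first-mode loadings ``A`` (I x M), per-slab scalings
``D_k = diag(C[k])`` (C is K x M), a shared M x M matrix ``F`` and per-slab
orthonormal projections ``P_k`` (J_k x M).  The constraint guarantees that the
Gram matrix of the varying-mode loadings ``F_k = P_k F`` is constant across
slabs, which is what makes the decomposition essentially unique.

This module provides the containers, HDF5/CSV readers and writers, slab
reconstruction and the R² fit metric.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

__all__ = [
    "SlabTensor",
    "FactorSet",
    "FitMetrics",
    "DataModelError",
    "read_slab_tensor",
    "write_slab_tensor",
    "read_factor_set",
    "write_factor_set",
    "reconstruct",
    "explained_variation",
    "noiseless_r2",
]


class DataModelError(ValueError):
    """Raised for invalid tensors, factor sets or degenerate metric inputs."""


@dataclass
class SlabTensor:
    """Ragged third-order data: K slabs of shape I x J_k."""

    slabs: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.slabs) < 1:
            raise DataModelError("a SlabTensor needs at least one slab (K >= 1)")
        slabs = []
        for k, s in enumerate(self.slabs):
            arr = np.asarray(s, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
                raise DataModelError(f"slab {k} is not a non-empty 2-D matrix")
            if not np.all(np.isfinite(arr)):
                raise DataModelError(f"slab {k} contains non-finite entries")
            slabs.append(arr)
        rows = {s.shape[0] for s in slabs}
        if len(rows) != 1:
            raise DataModelError(f"slabs disagree on the number of rows: {sorted(rows)}")
        self.slabs = slabs

    @property
    def I(self) -> int:  # noqa: E743 - domain notation
        return self.slabs[0].shape[0]

    @property
    def J(self) -> list[int]:
        return [s.shape[1] for s in self.slabs]

    @property
    def K(self) -> int:
        return len(self.slabs)

    @property
    def n_entries(self) -> int:
        return self.I * sum(self.J)

    def squared_norm(self) -> float:
        """Total squared Frobenius norm over all slabs."""
        return float(sum(np.sum(s * s) for s in self.slabs))

    def __iter__(self):
        return iter(self.slabs)

    def __getitem__(self, k: int) -> np.ndarray:
        return self.slabs[k]

    def allclose(self, other: "SlabTensor", atol: float = 0.0, rtol: float = 0.0) -> bool:
        if self.K != other.K or self.J != other.J:
            return False
        return all(
            np.allclose(a, b, atol=atol, rtol=rtol) for a, b in zip(self.slabs, other.slabs)
        )


@dataclass
class FactorSet:
    """Point estimates (A, C, F, {P_k}) of the PARAFAC2 factors.

    ``P`` holds one J_k x M matrix per slab.  Orthonormality of the P_k is a
    property of direct-fit solutions and of vMF modes, not of every factor set
    (the posterior mean of a vMF factor has singular values < 1); use
    :meth:`max_orthonormality_defect` to check it where it is expected.
    """

    A: np.ndarray
    C: np.ndarray
    F: np.ndarray
    P: list[np.ndarray]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.C = np.asarray(self.C, dtype=np.float64)
        self.F = np.asarray(self.F, dtype=np.float64)
        self.P = [np.asarray(p, dtype=np.float64) for p in self.P]
        M = self.A.shape[1]
        if self.C.ndim != 2 or self.C.shape[1] != M:
            raise DataModelError("C must be K x M with the same M as A")
        if self.F.shape != (M, M):
            raise DataModelError("F must be M x M")
        if len(self.P) != self.C.shape[0]:
            raise DataModelError("need one projection P_k per row of C")
        for k, p in enumerate(self.P):
            if p.ndim != 2 or p.shape[1] != M:
                raise DataModelError(f"P[{k}] must have M = {M} columns")

    @property
    def M(self) -> int:
        return self.A.shape[1]

    @property
    def K(self) -> int:
        return self.C.shape[0]

    def max_orthonormality_defect(self) -> float:
        """max_k || P_k' P_k - I ||_max — ~0 for direct-fit / vMF-mode factors."""
        M = self.M
        return max(
            float(np.max(np.abs(p.T @ p - np.eye(M)))) for p in self.P
        )

    def rescaled(self, s: float | np.ndarray) -> "FactorSet":
        """Jointly rescale A -> A*s, C -> C/s (componentwise); reconstruction-invariant."""
        s = np.broadcast_to(np.asarray(s, dtype=np.float64), (self.M,))
        return FactorSet(self.A * s, self.C / s, self.F.copy(), [p.copy() for p in self.P])


@dataclass
class FitMetrics:
    """Goodness of fit: R² = 1 - SSE/TSS aggregated over slabs."""

    r2: float
    per_slab_sse: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SLAB_RE = re.compile(r"slab_(\d+)\.csv$")


def _csv_dir_paths(path: Path) -> list[Path]:
    files = sorted(path.glob("slab_*.csv"), key=lambda p: int(_SLAB_RE.search(p.name).group(1)))
    if not files:
        raise DataModelError(f"no slab_*.csv files found in {path}")
    return files


def read_slab_tensor(path, format: str = "hdf5") -> SlabTensor:
    """Read a slab tensor from an HDF5 container or a directory of CSV files.

    HDF5 layout: datasets ``/slabs/{k}`` (0-based), float64.  CSV layout: one
    headerless comma-delimited file ``slab_{k:03d}.csv`` per slab.
    """
    path = Path(path)
    if not path.exists():
        raise DataModelError(f"input path does not exist: {path}")
    if format == "hdf5":
        with h5py.File(path, "r") as fh:
            grp = fh["slabs"]
            keys = sorted(grp.keys(), key=int)
            slabs = [np.asarray(grp[k][()], dtype=np.float64) for k in keys]
    elif format == "csv-dir":
        slabs = []
        for f in _csv_dir_paths(path):
            try:
                slabs.append(np.loadtxt(f, delimiter=",", ndmin=2, dtype=np.float64))
            except ValueError as exc:
                raise DataModelError(f"non-numeric cell in {f}: {exc}") from exc
    else:
        raise DataModelError(f"unknown format {format!r} (expected 'hdf5' or 'csv-dir')")
    return SlabTensor(slabs)


def write_slab_tensor(x: SlabTensor, path, format: str = "hdf5") -> None:
    """Write a slab tensor; ``read_slab_tensor`` round-trips it losslessly
    (bit-identical for HDF5, to formatting precision ~1e-16 for CSV)."""
    path = Path(path)
    if format == "hdf5":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("slabs")
            for k, s in enumerate(x.slabs):
                grp.create_dataset(str(k), data=s)
            fh.attrs["I"] = x.I
            fh.attrs["K"] = x.K
    elif format == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        for k, s in enumerate(x.slabs):
            np.savetxt(path / f"slab_{k:03d}.csv", s, delimiter=",", fmt="%.17g")
    else:
        raise DataModelError(f"unknown format {format!r} (expected 'hdf5' or 'csv-dir')")


def write_factor_set(f: FactorSet, path) -> None:
    """Store a factor set in an HDF5 file (/A, /C, /F, /P/{k})."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("A", data=f.A)
        fh.create_dataset("C", data=f.C)
        fh.create_dataset("F", data=f.F)
        grp = fh.create_group("P")
        for k, p in enumerate(f.P):
            grp.create_dataset(str(k), data=p)


def read_factor_set(path) -> FactorSet:
    path = Path(path)
    if not path.exists():
        raise DataModelError(f"input path does not exist: {path}")
    with h5py.File(path, "r") as fh:
        P = [np.asarray(fh["P"][k][()]) for k in sorted(fh["P"].keys(), key=int)]
        return FactorSet(fh["A"][()], fh["C"][()], fh["F"][()], P)


# ---------------------------------------------------------------------------
# Reconstruction and fit metrics
# ---------------------------------------------------------------------------


def reconstruct_slab(f: FactorSet, k: int) -> np.ndarray:
    """A diag(C[k]) F' P_k' — the model's k-th slab."""
    return (f.A * f.C[k]) @ f.F.T @ f.P[k].T


def reconstruct(f: FactorSet) -> SlabTensor:
    """Model reconstruction X̂_k = A D_k F' P_k' for every slab."""
    return SlabTensor([reconstruct_slab(f, k) for k in range(f.K)])


def explained_variation(x: SlabTensor, f: FactorSet) -> FitMetrics:
    """R² = 1 - Σ_k ||X_k - A D_k F' P_k'||² / Σ_k ||X_k||².

    Always <= 1; equals 1 iff the reconstruction is exact.  An all-zero data
    tensor makes the denominator vanish and is rejected.
    """
    if x.K != f.K:
        raise DataModelError(f"data has K={x.K} slabs but factors have K={f.K}")
    tss = x.squared_norm()
    if tss == 0.0:
        raise DataModelError("all-zero data tensor: R² is undefined (zero total sum of squares)")
    sse = []
    for k in range(x.K):
        r = x[k] - reconstruct_slab(f, k)
        if r.shape != x[k].shape:
            raise DataModelError(f"slab {k}: factor shapes do not match the data")
        sse.append(float(np.sum(r * r)))
    return FitMetrics(r2=1.0 - sum(sse) / tss, per_slab_sse=sse)


def noiseless_r2(signal: SlabTensor, f: FactorSet) -> float:
    """R² of a fitted factor set against the noise-free signal tensor.

    Identical to :func:`explained_variation` evaluated on the signal; it
    measures recovery of the true underlying structure rather than fit to a
    noisy realization.
    """
    return explained_variation(signal, f).r2
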