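"""Implicit genetic relationship matrix and conjugate-gradient solver.

The GRM is V = Z Z^T / M with Z the column-standardized genotype matrix
(z = (g - 2*p)/sqrt(2*p*(1-p)), p the sample allele frequency).  V is never
assembled: products V*v are computed from the packed genotypes, either
through a cached standardized matrix when it fits in memory or by streaming
marker blocks.  Zero-variance markers carry no relatedness information and
are dropped from M with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .genotype_io import GenotypeBlock, _BYTE_LUT

logger = logging.getLogger(__name__)

__all__ = ["GRMOperator", "PCGConfig", "PCGError", "grm_matvec", "pcg_solve"]


@dataclass
class PCGConfig:
    """Tolerances for the Jacobi-preconditioned conjugate-gradient solver."""

    rel_tolerance: float = 1e-6
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class PCGError(RuntimeError):
    """Conjugate gradient failed to reach tolerance; carries final residual."""

    def __init__(self, message: str, residual: float, n_iter: int):
        super().__init__(message)
        self.residual = residual
        self.n_iter = n_iter


class GRMOperator:
    """Matrix-free V = Z Z^T / M over a marker panel.

    Parameters
    ----------
    block
        Packed genotype panel (GRM markers, not test markers).
    cache_limit
        Materialize the standardized matrix when n*M is at most this many
        entries; above it, products stream over marker blocks.
    """

    def __init__(self, block: GenotypeBlock, cache_limit: int = 80_000_000):
        self.block = block
        self.n = block.n_samples
        calls = None
        if block.n_samples * block.n_variants <= cache_limit:
            calls = block.to_matrix()
            af = _column_af(calls)
        else:
            af = np.array(
                [_column_af(block.genotypes(j)[:, None])[0] for j in range(block.n_variants)]
            )
        keep = (af > 0.0) & (af < 1.0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "GRM panel: dropping %d zero-variance markers of %d",
                n_dropped,
                block.n_variants,
            )
        self.marker_indices = np.flatnonzero(keep)
        self.m = len(self.marker_indices)
        if self.m == 0:
            raise ValueError("GRM panel has no polymorphic markers")
        self.af = af[keep]
        self._mean = 2.0 * self.af
        self._sd = np.sqrt(2.0 * self.af * (1.0 - self.af))
        self._z: np.ndarray | None = None
        self._dense: np.ndarray | None = None
        self._diag: np.ndarray | None = None
        if calls is not None:
            self._z = self._standardize(calls[:, self.marker_indices])

    def _standardize(self, calls: np.ndarray) -> np.ndarray:
        g = calls.astype(np.float64)
        # mean-impute missing before standardizing
        miss = calls < 0
        if miss.any():
            g[miss] = np.broadcast_to(self._mean, g.shape)[miss]
        return (g - self._mean) / self._sd

    def standardized_matrix(self) -> np.ndarray:
        """Dense n x M standardized genotype matrix Z (materialized)."""
        if self._z is None:
            cols = self.block.to_matrix()[:, self.marker_indices]
            return self._standardize(cols)
        return self._z

    def matvec(self, v: np.ndarray, block_size: int = 4096) -> np.ndarray:
        """V @ v = Z (Z^T v) / M, streaming marker blocks if Z is not cached."""
        v = np.asarray(v, dtype=np.float64)
        if v.shape[0] != self.n:
            raise ValueError(f"vector length {v.shape[0]} != n_samples {self.n}")
        if self._z is not None:
            return self._z @ (self._z.T @ v) / self.m
        out = np.zeros_like(v, dtype=np.float64)
        for start in range(0, self.m, block_size):
            idx = self.marker_indices[start : start + block_size]
            raw = _BYTE_LUT[self.block.packed[:, idx]]
            calls = raw.transpose(0, 2, 1).reshape(-1, len(idx))[: self.n]
            g = calls.astype(np.float64)
            miss = calls < 0
            mean = self._mean[start : start + len(idx)]
            if miss.any():
                g[miss] = np.broadcast_to(mean, g.shape)[miss]
            z = (g - mean) / self._sd[start : start + len(idx)]
            out += z @ (z.T @ v)
        return out / self.m

    __call__ = matvec

    def matmat(self, v: np.ndarray) -> np.ndarray:
        """V @ V for a 2-D right-hand side (column-wise matvec semantics)."""
        z = self.standardized_matrix()
        return z @ (z.T @ v) / self.m

    def diag(self) -> np.ndarray:
        """Diagonal of V (row sums of Z**2 over markers, divided by M)."""
        if self._diag is not None:
            return self._diag
        if self._z is not None:
            self._diag = (self._z**2).sum(axis=1) / self.m
            return self._diag
        out = np.zeros(self.n)
        for start in range(0, self.m, 4096):
            idx = self.marker_indices[start : start + 4096]
            raw = _BYTE_LUT[self.block.packed[:, idx]]
            calls = raw.transpose(0, 2, 1).reshape(-1, len(idx))[: self.n]
            g = calls.astype(np.float64)
            miss = calls < 0
            mean = self._mean[start : start + len(idx)]
            if miss.any():
                g[miss] = np.broadcast_to(mean, g.shape)[miss]
            z = (g - mean) / self._sd[start : start + len(idx)]
            out += (z**2).sum(axis=1)
        self._diag = out / self.m
        return self._diag

    def dense(self) -> np.ndarray:
        """Assemble (and cache) dense V; intended for moderate n."""
        if self._dense is None:
            z = self.standardized_matrix()
            self._dense = (z @ z.T) / self.m
        return self._dense


def _column_af(calls: np.ndarray) -> np.ndarray:
    called = calls >= 0
    n_called = called.sum(axis=0)
    ac = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_called > 0, ac / (2.0 * np.maximum(n_called, 1)), 0.0)
    return af


def grm_matvec(op: GRMOperator, v: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`GRMOperator.matvec`."""
    return op.matvec(v)


def pcg_solve(
    apply_A: Callable[[np.ndarray], np.ndarray],
    rhs: np.ndarray,
    cfg: PCGConfig | None = None,
    diag: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Solve A x = rhs for symmetric positive-definite A by PCG.

    ``diag`` supplies the Jacobi preconditioner (diagonal of A); without it
    the iteration is plain CG.  Returns (solution, iteration count) with
    ||A x - rhs|| / ||rhs|| <= cfg.rel_tolerance, or raises :class:`PCGError`.
    """
    cfg = cfg or PCGConfig()
    rhs = np.asarray(rhs, dtype=np.float64)
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm == 0.0:
        return np.zeros_like(rhs), 0

    if diag is not None:
        inv_diag = 1.0 / np.asarray(diag, dtype=np.float64)
        precond = lambda r: inv_diag * r
    else:
        precond = lambda r: r

    x = np.zeros_like(rhs) if x0 is None else np.asarray(x0, dtype=np.float64).copy()
    r = rhs - apply_A(x) if x.any() else rhs.copy()
    z = precond(r)
    p = z.copy()
    rz = float(r @ z)
    res = np.linalg.norm(r)
    for it in range(1, cfg.max_iter + 1):
        if res / rhs_norm <= cfg.rel_tolerance:
            return x, it - 1
        Ap = apply_A(p)
        alpha = rz / float(p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        res = np.linalg.norm(r)
        z = precond(r)
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    if res / rhs_norm <= cfg.rel_tolerance:
        return x, cfg.max_iter
    raise PCGError(
        f"PCG did not converge in {cfg.max_iter} iterations "
        f"(relative residual {res / rhs_norm:.3e})",
        residual=res / rhs_norm,
        n_iter=cfg.max_iter,
    )
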