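"""Matrix primitives shared by the solvers.

Three operations: a skinny (rank-revealing) SVD with a fixed sign
convention, elementwise soft thresholding (the proximal operator of the
l1 norm), and singular value thresholding (the proximal operator of the
nuclear norm).  These are the only building blocks the ALM loop needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["SkinnySVD", "skinny_svd", "soft_threshold", "svt"]


@dataclass(frozen=True)
class SkinnySVD:
    """Rank-truncated SVD ``M = U @ diag(S) @ V.T``.

    U and V have orthonormal columns; S is non-negative and sorted in
    non-increasing order; ``r = len(S)`` is the numerical rank retained.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray

    @property
    def rank(self) -> int:
        return self.S.size

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.S) @ self.V.T


def _check_finite(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    return M


def skinny_svd(M, rank_tol: float = 1e-12) -> SkinnySVD:
    """SVD keeping only singular values above ``rank_tol * sigma_max``.

    The sign of each singular pair is fixed so that the largest-magnitude
    entry of every U column is positive, making the factorization
    deterministic (LAPACK leaves a sign ambiguity per pair).
    """
    M = _check_finite(M)
    if rank_tol < 0:
        raise InvalidParameterError(f"rank_tol must be >= 0, got {rank_tol}")
    if M.ndim != 2:
        raise InvalidInputError(f"expected a 2-d array, got ndim={M.ndim}")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > rank_tol * s[0]
    else:
        keep = np.zeros(s.shape, dtype=bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    if s.size:
        idx = np.argmax(np.abs(U), axis=0)
        signs = np.sign(U[idx, np.arange(U.shape[1])])
        signs[signs == 0] = 1.0
        U = U * signs
        Vt = Vt * signs[:, None]
    return SkinnySVD(U=U, S=s, V=Vt.T)


def soft_threshold(M, tau: float) -> np.ndarray:
    """Elementwise ``sign(m) * max(|m| - tau, 0)``."""
    if tau < 0:
        raise InvalidParameterError(f"tau must be >= 0, got {tau}")
    M = np.asarray(M, dtype=float)
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def svt(M, tau: float) -> np.ndarray:
    """Singular value thresholding: shrink every singular value by tau.

    Returns ``U @ diag(max(S - tau, 0)) @ V.T`` from the SVD of M — the
    closed-form minimizer of ``tau*||A||_* + 0.5*||A - M||_F^2``.
    A zero matrix is returned immediately without invoking an SVD.
    """
    M = _check_finite(M)
    if tau < 0:
        raise InvalidParameterError(f"tau must be >= 0, got {tau}")
    if not np.any(M):
        return np.zeros_like(M)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt
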