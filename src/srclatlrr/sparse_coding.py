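"""l1-regularized least squares for sparse-representation coding.

Solves  J(x, lam) = min_x ||W x - y||_2^2 + lam ||x||_1  — the coding
step of both plain SRC (dictionary W = training matrix) and SRC-LatLRR
(dictionary D = LX, target Ly).  The backend is FISTA with adaptive
restart; the contract is the subgradient optimality condition, checked
every iteration, not any particular algorithm: on return the gradient
g = 2 W.T (W x - y) satisfies |g_j| <= lam + tol everywhere and
|g_j + lam*sign(x_j)| <= tol on the support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .proximal import soft_threshold

__all__ = ["SparseCode", "solve_l1ls", "delta_mask", "kkt_gap"]


@dataclass
class SparseCode:
    """Solution of the l1-regularized least-squares problem."""

    x: np.ndarray
    lambda_src: float
    objective: float
    residual_norm: float
    kkt_gap: float
    n_iter: int = 0


def kkt_gap(W, y, x, lam: float) -> float:
    """Maximum violation of the subgradient optimality conditions."""
    g = 2.0 * W.T @ (W @ x - y)
    on = x != 0
    viol_off = np.maximum(np.abs(g) - lam, 0.0)
    viol_on = np.abs(g + lam * np.sign(x))
    return float(np.max(np.where(on, viol_on, viol_off), initial=0.0))


def solve_l1ls(W, y, lambda_src: float, tol: float = 1e-6,
               max_iter: int = 5000) -> SparseCode:
    """Minimize ``||W x - y||_2^2 + lambda_src * ||x||_1``.

    FISTA with step 1/L, L = 2*sigma_max(W)^2, and gradient-based
    adaptive restart; stops when the KKT gap drops below ``tol``.
    """
    if lambda_src <= 0:
        raise InvalidParameterError(
            f"lambda_src must be > 0, got {lambda_src}")
    if tol <= 0:
        raise InvalidParameterError(f"tol must be > 0, got {tol}")
    W = np.asarray(W, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if W.ndim != 2:
        raise InvalidInputError("W must be a 2-d matrix")
    if W.shape[0] != y.size:
        raise InvalidInputError(
            f"dimension mismatch: W is {W.shape}, y has length {y.size}")
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(y))):
        raise InvalidInputError("W and y must be finite")

    n = W.shape[1]
    sigma_max = np.linalg.norm(W, 2) if np.any(W) else 0.0
    if sigma_max == 0.0:
        x = np.zeros(n)
        return SparseCode(x=x, lambda_src=lambda_src,
                          objective=float(y @ y),
                          residual_norm=float(np.linalg.norm(y)),
                          kkt_gap=0.0, n_iter=0)
    step = 1.0 / (2.0 * sigma_max**2)

    x = np.zeros(n)
    z = x.copy()
    t = 1.0
    gap = kkt_gap(W, y, x, lambda_src)
    it = 0
    while gap > tol and it < max_iter:
        it += 1
        grad = 2.0 * W.T @ (W @ z - y)
        x_new = soft_threshold(z - step * grad, step * lambda_src)
        if (z - x_new) @ (x_new - x) > 0:      # restart momentum
            z = x_new
            t = 1.0
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            z = x_new + ((t - 1.0) / t_new) * (x_new - x)
            t = t_new
        x = x_new
        gap = kkt_gap(W, y, x, lambda_src)

    resid = W @ x - y
    residual_norm = float(np.linalg.norm(resid))
    objective = residual_norm**2 + lambda_src * float(np.abs(x).sum())
    return SparseCode(x=x, lambda_src=lambda_src, objective=objective,
                      residual_norm=residual_norm, kkt_gap=gap, n_iter=it)


def delta_mask(x, class_assignments, class_id) -> np.ndarray:
    """Characteristic selection: keep coefficients of ``class_id``, zero
    the rest.  Summed over all classes the masks reconstruct x exactly."""
    x = np.asarray(x, dtype=float)
    classes = np.asarray(class_assignments)
    if classes.shape != x.shape:
        raise InvalidInputError(
            f"need one class per coefficient: {classes.shape} vs {x.shape}")
    if class_id not in classes:
        raise InvalidInputError(f"unknown class id {class_id!r}")
    out = np.where(classes == class_id, x, 0.0)
    return out
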