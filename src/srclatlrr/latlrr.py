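"""Latent low-rank representation (LatLRR) by inexact ALM.

Solves

    min_{Z,L,E}  ||Z||_* + ||L||_* + lam*||E||_1
    s.t.         X = X Z + L X + E

for a column-normalized gene-expression matrix X (m genes x n samples).
The three terms of the optimal decomposition are interpreted as the
principal features (XZ), the salient features (LX) and the sparse noise
(E); downstream classification keeps only D = LX.

The solver is the standard inexact augmented-Lagrange-multiplier scheme:
auxiliary variables J = Z and S = L decouple the nuclear-norm proximal
steps from the linear constraint, and each block update is the exact
minimizer of the augmented Lagrangian in that block.  Because expression
matrices are tall (m >> n), the m x m blocks L, S and Y3 are never
stored densely during iteration: every update keeps them in the factored
form G @ U.T with U the left singular vectors of X (rank r <= n), so the
per-iteration cost is O(m n r) and no m x m SVD or inverse is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .proximal import skinny_svd, soft_threshold, svt

__all__ = [
    "LatLRRParams",
    "LatLRRDecomposition",
    "fit_latlrr",
    "latlrr_objective",
    "feasible_baseline",
    "save_decomposition",
    "load_decomposition",
]


@dataclass(frozen=True)
class LatLRRParams:
    """Solver configuration.

    lambda_latlrr
        Weight on the l1 noise term; smaller values move more of X into
        E (more aggressive denoising).
    mu0, rho, mu_max
        Initial penalty, its growth factor per iteration and its cap.
    tol
        Feasibility tolerance: the maximum of the three constraint gaps
        (in the max-abs norm, relative to ``max|X|``) must fall below it.
    max_iter
        Iteration cap; exceeding it yields ``converged=False`` plus a
        warning, not an exception.
    """

    lambda_latlrr: float
    mu0: float = 1e-6
    rho: float = 1.1
    mu_max: float = 1e6
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self):
        if self.lambda_latlrr <= 0:
            raise InvalidParameterError(
                f"lambda_latlrr must be > 0, got {self.lambda_latlrr}")
        if self.mu0 <= 0:
            raise InvalidParameterError(f"mu0 must be > 0, got {self.mu0}")
        if self.rho <= 1:
            raise InvalidParameterError(f"rho must be > 1, got {self.rho}")
        if self.mu_max < self.mu0:
            raise InvalidParameterError("mu_max must be >= mu0")
        if self.tol <= 0:
            raise InvalidParameterError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise InvalidParameterError("max_iter must be >= 1")


@dataclass
class LatLRRDecomposition:
    """Optimal (Z, L, E) triple with convergence metadata."""

    Z: np.ndarray
    L: np.ndarray
    E: np.ndarray
    objective: float
    primal_residual: float
    E_l1: float
    n_iter: int
    converged: bool
    params: LatLRRParams
    constraint_gaps: dict = field(default_factory=dict)


def _nuclear_norm(M: np.ndarray) -> float:
    if not np.any(M):
        return 0.0
    return float(np.linalg.svd(M, compute_uv=False).sum())


def latlrr_objective(Z, L, E, lambda_latlrr: float) -> float:
    """``||Z||_* + ||L||_* + lambda * ||E||_1`` recomputed from scratch."""
    Z = np.asarray(Z, dtype=float)
    L = np.asarray(L, dtype=float)
    E = np.asarray(E, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise InvalidInputError(f"Z must be square, got shape {Z.shape}")
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise InvalidInputError(f"L must be square, got shape {L.shape}")
    if E.ndim != 2 or E.shape != (L.shape[0], Z.shape[0]):
        raise InvalidInputError(
            f"E shape {E.shape} inconsistent with Z {Z.shape} / L {L.shape}")
    return (_nuclear_norm(Z) + _nuclear_norm(L)
            + lambda_latlrr * float(np.abs(E).sum()))


def feasible_baseline(X):
    """The closed-form feasible point (Z, L, E) = (V V.T, 0, 0).

    V comes from the skinny SVD of X, so X Z = X exactly and the
    objective equals rank(X) (V V.T is an orthogonal projection whose
    nonzero singular values are all one).  Used as an optimality upper
    bound for the iterative solver.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X contains non-finite entries")
    m, n = X.shape
    dec = skinny_svd(X)
    Z = dec.V @ dec.V.T
    return Z, np.zeros((m, m)), np.zeros((m, n))


def _check_normalized(X: np.ndarray, atol: float = 1e-8) -> None:
    norms = np.linalg.norm(X, axis=0)
    bad = np.where(np.abs(norms - 1.0) > atol)[0]
    if bad.size:
        raise InvalidInputError(
            f"columns of X must have unit l2 norm (columns {bad[:5].tolist()}"
            f" have norms {norms[bad[:5]].round(6).tolist()}); normalize first"
            " or pass normalize=True")


def fit_latlrr(X, params: LatLRRParams, normalize: bool = False) -> LatLRRDecomposition:
    """Decompose X into principal features XZ, salient features LX and
    sparse noise E by inexact ALM.

    X must already have unit-l2 columns (the classifier's normalization
    step); pass ``normalize=True`` to have it rescaled here instead.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("X must be a 2-d matrix")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X contains non-finite entries")
    m, n = X.shape
    if n < 2:
        raise InvalidInputError(f"need at least 2 samples, got n={n}")
    if normalize:
        norms = np.linalg.norm(X, axis=0)
        if np.any(norms == 0):
            raise InvalidInputError("cannot normalize: zero column present")
        X = X / norms
    else:
        _check_normalized(X)

    lam = params.lambda_latlrr
    dec = skinny_svd(X)
    U, sig, V = dec.U, dec.S, dec.V          # X = U diag(sig) V.T, rank r
    r = sig.size
    # (I + X.T X)^-1 = I - V diag(sig^2/(1+sig^2)) V.T  (n x n, formed once)
    shrink = sig**2 / (1.0 + sig**2)
    inv_n = np.eye(n) - (V * shrink) @ V.T
    SigVt = sig[:, None] * V.T               # U.T X  (r x n)
    VSig = V * sig                           # X.T U  (n x r); M @ VSig = M X.T in factored form
    colscale = 1.0 / (1.0 + sig**2)          # right-multiplication by (I + X X.T)^-1

    Xt = X.T
    Z = np.zeros((n, n))
    J = np.zeros((n, n))
    Y2 = np.zeros((n, n))
    E = np.zeros((m, n))
    Y1 = np.zeros((m, n))
    GL = np.zeros((m, r))                    # L  = GL  @ U.T
    GS = np.zeros((m, r))                    # S  = GS  @ U.T
    GY3 = np.zeros((m, r))                   # Y3 = GY3 @ U.T
    mu = params.mu0

    normX_inf = np.abs(X).max()
    tol_abs = params.tol * (normX_inf if normX_inf > 0 else 1.0)

    converged = False
    n_iter = params.max_iter
    res = X.copy()
    for it in range(1, params.max_iter + 1):
        J = svt(Z + Y2 / mu, 1.0 / mu)
        # S-step: svt of (L + Y3/mu) = F @ U.T; the SVD of the factor F gives
        # the SVD of the product because U.T has orthonormal rows.
        F = GL + GY3 / mu
        if np.any(F):
            Pf, sf, Qft = np.linalg.svd(F, full_matrices=False)
            GS = (Pf * np.maximum(sf - 1.0 / mu, 0.0)) @ Qft
        else:
            GS = np.zeros((m, r))
        LX = GL @ SigVt
        Z = inv_n @ (Xt @ (X - LX - E) + J + (Xt @ Y1 - Y2) / mu)
        XZ = X @ Z
        N = (X - XZ - E) @ VSig + GS + (Y1 @ VSig - GY3) / mu
        GL = N * colscale
        LX = GL @ SigVt
        R = X - XZ - LX
        E = soft_threshold(R + Y1 / mu, lam / mu)
        res = R - E
        Y1 = Y1 + mu * res
        Y2 = Y2 + mu * (Z - J)
        GY3 = GY3 + mu * (GL - GS)
        # ||GL-GS||_F equals ||L-S||_F, an upper bound on ||L-S||_inf.
        gap = max(np.abs(res).max(), np.abs(Z - J).max(),
                  np.linalg.norm(GL - GS))
        if gap <= tol_abs:
            converged = True
            n_iter = it
            break
        mu = min(params.rho * mu, params.mu_max)

    if not converged:
        warnings.warn(
            f"LatLRR did not converge in {params.max_iter} iterations "
            f"(gap {gap:.3e} > tol {tol_abs:.3e})", RuntimeWarning)

    L = GL @ U.T
    E_l1 = float(np.abs(E).sum())
    normX = np.linalg.norm(X)
    objective = (_nuclear_norm(Z) + _nuclear_norm(GL) + lam * E_l1)
    gaps = {
        "constraint_inf": float(np.abs(res).max()),
        "ZJ_inf": float(np.abs(Z - J).max()),
        "LS_inf": float(np.abs((GL - GS) @ U.T).max()),
    }
    return LatLRRDecomposition(
        Z=Z, L=L, E=E,
        objective=float(objective),
        primal_residual=float(np.linalg.norm(res) / (normX if normX > 0 else 1.0)),
        E_l1=E_l1,
        n_iter=n_iter,
        converged=converged,
        params=params,
        constraint_gaps=gaps,
    )


def save_decomposition(path, dec: LatLRRDecomposition) -> None:
    """Persist a decomposition to an .npz archive (exact round-trip)."""
    p = dec.params
    np.savez(
        path,
        Z=dec.Z, L=dec.L, E=dec.E,
        objective=dec.objective,
        primal_residual=dec.primal_residual,
        E_l1=dec.E_l1,
        n_iter=dec.n_iter,
        converged=dec.converged,
        params=np.array([p.lambda_latlrr, p.mu0, p.rho, p.mu_max, p.tol,
                         float(p.max_iter)]),
        gaps=np.array([dec.constraint_gaps.get("constraint_inf", np.nan),
                       dec.constraint_gaps.get("ZJ_inf", np.nan),
                       dec.constraint_gaps.get("LS_inf", np.nan)]),
    )


def load_decomposition(path) -> LatLRRDecomposition:
    with np.load(path) as z:
        pv = z["params"]
        params = LatLRRParams(lambda_latlrr=float(pv[0]), mu0=float(pv[1]),
                              rho=float(pv[2]), mu_max=float(pv[3]),
                              tol=float(pv[4]), max_iter=int(pv[5]))
        gaps = z["gaps"]
        return LatLRRDecomposition(
            Z=z["Z"], L=z["L"], E=z["E"],
            objective=float(z["objective"]),
            primal_residual=float(z["primal_residual"]),
            E_l1=float(z["E_l1"]),
            n_iter=int(z["n_iter"]),
            converged=bool(z["converged"]),
            params=params,
            constraint_gaps={"constraint_inf": float(gaps[0]),
                             "ZJ_inf": float(gaps[1]),
                             "LS_inf": float(gaps[2])},
        )
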