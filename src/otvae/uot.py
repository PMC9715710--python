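"""Minibatch unbalanced optimal transport (UOT) between latent Gaussians.

The transport cost between two cells is the squared 2-Wasserstein distance
between their diagonal-Gaussian posteriors,

    C_ij = ||mu_xi - mu_yj||^2 + ||sigma_xi - sigma_yj||^2,

and the plan solves the unbalanced problem in which the marginal constraints
are relaxed into KL penalties with weight rho. The solver is an inexact
proximal point method (IPOT): iterated Sinkhorn-like scalings

    alpha <- (a / (G beta))^(rho/(rho+eps)),
    beta  <- (b / (G^T alpha))^(rho/(rho+eps)),   G_ij = T_ij^(l) e^(-C_ij/eps)

with the entropic kernel recentred at the previous plan. Because of the
recentring the entropic smoothing is annealed away across outer iterations:
the fixed point minimizes the *unregularized* UOT objective

    <C, T> + rho KL(T 1 || a) + rho KL(T^T 1 || b),

which is what :func:`uot_objective` evaluates by default. One scaling sweep is
performed per outer iteration (the standard inexactness); the beta update uses
the freshly updated alpha (Gauss-Seidel).

During training the plan is treated as a constant: the UOT loss
sum_ij C_ij T*_ij backpropagates through C only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .model import LatentGaussian


def gaussian_cost(lg_x: LatentGaussian, lg_y: LatentGaussian) -> np.ndarray:
    """Pairwise squared 2-Wasserstein cost between diagonal Gaussians."""
    if lg_x.mu.shape[1] != lg_y.mu.shape[1]:
        raise ValueError(
            f"latent dimension mismatch: {lg_x.mu.shape[1]} vs {lg_y.mu.shape[1]}"
        )
    C = _sqdist(lg_x.mu, lg_y.mu) + _sqdist(lg_x.sigma, lg_y.sigma)
    return np.maximum(C, 0.0)


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A.astype(np.float64)
    B = B.astype(np.float64)
    return (
        (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2.0 * A @ B.T
    )


def set_marginal_weights(
    weights_x: np.ndarray, weights_y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize user-supplied marginal weights to sum 1 per side."""
    out = []
    for w in (weights_x, weights_y):
        w = np.asarray(w, dtype=np.float64)
        if np.any(w < 0):
            raise ValueError("marginal weights must be non-negative")
        s = w.sum()
        if s <= 0:
            raise ValueError("marginal weights must not be all zero")
        out.append(w / s)
    return out[0], out[1]


def solve_uot_ipot(
    C: np.ndarray,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    epsilon: float = 0.1,
    rho: float = 1.0,
    outer_iters: int = 20,
    inner_iters: int = 1,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the minibatch UOT problem; returns the converged plan T*.

    Defaults: uniform marginals a = 1/B_x, b = 1/B_y, epsilon = 0.1, rho = 1,
    20 outer proximal iterations with one scaling sweep each, stopping early
    when the relative Frobenius change of the plan drops below ``tol``.
    ``init`` overrides the default a b^T starting plan (e.g. a slice of an
    accumulated global plan); it is renormalized to unit mass.
    """
    C = np.asarray(C, dtype=np.float64)
    if epsilon <= 0 or rho <= 0:
        raise ValueError("epsilon and rho must be positive")
    Bx, By = C.shape
    a = np.full(Bx, 1.0 / Bx) if a is None else np.asarray(a, dtype=np.float64)
    b = np.full(By, 1.0 / By) if b is None else np.asarray(b, dtype=np.float64)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("marginals must be strictly positive")

    if init is None:
        T = np.outer(a, b)
    else:
        T = np.asarray(init, dtype=np.float64)
        T = T / T.sum()
    K = np.exp(-C / epsilon)
    if not np.all(np.isfinite(K)):
        raise FloatingPointError(
            f"non-finite entropic kernel: C/epsilon in "
            f"[{C.min() / epsilon:.3g}, {C.max() / epsilon:.3g}]"
        )
    beta = np.full(By, 1.0 / Bx)
    q = rho / (rho + epsilon)
    tiny = 1e-300
    for _ in range(outer_iters):
        G = np.maximum(T * K, tiny)
        for _ in range(inner_iters):
            alpha = (a / np.maximum(G @ beta, tiny)) ** q
            beta = (b / np.maximum(G.T @ alpha, tiny)) ** q
        T_new = alpha[:, None] * G * beta[None, :]
        if not np.all(np.isfinite(T_new)):
            raise FloatingPointError(
                f"transport plan diverged: C in [{C.min():.3g}, {C.max():.3g}], "
                f"epsilon={epsilon}, rho={rho}"
            )
        denom = max(np.linalg.norm(T), tiny)
        rel = np.linalg.norm(T_new - T) / denom
        T = T_new
        if rel < tol:
            break
    return T


def uot_loss(C: np.ndarray, T_star: np.ndarray) -> float:
    """sum_ij C_ij T*_ij, the alignment loss (plan held fixed)."""
    if C.shape != T_star.shape:
        raise ValueError(f"shape mismatch: {C.shape} vs {T_star.shape}")
    return float(np.sum(C * T_star))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])) - p.sum() + q.sum())


def uot_objective(
    T: np.ndarray,
    C: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    rho: float,
    epsilon: float | None = None,
) -> float:
    """The UOT objective <C,T> + rho KL(T1||a) + rho KL(T^T 1||b).

    With ``epsilon`` given, adds the entropic term -eps * H(T) where
    H(T) = -sum T_ij (log T_ij - 1). The solver's fixed point minimizes the
    objective *without* the entropic term (see module docstring).
    """
    val = float(np.sum(C * T)) + rho * _kl(T.sum(1), a) + rho * _kl(T.sum(0), b)
    if epsilon is not None:
        Tm = np.maximum(T, 1e-300)
        val += epsilon * float(np.sum(T * (np.log(Tm) - 1.0)))
    return val


def init_global_plan(n_x: int, n_y: int, warn_bytes: int = 10**8) -> np.ndarray:
    """Dense global plan initialized uniform at 1/(n_x n_y)."""
    footprint = n_x * n_y * 8
    if footprint > warn_bytes:
        warnings.warn(
            f"global transport plan will occupy {footprint / 1e9:.2f} GB "
            f"({n_x} x {n_y} float64)"
        )
    return np.full((n_x, n_y), 1.0 / (n_x * n_y))


def update_global_plan(
    T: np.ndarray, T_B_star: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Write the minibatch plan into the global plan at (rows x cols), in place."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    for idx, n, side in ((rows, T.shape[0], "row"), (cols, T.shape[1], "col")):
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"duplicate {side} indices")
        if idx.min() < 0 or idx.max() >= n:
            raise IndexError(f"{side} index out of range [0, {n})")
    if T_B_star.shape != (len(rows), len(cols)):
        raise ValueError("minibatch plan shape does not match index sets")
    T[np.ix_(rows, cols)] = T_B_star
    return T


def save_plan_mtx(path, T: np.ndarray, mass_cutoff: float = 0.0) -> None:
    """Export the plan as a sparse MTX triplet, zeroing entries <= cutoff."""
    Ts = np.where(T > mass_cutoff, T, 0.0)
    mmwrite(str(path), sp.coo_matrix(Ts))


def save_plan_csv(path, T: np.ndarray, row_ids, col_ids) -> None:
    """Export the dense plan as CSV with cell-id row/column headers."""
    pd.DataFrame(T, index=list(row_ids), columns=list(col_ids)).to_csv(path)
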