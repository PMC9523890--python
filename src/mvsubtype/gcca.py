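"""Linear generalized CCA with a closed-form eigendecomposition solution.

Given J views ``X_j`` (N x p_j), finds a shared orthonormal embedding
``G`` (N x k) and per-view projections ``U_j`` (p_j x k) minimizing

    sum_j || G - X_j U_j ||_F^2   subject to  G^T G = I_k.

``G`` holds the top-k eigenvectors of ``M = sum_j X_j (X_j^T X_j)^{-1} X_j^T``
and the optimal objective equals ``J*k - sum_i lambda_i(M)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

__all__ = [
    "GccaResult",
    "SingularViewError",
    "fit_gcca",
    "gcca_objective",
    "project_view",
    "standardize_views",
    "fix_eigenvector_signs",
]


class SingularViewError(np.linalg.LinAlgError):
    """Raised when ``X_j^T X_j`` is singular and no ridge was requested."""


@dataclass
class GccaResult:
    """Solution of the shared-embedding problem.

    Attributes
    ----------
    G : ndarray of shape (N, k)
        View-independent embedding with orthonormal columns.
    U : list of ndarray
        Per-view projections, ``U[j]`` of shape (p_j, k).
    eigenvalues : ndarray of shape (k,)
        Top-k eigenvalues of the summed projector matrix, nonincreasing.
    objective_value : float
        ``J*k - eigenvalues.sum()``; equals the direct reconstruction
        objective at the optimum.
    """

    G: np.ndarray
    U: list[np.ndarray] = field(repr=False)
    eigenvalues: np.ndarray
    objective_value: float
    k: int
    ridge: float


def standardize_views(
    views: list[np.ndarray],
    means: list[np.ndarray] | None = None,
    stds: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Column z-score each view; constant columns are left centered only.

    When ``means``/``stds`` are supplied (training-set statistics) they are
    applied instead of being estimated, so held-out samples are scaled
    consistently with the fit.
    """
    out, out_means, out_stds = [], [], []
    for j, X in enumerate(views):
        X = np.asarray(X, dtype=float)
        mu = X.mean(axis=0) if means is None else means[j]
        sd = X.std(axis=0) if stds is None else stds[j]
        sd = np.where(sd > 0, sd, 1.0)
        out.append((X - mu) / sd)
        out_means.append(mu)
        out_stds.append(sd)
    return out, out_means, out_stds


def fix_eigenvector_signs(G: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Makes results reproducible across eigensolver backends, which return
    eigenvectors up to sign.
    """
    idx = np.argmax(np.abs(G), axis=0)
    signs = np.sign(G[idx, np.arange(G.shape[1])])
    signs[signs == 0] = 1.0
    return G * signs


def _view_cholesky(X: np.ndarray, ridge: float, j: int):
    """Cholesky factor of ``X^T X + ridge*I``, with a named singularity error."""
    S = X.T @ X
    if ridge > 0:
        S = S + ridge * np.eye(S.shape[0])
    try:
        return sla.cho_factor(S, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - message path
        raise SingularViewError(
            f"view {j}: X^T X is singular and ridge=0; pass ridge > 0"
        ) from exc


def fit_gcca(views: list[np.ndarray], k: int, ridge: float = 0.0) -> GccaResult:
    """Closed-form fit of the shared embedding on ``views``.

    Parameters
    ----------
    views
        List of (N, p_j) arrays sharing rows. Callers are expected to have
        standardized columns (see :func:`standardize_views`); the solver
        itself is scale-covariant only through the per-view whitening.
    k
        Embedding dimension, ``k <= N``.
    ridge
        Nonnegative value added to the diagonal of each ``X_j^T X_j``
        before inversion. Required when any view is column rank-deficient.
    """
    if not views:
        raise ValueError("need at least one view")
    N = views[0].shape[0]
    if any(X.shape[0] != N for X in views):
        raise ValueError("all views must share the same number of rows")
    if k > N:
        raise ValueError(f"k={k} exceeds the number of samples N={N}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")

    J = len(views)
    views = [np.asarray(X, dtype=float) for X in views]

    # M is N x N and explicit: sample sizes here are desk scale.
    M = np.zeros((N, N))
    chos = []
    for j, X in enumerate(views):
        cho = _view_cholesky(X, ridge, j)
        chos.append(cho)
        M += X @ sla.cho_solve(cho, X.T)

    evals, evecs = sla.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = evals[order][:k]
    G = fix_eigenvector_signs(evecs[:, order[:k]])

    U = [sla.cho_solve(cho, X.T @ G) for cho, X in zip(chos, views)]
    objective = float(J * k - evals.sum())
    return GccaResult(
        G=G,
        U=U,
        eigenvalues=evals,
        objective_value=objective,
        k=k,
        ridge=ridge,
    )


def gcca_objective(
    views: list[np.ndarray], G: np.ndarray, U: list[np.ndarray]
) -> float:
    """Direct evaluation of ``sum_j ||G - X_j U_j||_F^2``."""
    if len(views) != len(U):
        raise ValueError("one projection per view required")
    total = 0.0
    for j, (X, Uj) in enumerate(zip(views, U)):
        if X.shape[1] != Uj.shape[0] or G.shape != (X.shape[0], Uj.shape[1]):
            raise ValueError(f"view {j}: incompatible shapes")
        total += float(np.sum((G - X @ Uj) ** 2))
    return total


def project_view(features: np.ndarray, U_j: np.ndarray) -> np.ndarray:
    """Project samples into the embedding space: ``features @ U_j``."""
    features = np.asarray(features, dtype=float)
    U_j = np.asarray(U_j, dtype=float)
    if features.shape[1] != U_j.shape[0]:
        raise ValueError(
            f"feature width {features.shape[1]} != projection rows {U_j.shape[0]}"
        )
    return features @ U_j
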