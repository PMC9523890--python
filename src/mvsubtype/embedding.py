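"""Embedding diagnostics: variance-explained component selection and
per-component canonical correlations between projected views."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EmbeddingSelection",
    "variance_explained",
    "variance_curve",
    "select_components",
    "canonical_correlations",
    "correlation_table",
]


@dataclass
class EmbeddingSelection:
    variance_curve: np.ndarray  # fraction explained at r = 1..k_max
    chosen_r: int
    target_fraction: float
    capped: bool = False


def _check_orthonormal(G: np.ndarray, tol: float = 1e-6) -> None:
    gram = G.T @ G
    err = np.max(np.abs(gram - np.eye(G.shape[1])))
    if err > tol:
        raise ValueError(f"G columns are not orthonormal (max |G'G - I| = {err:.2e})")


def variance_explained(views: list[np.ndarray], G: np.ndarray, r: int) -> float:
    """Fraction of total view variance captured by the first r embedding
    columns: sum_j ||G_r G_r' X_j||_F^2 / sum_j ||X_j||_F^2.

    ``views`` should be the standardized input views; ``G`` must have
    orthonormal columns.
    """
    if r < 0 or r > G.shape[1]:
        raise ValueError(f"r={r} outside [0, {G.shape[1]}]")
    if r == 0:
        return 0.0
    _check_orthonormal(G)
    Gr = G[:, :r]
    num = sum(float(np.sum((Gr @ (Gr.T @ X)) ** 2)) for X in views)
    den = sum(float(np.sum(X**2)) for X in views)
    if den == 0:
        raise ValueError("views have zero total variance")
    return num / den


def variance_curve(views: list[np.ndarray], G: np.ndarray) -> np.ndarray:
    """Variance explained at every r = 1..k; nondecreasing by construction."""
    _check_orthonormal(G)
    den = sum(float(np.sum(X**2)) for X in views)
    per_comp = np.zeros(G.shape[1])
    for X in views:
        per_comp += np.sum((G.T @ X) ** 2, axis=1)
    return np.cumsum(per_comp) / den


def select_components(curve: np.ndarray, target_fraction: float) -> EmbeddingSelection:
    """Smallest r whose explained fraction meets the target; capped at k_max
    (with a warning) when the target is never reached."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty variance curve")
    if np.any(np.diff(curve) < -1e-12):
        raise ValueError("variance curve must be nondecreasing")
    meets = np.nonzero(curve >= target_fraction)[0]
    if meets.size:
        return EmbeddingSelection(curve, int(meets[0]) + 1, target_fraction)
    warnings.warn(
        f"target fraction {target_fraction} never reached; using all "
        f"{curve.size} components",
        stacklevel=2,
    )
    return EmbeddingSelection(curve, curve.size, target_fraction, capped=True)


def canonical_correlations(proj_a: np.ndarray, proj_b: np.ndarray) -> np.ndarray:
    """Pearson correlation between matched columns of two projections.

    This is the per-embedded-feature quantity: component i of view a against
    component i of view b. Zero-variance columns yield NaN for that
    component rather than an error.
    """
    proj_a = np.asarray(proj_a, dtype=float)
    proj_b = np.asarray(proj_b, dtype=float)
    if proj_a.shape != proj_b.shape:
        raise ValueError("projections must share shape")
    a = proj_a - proj_a.mean(axis=0)
    b = proj_b - proj_b.mean(axis=0)
    sa = np.sqrt(np.sum(a**2, axis=0))
    sb = np.sqrt(np.sum(b**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.sum(a * b, axis=0) / (sa * sb)
    corr[(sa == 0) | (sb == 0)] = np.nan
    return corr


def correlation_table(
    projections: list[np.ndarray], split: str = "train"
) -> pd.DataFrame:
    """Long-format per-pair, per-component correlation table
    (component, view_pair, split, correlation)."""
    rows = []
    J = len(projections)
    for a in range(J):
        for b in range(a + 1, J):
            corr = canonical_correlations(projections[a], projections[b])
            for i, c in enumerate(corr):
                rows.append(
                    {
                        "component": i + 1,
                        "view_pair": f"view{a + 1}-view{b + 1}",
                        "split": split,
                        "correlation": c,
                    }
                )
    return pd.DataFrame(rows)
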