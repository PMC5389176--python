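"""Reference correlation estimators: Pearson and Schäfer–Strimmer shrinkage.

Both can be masked to a block structure (entries outside the blocks set to
exactly zero), which is how block-informed versions of these estimators are
built for comparison with the empirical-Bayes method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockStructure

__all__ = ["MaskedEstimate", "pearson", "corpcor_shrinkage", "apply_block_mask"]


@dataclass(frozen=True)
class MaskedEstimate:
    """A correlation estimate, optionally masked to a block structure."""

    R_hat: np.ndarray
    structure: BlockStructure | None = None
    shrinkage: float | None = None  # delta-hat for the shrinkage estimator


def _validated(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variables)")
    if X.shape[0] < 3:
        raise ValueError(f"need at least 3 samples, got n={X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    sd = X.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant (zero-variance) variables at indices {constant.tolist()}"
        )
    return X


def pearson(X: np.ndarray) -> MaskedEstimate:
    """Product-moment (Pearson) correlation matrix of the columns of X."""
    X = _validated(X)
    R = np.corrcoef(X, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return MaskedEstimate(R_hat=R)


def corpcor_shrinkage(X: np.ndarray) -> MaskedEstimate:
    """Analytic linear shrinkage of the correlations toward zero.

    Off-diagonal entries are scaled by ``1 - delta`` with the data-driven
    intensity ``delta = min(1, sum var_hat(r_ij) / sum r_ij^2)``, where
    ``var_hat(r_ij)`` is the unbiased estimate of the sampling variance of
    each correlation computed from the per-sample products of standardized
    scores.  This is the zero-off-diagonal-target shrinkage estimator of
    the corpcor family.
    """
    X = _validated(X)
    n, p = X.shape
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = (Xs.T @ Xs) / (n - 1)
    # w_kij = x_ki x_kj; var_hat(r_ij) = n/(n-1)^3 * sum_k (w_kij - w_bar_ij)^2
    W = np.einsum("ki,kj->kij", Xs, Xs)
    w_bar = W.mean(axis=0)
    var_r = (n / (n - 1.0) ** 3) * ((W - w_bar) ** 2).sum(axis=0)
    iu = np.triu_indices(p, k=1)
    denom = float((R[iu] ** 2).sum())
    delta = 1.0 if denom == 0.0 else min(1.0, max(0.0, float(var_r[iu].sum()) / denom))
    R_star = (1.0 - delta) * R
    np.fill_diagonal(R_star, 1.0)
    return MaskedEstimate(R_hat=R_star, shrinkage=delta)


def apply_block_mask(R_hat: np.ndarray, structure: BlockStructure) -> MaskedEstimate:
    """Zero every entry outside the blocks; within-block entries untouched."""
    R_hat = np.asarray(R_hat, dtype=float)
    if R_hat.shape != (structure.p, structure.p):
        raise ValueError("R_hat shape does not match structure.p")
    mask = structure.same_block_mask(include_diagonal=True)
    return MaskedEstimate(R_hat=np.where(mask, R_hat, 0.0), structure=structure)
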