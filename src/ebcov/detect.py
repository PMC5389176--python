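"""Data-driven discovery of the block partition.

Two routes are provided.  Thresholding treats the sample correlation matrix
as a graph with an edge wherever ``|r_ij|`` reaches the threshold and takes
connected components as blocks.  When no threshold is known, a grid of
candidate thresholds is scored by AIC under a Gaussian model whose
covariance is the block-diagonal, averaged-correlation matrix each
candidate induces, and the minimizing threshold is selected.

Thresholding uses absolute correlations: co-repression (strong negative
correlation) is as much evidence of shared regulation as co-activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .blocks import BlockStructure
from .prior import _check_correlation_matrix, build_prior

__all__ = [
    "ThresholdScan",
    "blocks_from_threshold",
    "mvn_loglik",
    "select_threshold_aic",
    "DEFAULT_AIC_GRID",
]

#: default candidate thresholds for AIC selection
DEFAULT_AIC_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


@dataclass(frozen=True)
class ThresholdScan:
    """Result of an AIC threshold scan.

    ``chosen`` minimizes ``aic_values``; AIC ties are broken toward the
    larger threshold (the sparser, more parsimonious model).
    """

    thresholds: tuple[float, ...]
    aic_values: tuple[float, ...]
    n_parameters: tuple[int, ...]
    logliks: tuple[float, ...]
    structures: tuple[BlockStructure, ...]
    chosen: float

    @property
    def chosen_index(self) -> int:
        return self.thresholds.index(self.chosen)

    @property
    def chosen_structure(self) -> BlockStructure:
        return self.structures[self.chosen_index]


def blocks_from_threshold(R_sample: np.ndarray, threshold: float) -> BlockStructure:
    """Connected components of the graph with edges where ``|r_ij| >= t``.

    Each component is completely uncorrelated (above threshold) with every
    other component, so components map one-to-one onto blocks.
    """
    R = _check_correlation_matrix(R_sample)
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    p = R.shape[0]
    adj = np.abs(R) >= threshold
    np.fill_diagonal(adj, False)
    graph = nx.from_numpy_array(adj)
    graph.add_nodes_from(range(p))
    comps = [sorted(c) for c in nx.connected_components(graph)]
    return BlockStructure.from_blocks(p, comps)


def mvn_loglik(S_hat: np.ndarray, omega: np.ndarray, n: int) -> float:
    """Gaussian log-likelihood of data with scatter ``S_hat`` under covariance
    ``omega``: ``-(n/2) [ln det Ω + tr(Ω⁻¹ Ŝ) + p ln 2π]``.

    ``S_hat`` is the maximum-likelihood covariance (scatter divided by n).
    """
    S_hat = np.asarray(S_hat, dtype=float)
    omega = np.asarray(omega, dtype=float)
    p = omega.shape[0]
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError("model covariance is not positive definite")
    trace_term = float(np.trace(np.linalg.solve(omega, S_hat)))
    return -0.5 * n * (logdet + trace_term + p * np.log(2.0 * np.pi))


def select_threshold_aic(
    R_sample: np.ndarray,
    S_hat: np.ndarray,
    n: int,
    grid: tuple[float, ...] | None = None,
) -> ThresholdScan:
    """Scan candidate thresholds and pick the one minimizing AIC.

    For each candidate ``t`` the induced partition defines a block-diagonal
    model covariance: the averaged-correlation block matrix (the same
    construction as the prior) rescaled by the sample standard deviations.
    The parameter count is the number of free entries of a block-diagonal
    covariance, ``sum_b m_b (m_b + 1) / 2``.
    """
    R = _check_correlation_matrix(R_sample)
    S_hat = np.asarray(S_hat, dtype=float)
    if grid is None:
        grid = DEFAULT_AIC_GRID
    grid = tuple(float(t) for t in grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    for t in grid:
        if not 0.0 <= t < 1.0:
            raise ValueError(f"grid threshold {t} outside [0, 1)")

    sd = np.sqrt(np.diag(S_hat))
    scale = np.outer(sd, sd)
    thresholds, aics, ks, lls, structs = [], [], [], [], []
    for t in grid:
        structure = blocks_from_threshold(R, t)
        z = build_prior(R, structure).z
        omega = z * scale
        k = sum(m * (m + 1) // 2 for m in structure.sizes)
        ll = mvn_loglik(S_hat, omega, n)
        thresholds.append(t)
        aics.append(2.0 * k - 2.0 * ll)
        ks.append(k)
        lls.append(ll)
        structs.append(structure)

    best = 0
    for i in range(1, len(thresholds)):
        # <= : ties go to the larger threshold (grid is ascending)
        if aics[i] <= aics[best]:
            best = i
    return ThresholdScan(
        thresholds=tuple(thresholds),
        aic_values=tuple(aics),
        n_parameters=tuple(ks),
        logliks=tuple(lls),
        structures=tuple(structs),
        chosen=thresholds[best],
    )
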