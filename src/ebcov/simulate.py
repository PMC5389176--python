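"""Synthetic ground truth: block-diagonal correlation matrices and MVN draws.

The generator follows the constructive recipe of Hardin and colleagues for
positive-definite block correlation matrices: start from the exact
constant-correlation block matrix (within-block correlation ``rho_within``,
zero between blocks) and optionally add a controlled perturbation built
from random unit vectors, which keeps the diagonal at one and bounds the
spectral distortion by ``epsilon_noise``.  With ``epsilon_noise = 0`` (the
default) the truth is the unperturbed constant-correlation matrix.

Default scenario: 50 genes in 5 blocks of sizes (5, 8, 10, 12, 15), within-
block correlation 0.7, samples of size 10/15/20 — small-n conditions typical
of expression experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .blocks import BlockStructure

__all__ = [
    "TruthScenario",
    "ReplicateDraw",
    "make_truth",
    "draw",
    "DEFAULT_BLOCK_SIZES",
    "DEFAULT_RHO",
]

DEFAULT_BLOCK_SIZES = (5, 8, 10, 12, 15)
DEFAULT_RHO = 0.7


@dataclass(frozen=True)
class TruthScenario:
    """A ground-truth correlation matrix and the partition that built it."""

    p: int
    structure: BlockStructure
    rho_within: float
    epsilon_noise: float
    Sigma_true: np.ndarray
    seed: int | None


@dataclass(frozen=True)
class ReplicateDraw:
    """An ``n x p`` multivariate-normal sample from a truth scenario."""

    scenario: TruthScenario
    n: int
    X: np.ndarray
    seed: int | None


def _contiguous_structure(block_sizes: Sequence[int]) -> BlockStructure:
    blocks = []
    start = 0
    for m in block_sizes:
        blocks.append(range(start, start + m))
        start += m
    return BlockStructure.from_blocks(start, blocks)


def make_truth(
    p: int = 50,
    block_sizes: Sequence[int] = DEFAULT_BLOCK_SIZES,
    rho_within: float = DEFAULT_RHO,
    epsilon_noise: float = 0.0,
    seed: int | None = None,
) -> TruthScenario:
    """Build a positive-definite block-diagonal truth correlation matrix.

    Raises
    ------
    ValueError
        If the block sizes do not sum to ``p`` or the noise level makes
        positive definiteness impossible (needs ``rho + epsilon < 1``).
    """
    block_sizes = tuple(int(m) for m in block_sizes)
    if any(m < 1 for m in block_sizes):
        raise ValueError("block sizes must be positive")
    if sum(block_sizes) != p:
        raise ValueError(f"block sizes sum to {sum(block_sizes)}, expected p={p}")
    if not 0.0 <= rho_within < 1.0:
        raise ValueError("rho_within must be in [0, 1)")
    if epsilon_noise < 0 or rho_within + epsilon_noise >= 1.0:
        raise ValueError("need epsilon_noise >= 0 and rho_within + epsilon_noise < 1")

    structure = _contiguous_structure(block_sizes)
    Sigma = np.eye(p)
    for block in structure.blocks:
        idx = np.asarray(block)
        Sigma[np.ix_(idx, idx)] = rho_within
    np.fill_diagonal(Sigma, 1.0)

    if epsilon_noise > 0:
        rng = np.random.default_rng(seed)
        # Gram matrix of random unit vectors: PSD with unit diagonal, so
        # eps*(Q - I) perturbs off-diagonals, keeps diag(Sigma)=1, and shifts
        # eigenvalues by at most eps below; PD holds since lambda_min of the
        # constant-correlation part is 1 - rho > eps.
        U = rng.standard_normal((p, p))
        U /= np.linalg.norm(U, axis=0, keepdims=True)
        Q = U.T @ U
        Sigma = Sigma + epsilon_noise * (Q - np.eye(p))
        Sigma = (Sigma + Sigma.T) / 2.0

    eigmin = float(np.linalg.eigvalsh(Sigma)[0])
    if eigmin <= 0:
        raise ValueError(f"truth matrix not positive definite (min eig {eigmin:g})")
    return TruthScenario(
        p=p,
        structure=structure,
        rho_within=rho_within,
        epsilon_noise=epsilon_noise,
        Sigma_true=Sigma,
        seed=seed,
    )


def draw(scenario: TruthScenario, n: int, seed: int | None = None) -> ReplicateDraw:
    """Draw ``n`` i.i.d. mean-zero MVN samples with covariance ``Sigma_true``."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(scenario.Sigma_true)
    X = rng.standard_normal((n, scenario.p)) @ L.T
    return ReplicateDraw(scenario=scenario, n=n, X=X, seed=seed)
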