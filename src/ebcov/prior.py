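"""Block-diagonal prior correlation matrices with constant within-block level.

The prior matrix ``z`` is block diagonal: zero between blocks, and a single
constant correlation ``gamma_b`` inside each block ``b``, estimated as the
average of the sample correlations among the block's members.  A constant
correlation block of size ``m`` is positive definite exactly when
``-1/(m-1) < gamma < 1`` (its eigenvalues are ``1+(m-1)*gamma`` and
``1-gamma``), and a block-diagonal matrix is positive definite iff each
block is, so ``z`` remains a valid inverse-Wishart prior scale matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockStructure

__all__ = ["PriorSpec", "build_prior", "EPS_PD"]

#: margin keeping each constant-correlation block strictly positive definite
EPS_PD = 1e-6


@dataclass(frozen=True)
class PriorSpec:
    """The block-diagonal prior: a structure, per-block constants, and z.

    ``gammas[b]`` is ``nan`` for singleton blocks, which contribute a 1x1
    identity block and have no off-diagonal correlation to set.
    """

    structure: BlockStructure
    gammas: tuple[float, ...]
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != (self.structure.p, self.structure.p):
            raise ValueError("z shape does not match structure.p")


def _check_correlation_matrix(R: np.ndarray, name: str = "R_sample") -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError(f"{name} must have unit diagonal")
    return R


def build_prior(R_sample: np.ndarray, structure: BlockStructure) -> PriorSpec:
    """Average sample correlations within each block into the prior ``z``.

    For block ``b`` of size ``m_b >= 2``, ``gamma_b`` is the unweighted mean
    of the off-diagonal sample correlations among its members, clamped into
    ``(-1/(m_b-1) + EPS_PD, 1 - EPS_PD)`` so the block stays positive
    definite.  Entries between blocks are zero; the diagonal is one.
    """
    R = _check_correlation_matrix(R_sample)
    if R.shape[0] != structure.p:
        raise ValueError(
            f"R_sample is {R.shape[0]}x{R.shape[0]} but structure has p={structure.p}"
        )
    z = np.eye(structure.p)
    gammas: list[float] = []
    for block in structure.blocks:
        m = len(block)
        if m == 1:
            gammas.append(float("nan"))
            continue
        idx = np.asarray(block)
        sub = R[np.ix_(idx, idx)]
        gamma = (sub.sum() - m) / (m * (m - 1))  # mean over off-diagonal pairs
        gamma = float(np.clip(gamma, -1.0 / (m - 1) + EPS_PD, 1.0 - EPS_PD))
        gammas.append(gamma)
        z[np.ix_(idx, idx)] = gamma
    np.fill_diagonal(z, 1.0)
    return PriorSpec(structure=structure, gammas=tuple(gammas), z=z)
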