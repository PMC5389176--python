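"""Empirical-Bayes posterior-mean covariance/correlation estimation.

The covariance ``eta`` of mean-centred Gaussian data is given a conjugate
inverse-Wishart prior whose scale matrix is ``lambda * z``, with ``z`` the
block-diagonal prior correlation matrix and ``lambda`` a scalar prior
strength.  With scatter ``S`` from ``n`` samples the posterior is again
inverse Wishart, and the estimate is its mean

    eta0 = (lambda * z + S) / (lambda + n)

Variables are standardized (mean 0, variance 1, divisor ``n``) before
estimation, so ``S / n`` equals the sample correlation matrix and ``z``
lives on the same scale; on that working scale ``eta0`` is the convex
combination ``w*z + (1-w)*R_sample`` with ``w = lambda / (lambda + n)``,
re-standardized to exact unit diagonal.  A covariance-scale estimate is
recovered by rescaling with the sample standard deviations.

``lambda`` itself is estimated from the first-order approximation to the
sampling variance of a correlation coefficient around its prior value,

    E[(rho_ij[eta] - rho_ij[z])^2]  ~=  (1 - rho_ij[z]^2)^2 / (lambda + 3),

solved for ``lambda`` after averaging numerator and denominator over all
off-diagonal pairs (ratio of means, which is robust to pairs whose
observed discrepancy is nearly zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .blocks import BlockStructure, blocks_from_list
from .detect import blocks_from_threshold, select_threshold_aic, ThresholdScan
from .prior import PriorSpec, build_prior

__all__ = [
    "SampleSummary",
    "PosteriorEstimate",
    "LAMBDA_MIN",
    "LAMBDA_MAX",
    "estimate_lambda",
    "posterior_mean",
    "estimate",
]

LAMBDA_MIN = 1e-3
LAMBDA_MAX = 1e6


@dataclass(frozen=True)
class SampleSummary:
    """Standardized data and its scatter/correlation summaries."""

    X: np.ndarray  # n x p, standardized columns
    mu_prime: np.ndarray  # per-variable sample mean of the raw data
    sd: np.ndarray  # per-variable sample standard deviation (divisor n)
    S: np.ndarray  # scatter of the standardized data: X'X (= n * R_sample)
    R_sample: np.ndarray
    n: int
    p: int

    @classmethod
    def from_data(cls, X: np.ndarray) -> "SampleSummary":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x variables)")
        n, p = X.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got n={n}")
        if p < 2:
            raise ValueError(f"need at least 2 variables, got p={p}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        mu = X.mean(axis=0)
        sd = X.std(axis=0)  # divisor n, matching the scatter convention
        constant = np.flatnonzero(sd == 0)
        if constant.size:
            raise ValueError(
                f"constant (zero-variance) variables at indices {constant.tolist()}"
            )
        Xs = (X - mu) / sd
        R = (Xs.T @ Xs) / n
        np.fill_diagonal(R, 1.0)
        R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
        return cls(X=Xs, mu_prime=mu, sd=sd, S=n * R, R_sample=R, n=n, p=p)


@dataclass(frozen=True)
class PosteriorEstimate:
    """Posterior-mean estimate on the correlation working scale."""

    lambda_: float
    eta0: np.ndarray  # posterior mean (lambda z + S) / (lambda + n)
    R_eb: np.ndarray  # eta0 standardized to exact unit diagonal
    prior: PriorSpec
    n: int
    threshold_scan: ThresholdScan | None = None

    @property
    def prior_weight(self) -> float:
        """Weight ``w = lambda / (lambda + n)`` of the prior in the blend."""
        return self.lambda_ / (self.lambda_ + self.n)

    def covariance(self, sd: Sequence[float] | np.ndarray) -> np.ndarray:
        """Rescale the correlation estimate by standard deviations."""
        sd = np.asarray(sd, dtype=float)
        return self.R_eb * np.outer(sd, sd)


def estimate_lambda(R_sample: np.ndarray, z: np.ndarray) -> float:
    """Prior strength from the discrepancy between sample and prior
    correlations, ``lambda = v_bar / d_bar - 3`` clamped to
    ``[LAMBDA_MIN, LAMBDA_MAX]``.

    ``d_bar`` averages ``(r_ij - z_ij)^2`` and ``v_bar`` averages
    ``(1 - z_ij^2)^2`` over the off-diagonal pairs ``i < j`` (all pairs,
    including between-block pairs where ``z_ij = 0``).
    """
    R_sample = np.asarray(R_sample, dtype=float)
    z = np.asarray(z, dtype=float)
    if R_sample.shape != z.shape:
        raise ValueError("R_sample and z must have the same shape")
    p = R_sample.shape[0]
    if p < 2:
        raise ValueError("lambda estimation needs p >= 2 (no off-diagonal pairs)")
    iu = np.triu_indices(p, k=1)
    d_bar = float(np.mean((R_sample[iu] - z[iu]) ** 2))
    v_bar = float(np.mean((1.0 - z[iu] ** 2) ** 2))
    if d_bar == 0.0:
        return LAMBDA_MAX  # sample agrees with the prior exactly: trust it fully
    return float(np.clip(v_bar / d_bar - 3.0, LAMBDA_MIN, LAMBDA_MAX))


def posterior_mean(
    summary: SampleSummary, prior: PriorSpec, lambda_: float
) -> PosteriorEstimate:
    """The inverse-Wishart posterior mean ``(lambda z + S)/(lambda + n)``.

    On the standardized working scale this is the convex blend
    ``w z + (1-w) R_sample``; the returned ``R_eb`` re-standardizes it to
    exact unit diagonal.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    if prior.z.shape != summary.S.shape:
        raise ValueError("prior and summary dimensions disagree")
    eta0 = (lambda_ * prior.z + summary.S) / (lambda_ + summary.n)
    d = np.sqrt(np.diag(eta0))
    R_eb = eta0 / np.outer(d, d)
    np.fill_diagonal(R_eb, 1.0)
    return PosteriorEstimate(
        lambda_=float(lambda_), eta0=eta0, R_eb=R_eb, prior=prior, n=summary.n
    )


Mode = Literal["groups", "threshold", "aic"]


def estimate(
    X: np.ndarray,
    mode: Mode,
    *,
    structure: BlockStructure | None = None,
    groups: Sequence[Sequence[str]] | None = None,
    labels: Sequence[str] | None = None,
    threshold: float | None = None,
    aic_grid: Sequence[float] | None = None,
) -> PosteriorEstimate:
    """Full pipeline: standardize, find blocks, build the prior, estimate
    ``lambda`` and return the posterior-mean correlation estimate.

    Parameters
    ----------
    X
        ``n x p`` data matrix (samples in rows).
    mode
        Block-discovery route: ``"groups"`` (caller supplies ``structure``
        or named ``groups`` + ``labels``), ``"threshold"`` (graph
        components at ``|r| >= threshold``), or ``"aic"`` (threshold chosen
        by AIC over a grid).
    """
    summary = SampleSummary.from_data(X)
    scan: ThresholdScan | None = None
    if mode == "groups":
        if structure is None:
            if groups is None or labels is None:
                raise ValueError("mode='groups' needs structure, or groups + labels")
            structure = blocks_from_list(groups, labels)
        if structure.p != summary.p:
            raise ValueError("structure.p does not match the data")
    elif mode == "threshold":
        if threshold is None:
            raise ValueError("mode='threshold' needs a threshold")
        structure = blocks_from_threshold(summary.R_sample, threshold)
    elif mode == "aic":
        scan = select_threshold_aic(
            summary.R_sample,
            summary.S / summary.n,
            summary.n,
            grid=tuple(aic_grid) if aic_grid is not None else None,
        )
        structure = scan.chosen_structure
    else:
        raise ValueError(f"unknown mode {mode!r}")

    prior = build_prior(summary.R_sample, structure)
    lam = estimate_lambda(summary.R_sample, prior.z)
    est = posterior_mean(summary, prior, lam)
    if scan is not None:
        est = PosteriorEstimate(
            lambda_=est.lambda_,
            eta0=est.eta0,
            R_eb=est.R_eb,
            prior=est.prior,
            n=est.n,
            threshold_scan=scan,
        )
    return est
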