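"""Scoring estimators against a known truth, and the replicate study driver.

Metrics
-------
* Frobenius distance to the truth matrix, either over all entries or
  restricted to the entries inside the true blocks.
* FDR and TPR of significance calls.  A pair is called significant by the
  two-sided t-test on its estimated correlation, ``t = r sqrt((n-2)/(1-r^2))``
  with ``n - 2`` degrees of freedom; a pair is a true positive when it lies
  inside a true block (the truth's between-block correlations are zero).

The study driver repeats the full simulation pipeline over independent
replicates: draw a truth matrix, sample ``n`` expression profiles, fit the
empirical-Bayes estimator (known groups, fixed threshold, and AIC-selected
threshold) alongside the Pearson and shrinkage baselines masked to either
the known or threshold-derived blocks, and accumulate the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import apply_block_mask, corpcor_shrinkage, pearson
from .blocks import BlockStructure
from .detect import blocks_from_threshold
from .estimator import estimate
from .simulate import DEFAULT_BLOCK_SIZES, DEFAULT_RHO, draw, make_truth

__all__ = [
    "EvalReport",
    "StudyConfig",
    "frobenius_distance",
    "correlation_pvalues",
    "significance_calls",
    "fdr_tpr",
    "run_study",
    "summary_table",
]

METRICS = ("frobenius_block", "frobenius_full", "fdr", "tpr")

#: estimators exercised by the study, in table order
STUDY_METHODS = (
    "pearson_block",
    "corpcor_block",
    "eb",
    "pearson_threshold",
    "corpcor_threshold",
    "eb_threshold",
    "eb_aic",
)


def frobenius_distance(
    R_hat: np.ndarray,
    Sigma_true: np.ndarray,
    restrict: str = "full",
    structure: BlockStructure | None = None,
) -> float:
    """Square root of the sum of squared entrywise differences.

    ``restrict="blocks"`` sums only over entries inside the true blocks
    (both triangles; diagonal entries match by construction and contribute
    zero) and requires ``structure``.
    """
    R_hat = np.asarray(R_hat, dtype=float)
    Sigma_true = np.asarray(Sigma_true, dtype=float)
    if R_hat.shape != Sigma_true.shape:
        raise ValueError("matrix shapes disagree")
    diff = R_hat - Sigma_true
    if restrict == "full":
        return float(np.linalg.norm(diff))
    if restrict == "blocks":
        if structure is None:
            raise ValueError("restrict='blocks' requires a structure")
        mask = structure.same_block_mask(include_diagonal=True)
        return float(np.sqrt((diff[mask] ** 2).sum()))
    raise ValueError(f"unknown restrict {restrict!r}")


def correlation_pvalues(R_hat: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values of the t-test on each off-diagonal correlation.

    Entries with ``|r| = 1`` get p-value 0 by convention; the diagonal is
    set to 1 (never called).
    """
    if n < 3:
        raise ValueError("t-test needs n >= 3")
    R = np.asarray(R_hat, dtype=float)
    r = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals = np.where(np.abs(r) >= 1.0, 0.0, pvals)
    np.fill_diagonal(pvals, 1.0)
    return pvals


def significance_calls(R_hat: np.ndarray, n: int, alpha: float = 0.05) -> np.ndarray:
    """Boolean matrix of significant correlations (two-sided, level alpha)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    calls = correlation_pvalues(R_hat, n) < alpha
    np.fill_diagonal(calls, False)
    return calls


def fdr_tpr(
    calls: np.ndarray, Sigma_true: np.ndarray, structure: BlockStructure
) -> tuple[float, float]:
    """Confusion rates over unordered off-diagonal pairs.

    Positives are pairs inside a true block (nonzero true correlation);
    FDR = FP / max(FP + TP, 1) and TPR = TP / (TP + FN).
    """
    calls = np.asarray(calls, dtype=bool)
    p = calls.shape[0]
    if Sigma_true.shape != (p, p):
        raise ValueError("shapes disagree")
    iu = np.triu_indices(p, k=1)
    called = calls[iu]
    positive = structure.same_block_mask(include_diagonal=False)[iu]
    tp = int(np.sum(called & positive))
    fp = int(np.sum(called & ~positive))
    fn = int(np.sum(~called & positive))
    fdr = fp / max(fp + tp, 1)
    tpr = tp / max(tp + fn, 1)
    return float(fdr), float(tpr)


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the replicate study (defaults mirror the simulation
    scenario: 50 genes, 5 blocks, within-block correlation 0.7)."""

    p: int = 50
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    rho_within: float = DEFAULT_RHO
    epsilon_noise: float = 0.0
    sample_sizes: tuple[int, ...] = (10, 15, 20)
    reps: int = 100
    threshold: float = 0.7
    alpha: float = 0.05
    aic_grid: tuple[float, ...] | None = None
    seed: int = 0
    methods: tuple[str, ...] = STUDY_METHODS


@dataclass
class EvalReport:
    """Per-replicate metric values for one (method, n) cell of the study."""

    method: str
    n: int
    values: dict[str, list[float]] = field(
        default_factory=lambda: {m: [] for m in METRICS}
    )

    @property
    def reps(self) -> int:
        return len(self.values[METRICS[0]])

    def mean(self, metric: str) -> float:
        return float(np.mean(self.values[metric]))

    def sd(self, metric: str) -> float:
        return float(np.std(self.values[metric], ddof=1))

    def record(self, **metrics: float) -> None:
        for name, value in metrics.items():
            self.values[name].append(float(value))


def _fit_all(
    X: np.ndarray,
    truth_structure: BlockStructure,
    threshold: float,
    aic_grid: tuple[float, ...] | None,
    methods: Sequence[str],
) -> dict[str, np.ndarray]:
    """Correlation estimates of every requested method on one replicate."""
    out: dict[str, np.ndarray] = {}
    R_pearson = pearson(X).R_hat
    need_threshold = any(m.endswith("_threshold") for m in methods)
    thr_structure = (
        blocks_from_threshold(R_pearson, threshold) if need_threshold else None
    )
    R_corpcor = None
    if any(m.startswith("corpcor") for m in methods):
        R_corpcor = corpcor_shrinkage(X).R_hat

    for method in methods:
        if method == "pearson_block":
            out[method] = apply_block_mask(R_pearson, truth_structure).R_hat
        elif method == "corpcor_block":
            out[method] = apply_block_mask(R_corpcor, truth_structure).R_hat
        elif method == "eb":
            out[method] = estimate(X, "groups", structure=truth_structure).R_eb
        elif method == "pearson_threshold":
            out[method] = apply_block_mask(R_pearson, thr_structure).R_hat
        elif method == "corpcor_threshold":
            out[method] = apply_block_mask(R_corpcor, thr_structure).R_hat
        elif method == "eb_threshold":
            out[method] = estimate(X, "threshold", threshold=threshold).R_eb
        elif method == "eb_aic":
            out[method] = estimate(X, "aic", aic_grid=aic_grid).R_eb
        else:
            raise ValueError(f"unknown study method {method!r}")
    return out


def run_study(config: StudyConfig = StudyConfig()) -> list[EvalReport]:
    """Run the replicate study and return one report per (method, n).

    Each replicate draws a fresh truth matrix and one sample per sample
    size; the master seed makes the whole study reproducible.
    """
    reports = {
        (m, n): EvalReport(method=m, n=n)
        for m in config.methods
        for n in config.sample_sizes
    }
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.reps)
    for rep in range(config.reps):
        truth_seed, *draw_seeds = [
            int(s.generate_state(1)[0] % (2**31)) for s in rep_seeds[rep].spawn(1 + len(config.sample_sizes))
        ]
        scenario = make_truth(
            p=config.p,
            block_sizes=config.block_sizes,
            rho_within=config.rho_within,
            epsilon_noise=config.epsilon_noise,
            seed=truth_seed,
        )
        for n, dseed in zip(config.sample_sizes, draw_seeds):
            X = draw(scenario, n, seed=dseed).X
            fits = _fit_all(
                X, scenario.structure, config.threshold, config.aic_grid, config.methods
            )
            for method, R_hat in fits.items():
                calls = significance_calls(R_hat, n, config.alpha)
                fdr, tpr = fdr_tpr(calls, scenario.Sigma_true, scenario.structure)
                reports[(method, n)].record(
                    frobenius_block=frobenius_distance(
                        R_hat, scenario.Sigma_true, "blocks", scenario.structure
                    ),
                    frobenius_full=frobenius_distance(
                        R_hat, scenario.Sigma_true, "full"
                    ),
                    fdr=fdr,
                    tpr=tpr,
                )
    return [reports[(m, n)] for m in config.methods for n in config.sample_sizes]


def summary_table(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Long-format summary: one row per (method, n, metric) with mean/sd."""
    rows = []
    for rep in reports:
        for metric in METRICS:
            rows.append(
                {
                    "method": rep.method,
                    "n": rep.n,
                    "metric": metric,
                    "mean": rep.mean(metric),
                    "sd": rep.sd(metric),
                    "reps": rep.reps,
                }
            )
    return pd.DataFrame(rows)


def replicate_table(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Long-format per-replicate values, for inspection or re-analysis."""
    rows = []
    for rep in reports:
        for metric in METRICS:
            for i, v in enumerate(rep.values[metric]):
                rows.append(
                    {
                        "method": rep.method,
                        "n": rep.n,
                        "metric": metric,
                        "replicate": i,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)
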