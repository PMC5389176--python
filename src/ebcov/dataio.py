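"""Reading expression matrices and writing estimation results.

Expression input follows the ubiquitous genes-as-rows convention: first
column gene identifiers, header row of sample identifiers, TSV or CSV.
Internally the package works samples x genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import PosteriorEstimate

__all__ = ["EdgeRecord", "read_expression", "write_expression", "write_outputs", "edge_table"]


@dataclass(frozen=True)
class EdgeRecord:
    """One significant undirected edge (gene_a < gene_b lexicographically)."""

    gene_a: str
    gene_b: str
    correlation: float
    p_value: float
    same_block: bool


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples matrix (TSV or CSV, sniffed from content).

    Returns a DataFrame indexed by gene identifier with sample columns.
    Rejects ragged rows, non-numeric cells and duplicate gene identifiers
    with errors naming the offender.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate gene identifiers: {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric or missing value at gene {bad[0]!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError("expression matrix is empty")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV (round-trips read_expression)."""
    df.to_csv(path, sep="\t", index_label="gene")


def edge_table(
    labels,
    R_hat: np.ndarray,
    pvalues: np.ndarray,
    calls: np.ndarray,
    same_block: np.ndarray,
) -> list[EdgeRecord]:
    """Significant upper-triangle pairs as deduplicated edge records."""
    labels = list(labels)
    p = len(labels)
    records = []
    for i in range(p):
        for j in range(i + 1, p):
            if not calls[i, j]:
                continue
            a, b = sorted((labels[i], labels[j]))
            records.append(
                EdgeRecord(
                    gene_a=a,
                    gene_b=b,
                    correlation=float(R_hat[i, j]),
                    p_value=float(pvalues[i, j]),
                    same_block=bool(same_block[i, j]),
                )
            )
    return records


def write_outputs(
    estimate: PosteriorEstimate,
    labels,
    pvalues: np.ndarray,
    calls: np.ndarray,
    out_dir,
    *,
    extra_params: dict | None = None,
) -> dict[str, Path]:
    """Write the estimated correlation matrix, significant-edge list and a
    fitted-parameter sidecar under ``out_dir``.

    Returns the paths written, keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = list(labels)

    matrix_path = out_dir / "correlation_eb.tsv"
    pd.DataFrame(estimate.R_eb, index=labels, columns=labels).to_csv(
        matrix_path, sep="\t", index_label="gene"
    )

    same_block = estimate.prior.structure.same_block_mask(include_diagonal=False)
    edges = edge_table(labels, estimate.R_eb, pvalues, calls, same_block)
    edges_path = out_dir / "edges.tsv"
    pd.DataFrame(
        [e.__dict__ for e in edges],
        columns=["gene_a", "gene_b", "correlation", "p_value", "same_block"],
    ).to_csv(edges_path, sep="\t", index=False)

    params = {
        "lambda": estimate.lambda_,
        "prior_weight": estimate.prior_weight,
        "n": estimate.n,
        "p": estimate.prior.structure.p,
        "n_blocks": estimate.prior.structure.n_blocks,
        "blocks": [
            [labels[i] for i in block] for block in estimate.prior.structure.blocks
        ],
        "gammas": [
            None if np.isnan(g) else g for g in estimate.prior.gammas
        ],
    }
    if estimate.threshold_scan is not None:
        params["aic_chosen_threshold"] = estimate.threshold_scan.chosen
    if extra_params:
        params.update(extra_params)
    params_path = out_dir / "parameters.json"
    params_path.write_text(json.dumps(params, indent=2))

    return {"matrix": matrix_path, "edges": edges_path, "parameters": params_path}
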