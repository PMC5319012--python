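"""Tissue-specificity scoring with the tau index.

tau = sum_i (1 - x_i / x_max) / (n - 1) for a non-negative per-tissue
expression vector x with n >= 2 tissues.  tau is 0 for perfectly uniform
expression and 1 for single-tissue (one-hot) expression, and is invariant
to rescaling of the vector.  An all-zero vector has no defined score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_model import MetaExon


class SpecificityError(ValueError):
    pass


@dataclass
class SpecificityScore:
    feature_id: str
    score: float  # NaN when undefined (all-zero expression)
    per_tissue: np.ndarray


def tau_specificity(expression) -> float:
    """Tau specificity of one feature's per-tissue expression vector.

    Returns NaN for an all-zero vector (specificity undefined).
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise SpecificityError("need a 1-d vector over >=2 tissues")
    if (x < 0).any():
        raise SpecificityError("expression values must be non-negative")
    xmax = x.max()
    if xmax == 0:
        return float("nan")
    return float((1.0 - x / xmax).sum() / (x.size - 1))


def _parse_feature_id(feature: str) -> tuple[str, int, int] | None:
    try:
        chrom, rng = feature.rsplit(":", 1)
        start, end = rng.split("-")
        return chrom, int(start), int(end)
    except ValueError:
        return None


def exon_specificity_table(
    matrix: pd.DataFrame, meta_exons: list[MetaExon]
) -> list[SpecificityScore]:
    """Score meta-exons from a tissue x exonic-part expression matrix.

    Rows are tissues; column names are feature ids of the form
    ``chrom:start-end`` mapping onto meta-exon coordinates.  Columns that
    map to no meta-exon are skipped with a warning.
    """
    by_coord = {(m.chrom, m.start, m.end): m for m in meta_exons}
    out: list[SpecificityScore] = []
    for col in matrix.columns:
        coord = _parse_feature_id(str(col))
        if coord is None or coord not in by_coord:
            warnings.warn(
                f"expression column {col!r} maps to no meta-exon; skipped",
                stacklevel=2,
            )
            continue
        values = matrix[col].to_numpy(dtype=float)
        out.append(SpecificityScore(str(col), tau_specificity(values), values))
    return out


def read_expression_matrix(path) -> pd.DataFrame:
    """Tissue x feature TSV: first column = tissue name, header row =
    feature ids ``chrom:start-end``."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_scores(scores: list[SpecificityScore], path) -> None:
    pd.DataFrame(
        {"feature": [s.feature_id for s in scores],
         "tau": [s.score for s in scores]}
    ).to_csv(path, sep="\t", index=False)
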