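"""Per-sample size factors and depth adjustment.

Library-size differences between samples are corrected with a
median-of-ratios estimator computed on per-meta-exon coverage sums: the
reference profile is the per-region geometric mean across samples
(regions containing any zero are excluded), each sample's factor is the
median over regions of its summary divided by the reference, and the
factors are rescaled to geometric mean 1 so they are identifiable.
Counts and coverage are *divided* by the factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .gene_model import GeneModel, MetaExon, build_meta_exons
from .track_io import CoverageSet


class NormalizationError(ValueError):
    pass


@dataclass
class SizeFactors:
    samples: list[str]
    factors: np.ndarray
    method: str  # median_ratio | user_supplied

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise NormalizationError("size factors must be positive")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.samples, self.factors.tolist()))


def estimate_size_factors(
    summaries: np.ndarray, samples: Sequence[str] | None = None
) -> SizeFactors:
    """Median-of-ratios size factors from a region x sample summary matrix.

    Raises if fewer than 2 regions have all-positive values (the message
    suggests supplying user factors instead).
    """
    summaries = np.asarray(summaries, dtype=float)
    if summaries.ndim != 2 or summaries.shape[1] < 2:
        raise NormalizationError("need a region x sample matrix with >=2 samples")
    positive = (summaries > 0).all(axis=1)
    if positive.sum() < 2:
        raise NormalizationError(
            "fewer than 2 regions with positive coverage in all samples; "
            "size factors cannot be estimated — supply user size factors "
            "in the project file instead"
        )
    usable = summaries[positive]
    log_ref = np.log(usable).mean(axis=1)  # per-region geometric mean (log)
    log_factors = np.median(np.log(usable) - log_ref[:, None], axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    factors = np.exp(log_factors)
    if samples is None:
        samples = [f"sample_{i}" for i in range(summaries.shape[1])]
    return SizeFactors(list(samples), factors, "median_ratio")


def adjust(values: np.ndarray, factors: np.ndarray | SizeFactors) -> np.ndarray:
    """Divide each sample column (last axis) by its size factor."""
    if isinstance(factors, SizeFactors):
        factors = factors.factors
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise NormalizationError("size factors must be positive")
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != factors.shape[0]:
        raise NormalizationError(
            f"need one factor per sample column: {values.shape[-1]} columns, "
            f"{factors.shape[0]} factors"
        )
    return values / factors


def meta_exon_summaries(
    coverage: CoverageSet, meta_exons: Iterable[MetaExon]
) -> np.ndarray:
    """Per-meta-exon raw coverage sums, region x sample."""
    rows = []
    for me in meta_exons:
        lo = max(me.start, coverage.start) - coverage.start
        hi = min(me.end, coverage.end) - coverage.start
        if lo >= hi:
            continue
        rows.append(coverage.matrix[:, lo:hi].sum(axis=1))
    if not rows:
        raise NormalizationError("no meta-exon overlaps the coverage span")
    return np.vstack(rows)


def size_factors_from_genes(
    coverages: Sequence[CoverageSet], genes: Sequence[GeneModel]
) -> SizeFactors:
    """Convenience: pool per-meta-exon summaries over several gene loci."""
    blocks = [
        meta_exon_summaries(cov, build_meta_exons(gene))
        for cov, gene in zip(coverages, genes)
    ]
    samples = coverages[0].samples
    return estimate_size_factors(np.vstack(blocks), samples)
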