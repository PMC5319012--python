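"""Static rendering of the viewer's core visuals.

Three plot families, written as SVG or PNG:

* coverage — one center line (mean or median) per condition with a
  shaded band from the 25th to the 75th percentile across that
  condition's samples; optional log2(x+1) transform;
* ratio — the per-base two-condition coverage ratio r(p); constitutive
  exons sit flat near 0.5 and alternatively spliced regions bulge away;
* isoforms — one row per selected transcript, a meta-exon track with
  candidate exons highlighted in red, and sense/antisense overlap tracks
  color-coded orange/red (antisense non-exonic/exonic) and light/dark
  blue (sense non-exonic/exonic).

Introns are compressed to a fixed plot width by default so exons stay
readable.  Rendering is pure: the SVG output is byte-stable for
identical inputs (hash salt pinned, no timestamps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .event_detection import SpliceEventCandidate, coverage_ratio, exon_groups
from .gene_model import GeneModel, MetaExon, OverlapAnnotation, build_meta_exons
from .track_io import CoverageSet


class PlotError(ValueError):
    pass


INTRON_PLOT_WIDTH = 60  # plot units per compressed intron

OVERLAP_COLORS = {
    ("antisense", "non_exonic"): "orange",
    ("antisense", "exonic"): "red",
    ("sense", "non_exonic"): "lightblue",
    ("sense", "exonic"): "darkblue",
}

DEFAULT_CONDITION_COLORS = ["#1f77b4", "#d62728", "#2ca02c", "#9467bd"]


@dataclass
class PlotSpec:
    mode: str = "coverage"  # coverage | log2_coverage | ratio
    center: str = "mean"  # mean | median
    samples: list[str] | None = None  # None = all
    transcripts: list[str] | None = None  # None = all
    colors: dict[str, str] | None = None  # condition -> color
    introns: str = "compressed"  # compressed | to_scale
    figsize: tuple[float, float] = (10.0, 3.0)

    def __post_init__(self):
        if self.mode not in {"coverage", "log2_coverage", "ratio"}:
            raise PlotError(f"unknown plot mode {self.mode!r}")
        if self.center not in {"mean", "median"}:
            raise PlotError(f"unknown center statistic {self.center!r}")
        if self.introns not in {"compressed", "to_scale"}:
            raise PlotError(f"unknown intron display {self.introns!r}")


def _pin_determinism() -> None:
    plt.rcParams["svg.hashsalt"] = "aseview"
    plt.rcParams["path.simplify"] = False


def _save(fig, path: str | Path) -> None:
    path = Path(path)
    _pin_determinism()
    if path.suffix.lower() == ".svg":
        fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)
    plt.close(fig)


def genomic_axis(
    span: tuple[int, int],
    meta_exons: Sequence[MetaExon],
    introns: str = "compressed",
) -> np.ndarray:
    """Plot-x coordinate for every base of the span.

    In compressed mode every exonic base occupies one unit while each
    maximal non-exonic run is squeezed into INTRON_PLOT_WIDTH units.
    """
    start, end = span
    n = end - start
    if introns == "to_scale":
        return np.arange(n, dtype=float)
    exonic = np.zeros(n, dtype=bool)
    for me in meta_exons:
        lo, hi = max(me.start, start) - start, min(me.end, end) - start
        if lo < hi:
            exonic[lo:hi] = True
    widths = np.ones(n)
    i = 0
    while i < n:
        if not exonic[i]:
            j = i
            while j < n and not exonic[j]:
                j += 1
            widths[i:j] = INTRON_PLOT_WIDTH / (j - i)
            i = j
        else:
            i += 1
    return np.cumsum(widths) - widths


def condition_band(block: np.ndarray, center: str = "mean"):
    """Center line and 25th/75th percentile band across samples (axis 0).

    Percentiles use the linear-interpolation convention, pinned so that
    rendered output is reproducible.
    """
    c = (np.mean(block, axis=0) if center == "mean"
         else np.median(block, axis=0))
    q25 = np.percentile(block, 25, axis=0, method="linear")
    q75 = np.percentile(block, 75, axis=0, method="linear")
    return c, q25, q75


def _condition_colors(conditions: Sequence[str],
                      colors: dict[str, str] | None) -> dict[str, str]:
    uniq = list(dict.fromkeys(conditions))
    out = {}
    for i, c in enumerate(uniq):
        out[c] = (colors or {}).get(
            c, DEFAULT_CONDITION_COLORS[i % len(DEFAULT_CONDITION_COLORS)]
        )
    return out


def _subset(coverage: CoverageSet, spec: PlotSpec) -> CoverageSet:
    if spec.samples is None:
        return coverage
    rows = [i for i, s in enumerate(coverage.samples) if s in spec.samples]
    if not rows:
        raise PlotError("sample selection matches no sample")
    return CoverageSet(
        coverage.chrom, coverage.start, coverage.end,
        [coverage.samples[i] for i in rows],
        [coverage.conditions[i] for i in rows],
        coverage.matrix[rows],
        (np.asarray(coverage.size_factors)[rows]
         if coverage.size_factors is not None else None),
    )


def render_coverage(
    coverage: CoverageSet,
    spec: PlotSpec,
    meta_exons: Sequence[MetaExon] = (),
    path: str | Path = "coverage.svg",
) -> Path:
    """Per-condition coverage with 25th-75th percentile bands."""
    cov = _subset(coverage, spec)
    values = cov.adjusted()
    if spec.mode == "log2_coverage":
        values = np.log2(values + 1.0)
    x = genomic_axis((cov.start, cov.end), meta_exons, spec.introns)
    colors = _condition_colors(cov.conditions, spec.colors)
    fig, ax = plt.subplots(figsize=spec.figsize)
    for cond, color in colors.items():
        rows = cov.condition_samples(cond)
        center, q25, q75 = condition_band(values[rows], spec.center)
        ax.fill_between(x, q25, q75, color=color, alpha=0.25, linewidth=0)
        ax.plot(x, center, color=color,
                label=f"{cond} (n={len(rows)}, {spec.center})")
    ax.set_xlabel(f"{cov.chrom}:{cov.start}-{cov.end} ({spec.introns} introns)")
    ax.set_ylabel("log2(coverage+1)" if spec.mode == "log2_coverage"
                  else "adjusted coverage")
    ax.legend(loc="upper right", fontsize=8)
    _save(fig, path)
    return Path(path)


def render_ratio(
    coverage: CoverageSet,
    spec: PlotSpec,
    meta_exons: Sequence[MetaExon] = (),
    path: str | Path = "ratio.svg",
) -> Path:
    """Per-base condition coverage ratio; undefined bases are gaps."""
    cov = _subset(coverage, spec)
    conds = list(dict.fromkeys(cov.conditions))
    if len(conds) != 2:
        raise PlotError(
            f"ratio plot needs exactly 2 conditions, got {len(conds)}"
        )
    r = coverage_ratio(cov, (conds[0], conds[1]))
    x = genomic_axis((cov.start, cov.end), meta_exons, spec.introns)
    colors = _condition_colors(cov.conditions, spec.colors)
    fig, ax = plt.subplots(figsize=spec.figsize)
    ax.plot(x, r, color=colors[conds[0]],
            label=f"{conds[0]} / ({conds[0]}+{conds[1]})")
    ax.axhline(0.5, color="gray", linewidth=0.7, linestyle="--")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(f"{cov.chrom}:{cov.start}-{cov.end} ({spec.introns} introns)")
    ax.set_ylabel("coverage ratio r(p)")
    ax.legend(loc="upper right", fontsize=8)
    _save(fig, path)
    return Path(path)


def render_isoforms(
    gene: GeneModel,
    spec: PlotSpec,
    candidates: Sequence[SpliceEventCandidate] = (),
    overlaps: Sequence[OverlapAnnotation] = (),
    path: str | Path = "isoforms.svg",
) -> Path:
    """Transcript rows plus meta-exon and overlap tracks.

    Meta-exons belonging to exon-skipping candidates supported by both
    evidence paths are drawn red; overlap glyphs follow the viewer's
    orange/red (antisense) and light/dark blue (sense) code.
    """
    selection = spec.transcripts or [t.id for t in gene.transcripts]
    transcripts = [t for t in gene.transcripts if t.id in selection]
    if not transcripts:
        raise PlotError("transcript selection matches no transcript")
    metas = build_meta_exons(gene)
    highlighted = {
        (c.meta_exon.start, c.meta_exon.end)
        for c in candidates
        if c.event_type == "exon_skipping" and c.support_class == "both"
    }
    span = gene.span
    x = genomic_axis(span, metas, spec.introns)

    def xpos(g: int) -> float:
        g = min(max(g, span[0]), span[1] - 1)
        return float(x[g - span[0]])

    n_rows = len(transcripts) + 3  # + meta track + AS + S overlap tracks
    fig, ax = plt.subplots(figsize=(spec.figsize[0], 0.45 * n_rows + 0.8))
    y = n_rows - 1

    for orientation, label in (("antisense", "AS transcripts"),
                               ("sense", "S transcripts")):
        for ov in overlaps:
            if ov.orientation != orientation:
                continue
            color = OVERLAP_COLORS[(ov.orientation, ov.overlap_kind)]
            ax.barh(y, xpos(ov.interval[1]) - xpos(ov.interval[0]),
                    left=xpos(ov.interval[0]), height=0.5, color=color)
        ax.text(-0.01, y, label, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=7)
        y -= 1

    for me in metas:
        color = ("red" if (me.start, me.end) in highlighted or me.highlight
                 else "0.6")
        ax.barh(y, xpos(me.end) - xpos(me.start), left=xpos(me.start),
                height=0.5, color=color)
    arrow = "→" if gene.strand == "+" else "←"
    ax.text(-0.01, y, f"meta exons {arrow}",
            transform=ax.get_yaxis_transform(), ha="right", va="center",
            fontsize=7)
    y -= 1

    for tx in transcripts:
        ax.plot([xpos(tx.start), xpos(tx.end)], [y, y],
                color="black", linewidth=0.8, zorder=1)
        for exon in tx.exons:
            ax.barh(y, xpos(exon.end) - xpos(exon.start),
                    left=xpos(exon.start), height=0.5, color="#444466",
                    zorder=2)
        label = tx.id + (" (incomplete)" if tx.is_incomplete else "")
        ax.text(-0.01, y, label, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=7)
        y -= 1

    ax.set_ylim(-0.5, n_rows - 0.5)
    ax.set_yticks([])
    ax.set_xlabel(
        f"{gene.chrom}:{span[0]}-{span[1]} ({gene.strand}) "
        f"({spec.introns} introns)"
    )
    fig.subplots_adjust(left=0.2)
    _save(fig, path)
    return Path(path)
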