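"""Alternative-splicing event detection from junction pairs and coverage.

The caller works per gene and per unordered pair of conditions.  For each
meta-exon it follows two independent evidence paths:

* **PSI path** — every (inclusion, exclusion) junction combination is
  scored; the inclusion junction abuts the meta-exon, the exclusion
  junction's intron spans it entirely.  Per sample,
  ``PSI = incl / (incl + excl)`` on size-factor-adjusted counts
  (undefined when the denominator is 0).  The pair with the largest
  between-condition mean-PSI difference is kept and a Welch t-test on the
  per-sample PSI values provides the p-value.  If that best pair uses an
  unannotated junction, the best pair restricted to known junctions is
  reported alongside.
* **Ratio path** — at each base p, ``r(p) = m_A(p) / (m_A(p) + m_B(p))``
  where ``m_c`` is the condition's mean adjusted coverage (undefined
  where the denominator is 0).  The per-base ratios over the target exon
  group are Welch-tested against the per-group mean ratios of the
  remaining groups.

A candidate is emitted when either path passes its thresholds; its
support class records which.  Exon-skipping candidates supported by both
paths get their meta-exon highlighted, mirroring the viewer's red
meta-exon track.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import ExonGroup, GeneModel, MetaExon, build_meta_exons
from .track_io import CoverageSet, Junction, JunctionTable


@dataclass
class DetectionConfig:
    """Thresholds of the caller; single source of truth for CLI defaults."""

    p_threshold: float = 0.05
    delta_psi_threshold: float = 0.1
    delta_ratio_threshold: float = 0.1
    min_depth: float = 5.0
    min_frac: float = 0.7
    novel_flank: int = 50
    raw_junction_psi: bool = False  # PSI on raw instead of adjusted counts


@dataclass
class JunctionPair:
    inclusion: Junction
    exclusion: Junction
    target_meta_exon: MetaExon
    uses_novel: bool

    @property
    def sort_coords(self) -> tuple[int, int, int, int]:
        return (self.inclusion.donor_end, self.inclusion.acceptor_start,
                self.exclusion.donor_end, self.exclusion.acceptor_start)


@dataclass
class PsiResult:
    conditions: tuple[str, str]
    psi: np.ndarray  # per sample, NaN where undefined
    mean_a: float
    mean_b: float
    p_value: float  # NaN when untestable

    @property
    def delta_psi(self) -> float:
        if math.isnan(self.mean_a) or math.isnan(self.mean_b):
            return float("nan")
        return abs(self.mean_a - self.mean_b)

    @property
    def signed_delta(self) -> float:
        return self.mean_a - self.mean_b


@dataclass
class RatioResult:
    conditions: tuple[str, str]
    target_mean: float
    background_mean: float
    p_value: float
    testable: bool

    @property
    def delta_ratio(self) -> float:
        if not self.testable:
            return float("nan")
        return abs(self.target_mean - self.background_mean)


@dataclass
class SpliceEventCandidate:
    gene_id: str
    meta_exon: MetaExon
    conditions: tuple[str, str]
    best_pair: JunctionPair | None
    best_known_pair: JunctionPair | None
    psi: PsiResult | None
    ratio: RatioResult | None
    support_class: str  # psi_only | ratio_only | both
    event_type: str  # exon_skipping | alt_donor | alt_acceptor | other

    @property
    def min_p(self) -> float:
        ps = []
        if self.psi is not None and not math.isnan(self.psi.p_value):
            ps.append(self.psi.p_value)
        if self.ratio is not None and self.ratio.testable:
            ps.append(self.ratio.p_value)
        return min(ps) if ps else float("nan")


# ---------------------------------------------------------------------------
# statistics helpers


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t-test p-value with a zero-variance guard.

    When both groups are constant, the test statistic is undefined; we
    return 1.0 for equal means (no evidence of change) and 0.0 otherwise
    (the change is certain given the data).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # near-constant groups trigger a precision warning; the
        # zero-variance guard above handles the truly degenerate case
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p)


# ---------------------------------------------------------------------------
# isoform pre-selection


def select_isoforms(
    gene: GeneModel,
    coverage: CoverageSet,
    min_depth: float = 5.0,
    min_frac: float = 0.7,
) -> set[str]:
    """Discard isoforms containing exons with insufficient coverage.

    A transcript is retained iff every one of its exons has, in at least
    one condition, a fraction >= ``min_frac`` of bases whose mean adjusted
    coverage is >= ``min_depth``.  If every transcript fails, the
    best-scoring one is kept so downstream steps always have a scaffold.
    """
    cond_means = {
        c: coverage.condition_mean(c) for c in dict.fromkeys(coverage.conditions)
    }
    scores: dict[str, float] = {}
    selected: set[str] = set()
    for tx in gene.transcripts:
        worst = 1.0
        for exon in tx.exons:
            lo = max(exon.start, coverage.start) - coverage.start
            hi = min(exon.end, coverage.end) - coverage.start
            if lo >= hi:
                worst = 0.0
                continue
            best_frac = max(
                float((m[lo:hi] >= min_depth).mean()) for m in cond_means.values()
            )
            worst = min(worst, best_frac)
        scores[tx.id] = worst
        if worst >= min_frac:
            selected.add(tx.id)
    if not selected and scores:
        best = max(sorted(scores), key=lambda t: scores[t])
        selected = {best}
    return selected


def exon_groups(gene: GeneModel, selected: set[str]) -> list[ExonGroup]:
    """One exon group per meta-exon of the selected isoforms."""
    transcripts = [t for t in gene.transcripts if t.id in selected]
    metas = build_meta_exons(transcripts)
    return [ExonGroup(m, (m.start, m.end)) for m in metas]


# ---------------------------------------------------------------------------
# PSI path


def enumerate_pairs(
    table: JunctionTable, meta_exon: MetaExon
) -> list[JunctionPair]:
    """All inclusion/exclusion junction combinations for a meta-exon.

    Inclusion junctions land on the meta-exon boundary (acceptor at its
    start or donor at its end); exclusion junction introns strictly
    contain the meta-exon.  ``uses_novel`` flags pairs with an
    unannotated member.
    """
    s, e = meta_exon.start, meta_exon.end
    inclusion = [
        j for j in table.junctions
        if j.chrom == meta_exon.chrom
        and (j.acceptor_start == s or j.donor_end == e)
    ]
    exclusion = [
        j for j in table.junctions
        if j.chrom == meta_exon.chrom
        and j.donor_end <= s and j.acceptor_start >= e
        and (j.donor_end < s or j.acceptor_start > e)
    ]
    pairs = [
        JunctionPair(i, x, meta_exon, uses_novel=not (i.known and x.known))
        for i in inclusion
        for x in exclusion
    ]
    pairs.sort(key=lambda p: p.sort_coords)
    return pairs


def score_pair(
    pair: JunctionPair,
    table: JunctionTable,
    size_factors: np.ndarray | None,
    sample_conditions: Sequence[str],
    cond_pair: tuple[str, str],
    raw: bool = False,
) -> PsiResult:
    """Per-sample PSI and Welch t-test for one junction pair.

    PSI is undefined for a sample whose adjusted inclusion + exclusion
    count is 0; undefined samples are excluded from means and the test,
    and the p-value is undefined with <2 defined samples in either
    condition.
    """
    incl = table.row(pair.inclusion).astype(float)
    excl = table.row(pair.exclusion).astype(float)
    if size_factors is not None and not raw:
        incl = incl / size_factors
        excl = excl / size_factors
    denom = incl + excl
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, incl / denom, np.nan)
    groups = []
    for cond in cond_pair:
        mask = np.array([c == cond for c in sample_conditions])
        vals = psi[mask]
        groups.append(vals[~np.isnan(vals)])
    mean_a = float(groups[0].mean()) if groups[0].size else float("nan")
    mean_b = float(groups[1].mean()) if groups[1].size else float("nan")
    p = _welch(groups[0], groups[1])
    return PsiResult(cond_pair, psi, mean_a, mean_b, p)


def best_pair(
    scored: Sequence[tuple[JunctionPair, PsiResult]],
    table: JunctionTable,
    size_factors: np.ndarray | None = None,
) -> tuple[tuple[JunctionPair, PsiResult] | None,
           tuple[JunctionPair, PsiResult] | None]:
    """The pair with the largest delta PSI, plus the known-only fallback.

    Ties break on larger total adjusted count, then lexicographically
    smallest junction coordinates.  The fallback (best pair among fully
    annotated junctions) is returned only when the overall best uses a
    novel junction.
    """
    def total_count(pair: JunctionPair) -> float:
        c = table.row(pair.inclusion) + table.row(pair.exclusion)
        if size_factors is not None:
            c = c / size_factors
        return float(c.sum())

    defined = [(p, r) for p, r in scored if not math.isnan(r.delta_psi)]
    if not defined:
        return None, None

    def key(item):
        pair, res = item
        return (-res.delta_psi, -total_count(pair), pair.sort_coords)

    best = min(defined, key=key)
    best_known = None
    if best[0].uses_novel:
        known = [(p, r) for p, r in defined if not p.uses_novel]
        if known:
            best_known = min(known, key=key)
    return best, best_known


# ---------------------------------------------------------------------------
# ratio path


def coverage_ratio(
    coverage: CoverageSet, cond_pair: tuple[str, str]
) -> np.ndarray:
    """Per-base r(p) = m_A / (m_A + m_B); NaN where both conditions are 0."""
    m_a = coverage.condition_mean(cond_pair[0])
    m_b = coverage.condition_mean(cond_pair[1])
    denom = m_a + m_b
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, m_a / denom, np.nan)


def ratio_test(
    coverage: CoverageSet,
    groups: Sequence[ExonGroup],
    target_index: int,
    cond_pair: tuple[str, str],
) -> RatioResult:
    """Test the target group's per-base coverage ratios against the
    per-group mean ratios of the remaining groups (Welch t-test).

    Untestable when fewer than 2 remaining groups have defined ratios or
    the target has fewer than 2 defined bases.
    """
    r = coverage_ratio(coverage, cond_pair)

    def group_values(g: ExonGroup) -> np.ndarray:
        lo = max(g.positions[0], coverage.start) - coverage.start
        hi = min(g.positions[1], coverage.end) - coverage.start
        vals = r[lo:hi] if lo < hi else np.empty(0)
        return vals[~np.isnan(vals)]

    target_vals = group_values(groups[target_index])
    background = []
    for i, g in enumerate(groups):
        if i == target_index:
            continue
        vals = group_values(g)
        if vals.size:
            background.append(float(vals.mean()))
    if target_vals.size < 2 or len(background) < 2:
        return RatioResult(cond_pair, float("nan"), float("nan"),
                           float("nan"), testable=False)
    bg = np.asarray(background)
    p = _welch(target_vals, bg)
    return RatioResult(cond_pair, float(target_vals.mean()),
                       float(bg.mean()), p, testable=True)


# ---------------------------------------------------------------------------
# classification


def classify_event(
    pair: JunctionPair,
    meta_exons: Sequence[MetaExon],
    strand: str,
) -> str:
    """Classify a junction pair as exon_skipping / alt_donor /
    alt_acceptor / other.

    Exon skipping: both junctions share the anchor away from the target
    meta-exon, the inclusion junction lands on the target, and the
    exclusion intron skips exactly the target (no other meta-exon
    inside).  Alternative donor/acceptor: the junctions share one splice
    site and differ at the other, with the donor side oriented by strand
    (on ``+`` the genomic-left end of an intron is the donor).
    """
    incl, excl = pair.inclusion, pair.exclusion
    target = pair.target_meta_exon
    others_inside = any(
        m.start < excl.acceptor_start and m.end > excl.donor_end
        and (m.start, m.end) != (target.start, target.end)
        for m in meta_exons
    )
    upstream_side = (incl.acceptor_start == target.start
                     and incl.donor_end == excl.donor_end)
    downstream_side = (incl.donor_end == target.end
                       and incl.acceptor_start == excl.acceptor_start)
    if (upstream_side or downstream_side) and not others_inside:
        # exclusion spans only the target, inclusion abuts it: cassette
        return "exon_skipping"
    shares_left = incl.donor_end == excl.donor_end
    shares_right = incl.acceptor_start == excl.acceptor_start
    if shares_left != shares_right:  # exactly one shared splice site
        if shares_right:  # differ at genomic-left end
            return "alt_donor" if strand == "+" else "alt_acceptor"
        return "alt_acceptor" if strand == "+" else "alt_donor"
    return "other"


# ---------------------------------------------------------------------------
# driver


def detect_events(
    gene: GeneModel,
    table: JunctionTable,
    coverage: CoverageSet,
    config: DetectionConfig | None = None,
) -> list[SpliceEventCandidate]:
    """Run both evidence paths over every meta-exon and condition pair.

    Candidates are sorted by their smallest p-value; exon-skipping
    candidates supported by both paths have ``meta_exon.highlight`` set.
    Deterministic given its inputs.
    """
    config = config or DetectionConfig()
    selected = select_isoforms(gene, coverage, config.min_depth, config.min_frac)
    groups = exon_groups(gene, selected)
    metas = [g.meta_exon for g in groups]
    conds = list(dict.fromkeys(coverage.conditions))
    factors = (np.asarray(coverage.size_factors)
               if coverage.size_factors is not None else None)
    candidates: list[SpliceEventCandidate] = []
    for cond_pair in itertools.combinations(conds, 2):
        for gi, group in enumerate(groups):
            me = group.meta_exon
            pairs = enumerate_pairs(table, me)
            scored = [
                (p, score_pair(p, table, factors, coverage.conditions,
                               cond_pair, raw=config.raw_junction_psi))
                for p in pairs
            ]
            best, best_known = best_pair(scored, table, factors)
            psi_res = best[1] if best else None
            psi_pass = (
                psi_res is not None
                and not math.isnan(psi_res.p_value)
                and psi_res.p_value <= config.p_threshold
                and psi_res.delta_psi >= config.delta_psi_threshold
            )
            ratio_res = ratio_test(coverage, groups, gi, cond_pair)
            ratio_pass = (
                ratio_res.testable
                and not math.isnan(ratio_res.p_value)
                and ratio_res.p_value <= config.p_threshold
                and ratio_res.delta_ratio >= config.delta_ratio_threshold
            )
            if not (psi_pass or ratio_pass):
                continue
            support = ("both" if psi_pass and ratio_pass
                       else "psi_only" if psi_pass else "ratio_only")
            event_type = (classify_event(best[0], metas, gene.strand)
                          if best else "other")
            if support == "both" and event_type == "exon_skipping":
                me.highlight = True
            candidates.append(
                SpliceEventCandidate(
                    gene.gene_id, me, cond_pair,
                    best[0] if best else None,
                    best_known[0] if best_known else None,
                    psi_res, ratio_res, support, event_type,
                )
            )
    candidates.sort(
        key=lambda c: (
            math.inf if math.isnan(c.min_p) else c.min_p,
            c.meta_exon.start, c.conditions,
        )
    )
    return candidates


# ---------------------------------------------------------------------------
# result table


def _fmt_junction(j: Junction | None) -> str:
    if j is None:
        return ""
    return f"{j.chrom}:{j.donor_end}-{j.acceptor_start}"


def results_to_frame(
    candidates: Sequence[SpliceEventCandidate], samples: Sequence[str]
) -> pd.DataFrame:
    """Flatten candidates into the result table (one row per candidate).

    A Benjamini-Hochberg column over the PSI p-values is included for
    convenience; it is informational only and never used for filtering.
    """
    rows = []
    for c in candidates:
        row: dict = {
            "gene": c.gene_id,
            "chrom": c.meta_exon.chrom,
            "meta_exon_start": c.meta_exon.start,
            "meta_exon_end": c.meta_exon.end,
            "event_type": c.event_type,
            "condition_A": c.conditions[0],
            "condition_B": c.conditions[1],
            "incl_junction": _fmt_junction(c.best_pair.inclusion if c.best_pair else None),
            "excl_junction": _fmt_junction(c.best_pair.exclusion if c.best_pair else None),
            "known_only_pair": (
                _fmt_junction(c.best_known_pair.inclusion) + "|"
                + _fmt_junction(c.best_known_pair.exclusion)
                if c.best_known_pair else ""
            ),
        }
        for i, s in enumerate(samples):
            row[f"psi_{s}"] = (float(c.psi.psi[i])
                               if c.psi is not None else float("nan"))
        row.update(
            {
                "mean_psi_A": c.psi.mean_a if c.psi else float("nan"),
                "mean_psi_B": c.psi.mean_b if c.psi else float("nan"),
                "delta_psi": c.psi.delta_psi if c.psi else float("nan"),
                "psi_pvalue": c.psi.p_value if c.psi else float("nan"),
                "delta_ratio": c.ratio.delta_ratio if c.ratio else float("nan"),
                "ratio_pvalue": c.ratio.p_value if c.ratio else float("nan"),
                "support_class": c.support_class,
                "highlight": c.meta_exon.highlight,
            }
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        p = df["psi_pvalue"].to_numpy(dtype=float)
        df["psi_pvalue_bh"] = _benjamini_hochberg(p)
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values; NaNs pass through."""
    adj = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    m = ok.sum()
    if m == 0:
        return adj
    order = np.argsort(p[ok])
    ranked = p[ok][order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    adj[ok] = vals
    return adj


def write_results(
    candidates: Sequence[SpliceEventCandidate],
    samples: Sequence[str],
    path,
) -> None:
    results_to_frame(candidates, samples).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
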