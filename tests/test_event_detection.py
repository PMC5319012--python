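import itertools
import math

import numpy as np
import pytest

from aseview.event_detection import (
    DetectionConfig,
    best_pair,
    classify_event,
    coverage_ratio,
    detect_events,
    enumerate_pairs,
    exon_groups,
    ratio_test,
    results_to_frame,
    score_pair,
    select_isoforms,
)
from aseview.gene_model import GeneModel, MetaExon, build_meta_exons
from aseview.track_io import CoverageSet, Junction, merge_junction_tables

from conftest import make_transcript


def table_of(entries_per_sample):
    """entries_per_sample: list of (sample, {Junction: count})."""
    return merge_junction_tables(
        [(s, list(d.items())) for s, d in entries_per_sample]
    )


def coverage_of(gene, matrix, conditions, factors=None):
    samples = [f"s{i}" for i in range(len(matrix))]
    return CoverageSet(gene.chrom, gene.start, gene.end, samples,
                       conditions, np.asarray(matrix, float), factors)


# ---------------------------------------------------------------------------
# isoform pre-selection


def _flat_coverage(gene, level_by_interval, n_samples=4):
    length = gene.end - gene.start
    row = np.zeros(length)
    for (s, e), level in level_by_interval.items():
        row[s - gene.start:e - gene.start] = level
    return np.tile(row, (n_samples, 1))


def test_transcript_with_uncovered_exon_discarded(cassette_gene):
    cov = coverage_of(
        cassette_gene,
        _flat_coverage(cassette_gene,
                       {(1000, 1100): 50, (1400, 1500): 50}),  # cassette at 0
        ["A", "A", "B", "B"],
    )
    assert select_isoforms(cassette_gene, cov) == {"tx_out"}


def test_uniformly_covered_transcripts_retained(cassette_gene):
    cov = coverage_of(
        cassette_gene,
        _flat_coverage(cassette_gene, {(1000, 1500): 50}),
        ["A", "A", "B", "B"],
    )
    assert select_isoforms(cassette_gene, cov) == {"tx_in", "tx_out"}


def test_one_condition_suffices_for_retention(cassette_gene):
    # cassette exon covered in condition A only
    length = cassette_gene.end - cassette_gene.start
    base = _flat_coverage(cassette_gene,
                          {(1000, 1100): 50, (1400, 1500): 50}, 4)
    base[:2, 200:300] = 50  # A samples cover the cassette exon [1200,1300)
    cov = coverage_of(cassette_gene, base, ["A", "A", "B", "B"])
    assert select_isoforms(cassette_gene, cov) == {"tx_in", "tx_out"}


def test_all_failing_keeps_best_scoring(cassette_gene):
    cov = coverage_of(cassette_gene,
                      np.zeros((4, cassette_gene.end - cassette_gene.start)),
                      ["A", "A", "B", "B"])
    got = select_isoforms(cassette_gene, cov)
    assert len(got) == 1


def test_unexpressed_isoform_removed_but_junctions_unchanged(cassette_gene,
                                                             cassette_junctions):
    """With the inclusion isoform unexpressed, only the skipping isoform
    is selected, and pair enumeration on the junction table is unaffected."""
    incl_up, incl_down, excl = cassette_junctions
    cov = coverage_of(
        cassette_gene,
        _flat_coverage(cassette_gene,
                       {(1000, 1100): 80, (1400, 1500): 80}),
        ["A", "A", "B", "B"],
    )
    assert select_isoforms(cassette_gene, cov) == {"tx_out"}
    table = table_of(
        [("s0", {incl_up: 5, excl: 90}), ("s1", {incl_up: 4, excl: 80}),
         ("s2", {incl_up: 6, excl: 85}), ("s3", {incl_up: 5, excl: 88})]
    )
    cassette_meta = MetaExon("chr1", 1200, 1300)
    pairs = enumerate_pairs(table, cassette_meta)
    assert [(p.inclusion.intron, p.exclusion.intron) for p in pairs] == \
        [((1100, 1200), (1100, 1400))]


# ---------------------------------------------------------------------------
# pair enumeration


def test_cassette_has_two_inclusion_one_exclusion(cassette_gene,
                                                  cassette_junctions):
    incl_up, incl_down, excl = cassette_junctions
    table = table_of([("s", {incl_up: 1, incl_down: 2, excl: 3})])
    (meta,) = [m for m in build_meta_exons(cassette_gene)
               if (m.start, m.end) == (1200, 1300)]
    pairs = enumerate_pairs(table, meta)
    assert len(pairs) == 2
    assert {p.inclusion.intron for p in pairs} == {(1100, 1200), (1300, 1400)}
    assert all(p.exclusion.intron == (1100, 1400) for p in pairs)


def test_exon_without_spanning_junction_has_no_pairs(cassette_junctions):
    incl_up, incl_down, _ = cassette_junctions
    table = table_of([("s", {incl_up: 1, incl_down: 2})])
    assert enumerate_pairs(table, MetaExon("chr1", 1200, 1300)) == []


def test_enumerate_pairs_matches_brute_force(rng):
    """Random junction sets vs an exhaustive loop over all ordered pairs."""
    for _ in range(30):
        meta = MetaExon("chr1", 500, 600)
        junctions = {}
        for _ in range(int(rng.integers(2, 15))):
            d = int(rng.integers(0, 12)) * 50 + 300
            a = d + 50 + int(rng.integers(0, 8)) * 50
            if d < a:
                try:
                    junctions[Junction("chr1", d, a)] = 1
                except Exception:
                    pass
        table = table_of([("s", junctions)])
        got = {(p.inclusion.intron, p.exclusion.intron)
               for p in enumerate_pairs(table, meta)}
        expected = set()
        for i in table.junctions:
            for x in table.junctions:
                abuts = i.acceptor_start == 500 or i.donor_end == 600
                spans = (x.donor_end <= 500 and x.acceptor_start >= 600
                         and (x.donor_end, x.acceptor_start) != (500, 600))
                if abuts and spans:
                    expected.add((i.intron, x.intron))
        assert got == expected


# ---------------------------------------------------------------------------
# PSI scoring


def _score(incl_counts, excl_counts, conditions, factors=None, raw=False):
    from aseview.event_detection import JunctionPair
    from aseview.track_io import JunctionTable

    j_in = Junction("chr1", 100, 200, known=True)
    j_ex = Junction("chr1", 100, 400, known=True)
    samples = [f"s{i}" for i in range(len(incl_counts))]
    table = JunctionTable([j_in, j_ex],
                          np.array([incl_counts, excl_counts], float),
                          samples)
    pair = JunctionPair(j_in, j_ex, MetaExon("chr1", 200, 300),
                        uses_novel=False)
    return score_pair(pair, table, factors, conditions, ("A", "B"), raw=raw)


def test_symmetric_counts_give_flat_psi():
    res = _score([50] * 6, [50] * 6, ["A"] * 3 + ["B"] * 3)
    np.testing.assert_allclose(res.psi, 0.5)
    assert res.delta_psi == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_zero_inclusion_gives_psi_zero():
    res = _score([0] * 4, [10, 20, 30, 40], ["A", "A", "B", "B"])
    np.testing.assert_allclose(res.psi, 0.0)


def test_zero_denominator_is_undefined_not_zero():
    res = _score([0, 5, 5, 5], [0, 5, 5, 5], ["A", "A", "B", "B"])
    assert math.isnan(res.psi[0])
    assert not math.isnan(res.mean_b)
    # <2 defined samples in condition A -> p undefined
    assert math.isnan(res.p_value)


def test_psi_role_swap_symmetry(rng):
    incl = rng.integers(1, 100, 6).tolist()
    excl = rng.integers(1, 100, 6).tolist()
    conds = ["A"] * 3 + ["B"] * 3
    fwd = _score(incl, excl, conds)
    rev = _score(excl, incl, conds)
    np.testing.assert_allclose(rev.psi, 1.0 - fwd.psi)
    assert rev.delta_psi == pytest.approx(fwd.delta_psi)
    assert rev.p_value == pytest.approx(fwd.p_value)


def test_condition_swap_negates_signed_delta(rng):
    incl = rng.integers(1, 100, 6).tolist()
    excl = rng.integers(1, 100, 6).tolist()
    j_in = Junction("chr1", 100, 200)
    j_ex = Junction("chr1", 100, 400)
    table = table_of([(f"s{i}", {j_in: a, j_ex: b})
                      for i, (a, b) in enumerate(zip(incl, excl))])
    from aseview.event_detection import JunctionPair

    pair = JunctionPair(table.junctions[0], table.junctions[1],
                        MetaExon("chr1", 200, 300), False)
    conds = ["A"] * 3 + ["B"] * 3
    ab = score_pair(pair, table, None, conds, ("A", "B"))
    ba = score_pair(pair, table, None, conds, ("B", "A"))
    assert ba.signed_delta == pytest.approx(-ab.signed_delta)
    assert ba.p_value == pytest.approx(ab.p_value)


def test_size_factor_invariance_of_psi(rng):
    """Scaling each sample's counts by its factor and passing those factors
    reproduces the unscaled result exactly."""
    incl = rng.integers(10, 100, 6).astype(float)
    excl = rng.integers(10, 100, 6).astype(float)
    factors = rng.uniform(0.5, 2.0, 6)
    conds = ["A"] * 3 + ["B"] * 3
    base = _score(incl.tolist(), excl.tolist(), conds,
                  factors=np.ones(6))
    scaled = _score((incl * factors).tolist(), (excl * factors).tolist(),
                    conds, factors=factors)
    np.testing.assert_allclose(scaled.psi, base.psi)
    assert scaled.p_value == pytest.approx(base.p_value)


def test_raw_psi_switch_ignores_factors(rng):
    incl = [10, 20, 30, 40]
    excl = [30, 20, 10, 40]
    conds = ["A", "A", "B", "B"]
    factors = np.array([1.0, 2.0, 0.5, 1.5])
    raw = _score(incl, excl, conds, factors=factors, raw=True)
    nof = _score(incl, excl, conds, factors=None)
    np.testing.assert_allclose(raw.psi, nof.psi)


# ---------------------------------------------------------------------------
# best pair


def _fake_scored(rng, n, meta):
    from aseview.event_detection import JunctionPair, PsiResult

    scored = []
    table_entries = {}
    for k in range(n):
        d = 100 + 10 * k
        i = Junction("chr1", d, 200, known=bool(rng.integers(2)))
        x = Junction("chr1", d - 5, 400 + k, known=bool(rng.integers(2)))
        table_entries[i] = int(rng.integers(1, 50))
        table_entries[x] = int(rng.integers(1, 50))
        pair = JunctionPair(i, x, meta, uses_novel=not (i.known and x.known))
        psi = rng.uniform(0, 1, 4)
        mean_a, mean_b = float(psi[:2].mean()), float(psi[2:].mean())
        scored.append(
            (pair, PsiResult(("A", "B"), psi, mean_a, mean_b, 0.5))
        )
    table = table_of([("s0", table_entries), ("s1", table_entries),
                      ("s2", table_entries), ("s3", table_entries)])
    return scored, table


def test_best_pair_takes_largest_delta(cassette_junctions):
    meta = MetaExon("chr1", 200, 300)
    rng = np.random.default_rng(5)
    scored, table = _fake_scored(rng, 2, meta)
    # force deltas 0.4 and 0.1
    scored[0][1].mean_a, scored[0][1].mean_b = 0.7, 0.3
    scored[1][1].mean_a, scored[1][1].mean_b = 0.5, 0.4
    best, _ = best_pair(scored, table)
    assert best[0] is scored[0][0]


def test_best_pair_reports_known_only_fallback():
    from aseview.event_detection import JunctionPair, PsiResult

    meta = MetaExon("chr1", 200, 300)
    novel_i = Junction("chr1", 150, 200, known=False)
    known_i = Junction("chr1", 100, 200, known=True)
    x = Junction("chr1", 90, 400, known=True)
    table = table_of([("s", {novel_i: 10, known_i: 10, x: 10})])
    p_novel = JunctionPair(novel_i, x, meta, uses_novel=True)
    p_known = JunctionPair(known_i, x, meta, uses_novel=False)
    scored = [
        (p_novel, PsiResult(("A", "B"), np.array([0.9]), 0.9, 0.1, 0.01)),
        (p_known, PsiResult(("A", "B"), np.array([0.6]), 0.6, 0.3, 0.02)),
    ]
    best, fallback = best_pair(scored, table)
    assert best[0] is p_novel
    assert fallback[0] is p_known


def test_best_pair_matches_exhaustive_oracle(rng):
    meta = MetaExon("chr1", 200, 300)
    for _ in range(30):
        scored, table = _fake_scored(rng, int(rng.integers(1, 10)), meta)
        best, fallback = best_pair(scored, table)

        def oracle_key(item):
            pair, res = item
            total = float((table.row(pair.inclusion)
                           + table.row(pair.exclusion)).sum())
            return (-abs(res.mean_a - res.mean_b), -total, pair.sort_coords)

        expected = min(scored, key=oracle_key)
        assert best[0] is expected[0]
        if expected[0].uses_novel:
            known = [s for s in scored if not s[0].uses_novel]
            if known:
                assert fallback[0] is min(known, key=oracle_key)[0]
            else:
                assert fallback is None
        else:
            assert fallback is None


# ---------------------------------------------------------------------------
# ratio test


def _cassette_setup(level_a, level_b, cassette_a, cassette_b, gene):
    """4 samples, 2 per condition; the cassette exon [1200,1300) has its own
    per-condition level."""
    length = gene.end - gene.start
    rows = []
    for cond_level, cas_level in ((level_a, cassette_a), (level_a, cassette_a),
                                  (level_b, cassette_b), (level_b, cassette_b)):
        row = np.zeros(length)
        for s, e in [(1000, 1100), (1400, 1500)]:
            row[s - gene.start:e - gene.start] = cond_level
        row[1200 - gene.start:1300 - gene.start] = cas_level
        rows.append(row)
    return coverage_of(gene, rows, ["A", "A", "B", "B"])


def _groups(gene):
    return exon_groups(gene, {t.id for t in gene.transcripts})


def test_identical_conditions_give_flat_half_ratio(cassette_gene):
    cov = _cassette_setup(50, 50, 30, 30, cassette_gene)
    r = coverage_ratio(cov, ("A", "B"))
    exonic = ~np.isnan(r)
    np.testing.assert_allclose(r[exonic], 0.5)
    res = ratio_test(cov, _groups(cassette_gene), 1, ("A", "B"))
    assert res.delta_ratio == pytest.approx(0.0)


def test_condition_exclusive_exon_hits_ratio_one(cassette_gene):
    cov = _cassette_setup(50, 50, 40, 0, cassette_gene)
    res = ratio_test(cov, _groups(cassette_gene), 1, ("A", "B"))
    assert res.target_mean == pytest.approx(1.0)
    assert res.background_mean == pytest.approx(0.5)
    assert res.delta_ratio == pytest.approx(0.5)


def test_ratio_test_untestable_with_too_few_groups(cassette_gene):
    cov = _cassette_setup(50, 50, 40, 10, cassette_gene)
    groups = _groups(cassette_gene)[:2]  # only one remaining group
    res = ratio_test(cov, groups, 1, ("A", "B"))
    assert not res.testable
    assert math.isnan(res.delta_ratio)


def test_zero_coverage_bases_are_undefined(cassette_gene):
    cov = coverage_of(cassette_gene,
                      np.zeros((4, cassette_gene.end - cassette_gene.start)),
                      ["A", "A", "B", "B"])
    r = coverage_ratio(cov, ("A", "B"))
    assert np.isnan(r).all()


def test_ratio_size_factor_invariance(cassette_gene, rng):
    base = _cassette_setup(50, 50, 45, 5, cassette_gene)
    factors = rng.uniform(0.5, 2.0, 4)
    scaled = CoverageSet(base.chrom, base.start, base.end, base.samples,
                         base.conditions, base.matrix * factors[:, None],
                         size_factors=factors)
    g = _groups(cassette_gene)
    a = ratio_test(base, g, 1, ("A", "B"))
    b = ratio_test(scaled, g, 1, ("A", "B"))
    assert b.target_mean == pytest.approx(a.target_mean)
    assert b.delta_ratio == pytest.approx(a.delta_ratio)


# ---------------------------------------------------------------------------
# classification


def _pair(incl, excl, target):
    from aseview.event_detection import JunctionPair

    return JunctionPair(incl, excl, target, uses_novel=False)


def test_cassette_pair_is_exon_skipping(cassette_gene, cassette_junctions):
    incl_up, incl_down, excl = cassette_junctions
    metas = build_meta_exons(cassette_gene)
    target = metas[1]
    assert classify_event(_pair(incl_up, excl, target), metas, "+") \
        == "exon_skipping"
    assert classify_event(_pair(incl_down, excl, target), metas, "+") \
        == "exon_skipping"


def test_shared_acceptor_differing_donor_is_alt_donor():
    # the exclusion skips the target AND the next meta-exon, so this is not
    # a clean cassette; the junctions share the acceptor and differ at the
    # donor side
    target = MetaExon("chr1", 200, 300)
    metas = [MetaExon("chr1", 0, 100), target, MetaExon("chr1", 400, 500),
             MetaExon("chr1", 600, 700)]
    incl = Junction("chr1", 300, 600)
    excl = Junction("chr1", 150, 600)
    assert classify_event(_pair(incl, excl, target), metas, "+") == "alt_donor"
    assert classify_event(_pair(incl, excl, target), metas, "-") \
        == "alt_acceptor"


def test_classification_matches_rule_table(rng):
    """Random pairs against a brute-force restatement of the rules."""
    metas = [MetaExon("chr1", 0, 100), MetaExon("chr1", 200, 300),
             MetaExon("chr1", 400, 500), MetaExon("chr1", 600, 700)]
    target = metas[1]

    def oracle(incl, excl, strand):
        contains_other = any(
            m.start < excl.acceptor_start and m.end > excl.donor_end
            and (m.start, m.end) != (target.start, target.end)
            for m in metas
        )
        up = (incl.acceptor_start == target.start
              and incl.donor_end == excl.donor_end)
        down = (incl.donor_end == target.end
                and incl.acceptor_start == excl.acceptor_start)
        if (up or down) and not contains_other:
            return "exon_skipping"
        left = incl.donor_end == excl.donor_end
        right = incl.acceptor_start == excl.acceptor_start
        if left ^ right:
            if right:
                return "alt_donor" if strand == "+" else "alt_acceptor"
            return "alt_acceptor" if strand == "+" else "alt_donor"
        return "other"

    anchors = [0, 50, 100, 150, 200, 300, 350, 400, 500, 600, 700]
    for _ in range(300):
        d1, a1 = sorted(rng.choice(anchors, 2, replace=False))
        d2, a2 = sorted(rng.choice(anchors, 2, replace=False))
        strand = "+" if rng.random() < 0.5 else "-"
        incl = Junction("chr1", int(d1), int(a1))
        excl_d = min(int(d2), 200)
        excl_a = max(int(a2), 300)
        if excl_d == 200 and excl_a == 300:
            continue
        excl = Junction("chr1", excl_d, excl_a)
        assert classify_event(_pair(incl, excl, target), metas, strand) \
            == oracle(incl, excl, strand)


# ---------------------------------------------------------------------------
# driver


def test_gene_with_zero_junctions_yields_nothing(cassette_gene):
    table = table_of([(f"s{i}", {}) for i in range(4)])
    cov = coverage_of(
        cassette_gene,
        _flat_coverage(cassette_gene, {(1000, 1500): 50}),
        ["A", "A", "B", "B"],
    )
    assert detect_events(cassette_gene, table, cov) == []


def _cassette_dataset(psi_a=0.9, psi_b=0.2, depth=100):
    from aseview.simulate import SimScenario, junction_table, simulate_counts

    sc = SimScenario(seed=11, psi=(psi_a, psi_b), depth=depth,
                     noise="binomial")
    data = simulate_counts(sc)
    data.coverage.size_factors = np.ones(6)
    return data, junction_table(data)


def test_single_cassette_event_detected_with_both_supports():
    data, table = _cassette_dataset()
    cands = detect_events(data.gene, table, data.coverage)
    assert len(cands) == 1
    c = cands[0]
    assert (c.meta_exon.start, c.meta_exon.end) == \
        (data.truth["meta_exon_start"], data.truth["meta_exon_end"])
    assert c.support_class == "both"
    assert c.event_type == "exon_skipping"
    assert c.meta_exon.highlight


def test_detection_is_deterministic():
    data, table = _cassette_dataset()
    f1 = results_to_frame(detect_events(data.gene, table, data.coverage),
                          data.coverage.samples)
    f2 = results_to_frame(detect_events(data.gene, table, data.coverage),
                          data.coverage.samples)
    assert f1.equals(f2)


def test_detection_power_nondecreasing_in_depth():
    """At fixed delta PSI the true event is found at least as often at
    depth 200 as at depth 20."""
    from aseview.simulate import SimScenario, junction_table, simulate_counts

    def rate(depth, n_seeds=30):
        hits = 0
        for seed in range(n_seeds):
            sc = SimScenario(seed=seed, psi=(0.8, 0.3), depth=depth)
            data = simulate_counts(sc)
            data.coverage.size_factors = np.ones(6)
            cands = detect_events(data.gene, junction_table(data),
                                  data.coverage)
            hits += any(
                (c.meta_exon.start, c.meta_exon.end)
                == (data.truth["meta_exon_start"], data.truth["meta_exon_end"])
                for c in cands
            )
        return hits / n_seeds

    assert rate(200) >= rate(20)


def test_thresholds_gate_candidates():
    data, table = _cassette_dataset(psi_a=0.55, psi_b=0.5)
    strict = DetectionConfig(delta_psi_threshold=0.3,
                             delta_ratio_threshold=0.3)
    assert detect_events(data.gene, table, data.coverage, strict) == []
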