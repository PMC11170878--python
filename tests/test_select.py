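"""Selection procedures: JDORSP, JEP baseline, CI non-overlap baseline."""

import pytest

from jdorsp.dorstat import (
    Classification,
    ContingencyTable,
    DORResult,
    PatternStats,
    attach_stats,
)
from jdorsp.miner import MiningResult, SupportRecord, mine_frequent
from jdorsp.select import (
    report_frame,
    select_jdorsp,
    select_jep,
    select_non_overlap,
    transition_counts,
)
from jdorsp.seqdb import SequenceDatabase, parse_pattern, render_pattern
from jdorsp.synthetic import CohortConfig, simulate_database

from conftest import mk_seq, recovery_attributes, recovery_motif


def _record(text, parent=None, kind="root", supports=(10, 10)):
    return SupportRecord(
        pattern=parse_pattern(text),
        support_total=sum(supports),
        support_died=supports[0],
        support_survived=supports[1],
        parent=parse_pattern(parent) if parent else None,
        extension_kind=kind,
    )


def _stats(dor, ci_low, ci_high):
    if ci_high < 1:
        cls = Classification.PROTECTION
    elif ci_low > 1:
        cls = Classification.RISK
    else:
        cls = Classification.NOT_SIGNIFICANT
    return PatternStats(
        ContingencyTable(5, 5, 5, 5),
        DORResult(
            dor=dor, ci_low=ci_low, ci_high=ci_high, xhm=2.0, z=1.96,
            corrected=False, classification=cls,
        ),
    )


def _result(records):
    return MiningResult(
        records={r.pattern: r for r in records},
        minsup=0.1,
        mode="per-class",
        n_total=465,
        n_died=87,
        n_survived=378,
    )


@pytest.fixture
def risk_parent_with_protective_extensions():
    """A risky 3-item parent whose two 4-item extensions are protective."""
    parent = "BAL_4 < BAL_4 < DIUR_2"
    records = [
        _record(parent),
        _record("BAL_4 < BAL_4 < DIUR_2 < PH_4", parent=parent, kind="S"),
        _record("BAL_4 < BAL_4 < DIUR_2 = PH_4", parent=parent, kind="I"),
    ]
    stats = {
        parse_pattern(parent): _stats(1.68, 1.05, 2.69),
        parse_pattern("BAL_4 < BAL_4 < DIUR_2 < PH_4"): _stats(0.18, 0.05, 0.67),
        parse_pattern("BAL_4 < BAL_4 < DIUR_2 = PH_4"): _stats(0.23, 0.08, 0.69),
    }
    return _result(records), stats


def test_jdorsp_all_keeps_both_extensions(risk_parent_with_protective_extensions):
    result, stats = risk_parent_with_protective_extensions
    report = select_jdorsp(result, stats=stats, mode="all")
    assert report.n_initial == 1
    family = report.families[0]
    assert len(family.extensions) == 2
    assert family.direction == "RISK->PROTECTION"
    # SUR from 2-decimal DORs: |1.68 - 0.18| = 1.50
    assert family.sur == pytest.approx(1.50)


def test_jdorsp_best_takes_smallest_dor_for_risk_parent(
    risk_parent_with_protective_extensions,
):
    result, stats = risk_parent_with_protective_extensions
    report = select_jdorsp(result, stats=stats, mode="best")
    (family,) = report.families
    assert len(family.extensions) == 1
    assert (
        render_pattern(family.extensions[0].record.pattern)
        == "BAL_4 < BAL_4 < DIUR_2 < PH_4"
    )  # DOR 0.18 < 0.23: the most protective jump


def test_jdorsp_skips_same_direction_and_non_significant():
    parent = "A_0"
    records = [
        _record(parent),
        _record("A_0 < B_0", parent=parent, kind="S"),
        _record("A_0 < C_0", parent=parent, kind="S"),
    ]
    stats = {
        parse_pattern("A_0"): _stats(2.5, 1.2, 5.0),     # RISK parent
        parse_pattern("A_0 < B_0"): _stats(3.0, 1.5, 6.0),   # RISK ext
        parse_pattern("A_0 < C_0"): _stats(0.9, 0.4, 1.8),   # not significant
    }
    assert select_jdorsp(_result(records), stats=stats).families == []


def test_jdorsp_never_emits_non_significant_parent():
    records = [_record("A_0"), _record("A_0 < B_0", parent="A_0", kind="S")]
    stats = {
        parse_pattern("A_0"): _stats(1.0, 0.6, 1.7),
        parse_pattern("A_0 < B_0"): _stats(4.0, 2.0, 8.0),
    }
    assert select_jdorsp(_result(records), stats=stats).families == []


def test_jep_support_in_exactly_one_class():
    records = [
        _record("A_0", supports=(5, 0)),
        _record("B_0", supports=(5, 1)),
        _record("C_0", supports=(0, 9)),
    ]
    jeps = {render_pattern(r.pattern) for r in select_jep(_result(records))}
    assert jeps == {"A_0", "C_0"}


def test_non_overlap_keeps_disjoint_significant_pairs():
    parent = "A_0"
    records = [
        _record(parent),
        _record("A_0 < B_0", parent=parent, kind="S"),  # disjoint, opposite
        _record("A_0 < C_0", parent=parent, kind="S"),  # overlapping, same side
        _record("A_0 < D_0", parent=parent, kind="S"),  # crosses 1
    ]
    stats = {
        parse_pattern("A_0"): _stats(1.68, 1.05, 2.69),
        parse_pattern("A_0 < B_0"): _stats(0.18, 0.05, 0.67),
        parse_pattern("A_0 < C_0"): _stats(2.60, 2.00, 3.50),
        parse_pattern("A_0 < D_0"): _stats(0.95, 0.80, 1.20),
    }
    report = select_non_overlap(_result(records), stats=stats)
    (family,) = report.families
    kept = {render_pattern(e.record.pattern) for e in family.extensions}
    assert kept == {"A_0 < B_0"}
    counts = transition_counts(report)
    assert counts.risk_to_prot == 1 and counts.total == 1


def test_non_overlap_keeps_same_direction_when_disjoint():
    parent = "A_0"
    records = [_record(parent), _record("A_0 < B_0", parent=parent, kind="S")]
    stats = {
        parse_pattern("A_0"): _stats(1.5, 1.1, 1.9),
        parse_pattern("A_0 < B_0"): _stats(4.0, 2.5, 8.0),
    }
    report = select_non_overlap(_result(records), stats=stats)
    assert transition_counts(report).risk_to_risk == 1


def test_transition_counts_empty_report():
    report = select_jdorsp(_result([_record("A_0")]),
                           stats={parse_pattern("A_0"): _stats(1.0, 0.5, 2.0)})
    c = transition_counts(report)
    assert (c.prot_to_risk, c.prot_to_prot, c.risk_to_risk, c.risk_to_prot) == (
        0, 0, 0, 0,
    )


def test_report_frame_layout(risk_parent_with_protective_extensions):
    result, stats = risk_parent_with_protective_extensions
    frame = report_frame(select_jdorsp(result, stats=stats, mode="all"))
    assert list(frame["id"]) == ["1", "1A", "1B"]
    assert frame.loc[0, "meaning"] == "RISK"
    assert frame.loc[1, "meaning"] == "PROTECTION"
    assert frame.loc[0, "patients"] == 10  # tp + fp of the placeholder table


# ---------------------------------------------------------------------------
# structural properties on a simulated cohort
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def mined_cohort():
    config = CohortConfig(
        n_patients=800,
        attributes=recovery_attributes(),
        motifs=(recovery_motif(),),
        seed=21,
    )
    db = simulate_database(config)
    result = mine_frequent(db, minsup=0.16, mode="per-class", max_length=3)
    return result, attach_stats(result)


def test_jdorsp_is_subset_of_non_overlap(mined_cohort):
    result, stats = mined_cohort
    jdorsp_pairs = {
        (f.parent.pattern, e.record.pattern)
        for f in select_jdorsp(result, stats=stats).families
        for e in f.extensions
    }
    overlap_pairs = {
        (f.parent.pattern, e.record.pattern)
        for f in select_non_overlap(result, stats=stats).families
        for e in f.extensions
    }
    assert jdorsp_pairs  # the planted motif guarantees at least one family
    assert jdorsp_pairs <= overlap_pairs


def test_jdorsp_has_zero_same_direction_transitions(mined_cohort):
    result, stats = mined_cohort
    counts = transition_counts(select_jdorsp(result, stats=stats))
    assert counts.prot_to_prot == 0
    assert counts.risk_to_risk == 0
    assert counts.total == counts.prot_to_risk + counts.risk_to_prot > 0


def test_best_families_subset_of_all(mined_cohort):
    result, stats = mined_cohort
    all_report = select_jdorsp(result, stats=stats, mode="all")
    best_report = select_jdorsp(result, stats=stats, mode="best")
    all_by_parent = {
        f.parent.pattern: {e.record.pattern for e in f.extensions}
        for f in all_report.families
    }
    assert len(best_report.families) == len(all_report.families)
    for family in best_report.families:
        assert len(family.extensions) == 1
        assert (
            family.extensions[0].record.pattern
            in all_by_parent[family.parent.pattern]
        )


def test_non_overlap_categories_partition_extensions(mined_cohort):
    result, stats = mined_cohort
    report = select_non_overlap(result, stats=stats)
    assert transition_counts(report).total == report.n_extensions
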