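"""Synthetic cohort generator: determinism, distributions, planted motifs."""

import math

import numpy as np
import pandas as pd
import pytest

from jdorsp.discretize import discretize_cohort, identity_scheme
from jdorsp.dorstat import attach_stats
from jdorsp.miner import mine_frequent
from jdorsp.seqdb import Item, contains, parse_pattern
from jdorsp.select import select_jdorsp
from jdorsp.synthetic import (
    AttributeSpec,
    CohortConfig,
    MotifSpec,
    default_attributes,
    expected_contingency,
    load_cohort_config,
    simulate_cohort,
    simulate_database,
)

from conftest import recovery_attributes, recovery_motif


def test_same_seed_is_byte_identical():
    config = CohortConfig(n_patients=60, seed=5)
    rec1, lab1 = simulate_cohort(config)
    rec2, lab2 = simulate_cohort(config)
    assert rec1.equals(rec2) and lab1.equals(lab2)
    rec3, _ = simulate_cohort(CohortConfig(n_patients=60, seed=6))
    assert not rec1.equals(rec3)


def test_record_shape_without_missingness():
    config = CohortConfig(n_patients=30, seed=0)
    records, labels = simulate_cohort(config)
    assert len(records) == 30 * config.n_days * len(config.attributes)
    assert len(labels) == 30
    assert set(records["attribute"]) == {"INC", "DIUR", "BAL", "BIC", "PH", "BE"}


def test_death_count_near_binomial_expectation():
    config = CohortConfig(n_patients=465, seed=13)
    _, labels = simulate_cohort(config)
    deaths = int((labels["outcome"] == "died").sum())
    sigma = math.sqrt(465 * config.death_rate * (1 - config.death_rate))
    assert abs(deaths - 87) <= 3 * sigma


def test_forced_parent_present_in_every_sequence():
    motif = MotifSpec(
        parent=parse_pattern("PH_0 < PH_0"),
        extension_item=Item.parse("BAL_4"),
        extension_kind="S",
        p_parent=(1.0, 1.0),
        p_extension=(0.0, 0.0),
    )
    config = CohortConfig(n_patients=50, motifs=(motif,), seed=2)
    db = simulate_database(config)
    assert all(contains(seq, motif.parent) for seq in db.sequences)


def test_simulate_database_equals_discretize_path():
    config = CohortConfig(
        n_patients=40, motifs=(recovery_motif(),),
        attributes=recovery_attributes(), seed=9,
    )
    fast = simulate_database(config)
    records, labels = simulate_cohort(config)
    slow = discretize_cohort(
        records, identity_scheme(config.attribute_intervals()), labels
    )
    assert len(fast) == len(slow)
    for a, b in zip(fast.sequences, slow.sequences):
        assert (a.sid, a.elements, a.label) == (b.sid, b.elements, b.label)


def test_baseline_frequencies_match_configuration():
    config = CohortConfig(n_patients=1200, seed=4)
    records, _ = simulate_cohort(config)
    n_draws = 1200 * config.n_days
    for attr in config.attributes:
        values = records.loc[records["attribute"] == attr.name, "value"]
        for interval, p in enumerate(attr.baseline):
            observed = int((values == interval).sum())
            sigma = math.sqrt(n_draws * p * (1 - p))
            assert abs(observed - n_draws * p) <= 3 * sigma + 1, (
                attr.name, interval,
            )


def test_motif_longer_than_study_window_rejected():
    motif = MotifSpec(
        parent=parse_pattern("PH_1 < PH_1 < PH_1 < PH_1 < PH_1"),
        extension_item=Item.parse("BE_0"),
        extension_kind="S",
        p_parent=(0.5, 0.5),
        p_extension=(0.5, 0.5),
    )
    with pytest.raises(ValueError, match="days"):
        CohortConfig(n_patients=20, n_days=5, motifs=(motif,))


def test_motif_validation_errors():
    with pytest.raises(ValueError, match="probability"):
        MotifSpec(
            parent=parse_pattern("PH_1"),
            extension_item=Item.parse("BE_0"),
            extension_kind="S",
            p_parent=(1.5, 0.5),
            p_extension=(0.5, 0.5),
        )
    motif = MotifSpec(
        parent=parse_pattern("XX_0"),
        extension_item=Item.parse("BE_0"),
        extension_kind="S",
        p_parent=(0.5, 0.5),
        p_extension=(0.5, 0.5),
    )
    with pytest.raises(ValueError, match="unknown attribute"):
        CohortConfig(n_patients=20, motifs=(motif,))


def test_expected_contingency_odds_algebra():
    motif = MotifSpec(
        parent=parse_pattern("PH_1"),
        extension_item=Item.parse("BE_0"),
        extension_kind="S",
        p_parent=(0.5, 0.5),
        p_extension=(0.8, 0.2),
    )
    config = CohortConfig(
        n_patients=1000, death_rate=0.2, motifs=(motif,), seed=0
    )
    among_carriers = expected_contingency(
        config, motif, which="extension", population="parent_carriers"
    )
    assert among_carriers.dor == pytest.approx(16.0)
    # symmetric class probabilities give no association
    symmetric = MotifSpec(
        parent=parse_pattern("PH_1"),
        extension_item=Item.parse("BE_0"),
        extension_kind="S",
        p_parent=(0.4, 0.4),
        p_extension=(0.3, 0.3),
    )
    config2 = CohortConfig(n_patients=1000, motifs=(symmetric,), seed=0)
    assert expected_contingency(config2, symmetric).dor == pytest.approx(1.0)
    assert expected_contingency(
        config2, symmetric, which="parent"
    ).dor == pytest.approx(1.0)


def test_recovery_motif_plants_dor_sixteen(recovery_config):
    motif = recovery_config.motifs[0]
    assert expected_contingency(recovery_config, motif).dor == pytest.approx(16.0)
    assert expected_contingency(
        recovery_config, motif, which="parent"
    ).dor == pytest.approx(0.25)


def test_single_replicate_end_to_end_recovery(recovery_config):
    config = recovery_config.with_seed(77)
    db = simulate_database(config)
    result = mine_frequent(db, minsup=0.16, mode="per-class", max_length=3)
    stats = attach_stats(result)
    report = select_jdorsp(result, stats=stats)
    motif = config.motifs[0]
    hits = [
        f
        for f in report.families
        if f.parent.pattern == motif.parent
        and any(e.record.pattern == motif.extension_pattern for e in f.extensions)
    ]
    assert hits, "planted protection->risk motif must surface as a JDORSP family"
    assert hits[0].direction == "PROTECTION->RISK"


def test_null_cohort_rarely_yields_families():
    # No planted motif: families can arise only from chance significance of
    # both a parent and an oppositely-significant extension; with the CI's
    # nominal 5% level per pattern the joint rate per lineage edge is well
    # below 5% (multiple testing across edges is what the loose bound absorbs).
    config = CohortConfig(n_patients=400, seed=31)
    db = simulate_database(config)
    result = mine_frequent(db, minsup=0.2, mode="per-class", max_length=3)
    stats = attach_stats(result)
    report = select_jdorsp(result, stats=stats)
    n_edges = sum(len(result.children_of(r.pattern)) for r in result)
    assert n_edges > 0
    assert report.n_extensions <= max(3, 0.05 * n_edges)


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "cohort.yaml"
    path.write_text(
        """
n_patients: 120
death_rate: 0.25
n_days: 4
seed: 99
attributes:
  - name: PH
    baseline: [0.1, 0.8, 0.1]
  - name: BAL
    baseline: [0.5, 0.5]
    baseline_died: [0.2, 0.8]
motifs:
  - parent: "PH_0 < PH_0"
    extension: "BAL_1"
    kind: S
    p_parent: [0.5, 0.8]
    p_extension: [0.8, 0.05]
"""
    )
    config = load_cohort_config(path)
    assert config.n_patients == 120
    assert config.n_days == 4
    assert config.attribute_intervals() == {"PH": 3, "BAL": 2}
    motif = config.motifs[0]
    assert str(motif.parent) == "PH_0 < PH_0"
    assert motif.extension_kind == "S"
    assert motif.p_extension == (0.8, 0.05)
    # and it simulates
    records, labels = simulate_cohort(config)
    assert len(labels) == 120
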