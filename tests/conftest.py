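"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import random

import pytest

from jdorsp.seqdb import (
    Item,
    Outcome,
    SequenceDatabase,
    TemporalSequence,
    make_itemset,
)
from jdorsp.synthetic import (
    AttributeSpec,
    CohortConfig,
    MotifSpec,
    default_attributes,
)
from jdorsp.seqdb import parse_pattern


def mk_seq(sid, itemsets, label=Outcome.SURVIVED, days=None):
    """Build a TemporalSequence from lists of item tokens like ['A_0', 'B_1']."""
    if days is None:
        days = range(len(itemsets))
    elements = tuple(
        (day, make_itemset(Item.parse(tok) for tok in tokens))
        for day, tokens in zip(days, itemsets)
    )
    return TemporalSequence(sid=str(sid), elements=elements, label=Outcome.parse(label))


def random_micro_db(rnd: random.Random, alphabet="ABCDE") -> SequenceDatabase:
    """A tiny random labeled database within the brute-force size guard."""
    items = [f"{a}_0" for a in alphabet]
    n = rnd.randint(2, 6)
    seqs = []
    for i in range(n):
        itemsets = [
            rnd.sample(items, rnd.randint(1, 2)) for _ in range(rnd.randint(1, 4))
        ]
        seqs.append(mk_seq(f"s{i}", itemsets, rnd.choice(["died", "survived"])))
    return SequenceDatabase(seqs)


def recovery_attributes():
    """Default ICBU attributes with zero baseline mass on the motif items.

    PH_0 and BAL_4 occur only when planted, making the closed-form expected
    contingency table of the recovery motif exact.
    """
    attrs = []
    for a in default_attributes():
        if a.name == "PH":
            r = 0.2 / 5
            attrs.append(AttributeSpec("PH", (0.0, r, r, 0.8, r, r, r)))
        elif a.name == "BAL":
            r = 0.2 / 3
            attrs.append(AttributeSpec("BAL", (r, 0.8, r, r, 0.0)))
        else:
            attrs.append(a)
    return tuple(attrs)


def recovery_motif() -> MotifSpec:
    """Protective parent (DOR 0.25) with a risky S-extension (cohort DOR 16)."""
    return MotifSpec(
        parent=parse_pattern("PH_0 < PH_0"),
        extension_item=Item.parse("BAL_4"),
        extension_kind="S",
        p_parent=(0.5, 0.8),
        p_extension=(0.8, 0.05),
    )


@pytest.fixture
def recovery_config() -> CohortConfig:
    return CohortConfig(
        n_patients=2000,
        attributes=recovery_attributes(),
        motifs=(recovery_motif(),),
        seed=0,
    )
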