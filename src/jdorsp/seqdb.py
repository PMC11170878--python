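"""Domain types for discretized clinical sequences and sequential patterns.

A patient's record is a *temporal sequence*: a day-ordered list of itemsets,
where each item is one discretized measurement such as ``PH_3`` (attribute
``PH``, discretization interval 3).  A *pattern* is an ordered list of
itemsets joined by the temporal operators ``<`` (strictly before) and ``=``
(same day); the "after" operator is never needed because every relation is
expressed from the earlier time point.  Pattern strings look like::

    BAL_4 < BAL_4 < DIUR_2 = PH_4

meaning: very high fluid balance on two (not necessarily consecutive) days,
later followed by a day on which diuresis is in interval 2 *and* pH is in
interval 4 simultaneously.

Only the order of days matters to patterns; absolute day values are never
inspected.  Items inside an itemset are kept in canonical order (attribute
name alphabetically, then interval index), which makes pattern equality,
hashing and rendering deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "Outcome",
    "Item",
    "Itemset",
    "Pattern",
    "TemporalSequence",
    "SequenceDatabase",
    "PatternError",
    "make_itemset",
    "parse_pattern",
    "render_pattern",
    "pattern_length",
    "contains",
]

_ITEM_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)_(\d+)$")


class PatternError(ValueError):
    """Raised for malformed pattern strings or invalid pattern structure."""


class Outcome(str, Enum):
    """Binary patient outcome label."""

    DIED = "died"
    SURVIVED = "survived"

    @classmethod
    def parse(cls, value: "str | Outcome") -> "Outcome":
        if isinstance(value, Outcome):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"outcome must be 'died' or 'survived', got {value!r}"
            ) from None


class Item(NamedTuple):
    """One discretized measurement: attribute name plus interval index."""

    attribute: str
    interval: int

    def __str__(self) -> str:
        return f"{self.attribute}_{self.interval}"

    @classmethod
    def parse(cls, token: str) -> "Item":
        m = _ITEM_RE.match(token.strip())
        if m is None:
            raise PatternError(f"malformed item token: {token!r}")
        return cls(m.group(1), int(m.group(2)))


#: An itemset is a canonically ordered tuple of distinct items.
Itemset = tuple  # tuple[Item, ...]


def make_itemset(items: Iterable[Item]) -> Itemset:
    """Build a canonical itemset: sorted by (attribute, interval), no duplicates."""
    ordered = tuple(sorted(items))
    if not ordered:
        raise PatternError("itemset must be non-empty")
    for a, b in zip(ordered, ordered[1:]):
        if a == b:
            raise PatternError(f"duplicate item in itemset: {a}")
    return ordered


@dataclass(frozen=True)
class Pattern:
    """An ordered list of itemsets; ``<`` between itemsets, ``=`` within."""

    itemsets: tuple  # tuple[Itemset, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "itemsets", tuple(self.itemsets))

    @property
    def length(self) -> int:
        """Total number of item instances (a k-pattern has length k)."""
        return sum(len(s) for s in self.itemsets)

    def __str__(self) -> str:
        return render_pattern(self)

    def __len__(self) -> int:
        return self.length

    def __bool__(self) -> bool:
        return bool(self.itemsets)


def render_pattern(pattern: Pattern) -> str:
    """Canonical string form: items joined by ``=`` within an itemset, itemsets by ``<``."""
    return " < ".join(
        " = ".join(str(item) for item in itemset) for itemset in pattern.itemsets
    )


def parse_pattern(text: str) -> Pattern:
    """Parse a pattern string; the exact inverse of :func:`render_pattern`.

    Grammar: ``ITEM ((" = " | " < ") ITEM)*`` with ``ITEM = ATTR_k``.
    Items inside an itemset are canonicalized to alphabetical order, so
    ``parse_pattern("PH_4 = DIUR_2")`` renders back as ``"DIUR_2 = PH_4"``.
    """
    if not text or not text.strip():
        raise PatternError("empty pattern string")
    itemsets = []
    for group in re.split(r"\s*<\s*", text.strip()):
        tokens = re.split(r"\s*=\s*", group)
        if any(not t.strip() for t in tokens):
            raise PatternError(f"empty itemset or dangling operator in: {text!r}")
        itemsets.append(make_itemset(Item.parse(t) for t in tokens))
    return Pattern(tuple(itemsets))


def pattern_length(pattern: Pattern) -> int:
    """Total item-instance count of *pattern*."""
    return pattern.length


@dataclass(frozen=True)
class TemporalSequence:
    """A patient's day-ordered record of itemsets plus the outcome label.

    Timestamps are integer day indices (0-based), strictly increasing, with
    at most one itemset per day.  Days with no measurements are simply
    absent; missing attribute measurements yield smaller itemsets.
    """

    sid: str
    elements: tuple  # tuple[tuple[int, Itemset], ...]
    label: Outcome

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        days = [d for d, _ in self.elements]
        for a, b in zip(days, days[1:]):
            if b <= a:
                raise ValueError(
                    f"sequence {self.sid!r}: timestamps must be strictly "
                    f"increasing (got day {a} then {b})"
                )
        for _, itemset in self.elements:
            make_itemset(itemset)  # validates non-empty / no duplicates

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.elements)

    def itemsets(self) -> tuple:
        return tuple(s for _, s in self.elements)

    def as_pattern(self) -> Pattern:
        """View this sequence as a pattern (drops absolute timestamps)."""
        return Pattern(self.itemsets())


@dataclass
class SequenceDatabase:
    """A labeled cohort of temporal sequences — the mining substrate."""

    sequences: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sids = [s.sid for s in self.sequences]
        if len(set(sids)) != len(sids):
            dupes = sorted({s for s in sids if sids.count(s) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")

    @property
    def n_total(self) -> int:
        return len(self.sequences)

    @property
    def n_died(self) -> int:
        return sum(1 for s in self.sequences if s.label is Outcome.DIED)

    @property
    def n_survived(self) -> int:
        return sum(1 for s in self.sequences if s.label is Outcome.SURVIVED)

    def class_size(self, outcome: Outcome) -> int:
        return sum(1 for s in self.sequences if s.label is outcome)

    def __iter__(self) -> Iterator[TemporalSequence]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def contains(sequence: TemporalSequence, pattern: Pattern) -> bool:
    """True iff *pattern* embeds in *sequence* as a subsequence.

    There must be strictly increasing element positions i_1 < ... < i_n such
    that each pattern itemset is a subset of the sequence itemset at its
    position.  Gaps are allowed: the matched days need not be consecutive.
    The empty pattern is vacuously contained.

    The greedy earliest-match strategy used here is exact for this
    containment relation: matching each pattern itemset at the earliest
    feasible position never precludes a later embedding.
    """
    sets = [frozenset(s) for _, s in sequence.elements]
    pos = -1
    for itemset in pattern.itemsets:
        need = frozenset(itemset)
        for j in range(pos + 1, len(sets)):
            if need <= sets[j]:
                pos = j
                break
        else:
            return False
    return True
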