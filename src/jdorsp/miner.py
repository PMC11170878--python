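"""Frequent multivariate sequential pattern enumeration with lineage.

The miner grows patterns one item at a time from frequent single items.
Each pattern is produced exactly once via its canonical parent (the pattern
obtained by deleting the last-added item):

* **S-extension** — append a new singleton itemset after the last one
  (the added item occurs on a strictly later day);
* **I-extension** — add an item to the last itemset (same day), restricted
  to items strictly greater in canonical order than the current last item,
  which is what makes the generation duplicate-free.

Support is anti-monotone (an extension can only lose supporting sequences),
so search is pruned at infrequent patterns.  Support counting is exact
subsequence containment, vectorized across sequences with per-item day
bitmasks; correctness is defined by — and tested against — the exhaustive
:func:`brute_force_mine` oracle.

Two threshold modes exist.  ``per-class`` mines the survivor and
non-survivor subsets separately and returns the union (a pattern is kept if
frequent in either class); every record still carries both class supports
counted over the full cohort.  ``global`` applies one threshold to the whole
database.  A pattern supported by exactly ``ceil(minsup * class_size)``
sequences is frequent (``>=`` comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

from .seqdb import Outcome, Pattern, SequenceDatabase, render_pattern

__all__ = [
    "SupportRecord",
    "MiningResult",
    "mine_frequent",
    "enumerate_extensions",
    "brute_force_mine",
]

ROOT = "root"
S_EXT = "S"
I_EXT = "I"

_MAX_ELEMENTS = 63  # day-position bitmasks live in one uint64


@dataclass(frozen=True)
class SupportRecord:
    """A frequent pattern with class-split support and generation lineage."""

    pattern: Pattern
    support_total: int
    support_died: int
    support_survived: int
    parent: "Pattern | None"
    extension_kind: str  # "S" | "I" | "root"

    def __post_init__(self) -> None:
        if self.support_total != self.support_died + self.support_survived:
            raise ValueError("support_total must equal the sum of class supports")


@dataclass
class MiningResult:
    """All frequent patterns of a labeled database, closed under parent links."""

    records: dict  # dict[Pattern, SupportRecord]
    minsup: float
    mode: str
    n_total: int
    n_died: int
    n_survived: int
    max_length: "int | None" = None
    _children: "dict | None" = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, pattern: Pattern) -> bool:
        return pattern in self.records

    def get(self, pattern: Pattern) -> "SupportRecord | None":
        return self.records.get(pattern)

    def children_of(self, parent: Pattern) -> list:
        """All frequent records generated from *parent* (one extension step)."""
        if self._children is None:
            index: dict = {}
            for rec in self.records.values():
                if rec.parent is not None:
                    index.setdefault(rec.parent, []).append(rec)
            self._children = index
        return list(self._children.get(parent, []))

    def to_frame(self) -> pd.DataFrame:
        """Pattern table with support and lineage columns."""
        rows = [
            {
                "pattern": render_pattern(rec.pattern),
                "length": rec.pattern.length,
                "support_total": rec.support_total,
                "support_died": rec.support_died,
                "support_survived": rec.support_survived,
                "parent": render_pattern(rec.parent) if rec.parent else "",
                "extension_kind": rec.extension_kind,
            }
            for rec in self.records.values()
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                "pattern",
                "length",
                "support_total",
                "support_died",
                "support_survived",
                "parent",
                "extension_kind",
            ],
        )
        return frame.sort_values(["length", "pattern"], kind="stable").reset_index(
            drop=True
        )


def enumerate_extensions(parent: Pattern, result: MiningResult) -> list:
    """The frequent (l+1)-patterns whose lineage parent is *parent*.

    Returns ``[(record, kind), ...]`` with kind ``"S"`` or ``"I"``.
    """
    if parent not in result.records:
        raise KeyError(f"pattern not in mining result: {render_pattern(parent)!r}")
    return [(rec, rec.extension_kind) for rec in result.children_of(parent)]


def _validate(db: SequenceDatabase, minsup: float, mode: str) -> None:
    if not db.sequences:
        raise ValueError("cannot mine an empty database")
    if not (0.0 < minsup <= 1.0):
        raise ValueError(f"minsup must be in (0, 1], got {minsup}")
    if mode not in ("per-class", "global"):
        raise ValueError(f"mode must be 'per-class' or 'global', got {mode!r}")
    if mode == "per-class" and (db.n_died == 0 or db.n_survived == 0):
        raise ValueError("per-class mining requires both outcome classes present")


def _threshold_fn(db: SequenceDatabase, minsup: float, mode: str):
    thr_died = math.ceil(minsup * db.n_died)
    thr_surv = math.ceil(minsup * db.n_survived)
    thr_glob = math.ceil(minsup * db.n_total)
    if mode == "global":
        return lambda sd, ss: sd + ss >= thr_glob
    return lambda sd, ss: sd >= thr_died or ss >= thr_surv


class _BitIndex:
    """Per-item day-position bitmasks enabling vectorized containment checks."""

    def __init__(self, db: SequenceDatabase, alphabet: list):
        self.alphabet = alphabet
        self.item_index = {item: j for j, item in enumerate(alphabet)}
        n = len(db.sequences)
        self.bits = np.zeros((n, len(alphabet)), dtype=np.uint64)
        for i, seq in enumerate(db.sequences):
            if len(seq.elements) > _MAX_ELEMENTS:
                raise ValueError(
                    f"sequence {seq.sid!r} has more than {_MAX_ELEMENTS} elements"
                )
            for pos, (_, itemset) in enumerate(seq.elements):
                for item in itemset:
                    j = self.item_index.get(item)
                    if j is not None:
                        self.bits[i, j] |= np.uint64(1) << np.uint64(pos)
        self.died = np.array(
            [s.label is Outcome.DIED for s in db.sequences], dtype=bool
        )

    def contains_rows(self, pattern_idx: tuple, rows: np.ndarray) -> np.ndarray:
        """Boolean mask over *rows*: which sequences contain the pattern.

        Greedy earliest-position embedding, carried out simultaneously for
        all rows with bit arithmetic (lowest set bit above the previous
        match position).
        """
        one = np.uint64(1)
        zero = np.uint64(0)
        full = np.uint64(0xFFFFFFFFFFFFFFFF)
        pos = np.full(rows.shape[0], -1, dtype=np.int64)
        alive = np.ones(rows.shape[0], dtype=bool)
        for idxs in pattern_idx:
            mask = self.bits[rows, idxs[0]].copy()
            for j in idxs[1:]:
                mask &= self.bits[rows, j]
            mask[~alive] = zero
            shift = (pos + 1).astype(np.uint64)
            mask &= full << shift
            ok = mask != zero
            low = mask & (~mask + one)  # lowest set bit (two's complement)
            low[~ok] = one
            # exact: low is a power of two ≤ 2**62
            pos = np.where(ok, np.log2(low.astype(np.float64)).astype(np.int64), pos)
            alive = ok
            if not alive.any():
                break
        return alive


def mine_frequent(
    db: SequenceDatabase,
    minsup: float,
    mode: str = "per-class",
    max_length: "int | None" = None,
) -> MiningResult:
    """Enumerate every frequent pattern of *db* with class supports and lineage.

    Parameters
    ----------
    db
        Labeled sequence database.
    minsup
        Minimum support fraction in (0, 1]; the count threshold is
        ``ceil(minsup * class_size)`` (per-class mode) or
        ``ceil(minsup * n_total)`` (global mode), compared with ``>=``.
    mode
        ``"per-class"`` (union of patterns frequent among survivors or among
        non-survivors) or ``"global"``.
    max_length
        Optional cap on pattern length (total item instances); ``None``
        mines to the maximal frequent length.
    """
    _validate(db, minsup, mode)
    frequent = _threshold_fn(db, minsup, mode)

    alphabet = sorted(
        {item for seq in db.sequences for _, itemset in seq.elements for item in itemset}
    )
    index = _BitIndex(db, alphabet)
    all_rows = np.arange(len(db.sequences))

    records: dict = {}
    one = np.uint64(1)
    full = np.uint64(0xFFFFFFFFFFFFFFFF)

    def lowbit_pos(mask: np.ndarray) -> np.ndarray:
        low = mask & (~mask + one)
        # exact: low is a power of two ≤ 2**62
        return np.log2(low.astype(np.float64)).astype(np.int64)

    # Stack entries carry the greedy embedding state of each frequent
    # pattern: supporting rows, the match position of the last itemset
    # (pos_last) and of the itemset before it (pos_prev).  Greedy earliest
    # positions dominate every other embedding, so a child's containment
    # follows incrementally: an S-extension item must occur after pos_last;
    # an I-extension re-matches the enlarged last itemset after pos_prev.
    stack: list = []
    frequent_items: list = []
    for j in range(len(alphabet)):
        has = index.bits[:, j] != 0
        rows = all_rows[has]
        sd = int(index.died[rows].sum())
        ss = rows.shape[0] - sd
        if rows.shape[0] and frequent(sd, ss):
            frequent_items.append(j)
            pat = ((j,),)
            records[pat] = (sd, ss, None, ROOT)
            pos_last = lowbit_pos(index.bits[rows, j])
            pos_prev = np.full(rows.shape[0], -1, dtype=np.int64)
            stack.append((pat, 1, rows, pos_prev, pos_last))

    while stack:
        pat, length, rows, pos_prev, pos_last = stack.pop()
        if max_length is not None and length >= max_length:
            continue
        last = pat[-1]
        after_last = full << (pos_last + 1).astype(np.uint64)
        after_prev = full << (pos_prev + 1).astype(np.uint64)
        last_mask = None
        for j in frequent_items:
            # S-extension: new singleton itemset strictly after pos_last
            mask = index.bits[rows, j] & after_last
            ok = mask != 0
            if ok.any():
                sd = int(index.died[rows[ok]].sum())
                ss = int(ok.sum()) - sd
                if frequent(sd, ss):
                    child = pat + ((j,),)
                    records[child] = (sd, ss, pat, S_EXT)
                    stack.append(
                        (child, length + 1, rows[ok], pos_last[ok],
                         lowbit_pos(mask[ok]))
                    )
            # I-extension: add j (> last item, canonical order) to the last
            # itemset; re-match the enlarged itemset after pos_prev
            if j > last[-1]:
                if last_mask is None:
                    last_mask = index.bits[rows, last[0]].copy()
                    for k in last[1:]:
                        last_mask &= index.bits[rows, k]
                mask = last_mask & index.bits[rows, j] & after_prev
                ok = mask != 0
                if ok.any():
                    sd = int(index.died[rows[ok]].sum())
                    ss = int(ok.sum()) - sd
                    if frequent(sd, ss):
                        child = pat[:-1] + (last + (j,),)
                        records[child] = (sd, ss, pat, I_EXT)
                        stack.append(
                            (child, length + 1, rows[ok], pos_prev[ok],
                             lowbit_pos(mask[ok]))
                        )

    def to_pattern(idx_pat) -> Pattern:
        return Pattern(
            tuple(tuple(alphabet[j] for j in itemset) for itemset in idx_pat)
        )

    out: dict = {}
    for idx_pat, (sd, ss, parent_idx, kind) in records.items():
        pat = to_pattern(idx_pat)
        out[pat] = SupportRecord(
            pattern=pat,
            support_total=sd + ss,
            support_died=sd,
            support_survived=ss,
            parent=to_pattern(parent_idx) if parent_idx is not None else None,
            extension_kind=kind,
        )
    return MiningResult(
        records=out,
        minsup=minsup,
        mode=mode,
        n_total=db.n_total,
        n_died=db.n_died,
        n_survived=db.n_survived,
        max_length=max_length,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_BF_MAX_SEQUENCES = 8
_BF_MAX_ALPHABET = 8
_BF_MAX_SEQ_LENGTH = 12


def _bf_contains(seq_sets: list, itemsets: tuple) -> bool:
    """Exhaustive embedding check: tries every increasing position mapping."""
    k = len(itemsets)
    needs = [frozenset(s) for s in itemsets]
    for positions in combinations(range(len(seq_sets)), k):
        if all(needs[i] <= seq_sets[positions[i]] for i in range(k)):
            return True
    return False


def _canonical_parent(idx_pat: tuple):
    """Delete the last-added item; returns (parent or None, kind of child)."""
    if len(idx_pat) == 1 and len(idx_pat[0]) == 1:
        return None, ROOT
    last = idx_pat[-1]
    if len(last) == 1:
        return idx_pat[:-1], S_EXT
    return idx_pat[:-1] + (last[:-1],), I_EXT


def brute_force_mine(
    db: SequenceDatabase,
    minsup: float,
    mode: str = "per-class",
    max_length: "int | None" = None,
) -> MiningResult:
    """Exhaustive generate-and-test miner for micro databases (test oracle).

    Enumerates every distinct subsequence occurring in the database (any
    pattern with positive support is a subsequence of some sequence), counts
    supports by trying all embeddings, and applies the same threshold rule
    as :func:`mine_frequent`.  Deliberately shares no machinery with the
    production miner.  Refuses inputs beyond its size guard.
    """
    _validate(db, minsup, mode)
    alphabet = {item for seq in db.sequences for _, s in seq.elements for item in s}
    if len(db.sequences) > _BF_MAX_SEQUENCES:
        raise ValueError(f"brute force limited to {_BF_MAX_SEQUENCES} sequences")
    if len(alphabet) > _BF_MAX_ALPHABET:
        raise ValueError(f"brute force limited to {_BF_MAX_ALPHABET} distinct items")
    if any(seq.length > _BF_MAX_SEQ_LENGTH for seq in db.sequences):
        raise ValueError(
            f"brute force limited to sequence length {_BF_MAX_SEQ_LENGTH}"
        )
    frequent = _threshold_fn(db, minsup, mode)

    candidates: set = set()
    for seq in db.sequences:
        element_subsets = []
        for _, itemset in seq.elements:
            subs = []
            items = tuple(sorted(itemset))
            for r in range(len(items) + 1):
                subs.extend(combinations(items, r))
            element_subsets.append(subs)
        for choice in product(*element_subsets):
            pat = tuple(s for s in choice if s)
            if pat:
                candidates.add(pat)

    seq_sets = {
        seq.sid: [frozenset(s) for _, s in seq.elements] for seq in db.sequences
    }
    out: dict = {}
    for idx_pat in sorted(candidates):
        if max_length is not None and sum(len(s) for s in idx_pat) > max_length:
            continue
        sd = ss = 0
        for seq in db.sequences:
            if _bf_contains(seq_sets[seq.sid], idx_pat):
                if seq.label is Outcome.DIED:
                    sd += 1
                else:
                    ss += 1
        if (sd + ss) and frequent(sd, ss):
            parent_idx, kind = _canonical_parent(idx_pat)
            pat = Pattern(idx_pat)
            out[pat] = SupportRecord(
                pattern=pat,
                support_total=sd + ss,
                support_died=sd,
                support_survived=ss,
                parent=Pattern(parent_idx) if parent_idx is not None else None,
                extension_kind=kind,
            )
    return MiningResult(
        records=out,
        minsup=minsup,
        mode=mode,
        n_total=db.n_total,
        n_died=db.n_died,
        n_survived=db.n_survived,
        max_length=max_length,
    )
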