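"""File formats for the pipeline stages.

Everything is UTF-8 CSV with a header row and "." as the decimal
separator.  Two files carry a small amount of metadata in leading comment
lines (``# key=value``) so a later stage can recover cohort margins and
mining parameters without re-reading the raw data:

* sequence files: ``patient_id, day, item, outcome``
* pattern files: ``pattern, length, support_total, support_died,
  support_survived, parent, extension_kind`` behind a metadata block
  recording n_total / n_died / n_survived / minsup / mode.
"""

from __future__ import annotations

import pandas as pd

from .miner import MiningResult, SupportRecord
from .seqdb import (
    Item,
    Outcome,
    SequenceDatabase,
    TemporalSequence,
    make_itemset,
    parse_pattern,
)

__all__ = [
    "read_cohort_csv",
    "write_sequence_db",
    "read_sequence_db",
    "write_mining_result",
    "read_mining_result",
]


def read_cohort_csv(data_path, labels_path=None) -> tuple:
    """Load long-format measurements (and optionally a separate label file).

    Returns ``(records, labels_or_None)``; labels may instead live in an
    ``outcome`` column of the data file.
    """
    records = pd.read_csv(data_path)
    labels = pd.read_csv(labels_path) if labels_path is not None else None
    return records, labels


def write_sequence_db(db: SequenceDatabase, path) -> None:
    rows = []
    for seq in db.sequences:
        for day, itemset in seq.elements:
            for item in itemset:
                rows.append(
                    {
                        "patient_id": seq.sid,
                        "day": day,
                        "item": str(item),
                        "outcome": seq.label.value,
                    }
                )
    pd.DataFrame(rows, columns=["patient_id", "day", "item", "outcome"]).to_csv(
        path, index=False
    )


def read_sequence_db(path) -> SequenceDatabase:
    frame = pd.read_csv(path)
    sequences = []
    if len(frame) == 0:
        return SequenceDatabase([])
    for pid, grp in frame.groupby("patient_id", sort=True):
        outcomes = set(grp["outcome"])
        if len(outcomes) != 1:
            raise ValueError(f"patient {pid!r}: inconsistent outcome labels")
        elements = []
        for day, day_grp in grp.groupby("day", sort=True):
            elements.append(
                (int(day), make_itemset(Item.parse(t) for t in day_grp["item"]))
            )
        sequences.append(
            TemporalSequence(
                sid=str(pid),
                elements=tuple(elements),
                label=Outcome.parse(outcomes.pop()),
            )
        )
    return SequenceDatabase(sequences)


def write_mining_result(result: MiningResult, path) -> None:
    meta = {
        "n_total": result.n_total,
        "n_died": result.n_died,
        "n_survived": result.n_survived,
        "minsup": result.minsup,
        "mode": result.mode,
        "max_length": "" if result.max_length is None else result.max_length,
    }
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        result.to_frame().to_csv(fh, index=False)


def read_mining_result(path) -> MiningResult:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    for key in ("n_total", "n_died", "n_survived", "minsup", "mode"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata line '# {key}=...'")
    records: dict = {}
    for row in frame.itertuples():
        pattern = parse_pattern(row.pattern)
        parent = (
            parse_pattern(row.parent)
            if isinstance(row.parent, str) and row.parent.strip()
            else None
        )
        records[pattern] = SupportRecord(
            pattern=pattern,
            support_total=int(row.support_total),
            support_died=int(row.support_died),
            support_survived=int(row.support_survived),
            parent=parent,
            extension_kind=str(row.extension_kind),
        )
    max_length = meta.get("max_length", "")
    return MiningResult(
        records=records,
        minsup=float(meta["minsup"]),
        mode=meta["mode"],
        n_total=int(meta["n_total"]),
        n_died=int(meta["n_died"]),
        n_survived=int(meta["n_survived"]),
        max_length=int(max_length) if max_length not in ("", "nan") else None,
    )
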