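"""Temporal-attribute discretization: raw daily measurements → SequenceDatabase.

Each continuous attribute is cut into intervals by a named scheme of strictly
increasing thresholds; k cut points define k+1 intervals indexed 0..k.  All
intervals are left-closed/right-open ``[a, b)`` with open outer ends, so a
value exactly on a cut point falls into the higher interval.

Two schemes for the six intensive-care-burns-unit attributes ship as
constants: ``expert`` (clinical reference ranges, e.g. PH_3 = normal pH
[7.35, 7.45)) and ``ucpd`` (cut points produced by unsupervised
correlation-preserving discretization).  User schemes load from YAML.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .seqdb import (
    Item,
    Outcome,
    SequenceDatabase,
    TemporalSequence,
    make_itemset,
)

__all__ = [
    "DiscretizationScheme",
    "builtin_scheme",
    "identity_scheme",
    "discretize_value",
    "discretize_cohort",
    "load_scheme",
    "dump_scheme",
]

# Units: INC managed liquids (cc), DIUR diuresis (dc), BAL fluid balance (dc),
# BIC bicarbonate (mmol/L), PH unitless, BE base excess (mEq/L).
_EXPERT_CUTS: dict[str, tuple[float, ...]] = {
    "INC": (2.3, 3.66, 5.78),
    "DIUR": (0.5, 1.0, 1.9),
    "BAL": (-2.0, 10.5, 20.4, 52.22),
    "BIC": (17.0, 21.0, 25.0, 29.0),
    "PH": (7.20, 7.30, 7.35, 7.45, 7.50, 7.60),
    "BE": (-4.0, -2.0, 2.0, 4.0),
}

_UCPD_CUTS: dict[str, tuple[float, ...]] = {
    "INC": (0.2303, 0.2913, 0.3203, 0.5588),
    "DIUR": (1.4941, 1.7749, 2.0857, 2.1697),
    "BAL": (0.5701, 4.7804, 7.4763, 13.1833),
    "BIC": (16.5, 17.6667, 19.6167, 23.0333),
    "PH": (7.2767, 7.29, 7.3667, 7.3983),
    "BE": (-7.8833, -6.63333, -4.3167, -0.2333),
}


@dataclass(frozen=True)
class DiscretizationScheme:
    """A named mapping attribute → strictly increasing cut points."""

    name: str
    cut_points: Mapping[str, tuple]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "cut_points",
            {a: tuple(float(c) for c in cuts) for a, cuts in self.cut_points.items()},
        )
        for attr, cuts in self.cut_points.items():
            if not cuts:
                raise ValueError(f"attribute {attr!r}: needs at least one cut point")
            for a, b in zip(cuts, cuts[1:]):
                if b <= a:
                    raise ValueError(
                        f"attribute {attr!r}: cut points must be strictly "
                        f"increasing (got {a} then {b})"
                    )

    @property
    def attributes(self) -> tuple:
        return tuple(self.cut_points)

    def n_intervals(self, attribute: str) -> int:
        return len(self.cut_points[attribute]) + 1

    def item(self, attribute: str, value: float) -> Item:
        return Item(attribute, discretize_value(value, self.cut_points[attribute]))


def builtin_scheme(name: str) -> DiscretizationScheme:
    """Return one of the shipped schemes: ``"expert"`` or ``"ucpd"``."""
    key = name.strip().lower()
    if key == "expert":
        return DiscretizationScheme("expert", _EXPERT_CUTS)
    if key == "ucpd":
        return DiscretizationScheme("ucpd", _UCPD_CUTS)
    raise KeyError(f"unknown built-in scheme {name!r}; expected 'expert' or 'ucpd'")


def identity_scheme(attribute_intervals: Mapping[str, int]) -> DiscretizationScheme:
    """Scheme under which the numeric value i (0 ≤ i < k) maps to interval i.

    Useful for data whose values already are interval indices, e.g. the
    output of the synthetic cohort generator.
    """
    cuts = {}
    for attr, k in attribute_intervals.items():
        if k < 2:
            raise ValueError(f"attribute {attr!r}: need at least 2 intervals")
        cuts[attr] = tuple(float(i) for i in range(1, k))
    return DiscretizationScheme("identity", cuts)


def discretize_value(value: float, cut_points: Sequence[float]) -> int:
    """Interval index of *value*: i such that value ∈ [c_{i-1}, c_i).

    Boundaries are left-closed/right-open; c_{-1} = −∞ and c_k = +∞.
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot discretize non-finite value {value!r}")
    return bisect_right(cut_points, value)


def discretize_cohort(
    records: pd.DataFrame,
    scheme: DiscretizationScheme,
    labels: "pd.DataFrame | Mapping[str, object] | None" = None,
) -> SequenceDatabase:
    """Build one TemporalSequence per patient from long-format measurements.

    Parameters
    ----------
    records
        Columns ``patient_id``, ``day`` (integer), ``attribute``, ``value``.
        An optional ``outcome`` column may carry the label instead of
        *labels*.
    scheme
        The active discretization scheme; every attribute in *records* must
        be defined in it.
    labels
        Either a DataFrame with columns ``patient_id``/``outcome`` or a
        mapping patient_id → outcome.  Required when *records* has no
        ``outcome`` column.
    """
    required = {"patient_id", "day", "attribute", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    label_map: dict = {}
    if labels is not None:
        if isinstance(labels, pd.DataFrame):
            label_map = {
                row.patient_id: Outcome.parse(row.outcome)
                for row in labels.itertuples()
            }
        else:
            label_map = {pid: Outcome.parse(out) for pid, out in labels.items()}
    elif "outcome" in records.columns:
        for pid, grp in records.groupby("patient_id", sort=False):
            outs = set(grp["outcome"])
            if len(outs) != 1:
                raise ValueError(f"patient {pid!r}: inconsistent outcome labels")
            label_map[pid] = Outcome.parse(outs.pop())
    elif len(records) == 0:
        label_map = {}
    else:
        raise ValueError("no labels: provide a label table or an 'outcome' column")

    unknown = set(records["attribute"]) - set(scheme.attributes)
    if unknown:
        raise KeyError(
            f"attribute(s) not in scheme {scheme.name!r}: {sorted(unknown)}"
        )
    dup = records.duplicated(subset=["patient_id", "day", "attribute"], keep=False)
    if dup.any():
        first = records.loc[dup, ["patient_id", "day", "attribute"]].iloc[0]
        raise ValueError(
            "duplicate measurement for (patient_id={0}, day={1}, attribute={2})".format(
                first["patient_id"], first["day"], first["attribute"]
            )
        )

    sequences = []
    for pid, grp in records.groupby("patient_id", sort=True):
        if pid not in label_map:
            raise ValueError(f"patient {pid!r} has no outcome label")
        elements = []
        for day, day_grp in grp.groupby("day", sort=True):
            items = [
                scheme.item(row.attribute, float(row.value))
                for row in day_grp.itertuples()
            ]
            elements.append((int(day), make_itemset(items)))
        sequences.append(
            TemporalSequence(sid=str(pid), elements=tuple(elements), label=label_map[pid])
        )
    return SequenceDatabase(sequences)


def load_scheme(path) -> DiscretizationScheme:
    """Load a scheme from YAML: ``{name: ..., cut_points: {ATTR: [..]}}``."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "cut_points" not in payload:
        raise ValueError(f"{path}: expected a mapping with a 'cut_points' key")
    return DiscretizationScheme(
        name=str(payload.get("name", "custom")),
        cut_points={str(k): tuple(v) for k, v in payload["cut_points"].items()},
    )


def dump_scheme(scheme: DiscretizationScheme, path) -> None:
    """Write a scheme to YAML; :func:`load_scheme` is the exact inverse."""
    payload = {
        "name": scheme.name,
        "cut_points": {a: list(c) for a, c in scheme.cut_points.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
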