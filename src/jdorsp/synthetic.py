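"""Seeded synthetic cohorts with plantable discriminative motifs.

The generator emulates the structure the pipeline assumes: a cohort of
patients, each observed for a fixed number of days (default 5) over six
intensive-care-burns-unit attributes (INC, DIUR, BAL, BIC, PH, BE), with a
binary outcome drawn at the study death rate (default 87/465 ≈ 18.7%).

Baseline items are drawn independently per (patient, day, attribute) from a
per-attribute distribution over interval indices, concentrated on the
clinically "normal" interval — most measurements of most patients sit in or
near the reference range.  On top of the baseline, *motifs* are planted: a
parent pattern embedded with class-conditional probability on randomly
chosen increasing days (overwriting the baseline items there), optionally
followed by one S- or I-extension item planted conditionally on the parent.
Motifs create exactly the parent/extension DOR contrast the selection stage
is meant to recover, with a closed-form expected contingency table.

Emitted values are interval indices; :func:`identity_scheme` (re-exported
from the discretization module) turns the long-format records back into a
sequence database, so the full pipeline runs end to end on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .discretize import identity_scheme  # noqa: F401  (re-exported convenience)
from .seqdb import Item, Pattern, SequenceDatabase, parse_pattern

__all__ = [
    "AttributeSpec",
    "MotifSpec",
    "CohortConfig",
    "default_attributes",
    "simulate_cohort",
    "simulate_database",
    "expected_contingency",
    "ExpectedTable",
    "load_cohort_config",
]

# Expert-scheme interval counts and the index of the clinically normal
# interval for each attribute.
_ATTR_SHAPE = {
    "INC": (4, 1),
    "DIUR": (4, 2),
    "BAL": (5, 1),
    "BIC": (5, 2),
    "PH": (7, 3),
    "BE": (5, 2),
}
_MODAL_P = 0.8


@dataclass(frozen=True)
class AttributeSpec:
    """One synthetic attribute: interval count and baseline item distribution."""

    name: str
    baseline: tuple  # probabilities over interval indices (survivors/default)
    baseline_died: "tuple | None" = None  # optional class-conditional override

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline", tuple(float(p) for p in self.baseline))
        if self.baseline_died is not None:
            object.__setattr__(
                self, "baseline_died", tuple(float(p) for p in self.baseline_died)
            )
            if len(self.baseline_died) != len(self.baseline):
                raise ValueError(f"{self.name}: class distributions differ in length")
        for dist in (self.baseline, self.baseline_died):
            if dist is None:
                continue
            if any(p < 0 or p > 1 for p in dist):
                raise ValueError(f"{self.name}: probabilities must lie in [0, 1]")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: distribution must sum to 1")

    @property
    def n_intervals(self) -> int:
        return len(self.baseline)

    def distribution(self, died: bool) -> tuple:
        if died and self.baseline_died is not None:
            return self.baseline_died
        return self.baseline


@dataclass(frozen=True)
class MotifSpec:
    """A plantable parent pattern plus one conditional extension item.

    ``p_parent`` and ``p_extension`` are (died, survived) probability pairs;
    the extension is planted only in patients whose parent was planted.
    """

    parent: Pattern
    extension_item: Item
    extension_kind: str  # "S" | "I"
    p_parent: tuple  # (P[plant | died], P[plant | survived])
    p_extension: tuple  # conditional on parent planted

    def __post_init__(self) -> None:
        if self.extension_kind not in ("S", "I"):
            raise ValueError(f"extension_kind must be 'S' or 'I', got {self.extension_kind!r}")
        object.__setattr__(self, "p_parent", tuple(float(p) for p in self.p_parent))
        object.__setattr__(
            self, "p_extension", tuple(float(p) for p in self.p_extension)
        )
        for pair in (self.p_parent, self.p_extension):
            if len(pair) != 2 or any(p < 0 or p > 1 for p in pair):
                raise ValueError(f"invalid probability pair {pair!r}")
        if self.extension_kind == "I" and self.extension_item in self.parent.itemsets[-1]:
            raise ValueError("I-extension item already present in the last itemset")

    @property
    def extension_pattern(self) -> Pattern:
        """The planted (l+1)-pattern the pipeline should rediscover."""
        from .seqdb import make_itemset

        if self.extension_kind == "S":
            return Pattern(self.parent.itemsets + ((self.extension_item,),))
        last = make_itemset(self.parent.itemsets[-1] + (self.extension_item,))
        return Pattern(self.parent.itemsets[:-1] + (last,))

    def n_days_needed(self) -> int:
        return len(self.parent.itemsets) + (1 if self.extension_kind == "S" else 0)

    def all_items(self) -> Iterable[Item]:
        for itemset in self.parent.itemsets:
            yield from itemset
        yield self.extension_item


def default_attributes() -> list:
    """Six ICBU attributes with baselines concentrated on the normal interval."""
    attrs = []
    for name, (k, modal) in _ATTR_SHAPE.items():
        rest = (1.0 - _MODAL_P) / (k - 1)
        baseline = tuple(_MODAL_P if i == modal else rest for i in range(k))
        attrs.append(AttributeSpec(name=name, baseline=baseline))
    return attrs


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 465
    death_rate: float = 87 / 465
    n_days: int = 5
    attributes: tuple = field(default_factory=lambda: tuple(default_attributes()))
    motifs: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "motifs", tuple(self.motifs))
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if not (0.0 <= self.death_rate <= 1.0):
            raise ValueError("death_rate must lie in [0, 1]")
        intervals = self.attribute_intervals()
        for motif in self.motifs:
            if motif.n_days_needed() > self.n_days:
                raise ValueError(
                    f"motif {motif.parent} needs {motif.n_days_needed()} days "
                    f"but the cohort has {self.n_days}"
                )
            for item in motif.all_items():
                if item.attribute not in intervals:
                    raise ValueError(f"motif item {item}: unknown attribute")
                if item.interval >= intervals[item.attribute]:
                    raise ValueError(f"motif item {item}: interval out of range")

    def attribute_intervals(self) -> dict:
        return {a.name: a.n_intervals for a in self.attributes}

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _simulate_arrays(config: CohortConfig):
    """Core draw: (died, {attribute: (n_patients, n_days) interval indices})."""
    rng = np.random.default_rng(config.seed)
    n, days = config.n_patients, config.n_days
    died = rng.random(n) < config.death_rate

    data = {}
    for attr in config.attributes:
        draws = np.empty((n, days), dtype=np.int64)
        for is_dead in (False, True):
            rows = np.nonzero(died == is_dead)[0]
            if rows.size == 0:
                continue
            cdf = np.cumsum(attr.distribution(is_dead))
            u = rng.random((rows.size, days))
            draws[rows] = np.searchsorted(cdf, u, side="right")
        data[attr.name] = draws

    for motif in config.motifs:
        k_parent = len(motif.parent.itemsets)
        k_total = motif.n_days_needed()
        plant_parent = rng.random(n) < np.where(
            died, motif.p_parent[0], motif.p_parent[1]
        )
        plant_ext = plant_parent & (
            rng.random(n) < np.where(died, motif.p_extension[0], motif.p_extension[1])
        )
        for patient in np.nonzero(plant_parent)[0]:
            chosen = np.sort(rng.choice(days, size=k_total, replace=False))
            for itemset, day in zip(motif.parent.itemsets, chosen[:k_parent]):
                for item in itemset:
                    data[item.attribute][patient, day] = item.interval
            if plant_ext[patient]:
                ext_day = chosen[-1] if motif.extension_kind == "S" else chosen[k_parent - 1]
                data[motif.extension_item.attribute][patient, ext_day] = (
                    motif.extension_item.interval
                )
    return died, data


def simulate_cohort(config: CohortConfig):
    """Draw one cohort; returns (records, labels) long-format DataFrames.

    ``records`` has columns patient_id / day / attribute / value where the
    value is the interval index (consume with the identity scheme);
    ``labels`` has patient_id / outcome.  Deterministic given the seed.
    """
    died, data = _simulate_arrays(config)
    n, days = config.n_patients, config.n_days
    width = len(str(n))
    pids = np.array([f"P{i:0{width}d}" for i in range(n)])
    attr_names = [a.name for a in config.attributes]
    records = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, days * len(attr_names)),
            "day": np.tile(np.repeat(np.arange(days), len(attr_names)), n),
            "attribute": np.tile(attr_names, n * days),
            "value": np.stack([data[a] for a in attr_names], axis=2).ravel(),
        }
    )
    labels = pd.DataFrame(
        {
            "patient_id": pids,
            "outcome": np.where(died, "died", "survived"),
        }
    )
    return records, labels


def simulate_database(config: CohortConfig) -> SequenceDatabase:
    """Simulate a cohort directly as a :class:`SequenceDatabase`.

    Equivalent to ``discretize_cohort(*simulate_cohort(config), identity
    scheme)`` but skips the long-format round trip; the two paths produce
    identical databases (the identity scheme maps interval index i to
    interval i).
    """
    from .seqdb import Outcome, TemporalSequence, make_itemset

    rng_out = _simulate_arrays(config)
    died, data = rng_out
    n, days = config.n_patients, config.n_days
    attr_names = [a.name for a in config.attributes]
    width = len(str(n))
    sequences = []
    for i in range(n):
        elements = tuple(
            (
                day,
                make_itemset(
                    Item(name, int(data[name][i, day])) for name in attr_names
                ),
            )
            for day in range(days)
        )
        sequences.append(
            TemporalSequence(
                sid=f"P{i:0{width}d}",
                elements=elements,
                label=Outcome.DIED if died[i] else Outcome.SURVIVED,
            )
        )
    return SequenceDatabase(sequences)


@dataclass(frozen=True)
class ExpectedTable:
    """Real-valued expected 2×2 cells for a planted pattern."""

    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def dor(self) -> float:
        return (self.tp * self.tn) / (self.fp * self.fn)


def expected_contingency(
    config: CohortConfig,
    motif: MotifSpec,
    which: str = "extension",
    population: str = "cohort",
) -> ExpectedTable:
    """Closed-form expected contingency table for a planted motif.

    ``which`` selects the parent or the extension pattern; ``population``
    is ``"cohort"`` (the table the pipeline actually builds) or
    ``"parent_carriers"`` (conditioning on the parent being planted, where
    the extension's expected DOR is simply the odds ratio of its two
    conditional plant probabilities).  Accidental baseline occurrences of
    the motif are not modeled, so this is exact only insofar as the motif
    items are rare under the baseline.
    """
    if motif not in config.motifs:
        raise ValueError("motif is not part of the configuration")
    n, dr = config.n_patients, config.death_rate
    pp_d, pp_s = motif.p_parent
    pe_d, pe_s = motif.p_extension

    if which == "parent":
        carry_d, carry_s = pp_d, pp_s
        n_died, n_surv = n * dr, n * (1 - dr)
    elif which == "extension":
        if population == "parent_carriers":
            carry_d, carry_s = pe_d, pe_s
            n_died, n_surv = n * dr * pp_d, n * (1 - dr) * pp_s
        elif population == "cohort":
            carry_d, carry_s = pp_d * pe_d, pp_s * pe_s
            n_died, n_surv = n * dr, n * (1 - dr)
        else:
            raise ValueError(f"unknown population {population!r}")
    else:
        raise ValueError(f"which must be 'parent' or 'extension', got {which!r}")

    tp = n_died * carry_d
    fp = n_surv * carry_s
    return ExpectedTable(tp=tp, fp=fp, fn=n_died - tp, tn=n_surv - fp)


def load_cohort_config(path) -> CohortConfig:
    """Read a cohort configuration from YAML.

    Schema::

        n_patients: 465
        death_rate: 0.18709
        n_days: 5
        seed: 7
        attributes:            # optional; defaults to the six ICBU attributes
          - name: PH
            baseline: [0.03, 0.03, 0.03, 0.8, 0.04, 0.04, 0.03]
            baseline_died: [...]   # optional
        motifs:                # optional
          - parent: "PH_3 < PH_3"
            extension: "BAL_4"
            kind: S
            p_parent: [0.5, 0.8]
            p_extension: [0.8, 0.05]
    """
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("n_patients", "n_days", "seed"):
        if key in payload:
            kwargs[key] = int(payload[key])
    if "death_rate" in payload:
        kwargs["death_rate"] = float(payload["death_rate"])
    if "attributes" in payload:
        kwargs["attributes"] = tuple(
            AttributeSpec(
                name=str(a["name"]),
                baseline=tuple(a["baseline"]),
                baseline_died=tuple(a["baseline_died"]) if "baseline_died" in a else None,
            )
            for a in payload["attributes"]
        )
    if "motifs" in payload:
        kwargs["motifs"] = tuple(
            MotifSpec(
                parent=parse_pattern(str(m["parent"])),
                extension_item=Item.parse(str(m["extension"])),
                extension_kind=str(m["kind"]),
                p_parent=tuple(m["p_parent"]),
                p_extension=tuple(m["p_extension"]),
            )
            for m in payload["motifs"]
        )
    return CohortConfig(**kwargs)
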