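"""Pattern selection: JDORSP and the two threshold-free baselines.

JDORSP ("jumping DOR sequential patterns") keeps a parent pattern p of
length l together with those of its frequent length-(l+1) extensions whose
statistical role is the *opposite* significant one: a significantly
protective parent with significantly risky extensions, or vice versa.  The
clinical reading is an abrupt jump in prognosis caused by one additional
observation.  ``mode="best"`` keeps a single extension per parent, chosen
by beam search on the DOR: the lowest DOR (most protective) when the parent
is a risk factor, the highest when the parent is protective.

Baselines:

* **JEP** — jumping emerging patterns: patterns with positive support in
  exactly one outcome class (infinite growth rate).
* **CI non-overlap** — parent/extension pairs where both 95% CIs exclude 1
  and the two intervals do not overlap (statistically different DORs).
  Every JDORSP pair satisfies this, so JDORSP ⊆ non-overlap by
  construction: opposite-side significant intervals cannot meet across 1.

"Extension" always means the miner's one-step lineage (a single S- or
I-extension), never an arbitrary superpattern, and only frequent extensions
exist in a mining result.  Families are ranked by descending SUR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dorstat import (
    Classification,
    ContingencyTable,
    DORResult,
    Z_95,
    attach_stats,
    surprisingness,
)
from .miner import MiningResult, SupportRecord
from .seqdb import render_pattern

__all__ = [
    "ScoredExtension",
    "PatternFamily",
    "TransitionCounts",
    "SelectionReport",
    "select_jdorsp",
    "select_jep",
    "select_non_overlap",
    "transition_counts",
    "report_frame",
]

_SIGNIFICANT = (Classification.PROTECTION, Classification.RISK)

_OPPOSITE = {
    Classification.PROTECTION: Classification.RISK,
    Classification.RISK: Classification.PROTECTION,
}


@dataclass(frozen=True)
class ScoredExtension:
    record: SupportRecord
    kind: str  # "S" | "I"
    table: ContingencyTable
    stats: DORResult
    delta: float  # |dor_parent - dor_extension|, full precision


@dataclass
class PatternFamily:
    """A parent pattern with its selected extensions, SUR, and direction."""

    parent: SupportRecord
    parent_table: ContingencyTable
    parent_stats: DORResult
    extensions: list
    sur: float
    direction: "str | None"  # e.g. "RISK->PROTECTION"; None when mixed


@dataclass(frozen=True)
class TransitionCounts:
    """Table of parent→extension significance transitions."""

    prot_to_risk: int = 0
    prot_to_prot: int = 0
    risk_to_risk: int = 0
    risk_to_prot: int = 0

    @property
    def total(self) -> int:
        return (
            self.prot_to_risk + self.prot_to_prot + self.risk_to_risk + self.risk_to_prot
        )


@dataclass
class SelectionReport:
    """Selected families plus the bookkeeping a summary table needs."""

    method: str
    families: list = field(default_factory=list)

    @property
    def n_initial(self) -> int:
        return len(self.families)

    @property
    def n_extensions(self) -> int:
        return sum(len(f.extensions) for f in self.families)

    @property
    def n_patterns(self) -> int:
        """Initial patterns plus extension patterns."""
        return self.n_initial + self.n_extensions

    @property
    def counts(self) -> TransitionCounts:
        return transition_counts(self)


def _family_sur(parent_stats: DORResult, extensions: list) -> float:
    return surprisingness(
        parent_stats.dor, [e.stats.dor for e in extensions], rounded=True
    )


def _sorted_families(families: list) -> list:
    return sorted(
        families, key=lambda f: (-f.sur, render_pattern(f.parent.pattern))
    )


def _pick_best(parent_stats: DORResult, extensions: list) -> list:
    """Beam-search step: single extension with extremal DOR.

    Lowest DOR when the parent is a risk factor (most protective jump),
    highest when the parent is protective; for mixed-direction candidate
    sets (possible under the non-overlap baseline) the extension farthest
    from the parent's DOR wins.  Ties break on canonical pattern string.
    """
    if parent_stats.classification is Classification.RISK:
        key = lambda e: (e.stats.dor, render_pattern(e.record.pattern))
        return [min(extensions, key=key)]
    if parent_stats.classification is Classification.PROTECTION:
        key = lambda e: (-e.stats.dor, render_pattern(e.record.pattern))
        return [min(extensions, key=key)]
    key = lambda e: (-e.delta, render_pattern(e.record.pattern))
    return [min(extensions, key=key)]


def _scored_children(
    result: MiningResult, stats: dict, parent: SupportRecord
) -> list:
    parent_dor = stats[parent.pattern].dor.dor
    out = []
    for child in result.children_of(parent.pattern):
        table, dres = stats[child.pattern]
        out.append(
            ScoredExtension(
                record=child,
                kind=child.extension_kind,
                table=table,
                stats=dres,
                delta=abs(parent_dor - dres.dor),
            )
        )
    return out


def select_jdorsp(
    result: MiningResult,
    stats: "dict | None" = None,
    mode: str = "all",
    z: float = Z_95,
) -> SelectionReport:
    """Select jumping-DOR families: significant parent, opposite-significant extensions.

    Parameters
    ----------
    result
        A mining result with lineage links.
    stats
        Pattern → :class:`~jdorsp.dorstat.PatternStats`; computed from the
        result's supports and cohort margins when omitted.
    mode
        ``"all"`` keeps every opposite-significant extension; ``"best"``
        keeps exactly one per parent (extremal DOR, see module docstring).
    """
    if mode not in ("all", "best"):
        raise ValueError(f"mode must be 'all' or 'best', got {mode!r}")
    if stats is None:
        stats = attach_stats(result, z=z)
    families = []
    for rec in result:
        if rec.pattern not in stats:
            raise KeyError(f"missing stats for {render_pattern(rec.pattern)!r}")
        ptable, pstats = stats[rec.pattern]
        if pstats.classification not in _SIGNIFICANT:
            continue
        wanted = _OPPOSITE[pstats.classification]
        qualifying = [
            e
            for e in _scored_children(result, stats, rec)
            if e.stats.classification is wanted
        ]
        if not qualifying:
            continue
        if mode == "best":
            qualifying = _pick_best(pstats, qualifying)
        direction = f"{pstats.classification.value}->{wanted.value}"
        families.append(
            PatternFamily(
                parent=rec,
                parent_table=ptable,
                parent_stats=pstats,
                extensions=qualifying,
                sur=_family_sur(pstats, qualifying),
                direction=direction,
            )
        )
    return SelectionReport(method=f"jdorsp-{mode}", families=_sorted_families(families))


def select_jep(result: MiningResult) -> list:
    """Jumping emerging patterns: support > 0 in exactly one outcome class."""
    return [
        rec
        for rec in result
        if (rec.support_died == 0) != (rec.support_survived == 0)
    ]


def _intervals_overlap(a: DORResult, b: DORResult) -> bool:
    # closed intervals; boundary contact counts as overlap (conservative)
    return max(a.ci_low, b.ci_low) <= min(a.ci_high, b.ci_high)


def select_non_overlap(
    result: MiningResult,
    stats: "dict | None" = None,
    mode: str = "all",
    z: float = Z_95,
) -> SelectionReport:
    """CI non-overlap baseline: both CIs exclude 1 and do not overlap each other."""
    if mode not in ("all", "best"):
        raise ValueError(f"mode must be 'all' or 'best', got {mode!r}")
    if stats is None:
        stats = attach_stats(result, z=z)
    families = []
    for rec in result:
        ptable, pstats = stats[rec.pattern]
        if pstats.classification not in _SIGNIFICANT:
            continue
        qualifying = [
            e
            for e in _scored_children(result, stats, rec)
            if e.stats.classification in _SIGNIFICANT
            and not _intervals_overlap(pstats, e.stats)
        ]
        if not qualifying:
            continue
        if mode == "best":
            qualifying = _pick_best(pstats, qualifying)
        directions = {e.stats.classification for e in qualifying}
        direction = (
            f"{pstats.classification.value}->{directions.pop().value}"
            if len(directions) == 1
            else None
        )
        families.append(
            PatternFamily(
                parent=rec,
                parent_table=ptable,
                parent_stats=pstats,
                extensions=qualifying,
                sur=_family_sur(pstats, qualifying),
                direction=direction,
            )
        )
    return SelectionReport(
        method=f"non-overlap-{mode}", families=_sorted_families(families)
    )


def transition_counts(report: SelectionReport) -> TransitionCounts:
    """Tally parent→extension pairs by (parent class, extension class)."""
    keys = {
        (Classification.PROTECTION, Classification.RISK): "prot_to_risk",
        (Classification.PROTECTION, Classification.PROTECTION): "prot_to_prot",
        (Classification.RISK, Classification.RISK): "risk_to_risk",
        (Classification.RISK, Classification.PROTECTION): "risk_to_prot",
    }
    tally = {v: 0 for v in keys.values()}
    for family in report.families:
        for ext in family.extensions:
            key = keys.get(
                (family.parent_stats.classification, ext.stats.classification)
            )
            if key is not None:
                tally[key] += 1
    return TransitionCounts(**tally)


def report_frame(report: SelectionReport) -> pd.DataFrame:
    """Report table: one row per parent and per extension.

    Families are numbered 1.. in descending-SUR order; extensions carry
    letter suffixes (1A, 1B, ...), mirroring the conventional layout of
    pattern/extension listings.
    """
    rows = []
    for fam_no, family in enumerate(report.families, start=1):
        ptable, pstats = family.parent_table, family.parent_stats
        rows.append(
            {
                "id": str(fam_no),
                "pattern": render_pattern(family.parent.pattern),
                "sur": round(family.sur, 2),
                "dor": pstats.dor,
                "ci_low": pstats.ci_low,
                "ci_high": pstats.ci_high,
                "patients": ptable.carriers,
                "deaths": ptable.tp,
                "pct_death": ptable.pct_death if ptable.carriers else float("nan"),
                "meaning": pstats.classification.value,
                "direction": family.direction or "",
            }
        )
        for letter, ext in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", family.extensions):
            rows.append(
                {
                    "id": f"{fam_no}{letter}",
                    "pattern": render_pattern(ext.record.pattern),
                    "sur": round(family.sur, 2),
                    "dor": ext.stats.dor,
                    "ci_low": ext.stats.ci_low,
                    "ci_high": ext.stats.ci_high,
                    "patients": ext.table.carriers,
                    "deaths": ext.table.tp,
                    "pct_death": ext.table.pct_death
                    if ext.table.carriers
                    else float("nan"),
                    "meaning": ext.stats.classification.value,
                    "direction": family.direction or "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "pattern",
            "sur",
            "dor",
            "ci_low",
            "ci_high",
            "patients",
            "deaths",
            "pct_death",
            "meaning",
            "direction",
        ],
    )
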