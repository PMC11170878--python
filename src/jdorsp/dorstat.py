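"""Epidemiological statistics on the pattern × outcome 2×2 table.

Orientation: a pattern plays the role of a diagnostic test for death —
TP = carriers that died, FP = carriers that survived, FN = non-carriers
that died, TN = non-carriers that survived.  The diagnostic odds ratio

    DOR = (TP/FN) / (FP/TN) = (TP·TN) / (FP·FN)

is > 1 when the pattern is associated with death (risk factor) and < 1 when
it is associated with survival (protection factor).  Its 95% confidence
interval is the test-based interval

    CI = DOR^(1 ± Z/Xhm),
    Xhm = sqrt((n−1)(TP·TN − FP·FN)² / ((TP+FP)(FN+TN)(TP+FN)(FP+TN)))

with Z = 1.96, where Xhm is the square root of the Mantel–Haenszel
chi-square.  When any cell is zero the DOR or its interval degenerates, so
0.5 is added to *all four* cells (Haldane-type continuity correction) before
computing both the DOR and Xhm; the correction is applied only when needed,
never unconditionally, and n is then the sum of the corrected cells.

A pattern is classified as a significant PROTECTION factor when the entire
CI lies below 1, a significant RISK factor when it lies entirely above 1,
and NOT_SIGNIFICANT when the CI covers 1.

The surprisingness score SUR of a pattern p with extensions P_x is
``max_{x in P_x} |dor(p) − dor(x)|``; report tables round each DOR to two
decimals before differencing so the printed SUR is self-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "Classification",
    "ContingencyTable",
    "DORResult",
    "PatternStats",
    "build_contingency",
    "sensitivity",
    "specificity",
    "diagnostic_odds_ratio",
    "surprisingness",
    "attach_stats",
    "stats_frame",
]

Z_95 = 1.96


class Classification(str, Enum):
    PROTECTION = "PROTECTION"
    RISK = "RISK"
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: exposure = pattern present, disease = death."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if float(v) != int(v) or v < 0:
                raise ValueError(
                    f"cell {name} must be a non-negative integer, got {v!r}"
                )
            object.__setattr__(self, name, int(v))
        if self.n < 2:
            raise ValueError(f"table total must be at least 2, got {self.n}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def carriers(self) -> int:
        return self.tp + self.fp

    @property
    def pct_death(self) -> float:
        """Death proportion among pattern carriers: TP/(TP+FP)."""
        if self.carriers == 0:
            raise ZeroDivisionError("pattern has no carriers")
        return self.tp / self.carriers


@dataclass(frozen=True)
class DORResult:
    """Diagnostic odds ratio with test-based CI and significance class."""

    dor: float
    ci_low: float
    ci_high: float
    xhm: float
    z: float
    corrected: bool
    classification: Classification


class PatternStats(NamedTuple):
    table: ContingencyTable
    dor: DORResult


def build_contingency(
    carriers_died: int,
    carriers_total: int,
    cohort_died: int,
    cohort_total: int,
) -> ContingencyTable:
    """2×2 table from carrier counts and cohort margins.

    Example: a pattern carried by 279 of 465 patients, 43 of whom died, in
    a cohort with 87 deaths, gives TP=43, FP=236, FN=44, TN=142.
    """
    tp = carriers_died
    fp = carriers_total - carriers_died
    fn = cohort_died - carriers_died
    tn = cohort_total - cohort_died - fp
    if min(tp, fp, fn, tn) < 0:
        raise ValueError(
            "inconsistent counts: derived cells "
            f"tp={tp}, fp={fp}, fn={fn}, tn={tn} must all be non-negative"
        )
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def sensitivity(table: ContingencyTable) -> float:
    """TP / (TP + FN): proportion of deaths carrying the pattern."""
    denom = table.tp + table.fn
    if denom == 0:
        raise ZeroDivisionError("sensitivity undefined: no diseased subjects")
    return table.tp / denom


def specificity(table: ContingencyTable) -> float:
    """TN / (TN + FP): proportion of survivors not carrying the pattern."""
    denom = table.tn + table.fp
    if denom == 0:
        raise ZeroDivisionError("specificity undefined: no disease-free subjects")
    return table.tn / denom


def diagnostic_odds_ratio(table: ContingencyTable, z: float = Z_95) -> DORResult:
    """DOR, Mantel–Haenszel test-based 95% CI, and significance class.

    The 0.5 continuity correction is applied to all four cells when (and
    only when) at least one cell is zero; both the DOR and Xhm then use the
    corrected cells, with n equal to their sum.
    """
    cells = (table.tp, table.fp, table.fn, table.tn)
    corrected = any(c == 0 for c in cells)
    tp, fp, fn, tn = (c + 0.5 for c in cells) if corrected else map(float, cells)

    dor = (tp * tn) / (fp * fn)
    n = tp + fp + fn + tn
    cross = tp * tn - fp * fn
    denom = (tp + fp) * (fn + tn) * (tp + fn) * (fp + tn)
    xhm = math.sqrt((n - 1) * cross * cross / denom)

    if xhm > 0.0:
        exponent = z / xhm
        bounds = sorted((dor ** (1.0 - exponent), dor ** (1.0 + exponent)))
        ci_low, ci_high = bounds
    else:
        # DOR exactly 1: the test statistic carries no information.
        ci_low, ci_high = 0.0, math.inf

    if ci_high < 1.0:
        classification = Classification.PROTECTION
    elif ci_low > 1.0:
        classification = Classification.RISK
    else:
        classification = Classification.NOT_SIGNIFICANT

    return DORResult(
        dor=dor,
        ci_low=ci_low,
        ci_high=ci_high,
        xhm=xhm,
        z=z,
        corrected=corrected,
        classification=classification,
    )


def surprisingness(
    parent_dor: float,
    extension_dors: Iterable[float],
    rounded: bool = False,
) -> float:
    """SUR: max absolute DOR difference between a pattern and its extensions.

    With ``rounded=True`` each DOR is first rounded to 2 decimals, matching
    how report tables print the score (e.g. |0.59 − 4.06| = 3.47).
    """
    dors = list(extension_dors)
    if not dors:
        raise ValueError("surprisingness requires at least one extension")
    if rounded:
        parent_dor = round(parent_dor, 2)
        dors = [round(d, 2) for d in dors]
    return max(abs(parent_dor - d) for d in dors)


def attach_stats(result, z: float = Z_95) -> dict:
    """Score every record of a mining result: pattern → PatternStats.

    Carrier counts are the pattern's full-cohort supports; the margins come
    from the mining result's database summary.
    """
    stats: dict = {}
    for rec in result:
        table = build_contingency(
            carriers_died=rec.support_died,
            carriers_total=rec.support_total,
            cohort_died=result.n_died,
            cohort_total=result.n_total,
        )
        stats[rec.pattern] = PatternStats(table, diagnostic_odds_ratio(table, z=z))
    return stats


def stats_frame(result, z: float = Z_95) -> pd.DataFrame:
    """Pattern table with contingency and DOR columns appended."""
    from .seqdb import render_pattern

    stats = attach_stats(result, z=z)
    rows = []
    for rec in result:
        table, dor = stats[rec.pattern]
        rows.append(
            {
                "pattern": render_pattern(rec.pattern),
                "length": rec.pattern.length,
                "support_total": rec.support_total,
                "support_died": rec.support_died,
                "support_survived": rec.support_survived,
                "parent": render_pattern(rec.parent) if rec.parent else "",
                "extension_kind": rec.extension_kind,
                "tp": table.tp,
                "fp": table.fp,
                "fn": table.fn,
                "tn": table.tn,
                "dor": dor.dor,
                "ci_low": dor.ci_low,
                "ci_high": dor.ci_high,
                "corrected": dor.corrected,
                "classification": dor.classification.value,
                "pct_death": table.pct_death if table.carriers else float("nan"),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["length", "pattern"], kind="stable")
        .reset_index(drop=True)
    )
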