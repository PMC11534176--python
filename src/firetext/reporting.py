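"""Aggregate tables with half-up rounding and small-cell suppression.

Aggregate outputs mask any category count below a threshold (default 10) as
"<10", with its percent shown as "<5", so that published tables cannot
expose near-identifiable groups.  Exact counts are retained internally and
only written out when explicitly requested as unsafe.  Percent rounding is
half-up — 13/90 prints as 14%, 16/90 as 18% — not banker's rounding, which
would differ at .5 boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .categorize import CATEGORIES, NoteCategory
from .cohort import IndicationResult

INDICATION_LABELS = ("icd", "smartform", "both")

DEFAULT_SUPPRESSION_THRESHOLD = 10
#: Displayed percent ceiling for suppressed rows.
SUPPRESSED_PERCENT_LABEL = "<5"
SUPPRESSED_COUNT_LABEL = "<10"


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TableRow:
    label: str
    count: int
    percent: float
    display_count: str
    display_percent: str


@dataclass(frozen=True)
class AggregateTable:
    """Rows with exact internal counts plus display strings after suppression."""

    rows: tuple[TableRow, ...]
    suppressed: frozenset[str]
    total: int

    def __post_init__(self) -> None:
        if sum(r.count for r in self.rows) != self.total:
            raise ValueError("row counts do not sum to total")

    def counts(self) -> dict[str, int]:
        return {r.label: r.count for r in self.rows}

    def percents(self) -> dict[str, float]:
        return {r.label: r.percent for r in self.rows}

    def to_frame(self, unsafe: bool = False) -> pd.DataFrame:
        """Display table; with ``unsafe=True`` the exact suppressed counts."""
        if unsafe:
            data = [(r.label, r.count, r.percent) for r in self.rows]
            return pd.DataFrame(data, columns=["category", "n", "percent"])
        data = [(r.label, r.display_count, r.display_percent) for r in self.rows]
        return pd.DataFrame(data, columns=["category", "n", "percent"])

    def to_text(self) -> str:
        width = max(len(r.label) for r in self.rows) + 2
        lines = [f"{'Category':<{width}}{'%':>6}  {'N':>5}"]
        for r in self.rows:
            lines.append(f"{r.label:<{width}}{r.display_percent:>6}  {r.display_count:>5}")
        lines.append(f"{'Total':<{width}}{'100':>6}  {self.total:>5}")
        return "\n".join(lines)


def _indication_one(results: list[IndicationResult]) -> AggregateTable:
    counts = Counter(r.source for r in results)
    bad = set(counts) - set(INDICATION_LABELS)
    if bad:
        raise ValueError(f"unexpected indication sources: {bad}")
    total = len(results)
    rows = []
    for label in INDICATION_LABELS:
        n = counts.get(label, 0)
        pct = round_half_up(100 * n / total, 1)
        rows.append(TableRow(label, n, pct, str(n), f"{pct:.1f}"))
    return AggregateTable(tuple(rows), frozenset(), total)


def indication_table(
    population: list[IndicationResult], sample: list[IndicationResult]
) -> tuple[AggregateTable, AggregateTable]:
    """Indication-source composition of the exposed population and the
    review sample, percents rounded to one decimal.  No suppression: the
    table reports proportions of an already-aggregated cohort."""
    if not population or not sample:
        raise ValueError("population and sample must be non-empty")
    return _indication_one(population), _indication_one(sample)


def category_table(
    labels: list[NoteCategory],
    suppression_threshold: int = DEFAULT_SUPPRESSION_THRESHOLD,
) -> AggregateTable:
    """Category distribution with integer percents and small-cell suppression.

    A row whose count is strictly below the threshold displays "<10" and
    "<5"; exact values stay on the row object for unsafe export.
    """
    if not labels:
        raise ValueError("no labels supplied")
    counts = Counter(lab.value for lab in labels)
    total = len(labels)
    rows = []
    suppressed = set()
    for cat in CATEGORIES:
        n = counts.get(cat, 0)
        pct = round_half_up(100 * n / total, 0)
        if n < suppression_threshold:
            suppressed.add(cat)
            rows.append(TableRow(cat, n, pct, SUPPRESSED_COUNT_LABEL, SUPPRESSED_PERCENT_LABEL))
        else:
            rows.append(TableRow(cat, n, pct, str(n), f"{pct:.0f}"))
    return AggregateTable(tuple(rows), frozenset(suppressed), total)
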