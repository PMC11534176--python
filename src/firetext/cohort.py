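"""Exposure-cohort derivation from structured EHR records.

A patient carries an *indication of exposure to firearm violence* when
either (a) a firearm-injury ICD-10-CM code appears on their diagnosis or
problem list inside the ICD study window, or (b) a behavioral-health trauma
SmartForm records a qualifying "exposure to gun violence" value (recent /
historical) inside the SmartForm window, which opens when the form was
deployed (2022-02-01).  The indication *source* is one of ``icd``,
``smartform``, ``both`` or ``none``.

The firearm code list is a parameter, not a fixed fact: the default is the
conventional external-cause surveillance families (unintentional W32-W34,
intentional self-harm X72-X74, assault X93-X95, undetermined Y22-Y24, and
legal-intervention Y35.0), matched by prefix so 7th-character encounter
extensions qualify.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import date

INDICATION_SOURCES = ("icd", "smartform", "both", "none")

#: External-cause-of-injury firearm code families (ICD-10-CM prefixes).
DEFAULT_FIREARM_CODE_PREFIXES = frozenset(
    {"W32", "W33", "W34", "X72", "X73", "X74", "X93", "X94", "X95",
     "Y22", "Y23", "Y24", "Y35.0"}
)

DEFAULT_QUALIFYING_SMARTFORM_VALUES = frozenset({"recent", "historical"})


@dataclass(frozen=True)
class StructuredRecord:
    """Per-patient dated ICD and SmartForm events."""

    patient_id: str
    icd_events: tuple[tuple[str, date], ...] = ()
    smartform_events: tuple[tuple[str, date], ...] = ()

    def __post_init__(self) -> None:
        if not self.patient_id.strip():
            raise ValueError("patient_id is empty")
        object.__setattr__(self, "icd_events", tuple(self.icd_events))
        object.__setattr__(self, "smartform_events", tuple(self.smartform_events))


@dataclass(frozen=True)
class CohortConfig:
    icd_window: tuple[date, date] = (date(2012, 1, 1), date(2022, 12, 31))
    smartform_window: tuple[date, date] = (date(2022, 2, 1), date(2022, 12, 31))
    firearm_code_prefixes: frozenset[str] = DEFAULT_FIREARM_CODE_PREFIXES
    qualifying_smartform_values: frozenset[str] = DEFAULT_QUALIFYING_SMARTFORM_VALUES

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("icd_window", self.icd_window),
                               ("smartform_window", self.smartform_window)):
            if lo > hi:
                raise ValueError(f"{name} start {lo} after end {hi}")


@dataclass(frozen=True)
class IndicationResult:
    patient_id: str
    source: str

    def __post_init__(self) -> None:
        if self.source not in INDICATION_SOURCES:
            raise ValueError(f"unknown indication source {self.source!r}")


def _normalize_code(code: str) -> str:
    return code.replace(".", "").strip().upper()


def code_is_firearm(code: str, prefixes: frozenset[str]) -> bool:
    """Prefix match, case- and dot-insensitive, so e.g. W34.00XA qualifies."""
    norm = _normalize_code(code)
    return any(norm.startswith(_normalize_code(p)) for p in prefixes)


def _in_window(d: date, window: tuple[date, date]) -> bool:
    return window[0] <= d <= window[1]


def classify_indication(record: StructuredRecord, config: CohortConfig) -> IndicationResult:
    """Derive a patient's indication source from their structured events."""
    icd_hit = any(
        code_is_firearm(code, config.firearm_code_prefixes) and _in_window(d, config.icd_window)
        for code, d in record.icd_events
    )
    sf_hit = any(
        value.strip().lower() in config.qualifying_smartform_values
        and _in_window(d, config.smartform_window)
        for value, d in record.smartform_events
    )
    if icd_hit and sf_hit:
        source = "both"
    elif icd_hit:
        source = "icd"
    elif sf_hit:
        source = "smartform"
    else:
        source = "none"
    return IndicationResult(record.patient_id, source)


def build_cohort(
    records: list[StructuredRecord], config: CohortConfig | None = None
) -> tuple[list[IndicationResult], dict[str, float]]:
    """Classify every record and return the included cohort and its mixture.

    Returns the results with ``source != "none"`` plus the proportion of each
    source among included patients (proportions sum to 1 when the cohort is
    non-empty).
    """
    if not records:
        raise ValueError("no structured records supplied")
    config = config or CohortConfig()
    results = [classify_indication(r, config) for r in records]
    included = [r for r in results if r.source != "none"]
    counts = Counter(r.source for r in included)
    n = len(included)
    mixture = {src: counts.get(src, 0) / n for src in ("icd", "smartform", "both")} if n else {}
    return included, mixture
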