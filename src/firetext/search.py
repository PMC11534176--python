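"""Corpus-level text string search: per-note hit summaries and patient counts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

from .lexicon import DEFAULT_CONTEXT_WINDOW, Lexicon, MatchMode, TermMatch, find_matches

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClinicalNote:
    """A free-text note; ``note_type`` is uncontrolled (primary care,
    behavioral health, refill request, ...) and notes are never filtered by it."""

    note_id: str
    patient_id: str
    date: date
    note_type: str
    text: str


@dataclass(frozen=True)
class NoteHit:
    """A note with at least one lexicon match."""

    note_id: str
    patient_id: str
    matches: tuple[TermMatch, ...]
    categories_hit: frozenset[str]

    def __post_init__(self) -> None:
        if not self.matches:
            raise ValueError("NoteHit requires at least one match")
        cats = frozenset(m.term.term_category for m in self.matches)
        if cats != self.categories_hit:
            raise ValueError("categories_hit inconsistent with matches")


@dataclass
class SearchResult:
    hits: list[NoteHit]
    patients_by_category: dict[str, int]
    n_patients_matched: int
    n_notes_searched: int
    n_empty_skipped: int


def search_corpus(
    notes: list[ClinicalNote],
    lexicon: Lexicon,
    mode: MatchMode = "substring",
    context_chars: int = DEFAULT_CONTEXT_WINDOW,
) -> SearchResult:
    """Apply the lexicon to every note and summarize hits.

    Returns one :class:`NoteHit` per note with >=1 match, distinct-patient
    counts per term category (a patient counts in a category if any of their
    notes hits it), and the overall distinct matched-patient count.  Notes
    with empty text are skipped and tallied.  Hit detection is per note:
    matches never combine text across notes.
    """
    seen_ids: set[str] = set()
    for note in notes:
        if note.note_id in seen_ids:
            raise ValueError(f"duplicate note_id: {note.note_id}")
        seen_ids.add(note.note_id)

    hits: list[NoteHit] = []
    patients_in_cat: dict[str, set[str]] = {}
    matched_patients: set[str] = set()
    n_empty = 0
    for note in notes:
        if not note.text:
            n_empty += 1
            continue
        matches = find_matches(
            note.text, lexicon, mode=mode, note_id=note.note_id, context_chars=context_chars
        )
        if not matches:
            continue
        cats = frozenset(m.term.term_category for m in matches)
        hits.append(NoteHit(note.note_id, note.patient_id, tuple(matches), cats))
        matched_patients.add(note.patient_id)
        for cat in cats:
            patients_in_cat.setdefault(cat, set()).add(note.patient_id)
    if n_empty:
        log.info("skipped %d empty notes", n_empty)
    return SearchResult(
        hits=hits,
        patients_by_category={c: len(p) for c, p in sorted(patients_in_cat.items())},
        n_patients_matched=len(matched_patients),
        n_notes_searched=len(notes) - n_empty,
        n_empty_skipped=n_empty,
    )
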