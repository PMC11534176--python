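"""Line-delimited record formats for notes, structured records and labels.

Everything is plain text: one JSON object per line for notes and structured
records (dates ISO-8601), tab-delimited tables for labels and truth
manifests.  These are the formats the pipeline both consumes and emits, so
a run's outputs can be fed back in.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

from .cohort import StructuredRecord
from .search import ClinicalNote, NoteHit
from .synthetic import LabeledNote


def _d(s: str) -> date:
    return date.fromisoformat(s)


def write_notes(notes: list[ClinicalNote], path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in notes:
            fh.write(json.dumps({
                "note_id": n.note_id,
                "patient_id": n.patient_id,
                "date": n.date.isoformat(),
                "note_type": n.note_type,
                "text": n.text,
            }) + "\n")


def read_notes(path: str | Path) -> list[ClinicalNote]:
    notes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        r = json.loads(line)
        notes.append(ClinicalNote(r["note_id"], r["patient_id"], _d(r["date"]),
                                  r.get("note_type", ""), r.get("text", "")))
    return notes


def write_records(records: list[StructuredRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps({
                "patient_id": r.patient_id,
                "icd_events": [[c, d.isoformat()] for c, d in r.icd_events],
                "smartform_events": [[v, d.isoformat()] for v, d in r.smartform_events],
            }) + "\n")


def read_records(path: str | Path) -> list[StructuredRecord]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        r = json.loads(line)
        out.append(StructuredRecord(
            r["patient_id"],
            tuple((c, _d(d)) for c, d in r.get("icd_events", [])),
            tuple((v, _d(d)) for v, d in r.get("smartform_events", [])),
        ))
    return out


def write_truth_manifest(labeled: list[LabeledNote], path: str | Path) -> None:
    """Tab-delimited ground truth: note_id, truth_category, spans."""
    lines = ["note_id\ttruth_category\tspans"]
    for ln in labeled:
        spans = ";".join(f"{s}:{e}:{surf}" for s, e, surf in ln.truth_spans)
        lines.append(f"{ln.note.note_id}\t{ln.truth_category or 'none'}\t{spans}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_hits(hits: list[NoteHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(json.dumps({
                "note_id": h.note_id,
                "patient_id": h.patient_id,
                "categories_hit": sorted(h.categories_hit),
                "matches": [
                    {"start": m.start, "end": m.end, "matched_text": m.matched_text,
                     "term": m.term.surface, "term_category": m.term.term_category}
                    for m in h.matches
                ],
            }) + "\n")


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    lines = ["note_id\tcategory"]
    lines += [f"{nid}\t{cat}" for nid, cat in sorted(labels.items())]
    Path(path).write_text("\n".join(lines) + "\n")
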