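"""Stratified chart-review sampling: n notes per term category, one note per
patient, patients distinct across categories.

The study design draws a fixed number of notes to represent each term
category, with every sampled note coming from a different patient.  The
scheme here processes strata sequentially in the fixed order (broad,
gun_only, shooting): within a stratum it samples patients uniformly without
replacement from those eligible and not already consumed by an earlier
stratum, then samples one qualifying note uniformly per chosen patient.
Input is sorted before sampling so the plan depends only on (hits, n, seed),
not on input order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .lexicon import TERM_CATEGORIES
from .search import NoteHit


class InfeasibleSampleError(ValueError):
    """A stratum has fewer eligible distinct patients than requested."""

    def __init__(self, category: str, requested: int, available: int):
        self.category = category
        self.requested = requested
        self.available = available
        self.shortfall = requested - available
        super().__init__(
            f"category {category!r}: requested {requested} distinct patients, "
            f"only {available} eligible (shortfall {self.shortfall})"
        )


@dataclass(frozen=True)
class SamplePlan:
    """Sampled (patient_id, note_id) pairs per term category."""

    per_category: dict[str, tuple[tuple[str, str], ...]]
    seed: int

    def __post_init__(self) -> None:
        patients = [p for pairs in self.per_category.values() for p, _ in pairs]
        if len(patients) != len(set(patients)):
            raise ValueError("a patient appears more than once in the plan")

    @property
    def n_notes(self) -> int:
        return sum(len(v) for v in self.per_category.values())

    @property
    def patient_ids(self) -> set[str]:
        return {p for pairs in self.per_category.values() for p, _ in pairs}

    @property
    def note_ids(self) -> set[str]:
        return {n for pairs in self.per_category.values() for _, n in pairs}


def stratified_sample(hits: list[NoteHit], n_per_category: int, seed: int) -> SamplePlan:
    """Draw the stratified sample described above, reproducibly from ``seed``.

    Raises :class:`InfeasibleSampleError` naming the first stratum whose pool
    of not-yet-consumed eligible patients is smaller than ``n_per_category``.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")

    # patient -> category -> sorted qualifying note ids
    eligible: dict[str, dict[str, list[str]]] = {}
    for hit in sorted(hits, key=lambda h: (h.patient_id, h.note_id)):
        for cat in hit.categories_hit:
            eligible.setdefault(hit.patient_id, {}).setdefault(cat, []).append(hit.note_id)

    rng = random.Random(seed)
    taken: set[str] = set()
    plan: dict[str, tuple[tuple[str, str], ...]] = {}
    for cat in TERM_CATEGORIES:
        pool = sorted(
            pid for pid, cats in eligible.items() if cat in cats and pid not in taken
        )
        if len(pool) < n_per_category:
            raise InfeasibleSampleError(cat, n_per_category, len(pool))
        chosen = rng.sample(pool, n_per_category)
        entries = []
        for pid in sorted(chosen):
            note_id = rng.choice(eligible[pid][cat])
            entries.append((pid, note_id))
            taken.add(pid)
        plan[cat] = tuple(entries)
    return SamplePlan(per_category=plan, seed=seed)


def write_plan(plan: SamplePlan, path: str | Path) -> None:
    lines = [f"# seed: {plan.seed}", "category\tpatient_id\tnote_id"]
    for cat in TERM_CATEGORIES:
        for pid, nid in plan.per_category.get(cat, ()):
            lines.append(f"{cat}\t{pid}\t{nid}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_plan(path: str | Path) -> SamplePlan:
    seed = 0
    per_category: dict[str, list[tuple[str, str]]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("# seed:"):
            seed = int(line.split(":", 1)[1])
            continue
        if not line or line.startswith(("#", "category\t")):
            continue
        cat, pid, nid = line.split("\t")
        per_category.setdefault(cat, []).append((pid, nid))
    return SamplePlan({c: tuple(v) for c, v in per_category.items()}, seed)
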