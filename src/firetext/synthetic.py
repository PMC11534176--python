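"""Synthetic EHR corpus generator with ground-truth labels.

Real patient-level EHR data cannot be shared, so every pipeline stage is
exercised on synthetic patients instead.  The generator emulates the
statistical structure the study describes without any clinical-language
realism: structured indication records drawn from the observed
indication-source mixture (66.4% ICD / 33.3% SmartForm / 0.3% both);
free-text notes built by filling short phrase templates, one family per
context category, including the confounders that motivate the refinement
filters (provider surnames containing "gun", injectable "shot"s,
"shooting" pain, bracketed EHR template phrases, nailgun-type red herrings);
and decoy notes with no firearm term at all.  Every note carries its
ground-truth category and term spans, making the output a labeled corpus.

All names, identifiers and dates are fabricated; nothing is drawn from real
data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

from .categorize import CATEGORIES
from .cohort import StructuredRecord
from .lexicon import Lexicon, default_lexicon, find_matches
from .search import ClinicalNote

#: Observed share of exposed patients by indication source (icd, smartform, both).
DEFAULT_INDICATION_MIXTURE = (0.664, 0.333, 0.003)

#: Chart-review distribution over the seven context categories.  The three
#: small categories are only known to be below the suppression threshold and
#: to sum to 5 of 90; this fixes the 2/2/1 split.
TABLE3_COUNTS = {
    "exposure": 13,
    "assessment": 36,
    "guidance_education": 20,
    "treatment_care": 16,
    "template_shot": 2,
    "name_contains_term": 2,
    "other": 1,
}

DEFAULT_CATEGORY_MIXTURE = {k: v / 90 for k, v in TABLE3_COUNTS.items()}

#: Regex denylist the generated corpus must never match (SSN, phone, MRN-like).
PHI_DENYLIST = (
    r"\b\d{3}-\d{2}-\d{4}\b",
    r"\(\d{3}\)\s?\d{3}-\d{4}\b",
    r"\bMRN[:#]?\s*\d{6,}\b",
)

_SIDES = ("left", "right")
_SITES = ("shoulder", "thigh", "abdomen", "forearm", "calf")
_MONTHS = ("January", "March", "June", "August", "October")
_YEARS = ("2014", "2016", "2018", "2019", "2021")
_GUN_SURNAMES = ("Gunther", "Gunderson", "Gunnarson", "Gunnell")
_NOTE_TYPES = ("primary care", "behavioral health", "refill request", "nurse visit")

# One template family per truth category.  Slots are filled with synthetic
# values; each instantiated text must categorize back to its own family.
TEMPLATES: dict[str, tuple[str, ...]] = {
    "exposure": (
        "She hears gunshots outside her apartment most nights.",
        "Gunshot wound of the {side} lower leg.",
        "Pt reports he suffered a GSW to the {site} in {year}.",
        "Pt. was robbed at gunpoint last {month}.",
        "He recalls his father's friend sticking a gun in his mouth.",
        "History of gunshot injury to the {site}.",
    ),
    "assessment": (
        "No access to firearms.",
        "Do you have any guns in the home? No.",
        "Pt denies SI/HI; no guns in the house.",
        "Talks or writes about death, including talking about guns, knives or pills? No.",
        "Guns in the home. Locked up.",
        "Any access to firearms? Pt denies.",
    ),
    "guidance_education": (
        "Remove guns from the home.",
        "Make sure any guns in the home are locked up.",
        "Gun safety: education done.",
        "Keep opioids under lock and key. They are far more dangerous than blasting caps, and guns.",
        "Discussed gun safety with caregiver; education provided.",
    ),
    "treatment_care": (
        "Shooting pain all the way down the {side} leg.",
        "Shot of Hepatitis A given today.",
        "Here for dmpa shot only.",
        "Cortisone shot in {side} knee.",
        "Flu shot administered in {side} deltoid.",
    ),
    "template_shot": (
        "[Shot for Birth Control: Care Instructions.]",
        "[Flu Shot: Care Instructions.]",
    ),
    "name_contains_term": (
        "Seen by Dr. {surname} for follow-up.",
        "Appointment scheduled with Dr. {surname} next week.",
    ),
    "other": (
        "Shot a nailgun at the job site, minor injury to hand.",
        "Snap shot includes current meds/allergies/problem list.",
    ),
}

DECOY_TEMPLATES = (
    "Patient here for medication refill.",
    "Follow-up for hypertension; blood pressure well controlled.",
    "Discussed diet and exercise; labs ordered.",
    "Patient reports improved sleep with current regimen.",
    "Annual wellness visit completed; no acute concerns.",
)

_ICD_CODES = (
    "W34.00XA", "W33.00XA", "W32.0XXA", "X72.XXXA", "X74.8XXA",
    "X93.XXXA", "X95.8XXA", "Y22.XXXA", "Y24.XXXA",
)
_NOISE_ICD_CODES = ("I10", "E11.9", "Z23", "F41.1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults reproduce the study's mixtures."""

    n_patients: int = 100
    indication_mixture: tuple[float, float, float] = DEFAULT_INDICATION_MIXTURE
    notes_per_patient: tuple[int, int] = (1, 5)
    category_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIXTURE)
    )
    decoy_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(p < 0 for p in self.indication_mixture) or any(
            p < 0 for p in self.category_mixture.values()
        ):
            raise ValueError("mixture proportions must be non-negative")
        for name, total in (
            ("indication_mixture", sum(self.indication_mixture)),
            ("category_mixture", sum(self.category_mixture.values())),
        ):
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, expected 1")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must be in [0, 1]")


@dataclass(frozen=True)
class LabeledNote:
    """A synthetic note with its ground-truth category and term spans.

    ``truth_category`` is None for decoy notes containing no firearm term.
    """

    note: ClinicalNote
    truth_category: str | None
    truth_spans: tuple[tuple[int, int, str], ...]


def _rand_date(rng: random.Random, lo: date, hi: date) -> date:
    return lo + timedelta(days=rng.randrange((hi - lo).days + 1))


def _fill(template: str, rng: random.Random) -> str:
    return template.format(
        side=rng.choice(_SIDES),
        site=rng.choice(_SITES),
        month=rng.choice(_MONTHS),
        year=rng.choice(_YEARS),
        surname=rng.choice(_GUN_SURNAMES),
    )


def _make_note(
    note_id: str,
    patient_id: str,
    category: str | None,
    rng: random.Random,
    lexicon: Lexicon,
    template_index: int | None = None,
) -> LabeledNote:
    if category is None:
        templates = DECOY_TEMPLATES
    else:
        templates = TEMPLATES[category]
    idx = rng.randrange(len(templates)) if template_index is None else template_index % len(templates)
    text = _fill(templates[idx], rng)
    note = ClinicalNote(
        note_id=note_id,
        patient_id=patient_id,
        date=_rand_date(rng, date(2012, 1, 1), date(2022, 12, 31)),
        note_type=rng.choice(_NOTE_TYPES),
        text=text,
    )
    spans = tuple(
        (m.start, m.end, m.term.surface) for m in find_matches(text, lexicon, note_id=note_id)
    )
    return LabeledNote(note=note, truth_category=category, truth_spans=spans)


def _make_record(patient_id: str, source: str, rng: random.Random) -> StructuredRecord:
    icd_events: list[tuple[str, date]] = []
    sf_events: list[tuple[str, date]] = []
    if source in ("icd", "both"):
        icd_events.append(
            (rng.choice(_ICD_CODES), _rand_date(rng, date(2012, 1, 1), date(2022, 12, 31)))
        )
    if source in ("smartform", "both"):
        sf_events.append(
            (rng.choice(("recent", "historical")), _rand_date(rng, date(2022, 2, 1), date(2022, 12, 31)))
        )
    # Non-qualifying noise: benign codes anywhere, and SmartForm values that
    # miss either the value set or the window.
    if rng.random() < 0.4:
        icd_events.append(
            (rng.choice(_NOISE_ICD_CODES), _rand_date(rng, date(2012, 1, 1), date(2022, 12, 31)))
        )
    if rng.random() < 0.2:
        sf_events.append(("none", _rand_date(rng, date(2022, 2, 1), date(2022, 12, 31))))
    if rng.random() < 0.1:
        sf_events.append(("recent", _rand_date(rng, date(2021, 1, 1), date(2022, 1, 31))))
    return StructuredRecord(patient_id, tuple(icd_events), tuple(sf_events))


def generate_population(
    config: GeneratorConfig,
) -> tuple[list[StructuredRecord], list[LabeledNote]]:
    """Generate structured records and labeled notes for an exposed cohort.

    Every patient carries at least one qualifying indication (the mixture is
    over exposed patients, matching the study population), one to several
    notes, and each non-decoy note instantiates a template of its truth
    category.  Byte-identical output for identical config.
    """
    rng = random.Random(config.seed)
    lexicon = default_lexicon()
    sources = ("icd", "smartform", "both")
    cat_names = tuple(config.category_mixture)
    cat_weights = tuple(config.category_mixture[c] for c in cat_names)

    records: list[StructuredRecord] = []
    notes: list[LabeledNote] = []
    note_serial = 0
    for i in range(config.n_patients):
        pid = f"SP{i:06d}"
        source = rng.choices(sources, weights=config.indication_mixture)[0]
        records.append(_make_record(pid, source, rng))
        lo, hi = config.notes_per_patient
        for _ in range(rng.randint(lo, hi)):
            note_serial += 1
            if rng.random() < config.decoy_fraction:
                category = None
            else:
                category = rng.choices(cat_names, weights=cat_weights)[0]
            notes.append(_make_note(f"SN{note_serial:07d}", pid, category, rng, lexicon))
    return records, notes


def make_table3_fixture(seed: int) -> list[LabeledNote]:
    """Build the 90-note chart-review fixture with fixed category counts.

    Exactly 90 notes from 90 distinct synthetic patients with truth counts
    exposure 13, assessment 36, guidance_education 20, treatment_care 16,
    template_shot 2, name_contains_term 2, other 1 (the three small cells
    are known only to be under 10 and to total 5; the 2/2/1 split is this
    package's fixed choice).  Templates rotate within each category so every
    phrase family appears.  Deterministic in ``seed``.
    """
    rng = random.Random(seed)
    lexicon = default_lexicon()
    notes: list[LabeledNote] = []
    serial = 0
    for category in CATEGORIES:
        for k in range(TABLE3_COUNTS[category]):
            serial += 1
            notes.append(
                _make_note(
                    note_id=f"FN{serial:04d}",
                    patient_id=f"FP{serial:04d}",
                    category=category,
                    rng=rng,
                    lexicon=lexicon,
                    template_index=k,
                )
            )
    rng.shuffle(notes)
    return notes
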