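from datetime import date

import pytest

from firetext import ClinicalNote, default_lexicon, default_rules


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


def make_note(text: str, note_id: str = "n1", patient_id: str = "p1") -> ClinicalNote:
    return ClinicalNote(note_id, patient_id, date(2022, 6, 1), "primary care", text)


@pytest.fixture
def note_factory():
    return make_note
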