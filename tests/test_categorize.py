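"""Context categorization and refinement filters on chart-review phrases."""

import pytest

from firetext.categorize import (
    CATEGORIES,
    NoteCategory,
    apply_refinement_filters,
    categorize_match,
    categorize_note,
    refine_match,
)
from firetext.lexicon import find_matches
from firetext.search import NoteHit
from firetext.synthetic import make_table3_fixture


def matches_for(text, lexicon):
    return find_matches(text, lexicon, note_id="n1")


class TestCategorizeMatch:
    @pytest.mark.parametrize(
        "text,surface,expected",
        [
            ("Seen by Dr. Gunther today.", "gun", "name_contains_term"),
            ("cortisone shot in left knee", "shot", "treatment_care"),
            ("shooting pain all the way down", "shooting", "treatment_care"),
            ("Do you have any guns in the home? No", "gun", "assessment"),
            ("No access to firearms.", "firearm", "assessment"),
            ("Remove guns from the home.", "gun", "guidance_education"),
            ("Shot a nailgun", "shot", "other"),
            ("[Shot for Birth Control: Care Instructions.]", "shot", "template_shot"),
            ("She hears gunshots at night.", "gunshot", "exposure"),
            ("suffered a GSW.", "gsw", "exposure"),
        ],
    )
    def test_single_match_labels(self, lexicon, rules, text, surface, expected):
        matched = [m for m in matches_for(text, lexicon) if m.term.surface == surface]
        assert matched, f"no {surface!r} match in {text!r}"
        assert categorize_match(matched[0], rules) == expected


class TestCategorizeNote:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Gunshot wound of the right lower leg.", "exposure"),
            ("Remove guns from the home.", "guidance_education"),
            ("Pt. was robbed at gunpoint.", "exposure"),
            ("Here for dmpa shot only.", "treatment_care"),
            ("Guns in the home. Locked up.", "assessment"),
        ],
    )
    def test_note_labels(self, note_factory, lexicon, rules, text, expected):
        note = note_factory(text)
        assert categorize_note(note, matches_for(text, lexicon), rules).value == expected

    def test_exposure_outranks_assessment_across_matches(self, note_factory, lexicon, rules):
        # two cue sites far enough apart that each match sees only its own cue
        text = "She hears gunshots every night near the bus stop on her street." \
               + " " * 30 + "Safety screen: no guns in the home."
        note = note_factory(text)
        matches = matches_for(text, lexicon)
        labels = {categorize_match(m, rules) for m in matches}
        assert {"exposure", "assessment"} <= labels
        assert categorize_note(note, matches, rules).value == "exposure"

    def test_empty_match_list_rejected(self, note_factory, rules):
        with pytest.raises(ValueError, match="without matches"):
            categorize_note(note_factory("no terms here"), [], rules)

    def test_mutual_exclusivity_single_label(self, note_factory, lexicon, rules):
        for text in ["gun shot shooting firearm gsw", "gun safety and gunshot wound"]:
            cat = categorize_note(note_factory(text), matches_for(text, lexicon), rules)
            assert isinstance(cat, NoteCategory)
            assert cat.value in CATEGORIES


class TestRefinementFilters:
    @pytest.mark.parametrize(
        "text,surface,reason",
        [
            ("[Shot for Birth Control: Care Instructions.]", "shot", "template_phrase"),
            ("Shot of Hepatitis A.", "shot", "injection_shot"),
            ("cortisone shot in left knee", "shot", "injection_shot"),
            ("shooting pain all the way down", "shooting", "pain_shooting"),
            ("Seen by Dr. Gunther.", "gun", "proper_name"),
        ],
    )
    def test_removal_reasons(self, lexicon, rules, text, surface, reason):
        (m,) = [m for m in matches_for(text, lexicon) if m.term.surface == surface]
        assert refine_match(m, rules, lexicon) == reason

    @pytest.mark.parametrize(
        "text,surface",
        [
            ("suffered a GSW.", "gsw"),
            ("Pt. was robbed at gunpoint.", "gunpoint"),
            ("Gunshot wound of the right lower leg.", "gunshot"),
            ("shooting pain after an old gunshot wound", "shooting"),  # other firearm term present
        ],
    )
    def test_genuine_firearm_matches_kept(self, lexicon, rules, text, surface):
        (m,) = [m for m in matches_for(text, lexicon) if m.term.surface == surface]
        assert refine_match(m, rules, lexicon) is None

    def test_partition_into_kept_and_removed(self, lexicon, rules):
        texts = {
            "n1": "Shot of Hepatitis A.",
            "n2": "suffered a GSW at age 20.",
            "n3": "Seen by Dr. Gunther.",
        }
        hits = []
        for nid, text in texts.items():
            ms = find_matches(text, lexicon, note_id=nid)
            hits.append(NoteHit(nid, nid, tuple(ms), frozenset(m.term.term_category for m in ms)))
        result = apply_refinement_filters(hits, rules, lexicon)
        n_in = sum(len(h.matches) for h in hits)
        assert len(result.kept) + len(result.removed) == n_in
        assert set(result.kept).isdisjoint({m for m, _ in result.removed})

    def test_fully_removed_note_is_never_exposure(self, note_factory, lexicon, rules):
        for text in ["Shot of Hepatitis A.", "Seen by Dr. Gunther.",
                     "shooting pain all the way down"]:
            ms = matches_for(text, lexicon)
            hit = NoteHit("n1", "p1", tuple(ms), frozenset(m.term.term_category for m in ms))
            result = apply_refinement_filters([hit], rules, lexicon)
            if not result.kept:
                cat = categorize_note(note_factory(text), ms, rules)
                assert cat.value != "exposure"


def test_fixture_categories_fully_recovered(lexicon, rules):
    """The rule set recovers every ground-truth label on the 90-note fixture."""
    for ln in make_table3_fixture(seed=13):
        ms = find_matches(ln.note.text, lexicon, note_id=ln.note.note_id)
        got = categorize_note(ln.note, ms, rules).value
        assert got == ln.truth_category, ln.note.text
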