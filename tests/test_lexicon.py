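"""Lexicon loading, validation, and offset matching against a naive oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firetext.lexicon import (
    Lexicon,
    LexiconError,
    LexiconTerm,
    find_matches,
    load_lexicon,
)


def naive_scan(text: str, lexicon: Lexicon) -> set[tuple[int, int, str, str]]:
    """Independent all-positions character scan (the matching oracle)."""
    folded = text.lower()
    found = set()
    for term in lexicon.terms:
        k = len(term.surface)
        for i in range(len(text) - k + 1):
            if folded[i : i + k] == term.surface:
                found.add((i, i + k, term.surface, term.term_category))
    return found


def as_tuples(matches):
    return {(m.start, m.end, m.term.surface, m.term.term_category) for m in matches}


class TestLoadLexicon:
    def test_loads_exemplar_rows(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text(
            "firearm\tbroad\ngun\tgun_only\nshot\tshooting\n"
            "shooting\tshooting\ngunshot\tshooting\n"
        )
        lex = load_lexicon(p)
        assert len(lex.terms) == 5
        assert lex.categories == {"broad", "gun_only", "shooting"}

    def test_comma_delimited_and_comments(self, tmp_path):
        p = tmp_path / "lex.csv"
        p.write_text("# comment\nfirearm,broad\ngun,gun_only\nshot,shooting\n")
        assert len(load_lexicon(p).terms) == 3

    @pytest.mark.parametrize(
        "content,err",
        [
            ("gun\tgun_only\ngun\tgun_only\n", "duplicate"),
            ("pistol\tweapons\n", "unknown term category"),
            ("", "no terms"),
        ],
    )
    def test_rejects_invalid_files(self, tmp_path, content, err):
        p = tmp_path / "lex.tsv"
        p.write_text(content)
        with pytest.raises(LexiconError, match=err):
            load_lexicon(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_lexicon(tmp_path / "absent.tsv")

    def test_requires_all_three_categories(self):
        with pytest.raises(LexiconError, match="no terms in categories"):
            Lexicon((LexiconTerm("gun", "gun_only"),))


class TestFindMatches:
    def test_empty_text(self, lexicon):
        assert find_matches("", lexicon) == []

    def test_substring_inside_longer_token(self, lexicon):
        matches = find_matches("Pt. was robbed at gunpoint.", lexicon)
        gun = [m for m in matches if m.term.surface == "gun"]
        assert len(gun) == 1
        assert (gun[0].start, gun[0].end, gun[0].matched_text) == (18, 21, "gun")

    def test_word_boundary_suppresses_embedded_hit(self, lexicon):
        text = "Provider name includes Gunther"
        sub = find_matches(text, lexicon, mode="substring")
        assert [m.matched_text for m in sub] == ["Gun"]
        assert find_matches(text, lexicon, mode="word_boundary") == []

    def test_overlapping_terms_all_reported(self, lexicon):
        matches = find_matches("gunshot", lexicon)
        assert as_tuples(matches) == naive_scan("gunshot", lexicon)
        surfaces = {m.term.surface for m in matches}
        assert {"gun", "shot", "gunshot"} <= surfaces

    def test_sorted_by_start_then_end(self, lexicon):
        matches = find_matches("shot and gunshot wounds", lexicon)
        keys = [(m.start, m.end) for m in matches]
        assert keys == sorted(keys)

    def test_context_window_and_offsets(self, lexicon):
        text = "x" * 100 + "gun" + "y" * 100
        (m,) = [m for m in find_matches(text, lexicon) if m.term.surface == "gun"]
        assert m.start == 100 and m.end == 103
        assert m.context_window == text[40:163]
        assert m.context_window[m.start - m.context_start : m.end - m.context_start] == "gun"


TEXT_ALPHABET = "abcdefgunshotGUNSHOT .,-"


@st.composite
def text_and_lexicon(draw):
    text = draw(st.text(alphabet=TEXT_ALPHABET, max_size=500))
    words = draw(
        st.lists(
            st.text(alphabet="gunshot", min_size=1, max_size=6), min_size=1, max_size=7
        )
    )
    terms = [LexiconTerm("firearm", "broad"), LexiconTerm("gun", "gun_only"),
             LexiconTerm("shot", "shooting")]
    cats = ("broad", "gun_only", "shooting")
    for i, w in enumerate(words):
        t = LexiconTerm(w, cats[i % 3])
        if (t.surface, t.term_category) not in {(x.surface, x.term_category) for x in terms}:
            terms.append(t)
    return text, Lexicon(tuple(terms))


class TestMatcherProperties:
    @settings(max_examples=200, derandomize=True)
    @given(text_and_lexicon())
    def test_equivalence_with_naive_oracle(self, tl):
        text, lex = tl
        assert as_tuples(find_matches(text, lex)) == naive_scan(text, lex)

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet=TEXT_ALPHABET, max_size=300))
    def test_case_insensitivity(self, lexicon, text):
        lower = as_tuples(find_matches(text, lexicon))
        upper = as_tuples(find_matches(text.upper(), lexicon))
        assert lower == upper

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet=TEXT_ALPHABET, max_size=300))
    def test_adding_a_term_never_removes_matches(self, lexicon, text):
        base = as_tuples(find_matches(text, lexicon))
        grown = lexicon.with_term(LexiconTerm("sho", "shooting"))
        assert base <= as_tuples(find_matches(text, grown))
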