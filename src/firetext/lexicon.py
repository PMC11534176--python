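"""Firearm term lexicon: loading, validation, and character-offset matching.

The lexicon partitions search terms into three categories used for
firearm-exposure surveillance in clinical text: ``broad`` firearm-violence
terms (e.g. "firearm"), ``gun_only`` terms (e.g. "gun"), and ``shooting``
verbs (e.g. "shot").  Matching is case-insensitive and, by default,
substring-based: a term may match inside a longer token ("gun" inside
"gunpoint" or "Gunther").  That behaviour is deliberate — the downstream
context categorizer needs to see those hits in order to filter them — and a
``word_boundary`` mode is available when it is not wanted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

TERM_CATEGORIES = ("broad", "gun_only", "shooting")

MatchMode = Literal["substring", "word_boundary"]

#: Characters of context captured either side of a match.
DEFAULT_CONTEXT_WINDOW = 60


class LexiconError(ValueError):
    """Raised for malformed or invalid lexicon input."""


@dataclass(frozen=True)
class LexiconTerm:
    """A single lowercase search term with its category."""

    surface: str
    term_category: str

    def __post_init__(self) -> None:
        surface = self.surface.strip().lower()
        if not surface:
            raise LexiconError("lexicon term surface is empty")
        if self.term_category not in TERM_CATEGORIES:
            raise LexiconError(
                f"unknown term category {self.term_category!r}; "
                f"expected one of {TERM_CATEGORIES}"
            )
        object.__setattr__(self, "surface", surface)


@dataclass(frozen=True)
class Lexicon:
    """An immutable collection of terms covering all three categories."""

    terms: tuple[LexiconTerm, ...]
    version_label: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.terms:
            raise LexiconError("lexicon contains no terms")
        seen: set[tuple[str, str]] = set()
        for term in self.terms:
            key = (term.surface, term.term_category)
            if key in seen:
                raise LexiconError(f"duplicate lexicon row: {key}")
            seen.add(key)
        present = {t.term_category for t in self.terms}
        missing = [c for c in TERM_CATEGORIES if c not in present]
        if missing:
            raise LexiconError(f"lexicon has no terms in categories: {missing}")

    @property
    def categories(self) -> set[str]:
        return {t.term_category for t in self.terms}

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.terms]

    def with_term(self, term: LexiconTerm) -> "Lexicon":
        return Lexicon(self.terms + (term,), self.version_label)


@dataclass(frozen=True)
class TermMatch:
    """A lexicon hit at a character-offset span of a note.

    ``start``/``end`` index the original note text (0-based, end-exclusive).
    ``context_window`` is the surrounding text slice and ``context_start`` its
    offset in the note, so the match occupies
    ``context_window[start - context_start : end - context_start]``.
    """

    note_id: str
    start: int
    end: int
    matched_text: str
    term: LexiconTerm
    context_window: str
    context_start: int = 0


def _fold(text: str) -> str:
    """Lowercase ``text`` preserving character offsets.

    Characters whose lowercase form expands to several characters (rare
    outside Turkic dotted-I and ligatures) are left unchanged so that match
    offsets always index the original string.
    """
    lowered = text.lower()
    if len(lowered) == len(text):
        return lowered
    return "".join(c if len(c.lower()) != 1 else c.lower() for c in text)


def _is_word_char(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def load_lexicon(path: str | Path, version_label: str | None = None) -> Lexicon:
    """Load a two-column (term, category) delimited lexicon file.

    Columns may be separated by a tab or a comma; lines starting with ``#``
    and blank lines are ignored.  Category tokens must belong to
    ``{broad, gun_only, shooting}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lexicon file not found: {path}")
    terms: list[LexiconTerm] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) != 2:
            raise LexiconError(f"{path}:{lineno}: expected 'term<TAB>category', got {raw!r}")
        terms.append(LexiconTerm(parts[0].strip(), parts[1].strip()))
    return Lexicon(tuple(terms), version_label or path.stem)


def default_lexicon() -> Lexicon:
    """The built-in exemplar lexicon shipped with the package.

    Real deployments supply their full curated keyword list via
    :func:`load_lexicon`; this default carries the canonical exemplars of
    each category so the pipeline is runnable out of the box.
    """
    with resources.as_file(resources.files("firetext.data") / "lexicon.tsv") as p:
        return load_lexicon(p, version_label="builtin-exemplar")


def find_matches(
    text: str,
    lexicon: Lexicon,
    mode: MatchMode = "substring",
    note_id: str = "",
    context_chars: int = DEFAULT_CONTEXT_WINDOW,
) -> list[TermMatch]:
    """Return all lexicon matches in ``text``, sorted by (start, end).

    Matching is case-insensitive.  In ``substring`` mode a term matches
    anywhere, including inside longer tokens; overlapping matches from
    different terms (or the same term at different offsets) are all
    reported.  In ``word_boundary`` mode a match is kept only when not
    flanked by word characters.
    """
    if mode not in ("substring", "word_boundary"):
        raise ValueError(f"unknown match mode {mode!r}")
    if not text:
        return []
    folded = _fold(text)
    matches: list[TermMatch] = []
    for term in lexicon.terms:
        # Zero-width lookahead so overlapping occurrences are all found.
        pattern = re.compile(f"(?=({re.escape(term.surface)}))")
        for m in pattern.finditer(folded):
            start, end = m.start(), m.start() + len(term.surface)
            if mode == "word_boundary":
                if start > 0 and _is_word_char(text[start - 1]):
                    continue
                if end < len(text) and _is_word_char(text[end]):
                    continue
            ctx_start = max(0, start - context_chars)
            ctx_end = min(len(text), end + context_chars)
            matches.append(
                TermMatch(
                    note_id=note_id,
                    start=start,
                    end=end,
                    matched_text=text[start:end],
                    term=term,
                    context_window=text[ctx_start:ctx_end],
                    context_start=ctx_start,
                )
            )
    matches.sort(key=lambda m: (m.start, m.end, m.term.surface))
    return matches


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    lines = [f"# lexicon version: {lexicon.version_label}"]
    lines += [f"{t.surface}\t{t.term_category}" for t in lexicon.terms]
    Path(path).write_text("\n".join(lines) + "\n")
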