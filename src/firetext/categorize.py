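"""Rule-based context categorization of firearm keyword hits.

Chart review of keyword-matched notes shows firearm terms appearing in seven
mutually exclusive contexts: documented exposure to firearm violence or
injury; risk assessment ("do you have any guns in the home?"); anticipatory
guidance and education ("remove guns from the home"); treatment planning and
care delivery (immunization "shot", "shooting" pain); the word "shot" inside
an EHR template phrase; a keyword embedded in a proper name ("Gunther"); and
other.  This module operationalizes that review as an ordered cue-rule
engine plus the refinement filters that strip matches which do not represent
firearm violence (proper names, injectable "shot"s, "shooting" pain,
template boilerplate).

Rule order is a design choice, kept configurable: for a single match the
exclusion-like rules (name, template, other-cues, treatment) run before the
content rules because their cues are more specific; at note level *exposure*
outranks everything — any exposure evidence makes an exposure note, the
sensitivity-first convention of surveillance work.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .lexicon import Lexicon, TermMatch, default_lexicon, find_matches
from .search import ClinicalNote, NoteHit

CATEGORIES = (
    "exposure",
    "assessment",
    "guidance_education",
    "treatment_care",
    "template_shot",
    "name_contains_term",
    "other",
)

REMOVAL_REASONS = ("proper_name", "injection_shot", "pain_shooting", "template_phrase")


@dataclass(frozen=True)
class NoteCategory:
    value: str

    def __post_init__(self) -> None:
        if self.value not in CATEGORIES:
            raise ValueError(f"unknown note category {self.value!r}")


@dataclass(frozen=True)
class RuleSet:
    """Cue phrases per category, template phrases, and evaluation orders."""

    cues: dict[str, tuple[str, ...]]
    template_phrases: tuple[str, ...]
    injectable_cues: tuple[str, ...]
    precedence: tuple[str, ...]
    match_rule_order: tuple[str, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if sorted(self.precedence) != sorted(CATEGORIES):
            raise ValueError("precedence must be a permutation of the seven categories")
        bad = [c for c in self.match_rule_order if c not in CATEGORIES]
        if bad or len(set(self.match_rule_order)) != len(self.match_rule_order):
            raise ValueError(f"invalid match_rule_order entries: {bad or 'duplicates'}")


@dataclass(frozen=True)
class RefinementResult:
    kept: tuple[TermMatch, ...]
    removed: tuple[tuple[TermMatch, str], ...]


def load_rules(path: str | Path) -> RuleSet:
    """Load a rules file (YAML mapping, see the shipped default for schema)."""
    raw = yaml.safe_load(Path(path).read_text())
    cues = {cat: tuple(str(c).lower() for c in raw.get("cues", {}).get(cat, [])) for cat in CATEGORIES}
    return RuleSet(
        cues=cues,
        template_phrases=tuple(str(p).lower() for p in raw.get("template_phrases", [])),
        injectable_cues=tuple(str(c).lower() for c in raw.get("injectable_cues", [])),
        precedence=tuple(raw["precedence"]),
        match_rule_order=tuple(raw["match_rule_order"]),
        version=str(raw.get("version", "unversioned")),
    )


def default_rules() -> RuleSet:
    with resources.as_file(resources.files("firetext.data") / "rules.yaml") as p:
        return load_rules(p)


def _token_bounds(text: str, start: int, end: int) -> tuple[int, int]:
    """Expand [start, end) to the enclosing alphanumeric token."""
    lo, hi = start, end
    while lo > 0 and (text[lo - 1].isalnum() or text[lo - 1] == "_"):
        lo -= 1
    while hi < len(text) and (text[hi].isalnum() or text[hi] == "_"):
        hi += 1
    return lo, hi


def is_proper_name_hit(match: TermMatch) -> bool:
    """True when the match sits strictly inside a capitalized longer token.

    "gun" inside "Gunther" qualifies.  Two escapes keep ordinary sentence
    capitalization out: a token no longer than the term ("Gunshot" for the
    term "gunshot"), and a token that is just the term's plural ("Guns" at
    the start of "Guns in the home. Locked up.").
    """
    ctx = match.context_window
    s = match.start - match.context_start
    e = match.end - match.context_start
    lo, hi = _token_bounds(ctx, s, e)
    token = ctx[lo:hi]
    surf = match.term.surface
    if token.lower() in (surf, surf + "s", surf + "es"):
        return False
    return len(token) > len(surf) and token[:1].isupper()


def _context_folded(match: TermMatch) -> str:
    return match.context_window.lower()


def categorize_match(match: TermMatch, ruleset: RuleSet | None = None) -> str:
    """Label one match by the first rule in the rule-evaluation order that fires."""
    ruleset = ruleset or default_rules()
    ctx = _context_folded(match)
    for cat in ruleset.match_rule_order:
        if cat == "name_contains_term":
            if is_proper_name_hit(match):
                return cat
        elif cat == "template_shot":
            if any(p in ctx for p in ruleset.template_phrases):
                return cat
        else:
            if any(cue in ctx for cue in ruleset.cues.get(cat, ())):
                return cat
    return "other"


def categorize_note(
    note: ClinicalNote, matches: list[TermMatch], ruleset: RuleSet | None = None
) -> NoteCategory:
    """Assign the note its single category: the highest-precedence label
    among its matches' labels.  Deterministic; raises on an empty match list."""
    if not matches:
        raise ValueError(f"note {note.note_id}: cannot categorize without matches")
    ruleset = ruleset or default_rules()
    labels = {categorize_match(m, ruleset) for m in matches}
    for cat in ruleset.precedence:
        if cat in labels:
            return NoteCategory(cat)
    return NoteCategory("other")


def _has_other_firearm_evidence(match: TermMatch, lexicon: Lexicon) -> bool:
    """Any lexicon hit in the context window outside the match's own span?"""
    s = match.start - match.context_start
    e = match.end - match.context_start
    for m in find_matches(match.context_window, lexicon):
        if m.end <= s or m.start >= e:
            return True
    return False


def refine_match(
    match: TermMatch, ruleset: RuleSet, lexicon: Lexicon
) -> str | None:
    """Return a removal reason for a non-firearm-violence match, else None.

    Removal rules, in order: a template boilerplate phrase in context; a
    match strictly inside a capitalized longer token (proper name); "shot"
    with an injectable-medication cue in context; "shooting" with "pain" in
    context and no other firearm term nearby.
    """
    ctx = _context_folded(match)
    if any(p in ctx for p in ruleset.template_phrases):
        return "template_phrase"
    if is_proper_name_hit(match):
        return "proper_name"
    if match.term.surface == "shot" and any(c in ctx for c in ruleset.injectable_cues):
        return "injection_shot"
    if (
        match.term.surface == "shooting"
        and "pain" in ctx
        and not _has_other_firearm_evidence(match, lexicon)
    ):
        return "pain_shooting"
    return None


def apply_refinement_filters(
    hits: list[NoteHit], ruleset: RuleSet | None = None, lexicon: Lexicon | None = None
) -> RefinementResult:
    """Partition every match in ``hits`` into kept and removed-with-reason."""
    ruleset = ruleset or default_rules()
    lexicon = lexicon or default_lexicon()
    kept: list[TermMatch] = []
    removed: list[tuple[TermMatch, str]] = []
    for hit in hits:
        for match in hit.matches:
            reason = refine_match(match, ruleset, lexicon)
            if reason is None:
                kept.append(match)
            else:
                removed.append((match, reason))
    return RefinementResult(kept=tuple(kept), removed=tuple(removed))
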