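# Methods

`firetext` operationalizes a chart-review procedure for firearm-violence
exposure surveillance in ambulatory EHR data: find firearm keywords in
free-text clinical notes, decide from structured data which patients carry
an indication of exposure, draw a stratified review sample, assign each
sampled note one of seven mutually exclusive context categories with an
ordered cue-rule engine, strip keyword hits that do not represent firearm
violence, and publish only suppression-safe aggregates.

## Cohort rules

A patient has an *indication of exposure* when at least one of two criteria
holds:

- **ICD criterion** — a diagnosis/problem-list code whose normalized form
  (uppercased, dots removed) starts with a firearm external-cause prefix,
  dated inside the ICD window (default 2012-01-01 … 2022-12-31). The default
  prefix set is the conventional surveillance definition — unintentional
  W32–W34, self-harm X72–X74, assault X93–X95, undetermined Y22–Y24, legal
  intervention Y35.0 — and is a configurable parameter, not a fixed fact:
  results are code-set-dependent. Prefix matching admits 7th-character
  encounter extensions (W34.00XA).
- **SmartForm criterion** — a behavioral-health trauma-assessment field
  "exposure to gun violence" with value `recent` or `historical` (trimmed,
  case-insensitive; the two values are treated identically), dated inside
  the SmartForm window (default 2022-02-01 … 2022-12-31, opening at the
  form's deployment).

The indication *source* is `icd`, `smartform`, `both`, or `none`; sources
partition patients, and `none` patients are excluded from the cohort.

## Keyword matching

The lexicon partitions terms into `broad` (e.g. firearm), `gun_only` (gun)
and `shooting` (shot, shooting) categories. Matching is case-insensitive
and by default **substring**: "gun" matches inside "gunpoint", "nailgun"
and "Gunther". That is deliberate — the downstream categorizer and
refinement filters need to see such hits to classify or discard them — and
a `word_boundary` mode exists for stricter searches. Offsets always index
the original text; case-folding is per-character, leaving unchanged the
rare characters whose lowercase form changes length, so spans never drift.
The shipped lexicon contains only the canonical exemplar terms of each
category (firearm, gsw, gunpoint / gun / gunshot, shot, shooting); a full
curated keyword list is expected to be supplied as a two-column file.

The matcher is verified against an independent brute-force oracle (an
all-positions character scan) on randomized texts and lexicons; they must
agree exactly.

## Stratified sampling

The review sample takes `n_per_category` notes (default 30) per term
category, one note per patient, with patients distinct across categories.
The distinctness constraint does not pin down an algorithm, so the package
fixes the simplest one satisfying it: strata are processed sequentially in
the fixed order (broad, gun_only, shooting); within a stratum, patients are
sampled uniformly without replacement from those eligible and not consumed
by an earlier stratum, then one qualifying note is sampled uniformly per
patient. Input is sorted by (patient_id, note_id) first, so a plan depends
only on (hits, n, seed). A stratum that cannot be filled raises an error
naming the category and the shortfall; it is never silently relaxed.

## Context categorization

Seven mutually exclusive note categories: `exposure`, `assessment`,
`guidance_education`, `treatment_care`, `template_shot`,
`name_contains_term`, `other`. Each keyword match is labeled from its
context window (default 60 characters either side, configurable; the window
size is a package choice) by the first rule that fires, in the order: proper
name → template phrase → other-cues (nailgun, snap shot) → treatment →
guidance → assessment → exposure, falling through to `other`. Exclusion-like
rules run first because their cues are more specific; exposure is the
fallback among firearm-context cues. Cue matching is lowercase phrase
containment; the cue lists ship as an editable YAML rules file seeded from
the review's example phrases.

A note takes the highest-precedence label among its matches, with
precedence exposure > assessment > guidance_education > treatment_care >
template_shot > name_contains_term > other. Putting exposure first is the
sensitivity-first convention of surveillance: any exposure evidence makes
an exposure note. The manual review this mirrors did not state its
tie-break, so both orders are configuration, not fact. One edge case
follows from windowed labeling: when an exposure cue and an assessment cue
fall inside the *same* 60-character window, the shared context labels both
matches by the single-match rule order (assessment before exposure); the
exposure-first note precedence applies when the cues sit in separate
windows.

### Proper-name detection

A match counts as a proper-name hit when it sits strictly inside an
alphanumeric token that begins uppercase and is longer than the term
("gun" in "Gunther"). Two escapes keep ordinary sentence capitalization
out: a token no longer than the term ("Shot", "GSW"), and a token that is
just the term's plural — without the plural escape, "Guns in the home.
Locked up." (a canonical assessment phrase) would misread as a name.

### Refinement filters

Non-firearm-violence matches are removed with a machine-readable reason,
tested in order: `template_phrase` (context contains configured EHR
boilerplate such as "[Shot for Birth Control: Care Instructions.]");
`proper_name` (as above); `injection_shot` ("shot" with an
injectable-medication cue — immunization, vaccine, hepatitis, dmpa,
cortisone, birth control, flu, tetanus — in context); `pain_shooting`
("shooting" with "pain" in context and no other firearm term in the
window). Removal never mutates the hit list; kept ∪ removed equals the
input exactly. A note all of whose matches are removed is never an
exposure note.

## Synthetic corpus

No patient-level data are available, so the generator fabricates the
statistical structure the pipeline needs: indication sources drawn from the
observed mixture (66.4% ICD / 33.3% SmartForm / 0.3% both, configurable),
qualifying events dated inside the study windows plus non-qualifying noise
events (benign codes, out-of-window or `none` SmartForm values), one to
five notes per patient, 30% decoy notes containing no firearm term, and
non-decoy notes instantiated from short phrase templates — one family per
category, including the confounders that motivate the filters (gun-bearing
surnames, injectable "shot"s, shooting pain, bracketed template phrases,
nailgun red herrings). Slot fillers (body sites, months, surnames) are
synthetic; a denylist test asserts no SSN/phone/MRN-shaped strings appear.

The 90-note review fixture fixes category counts at 13 exposure /
36 assessment / 20 guidance / 16 treatment / 2 template / 2 name / 1 other;
the three small cells are known only to be under 10 and to sum to 5, and
the 2/2/1 split is this package's documented choice. Templates and cue
rules ship consistently: the categorizer recovers every fixture note's
ground-truth label, a property the test suite asserts at 100%.

What passing these tests shows is internal consistency — the rule engine
recovers labels on text drawn from its own template grammar. It does not
show performance on real clinical narrative, which has misspellings,
copy-forwarded text, section structure and negation scope the generator
deliberately does not model.

## Reporting

Aggregate tables round percents half-up (13/90 → 14%, 16/90 → 18%;
banker's rounding would differ at .5 boundaries): one decimal for
indication-source tables, integers for category tables. Any category row
with count strictly below the suppression threshold (default 10) displays
"<10" with percent "<5"; exact counts survive internally and are exported
only behind an explicit `unsafe` flag. Suppression alters display strings
only, never the underlying counts.

## Problem sizes

Tests and the acceptance script run at desk scale by design: the 90-note
fixture, populations of 500–600 synthetic patients for pipeline and
sampling checks, 5,000 patients for mixture recovery (within three binomial
standard errors), and 1,000 random instances for matcher–oracle
equivalence. The study's population-scale counts (9,598 patients, 541,823
notes, 5,489 matched patients) derive from private EHR data and are not
reproducible; the corresponding guarantees here are structural — funnel
monotonicity, mixture recovery, oracle equivalence.

## Known limitations

- Cue-phrase containment is not language understanding: paraphrases outside
  the cue lists fall to `other`, and negation is handled only insofar as
  the cue phrases encode it ("no guns").
- Substring matching over-generates by construction; the refinement
  filters, not the matcher, are responsible for precision.
- The sequential-exclusion sampling scheme is one of several designs
  satisfying the distinctness constraint; allocation of multi-category
  patients depends on stratum order.
- Copy-forwarded (duplicated) note text is not deduplicated.
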