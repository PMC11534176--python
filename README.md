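# firetext

Keyword-lexicon search and rule-based context categorization of firearm
terms in EHR clinical notes, for firearm-violence exposure surveillance.

Most firearm-violence data capture only acute injury — the ICD-coded
gunshot wound — while the broader spectrum of exposure (witnessing
violence, losing a loved one, being threatened) leaves its traces mainly in
free-text clinical notes. `firetext` implements the chart-review pipeline
used to assess that signal in ambulatory EHR data:

1. **cohort** — derive each patient's indication of exposure from
   structured data: a firearm external-cause ICD-10-CM code (prefix match
   against a configurable code set, default W32–W34, X72–X74, X93–X95,
   Y22–Y24, Y35.0, window 2012–2022) and/or a behavioral-health SmartForm
   "exposure to gun violence" value of recent/historical (window opening
   2022-02-01). Sources: `icd`, `smartform`, `both`, `none`.
2. **lexicon / search** — case-insensitive, character-offset keyword
   matching over notes with a three-category term lexicon (broad /
   gun_only / shooting), substring by default so hits inside "gunpoint",
   "nailgun" or "Gunther" are visible to the classifier.
3. **sampling** — a stratified review sample: n notes per term category
   (default 30), one note per patient, patients distinct across categories,
   reproducible from a seed.
4. **categorize** — seven mutually exclusive context categories assigned by
   ordered cue rules (exposure, assessment, guidance/education,
   treatment/care, "shot" in a template phrase, keyword inside a name,
   other), plus refinement filters that remove non-firearm-violence matches
   with a reason: proper names ("Gunther"), injectable "shot"s
   (hepatitis, dmpa, cortisone, flu, birth control), "shooting" pain, and
   EHR template boilerplate.
5. **reporting** — aggregate tables with half-up rounding and small-cell
   suppression: counts under 10 display as "<10" with percent "<5".
6. **synthetic** — a seeded generator of structured records and labeled
   notes with the study's statistical structure (indication mixture
   66.4/33.3/0.3%, template-built note text with ground-truth categories
   and spans, decoy notes), so the whole pipeline is testable without
   patient data.

See `docs/methods.md` for the rules, their rationale, and limitations.

## Worked example

```python
from pathlib import Path
from firetext import GeneratorConfig, RunConfig, generate_population, run_pipeline
from firetext import io as ftio

out = Path("demo")
out.mkdir(exist_ok=True)
records, labeled = generate_population(GeneratorConfig(n_patients=500, seed=1))
ftio.write_records(records, out / "records.jsonl")
ftio.write_notes([ln.note for ln in labeled], out / "notes.jsonl")

manifest = run_pipeline(RunConfig(
    records_path=str(out / "records.jsonl"),
    notes_path=str(out / "notes.jsonl"),
    out_dir=str(out / "run"),
    n_per_category=30,
    sampling_seed=7,
))
print(manifest["funnel"])
print((out / "run" / "category_table.txt").read_text())
```

prints the funnel — every synthetic patient carries an indication, 1,483
notes are searched, 452 patients have at least one keyword hit, and 90
notes are sampled —

```
{'patients_in_records': 500, 'patients_with_indication': 500,
 'patients_with_notes': 500, 'notes_searched': 1483,
 'patients_with_hits': 452, 'notes_sampled': 90}
```

and the suppressed category table for the 90 sampled notes:

```
Category                 %      N
exposure                30     27
assessment              33     30
guidance_education      12     11
treatment_care          20     18
template_shot           <5    <10
name_contains_term      <5    <10
other                   <5    <10
Total                  100     90
```

Each row is the share of sampled notes whose firearm keywords appear in
that context; the three small cells are suppressed for disclosure control
while exact counts remain available programmatically. The same run is
available from the shell via `firetext generate` and
`firetext run-all --config config.yaml`.

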