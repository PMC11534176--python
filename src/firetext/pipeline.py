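"""End-to-end orchestration: cohort -> notes -> search -> sample -> categorize -> report.

``run_pipeline`` mirrors the study funnel: patients with a structured
indication of firearm-violence exposure, of whom some have notes, of whom
some have keyword hits, from whom a stratified chart-review sample is drawn,
categorized and aggregated with suppression.  The run manifest echoes the
config, both seeds, and the funnel counts at every stage so a run can be
reproduced byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as ftio
from .categorize import RuleSet, categorize_note, default_rules, load_rules
from .cohort import CohortConfig, build_cohort
from .lexicon import Lexicon, default_lexicon, load_lexicon
from .reporting import category_table, indication_table
from .sampling import InfeasibleSampleError, stratified_sample, write_plan
from .search import search_corpus


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Paths, windows, seeds and knobs for one pipeline run."""

    records_path: str
    notes_path: str
    out_dir: str
    lexicon_path: str | None = None
    rules_path: str | None = None
    match_mode: str = "substring"
    n_per_category: int = 30
    sampling_seed: int = 0
    suppression_threshold: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lexicon = (
        load_lexicon(config.lexicon_path) if config.lexicon_path else default_lexicon()
    )
    rules = load_rules(config.rules_path) if config.rules_path else default_rules()

    records = _stage("read_records")(ftio.read_records)(config.records_path)
    notes = _stage("read_notes")(ftio.read_notes)(config.notes_path)

    cohort_results, mixture = _stage("cohort")(build_cohort)(records, CohortConfig())
    cohort_ids = {r.patient_id for r in cohort_results}

    cohort_notes = [n for n in notes if n.patient_id in cohort_ids]
    patients_with_notes = len({n.patient_id for n in cohort_notes})

    search_result = _stage("search")(search_corpus)(cohort_notes, lexicon, config.match_mode)
    ftio.write_hits(search_result.hits, out / "hits.jsonl")

    plan = _stage("sampling")(stratified_sample)(
        search_result.hits, config.n_per_category, config.sampling_seed
    )
    write_plan(plan, out / "sample_plan.tsv")

    note_by_id = {n.note_id: n for n in cohort_notes}
    matches_by_note = {h.note_id: list(h.matches) for h in search_result.hits}
    labels: dict[str, str] = {}
    sampled_ids = sorted(plan.note_ids)
    for nid in sampled_ids:
        cat = _stage("categorize")(categorize_note)(
            note_by_id[nid], matches_by_note[nid], rules
        )
        labels[nid] = cat.value
    ftio.write_labels(labels, out / "labels.tsv")

    from .categorize import NoteCategory

    table = _stage("report")(category_table)(
        [NoteCategory(v) for v in labels.values()], config.suppression_threshold
    )
    (out / "category_table.txt").write_text(table.to_text() + "\n")
    table.to_frame().to_csv(out / "category_table.tsv", sep="\t", index=False)

    sample_results = [r for r in cohort_results if r.patient_id in plan.patient_ids]
    pop_table, samp_table = _stage("report")(indication_table)(cohort_results, sample_results)
    (out / "indication_table.txt").write_text(
        "Population\n" + pop_table.to_text() + "\n\nSample\n" + samp_table.to_text() + "\n"
    )

    manifest = {
        "config": asdict(config),
        "seeds": {"sampling": config.sampling_seed},
        "lexicon_version": lexicon.version_label,
        "rules_version": rules.version,
        "funnel": {
            "patients_in_records": len(records),
            "patients_with_indication": len(cohort_results),
            "patients_with_notes": patients_with_notes,
            "notes_searched": search_result.n_notes_searched,
            "patients_with_hits": search_result.n_patients_matched,
            "notes_sampled": plan.n_notes,
        },
        "indication_mixture": mixture,
        "patients_by_term_category": search_result.patients_by_category,
        "category_counts": {r.label: r.count for r in table.rows},
        "category_display": {r.label: (r.display_count, r.display_percent) for r in table.rows},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
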