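"""End-to-end orchestration: generate -> cohort -> classify -> report."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .codes import default_code_lists
from .config import DEFAULT_CONFIG, StudyConfig
from .cohort import build_cohort
from .io import write_tables
from .reporting import build_report, build_switch_records, summarize_years, time_to_switch
from .response import classify
from .synth import ScenarioSpec, generate, paper_preset


def run_all(
    spec: ScenarioSpec | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    config: StudyConfig = DEFAULT_CONFIG,
) -> dict:
    """Run the full pipeline on synthetic data.

    Returns a dict with every intermediate artifact (bundle, ground truth,
    cohort, attrition, classification results, switch records, annual
    summary); when ``outdir`` is given, also writes the claim tables, the
    ground truth and all report tables there.
    """
    if spec is None:
        spec = paper_preset()
    if seed is not None:
        spec = replace(spec, rng_seed=seed)
    bundle, truth = generate(spec, config)
    cohort, attrition = build_cohort(bundle, default_code_lists(), config)
    results = classify(cohort, bundle, config)
    switches = build_switch_records(bundle, cohort)
    summary = summarize_years(bundle, cohort, results, config)
    out = {
        "spec": spec,
        "bundle": bundle,
        "truth": truth,
        "cohort": cohort,
        "attrition": attrition,
        "results": results,
        "switches": switches,
        "summary": summary,
        "time_to_switch": time_to_switch(switches),
    }
    if outdir is not None:
        outdir = Path(outdir)
        write_tables(bundle, outdir / "claims")
        truth.to_csv(outdir / "ground_truth.csv", index=False, lineterminator="\n")
        build_report(outdir / "report", bundle, cohort, attrition, results, config)
    return out
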