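"""Shared plumbing for the numbered analysis drivers: one simulated study
at the survey's conditions, cached under results/ so later steps reuse it."""

from __future__ import annotations

import json
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "simulated_survey"


def study_params(seed: int = 1):
    from polyhox.simulate import SimParams

    return SimParams(seed=seed, per_clone_error=0.0)


def load_study(seed: int = 1):
    """Simulate (or re-simulate — it is deterministic) the study inputs."""
    from polyhox.recovery import simulate_survey
    from polyhox.simulate import true_cdna

    params = study_params(seed)
    clones, panels, truth = simulate_survey(params)
    panel = panels["maternal"] + panels["paternal"]
    ref_cdna = {
        r.id.split(".")[0]: true_cdna(r, params)
        for r in panels["maternal"]
        if r.id.endswith(".m1")
    }
    return params, clones, panels, panel, ref_cdna, truth


def load_report(seed: int = 1) -> dict:
    """The consolidated pipeline report for the cached study (computed once)."""
    cache = SIM_DIR / f"report_seed{seed}.json"
    if cache.exists():
        return json.loads(cache.read_text())
    from polyhox.pipeline import PipelineConfig, analyze

    _, clones, _, panel, ref_cdna, _ = load_study(seed)
    report = analyze(
        clones["hybrid"], clones["maternal"], clones["paternal"],
        reference_panel=panel, reference_cdna_by_gene=ref_cdna,
        config=PipelineConfig(min_support=1, seed=seed),
    )
    cache.parent.mkdir(parents=True, exist_ok=True)
    cache.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
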