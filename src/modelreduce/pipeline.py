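"""End-to-end orchestration: simulate, screen, search, report.

The pipeline runs the four-stage procedure (full-model run, one-at-a-time
screening, candidate selection, Metropolis-Hastings factorial search) and
writes every report as CSV plus a JSON manifest that records the seed and
settings needed to recompute each number.
"""

from __future__ import annotations

import json
import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from .config import ReductionConfig
from .errors import ModelReduceError
from .factorial import (
    SearchResult,
    classify,
    convergence_trace,
    joint_probabilities,
    mh_search,
    replacement_probabilities,
)
from .model_core import (
    ModelSpec,
    ReplacementState,
    load_drivers,
    parse_model_spec,
    simulate,
)
from .screening import screen_all, screening_frame, select_candidates
from .skill_metrics import ObservationSet, SkillSummary, skill_summary, weighted_rss

__all__ = ["run_pipeline", "apply_replacement_set", "probability_table"]

log = logging.getLogger(__name__)


def apply_replacement_set(
    spec: ModelSpec, state: ReplacementState, drivers, obs: ObservationSet
) -> SkillSummary:
    """Skill of the model with a chosen replacement set applied.

    With the empty state this is the full model's skill; with all identified
    redundant and noise variables replaced it evaluates the "minimum model"
    analogue.
    """
    traj = simulate(spec, drivers, state)
    return skill_summary(obs, traj)


def probability_table(
    result: SearchResult,
    alpha_fractions,
    bands,
    screening_rows=None,
) -> pd.DataFrame:
    """Replacement probabilities with constants and classification labels.

    Variables dropped at screening never enter the factorial stage, so their
    replacement probability over the evaluated model set is zero; they are
    reported as contributing with a note.
    """
    table = replacement_probabilities(result, alpha_fractions)
    mid = alpha_fractions[len(alpha_fractions) // 2]
    table["constant"] = [
        result.candidates.constants[v] for v in table["variable"]
    ]
    table["classification"] = [
        classify(p, bands) for p in table[f"p_alpha_{mid:g}"]
    ]
    table["note"] = ""
    if screening_rows is not None:
        dropped = [r for r in screening_rows if r.variable not in result.candidates.names]
        extra = pd.DataFrame(
            {
                "variable": [r.variable for r in dropped],
                **{
                    f"p_alpha_{f:g}": [0.0] * len(dropped)
                    for f in alpha_fractions
                },
                "constant": [r.constant for r in dropped],
                "classification": ["contributing"] * len(dropped),
                "note": ["dropped at screening"] * len(dropped),
            }
        )
        table = pd.concat([table, extra], ignore_index=True)
    cols = (
        ["variable", "constant"]
        + [f"p_alpha_{f:g}" for f in alpha_fractions]
        + ["classification", "note"]
    )
    return table[cols]


def run_pipeline(config: ReductionConfig) -> dict:
    """Execute the full reduction procedure and write all report files.

    Returns a bundle with the in-memory stage results; report CSVs and the
    manifest land in ``config.output_dir``.  Idempotent for a fixed seed.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.search.seed,
        "settings": config.to_dict(),
        "versions": {
            "modelreduce": metadata.version("modelreduce"),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "files": [],
    }

    def _write(name: str, frame: pd.DataFrame):
        path = out / name
        frame.to_csv(path, index=False)
        manifest["files"].append(name)
        return path

    stage = "load"
    try:
        spec = parse_model_spec(Path(config.model_path).read_text())
        drivers = load_drivers(config.drivers_path)
        obs = ObservationSet(
            pd.read_csv(config.observations_path), config.se_fractions
        )

        stage = "full-model"
        log.info("stage %s: simulating full model", stage)
        full_traj = simulate(spec, drivers, ReplacementState.empty())
        rss_full = weighted_rss(obs, full_traj)
        skill = skill_summary(obs, full_traj)
        _write("skill.csv", skill.to_frame())
        manifest["rss_full"] = rss_full
        manifest["alphas"] = [f * rss_full for f in config.search.alpha_fractions]
        manifest["stages"]["full-model"] = {
            "rss_full": rss_full,
            "ns_pooled": skill.ns,
            "n_observations": len(obs),
        }

        stage = "screening"
        log.info("stage %s: start", stage)
        rows = screen_all(
            spec,
            drivers,
            obs,
            exclusions=config.exclusions,
            threshold=config.screening.threshold,
            grid_points=config.screening.grid_points,
        )
        _write("screening.csv", screening_frame(rows))
        candidates = select_candidates(rows, config.screening.threshold)
        manifest["stages"]["screening"] = {
            "n_screened": len(rows),
            "n_candidates": len(candidates),
            "threshold": config.screening.threshold,
        }
        log.info(
            "stage %s: %d screened, %d candidates", stage, len(rows), len(candidates)
        )
        if len(candidates) == 0:
            manifest["status"] = "stopped-after-screening: empty candidate set"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            log.warning("empty candidate set; pipeline stopped after screening")
            return {
                "spec": spec,
                "screening": rows,
                "candidates": candidates,
                "result": None,
                "manifest": manifest,
            }

        stage = "search"
        log.info("stage %s: start (n_unique=%d)", stage, config.search.n_unique)
        result = mh_search(spec, drivers, obs, candidates, config.search)
        manifest["stages"]["search"] = {
            "n_unique": result.n_unique,
            "n_iterations": result.n_iterations,
            "n_accepted": len(result.chain) - 1,
            "termination": result.termination,
        }

        stage = "reports"
        table = probability_table(
            result,
            config.search.alpha_fractions,
            config.report.bands,
            screening_rows=rows,
        )
        _write("probabilities.csv", table)
        if len(candidates) >= 2:
            _write(
                "joint.csv",
                joint_probabilities(
                    result,
                    config.search.alpha_fractions[config.search.driving_alpha_index],
                ),
            )
        trace = convergence_trace(
            result,
            interval=config.report.trace_interval,
            alpha_fraction=config.search.alpha_fractions[
                config.search.driving_alpha_index
            ],
        )
        _write("trace.csv", trace)
        tail = trace[trace["unique_count"] >= 0.9 * result.n_unique]
        stability = float(
            tail.groupby("variable")["probability"].agg(lambda s: s.max() - s.min()).max()
        )
        manifest["stages"]["reports"] = {"trace_tail_max_change": stability}
        manifest["status"] = "complete"
    except ModelReduceError as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete; reports in %s", out)
    return {
        "spec": spec,
        "screening": rows,
        "candidates": candidates,
        "result": result,
        "probabilities": table,
        "manifest": manifest,
    }
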