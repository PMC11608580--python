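"""End-to-end pipeline: quantify -> summarize -> infer -> randomize -> report.

Ties the stages together for a whole study, either loaded from the CSV
dialects or simulated by the generator, and serializes every result as
JSON/CSV so re-runs with the same configuration and seed are byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .coordination import (
    between_dyad_analysis,
    coordination_analysis,
    halves_analysis,
    records_table,
    window_sweep,
)
from .gaze import AOISpec, classify_frames, summaries_table, summarize_looking
from .mindedness import summarize_comments
from .randomization import randomization_test
from .streams import CameraModel, DyadSession, read_session, validate_study
from .synthetic import GeneratorConfig, generate_study

log = logging.getLogger("gazemind")


@dataclass
class RunConfig:
    """One pipeline run: either input tables or a generator configuration."""

    out_dir: Path
    frames_path: Path | None = None
    comments_path: Path | None = None
    generator: GeneratorConfig | None = None
    camera: CameraModel = field(default_factory=CameraModel)
    aoi: AOISpec = field(default_factory=AOISpec)
    geometry_mode: bool = False  # classify from gaze/polygons instead of flags
    window: float = 5.0
    sweep: tuple[float, ...] = (4.0, 5.0, 6.0)
    run_halves: bool = True
    B: int = 1000
    seed: int = 0
    shuffle_domain: str = "eligible"

    def __post_init__(self) -> None:
        has_files = self.frames_path is not None and self.comments_path is not None
        if has_files == (self.generator is not None):
            raise ValueError(
                "supply exactly one of (frames_path+comments_path) or generator"
            )


def load_sessions(config: RunConfig) -> list[DyadSession]:
    if config.generator is not None:
        return generate_study(config.generator)
    frames = pd.read_csv(config.frames_path)
    dyads = sorted(frames["dyad_id"].astype(str).unique())
    return [
        read_session(
            config.frames_path,
            config.comments_path,
            camera=config.camera,
            dyad_id=d,
        )
        for d in dyads
    ]


def _fit_dict(fit) -> dict:
    d = dataclasses.asdict(fit)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = [float(x) for x in v]
    return d


def _lrt_dict(t) -> dict:
    return {"chi2": t.chi2, "df": t.df, "p": t.p}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the report dict it also writes.

    Stages: face-looking classification (geometry or pass-through) ->
    per-dyad looking and comment summaries -> between-dyad GLM + LRT ->
    within-dyad coincidence GLMM + LRT with window sweep and halves
    contrast -> shuffle-null randomization test. Results land in
    ``out_dir`` as summaries.csv, coincidence.csv, results.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    log.info("stage 1/5: load & classify")
    sessions = load_sessions(config)
    sessions = [
        classify_frames(
            s, config.camera, config.aoi, passthrough=not config.geometry_mode
        )
        for s in sessions
    ]
    study_report = validate_study(sessions)
    for fl in study_report.flags:
        log.warning("dyad %s flagged: %s (%s)", fl.dyad_id, fl.reason, fl.value)
    report["n_sessions"] = len(sessions)
    report["flags"] = [dataclasses.asdict(fl) for fl in study_report.flags]

    log.info("stage 2/5: summaries")
    look = [summarize_looking(s) for s in sessions]
    comm = [
        summarize_comments(s.comments, dyad_id=s.dyad_id)
        for s in sessions
        if len(s.comments)
    ]
    tbl = summaries_table(look)
    ctbl = pd.DataFrame([dataclasses.asdict(c) for c in comm])
    tbl.merge(ctbl, on="dyad_id", how="left").to_csv(out / "summaries.csv", index=False)
    report["descriptives"] = {
        "mean_p_face_present": float(tbl["p_face_present"].mean()),
        "mean_p_pupil": float(tbl["p_pupil"].mean()),
        "mean_p_looking_total": float(tbl["p_looking_total"].mean()),
        "mean_p_looking_given_face_pupil": float(
            tbl["p_looking_given_face_pupil"].mean()
        ),
        "mean_n_comments": float(ctbl["n_comments"].mean()),
        "mean_prop_appropriate": float(ctbl["prop_appropriate"].mean()),
        "mean_prop_nonattuned": float(ctbl["prop_nonattuned"].mean()),
    }

    log.info("stage 3/5: between-dyad GLM")
    glm_fit, glm_lrt = between_dyad_analysis(look, comm)
    report["between_dyad"] = {"glm": _fit_dict(glm_fit), "lrt": _lrt_dict(glm_lrt)}

    log.info("stage 4/5: within-dyad coincidence GLMM")
    glmm_fit, glmm_lrt, records = coordination_analysis(sessions, window=config.window)
    records_table(records).to_csv(out / "coincidence.csv", index=False)
    report["coordination"] = {
        "window": config.window,
        "glmm": _fit_dict(glmm_fit),
        "lrt": _lrt_dict(glmm_lrt),
    }
    sweep = window_sweep(sessions, config.sweep)
    report["window_sweep"] = {
        str(w): {"effect": float(f.fixed_effects[1]), "lrt": _lrt_dict(t)}
        for w, (f, t) in sweep.items()
    }
    if config.run_halves:
        h_fit, h_lrt = halves_analysis(sessions, window=config.window)
        report["halves"] = {"glmm": _fit_dict(h_fit), "lrt": _lrt_dict(h_lrt)}

    log.info("stage 5/5: randomization test (B=%d)", config.B)
    rand = randomization_test(
        sessions,
        B=config.B,
        window=config.window,
        seed=config.seed,
        domain=config.shuffle_domain,
    )
    pd.DataFrame({"null_effect": rand.null_effects}).to_csv(
        out / "null_effects.csv", index=False
    )
    report["randomization"] = {
        "observed_effect": rand.observed_effect,
        "ci_low": rand.ci_low,
        "ci_high": rand.ci_high,
        "empirical_p": rand.empirical_p,
        "outside_ci": rand.outside_ci,
        "B": rand.B,
        "n_failed": rand.n_failed,
        "domain": rand.domain,
    }

    with open(out / "results.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if hasattr(obj, "item"):
        return obj.item()  # numpy scalars
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
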