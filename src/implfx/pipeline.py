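"""Run configuration and the end-to-end experiment runner.

A run chains any subset of the stages ``simulate-its``, ``fit-its``,
``simulate-survey``, ``fit-zoib``, ``simulate-qca`` and ``qca``; every
artifact is written under the output directory and recorded — with its
SHA-256 — in a run manifest, so that a re-run with the same configuration
can be checked for bitwise reproducibility. All randomness flows from one
root seed via named substreams per stage.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as iomod
from .errors import ConfigurationError
from .its import ITSModelConfig, analyze_panel
from .qca import analyze_qca
from .simulate import (
    ITSSimParams,
    QCASimParams,
    SurveySimParams,
    simulate_panel,
    simulate_qca,
    simulate_survey,
)
from .zoib import MultilevelSpec, fit_zoib_multilevel, rank_predictors

logger = logging.getLogger(__name__)

_STAGES = ("simulate-its", "fit-its", "simulate-survey", "fit-zoib", "simulate-qca", "qca")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Stage selection plus per-stage settings.

    ``its_units`` holds keyword dicts for :class:`ITSSimParams` (one per
    unit; seeds are filled from the run seed if omitted); the remaining
    stage configs mirror the corresponding parameter dataclasses.
    """

    stages: list[str] = field(default_factory=lambda: ["simulate-its", "fit-its"])
    seed: int = 0
    out_dir: str = "implfx-run"
    log_level: str = "INFO"
    its_units: list[dict] = field(default_factory=list)
    its_n_metrics: int = 1
    its_shared: dict = field(default_factory=dict)
    its_model: dict = field(default_factory=dict)
    survey_sim: dict = field(default_factory=dict)
    zoib_spec: dict = field(default_factory=dict)
    qca_sim: dict = field(default_factory=dict)
    qca_settings: dict = field(default_factory=dict)
    panel_csv: str | None = None
    survey_csv: str | None = None
    qca_csv: str | None = None

    def __post_init__(self):
        for st in self.stages:
            if st not in _STAGES:
                raise ConfigurationError(f"unknown stage {st!r}; choose from {_STAGES}")
        for attr in ("panel_csv", "survey_csv", "qca_csv"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{attr} references a missing file: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write the run manifest.

    Any stage failure aborts the run with the stage name; artifacts of
    completed stages are preserved on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest: dict = {
        "config": asdict(config),
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    state: dict = {}

    for stage in config.stages:
        t0 = time.time()
        try:
            arts = _run_stage(stage, config, state, out)
        except Exception as exc:
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            _write_manifest(manifest, artifacts, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        artifacts.extend(arts)
        manifest["stages"].append(
            {"name": stage, "seconds": round(time.time() - t0, 3),
             "artifacts": [p.name for p in arts]}
        )
    _write_manifest(manifest, artifacts, out)
    return manifest


def _write_manifest(manifest: dict, artifacts: list[Path], out: Path):
    manifest["outputs"] = {p.name: _sha256(p) for p in artifacts}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path) -> list[Path]:
    seed = stage_seed(config.seed, stage)
    if stage == "simulate-its":
        units = config.its_units or [
            {"n_pre": 24, "n_post": 24, "pre_intercept": 80.0, "post_intercept": 81.0,
             "pre_sd": 1.0, "post_sd": 0.7, "pre_ac": 0.3, "post_ac": 0.3}
        ]
        rng = np.random.default_rng(seed)
        params = []
        for spec in units:
            spec = dict(spec)
            spec.setdefault("seed", int(rng.integers(0, 2**31 - 1)))
            params.append(ITSSimParams(**spec))
        panel = simulate_panel(params, n_metrics=config.its_n_metrics, **config.its_shared)
        state["panel"] = panel
        return [
            iomod.write_panel(panel, out / "panel.csv"),
            iomod.write_truth(panel.truth, out / "panel_truth.yaml"),
        ]
    if stage == "fit-its":
        panel = state.get("panel")
        if panel is None:
            panel = iomod.read_panel(config.panel_csv)
        model_cfg = ITSModelConfig(**{"seed": seed, **config.its_model})
        report = analyze_panel(panel, model_cfg)
        p1 = out / "its_per_unit.csv"
        p2 = out / "its_pooled.csv"
        report.per_unit.to_csv(p1, index=False)
        report.pooled.to_csv(p2, index=False)
        state["its_report"] = report
        return [p1, p2]
    if stage == "simulate-survey":
        table = simulate_survey(SurveySimParams(**{"seed": seed, **config.survey_sim}))
        state["survey"] = table
        return [
            iomod.write_survey(table, out / "survey.csv"),
            iomod.write_truth(table.truth, out / "survey_truth.yaml"),
        ]
    if stage == "fit-zoib":
        table = state.get("survey")
        if table is None:
            table = iomod.read_survey(config.survey_csv)
        spec = MultilevelSpec(**{"seed": seed, **config.zoib_spec})
        post = fit_zoib_multilevel(table, spec)
        ranking = rank_predictors(post)
        p1 = out / "zoib_hyper_sd.csv"
        p2 = out / "zoib_ranking.csv"
        p3 = out / "zoib_diagnostics.json"
        post.hyper_sd_summary().to_csv(p1, index=False)
        ranking.levels.to_csv(p2, index=False)
        with open(p3, "w") as fh:
            json.dump(
                {
                    "divergences": post.divergences,
                    "dropped_levels": post.dropped_levels,
                    "parameters": post.diagnostics.to_dict("records"),
                },
                fh,
                indent=2,
            )
        state["zoib"] = post
        return [p1, p2, p3]
    if stage == "simulate-qca":
        qca_kwargs = dict(config.qca_sim)
        if "condition_names" in qca_kwargs:
            qca_kwargs["condition_names"] = tuple(qca_kwargs["condition_names"])
        data = simulate_qca(QCASimParams(**{"seed": seed, **qca_kwargs}))
        state["qca"] = data
        return [
            iomod.write_qca(data, out / "qca.csv"),
            iomod.write_truth(data.truth, out / "qca_truth.yaml"),
        ]
    if stage == "qca":
        data = state.get("qca")
        if data is None:
            data = iomod.read_qca(config.qca_csv)
        solution = analyze_qca(data, **config.qca_settings)
        p1 = out / "qca_solution.txt"
        p2 = out / "qca_measures.csv"
        with open(p1, "w") as fh:
            fh.write(solution.expression + "\n")
            fh.write(
                f"consistency={solution.consistency:.6f} coverage={solution.coverage:.6f}\n"
            )
        rep = solution.term_measures.copy()
        rep["kind"] = "sufficiency-term"
        nec = solution.necessity_report.copy()
        nec = nec.rename(columns={"condition": "term"})
        nec["kind"] = "necessity"
        import pandas as pd

        pd.concat([rep, nec], ignore_index=True).to_csv(p2, index=False)
        state["qca_solution"] = solution
        return [p1, p2]
    raise ConfigurationError(f"unknown stage {stage!r}")
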