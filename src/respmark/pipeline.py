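"""End-to-end reproducible pipeline: simulate -> select -> train -> evaluate.

A single master seed deterministically derives one seed per stage (a CRC of
the stage name XOR-folded into the master), so any stage can be re-run on
its own and still reproduce the full pipeline's outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .anfis import TrainConfig, model_to_dict
from .errors import InvalidParameterError
from .evaluate import compare_modes, fit_axis_models, importance_degree
from .motion_sim import simulate_study
from .selection import SelectionCriteria, selection_to_frame
from .session_io import write_session_csv

log = logging.getLogger("respmark")

MANIFEST_VERSION = 1


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32(stage) XOR master, folded below 2^31."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (master_seed & 0xFFFFFFFF)) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    n_sessions: int = 5
    duration_s: float = 60.0
    dt_s: float = 0.025
    seed: int = 0
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    train: TrainConfig = field(default_factory=TrainConfig)
    output_dir: str = "respmark_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_sessions < 2:
            raise InvalidParameterError("pipeline needs >= 2 sessions (train/test)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("criteria"), dict):
            d["criteria"] = SelectionCriteria(**d["criteria"])
        if isinstance(d.get("train"), dict):
            d["train"] = TrainConfig(**d["train"])
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seeds: dict
    outputs: dict  # stage -> list of file names
    timings_s: dict

    def to_dict(self) -> dict:
        return {
            "manifest_version": MANIFEST_VERSION,
            "respmark_version": self.version,
            "config": self.config,
            "stage_seeds": self.stage_seeds,
            "outputs": self.outputs,
            "timings_s": self.timings_s,
        }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order and write their artifacts.

    Writes the session CSVs, the scores table, the trained per-axis models
    for the CCA-selected subset, the mode-comparison report, the region
    importance ranking, and a manifest sufficient to re-run the pipeline
    identically.  Identical config implies identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: derive_seed(config.seed, s) for s in ("simulate", "train", "evaluate")}
    outputs: dict[str, list[str]] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        log.info("stage %-9s seed=%d", name, seeds.get(name, config.seed))
        return time.perf_counter()

    t0 = _stage("simulate")
    sessions = simulate_study(
        n_sessions=config.n_sessions,
        seed=seeds["simulate"],
        duration_s=config.duration_s,
        dt_s=config.dt_s,
    )
    files = []
    for i, sess in enumerate(sessions):
        p = out / f"session_{i:02d}.csv"
        write_session_csv(sess, p)
        files.extend([p.name, p.with_suffix(".yaml").name])
    outputs["simulate"] = files
    timings["simulate"] = time.perf_counter() - t0

    t0 = _stage("evaluate")
    train_cfg = dataclasses.replace(config.train, seed=seeds["train"])
    report = compare_modes(sessions, config.criteria, train_cfg)
    report.to_csv(out / "report.csv")
    ranking = importance_degree(sessions, train_config=train_cfg)
    ranking.to_csv(out / "importance.csv", index=False, float_format="%.10g")
    timings["evaluate"] = time.perf_counter() - t0
    outputs["evaluate"] = ["report.csv", "importance.csv"]

    # scores/selection table comes from compare_modes' internal selections;
    # recompute explicitly so scores.csv stands alone
    t0 = _stage("select")
    from .evaluate import _split_sessions
    from .selection import aggregate, score_all, select_markers

    train_sessions, _ = _split_sessions(sessions, train_cfg.train_fraction)
    results = [
        select_markers(aggregate(score_all(train_sessions, m)), config.criteria)
        for m in ("cca", "pca")
    ]
    selection_to_frame(results).to_csv(
        out / "scores.csv", index=False, float_format="%.10g"
    )
    outputs["select"] = ["scores.csv"]
    timings["select"] = time.perf_counter() - t0

    t0 = _stage("train")
    sel = sorted(results[0].selected) or ["M1"]
    models = fit_axis_models(train_sessions, sel, train_cfg)
    model_files = []
    for ax, model in models.items():
        p = out / f"model_{ax}.json"
        p.write_text(json.dumps(model_to_dict(model), indent=1))
        model_files.append(p.name)
    outputs["train"] = model_files
    timings["train"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        stage_seeds=seeds,
        outputs=outputs,
        timings_s=timings,
    )
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest
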