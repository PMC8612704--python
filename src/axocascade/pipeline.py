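"""Top-level pipeline: simulate -> motility -> events -> ordering report.

A single ``PipelineConfig`` (JSON-serializable, unknown keys rejected)
carries the cohort size, the cascade parameters, detection thresholds and
the master seed; every source of randomness flows from that seed, so the
same config reproduces the same outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import events, io, kymo, ordering
from .cascade import CascadeParams
from .simulate import generate_cohort

log = logging.getLogger("axocascade")


@dataclass
class PipelineConfig:
    n_axons: int = 22
    seed: int = 0
    params: CascadeParams = field(default_factory=CascadeParams)
    exclude_first_peak_window: float = 0.5
    motility_threshold_um: float = 5.0
    frame_interval_h: float = 10.0 / 60.0
    event_free: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.n_axons < 1:
            raise ValueError("n_axons must be >= 1")
        if self.motility_threshold_um <= 0:
            raise ValueError("motility_threshold_um must be positive")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        self.params.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "params" in d and isinstance(d["params"], dict):
            pd_ = dict(d["params"])
            pknown = {f.name for f in dataclasses.fields(CascadeParams)}
            punknown = set(pd_) - pknown
            if punknown:
                raise ValueError(f"unknown cascade parameter(s): {sorted(punknown)}")
            for k, v in pd_.items():
                if isinstance(v, list):
                    pd_[k] = tuple(v)
            d["params"] = CascadeParams(**pd_)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulate -> kymo -> events -> ordering and write artifacts.

    Returns the cohort report (also written as ``report.json``); trace,
    schedule, track and call tables are written alongside it.  Rerunning
    with the same config reproduces the outputs.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("simulate: n=%d seed=%d", config.n_axons, config.seed)
    cohort = generate_cohort(
        config.n_axons, config.params, config.seed, event_free=config.event_free
    )
    paths = io.write_cohort(cohort, out_dir)

    log.info("kymo: summarizing %d axons", config.n_axons)
    arrests: dict[str, Optional[float]] = {}
    for sched, bouts in zip(cohort.schedules, cohort.bouts):
        summaries = [
            kymo.summarize_bout(b, config.motility_threshold_um) for b in bouts
        ]
        post = [s for s in summaries if s.bout_start >= 0]
        arrests[sched.axon_id] = kymo.arrest_time(post) if post else None

    log.info("events: detecting on %d trace sets", len(cohort.traces))
    calls = []
    for traces in cohort.traces:
        c = events.detect_all(
            traces, exclude_first_peak_window=config.exclude_first_peak_window
        )
        c.times["mito_stop"] = arrests.get(traces.axon_id)
        calls.append(c)
    io.write_calls(calls, out_dir / "calls.tsv")

    log.info("ordering: assembling report")
    report = ordering.cohort_report(calls, frame_interval=config.frame_interval_h)
    report["config_hash"] = config.config_hash()
    report["seed"] = config.seed
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    config.to_json(out_dir / "config.json")
    log.info("done: report at %s", out_dir / "report.json")
    return report
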