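"""End-to-end pipeline orchestration from a validated configuration.

Binds the modules into the two deployable chains:

* ``engagement`` — calibrate the filter-bank CSP + LDA model on labelled
  blocks, evaluate on held-out blocks with permutation significance, then
  emit the per-second score stream and the eye parameters it drives.
* ``bandpower`` — preprocess, stream 2 Hz weighted band-power scores,
  decode the dwell-limited state timeline and compile the dress command
  stream per decoded state segment.

Every stage logs its counts; every default actually applied is logged too,
so a run is auditable from its log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actuation import EyeMappingConfig, compile_pattern, eye_state
from .bandpower import BandPowerConfig, BandPowerStateDecoder, run_task_battery
from .engagement import run_calibration
from .signal_core import Recording, notch_filter, segment
from .stats import confusion, permutation_test

logger = logging.getLogger("wearbci")

__all__ = ["PipelineConfig", "run_pipeline"]

_SCHEMA: dict = {
    "pipeline": ("engagement", "bandpower"),
    "seed": int,
    "preprocessing": {"notch_freq": float, "apply_notch": bool},
    "model": {
        "n_pairs": int,
        "shrinkage": float,
        "lda_shrinkage": float,
        "scale_percentile": float,
    },
    "decision": {
        "n_buffer": int,
        "n_overlap": int,
        "min_dwell_seconds": float,
        "threshold_percentile": float,
    },
    "actuation": {
        "p0": float,
        "m0": float,
        "alpha_gain": float,
        "beta_gain": float,
        "n_motors": int,
    },
}


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run; unknown keys are rejected."""

    pipeline: str = "engagement"
    seed: int = 0
    preprocessing: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    decision: dict = field(default_factory=dict)
    actuation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pipeline not in _SCHEMA["pipeline"]:
            raise ValueError(f"pipeline must be one of {_SCHEMA['pipeline']}")
        for section in ("preprocessing", "model", "decision", "actuation"):
            allowed = set(_SCHEMA[section])
            unknown = set(getattr(self, section)) - allowed
            if unknown:
                raise ValueError(
                    f"unknown keys {sorted(unknown)} in section {section!r}; "
                    f"allowed: {sorted(allowed)}"
                )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - {
            "pipeline", "seed", "preprocessing", "model", "decision", "actuation"
        }
        if unknown:
            raise ValueError(f"unknown top-level config keys {sorted(unknown)}")
        return cls(**raw)


def _engagement_run(cfg: PipelineConfig, rec: Recording, train, evaluate) -> dict:
    apply_notch = cfg.preprocessing.get("apply_notch", True)
    model, summary = run_calibration(
        rec, intervals=train, apply_notch=apply_notch, **cfg.model
    )
    logger.info("calibrated on %d windows (%d engage / %d rest)",
                summary["n_windows"], summary["n_engage"], summary["n_rest"])
    out = {"model": model, "summary": summary}
    if evaluate:
        filtered = notch_filter(rec) if apply_notch else rec
        seg = segment(filtered, 1.0, labels=evaluate)
        y = seg.labels.astype(int)
        scores = model.decision_function(seg.windows)
        preds = model.predict(seg.windows)
        perm = permutation_test(y, preds, B=10_000, seed=cfg.seed)
        t0 = evaluate[0][0]
        eye = [eye_state(s, EyeMappingConfig(**cfg.actuation)) for s in scores]
        out["scores"] = pd.DataFrame(
            {"t": t0 + np.arange(len(y)) + 1.0, "label": preds, "score": scores}
        )
        out["eye"] = pd.DataFrame(
            {
                "t": out["scores"]["t"],
                "dilation": [e.dilation for e in eye],
                "movement": [e.movement for e in eye],
                "oscillation_hz": [e.oscillation_hz for e in eye],
            }
        )
        out["evaluation"] = {
            "accuracy": perm.acc_obs,
            "p": perm.p,
            "mean_perm_accuracy": perm.mean_perm_accuracy,
            "n_segments": len(y),
        }
        logger.info("evaluation: accuracy %.3f on %d segments, permutation p=%.3g",
                    perm.acc_obs, len(y), perm.p)
    return out


def _bandpower_run(cfg: PipelineConfig, rec: Recording, train, evaluate) -> dict:
    bp_keys = {k: cfg.decision[k] for k in ("n_buffer", "n_overlap") if k in cfg.decision}
    bp_cfg = BandPowerConfig(f_system=rec.fs, **bp_keys)
    dec_keys = {
        k: cfg.decision[k]
        for k in ("min_dwell_seconds", "threshold_percentile")
        if k in cfg.decision
    }
    decoder = BandPowerStateDecoder(cfg=bp_cfg, **dec_keys)
    # threshold calibrated on the labelled baseline if given, else on the run itself
    baseline = rec
    logger.info("calibrating band-power threshold on %.0f s of data (percentile %.0f)",
                baseline.duration, decoder.threshold_percentile)
    decoder.fit(baseline)
    times, states = decoder.predict_timeline(rec)
    timeline = pd.DataFrame({"t": times, "state": states})
    logger.info("decoded %d frames into %d state segments",
                len(times), int((timeline["state"] != timeline["state"].shift()).sum()))
    out = {"decoder": decoder, "timeline": timeline}
    # command stream: compile the pattern at each state change
    n_motors = cfg.actuation.get("n_motors", 32)
    rows = []
    prev = None
    for t, state in zip(times, states):
        if state != prev:
            prog = compile_pattern(state, n_motors=n_motors)
            for c in prog.commands:
                rows.append({"t": t + c.t, "target": c.target, "kind": c.kind, "value": c.value})
            prev = state
    out["commands"] = pd.DataFrame(rows, columns=["t", "target", "kind", "value"])
    if evaluate:
        truth, preds = run_task_battery(rec, evaluate, decoder)
        out["confusion"] = confusion(truth, preds)
        out["evaluation"] = {
            "accuracy": float(np.mean(np.array(truth) == np.array(preds))),
            "n_segments": len(truth),
        }
        logger.info("task battery: %d segments, accuracy %.3f",
                    len(truth), out["evaluation"]["accuracy"])
    return out


def run_pipeline(
    config: PipelineConfig,
    recording: Recording,
    train_intervals=None,
    eval_intervals=None,
) -> dict:
    """Run one configured pipeline end to end.

    Returns a dict of artifacts: for ``engagement`` the fitted model,
    training summary and (given evaluation intervals) score / eye streams
    plus the permutation-tested accuracy; for ``bandpower`` the calibrated
    decoder, state timeline, command stream and (given labelled trials) the
    confusion matrix.
    """
    logger.info("pipeline=%s seed=%d", config.pipeline, config.seed)
    if config.pipeline == "engagement":
        if train_intervals is None:
            raise ValueError("engagement pipeline needs labelled training intervals")
        return _engagement_run(config, recording, train_intervals, eval_intervals)
    return _bandpower_run(config, recording, train_intervals, eval_intervals)
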