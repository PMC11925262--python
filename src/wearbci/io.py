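"""Readers and writers: recordings, labels, models and command streams.

The canonical on-disk recording format is a CSV (one column per channel,
header row = channel labels) with a JSON sidecar holding the sampling rate
and optional montage structure; this round-trips losslessly.  EDF files can
additionally be *read* when mne is installed.  Engagement models serialise
to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .actuation import ActuationProgram
from .engagement import EngagementClassifier
from .signal_core import BandDefinition, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "read_intervals",
    "write_intervals",
    "save_model",
    "load_model",
    "write_commands",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV + JSON sidecar (same stem, ``.json``)."""
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(path, index=False)
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "grid_of_channel": None
        if rec.grid_of_channel is None
        else rec.grid_of_channel.tolist(),
        "region_of_grid": None
        if rec.region_of_grid is None
        else {str(k): v for k, v in rec.region_of_grid.items()},
    }
    _sidecar(path).write_text(json.dumps(meta))


def _read_csv_recording(path: Path) -> Recording:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar} (field 'fs' required)")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"{sidecar}: missing required field 'fs'")
    df = pd.read_csv(path, float_precision="round_trip")
    labels = meta.get("channel_labels") or list(df.columns)
    if list(df.columns) != list(labels):
        raise ValueError(
            f"{path}: CSV header {list(df.columns)} does not match "
            f"sidecar channel_labels {list(labels)}"
        )
    region = meta.get("region_of_grid")
    return Recording(
        data=df.to_numpy().T,
        fs=float(meta["fs"]),
        channel_labels=list(labels),
        grid_of_channel=meta.get("grid_of_channel"),
        region_of_grid=None if region is None else {int(k): v for k, v in region.items()},
    )


def _read_edf_recording(path: Path) -> Recording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires mne (pip install mne)") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # mne loads volts; recordings are in µV
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording from CSV+JSON (or EDF, read-only, via mne)."""
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_edf_recording(path)
    if fmt == "csv":
        return _read_csv_recording(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_intervals(intervals, path: str | Path) -> None:
    """Labelled intervals as CSV with columns start_s, end_s, label."""
    pd.DataFrame(intervals, columns=["start_s", "end_s", "label"]).to_csv(path, index=False)


def read_intervals(path: str | Path, numeric_labels: bool = False) -> list[tuple]:
    df = pd.read_csv(path)
    for col in ("start_s", "end_s", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    labels = df["label"].astype(int) if numeric_labels else df["label"]
    return list(zip(df["start_s"].astype(float), df["end_s"].astype(float), labels))


def save_model(model: EngagementClassifier, path: str | Path) -> None:
    """Serialise a fitted engagement model (bands, filters, LDA, scale)."""
    payload = {
        "params": {
            k: v for k, v in model.get_params().items() if k != "bands"
        },
        "bands": [[b.name, b.lo, b.hi] for b in model.bands],
        "csp_filters": [W.tolist() for W in model.csp_.filters_],
        "classes": model.classes_.tolist(),
        "lda_weights": model.lda_weights_.tolist(),
        "lda_bias": model.lda_bias_,
        "score_scale": model.score_scale_,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> EngagementClassifier:
    payload = json.loads(Path(path).read_text())
    bands = tuple(BandDefinition(n, lo, hi) for n, lo, hi in payload["bands"])
    model = EngagementClassifier(bands=bands, **payload["params"])
    from .engagement import FilterBankCSP  # avoid import cycle at module load

    csp = FilterBankCSP(
        fs=model.fs,
        bands=bands,
        n_pairs=model.n_pairs,
        shrinkage=model.shrinkage,
        filter_order=model.filter_order,
        var_floor=model.var_floor,
    )
    csp.filters_ = [np.array(W) for W in payload["csp_filters"]]
    csp.classes_ = np.array(payload["classes"])
    model.csp_ = csp
    model.classes_ = csp.classes_
    model.lda_weights_ = np.array(payload["lda_weights"])
    model.lda_bias_ = float(payload["lda_bias"])
    model.score_scale_ = float(payload["score_scale"])
    return model


def write_commands(program: ActuationProgram, path: str | Path) -> None:
    """Actuation program as CSV with columns t, target, kind, value."""
    rows = [
        {
            "t": c.t,
            "target": c.target,
            "kind": c.kind,
            "value": c.value if c.kind == "servo_angle" else "#%02x%02x%02x" % c.value,
        }
        for c in program.commands
    ]
    pd.DataFrame(rows, columns=["t", "target", "kind", "value"]).to_csv(path, index=False)
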