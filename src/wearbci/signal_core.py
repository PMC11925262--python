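"""Core EEG containers and preprocessing operators shared by both pipelines.

The two wearables consume very different montages (a 4-channel dry-electrode
headband at 250 Hz and a 1,024-channel ultra-high-density grid system at
256 Hz) but share the same preprocessing vocabulary: causal Butterworth
filtering, bad-channel screening, common average referencing and
fixed-length segmentation.  Everything here is real-time-compatible, i.e.
filters are causal IIR (no zero-phase filtering, which would require future
samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "BandDefinition",
    "SegmentedWindows",
    "THETA",
    "ALPHA",
    "BETA",
    "notch_filter",
    "bandpass_filter",
    "detect_bad_channels",
    "common_average_reference",
    "segment",
]


@dataclass
class Recording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel.
    grid_of_channel : ndarray of int, optional
        Electrode-grid index per channel (ultra-high-density montages group
        16 electrodes per diamond-shaped grid).
    region_of_grid : dict, optional
        Map grid index -> neuroanatomical region, one of ``frontal``,
        ``occipital``, ``precentral``, ``postcentral``, ``other``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    grid_of_channel: np.ndarray | None = None
    region_of_grid: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if self.grid_of_channel is not None:
            self.grid_of_channel = np.asarray(self.grid_of_channel, dtype=int)
            if self.grid_of_channel.shape != (self.n_channels,):
                raise ValueError("grid_of_channel must have one entry per channel")
            if self.region_of_grid is not None:
                missing = set(np.unique(self.grid_of_channel)) - set(self.region_of_grid)
                if missing:
                    raise ValueError(f"region_of_grid misses grids {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording carrying new sample data."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, e.g. theta 4-8 Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"need 0 < lo < hi, got [{self.lo}, {self.hi}]")

    def validate_for(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name} [{self.lo}, {self.hi}] Hz exceeds Nyquist ({fs / 2} Hz)"
            )


# Canonical EEG rhythm bands used by the state decoder.  Theta indexes calm /
# meditative states, alpha relaxed wakefulness, beta alertness and stress.
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 12.0, 35.0)


@dataclass
class SegmentedWindows:
    """Fixed-length, non-overlapping labelled windows cut from a recording."""

    windows: np.ndarray  # (n_windows, n_channels, n_window_samples)
    labels: np.ndarray  # (n_windows,)
    window_seconds: float
    fs: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_windows, n_channels, n_samples)")
        if len(self.labels) != len(self.windows):
            raise ValueError("one label per window required")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]


def _butter_sos(order: int, Wn, btype: str, fs: float) -> np.ndarray:
    """Butterworth SOS with `order` = overall filter order.

    scipy's ``butter(N, btype='bandpass'|'bandstop')`` returns a filter of
    order 2N; the ``order`` argument here always names the final order, so a
    "4th-order Butterworth notch" is ``order=4``.
    """
    if btype in ("bandpass", "bandstop"):
        if order % 2:
            raise ValueError(f"{btype} order must be even, got {order}")
        N = order // 2
    else:
        N = order
    return sps.butter(N, Wn, btype=btype, fs=fs, output="sos")


def notch_filter(
    rec: Recording, freq: float = 50.0, order: int = 4, bandwidth: float = 4.0
) -> Recording:
    """Causal Butterworth band-stop removing mains interference.

    Realised as an ``order``-order band-stop over ``freq +/- bandwidth/2``
    (default 48-52 Hz), applied causally per channel.

    Raises
    ------
    ValueError
        If ``freq`` is at or above the Nyquist frequency.
    """
    nyq = rec.fs / 2
    if freq >= nyq:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist {nyq} Hz")
    lo, hi = freq - bandwidth / 2, freq + bandwidth / 2
    if lo <= 0 or hi >= nyq:
        raise ValueError(f"notch band [{lo}, {hi}] Hz invalid for fs={rec.fs}")
    sos = _butter_sos(order, [lo, hi], "bandstop", rec.fs)
    return rec.with_data(sps.sosfilt(sos, rec.data, axis=1))


def bandpass_filter(rec: Recording, band: BandDefinition, order: int = 4) -> Recording:
    """Causal Butterworth band-pass restricted to ``band``."""
    band.validate_for(rec.fs)
    sos = _butter_sos(order, [band.lo, band.hi], "bandpass", rec.fs)
    return rec.with_data(sps.sosfilt(sos, rec.data, axis=1))


def bandpass_array(x: np.ndarray, band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    """Band-pass a bare array along its last axis (helper for window data)."""
    band.validate_for(fs)
    sos = _butter_sos(order, [band.lo, band.hi], "bandpass", fs)
    return sps.sosfilt(sos, x, axis=-1)


def detect_bad_channels(
    rec: Recording,
    amp_limit: float = 200.0,
    flat_limit: float = 0.1,
    block_seconds: float = 10.0,
) -> set[int]:
    """Flag channels that rail or flat-line.

    A documented stand-in for proprietary online signal-quality scoring: the
    recording is cut into ``block_seconds`` blocks and a channel is flagged if
    in any block its peak absolute amplitude exceeds ``amp_limit`` (µV) or its
    standard deviation falls below ``flat_limit`` (µV).  Deterministic and
    invariant to channel ordering.
    """
    if amp_limit <= 0 or flat_limit <= 0:
        raise ValueError("limits must be positive")
    block = max(1, int(round(block_seconds * rec.fs)))
    bad: set[int] = set()
    for start in range(0, rec.n_samples, block):
        seg = rec.data[:, start : start + block]
        peak = np.abs(seg).max(axis=1)
        sd = seg.std(axis=1)
        bad |= set(np.flatnonzero((peak > amp_limit) | (sd < flat_limit)).tolist())
    return bad


def common_average_reference(rec: Recording, exclude: set[int] | None = None) -> Recording:
    """Re-reference every channel to the mean of the good channels.

    Channels in ``exclude`` (e.g. flagged by :func:`detect_bad_channels`) do
    not contribute to the average but are still re-referenced to it, so their
    samples remain on a comparable scale for inspection.
    """
    exclude = set() if exclude is None else set(exclude)
    included = [i for i in range(rec.n_channels) if i not in exclude]
    if not included:
        raise ValueError("cannot reference: every channel is excluded")
    avg = rec.data[included].mean(axis=0, keepdims=True)
    return rec.with_data(rec.data - avg)


def segment(
    rec: Recording,
    window_seconds: float = 1.0,
    labels: list[tuple[float, float, object]] | None = None,
) -> SegmentedWindows:
    """Cut a recording into non-overlapping fixed-length windows.

    Parameters
    ----------
    rec : Recording
    window_seconds : float
        Window duration; ``window_seconds * fs`` must be a whole number of
        samples.
    labels : list of (start_s, end_s, label), optional
        Half-open labelled intervals ``[start, end)`` in seconds.  Windows are
        tiled within each interval and carry its label; trailing partial
        windows are dropped.  Without labels the whole recording is tiled and
        every window is labelled ``None``.
    """
    n_win = window_seconds * rec.fs
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError(
            f"window of {window_seconds} s is not a whole number of samples at fs={rec.fs}"
        )
    n_win = int(round(n_win))
    if n_win > rec.n_samples:
        raise ValueError("window longer than recording")
    if labels is None:
        labels = [(0.0, rec.duration, None)]

    wins, labs = [], []
    for start_s, end_s, lab in labels:
        i0 = int(round(start_s * rec.fs))
        i1 = min(int(round(end_s * rec.fs)), rec.n_samples)
        for w0 in range(i0, i1 - n_win + 1, n_win):
            wins.append(rec.data[:, w0 : w0 + n_win])
            labs.append(lab)
    if not wins:
        raise ValueError("no complete window fits the labelled intervals")
    return SegmentedWindows(
        windows=np.stack(wins), labels=np.array(labs), window_seconds=window_seconds, fs=rec.fs
    )
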