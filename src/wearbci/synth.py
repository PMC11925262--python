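"""Synthetic EEG with state-dependent band-power structure.

No recordings ship with the package, so every pipeline stage is exercised
on simulated sessions instead.  Each labelled block is a sum of

* band-limited oscillations — constant-amplitude sinusoids at the band's
  centre frequency whose phase random-walks slowly (a phase-diffusing
  oscillator, linewidth set by the diffusion rate), independently per block
  and channel — placed on channels by region (or per channel for the
  4-channel headband),
* pink (1/f) background noise of configurable standard deviation, and
* an optional common 50 Hz mains component.

This emulates what the decoders actually consume — band-power contrasts
between conditions — not the biophysics of real EEG (no artifacts beyond
mains, no non-stationarity, no volume conduction).  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import ALPHA, BETA, THETA, BandDefinition, Recording

__all__ = [
    "Montage",
    "StateSpec",
    "SessionPlan",
    "default_uhd_montage",
    "headband_montage",
    "default_state_specs",
    "generate_recording",
    "generate_engagement_session",
    "generate_task_battery",
]

# region layout of the default 64-grid montage (grids, not channels)
DEFAULT_REGION_COUNTS = {
    "frontal": 16,
    "occipital": 12,
    "precentral": 8,
    "postcentral": 8,
    "other": 20,
}


@dataclass(frozen=True)
class Montage:
    """Channel labels plus grid/region structure of a recording setup."""

    channel_labels: tuple[str, ...]
    fs: float
    grid_of_channel: tuple[int, ...] | None = None
    region_of_grid: dict[int, str] | None = None

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def region_of_channel(self, ch: int) -> str:
        if self.grid_of_channel is None or self.region_of_grid is None:
            return "other"
        return self.region_of_grid[self.grid_of_channel[ch]]


def default_uhd_montage(
    region_counts: dict[str, int] | None = None,
    channels_per_grid: int = 16,
    fs: float = 256.0,
) -> Montage:
    """The 64-grid, 1,024-channel ultra-high-density montage.

    Grids are assigned to regions in blocks (16 frontal, 12 occipital, 8
    precentral, 8 postcentral, 20 other by default); pass ``region_counts``
    to scale the montage down for quick experiments.
    """
    region_counts = dict(region_counts or DEFAULT_REGION_COUNTS)
    region_of_grid: dict[int, str] = {}
    g = 0
    for region, count in region_counts.items():
        for _ in range(count):
            region_of_grid[g] = region
            g += 1
    n_grids = g
    grid_of_channel = tuple(gi for gi in range(n_grids) for _ in range(channels_per_grid))
    labels = tuple(
        f"G{gi:02d}E{e:02d}" for gi in range(n_grids) for e in range(channels_per_grid)
    )
    return Montage(labels, fs, grid_of_channel, region_of_grid)


def headband_montage(fs: float = 250.0) -> Montage:
    """The 4-channel dry-electrode headband over the occipital region."""
    return Montage(
        ("O1", "O2", "PO7", "PO8"),
        fs,
        grid_of_channel=(0, 0, 0, 0),
        region_of_grid={0: "occipital"},
    )


@dataclass(frozen=True)
class StateSpec:
    """Spectral recipe of one mental state.

    ``amplitudes`` maps a band to either a scalar (µV on every channel), a
    dict region -> µV, or a per-channel sequence of µV.
    """

    name: str
    amplitudes: dict[BandDefinition, object] = field(default_factory=dict)
    noise_sd: float = 5.0
    pink_exponent: float = 1.0
    line_noise_amp: float = 0.0
    # phase random-walk rate of the oscillators, rad^2/s; keeps channel
    # phases decorrelated within a block (a fixed phase would imprint a
    # block-specific cross-channel covariance no real rhythm has)
    phase_diffusion: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def channel_amplitudes(self, band: BandDefinition, montage: Montage) -> np.ndarray:
        spec = self.amplitudes.get(band, 0.0)
        n = montage.n_channels
        if isinstance(spec, dict):
            amps = np.array([spec.get(montage.region_of_channel(c), 0.0) for c in range(n)])
        else:
            amps = np.broadcast_to(np.asarray(spec, dtype=float), (n,)).copy()
        if (amps < 0).any():
            raise ValueError(f"negative amplitude in state {self.name!r}")
        return amps


@dataclass(frozen=True)
class SessionPlan:
    """Ordered labelled blocks making up one simulated session."""

    blocks: tuple[tuple[str, float], ...]
    montage: Montage

    def __post_init__(self) -> None:
        if any(dur <= 0 for _, dur in self.blocks):
            raise ValueError("block durations must be positive")

    @property
    def intervals(self) -> list[tuple[float, float, str]]:
        out, t = [], 0.0
        for state, dur in self.blocks:
            out.append((t, t + dur, state))
            t += dur
        return out

    @property
    def total_seconds(self) -> float:
        return sum(d for _, d in self.blocks)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit standard deviation."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_recording(
    plan: SessionPlan,
    specs: dict[str, StateSpec],
    seed: int | np.random.Generator = 0,
) -> tuple[Recording, list[tuple[float, float, str]]]:
    """Simulate a session and return it with its labelled intervals."""
    for state, _ in plan.blocks:
        if state not in specs:
            raise KeyError(f"no StateSpec for planned state {state!r}")
    rng = np.random.default_rng(seed)
    m = plan.montage
    fs = m.fs
    chunks = []
    for state, dur in plan.blocks:
        spec = specs[state]
        n = int(round(dur * fs))
        t = np.arange(n) / fs
        block = np.zeros((m.n_channels, n))
        for band in spec.amplitudes:
            amps = spec.channel_amplitudes(band, m)
            if not amps.any():
                continue
            f0 = (band.lo + band.hi) / 2.0
            phases = rng.uniform(0, 2 * np.pi, size=m.n_channels)[:, None]
            if spec.phase_diffusion > 0:
                steps = rng.standard_normal((m.n_channels, n))
                phases = phases + np.cumsum(
                    np.sqrt(spec.phase_diffusion / fs) * steps, axis=1
                )
            block += amps[:, None] * np.sin(2 * np.pi * f0 * t[None, :] + phases)
        if spec.noise_sd > 0:
            block += spec.noise_sd * _pink_noise(rng, (m.n_channels, n), spec.pink_exponent)
        if spec.line_noise_amp > 0:
            block += spec.line_noise_amp * np.sin(
                2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
            )
        chunks.append(block)
    rec = Recording(
        data=np.concatenate(chunks, axis=1),
        fs=fs,
        channel_labels=list(m.channel_labels),
        grid_of_channel=None if m.grid_of_channel is None else np.array(m.grid_of_channel),
        region_of_grid=m.region_of_grid,
    )
    return rec, plan.intervals


# ---------------------------------------------------------------------------
# Engagement (headband) sessions


def generate_engagement_session(
    effect_size: float = 2.0,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 5.0,
    base_alpha_amp: float = 8.0,
    engage_amp: float = 5.0,
    engage_band: BandDefinition = BandDefinition("engage", 6.0, 10.0),
    line_noise_amp: float = 2.0,
    block_seconds: float = 60.0,
) -> tuple[Recording, list, list]:
    """Calibration + evaluation session for the engagement decoder.

    Structure: four alternating 1-min calibration blocks (task, rest, task,
    rest — 4 min total) followed by an identically structured evaluation
    run whose 240 one-second segments (120 per class) mirror the deployed
    protocol.  The engaged state adds a 6-10 Hz oscillation of amplitude
    ``effect_size * engage_amp`` µV on the first two channels on top of the
    shared occipital alpha background; ``effect_size = 0`` makes the two
    conditions statistically identical.

    Returns
    -------
    (recording, train_intervals, eval_intervals)
        Intervals carry labels +1 (task) / -1 (rest).
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    m = headband_montage()
    rest = StateSpec(
        "rest",
        amplitudes={ALPHA: base_alpha_amp},
        noise_sd=noise_sd,
        line_noise_amp=line_noise_amp,
    )
    engage = StateSpec(
        "engage",
        amplitudes={
            ALPHA: base_alpha_amp,
            engage_band: np.array([1.0, 1.0, 0.0, 0.0]) * effect_size * engage_amp,
        },
        noise_sd=noise_sd,
        line_noise_amp=line_noise_amp,
    )
    order = ["engage", "rest", "engage", "rest"]
    plan = SessionPlan(tuple((s, block_seconds) for s in order * 2), m)
    rec, intervals = generate_recording(plan, {"rest": rest, "engage": engage}, seed)
    numeric = [(a, b, 1 if s == "engage" else -1) for a, b, s in intervals]
    half = len(order)
    return rec, numeric[:half], numeric[half:]


# ---------------------------------------------------------------------------
# Task-battery (grid montage) sessions


def default_state_specs(
    active_amp: float = 12.0,
    background_amp: float = 4.0,
    noise_sd: float = 5.0,
    line_noise_amp: float = 2.0,
) -> dict[str, StateSpec]:
    """Spectral recipes for the three task states plus an idle baseline.

    Each task state raises its namesake band to ``active_amp`` µV over the
    whole scalp while the other bands sit at ``background_amp``; idle keeps
    every band at background level.
    """
    def spec(name, active=None):
        amps = {THETA: background_amp, ALPHA: background_amp, BETA: background_amp}
        if active is not None:
            amps[active] = active_amp
        return StateSpec(name, amplitudes=amps, noise_sd=noise_sd, line_noise_amp=line_noise_amp)

    return {
        "theta": spec("theta", THETA),
        "alpha": spec("alpha", ALPHA),
        "beta": spec("beta", BETA),
        "idle": spec("idle"),
    }


def generate_task_battery(
    n_trials_per_state: int = 20,
    trial_seconds: float = 60.0,
    seed: int | np.random.Generator = 0,
    montage: Montage | None = None,
    specs: dict[str, StateSpec] | None = None,
    states: tuple[str, ...] = ("theta", "alpha", "beta"),
) -> tuple[Recording, list[tuple[float, float, str]]]:
    """Simulate the three-state task battery (20 x 1-min trials per state).

    Trials are interleaved theta, alpha, beta, theta, ... so every state is
    spread across the session.  Pass a scaled-down montage (e.g.
    ``default_uhd_montage(region_counts=...)`` with fewer grids) and fewer
    trials for quick runs; the full default battery is 60 minutes of
    1,024-channel data.
    """
    montage = montage or default_uhd_montage()
    specs = specs or default_state_specs()
    blocks = tuple(
        (state, trial_seconds) for _ in range(n_trials_per_state) for state in states
    )
    plan = SessionPlan(blocks, montage)
    return generate_recording(plan, specs, seed)
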