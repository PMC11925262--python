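"""Score-to-eye mapping and the dress motor/LED pattern compiler.

Hardware-free actuation: instead of driving UDP-connected displays or a
serial servo controller, these functions emit the exact parameter and
command streams the hardware would consume.

Eyes (engagement dress): the signed score s in [-10, +10] maps affinely to
pupil dilation and horizontal movement,

    P_dilation(s) = P0 + alpha * s        P_movement(s) = M0 + beta * s,

with identical values sent to the mirrored left and right displays.
Positive scores additionally speed up the horizontal oscillation.

Scales (animatronic dress): each decoded state compiles to a timed servo +
LED command program — theta a slow bottom-to-top purple sweep that then
reverses, alpha a single blue wave travelling from one lower hem to the
opposite one, beta a prompt mirrored jump of every scale to 60 degrees
(back after ~0.5 s) under flickering white light, idle all scales at rest
and LEDs dark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EyeMappingConfig",
    "EyeState",
    "eye_state",
    "MotorLayout",
    "PatternConfig",
    "ActuationCommand",
    "ActuationProgram",
    "compile_pattern",
]

PURPLE = (128, 0, 128)
BLUE = (0, 0, 255)
WHITE = (255, 255, 255)
OFF = (0, 0, 0)


@dataclass(frozen=True)
class EyeMappingConfig:
    """Affine score-to-pupil mapping parameters.

    Display units are normalised: dilation in [0, 1] (``p0`` = 0.5 is the
    neutral pupil), movement amplitude in [-1, 1] around the centred
    position ``m0`` = 0.  The gains give the change per score unit, so the
    score range +/-10 spans ``p0 +/- 10 * alpha_gain``.
    """

    p0: float = 0.5
    m0: float = 0.0
    alpha_gain: float = 0.04
    beta_gain: float = 0.05
    osc_freq_per_score: float = 0.2  # Hz of horizontal eye oscillation per positive score unit
    dilation_range: tuple[float, float] = (0.0, 1.0)
    movement_range: tuple[float, float] = (-1.0, 1.0)


@dataclass(frozen=True)
class EyeState:
    """Pupil parameters for one score sample, mirrored on both displays."""

    dilation: float
    movement: float
    oscillation_hz: float

    @property
    def displays(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(left, right) (dilation, movement) pairs — always identical."""
        return ((self.dilation, self.movement), (self.dilation, self.movement))


def eye_state(s: float, cfg: EyeMappingConfig = EyeMappingConfig()) -> EyeState:
    """Map an engagement score to pupil dilation / movement parameters."""
    s = float(np.clip(s, -10.0, 10.0))
    dilation = float(np.clip(cfg.p0 + cfg.alpha_gain * s, *cfg.dilation_range))
    movement = float(np.clip(cfg.m0 + cfg.beta_gain * s, *cfg.movement_range))
    return EyeState(dilation, movement, cfg.osc_freq_per_score * max(s, 0.0))


@dataclass(frozen=True)
class MotorLayout:
    """Bottom-to-top motor ordering, split into mirrored left/right halves."""

    left: tuple[int, ...]
    right: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right halves must pair up")
        if set(self.left) & set(self.right):
            raise ValueError("a motor cannot sit on both halves")

    @property
    def n_motors(self) -> int:
        return len(self.left) + len(self.right)

    @classmethod
    def default(cls, n_motors: int = 32) -> "MotorLayout":
        """Even split: motors 0..n/2-1 left (bottom to top), the rest right."""
        if n_motors < 2 or n_motors % 2:
            raise ValueError("n_motors must be even and >= 2")
        h = n_motors // 2
        return cls(tuple(range(h)), tuple(range(h, n_motors)))


@dataclass(frozen=True)
class PatternConfig:
    """Tempo and angle defaults of the four patterns.

    The source choreography is qualitative ("slow", "steady", "promptly");
    these constants quantify it: theta sweeps one scale level every 0.4 s,
    the alpha wave travels at 0.2 s per scale, beta returns after 0.5 s with
    a 0.1 s white flicker period.  Servo angles stay within [0, 90] degrees.
    """

    default_angle: float = 0.0
    lift_angle: float = 45.0
    beta_angle: float = 60.0
    theta_step_seconds: float = 0.4
    alpha_step_seconds: float = 0.2
    beta_return_seconds: float = 0.5
    beta_flicker_period: float = 0.1


@dataclass(frozen=True)
class ActuationCommand:
    t: float
    target: int
    kind: str  # "servo_angle" | "led_color"
    value: float | tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("command time must be >= 0")
        if self.kind == "servo_angle" and not 0.0 <= float(self.value) <= 90.0:
            raise ValueError(f"servo angle {self.value} outside [0, 90] degrees")


@dataclass(frozen=True)
class ActuationProgram:
    state: str
    commands: tuple[ActuationCommand, ...]
    loop: bool

    def __post_init__(self) -> None:
        ts = [c.t for c in self.commands]
        if ts != sorted(ts):
            raise ValueError("commands must be time-ordered")

    @property
    def duration(self) -> float:
        return self.commands[-1].t if self.commands else 0.0


def _cmds(t, targets, kind, value):
    return [ActuationCommand(t, m, kind, value) for m in targets]


def _theta(layout: MotorLayout, cfg: PatternConfig) -> list[ActuationCommand]:
    # slow bottom-up sweep (both halves level by level), then the reverse
    cmds = []
    levels = list(zip(layout.left, layout.right))
    for i, pair in enumerate(levels):
        t = i * cfg.theta_step_seconds
        cmds += _cmds(t, pair, "servo_angle", cfg.lift_angle)
        cmds += _cmds(t, pair, "led_color", PURPLE)
    t0 = len(levels) * cfg.theta_step_seconds
    for i, pair in enumerate(reversed(levels)):
        t = t0 + i * cfg.theta_step_seconds
        cmds += _cmds(t, pair, "servo_angle", cfg.default_angle)
        cmds += _cmds(t, pair, "led_color", OFF)
    return cmds


def _alpha(layout: MotorLayout, cfg: PatternConfig) -> list[ActuationCommand]:
    # one wave: up the left side from the hem, down the right side to the
    # opposite hem; LED fires together with its scale, both reset one step later
    order = list(layout.left) + list(reversed(layout.right))
    cmds = []
    for i, m in enumerate(order):
        t = i * cfg.alpha_step_seconds
        cmds.append(ActuationCommand(t, m, "servo_angle", cfg.lift_angle))
        cmds.append(ActuationCommand(t, m, "led_color", BLUE))
        t_off = t + cfg.alpha_step_seconds
        cmds.append(ActuationCommand(t_off, m, "servo_angle", cfg.default_angle))
        cmds.append(ActuationCommand(t_off, m, "led_color", OFF))
    return cmds


def _beta(layout: MotorLayout, cfg: PatternConfig) -> list[ActuationCommand]:
    # prompt mirrored jump of every scale to 60 deg, back after ~0.5 s;
    # white LEDs flicker throughout
    all_motors = list(layout.left) + list(layout.right)
    cmds = _cmds(0.0, all_motors, "servo_angle", cfg.beta_angle)
    t, on = 0.0, True
    while t < cfg.beta_return_seconds - 1e-12:
        cmds += _cmds(t, all_motors, "led_color", WHITE if on else OFF)
        t += cfg.beta_flicker_period
        on = not on
    cmds += _cmds(cfg.beta_return_seconds, all_motors, "servo_angle", cfg.default_angle)
    cmds += _cmds(cfg.beta_return_seconds, all_motors, "led_color", OFF)
    return cmds


def _idle(layout: MotorLayout, cfg: PatternConfig) -> list[ActuationCommand]:
    all_motors = list(layout.left) + list(layout.right)
    return _cmds(0.0, all_motors, "servo_angle", cfg.default_angle) + _cmds(
        0.0, all_motors, "led_color", OFF
    )


_PATTERNS = {"theta": _theta, "alpha": _alpha, "beta": _beta, "idle": _idle}


def compile_pattern(
    state: str,
    n_motors: int = 32,
    layout: MotorLayout | None = None,
    cfg: PatternConfig = PatternConfig(),
) -> ActuationProgram:
    """Compile a dress state into its timed servo/LED command program.

    Deterministic: identical inputs yield identical programs.  All states
    except idle loop until the decision layer changes state.
    """
    if state not in _PATTERNS:
        raise ValueError(f"unknown state {state!r}; expected one of {sorted(_PATTERNS)}")
    layout = layout or MotorLayout.default(n_motors)
    cmds = _PATTERNS[state](layout, cfg)
    cmds.sort(key=lambda c: (c.t, c.target, c.kind))
    return ActuationProgram(state=state, commands=tuple(cmds), loop=state != "idle")
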