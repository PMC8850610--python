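"""Trial/session timing of the neurofeedback task and its volume-index map.

A neurofeedback session opens with a 150 s rest block (first 10 volumes
discarded) followed by six trials.  Each trial shows an "equals" cue for
14 s, then a "plus" cue for 42 s.  The first 40 s of the plus period is the
induction period during which the participant tries to modulate
connectivity; its first 2 s are discarded to absorb hemodynamic delay, so
the remaining 38 s enter the FC computation.  The final 2 s of the plus
period is the calculation period, after which feedback is displayed.

The per-trial feedback display duration is a free parameter of the
schedule: the published protocol states the session total (512 s) but not
the feedback length, so the default here (26/6 s per trial) is the value
that makes a six-trial session sum to 512 s at TR = 1 s.  It is an
inference from the session total, not a protocol constant.

All volume windows are half-open ``[start, stop)`` with 0-based indices,
and non-integer seconds/TR ratios are floored to whole volumes so that no
window ever includes a partial-period volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import InputError, ValidationError

__all__ = [
    "TrialSchedule",
    "TrialWindows",
    "SegmentIndex",
    "build_schedule",
    "segment_session",
    "session_length_volumes",
]

Window = tuple[int, int]


@dataclass(frozen=True)
class TrialSchedule:
    """Timing constants of a neurofeedback session (seconds / volumes)."""

    rest_seconds: float = 150.0
    rest_discard_volumes: int = 10
    n_trials: int = 6
    equals_seconds: float = 14.0
    plus_seconds: float = 42.0
    induction_seconds: float = 40.0
    hemodynamic_discard_seconds: float = 2.0
    calculation_seconds: float = 2.0
    feedback_seconds: float = 26.0 / 6.0  # inferred from the 512 s session total

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        for name in ("rest_seconds", "equals_seconds", "plus_seconds",
                     "induction_seconds"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("rest_discard_volumes", "hemodynamic_discard_seconds",
                     "calculation_seconds", "feedback_seconds"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not math.isclose(self.induction_seconds + self.calculation_seconds,
                            self.plus_seconds, abs_tol=1e-9):
            raise ValidationError(
                "induction_seconds + calculation_seconds must equal "
                f"plus_seconds ({self.induction_seconds} + "
                f"{self.calculation_seconds} != {self.plus_seconds})"
            )
        if self.hemodynamic_discard_seconds >= self.induction_seconds:
            raise ValidationError(
                "hemodynamic discard must be shorter than the induction period"
            )

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialSchedule":
        return cls(**yaml.safe_load(Path(path).read_text()))


def build_schedule(**overrides) -> TrialSchedule:
    """Build a TrialSchedule, applying keyword overrides to the defaults."""
    return TrialSchedule(**overrides)


@dataclass(frozen=True)
class TrialWindows:
    """Half-open volume-index windows of one trial."""

    equals: Window
    induction_used: Window
    calculation: Window
    feedback: Window


@dataclass(frozen=True)
class SegmentIndex:
    """Volume-index map of a whole session at a given TR."""

    rest_used: Window
    trials: tuple[TrialWindows, ...]
    n_volumes: int
    tr_seconds: float

    def labels(self) -> np.ndarray:
        """Per-volume segment labels for the whole session."""
        lab = np.full(self.n_volumes, "other", dtype=object)
        lab[: self.rest_used[0]] = "rest_discard"
        lab[self.rest_used[0]: self.rest_used[1]] = "rest"
        for t in self.trials:
            lab[t.equals[0]: t.equals[1]] = "equals"
            lab[t.equals[1]: t.induction_used[0]] = "induction_discard"
            lab[t.induction_used[0]: t.induction_used[1]] = "induction"
            lab[t.calculation[0]: t.calculation[1]] = "calculation"
            lab[t.feedback[0]: t.feedback[1]] = "feedback"
        return lab


def _vols(seconds: float, tr: float) -> int:
    # floor with a tiny tolerance so e.g. 0.3/0.1 does not lose a volume
    return int(math.floor(seconds / tr + 1e-9))


def session_length_volumes(schedule: TrialSchedule, tr_seconds: float) -> int:
    """Number of volumes a full session occupies at the given TR."""
    per_trial = (
        _vols(schedule.equals_seconds, tr_seconds)
        + _vols(schedule.hemodynamic_discard_seconds, tr_seconds)
        + _vols(schedule.induction_seconds
                - schedule.hemodynamic_discard_seconds, tr_seconds)
        + _vols(schedule.calculation_seconds, tr_seconds)
        + _vols(schedule.feedback_seconds, tr_seconds)
    )
    return _vols(schedule.rest_seconds, tr_seconds) + schedule.n_trials * per_trial


def segment_session(schedule: TrialSchedule, tr_seconds: float,
                    n_volumes: int) -> SegmentIndex:
    """Map a schedule onto 0-based half-open volume windows.

    The induction-use window of each trial has
    ``floor((induction - hemodynamic_discard) / TR)`` volumes (38 at the
    default timing and TR = 1 s); the usable rest window starts after the
    discarded leading rest volumes.
    """
    if tr_seconds <= 0:
        raise ValidationError("tr_seconds must be positive")
    rest_vols = _vols(schedule.rest_seconds, tr_seconds)
    if schedule.rest_discard_volumes >= rest_vols:
        raise InputError("rest discard leaves no usable rest volumes")
    cursor = rest_vols
    rest_used: Window = (schedule.rest_discard_volumes, rest_vols)
    trials = []
    for _ in range(schedule.n_trials):
        eq = (cursor, cursor + _vols(schedule.equals_seconds, tr_seconds))
        cursor = eq[1] + _vols(schedule.hemodynamic_discard_seconds, tr_seconds)
        ind = (cursor, cursor + _vols(
            schedule.induction_seconds - schedule.hemodynamic_discard_seconds,
            tr_seconds))
        cursor = ind[1]
        calc = (cursor, cursor + _vols(schedule.calculation_seconds, tr_seconds))
        cursor = calc[1]
        fb = (cursor, cursor + _vols(schedule.feedback_seconds, tr_seconds))
        cursor = fb[1]
        trials.append(TrialWindows(eq, ind, calc, fb))
    if cursor > n_volumes:
        raise InputError(
            f"session of {n_volumes} volumes too short for schedule "
            f"needing {cursor} volumes at TR {tr_seconds}s"
        )
    return SegmentIndex(rest_used=rest_used, trials=tuple(trials),
                        n_volumes=n_volumes, tr_seconds=tr_seconds)
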