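"""Binocular gaze-trace container.

A :class:`GazeTrace` holds the raw time-ordered binocular samples for one
participant watching one stimulus.  Missing coordinates are stored as NaN and
mirrored by boolean validity flags; they are never zero-filled.  Off-screen
samples are retained (velocity estimation needs the full kinematic record)
and only excluded when metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ScreenGeometry, TrialWindow

__all__ = ["GazeTrace", "clip_to_window"]


@dataclass
class GazeTrace:
    """Time-ordered binocular raw samples for one participant x stimulus.

    Coordinate arrays are float64 with NaN marking missing samples; a
    coordinate is NaN iff the corresponding validity flag is False.
    Timestamps are milliseconds since trial start and must be strictly
    increasing.
    """

    participant_id: str
    group: str
    stimulus_id: str
    t: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    geometry: ScreenGeometry
    nominal_rate: float = 250.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.size
        for name in ("left_x", "left_y", "right_x", "right_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"GazeTrace.{name}: length mismatch")
            setattr(self, name, arr)
        for name in ("valid_left", "valid_right"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.size != n:
                raise ValueError(f"GazeTrace.{name}: length mismatch")
            setattr(self, name, arr)
        if not self.nominal_rate > 0:
            raise ValueError("nominal_rate must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"non-monotonic timestamps in trace {self.trace_id!r}")
        for vx, vy, flag, eye in (
            (self.left_x, self.left_y, self.valid_left, "left"),
            (self.right_x, self.right_y, self.valid_right, "right"),
        ):
            nan = np.isnan(vx) | np.isnan(vy)
            if np.any(nan != ~flag):
                raise ValueError(
                    f"trace {self.trace_id!r}: {eye}-eye coordinates must be NaN "
                    "exactly where the validity flag is False"
                )

    @property
    def trace_id(self) -> str:
        return f"{self.participant_id}:{self.stimulus_id}"

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0


def clip_to_window(trace: GazeTrace, window: TrialWindow) -> GazeTrace:
    """Restrict a trace to a trial window and re-zero its timestamps.

    Keeps samples with ``window.start <= t < window.end``; the retained
    timestamps are shifted so the window start maps to 0.

    Raises
    ------
    ValueError
        If no sample falls inside the window ("empty trial window").
    """
    mask = (trace.t >= window.start) & (trace.t < window.end)
    if not np.any(mask):
        raise ValueError(
            f"empty trial window {window.stimulus_id!r} for trace {trace.trace_id!r}"
        )
    return replace(
        trace,
        stimulus_id=window.stimulus_id,
        t=trace.t[mask] - window.start,
        left_x=trace.left_x[mask],
        left_y=trace.left_y[mask],
        right_x=trace.right_x[mask],
        right_y=trace.right_y[mask],
        valid_left=trace.valid_left[mask],
        valid_right=trace.valid_right[mask],
    )
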