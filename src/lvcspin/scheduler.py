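"""Placement of LVC anchors along a trajectory and frame-to-anchor assignment.

Three strategies are provided.  Fixed intervals and time-domain bisection
place anchors on the time grid a priori; the adaptive rule walks the
trajectory and reacts to the Kabsch RMSD from the current reference
geometry.  Because an LVC model predicts forward and backward in time
equally well, a reparametrization is only required at every *other* RMSD
threshold crossing: at odd crossings only the RMSD reference geometry is
moved to the crossing frame, while at even crossings a new anchor is
created there (the midpoint rule's backward reach covers the stretch in
between).  Frames are always assigned to the temporally nearest anchor,
ties resolved toward the earlier one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import InputError
from .geometry import Frame, kabsch_rmsd

__all__ = [
    "ParametrizationSchedule",
    "fixed_schedule",
    "bisection_schedule",
    "adaptive_schedule",
]

#: Relative tolerance used when comparing RMSD to the threshold, so that
#: crossings landing exactly on the threshold value are detected
#: deterministically in floating point.
_THRESHOLD_RTOL = 1e-12


@dataclass
class ParametrizationSchedule:
    """Anchor times plus the per-frame anchor assignment."""

    anchor_times: np.ndarray
    frame_times: np.ndarray
    assignment: np.ndarray
    mode: str
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.anchor_times = np.asarray(self.anchor_times, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=int)
        if np.any(np.diff(self.anchor_times) <= 0):
            raise InputError("anchor times must be strictly increasing")
        if self.assignment.shape != self.frame_times.shape:
            raise InputError("every frame needs an anchor assignment")
        if self.assignment.min(initial=0) < 0 or (
            self.assignment.size
            and self.assignment.max() >= self.anchor_times.size
        ):
            raise InputError("assignment indices out of range")

    @property
    def n_anchors(self) -> int:
        return self.anchor_times.size

    def anchor_for_frame(self, i: int) -> float:
        return float(self.anchor_times[self.assignment[i]])

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "threshold": self.threshold,
            "anchor_times": self.anchor_times.tolist(),
            "frame_times": self.frame_times.tolist(),
            "assignment": self.assignment.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParametrizationSchedule":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            payload["anchor_times"],
            payload["frame_times"],
            payload["assignment"],
            payload["mode"],
            payload.get("threshold"),
        )


def _nearest_assignment(frame_times: np.ndarray, anchor_times: np.ndarray) -> np.ndarray:
    """Nearest anchor per frame; equidistant ties go to the earlier anchor."""
    dist = np.abs(frame_times[:, None] - anchor_times[None, :])
    return np.argmin(dist, axis=1)  # argmin takes the first (earliest) on ties


def _default_frame_times(t0: float, t_end: float, dt: float) -> np.ndarray:
    n = int(round((t_end - t0) / dt))
    return t0 + dt * np.arange(n + 1)


def fixed_schedule(
    t0: float,
    t_end: float,
    interval: float,
    frame_times: Optional[Sequence[float]] = None,
    dt: float = 1.0,
) -> ParametrizationSchedule:
    """Anchors at t0, t0+interval, ... up to t_end (inclusive when on grid)."""
    if interval <= 0:
        raise InputError("interval must be positive")
    if t_end < t0:
        raise InputError("empty time range")
    if frame_times is None:
        frame_times = _default_frame_times(t0, t_end, dt)
    frame_times = np.asarray(frame_times, dtype=float)
    n_anchors = int(np.floor((t_end - t0) / interval + 1e-9)) + 1
    anchors = t0 + interval * np.arange(n_anchors)
    return ParametrizationSchedule(
        anchors, frame_times, _nearest_assignment(frame_times, anchors), "fixed"
    )


def bisection_schedule(
    t0: float,
    t_end: float,
    depth: int,
    frame_times: Optional[Sequence[float]] = None,
    dt: float = 1.0,
) -> ParametrizationSchedule:
    """Anchors at increasingly dense bisections of [t0, t_end].

    Depth 0 keeps only the endpoints; each increment adds the midpoint of
    every current interval, rounded onto the frame grid.
    """
    if depth < 0:
        raise InputError("depth must be nonnegative")
    if t_end <= t0:
        raise InputError("empty time range")
    if frame_times is None:
        frame_times = _default_frame_times(t0, t_end, dt)
    frame_times = np.asarray(frame_times, dtype=float)
    anchors = [t0, t_end]
    for _ in range(depth):
        mids = [(a + b) / 2 for a, b in zip(anchors, anchors[1:])]
        anchors = sorted(set(anchors) | set(mids))
    # snap onto the frame grid
    snapped = np.unique(
        [frame_times[np.argmin(np.abs(frame_times - a))] for a in anchors]
    )
    return ParametrizationSchedule(
        snapped, frame_times, _nearest_assignment(frame_times, snapped), "bisection"
    )


def adaptive_schedule(
    frames: Sequence[Frame],
    threshold: float,
    rmsd_fn: Optional[Callable] = None,
    mask: Optional[np.ndarray] = None,
) -> ParametrizationSchedule:
    """RMSD-threshold adaptive anchor placement (every-other-crossing rule).

    Walking forward from the first frame (the first anchor), each time the
    RMSD to the current reference geometry first reaches ``threshold`` is a
    crossing.  At odd crossings only the reference geometry moves to the
    crossing frame; at even crossings a new anchor is created there and
    becomes both the reference and the active model.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    if not frames:
        raise InputError("no frames supplied")
    times = np.array([f.time for f in frames])
    if np.any(np.diff(times) <= 0):
        raise InputError("frame times must be strictly increasing")
    if rmsd_fn is None:
        rmsd_fn = lambda a, b: kabsch_rmsd(a, b, mask=mask)  # noqa: E731
    anchors = [times[0]]
    reference = frames[0]
    crossings = 0
    for frame in frames[1:]:
        value = rmsd_fn(frame, reference)
        if value >= threshold * (1.0 - _THRESHOLD_RTOL):
            crossings += 1
            reference = frame
            if crossings % 2 == 0:
                anchors.append(frame.time)
    anchor_times = np.asarray(anchors, dtype=float)
    return ParametrizationSchedule(
        anchor_times,
        times,
        _nearest_assignment(times, anchor_times),
        "rmsd-adaptive",
        threshold=threshold,
    )
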