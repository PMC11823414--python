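"""Trajectory frames, periodic unwrapping and Kabsch-aligned RMSD.

Trajectories are read from (extended) XYZ files whose comment line may carry
``time=<fs>`` and ``box=<a> <b> <c>`` tokens.  Coordinates are Å on file and
bohr in memory; RMSD values are reported in Å.  Solvent point-charge sites
are ordinary sites flagged ``site_is_atom=False`` (element label 'X' by
convention) and participate in displacements and, by default, in RMSD.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, InputError
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "Frame",
    "PeriodicBox",
    "read_trajectory",
    "write_trajectory",
    "unwrap_to_reference",
    "kabsch_rmsd",
]


@dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic periodic box; edge lengths stored in bohr."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float).reshape(-1)
        if lengths.shape != (3,):
            raise InputError(f"box needs three edge lengths, got {lengths.shape}")
        if np.any(lengths <= 0):
            raise InputError("box edge lengths must be positive")
        object.__setattr__(self, "lengths", lengths)

    @classmethod
    def from_angstrom(cls, a: float, b: float, c: float) -> "PeriodicBox":
        return cls(np.array([a, b, c]) * ANGSTROM_TO_BOHR)

    @property
    def lengths_angstrom(self) -> np.ndarray:
        return self.lengths * BOHR_TO_ANGSTROM


@dataclass(frozen=True)
class Frame:
    """One trajectory snapshot: time (fs) plus per-site positions (bohr)."""

    time: float
    coordinates: np.ndarray
    elements: tuple
    site_is_atom: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"coordinates must be (N, 3), got {coords.shape}")
        flags = np.asarray(self.site_is_atom, dtype=bool).reshape(-1)
        if flags.shape[0] != coords.shape[0]:
            raise InputError("site_is_atom length must match coordinates")
        if len(self.elements) != coords.shape[0]:
            raise InputError("elements length must match coordinates")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "site_is_atom", flags)
        object.__setattr__(self, "elements", tuple(self.elements))

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[0]


_BOX_RE = re.compile(
    r"box=\s*([-+0-9.eE]+)[ ,]+([-+0-9.eE]+)[ ,]+([-+0-9.eE]+)"
)
_TIME_RE = re.compile(r"time=\s*([-+0-9.eE]+)")


def _parse_comment(comment: str) -> tuple[Optional[float], Optional[PeriodicBox]]:
    time = None
    box = None
    m = _TIME_RE.search(comment)
    if m:
        time = float(m.group(1))
    m = _BOX_RE.search(comment)
    if m:
        box = PeriodicBox.from_angstrom(*(float(g) for g in m.groups()))
    return time, box


def read_trajectory(
    path, box: Optional[PeriodicBox] = None
) -> tuple[list[Frame], Optional[PeriodicBox]]:
    """Read an (extended) XYZ trajectory.

    Returns the frame list and the periodic box (the ``box=`` token of the
    first frame wins over the ``box`` argument).  Frames missing a ``time=``
    token are numbered by index at 1 fs spacing.  Site label 'X' marks a
    point charge.
    """
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    pos = 0
    index = 0
    n_sites_ref: Optional[int] = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise FormatError(
                f"frame {index}: malformed site-count line {lines[pos]!r}"
            ) from exc
        if pos + 2 + count > len(lines):
            raise FormatError(f"frame {index}: truncated ({count} sites declared)")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        time, frame_box = _parse_comment(comment)
        if frame_box is not None and box is None:
            box = frame_box
        elements = []
        coords = np.empty((count, 3))
        for i in range(count):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise FormatError(f"frame {index}: malformed site line {i}")
            elements.append(parts[0])
            coords[i] = [float(p) for p in parts[1:4]]
        if n_sites_ref is None:
            n_sites_ref = count
        elif count != n_sites_ref:
            raise FormatError(
                f"frame {index}: site count {count} differs from first frame ({n_sites_ref})"
            )
        flags = np.array([e.upper() != "X" for e in elements])
        frames.append(
            Frame(
                time if time is not None else float(index),
                coords * ANGSTROM_TO_BOHR,
                tuple(elements),
                flags,
            )
        )
        pos += 2 + count
        index += 1
    times = [f.time for f in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise FormatError("frame times must be strictly increasing")
    return frames, box


def write_trajectory(
    path, frames: Sequence[Frame], box: Optional[PeriodicBox] = None
) -> None:
    """Write frames as extended XYZ (Å), with time= and box= comment tokens."""
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_sites}\n")
            comment = f"time={frame.time:.6f}"
            if box is not None:
                a, b, c = box.lengths_angstrom
                comment += f" box={a:.8f} {b:.8f} {c:.8f}"
            fh.write(comment + "\n")
            for el, xyz in zip(frame.elements, frame.coordinates * BOHR_TO_ANGSTROM):
                fh.write(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


def unwrap_to_reference(frame: Frame, reference: Frame, box: Optional[PeriodicBox]) -> Frame:
    """Shift sites by whole box edges to minimise displacement from ``reference``.

    Implements the minimum-image convention per coordinate: after unwrapping,
    every displacement component has magnitude at most half the box edge.
    The operation is idempotent and only ever adds integer multiples of box
    edges.
    """
    if box is None:
        raise ConfigurationError("periodic unwrapping requires a box")
    if frame.n_sites != reference.n_sites:
        raise InputError("frame and reference must have the same site count")
    delta = frame.coordinates - reference.coordinates
    shifts = np.round(delta / box.lengths) * box.lengths
    return replace(frame, coordinates=frame.coordinates - shifts)


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, Frame):
        return obj.coordinates
    return np.asarray(obj, dtype=float)


def kabsch_rmsd(a, b, mask: Optional[np.ndarray] = None) -> float:
    """RMSD (Å) after optimal translation and proper rotation.

    ``a`` and ``b`` may be Frames or plain (N, 3) arrays in bohr.  ``mask``
    selects the sites entering the superposition (e.g. atoms only); by
    default all sites, point charges included, are used.  Reflections are
    excluded (the rotation determinant is forced to +1).
    """
    p = _as_coords(a)
    q = _as_coords(b)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        p = p[mask]
        q = q[mask]
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise InputError(f"incompatible coordinate shapes {p.shape} vs {q.shape}")
    if p.shape[0] < 1:
        raise InputError("at least one site is required")
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    cov = p.T @ q
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = u @ diag @ vt
    diff = p @ rot - q
    rmsd_bohr = np.sqrt((diff**2).sum() / p.shape[0])
    return float(rmsd_bohr * BOHR_TO_ANGSTROM)
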