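"""Error and similarity diagnostics for approximate Hamiltonian series.

The truncation error of an approximate Hamiltonian against a reference is
the relative Frobenius deviation ||H_approx - H_ref||_F / ||H_ref||_F,
reported as a dimensionless fraction.  Density-trajectory agreement is the
normalized real inner product of the two vectorised density matrices, which
equals 1 for identical states and decays as the trajectories diverge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InputError, NumericError
from .geometry import Frame, PeriodicBox, unwrap_to_reference
from .hamiltonian import HamiltonianMatrix
from .lvc import ReferenceParametrization, lvc_hamiltonian
from .propagation import DensityState
from .stevens import SpinHamiltonianParameters, build_spin_hamiltonian, component_hamiltonians

__all__ = [
    "ErrorTrace",
    "hamiltonian_error",
    "term_errors",
    "similarity",
    "error_vs_separation",
    "displacement_from_frame",
]


@dataclass
class ErrorTrace:
    """Per-frame truncation errors with the anchor used for each frame."""

    times: np.ndarray
    errors: np.ndarray
    parametrization_times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        self.parametrization_times = np.asarray(self.parametrization_times, dtype=float)
        if not (len(self.times) == len(self.errors) == len(self.parametrization_times)):
            raise InputError("ErrorTrace fields must have equal lengths")
        if np.any(self.errors < 0):
            raise InputError("errors must be nonnegative")

    @property
    def relative_times(self) -> np.ndarray:
        return self.times - self.parametrization_times

    def signed_average(self) -> tuple[np.ndarray, np.ndarray]:
        """Average error over +/- relative time: (|rel time| grid, mean error)."""
        rel = self.relative_times
        mags = np.unique(np.abs(rel))
        avg = np.array([self.errors[np.abs(rel) == m].mean() for m in mags])
        return mags, avg


def hamiltonian_error(
    h_approx: HamiltonianMatrix,
    h_ref: HamiltonianMatrix,
    remove_shift: bool = False,
) -> float:
    """Relative Frobenius error of ``h_approx`` against ``h_ref``.

    ``remove_shift`` subtracts each matrix's mean diagonal (trace/d) first,
    making the metric insensitive to a global energy offset; the default
    keeps the raw, shift-sensitive comparison.
    """
    if h_approx.dimension != h_ref.dimension or h_approx.basis_tag != h_ref.basis_tag:
        raise InputError("Hamiltonians must share dimension and basis tag")
    a = h_approx.matrix
    r = h_ref.matrix
    if remove_shift:
        d = a.shape[0]
        a = a - (np.trace(a) / d) * np.eye(d)
        r = r - (np.trace(r) / d) * np.eye(d)
    denom = np.linalg.norm(r)
    if denom == 0.0:
        raise NumericError("reference Hamiltonian has zero Frobenius norm")
    return float(np.linalg.norm(a - r) / denom)


def term_errors(
    p_approx: SpinHamiltonianParameters,
    p_ref: SpinHamiltonianParameters,
) -> tuple[float, float, float]:
    """(SOC-only, crystal-field-only, total) errors between two parameter sets.

    Each spin-Hamiltonian term is built separately from both parameter sets
    and compared with :func:`hamiltonian_error`; the total uses the full
    build.
    """
    if (p_approx.L, p_approx.S) != (p_ref.L, p_ref.S) or p_approx.theta != p_ref.theta:
        raise InputError("parameter sets must share L, S and theta factors")
    soc_a, cf_a = component_hamiltonians(p_approx)
    soc_r, cf_r = component_hamiltonians(p_ref)
    soc_err = hamiltonian_error(soc_a, soc_r) if np.linalg.norm(soc_r.matrix) else 0.0
    cf_err = hamiltonian_error(cf_a, cf_r) if np.linalg.norm(cf_r.matrix) else 0.0
    total = hamiltonian_error(build_spin_hamiltonian(p_approx), build_spin_hamiltonian(p_ref))
    return soc_err, cf_err, total


def similarity(rho_a: DensityState, rho_b: DensityState, kind: str = "real") -> float:
    """Normalized inner product of two vectorised density matrices.

    ``kind='real'`` (default) takes Re<rho_a|rho_b>/(|rho_a||rho_b|), which
    is sign-sensitive and equals 1 only for identical states;
    ``kind='modulus'`` takes the magnitude instead.
    """
    if rho_a.vector.size != rho_b.vector.size:
        raise InputError("states must have the same dimension")
    if rho_a.basis_tag != rho_b.basis_tag:
        raise InputError("states must share a basis tag")
    na = np.linalg.norm(rho_a.vector)
    nb = np.linalg.norm(rho_b.vector)
    if na == 0.0 or nb == 0.0:
        raise InputError("zero-norm density state")
    inner = np.vdot(rho_a.vector, rho_b.vector) / (na * nb)
    if kind == "real":
        return float(np.real(inner))
    if kind == "modulus":
        return float(np.abs(inner))
    raise InputError(f"kind must be 'real' or 'modulus', got {kind!r}")


def displacement_from_frame(
    anchor: ReferenceParametrization,
    frame: Frame,
    box: Optional[PeriodicBox] = None,
    reference_frame: Optional[Frame] = None,
) -> np.ndarray:
    """Flattened displacement (bohr) of ``frame`` from the anchor geometry.

    With a box, the frame is first unwrapped to the minimum image relative
    to the anchor geometry.
    """
    if frame.n_sites != anchor.n_sites:
        raise InputError("frame and anchor must have the same site count")
    if box is not None:
        ref = reference_frame or Frame(
            frame.time, anchor.reference_geometry, frame.elements, frame.site_is_atom
        )
        frame = unwrap_to_reference(frame, ref, box)
    return (frame.coordinates - anchor.reference_geometry).reshape(-1)


def error_vs_separation(
    anchor: ReferenceParametrization,
    truth,
    frames: Sequence[Frame],
    box: Optional[PeriodicBox] = None,
) -> ErrorTrace:
    """Truncation error per frame against a ground-truth Hamiltonian source.

    ``truth`` is any object exposing ``hamiltonian(displacement) ->
    HamiltonianMatrix`` in the anchor's fixed reference basis (for synthetic
    studies, a :class:`lvcspin.synthetic.GroundTruthModel`).  Frames must
    bracket the anchor time so both forward and backward separations are
    sampled; the error at the anchor itself is zero by construction.
    """
    times = np.array([f.time for f in frames])
    if not (times.min() <= anchor.anchor_time <= times.max()):
        raise InputError(
            f"anchor time {anchor.anchor_time} fs outside frame range "
            f"[{times.min()}, {times.max()}]"
        )
    errors = []
    for frame in frames:
        disp = displacement_from_frame(anchor, frame, box)
        h_lvc = lvc_hamiltonian(anchor, disp, basis="reference")
        h_ref = truth.hamiltonian(disp)
        errors.append(hamiltonian_error(h_lvc, h_ref))
    anchor_times = np.full_like(times, anchor.anchor_time)
    return ErrorTrace(times, np.asarray(errors), anchor_times)
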