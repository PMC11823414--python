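"""Synthetic parametrizations, quadratic ground truth and test trajectories.

No reference electronic-structure data are distributed with this package, so
every pipeline stage is exercised against seeded synthetic systems:

* :func:`generate_parametrization` emulates the output of a multi-state
  spin-orbit calculation (energies, gradients, interstate couplings, SOC
  operator matrices) for an n-state, spin-S system — by default an
  18-state sextet (S = 5/2) lanthanide-like configuration, giving a
  108-dimensional product-basis Hamiltonian.

* :class:`GroundTruthModel` augments an anchor with quadratic couplings so
  that the "true" spin-free Hamiltonian contains curvature the first-order
  model cannot represent.  Truncation error is then nonzero away from the
  anchor, grows quadratically with displacement, and is geometry-correlated
  — the behaviour an explicit recalculation at every step would expose.
  :func:`reparametrize` re-expands the truth to first order about a new
  geometry, standing in for a fresh reference calculation there.

* :func:`generate_trajectory` superimposes seeded sinusoidal displacement
  modes (plus optional jitter) on a reference frame, emulating thermal
  motion whose RMSD from the anchor grows over a sub-period window.

* :func:`point_charge_b20` is the classic point-charge crystal-field toy:
  the leading axial parameter changes sign at the magic angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .geometry import Frame
from .hamiltonian import HamiltonianMatrix
from .lvc import (
    ReferenceParametrization,
    as_displacement,
    assemble_soc,
    diagonalize,
    evaluate_mch,
)
from .angular import angular_momentum_matrices
from .units import ANGSTROM_TO_BOHR

__all__ = [
    "ParamScales",
    "SyntheticTrajectorySpec",
    "GroundTruthModel",
    "generate_parametrization",
    "make_ground_truth",
    "reparametrize",
    "generate_trajectory",
    "frame_from_parametrization",
    "point_charge_b20",
]

_ELEMENT_CYCLE = ("N", "O", "C", "H")


@dataclass(frozen=True)
class ParamScales:
    """Magnitudes (hartree-based) of the random parametrization draws.

    Defaults emulate a low-lying lanthanide manifold: state energies spread
    over ~0.02 hartree (a few thousand cm^-1), gradient and coupling
    components of a few mHa/bohr (within the range reported for flexible
    complexes), and SOC matrix elements of ~5 mHa, comparable to a
    lanthanide one-electron spin-orbit constant, so that — as in real
    spin-orbit-coupled complexes — the SOC term dominates the magnitude of
    the total Hamiltonian while the crystal-field-like spin-free part
    carries most of the geometry variation.
    """

    energy_span: float = 0.02
    gradient: float = 5e-3
    nac: float = 5e-3
    soc: float = 5e-3

    def validate(self) -> None:
        for name in ("energy_span", "gradient", "nac", "soc"):
            if getattr(self, name) < 0:
                raise InputError(f"scale {name} must be nonnegative")


def _random_hermitian(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    a = rng.normal(scale=scale, size=(n, n)) + 1j * rng.normal(scale=scale, size=(n, n))
    return 0.5 * (a + a.conj().T)


def generate_parametrization(
    n_states: int = 18,
    spin_S: float = 2.5,
    n_sites: int = 8,
    scales: Optional[ParamScales] = None,
    seed: int = 0,
    n_charges: int = 2,
    assign_ml: bool = True,
    anchor_time: float = 0.0,
) -> ReferenceParametrization:
    """Seeded random LVC anchor emulating a multi-state SOC calculation.

    ``n_charges`` of the sites are flagged as solvent point charges.  With
    ``assign_ml`` (and n_states >= 2L+1 for L = (n_states-1)//2 capped at 5),
    the leading states carry M_L labels of an orbital term, enabling
    label-based spin-parameter projection; an 18-state sextet gets an
    11-state L=5 term plus a 7-state L=3 term, mirroring the 6H + 6F
    composition of an f^9 ion.
    """
    if n_states < 1:
        raise InputError("n_states must be at least 1")
    if n_sites < 1:
        raise InputError("n_sites must be at least 1")
    if not 0 <= n_charges <= n_sites:
        raise InputError("n_charges must lie in [0, n_sites]")
    scales = scales or ParamScales()
    scales.validate()
    rng = np.random.default_rng(seed)
    dof = 3 * n_sites
    energies = np.sort(rng.uniform(0.0, scales.energy_span, size=n_states))
    energies -= energies[0]
    gradients = rng.normal(scale=scales.gradient, size=(n_states, dof))
    nacs = rng.normal(scale=scales.nac, size=(n_states, n_states, dof))
    nacs = 0.5 * (nacs + np.swapaxes(nacs, 0, 1))
    for m in range(n_states):
        nacs[m, m, :] = 0.0
    soc = np.stack([_random_hermitian(rng, n_states, scales.soc) for _ in range(3)])
    geometry = rng.uniform(-4.0, 4.0, size=(n_sites, 3)) * ANGSTROM_TO_BOHR
    site_is_atom = np.ones(n_sites, dtype=bool)
    if n_charges > 0:
        site_is_atom[-n_charges:] = False
    elements = tuple(
        _ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)] if site_is_atom[i] else "X"
        for i in range(n_sites)
    )
    ml_labels = None
    if assign_ml:
        ml_labels = _default_ml_labels(n_states)
    return ReferenceParametrization(
        reference_geometry=geometry,
        site_is_atom=site_is_atom,
        elements=elements,
        reference_energies=energies,
        gradients=gradients,
        nacs=nacs,
        soc_operators=soc,
        spin_S=spin_S,
        anchor_time=anchor_time,
        ml_labels=ml_labels,
    )


def _default_ml_labels(n_states: int) -> Optional[np.ndarray]:
    """Assign orbital-term labels: an L=min(5, (n-1)//2) term first, then
    a second term with the remaining states (labels offset by 100 so they
    are never confused with the leading term)."""
    L = min(5, (n_states - 1) // 2)
    leading = 2 * L + 1
    if leading > n_states or leading == 0:
        return None
    labels = np.empty(n_states, dtype=int)
    labels[:leading] = np.arange(L, -L - 1, -1)
    rest = n_states - leading
    labels[leading:] = 100 + np.arange(rest)
    return labels


@dataclass
class GroundTruthModel:
    """Quadratic 'truth': an anchor plus mode-restricted second derivatives.

    The spin-free matrix elements gain 1/2 sum_k c_k[m,n] (u_k . DR)^2 where
    the u_k are a few unit displacement directions shared by all elements
    and c_k are symmetric per-pair coefficients — a sparse stand-in for the
    full tensor of second derivatives.  ``basis_rotation`` maps the root
    reference basis onto this model's own basis (identity for the root),
    so models re-expanded at later geometries stay comparable.
    """

    base: ReferenceParametrization
    mode_directions: np.ndarray  # (K, 3N), unit rows
    mode_coeffs: np.ndarray  # (K, n, n), symmetric, hartree/bohr^2
    basis_rotation: np.ndarray = None  # (n, n) real orthogonal
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode_directions = np.asarray(self.mode_directions, dtype=float)
        self.mode_coeffs = np.asarray(self.mode_coeffs, dtype=float)
        n = self.base.n_states
        k = self.mode_directions.shape[0]
        if self.mode_directions.shape != (k, self.base.n_dof):
            raise InputError("mode_directions must be (K, 3N)")
        if self.mode_coeffs.shape != (k, n, n):
            raise InputError("mode_coeffs must be (K, n, n)")
        if not np.allclose(self.mode_coeffs, np.swapaxes(self.mode_coeffs, 1, 2)):
            raise InputError("mode_coeffs must be symmetric in the state indices")
        if self.basis_rotation is None:
            self.basis_rotation = np.eye(n)
        self.basis_rotation = np.asarray(self.basis_rotation, dtype=float)

    # -- evaluation ----------------------------------------------------
    def mch_matrix(self, disp) -> np.ndarray:
        """True (quadratic) spin-free Hamiltonian in this model's own basis."""
        d = as_displacement(self.base, disp)
        linear = evaluate_mch(self.base, d).matrix.real
        proj = self.mode_directions @ d  # (K,)
        quad = 0.5 * np.einsum("k,kmn->mn", proj**2, self.mode_coeffs)
        return linear + quad

    def hamiltonian(self, disp) -> HamiltonianMatrix:
        """Full truth Hamiltonian (spin-free + SOC) in this model's own
        fixed reference basis, comparable with
        ``lvc_hamiltonian(model.base, disp, basis='reference')``."""
        mult = self.base.spin_multiplicity
        h = np.kron(self.mch_matrix(disp), np.eye(mult)).astype(complex)
        spins = angular_momentum_matrices(self.base.spin_S)
        for v, s in zip(self.base.soc_operators, spins):
            h += np.kron(v, s)
        return HamiltonianMatrix(h, "mch-eigenbasis-product")

    def hamiltonian_global(self, disp) -> HamiltonianMatrix:
        """Truth Hamiltonian rotated into the root reference basis."""
        return _to_global(self, self.mch_matrix(disp))

    def lvc_hamiltonian_global(self, disp) -> HamiltonianMatrix:
        """First-order (LVC) Hamiltonian from this anchor, root basis."""
        return _to_global(self, evaluate_mch(self.base, disp).matrix.real)


def _to_global(model: GroundTruthModel, mch_own: np.ndarray) -> HamiltonianMatrix:
    r = model.basis_rotation
    mult = model.base.spin_multiplicity
    mch_global = r @ mch_own @ r.T
    v_global = np.einsum("pm,amn,qn->apq", r, model.base.soc_operators, r)
    h = np.kron(mch_global, np.eye(mult)).astype(complex)
    spins = angular_momentum_matrices(model.base.spin_S)
    for v, s in zip(v_global, spins):
        h += np.kron(v, s)
    return HamiltonianMatrix(h, "mch-eigenbasis-product")


def make_ground_truth(
    base: ReferenceParametrization,
    n_modes: int = 4,
    quad_scale: float = 0.04,
    seed: int = 0,
) -> GroundTruthModel:
    """Attach seeded quadratic couplings to an anchor.

    ``quad_scale`` (hartree/bohr^2) sets the element-wise magnitude of the
    second derivatives; the default produces relative truncation errors of
    a few percent for displacements of a few tenths of a bohr, the regime
    in which the first-order model starts to degrade.
    """
    if n_modes < 1:
        raise InputError("n_modes must be at least 1")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_modes, base.n_dof))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coeffs = rng.normal(scale=quad_scale, size=(n_modes, base.n_states, base.n_states))
    coeffs = 0.5 * (coeffs + np.swapaxes(coeffs, 1, 2))
    return GroundTruthModel(base, dirs, coeffs, np.eye(base.n_states), seed)


def reparametrize(
    model: GroundTruthModel, disp, anchor_time: float
) -> GroundTruthModel:
    """Re-expand the truth to first order about a displaced geometry.

    Plays the role of a fresh reference calculation at the new geometry:
    the true spin-free Hamiltonian there is diagonalized; its eigenvalues
    become the new state energies, the local first derivatives (linear
    terms plus the quadratic contribution at the expansion point) rotated
    into the new eigenbasis become the new gradients and couplings, and the
    SOC operators and quadratic coefficients are rotated along.  The
    returned model's ``basis_rotation`` accumulates so Hamiltonians from
    different anchors remain comparable in the root basis.
    """
    base = model.base
    d0 = as_displacement(base, disp)
    m0 = model.mch_matrix(d0)
    evals, u_c = diagonalize(m0)
    u = u_c.real  # real symmetric input -> real orthogonal transform
    # first derivative of the true MCH at d0, own basis: (n, n, 3N)
    proj = model.mode_directions @ d0  # (K,)
    deriv = np.einsum(
        "kmn,ki->mni", model.mode_coeffs * proj[:, None, None], model.mode_directions
    )
    for m in range(base.n_states):
        deriv[m, m, :] += base.gradients[m]
    off = model.base.nacs.copy()
    for m in range(base.n_states):
        off[m, m, :] = 0.0
    deriv += off
    deriv_rot = np.einsum("pm,pqi,qn->mni", u, deriv, u)
    gradients = np.stack([deriv_rot[m, m, :] for m in range(base.n_states)])
    nacs = deriv_rot.copy()
    for m in range(base.n_states):
        nacs[m, m, :] = 0.0
    nacs = 0.5 * (nacs + np.swapaxes(nacs, 0, 1))
    soc = np.einsum("pm,apq,qn->amn", u, base.soc_operators, u)
    coeffs = np.einsum("pm,kpq,qn->kmn", u, model.mode_coeffs, u)
    # energies must be ascending for the parametrization contract; eigh
    # already returns them ascending.
    new_base = ReferenceParametrization(
        reference_geometry=base.reference_geometry + d0.reshape(-1, 3),
        site_is_atom=base.site_is_atom,
        elements=base.elements,
        reference_energies=evals,
        gradients=gradients,
        nacs=nacs,
        soc_operators=soc,
        spin_S=base.spin_S,
        anchor_time=anchor_time,
        ml_labels=None,  # eigenstates of the displaced MCH are label-mixed
    )
    return GroundTruthModel(
        new_base,
        model.mode_directions,
        coeffs,
        model.basis_rotation @ u,
        model.seed,
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Harmonic-motion trajectory settings.

    Amplitudes are Å, periods fs.  With periods well beyond the simulated
    window the displacement (and hence the RMSD from frame 0) grows
    monotonically over the window, emulating the divergence of an MD
    trajectory from its starting geometry.  ``jitter`` adds seeded white
    positional noise (Å).
    """

    n_frames: int = 100
    dt: float = 1.0
    mode_amplitudes: Sequence[float] = (0.12, 0.07, 0.04)
    mode_periods: Sequence[float] = (520.0, 760.0, 410.0)
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise InputError("n_frames must be at least 2")
        if len(self.mode_amplitudes) != len(self.mode_periods):
            raise InputError("need one period per amplitude")
        if any(p <= 0 for p in self.mode_periods):
            raise InputError("mode periods must be positive")
        if self.dt <= 0:
            raise InputError("dt must be positive")


def generate_trajectory(ref: Frame, spec: SyntheticTrajectorySpec) -> list[Frame]:
    """Seeded superposition of sinusoidal displacement modes on ``ref``.

    Frame 0 equals the reference exactly (sinusoids start at zero phase and
    jitter is suppressed there); all randomness (per-site mode patterns,
    jitter) derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = ref.n_sites
    patterns = rng.normal(size=(len(spec.mode_amplitudes), n, 3))
    patterns /= np.sqrt((patterns**2).mean(axis=(1, 2)))[:, None, None]
    frames = []
    for i in range(spec.n_frames):
        t = ref.time + i * spec.dt
        disp = np.zeros((n, 3))
        for amp, period, pat in zip(spec.mode_amplitudes, spec.mode_periods, patterns):
            disp += amp * np.sin(2 * np.pi * (i * spec.dt) / period) * pat
        if spec.jitter > 0 and i > 0:
            disp += rng.normal(scale=spec.jitter, size=(n, 3))
        coords = ref.coordinates + disp * ANGSTROM_TO_BOHR
        frames.append(replace(ref, time=t, coordinates=coords))
    return frames


def frame_from_parametrization(
    param: ReferenceParametrization, time: Optional[float] = None
) -> Frame:
    """The anchor geometry as a trajectory frame."""
    return Frame(
        param.anchor_time if time is None else time,
        param.reference_geometry.copy(),
        param.elements,
        param.site_is_atom,
    )


# ---------------------------------------------------------------------------
# Point-charge crystal-field toy
# ---------------------------------------------------------------------------

def point_charge_b20(charges: Sequence[tuple]) -> float:
    """Leading axial crystal-field parameter of a set of point charges.

    ``charges`` holds (q, r, theta) triples: charge (e), distance (any
    consistent length unit), polar angle (radians).  Returns

        B_2^0 = sum_i q_i (3 cos^2 theta_i - 1) / (2 r_i^3)

    with proportionality constant 1 (the radial expectation value and
    Stevens factor prefactors of a real ion are absorbed); the sign change
    at the magic angle (3 cos^2 theta = 1, ~54.7356 deg) is the point.
    """
    total = 0.0
    for q, r, theta in charges:
        if r <= 0:
            raise InputError("charge distance must be positive")
        total += q * (3.0 * np.cos(theta) ** 2 - 1.0) / (2.0 * r**3)
    return float(total)
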