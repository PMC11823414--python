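"""Linear vibronic coupling (LVC) reconstruction of molecular Hamiltonians.

A single multiconfigurational calculation at a reference (anchor) geometry
yields spin-free state energies E_m, state gradients kappa^(m), nonadiabatic
coupling vectors lambda^(mn) and the three spatial components of the mean-field
spin-orbit operator V_a in the reference eigenbasis.  The spin-free Hamiltonian
at a displaced geometry R = DR is then approximated to first order,

    H^MCH_mn(DR) = delta_mn (E_m + kappa^(m) . DR) + (1 - delta_mn) lambda^(mn) . DR,

diagonalised, and the same unitary is applied to each V_a before the
spin-orbit term is reassembled as sum_a V_a (x) S_a in the product basis of
spin-free states and spin projections.  The spin-orbit operator itself is
treated as geometry independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .angular import angular_momentum_matrices
from .errors import InputError, NumericError
from .hamiltonian import HamiltonianMatrix, hermiticity_defect

__all__ = [
    "ReferenceParametrization",
    "as_displacement",
    "evaluate_mch",
    "diagonalize",
    "transform_operator",
    "assemble_soc",
    "lvc_hamiltonian",
    "reference_hamiltonian",
]


@dataclass
class ReferenceParametrization:
    """One LVC anchor: everything needed to rebuild H at nearby geometries.

    Attributes
    ----------
    reference_geometry : (N, 3) float array, bohr
        Cartesian positions of all sites (atoms and point charges).
    site_is_atom : (N,) bool array
        True for atoms, False for solvent point charges.  Point charges
        enter displacements exactly like atoms.
    elements : tuple of str
        Site labels ('X' conventionally marks a point charge).
    reference_energies : (n,) float array, hartree
        Spin-free eigenvalues E_m at the anchor, ascending.
    gradients : (n, 3N) float array, hartree/bohr
        State gradients kappa^(m).
    nacs : (n, n, 3N) float array, hartree/bohr
        Interstate coupling vectors lambda^(mn); symmetric in (m, n),
        diagonal slots unused (zero).
    soc_operators : (3, n, n) complex array, hartree
        V_x, V_y, V_z in the anchor eigenbasis; each Hermitian.
    spin_S : float
        Half-integer total spin shared by all spin-free states (5/2 for a
        sextet lanthanide configuration).
    anchor_time : float, fs
        Trajectory time of the anchor geometry.
    ml_labels : optional (n,) int array
        Orbital projection labels for synthetic states built from a pure
        |L S M_L M_S> model; used to select a term block for spin-parameter
        projection.  None for unlabeled (ab-initio-like) states.
    """

    reference_geometry: np.ndarray
    site_is_atom: np.ndarray
    elements: tuple
    reference_energies: np.ndarray
    gradients: np.ndarray
    nacs: np.ndarray
    soc_operators: np.ndarray
    spin_S: float
    anchor_time: float = 0.0
    ml_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.reference_geometry = np.asarray(self.reference_geometry, dtype=float)
        self.site_is_atom = np.asarray(self.site_is_atom, dtype=bool)
        self.elements = tuple(self.elements)
        self.reference_energies = np.asarray(self.reference_energies, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.nacs = np.asarray(self.nacs, dtype=float)
        self.soc_operators = np.asarray(self.soc_operators, dtype=complex)
        if self.ml_labels is not None:
            self.ml_labels = np.asarray(self.ml_labels, dtype=int)
        self.validate()

    # -- sizes ---------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.reference_geometry.shape[0]

    @property
    def n_dof(self) -> int:
        return 3 * self.n_sites

    @property
    def n_states(self) -> int:
        return self.reference_energies.shape[0]

    @property
    def spin_multiplicity(self) -> int:
        return int(round(2 * self.spin_S)) + 1

    @property
    def dimension(self) -> int:
        """Order of the full product-basis Hamiltonian, n_states * (2S+1)."""
        return self.n_states * self.spin_multiplicity

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        geom = self.reference_geometry
        if geom.ndim != 2 or geom.shape[1] != 3 or geom.shape[0] < 1:
            raise InputError(f"reference_geometry must be (N, 3), got {geom.shape}")
        n_sites = geom.shape[0]
        if self.site_is_atom.shape != (n_sites,):
            raise InputError("site_is_atom length must match reference_geometry")
        if len(self.elements) != n_sites:
            raise InputError("elements length must match reference_geometry")
        n = self.reference_energies.shape[0]
        if n < 1:
            raise InputError("at least one spin-free state is required")
        if np.any(np.diff(self.reference_energies) < 0):
            raise InputError("reference_energies must be ascending")
        twos = 2 * self.spin_S
        if self.spin_S < 0 or abs(twos - round(twos)) > 1e-12:
            raise InputError(f"spin_S must be a nonnegative half-integer, got {self.spin_S}")
        dof = 3 * n_sites
        if self.gradients.shape != (n, dof):
            raise InputError(
                f"gradients must have shape {(n, dof)}, got {self.gradients.shape}"
            )
        if self.nacs.shape != (n, n, dof):
            raise InputError(
                f"nacs must have shape {(n, n, dof)}, got {self.nacs.shape}"
            )
        if not np.allclose(self.nacs, np.swapaxes(self.nacs, 0, 1)):
            raise InputError("nacs must be symmetric in the state indices")
        if self.soc_operators.shape != (3, n, n):
            raise InputError(
                f"soc_operators must have shape {(3, n, n)}, got {self.soc_operators.shape}"
            )
        for alpha, v in zip("xyz", self.soc_operators):
            if hermiticity_defect(v) > 1e-10:
                raise InputError(f"soc operator V_{alpha} is not Hermitian")
        if self.ml_labels is not None and self.ml_labels.shape != (n,):
            raise InputError("ml_labels length must match n_states")


def as_displacement(param: ReferenceParametrization, disp) -> np.ndarray:
    """Validate and flatten a displacement to a (3N,) bohr vector."""
    d = np.asarray(disp, dtype=float).reshape(-1)
    if d.shape[0] != param.n_dof:
        raise InputError(
            f"displacement has {d.shape[0]} components, expected {param.n_dof}"
        )
    if not np.all(np.isfinite(d)):
        raise InputError("displacement contains non-finite entries")
    return d


def evaluate_mch(param: ReferenceParametrization, disp) -> HamiltonianMatrix:
    """First-order spin-free Hamiltonian at displacement ``disp`` (bohr).

    Diagonal entries are E_m + kappa^(m).DR, off-diagonal (m, n) entries are
    lambda^(mn).DR; the result is real symmetric by construction.
    """
    d = as_displacement(param, disp)
    diag = param.reference_energies + param.gradients @ d
    off = param.nacs @ d
    np.fill_diagonal(off, 0.0)
    m = off + np.diag(diag)
    if not np.all(np.isfinite(m)):
        raise NumericError("MCH evaluation produced non-finite entries")
    return HamiltonianMatrix(m, "mch-eigenbasis-product")


def _fix_eigenvector_conventions(evals: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector phases and degenerate-column ordering.

    Each column is scaled so its largest-magnitude component is real and
    positive; within a degenerate cluster, columns are ordered by the index
    of their first significant component.
    """
    vecs = vecs.copy()
    dim = vecs.shape[1]
    for col in range(dim):
        idx = int(np.argmax(np.abs(vecs[:, col])))
        pivot = vecs[idx, col]
        if pivot != 0:
            vecs[:, col] *= np.conj(pivot) / abs(pivot)
    scale = max(np.max(np.abs(evals)), 1.0)
    tol = 1e-10 * scale
    start = 0
    while start < dim:
        stop = start + 1
        while stop < dim and abs(evals[stop] - evals[start]) <= tol:
            stop += 1
        if stop - start > 1:
            def first_significant(c: int) -> int:
                sig = np.flatnonzero(np.abs(vecs[:, c]) > 1e-8)
                return int(sig[0]) if sig.size else vecs.shape[0]

            order = sorted(range(start, stop), key=first_significant)
            vecs[:, start:stop] = vecs[:, order]
        start = stop
    return vecs


def diagonalize(H) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and a deterministic unitary diagonalising H.

    Accepts a :class:`HamiltonianMatrix` or a plain Hermitian array.  The
    returned transform U satisfies U^dagger H U = diag(eigenvalues); its
    column phases and degenerate-column order are fixed so repeated runs are
    bit-reproducible.
    """
    m = H.matrix if isinstance(H, HamiltonianMatrix) else np.asarray(H, dtype=complex)
    defect = hermiticity_defect(m)
    if defect > 1e-10:
        raise InputError(f"cannot diagonalize: Hermiticity defect {defect:.3e}")
    evals, vecs = np.linalg.eigh(m)
    vecs = _fix_eigenvector_conventions(evals, vecs)
    if np.isrealobj(H.matrix if isinstance(H, HamiltonianMatrix) else m):
        vecs = vecs.real.astype(complex)
    return evals, vecs


def transform_operator(operator: np.ndarray, transform: np.ndarray) -> np.ndarray:
    """Apply a basis change: U^dagger O U.

    Preserves Hermiticity, trace and the spectrum of ``operator``.
    """
    o = np.asarray(operator, dtype=complex)
    u = np.asarray(transform, dtype=complex)
    if o.ndim != 2 or o.shape[0] != o.shape[1]:
        raise InputError(f"operator must be square, got {o.shape}")
    if u.shape != o.shape:
        raise InputError(f"transform shape {u.shape} does not match operator {o.shape}")
    return u.conj().T @ o @ u


def assemble_soc(v_operators, spin_S: float) -> HamiltonianMatrix:
    """Spin-orbit Hamiltonian sum_a V_a (x) S_a in the product basis.

    ``v_operators`` are the three spatial operator matrices (x, y, z) over
    spin-free states; the product basis is spin-free-state-major with M_S
    descending within each state, so the Kronecker factors are (V, S).
    """
    vs = [np.asarray(v, dtype=complex) for v in v_operators]
    if len(vs) != 3:
        raise InputError("exactly three spatial SOC operator matrices are required")
    n = vs[0].shape[0]
    for alpha, v in zip("xyz", vs):
        if v.shape != (n, n):
            raise InputError(f"V_{alpha} has shape {v.shape}, expected {(n, n)}")
        if hermiticity_defect(v) > 1e-10:
            raise InputError(f"V_{alpha} is not Hermitian")
    spins = angular_momentum_matrices(spin_S)
    dim = n * (int(round(2 * spin_S)) + 1)
    h = np.zeros((dim, dim), dtype=complex)
    for v, s in zip(vs, spins):
        h += np.kron(v, s)
    return HamiltonianMatrix(h, "mch-eigenbasis-product")


def lvc_hamiltonian(
    param: ReferenceParametrization,
    disp,
    basis: str = "displaced",
) -> HamiltonianMatrix:
    """Full LVC Hamiltonian (spin-free + spin-orbit) at a displaced geometry.

    With ``basis='displaced'`` (default) the spin-free part is diagonalised
    and the SOC operators are rotated into the displaced eigenbasis before
    assembly, mirroring the reference electronic-structure workflow.  With
    ``basis='reference'`` the same operator is represented in the anchor's
    fixed product basis (no rotation); the two results are unitarily
    equivalent, and the fixed representation is the one used for error
    metrics because it is shared between different Hamiltonian sources.

    At zero displacement both variants reduce exactly to the anchor
    Hamiltonian diag(E) (x) 1 + sum_a V_a (x) S_a.
    """
    mch = evaluate_mch(param, disp)
    spins = angular_momentum_matrices(param.spin_S)
    mult = param.spin_multiplicity
    if basis == "reference":
        h = np.kron(mch.matrix, np.eye(mult))
        for v, s in zip(param.soc_operators, spins):
            h += np.kron(v, s)
        return HamiltonianMatrix(h, "mch-eigenbasis-product")
    if basis != "displaced":
        raise InputError(f"basis must be 'displaced' or 'reference', got {basis!r}")
    evals, u = diagonalize(mch)
    h = np.kron(np.diag(evals).astype(complex), np.eye(mult))
    for v, s in zip(param.soc_operators, spins):
        h += np.kron(transform_operator(v, u), s)
    return HamiltonianMatrix(h, "mch-eigenbasis-product")


def reference_hamiltonian(param: ReferenceParametrization) -> HamiltonianMatrix:
    """The anchor's own full Hamiltonian (zero displacement)."""
    return lvc_hamiltonian(param, np.zeros(param.n_dof), basis="reference")
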