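"""Unitary spin dynamics with a vectorised density matrix.

The density matrix is column-stacked into a vector |rho> so the
Liouville-von Neumann equation d rho/dt = -i [H, rho] becomes

    d|rho>/dt = -i G |rho>,    G = 1 (x) H  -  H^T (x) 1 ,

and each discrete step under a piecewise-constant Hamiltonian applies
exp(-i G dt).  The exponential-times-vector product is computed by a scaled
Taylor expansion: the step is divided into ceil(||G dt||_inf) equal substeps
and, within each, Taylor terms (each obtained by one application of the
exponent to the previous term) are accumulated until the next term would not
change any element by more than a small cutoff.  The dynamics are entirely
unitary: trace and purity are conserved to near machine precision, which the
propagator logs per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ConvergenceError, InputError
from .hamiltonian import HamiltonianMatrix, hermiticity_defect
from .lvc import diagonalize
from .units import KB_HARTREE_PER_K, fs_to_au

__all__ = [
    "PropagatorConfig",
    "DensityState",
    "vectorize_density",
    "unvectorize_density",
    "build_liouvillian",
    "CommutatorAction",
    "expm_times_vector",
    "thermal_state",
    "propagate",
    "population",
    "PropagationResult",
]


@dataclass
class PropagatorConfig:
    """Propagation settings.

    dt_fs : step length between Hamiltonians (fs); the MD spacing, 1 fs.
    taylor_cutoff : element-wise change below which the Taylor series stops.
    temperature : initial Boltzmann temperature (K).
    max_taylor_terms : safety bound per substep.
    """

    dt_fs: float = 1.0
    taylor_cutoff: float = 1e-14
    temperature: float = 300.0
    max_taylor_terms: int = 500

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise InputError("dt_fs must be positive")
        if self.taylor_cutoff <= 0:
            raise InputError("taylor_cutoff must be positive")


def vectorize_density(rho: np.ndarray) -> np.ndarray:
    """Column-stack a density matrix into a d^2 vector."""
    rho = np.asarray(rho, dtype=complex)
    return rho.reshape(-1, order="F")


def unvectorize_density(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_density`."""
    vec = np.asarray(vec, dtype=complex)
    d = int(round(math.sqrt(vec.size)))
    if d * d != vec.size:
        raise InputError(f"vector length {vec.size} is not a perfect square")
    return vec.reshape(d, d, order="F")


@dataclass
class DensityState:
    """A vectorised density matrix at a given time.

    Invariants (checked by :meth:`validate`): the reshaped matrix is
    Hermitian, has unit trace, and is positive semidefinite to tolerance.
    """

    vector: np.ndarray
    basis_tag: str = "initial-spin-eigenbasis"
    time: float = 0.0

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=complex).reshape(-1)

    @property
    def dimension(self) -> int:
        return int(round(math.sqrt(self.vector.size)))

    @property
    def matrix(self) -> np.ndarray:
        return unvectorize_density(self.vector)

    @property
    def trace(self) -> complex:
        return np.trace(self.matrix)

    @property
    def purity(self) -> float:
        return float(np.real(np.vdot(self.vector, self.vector)))

    def populations(self) -> np.ndarray:
        return np.real(np.diag(self.matrix))

    def validate(self, tol: float = 1e-10) -> None:
        m = self.matrix
        if hermiticity_defect(m) > tol:
            raise InputError("density matrix is not Hermitian")
        if abs(np.trace(m) - 1.0) > tol:
            raise InputError(f"density trace {np.trace(m):.12f} != 1")
        evals = np.linalg.eigvalsh(m)
        if evals.min() < -tol:
            raise InputError(f"density matrix has negative eigenvalue {evals.min():.3e}")


def build_liouvillian(H) -> np.ndarray:
    """Dense superoperator G = 1 (x) H - H^T (x) 1 (column-stacking).

    The action -i G |rho> reproduces -i vec(H rho - rho H); all eigenvalues
    of G are differences of eigenvalues of H, hence real.
    """
    m = H.matrix if isinstance(H, HamiltonianMatrix) else np.asarray(H, dtype=complex)
    if hermiticity_defect(m) > 1e-10:
        raise InputError("Liouvillian requires a Hermitian Hamiltonian")
    eye = np.eye(m.shape[0])
    return np.kron(eye, m) - np.kron(m.T, eye)


class CommutatorAction:
    """Matrix-free Liouvillian: applies G|rho> = vec(H rho - rho H).

    Equivalent to :func:`build_liouvillian` without forming the d^2 x d^2
    matrix; used by :func:`propagate` for larger Hamiltonians.
    """

    def __init__(self, h_matrix: np.ndarray):
        self.h = np.asarray(h_matrix, dtype=complex)
        if hermiticity_defect(self.h) > 1e-10:
            raise InputError("Liouvillian requires a Hermitian Hamiltonian")
        self.dim = self.h.shape[0] ** 2

    def apply(self, vec: np.ndarray) -> np.ndarray:
        rho = unvectorize_density(vec)
        return vectorize_density(self.h @ rho - rho @ self.h)

    def inf_norm(self) -> float:
        """Exact infinity norm of G, computed from rows of H.

        Row (r, c) of G sums |H[r, :]| and |H[c, :]| off their diagonals plus
        |H[r, r] - H[c, c]|.
        """
        absh = np.abs(self.h)
        offrow = absh.sum(axis=1) - np.abs(np.diag(self.h))
        diag = np.real(np.diag(self.h))
        total = offrow[:, None] + offrow[None, :] + np.abs(diag[:, None] - diag[None, :])
        return float(total.max())


def _generator_norm(g) -> float:
    if isinstance(g, CommutatorAction):
        return g.inf_norm()
    return float(np.abs(g).sum(axis=1).max())


def _generator_apply(g, vec: np.ndarray) -> np.ndarray:
    if isinstance(g, CommutatorAction):
        return g.apply(vec)
    return g @ vec


def expm_times_vector(
    g: Union[np.ndarray, CommutatorAction],
    vec: np.ndarray,
    dt_au: float,
    cfg: Optional[PropagatorConfig] = None,
) -> np.ndarray:
    """exp(-i G dt) v by substepped Taylor expansion.

    The number of substeps is the infinity norm of the dimensionless exponent
    -i G dt rounded up (at least one); within each substep terms are added
    until the next term would change no element by more than
    ``cfg.taylor_cutoff``.
    """
    cfg = cfg or PropagatorConfig()
    v = np.asarray(vec, dtype=complex).reshape(-1)
    norm = _generator_norm(g) * abs(dt_au)
    n_sub = max(1, math.ceil(norm))
    scale = -1j * dt_au / n_sub
    for _ in range(n_sub):
        acc = v
        term = v
        for k in range(1, cfg.max_taylor_terms + 1):
            term = scale / k * _generator_apply(g, term)
            if np.max(np.abs(term)) <= cfg.taylor_cutoff:
                break
            acc = acc + term
        else:
            raise ConvergenceError(
                f"Taylor series did not converge within {cfg.max_taylor_terms} terms "
                f"(substep norm {norm / n_sub:.3g}, cutoff {cfg.taylor_cutoff:g})"
            )
        v = acc
    return v


def thermal_state(H0, temperature: float) -> DensityState:
    """Boltzmann density over the eigenvalues of H0, off-diagonals zero.

    The returned state is expressed in the eigenbasis of H0 (tag
    ``initial-spin-eigenbasis``): rho = diag(p), p_i proportional to
    exp(-E_i / k_B T).
    """
    if temperature <= 0:
        raise InputError("temperature must be positive")
    m = H0.matrix if isinstance(H0, HamiltonianMatrix) else np.asarray(H0, dtype=complex)
    evals, _ = diagonalize(m)
    beta = 1.0 / (KB_HARTREE_PER_K * temperature)
    weights = np.exp(-beta * (evals - evals.min()))
    pops = weights / weights.sum()
    rho = np.diag(pops).astype(complex)
    return DensityState(vectorize_density(rho), "initial-spin-eigenbasis", 0.0)


@dataclass
class PropagationResult:
    """States plus per-step conservation and cost diagnostics."""

    states: list
    times: np.ndarray
    trace_drift: np.ndarray
    purity: np.ndarray
    substeps: np.ndarray
    initial_transform: np.ndarray = field(repr=False, default=None)

    @property
    def max_trace_drift(self) -> float:
        return float(np.max(self.trace_drift))

    def populations(self) -> np.ndarray:
        return np.stack([s.populations() for s in self.states])


def propagate(
    h_series: Sequence[HamiltonianMatrix],
    cfg: Optional[PropagatorConfig] = None,
    initial_state: Optional[DensityState] = None,
) -> PropagationResult:
    """Propagate through a piecewise-constant Hamiltonian series.

    All Hamiltonians are first rotated into the eigenbasis of the t=0
    Hamiltonian; the initial state is the thermal density there (or
    ``initial_state`` if provided, already in that basis).  Hamiltonian k
    governs the step from t_k to t_k + dt.  Returns all d^2-vector states
    (one more than the number of Hamiltonians) with trace/purity logs.
    """
    cfg = cfg or PropagatorConfig()
    if not h_series:
        raise InputError("empty Hamiltonian series")
    tags = {h.basis_tag for h in h_series}
    dims = {h.dimension for h in h_series}
    if len(tags) > 1 or len(dims) > 1:
        raise InputError(
            f"Hamiltonian series must share one basis and dimension, got {tags}, {dims}"
        )
    h0 = h_series[0]
    _, u0 = diagonalize(h0.matrix)
    rotated = [u0.conj().T @ h.matrix @ u0 for h in h_series]
    if initial_state is None:
        state0 = thermal_state(h0, cfg.temperature)
    else:
        state0 = initial_state
    dt_au = fs_to_au(cfg.dt_fs)
    v = state0.vector.copy()
    times = [0.0]
    states = [DensityState(v.copy(), "initial-spin-eigenbasis", 0.0)]
    trace_drift = [abs(states[0].trace - 1.0)]
    purity = [states[0].purity]
    substeps = []
    for k, hk in enumerate(rotated):
        action = CommutatorAction(hk)
        norm = action.inf_norm() * dt_au
        substeps.append(max(1, math.ceil(norm)))
        v = expm_times_vector(action, v, dt_au, cfg)
        t = (k + 1) * cfg.dt_fs
        state = DensityState(v.copy(), "initial-spin-eigenbasis", t)
        states.append(state)
        times.append(t)
        trace_drift.append(abs(state.trace - 1.0))
        purity.append(state.purity)
    return PropagationResult(
        states=states,
        times=np.asarray(times),
        trace_drift=np.asarray(trace_drift),
        purity=np.asarray(purity),
        substeps=np.asarray(substeps),
        initial_transform=u0,
    )


def population(state: DensityState, index: int) -> float:
    """Real diagonal element ``index`` of the reshaped density matrix."""
    d = state.dimension
    if not 0 <= index < d:
        raise InputError(f"population index {index} out of range for dimension {d}")
    return float(np.real(state.matrix[index, index]))
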