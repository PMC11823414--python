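"""Stevens crystal-field operators and the effective spin Hamiltonian.

The zero-field electron spin states of an anisotropic lanthanide complex are
modeled in the |L S M_L M_S> basis as

    H = lambda L.S + sum_{k in 2,4,6} sum_{q=-k}^{k} theta_k B_k^q (O_k^q (x) 1_S),

where lambda is the spin-orbit parameter, O_k^q are the extended Stevens
operator equivalents acting on the orbital space, theta_k are
configuration-specific operator-equivalent factors and B_k^q the crystal
field parameters.  Because the operator set {L.S, O_k^q (x) 1} is orthogonal
under the trace inner product, the parameters of an arbitrary Hermitian
matrix in this basis are recovered by simple trace ratios (least-squares
projection), and build/project round-trip exactly.

Operator convention: extended Stevens operators including the negative-q
(sine) members, built from the standard operator-equivalent polynomials
P_kq(J_z) via the symmetrised products

    O_k^{+q} = 1/4 [P_kq (J+^q + J-^q) + (J+^q + J-^q) P_kq]        (q > 0)
    O_k^{-q} = 1/(4i) [P_kq (J+^q - J-^q) + (J+^q - J-^q) P_kq]     (q > 0)
    O_k^{0}  = P_k0(J_z)

with the usual polynomials (X = J(J+1)), e.g. O_2^0 = 3 J_z^2 - X.  A golden
table of hand-evaluated matrices pins this convention in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Optional, Tuple

import numpy as np

from .angular import angular_momentum_matrices, ladder_operators, ls_coupling_operator
from .errors import InputError
from .hamiltonian import HamiltonianMatrix

__all__ = [
    "STEVENS_RANKS",
    "DY_GROUND_THETA",
    "AngularMomentumBasis",
    "SpinHamiltonianParameters",
    "stevens_operators",
    "build_spin_hamiltonian",
    "project_spin_parameters",
    "component_hamiltonians",
    "select_term_block",
]

#: Crystal-field ranks retained (time-even, f-element relevant).
STEVENS_RANKS = (2, 4, 6)

#: Tabulated Stevens operator-equivalent factors for the Dy3+ ground
#: multiplet (alpha, beta, gamma as exact rationals).  For synthetic models
#: with no physical configuration attached, theta_k = 1 is conventional.
DY_GROUND_THETA: Dict[int, float] = {
    2: float(Fraction(-2, 315)),
    4: float(Fraction(-8, 135135)),
    6: float(Fraction(4, 3864861)),
}

UNIT_THETA: Dict[int, float] = {2: 1.0, 4: 1.0, 6: 1.0}


@dataclass(frozen=True)
class AngularMomentumBasis:
    """The |L S M_L M_S> product basis, M_L-major, both projections descending."""

    L: int
    S: float

    def __post_init__(self) -> None:
        if self.L < 0 or self.L != int(self.L):
            raise InputError(f"L must be a nonnegative integer, got {self.L}")
        twos = 2 * self.S
        if self.S < 0 or abs(twos - round(twos)) > 1e-12:
            raise InputError(f"S must be a nonnegative half-integer, got {self.S}")

    @property
    def orbital_dimension(self) -> int:
        return 2 * int(self.L) + 1

    @property
    def spin_dimension(self) -> int:
        return int(round(2 * self.S)) + 1

    @property
    def dimension(self) -> int:
        return self.orbital_dimension * self.spin_dimension


@dataclass
class SpinHamiltonianParameters:
    """Spin-orbit parameter lambda plus the 27 crystal-field parameters B_k^q.

    ``cfps`` maps (k, q) -> B_k^q in hartree for k in {2, 4, 6}, |q| <= k;
    ``theta`` maps k -> theta_k (dimensionless, nonzero).
    """

    lambda_soc: float
    cfps: Dict[Tuple[int, int], float]
    L: int
    S: float
    theta: Dict[int, float] = field(default_factory=lambda: dict(UNIT_THETA))

    def __post_init__(self) -> None:
        expected = {(k, q) for k in STEVENS_RANKS for q in range(-k, k + 1)}
        missing = expected - set(self.cfps)
        extra = set(self.cfps) - expected
        if missing or extra:
            raise InputError(
                f"cfps must hold exactly the 27 (k, q) slots; missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        for k in STEVENS_RANKS:
            if k not in self.theta or self.theta[k] == 0:
                raise InputError(f"theta_{k} must be present and nonzero")

    @property
    def basis(self) -> AngularMomentumBasis:
        return AngularMomentumBasis(self.L, self.S)

    @classmethod
    def zeros(cls, L: int, S: float, theta: Optional[Dict[int, float]] = None):
        cfps = {(k, q): 0.0 for k in STEVENS_RANKS for q in range(-k, k + 1)}
        return cls(0.0, cfps, L, S, dict(theta or UNIT_THETA))


# ---------------------------------------------------------------------------
# Stevens operators
# ---------------------------------------------------------------------------

def _stevens_polynomial(k: int, q: int, jz: np.ndarray, x: float) -> np.ndarray:
    """P_kq(J_z): the operator-equivalent polynomial for rank k, |q| = q."""
    dim = jz.shape[0]
    eye = np.eye(dim, dtype=complex)
    jz2 = jz @ jz
    jz3 = jz2 @ jz
    jz4 = jz2 @ jz2
    jz5 = jz4 @ jz
    jz6 = jz4 @ jz2
    table = {
        (2, 0): 3 * jz2 - x * eye,
        (2, 1): jz,
        (2, 2): eye,
        (4, 0): 35 * jz4 - (30 * x - 25) * jz2 + (3 * x**2 - 6 * x) * eye,
        (4, 1): 7 * jz3 - (3 * x + 1) * jz,
        (4, 2): 7 * jz2 - (x + 5) * eye,
        (4, 3): jz,
        (4, 4): eye,
        (6, 0): (
            231 * jz6
            - (315 * x - 735) * jz4
            + (105 * x**2 - 525 * x + 294) * jz2
            + (-5 * x**3 + 40 * x**2 - 60 * x) * eye
        ),
        (6, 1): 33 * jz5 - (30 * x - 15) * jz3 + (5 * x**2 - 10 * x + 12) * jz,
        (6, 2): 33 * jz4 - (18 * x + 123) * jz2 + (x**2 + 10 * x + 102) * eye,
        (6, 3): 11 * jz3 - (3 * x + 59) * jz,
        (6, 4): 11 * jz2 - (x + 38) * eye,
        (6, 5): jz,
        (6, 6): eye,
    }
    return table[(k, q)]


def stevens_operators(L: int) -> Dict[Tuple[int, int], np.ndarray]:
    """The 27 extended Stevens operators O_k^q on the (2L+1)-dim orbital space.

    Each operator is Hermitian and traceless, and the full set is mutually
    orthogonal under Tr(A^dagger B).  For 2L < k the corresponding operators
    vanish identically (they are returned as zero matrices; a ``UserWarning``
    is emitted since the associated B_k^q are then unprojectable).
    """
    if L < 0 or L != int(L):
        raise InputError(f"L must be a nonnegative integer, got {L}")
    L = int(L)
    _, _, jz = angular_momentum_matrices(float(L))
    jplus, jminus = ladder_operators(float(L))
    x = L * (L + 1)
    ops: Dict[Tuple[int, int], np.ndarray] = {}
    degenerate_ranks = [k for k in STEVENS_RANKS if 2 * L < k]
    if degenerate_ranks:
        import warnings

        warnings.warn(
            f"rank(s) {degenerate_ranks} Stevens operators vanish for L={L}; "
            "the corresponding B_k^q cannot be represented",
            UserWarning,
            stacklevel=2,
        )
    for k in STEVENS_RANKS:
        ops[(k, 0)] = _stevens_polynomial(k, 0, jz, x)
        jp_q = np.eye(2 * L + 1, dtype=complex)
        jm_q = np.eye(2 * L + 1, dtype=complex)
        for q in range(1, k + 1):
            jp_q = jp_q @ jplus
            jm_q = jm_q @ jminus
            p = _stevens_polynomial(k, q, jz, x)
            cos_comb = jp_q + jm_q
            sin_comb = jp_q - jm_q
            ops[(k, q)] = 0.25 * (p @ cos_comb + cos_comb @ p)
            ops[(k, -q)] = -0.25j * (p @ sin_comb + sin_comb @ p)
    return ops


# ---------------------------------------------------------------------------
# Spin Hamiltonian build / project
# ---------------------------------------------------------------------------

def _operator_set(
    L: int, S: float, theta: Dict[int, float]
) -> tuple[np.ndarray, Dict[Tuple[int, int], np.ndarray]]:
    """L.S and the theta-scaled Stevens operators lifted to the product space."""
    ls = ls_coupling_operator(L, S)
    spin_dim = int(round(2 * S)) + 1
    eye_s = np.eye(spin_dim)
    lifted = {
        kq: theta[kq[0]] * np.kron(op, eye_s)
        for kq, op in stevens_operators(L).items()
    }
    return ls, lifted


def build_spin_hamiltonian(p: SpinHamiltonianParameters) -> HamiltonianMatrix:
    """H = lambda L.S + sum_kq theta_k B_k^q (O_k^q (x) 1_S), in the term basis."""
    ls, lifted = _operator_set(p.L, p.S, p.theta)
    h = p.lambda_soc * ls
    for kq, op in lifted.items():
        b = p.cfps[kq]
        if b != 0.0:
            h = h + b * op
    return HamiltonianMatrix(h, "term-basis")


def project_spin_parameters(
    H,
    basis: AngularMomentumBasis,
    theta: Optional[Dict[int, float]] = None,
) -> tuple[SpinHamiltonianParameters, float]:
    """Trace-orthogonal least-squares projection of (lambda, B_k^q) from H.

    Returns the recovered parameters together with the Frobenius norm of the
    residual (the part of H outside the span of the operator set, including
    any identity/trace component).  Round-trips
    :func:`build_spin_hamiltonian` to machine precision.
    """
    m = H.matrix if isinstance(H, HamiltonianMatrix) else np.asarray(H, dtype=complex)
    if m.shape != (basis.dimension, basis.dimension):
        raise InputError(
            f"Hamiltonian dimension {m.shape} does not match basis "
            f"dimension {basis.dimension}"
        )
    theta = dict(theta or UNIT_THETA)
    ls, lifted = _operator_set(basis.L, basis.S, theta)
    lam = float(np.real(np.vdot(ls, m)) / np.real(np.vdot(ls, ls)))
    residual = m - lam * ls
    cfps: Dict[Tuple[int, int], float] = {}
    for kq, op in lifted.items():
        denom = np.real(np.vdot(op, op))
        if denom == 0.0:  # vanishing operator (2L < k)
            cfps[kq] = 0.0
            continue
        b = float(np.real(np.vdot(op, m)) / denom)
        cfps[kq] = b
        residual = residual - b * op
    params = SpinHamiltonianParameters(lam, cfps, basis.L, basis.S, theta)
    return params, float(np.linalg.norm(residual))


def component_hamiltonians(
    p: SpinHamiltonianParameters,
) -> tuple[HamiltonianMatrix, HamiltonianMatrix]:
    """(SOC-only, crystal-field-only) pieces; they sum to the full build."""
    soc_only = SpinHamiltonianParameters.zeros(p.L, p.S, p.theta)
    soc_only.lambda_soc = p.lambda_soc
    cf_only = SpinHamiltonianParameters(0.0, dict(p.cfps), p.L, p.S, dict(p.theta))
    return build_spin_hamiltonian(soc_only), build_spin_hamiltonian(cf_only)


def select_term_block(
    H,
    ml_labels: np.ndarray,
    L: int,
    spin_multiplicity: int,
) -> np.ndarray:
    """Extract the |L S M_L M_S> block of a product-basis Hamiltonian.

    ``ml_labels`` assigns an M_L value to every spin-free state (labels
    outside [-L, L] or duplicated are rejected); states of the target term
    must appear exactly once per M_L.  The returned (2L+1)(2S+1) matrix is
    reordered M_L-descending so it lives in the standard term basis.
    """
    m = H.matrix if isinstance(H, HamiltonianMatrix) else np.asarray(H, dtype=complex)
    ml = np.asarray(ml_labels)
    wanted = np.arange(L, -L - 1, -1)
    state_order = []
    for target in wanted:
        hits = np.flatnonzero(ml == target)
        if hits.size != 1:
            raise InputError(
                f"term block needs exactly one state with M_L={target}, found {hits.size}"
            )
        state_order.append(int(hits[0]))
    idx = np.concatenate(
        [np.arange(s * spin_multiplicity, (s + 1) * spin_multiplicity) for s in state_order]
    )
    return m[np.ix_(idx, idx)]
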