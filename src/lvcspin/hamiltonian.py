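"""Hermitian Hamiltonian matrices tagged with the basis they are expressed in."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

#: Recognised basis tags.
#:
#: ``mch-eigenbasis-product``  – product of spin-free MCH eigenstates with
#:     the spin projections (state-major, M_S descending within each state);
#: ``term-basis``              – |L S M_L M_S> (M_L-major, both descending);
#: ``so-eigenbasis``           – eigenbasis of a spin-orbit-coupled Hamiltonian;
#: ``initial-spin-eigenbasis`` – eigenbasis of the t=0 Hamiltonian used for
#:     the dynamics.
BASIS_TAGS = (
    "mch-eigenbasis-product",
    "term-basis",
    "so-eigenbasis",
    "initial-spin-eigenbasis",
)

#: Relative Frobenius tolerance used for Hermiticity validation.
HERMITICITY_RTOL = 1e-12


def hermiticity_defect(matrix: np.ndarray) -> float:
    """Relative Frobenius deviation of ``matrix`` from its adjoint.

    Returns 0 for the zero matrix.
    """
    m = np.asarray(matrix)
    scale = np.linalg.norm(m)
    if scale == 0.0:
        return 0.0
    return float(np.linalg.norm(m - m.conj().T) / scale)


@dataclass(frozen=True)
class HamiltonianMatrix:
    """A Hermitian complex matrix (hartree) with a basis tag.

    The constructor validates squareness, the basis tag, and Hermiticity to
    within ``HERMITICITY_RTOL`` (relative Frobenius norm).
    """

    matrix: np.ndarray
    basis_tag: str = "mch-eigenbasis-product"
    _skip_checks: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        object.__setattr__(self, "matrix", m)
        if self._skip_checks:
            return
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError(f"Hamiltonian must be square, got shape {m.shape}")
        if self.basis_tag not in BASIS_TAGS:
            raise InputError(
                f"unknown basis tag {self.basis_tag!r}; expected one of {BASIS_TAGS}"
            )
        if not np.all(np.isfinite(m)):
            raise InputError("Hamiltonian contains non-finite entries")
        defect = hermiticity_defect(m)
        if defect > HERMITICITY_RTOL:
            raise InputError(
                f"matrix is not Hermitian: relative defect {defect:.3e} "
                f"exceeds {HERMITICITY_RTOL:.0e}"
            )

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def with_matrix(self, matrix: np.ndarray) -> "HamiltonianMatrix":
        """A copy carrying ``matrix`` and the same basis tag."""
        return HamiltonianMatrix(matrix, self.basis_tag)
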