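"""Angular momentum matrices in the |j m> basis with m descending.

The descending-m convention (m = j, j-1, ..., -j) is used everywhere in the
package, for spin, orbital and total angular momenta alike.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError


def _check_half_integer(j: float) -> float:
    twoj = 2.0 * j
    if j < 0 or abs(twoj - round(twoj)) > 1e-12:
        raise InputError(f"j must be a nonnegative half-integer, got {j}")
    return round(twoj) / 2.0


def angular_momentum_matrices(j: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (J_x, J_y, J_z) for angular momentum ``j`` (hbar = 1).

    Matrices are complex (2j+1)x(2j+1), with J_z = diag(j, j-1, ..., -j).
    Ladder matrix elements follow <m±1|J±|m> = sqrt(j(j+1) - m(m±1)).
    """
    j = _check_half_integer(j)
    dim = int(round(2 * j)) + 1
    m = j - np.arange(dim)  # descending
    jz = np.diag(m).astype(complex)
    jplus = np.zeros((dim, dim), dtype=complex)
    for col in range(1, dim):
        mc = m[col]
        jplus[col - 1, col] = np.sqrt(j * (j + 1) - mc * (mc + 1))
    jminus = jplus.conj().T
    jx = 0.5 * (jplus + jminus)
    jy = -0.5j * (jplus - jminus)
    return jx, jy, jz


def ladder_operators(j: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (J_+, J_-) for angular momentum ``j``."""
    jx, jy, _ = angular_momentum_matrices(j)
    return jx + 1j * jy, jx - 1j * jy


def ls_coupling_operator(L: int, S: float) -> np.ndarray:
    """Matrix of L.S = sum_a L_a (x) S_a in the |L S M_L M_S> product basis.

    Ordering is M_L-major with M_L and M_S both descending, matching the
    term-basis convention of :mod:`lvcspin.stevens`.
    """
    lx, ly, lz = angular_momentum_matrices(float(L))
    sx, sy, sz = angular_momentum_matrices(S)
    return (
        np.kron(lx, sx) + np.kron(ly, sy) + np.kron(lz, sz)
    )
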