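"""Stevens operators and the effective spin Hamiltonian build/projection."""

import json
from pathlib import Path

import numpy as np
import pytest

from lvcspin.angular import angular_momentum_matrices, ls_coupling_operator
from lvcspin.errors import InputError
from lvcspin.stevens import (
    DY_GROUND_THETA,
    AngularMomentumBasis,
    SpinHamiltonianParameters,
    build_spin_hamiltonian,
    component_hamiltonians,
    project_spin_parameters,
    select_term_block,
    stevens_operators,
)

GOLDEN = json.loads((Path(__file__).parent / "data" / "stevens_golden.json").read_text())


def random_parameters(rng, L=5, S=2.5, scale=1e-4, theta=None):
    cfps = {(k, q): float(rng.normal(scale=scale)) for k in (2, 4, 6) for q in range(-k, k + 1)}
    return SpinHamiltonianParameters(
        float(rng.normal(scale=10 * scale)), cfps, L, S, dict(theta or {2: 1.0, 4: 1.0, 6: 1.0})
    )


class TestAngularMomentum:
    @pytest.mark.parametrize("j", [0.5, 1.0, 2.5, 5.0])
    def test_casimir_and_commutator(self, j):
        jx, jy, jz = angular_momentum_matrices(j)
        dim = int(2 * j) + 1
        assert np.allclose(jx @ jx + jy @ jy + jz @ jz, j * (j + 1) * np.eye(dim), atol=1e-12)
        assert np.allclose(jx @ jy - jy @ jx, 1j * jz, atol=1e-12)

    def test_jz_descending_and_ladder_element(self):
        _, _, jz = angular_momentum_matrices(0.5)
        assert np.allclose(np.diag(jz), [0.5, -0.5])
        jx, _, _ = angular_momentum_matrices(1.0)
        assert np.isclose(jx[0, 1], 1 / np.sqrt(2))

    def test_non_half_integer_rejected(self):
        with pytest.raises(InputError):
            angular_momentum_matrices(0.7)


class TestStevensOperators:
    def test_golden_matrices(self):
        with pytest.warns(UserWarning):
            ops1 = stevens_operators(1)
        assert np.allclose(np.real(np.diag(ops1[(2, 0)])), GOLDEN["O20_J1_diag"])
        assert np.allclose(ops1[(2, 2)].real, GOLDEN["O22_J1"])
        assert np.isclose(ops1[(2, 1)][0, 1].real, GOLDEN["O21_J1_entry_01"])
        with pytest.warns(UserWarning):
            ops2 = stevens_operators(2)
        assert np.allclose(np.real(np.diag(ops2[(4, 0)])), GOLDEN["O40_J2_diag"])
        ops3 = stevens_operators(3)
        assert np.allclose(np.real(np.diag(ops3[(6, 0)])), GOLDEN["O60_J3_diag"])

    def test_hermitian_traceless_orthogonal(self):
        ops = stevens_operators(5)
        assert len(ops) == 27
        mats = list(ops.values())
        for m in mats:
            assert np.allclose(m, m.conj().T, atol=1e-10)
            assert abs(np.trace(m)) < 1e-10
        gram = np.array([[np.vdot(a, b) for b in mats] for a in mats])
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-10 * np.abs(np.diag(gram)).min()

    def test_vanishing_ranks_warn_and_are_zero(self):
        with pytest.warns(UserWarning):
            ops = stevens_operators(1)
        for q in range(-6, 7):
            assert np.allclose(ops[(6, q)], 0.0, atol=1e-12)


class TestBuildSpinHamiltonian:
    def test_lande_interval_spectrum(self):
        lam, L, S = 1.5e-3, 5, 2.5
        p = SpinHamiltonianParameters.zeros(L, S)
        p.lambda_soc = lam
        evals = np.sort(np.linalg.eigvalsh(build_spin_hamiltonian(p).matrix))
        expected = np.sort(
            np.concatenate(
                [
                    np.full(int(2 * J + 1), lam * (J * (J + 1) - L * (L + 1) - S * (S + 1)) / 2)
                    for J in np.arange(abs(L - S), L + S + 1)
                ]
            )
        )
        assert np.allclose(evals, expected, atol=1e-12)

    def test_axial_b20_diagonal(self):
        L, S = 2, 0.5
        p = SpinHamiltonianParameters.zeros(L, S, {2: 0.5, 4: 1.0, 6: 1.0})
        b20 = 2.3e-4
        p.cfps[(2, 0)] = b20
        with pytest.warns(UserWarning):
            h = build_spin_hamiltonian(p).matrix
        mls = np.repeat(np.arange(L, -L - 1, -1), 2)
        expected = 0.5 * b20 * (3 * mls**2 - L * (L + 1))
        assert np.allclose(np.diag(h).real, expected, atol=1e-15)
        assert np.allclose(h, np.diag(np.diag(h)))

    def test_all_zero_parameters(self):
        p = SpinHamiltonianParameters.zeros(5, 2.5)
        assert np.allclose(build_spin_hamiltonian(p).matrix, 0.0)

    def test_jz_symmetry_iff_axial(self, rng):
        L, S = 5, 2.5
        lz = angular_momentum_matrices(float(L))[2]
        sz = angular_momentum_matrices(S)[2]
        jz = np.kron(lz, np.eye(6)) + np.kron(np.eye(11), sz)
        axial = SpinHamiltonianParameters.zeros(L, S)
        axial.lambda_soc = 1e-3
        for k in (2, 4, 6):
            axial.cfps[(k, 0)] = float(rng.normal(scale=1e-4))
        h = build_spin_hamiltonian(axial).matrix
        assert np.abs(h @ jz - jz @ h).max() < 1e-12
        full = random_parameters(rng)
        h2 = build_spin_hamiltonian(full).matrix
        assert np.abs(h2 @ jz - jz @ h2).max() > 1e-8

    def test_kramers_degeneracy(self, rng):
        for _ in range(5):
            p = random_parameters(rng)
            evals = np.sort(np.linalg.eigvalsh(build_spin_hamiltonian(p).matrix))
            assert np.abs(evals[0::2] - evals[1::2]).max() < 1e-9


class TestProjection:
    def test_roundtrip_unit_theta(self, rng):
        p = random_parameters(rng)
        h = build_spin_hamiltonian(p)
        rec, residual = project_spin_parameters(h, AngularMomentumBasis(5, 2.5))
        assert abs(rec.lambda_soc - p.lambda_soc) <= 1e-10 * abs(p.lambda_soc)
        for kq, v in p.cfps.items():
            assert abs(rec.cfps[kq] - v) <= 1e-10 * max(abs(v), 1e-12)
        assert residual < 1e-12

    def test_roundtrip_dy_theta(self, rng):
        p = random_parameters(rng, theta=DY_GROUND_THETA)
        h = build_spin_hamiltonian(p)
        rec, residual = project_spin_parameters(
            h, AngularMomentumBasis(5, 2.5), DY_GROUND_THETA
        )
        for kq, v in p.cfps.items():
            assert abs(rec.cfps[kq] - v) <= 1e-9 * max(abs(v), 1e-12)
        assert residual < 1e-12

    def test_zero_hamiltonian_gives_zero_parameters(self):
        from lvcspin.hamiltonian import HamiltonianMatrix

        h = HamiltonianMatrix(np.zeros((66, 66), dtype=complex), "term-basis")
        rec, residual = project_spin_parameters(h, AngularMomentumBasis(5, 2.5))
        assert rec.lambda_soc == 0.0
        assert all(v == 0.0 for v in rec.cfps.values())
        assert residual == 0.0

    def test_orthogonal_perturbation_ignored(self, rng):
        """Adding a component outside the operator span must not shift the
        recovered parameters (here: a traceless spin-only perturbation that
        is trace-orthogonal to L.S and to every O_k^q (x) 1)."""
        p = random_parameters(rng)
        h = build_spin_hamiltonian(p).matrix
        sz = angular_momentum_matrices(2.5)[2]
        pert = 1e-3 * np.kron(np.eye(11), sz @ sz - np.trace(sz @ sz) / 6 * np.eye(6))
        from lvcspin.hamiltonian import HamiltonianMatrix

        rec, residual = project_spin_parameters(
            HamiltonianMatrix(h + pert, "term-basis"), AngularMomentumBasis(5, 2.5)
        )
        assert abs(rec.lambda_soc - p.lambda_soc) <= 1e-9 * abs(p.lambda_soc)
        for kq, v in p.cfps.items():
            assert abs(rec.cfps[kq] - v) <= 1e-9 * max(abs(v), 1e-12)
        assert residual == pytest.approx(np.linalg.norm(pert), rel=1e-9)

    def test_dimension_mismatch_rejected(self):
        from lvcspin.hamiltonian import HamiltonianMatrix

        h = HamiltonianMatrix(np.zeros((10, 10), dtype=complex), "term-basis")
        with pytest.raises(InputError):
            project_spin_parameters(h, AngularMomentumBasis(5, 2.5))


class TestComponents:
    def test_sum_property(self, rng):
        p = random_parameters(rng)
        soc, cf = component_hamiltonians(p)
        full = build_spin_hamiltonian(p)
        assert np.allclose(soc.matrix + cf.matrix, full.matrix, atol=1e-14)

    def test_zero_cf_when_no_cfps(self):
        p = SpinHamiltonianParameters.zeros(5, 2.5)
        p.lambda_soc = 1e-3
        soc, cf = component_hamiltonians(p)
        assert np.allclose(cf.matrix, 0.0)
        assert np.allclose(soc.matrix, 1e-3 * ls_coupling_operator(5, 2.5))


class TestTermBlockSelection:
    def test_label_selection_recovers_pure_term(self, rng):
        """Embed a 66-dim term Hamiltonian into a larger labeled state space
        and recover it by M_L-label selection."""
        p = random_parameters(rng)
        h_term = build_spin_hamiltonian(p).matrix
        n_states, mult = 14, 6
        labels = np.concatenate([np.arange(5, -6, -1), [100, 101, 102]])
        order = rng.permutation(n_states)
        labels = labels[order]
        big = np.zeros((n_states * mult, n_states * mult), dtype=complex)
        # scatter the term block into the permuted big matrix
        pos = {int(l): i for i, l in enumerate(labels) if l <= 50}
        for a, ml_a in enumerate(range(5, -6, -1)):
            for b, ml_b in enumerate(range(5, -6, -1)):
                ia, ib = pos[ml_a], pos[ml_b]
                big[
                    ia * mult : (ia + 1) * mult, ib * mult : (ib + 1) * mult
                ] = h_term[a * mult : (a + 1) * mult, b * mult : (b + 1) * mult]
        block = select_term_block(big, labels, 5, mult)
        assert np.allclose(block, h_term, atol=1e-14)

    def test_missing_label_rejected(self):
        labels = np.arange(5, -6, -1)
        labels[3] = 99
        with pytest.raises(InputError):
            select_term_block(np.zeros((66, 66)), labels, 5, 6)
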