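"""Core LVC reconstruction: first-order spin-free expansion, diagonalization,
operator transforms and spin-orbit assembly."""

import numpy as np
import pytest

from lvcspin import (
    HamiltonianMatrix,
    assemble_soc,
    diagonalize,
    evaluate_mch,
    hamiltonian_error,
    lvc_hamiltonian,
    reference_hamiltonian,
    transform_operator,
)
from lvcspin.angular import angular_momentum_matrices
from lvcspin.errors import InputError
from lvcspin.lvc import ReferenceParametrization, as_displacement
from lvcspin import synthetic as syn

from conftest import random_hermitian


def two_state_toy():
    """E = (0, 0.01) Ha, kappa = 0, lambda^(12) chosen so lambda.DR = 0.005."""
    nacs = np.zeros((2, 2, 3))
    nacs[0, 1] = nacs[1, 0] = [0.005, 0.0, 0.0]
    return ReferenceParametrization(
        reference_geometry=np.zeros((1, 3)),
        site_is_atom=np.array([True]),
        elements=("N",),
        reference_energies=np.array([0.0, 0.01]),
        gradients=np.zeros((2, 3)),
        nacs=nacs,
        soc_operators=np.zeros((3, 2, 2), dtype=complex),
        spin_S=0.0,
    )


class TestEvaluateMch:
    def test_zero_displacement_gives_reference_energies(self, small_param):
        h = evaluate_mch(small_param, np.zeros(small_param.n_dof))
        assert np.allclose(h.matrix, np.diag(small_param.reference_energies))

    def test_two_state_coupling_and_eigenvalues(self):
        param = two_state_toy()
        h = evaluate_mch(param, np.array([1.0, 0.0, 0.0]))
        assert np.allclose(h.matrix, [[0.0, 0.005], [0.005, 0.01]])
        evals, _ = diagonalize(h)
        expected = 0.005 + np.array([-1, 1]) * np.sqrt(0.005**2 + 0.005**2)
        assert np.allclose(evals, expected, atol=1e-15)

    def test_single_state_reduces_to_gradient_shift(self):
        param = ReferenceParametrization(
            reference_geometry=np.zeros((1, 3)),
            site_is_atom=np.array([True]),
            elements=("N",),
            reference_energies=np.array([0.1]),
            gradients=np.array([[0.002, 0.0, 0.0]]),
            nacs=np.zeros((1, 1, 3)),
            soc_operators=np.zeros((3, 1, 1), dtype=complex),
            spin_S=0.0,
        )
        h = evaluate_mch(param, [1.0, 0.0, 0.0])
        assert np.allclose(h.matrix, [[0.102]])

    def test_linearity_in_displacement(self, small_param, rng):
        d1 = rng.normal(size=small_param.n_dof)
        d2 = rng.normal(size=small_param.n_dof)
        e0 = np.diag(small_param.reference_energies)
        a, b = 0.7, -1.3
        lhs = evaluate_mch(small_param, a * d1 + b * d2).matrix - e0
        rhs = a * (evaluate_mch(small_param, d1).matrix - e0) + b * (
            evaluate_mch(small_param, d2).matrix - e0
        )
        assert np.allclose(lhs, rhs, atol=1e-14)

    def test_dimension_mismatch_rejected(self, small_param):
        with pytest.raises(InputError):
            evaluate_mch(small_param, np.zeros(small_param.n_dof + 1))
        with pytest.raises(InputError):
            as_displacement(small_param, [np.nan] * small_param.n_dof)


class TestDiagonalize:
    def test_diagonal_input_passthrough(self):
        h = HamiltonianMatrix(np.diag([3.0, 1.0, 2.0]).astype(complex))
        evals, u = diagonalize(h)
        assert np.allclose(evals, [1.0, 2.0, 3.0])
        # transform is a permutation of the identity columns
        perm = np.abs(u)
        assert np.allclose(perm @ perm.T, np.eye(3), atol=1e-12)
        assert np.allclose(np.sort(perm, axis=0)[-1], 1.0, atol=1e-12)

    def test_roundtrip_reconstruction(self, rng):
        m = random_hermitian(rng, 10)
        evals, u = diagonalize(HamiltonianMatrix(m))
        assert np.allclose(u @ np.diag(evals) @ u.conj().T, m, atol=1e-12)
        assert np.allclose(u.conj().T @ u, np.eye(10), atol=1e-12)
        assert np.all(np.diff(evals) >= 0)

    def test_deterministic_phases(self, rng):
        m = random_hermitian(rng, 6)
        _, u1 = diagonalize(HamiltonianMatrix(m))
        _, u2 = diagonalize(HamiltonianMatrix(m.copy()))
        assert np.array_equal(u1, u2)

    def test_non_hermitian_rejected(self):
        with pytest.raises(InputError):
            diagonalize(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestTransformOperator:
    def test_identity_transform_is_noop(self, rng):
        o = random_hermitian(rng, 5)
        assert np.allclose(transform_operator(o, np.eye(5)), o)

    def test_unitary_invariants(self, rng):
        o = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        u = np.linalg.qr(random_hermitian(rng, 6) + 1j * np.eye(6))[0]
        out = transform_operator(o, u)
        assert np.isclose(np.trace(out), np.trace(o))
        assert np.isclose(np.linalg.norm(out), np.linalg.norm(o))
        assert np.allclose(transform_operator(np.eye(6), u), np.eye(6), atol=1e-14)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            transform_operator(np.eye(3), np.eye(4))


class TestAssembleSoc:
    def test_zero_operators_give_zero(self):
        h = assemble_soc(np.zeros((3, 2, 2)), 0.5)
        assert np.allclose(h.matrix, 0.0)

    def test_vz_splitting_spin_half(self):
        v = 0.013
        vs = np.zeros((3, 1, 1), dtype=complex)
        vs[2, 0, 0] = v
        h = assemble_soc(vs, 0.5)
        assert np.allclose(h.matrix, np.diag([v / 2, -v / 2]))

    def test_matches_elementwise_wigner_sum(self, rng):
        vs = np.stack([random_hermitian(rng, 2) for _ in range(3)])
        s_mats = angular_momentum_matrices(0.5)
        h = assemble_soc(vs, 0.5).matrix
        brute = np.zeros((4, 4), dtype=complex)
        for m in range(2):
            for n in range(2):
                for ms in range(2):
                    for msp in range(2):
                        val = sum(
                            vs[a][m, n] * s_mats[a][ms, msp] for a in range(3)
                        )
                        brute[2 * m + ms, 2 * n + msp] = val
        assert np.allclose(h, brute, atol=1e-14)

    def test_non_hermitian_rejected(self, rng):
        bad = np.zeros((3, 2, 2), dtype=complex)
        bad[0, 0, 1] = 1.0
        with pytest.raises(InputError):
            assemble_soc(bad, 0.5)


class TestLvcHamiltonian:
    def test_exact_at_anchor(self, small_param):
        h = lvc_hamiltonian(small_param, np.zeros(small_param.n_dof))
        ref = reference_hamiltonian(small_param)
        assert hamiltonian_error(h, ref) < 1e-12

    def test_constant_model_ignores_displacement(self, rng):
        param = syn.generate_parametrization(
            n_states=3,
            spin_S=0.5,
            n_sites=2,
            scales=syn.ParamScales(gradient=0.0, nac=0.0),
            seed=1,
        )
        d = rng.normal(size=param.n_dof)
        h = lvc_hamiltonian(param, d)
        h0 = lvc_hamiltonian(param, np.zeros(param.n_dof))
        assert np.allclose(h.matrix, h0.matrix, atol=1e-13)

    def test_displaced_and_reference_basis_agree_spectrally(self, small_param, rng):
        d = 0.1 * rng.normal(size=small_param.n_dof)
        hd = lvc_hamiltonian(small_param, d, basis="displaced")
        hr = lvc_hamiltonian(small_param, d, basis="reference")
        assert np.allclose(
            np.linalg.eigvalsh(hd.matrix), np.linalg.eigvalsh(hr.matrix), atol=1e-12
        )

    def test_soc_norm_invariant_under_displacement(self, small_param, rng):
        """The MCH rotation is unitary, so the SOC block's Frobenius norm
        cannot depend on the displacement."""
        mult = small_param.spin_multiplicity
        e = np.zeros(small_param.n_dof)
        soc_ref = (
            lvc_hamiltonian(small_param, e).matrix
            - np.kron(np.diag(small_param.reference_energies), np.eye(mult))
        )
        from lvcspin.lvc import evaluate_mch as _emch

        for _ in range(3):
            d = 0.2 * rng.normal(size=small_param.n_dof)
            hd = lvc_hamiltonian(small_param, d)
            evals, _u = diagonalize(_emch(small_param, d))
            soc_d = hd.matrix - np.kron(np.diag(evals), np.eye(mult))
            assert np.isclose(
                np.linalg.norm(soc_d), np.linalg.norm(soc_ref), rtol=1e-10
            )

    def test_error_grows_with_quadratic_truth_amplitude(self, small_param):
        truth = syn.make_ground_truth(small_param, seed=5)
        direction = np.ones(small_param.n_dof) / np.sqrt(small_param.n_dof)
        errors = []
        for amp in (0.01, 0.02, 0.04):
            d = amp * direction
            errors.append(
                hamiltonian_error(
                    lvc_hamiltonian(small_param, d, basis="reference"),
                    truth.hamiltonian(d),
                )
            )
        assert errors[0] < errors[1] < errors[2]

    def test_returned_matrices_are_hermitian(self, sextet_param, rng):
        d = 0.1 * rng.normal(size=sextet_param.n_dof)
        from lvcspin.hamiltonian import hermiticity_defect

        assert hermiticity_defect(lvc_hamiltonian(sextet_param, d).matrix) < 1e-12


class TestParametrizationValidation:
    def test_rejects_unsorted_energies(self, small_param):
        with pytest.raises(InputError):
            ReferenceParametrization(
                reference_geometry=small_param.reference_geometry,
                site_is_atom=small_param.site_is_atom,
                elements=small_param.elements,
                reference_energies=small_param.reference_energies[::-1].copy(),
                gradients=small_param.gradients,
                nacs=small_param.nacs,
                soc_operators=small_param.soc_operators,
                spin_S=small_param.spin_S,
            )

    def test_rejects_wrong_gradient_shape(self, small_param):
        with pytest.raises(InputError):
            ReferenceParametrization(
                reference_geometry=small_param.reference_geometry,
                site_is_atom=small_param.site_is_atom,
                elements=small_param.elements,
                reference_energies=small_param.reference_energies,
                gradients=small_param.gradients[:, :-1],
                nacs=small_param.nacs,
                soc_operators=small_param.soc_operators,
                spin_S=small_param.spin_S,
            )

    def test_dimension_counts(self, sextet_param):
        assert sextet_param.spin_multiplicity == 6
        assert sextet_param.dimension == 72
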