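"""RDC back-calculation, scoring, scaling and SVD tensor fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdcsel.constants import d_max
from rdcsel.rdc import (
    AlignmentTensor,
    RDCSet,
    back_calculate,
    ensemble_average,
    fit_tensor_svd,
    optimal_scale,
    q_factor,
)
from rdcsel.structure import Structure


def _structure_from_vectors(vectors):
    """One N-H pair per residue with the given bond directions."""
    vectors = np.asarray(vectors, dtype=float)
    vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    n = len(vectors)
    resids = np.repeat(np.arange(1, n + 1), 2)
    names = np.tile(np.array(["N", "H"], dtype=object), n)
    coords = np.zeros((2 * n, 3))
    coords[0::2] = np.arange(n)[:, None] * [10.0, 0.0, 0.0]
    coords[1::2] = coords[0::2] + 1.02 * vectors
    return Structure(resids, names, coords), [(i + 1, "N", "H") for i in range(n)]


def _random_tensor(rng, scale=1e-3):
    m = rng.normal(size=(3, 3))
    s = 0.5 * (m + m.T)
    s -= np.eye(3) * (np.trace(s) / 3)
    return AlignmentTensor(s * scale)


class TestAlignmentTensor:
    def test_rejects_asymmetric_and_traced(self):
        with pytest.raises(ValueError, match="symmetric"):
            AlignmentTensor([[0, 1, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="traceless"):
            AlignmentTensor(np.eye(3))

    def test_eigenvalues_ordered_by_magnitude_and_sum_zero(self, rng):
        t = _random_tensor(rng)
        w = t.eigenvalues
        assert abs(w).tolist() == sorted(abs(w))
        assert abs(w.sum()) < 1e-12

    def test_axial_form(self):
        t = AlignmentTensor.axial(2e-3)
        assert np.allclose(np.diag(t.elements), [-1e-3, -1e-3, 2e-3])


class TestBackCalculate:
    def test_zero_tensor_gives_zero_couplings(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(6, 3)))
        calc = back_calculate(structure, AlignmentTensor.zero(), keys)
        assert np.allclose(calc.values, 0.0)

    def test_axial_tensor_closed_form(self):
        """Vector along the unique axis gives D_max*s; at the magic
        angle the coupling vanishes."""
        s = 1e-3
        magic = np.array([np.sqrt(2 / 3), 0.0, np.sqrt(1 / 3)])
        structure, keys = _structure_from_vectors([[0, 0, 1.0], magic])
        calc = back_calculate(structure, AlignmentTensor.axial(s), keys)
        assert calc.values[0] == pytest.approx(d_max("N", "H") * s, rel=1e-12)
        assert calc.values[1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_double_loop(self, rng):
        """Oracle: explicit sum over i, j of S_ij cos(phi_i) cos(phi_j)."""
        vectors = rng.normal(size=(20, 3))
        structure, keys = _structure_from_vectors(vectors)
        tensor = _random_tensor(rng)
        calc = back_calculate(structure, tensor, keys)
        unit = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
        for k, v in enumerate(unit):
            expected = 0.0
            for i in range(3):
                for j in range(3):
                    expected += tensor.elements[i, j] * v[i] * v[j]
            expected *= d_max("N", "H")
            assert calc.values[k] == pytest.approx(expected, rel=1e-10)

    def test_missing_atom_reports_residue(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(3, 3)))
        with pytest.raises(KeyError, match="residue 2"):
            back_calculate(structure, AlignmentTensor.zero(), [(2, "N", "XX")])

    def test_linearity_in_tensor(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(8, 3)))
        t1, t2 = _random_tensor(rng), _random_tensor(rng)
        a, b = 0.7, -1.3
        combined = back_calculate(structure, a * t1 + b * t2, keys).values
        parts = (a * back_calculate(structure, t1, keys).values
                 + b * back_calculate(structure, t2, keys).values)
        assert np.allclose(combined, parts, rtol=1e-12)

    def test_joint_rotation_leaves_couplings_unchanged(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(10, 3)))
        tensor = _random_tensor(rng)
        ref = back_calculate(structure, tensor, keys).values
        from scipy.spatial.transform import Rotation

        for seed in range(3):
            R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            rotated = back_calculate(
                structure.transformed(rotation=R), tensor.rotated(R), keys
            ).values
            assert np.allclose(rotated, ref, atol=1e-9)


class TestEnsembleAverage:
    def test_single_member_is_identity(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(5, 3)))
        tensor = _random_tensor(rng)
        avg = ensemble_average([(structure, tensor)], keys)
        assert np.allclose(avg.values, back_calculate(structure, tensor, keys).values)

    def test_opposite_tensors_cancel(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(5, 3)))
        tensor = _random_tensor(rng)
        avg = ensemble_average([(structure, tensor), (structure, -tensor)], keys)
        assert np.allclose(avg.values, 0.0, atol=1e-12)

    def test_matches_explicit_mean(self, rng):
        members = []
        structure, keys = _structure_from_vectors(rng.normal(size=(7, 3)))
        for _ in range(4):
            members.append((structure, _random_tensor(rng)))
        avg = ensemble_average(members, keys).values
        manual = np.mean(
            [back_calculate(s, t, keys).values for s, t in members], axis=0
        )
        assert np.allclose(avg, manual, atol=1e-12)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([], [(1, "N", "H")])


class TestQFactor:
    def test_identities(self):
        exp = RDCSet.from_arrays([(i, "N", "H") for i in (1, 2, 3)], [1.0, 2.0, 3.0])
        assert q_factor(exp, exp) == 0.0
        flipped = exp.with_values(-exp.values)
        assert q_factor(flipped, exp) == pytest.approx(2.0)

    def test_hand_example(self):
        """exp (1,2,3), calc (1,2,4): Q = sqrt(1/14)."""
        keys = [(i, "N", "H") for i in (1, 2, 3)]
        exp = RDCSet.from_arrays(keys, [1.0, 2.0, 3.0])
        calc = RDCSet.from_arrays(keys, [1.0, 2.0, 4.0])
        assert q_factor(calc, exp) == pytest.approx(np.sqrt(1.0 / 14.0), rel=1e-12)

    def test_zero_experimental_rejected(self):
        keys = [(1, "N", "H"), (2, "N", "H")]
        exp = RDCSet.from_arrays(keys, [0.0, 0.0])
        calc = RDCSet.from_arrays(keys, [1.0, 1.0])
        with pytest.raises(ZeroDivisionError):
            q_factor(calc, exp)

    def test_disjoint_keys_rejected(self):
        a = RDCSet.from_arrays([(1, "N", "H")], [1.0])
        b = RDCSet.from_arrays([(2, "N", "H")], [1.0])
        with pytest.raises(ValueError, match="no keys"):
            q_factor(a, b)


class TestOptimalScale:
    def test_exact_rescaling(self):
        keys = [(i, "N", "H") for i in range(1, 5)]
        exp = RDCSet.from_arrays(keys, [1.0, -2.0, 3.0, 0.5])
        calc = exp.with_values(2.0 * exp.values)
        s, q = optimal_scale(calc, exp)
        assert s == pytest.approx(0.5)
        assert q == pytest.approx(0.0, abs=1e-14)

    def test_orthogonal_gives_zero_scale(self):
        keys = [(1, "N", "H"), (2, "N", "H")]
        exp = RDCSet.from_arrays(keys, [1.0, 1.0])
        calc = RDCSet.from_arrays(keys, [1.0, -1.0])
        s, _ = optimal_scale(calc, exp)
        assert s == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_grid_search(self, seed):
        """Oracle: fine 1-D grid search over the scale factor."""
        rng = np.random.default_rng(seed)
        keys = [(i, "N", "H") for i in range(1, 9)]
        exp = RDCSet.from_arrays(keys, rng.normal(size=8))
        calc = RDCSet.from_arrays(keys, rng.normal(size=8))
        s_star, q_star = optimal_scale(calc, exp)
        grid = np.linspace(s_star - 2.0, s_star + 2.0, 4001)
        qs = [
            q_factor(calc.with_values(calc.values * s), exp) for s in grid
        ]
        assert q_star <= min(qs) + 1e-9
        assert abs(grid[int(np.argmin(qs))] - s_star) <= 1.1e-3  # grid resolution

    def test_scaling_never_worsens_q(self, rng):
        keys = [(i, "N", "H") for i in range(1, 13)]
        for _ in range(10):
            exp = RDCSet.from_arrays(keys, rng.normal(size=12))
            calc = RDCSet.from_arrays(keys, rng.normal(size=12))
            s, q_min = optimal_scale(calc, exp)
            assert q_min <= q_factor(calc, exp) + 1e-12


class TestFitTensorSVD:
    def test_exact_recovery_noise_free(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(10, 3)))
        truth = _random_tensor(rng)
        exp = back_calculate(structure, truth, keys)
        fitted, q = fit_tensor_svd(structure, exp)
        assert np.allclose(fitted.elements, truth.elements, atol=1e-8)
        assert q == pytest.approx(0.0, abs=1e-10)

    def test_underdetermined_rejected(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(4, 3)))
        exp = RDCSet.from_arrays(keys, rng.normal(size=4))
        with pytest.raises(ValueError, match=">=5"):
            fit_tensor_svd(structure, exp)

    def test_degenerate_directions_rejected(self, rng):
        structure, keys = _structure_from_vectors(np.tile([0.0, 0.0, 1.0], (6, 1)))
        exp = RDCSet.from_arrays(keys, rng.normal(size=6))
        with pytest.raises(ValueError, match="rank"):
            fit_tensor_svd(structure, exp)

    def test_noisy_fit_matches_normal_equations(self, rng):
        """Oracle: explicit normal-equations least squares."""
        vectors = rng.normal(size=(25, 3))
        structure, keys = _structure_from_vectors(vectors)
        truth = _random_tensor(rng)
        clean = back_calculate(structure, truth, keys)
        exp = clean.with_values(clean.values + rng.normal(0, 0.5, 25))
        fitted, _ = fit_tensor_svd(structure, exp)

        from rdcsel.rdc import _design_matrix, _dmax_vector

        unit = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
        A = _design_matrix(unit) * _dmax_vector(keys)[:, None]
        params = np.linalg.solve(A.T @ A, A.T @ exp.values)
        expected = AlignmentTensor.from_independent(*params)
        assert np.allclose(fitted.elements, expected.elements, atol=1e-8)

    def test_roundtrip_reproduces_input(self, rng):
        structure, keys = _structure_from_vectors(rng.normal(size=(12, 3)))
        truth = _random_tensor(rng)
        exp = back_calculate(structure, truth, keys)
        fitted, _ = fit_tensor_svd(structure, exp)
        again = back_calculate(structure, fitted, keys)
        assert np.allclose(again.values, exp.values, atol=1e-9)


class TestRDCSet:
    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RDCSet.from_arrays([(1, "N", "H"), (1, "N", "H")], [1.0, 2.0])

    def test_default_uncertainty_applied(self):
        rdcs = RDCSet.from_arrays([(1, "N", "H")], [5.0])
        assert rdcs.sigmas[0] == pytest.approx(0.3)

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(ValueError, match="uncertainty"):
            RDCSet.from_arrays([(1, "N", "H")], [1.0], sigmas=[-0.1])
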