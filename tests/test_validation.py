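"""Control procedures: scrambling, synthetic targets, tensor-magnitude
error and population recovery."""

import numpy as np
import pytest

from rdcsel.analysis import BasinSpec, basin_populations, build_distribution
from rdcsel.ga import GAConfig, run_ga
from rdcsel.validation import (
    FOLD_LADDER,
    NOISE_LADDER_PCT,
    SyntheticTarget,
    make_synthetic_rdcs,
    population_recovery_sweep,
    reconstruct_and_score,
    scaled_pool_rdcs,
    scramble_rdcs,
)

UNI_BOX = BasinSpec("uni", (52.5, 67.5), (117.5, 132.5))


class TestScramble:
    def test_value_multiset_preserved(self, small_pool):
        from rdcsel.rdc import RDCSet

        exp = RDCSet.from_arrays(small_pool.rdc_keys, small_pool.rdc_matrix[3])
        scrambled = scramble_rdcs(exp, rng_seed=1)
        assert sorted(scrambled.values) == pytest.approx(sorted(exp.values))
        assert scrambled.keys == exp.keys

    def test_seeded_and_reproducible(self, small_pool):
        from rdcsel.rdc import RDCSet

        exp = RDCSet.from_arrays(small_pool.rdc_keys, small_pool.rdc_matrix[3])
        a = scramble_rdcs(exp, rng_seed=5)
        b = scramble_rdcs(exp, rng_seed=5)
        assert np.array_equal(a.values, b.values)

    def test_too_few_records_rejected(self):
        from rdcsel.rdc import RDCSet

        with pytest.raises(ValueError):
            scramble_rdcs(RDCSet.from_arrays([(1, "N", "H")], [1.0]))


class TestSyntheticTargets:
    def test_single_conformer_box_exact(self, medium_pool):
        """A box holding one conformer with 0% noise reproduces that
        conformer's couplings exactly."""
        idx = 150
        ta, tl = medium_pool.angles[idx]
        eps = 0.4
        others = [
            i for i in range(len(medium_pool))
            if i != idx
            and abs(medium_pool.angles[i, 0] - ta) <= eps
            and abs(medium_pool.angles[i, 1] - tl) <= eps
        ]
        assert not others, "box not unique; shrink eps"
        box = BasinSpec("one", (ta - eps, ta + eps), (tl - eps, tl + eps))
        target = SyntheticTarget((box,), (1.0,), 0.0)
        synth = make_synthetic_rdcs(medium_pool, target)
        assert np.allclose(synth.values, medium_pool.rdc_matrix[idx], atol=1e-12)
        assert list(synth.generator_indices["one"]) == [idx]

    def test_two_boxes_equal_weight_mean_oracle(self, medium_pool):
        b1 = BasinSpec("a", (35.0, 50.0), (95.0, 110.0))
        b2 = BasinSpec("b", (70.0, 85.0), (140.0, 155.0))
        target = SyntheticTarget((b1, b2), (0.5, 0.5), 0.0)
        synth = make_synthetic_rdcs(medium_pool, target)
        i1 = medium_pool.in_box((b1.ampbd_range, b1.lid_range))
        i2 = medium_pool.in_box((b2.ampbd_range, b2.lid_range))
        manual = 0.5 * medium_pool.rdc_matrix[i1].mean(0) + 0.5 * medium_pool.rdc_matrix[i2].mean(0)
        assert np.allclose(synth.values, manual, atol=1e-12)

    def test_noise_scale_is_percent_of_max(self, medium_pool):
        target = SyntheticTarget((UNI_BOX,), (1.0,), 6.0, rng_seed=3)
        clean = make_synthetic_rdcs(
            medium_pool, SyntheticTarget((UNI_BOX,), (1.0,), 0.0)
        )
        noisy = make_synthetic_rdcs(medium_pool, target)
        resid = noisy.values - clean.values
        sigma = 0.06 * np.abs(clean.values).max()
        assert abs(resid.std() - sigma) / sigma < 0.25  # ~100 samples

    def test_empty_box_rejected(self, medium_pool):
        bad = SyntheticTarget((BasinSpec("x", (0.0, 2.0), (0.0, 2.0)),), (1.0,))
        with pytest.raises(ValueError, match="no pool conformer"):
            make_synthetic_rdcs(medium_pool, bad)

    def test_populations_validated(self):
        with pytest.raises(ValueError):
            SyntheticTarget((UNI_BOX,), (0.8,))

    def test_stated_noise_ladder(self):
        assert NOISE_LADDER_PCT == (1.0, 3.0, 6.0)


class TestTensorError:
    def test_fold_one_identity(self, medium_pool):
        scaled = scaled_pool_rdcs(medium_pool, 1.0)
        assert np.allclose(scaled.rdc_matrix, medium_pool.rdc_matrix, atol=1e-15)

    def test_corner_conformer_scaled_by_full_fold(self, medium_pool):
        """Oracle: closed-form exponential interpolation along the
        normalized opening coordinate."""
        fold = 10.0
        scaled = scaled_pool_rdcs(medium_pool, fold)
        lo, hi = medium_pool.angles.min(0), medium_pool.angles.max(0)
        centre, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        u = (medium_pool.angles - centre) / half
        d = np.clip(np.linalg.norm(u, axis=1) / np.sqrt(2), 0, 1)
        expected = medium_pool.rdc_matrix * (fold ** d)[:, None]
        assert np.allclose(scaled.rdc_matrix, expected, rtol=1e-9)
        corner = int(np.argmax(d))
        if d[corner] >= 1.0 - 1e-9:
            ratio = scaled.rdc_matrix[corner] / medium_pool.rdc_matrix[corner]
            assert np.allclose(ratio, fold, atol=1e-9)

    def test_stated_fold_ladder(self):
        assert FOLD_LADDER == (2.0, 3.0, 10.0, 20.0, 50.0)

    def test_fold_one_run_identical_to_unperturbed(self, medium_pool):
        target = SyntheticTarget((UNI_BOX,), (1.0,), 1.0, rng_seed=2)
        synth = make_synthetic_rdcs(medium_pool, target)
        cfg = GAConfig(n_ensembles=80, n_steps=100, n_repeats=2, rng_seed=4)
        plain = run_ga(medium_pool, synth, 4, cfg)
        scaled = run_ga(scaled_pool_rdcs(medium_pool, 1.0), synth, 4, cfg)
        for a, b in zip(plain.best, scaled.best):
            assert np.array_equal(a.member_indices, b.member_indices)


class TestReconstruction:
    def test_zero_noise_exact_when_generators_representable(self, small_pool):
        """With 0% noise and N equal to the number of generating
        conformers, the GA recovers the generators exactly (Q ~ 0) and
        the target box is occupied."""
        # a box holding exactly two conformers of the 5x5-grid pool
        box = BasinSpec("tiny", (44.0, 61.0), (105.0, 110.0))
        idx = small_pool.in_box((box.ampbd_range, box.lid_range))
        assert len(idx) == 2, "fixture pool changed; adjust box"
        target = SyntheticTarget((box,), (1.0,), 0.0)
        synth = make_synthetic_rdcs(small_pool, target)
        cfg = GAConfig(n_ensembles=150, n_steps=300, n_repeats=3, rng_seed=9)
        res = run_ga(small_pool, synth, len(idx), cfg)
        assert res.q_work.min() < 1e-6
        best = res.best[int(np.argmin(res.q_work))]
        assert sorted(best.member_indices) == sorted(idx)

    def test_recovered_population_close_to_target(self, medium_pool):
        target = SyntheticTarget((UNI_BOX,), (1.0,), 1.0, rng_seed=1)
        cfg = GAConfig(n_ensembles=150, n_steps=250, n_repeats=5, rng_seed=2)
        _, errors, n_star, pops = reconstruct_and_score(
            medium_pool, target, cfg, sizes=(1, 4, 8),
            n_holdout_sets=2, runs_per_set=2,
        )
        assert errors["uni"] < 0.3  # coarse pool; acceptance uses full scale
        assert n_star in (1, 4, 8)


class TestRecoverySweep:
    def test_pure_states_recovered_without_error(self, medium_pool):
        closed = BasinSpec("closed", (32.0, 47.0), (95.0, 110.0))
        open_ = BasinSpec("open", (73.0, 88.0), (140.0, 155.0))
        cfg = GAConfig(n_ensembles=100, n_steps=200, n_repeats=4, rng_seed=3)
        max_dev, curves = population_recovery_sweep(
            medium_pool, (closed, open_), n_size=8, step=1.0, folds=(), config=cfg
        )
        # step=1.0 -> endpoints only: p = 0 and p = 1
        assert set(curves[1.0]) == {0.0, 1.0}
        assert max_dev[1.0] < 0.05

    def test_bisection_scoring_basins_partition_plane(self):
        from rdcsel.validation import bisection_basins

        closed = BasinSpec("closed", (32.0, 47.0), (95.0, 110.0))
        open_ = BasinSpec("open", (73.0, 88.0), (140.0, 155.0))
        cs, os_ = bisection_basins(closed, open_)
        assert cs.label == "closed" and os_.label == "open"
        # the split separates the generating boxes
        assert cs.contains(40.0, 100.0) and not cs.contains(80.0, 148.0)
        assert os_.contains(80.0, 148.0) and not os_.contains(40.0, 100.0)

    def test_overlapping_basins_rejected(self, medium_pool):
        a = BasinSpec("a", (40.0, 60.0), (95.0, 120.0))
        b = BasinSpec("b", (55.0, 70.0), (110.0, 130.0))
        with pytest.raises(ValueError):
            population_recovery_sweep(medium_pool, (a, b))
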