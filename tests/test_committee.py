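"""Committee statistics, training behavior, calibration, serialization."""

import numpy as np
import pytest

from advpes import (
    CommitteeModel,
    Configuration,
    DoubleWell,
    InDomainClassifier,
    TrainConfig,
    ensemble_statistics,
    matching_loss,
    model_forces,
)
from advpes.committee import CommitteeResults
from advpes.nn import MLP


class TestEnsembleStatistics:
    def test_identical_members_have_zero_variance(self):
        E = np.array([1.3, 1.3, 1.3])
        F = np.zeros((3, 2, 3)) + 0.7
        pred = ensemble_statistics(E, F)
        assert pred.var_energy == 0.0
        assert pred.var_forces == pytest.approx(0.0, abs=1e-30)

    def test_worked_energy_variance(self):
        # two members with energies {e, e+2}: unbiased variance (1+1)/(2-1) = 2
        for e in (-5.0, 0.0, 3.7):
            pred = ensemble_statistics(np.array([e, e + 2.0]), np.zeros((2, 1, 3)))
            assert pred.var_energy == pytest.approx(2.0)

    def test_worked_force_variance(self):
        # single atom, forces {(0,0,0), (2,0,0)}: each member deviates by
        # norm^2 = 1 from the mean, divided by 3 components, summed, /(M-1)
        F = np.array([[[0.0, 0.0, 0.0]], [[2.0, 0.0, 0.0]]])
        pred = ensemble_statistics(np.zeros(2), F)
        assert pred.var_forces == pytest.approx(2.0 / 3.0)

    def test_vectorized_force_variance_matches_triple_loop(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            M, n = int(rng.integers(2, 6)), int(rng.integers(1, 5))
            F = rng.normal(size=(M, n, 3))
            pred = ensemble_statistics(rng.normal(size=M), F)
            mean = F.mean(axis=0)
            acc = 0.0
            for m in range(M):
                s = 0.0
                for i in range(n):
                    for j in range(3):
                        s += (F[m, i, j] - mean[i, j]) ** 2
                acc += s / (3 * n)
            assert pred.var_forces == pytest.approx(acc / (M - 1), abs=1e-10)

    def test_member_order_invariance(self):
        rng = np.random.default_rng(5)
        E = rng.normal(size=4)
        F = rng.normal(size=(4, 2, 3))
        a = ensemble_statistics(E, F)
        perm = [2, 0, 3, 1]
        b = ensemble_statistics(E[perm], F[perm])
        assert a.var_energy == pytest.approx(b.var_energy)
        assert a.var_forces == pytest.approx(b.var_forces)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            ensemble_statistics(np.array([1.0]), np.zeros((1, 1, 3)))


class TestMatchingLoss:
    def test_perfect_prediction_is_zero(self):
        assert matching_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_energy_only_worked_example(self):
        # N=1, alpha_E=1, alpha_F=0, E=0, Ehat=2 -> 4
        assert matching_loss([0.0], [2.0]) == pytest.approx(4.0)

    def test_force_only_worked_example(self):
        # N=1, alpha_F=1, single atom force error (1,0,0) -> squared norm 1
        loss = matching_loss(
            [0.0], [0.0], F=[[[0.0, 0.0, 0.0]]], F_hat=[[[1.0, 0.0, 0.0]]],
            alpha_E=0.0, alpha_F=1.0,
        )
        assert loss == pytest.approx(1.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            matching_loss([], [])


class TestModelForces:
    def test_constant_model_zero_forces(self):
        net = MLP(2, [8], seed=0)
        for W in net.W:
            W[:] = 0.0
        cfg = Configuration(np.array([0.3, -0.4]))
        assert model_forces(net, cfg) == pytest.approx(np.zeros(2))

    def test_forces_match_finite_differences(self):
        net = MLP(2, [16, 16], seed=3)
        rng = np.random.default_rng(0)
        h = 1e-6
        for p in rng.normal(size=(10, 2)):
            f = model_forces(net, Configuration(p))
            for j in range(2):
                e = np.zeros(2)
                e[j] = h
                fd = -(net.energy((p + e)[None])[0] - net.energy((p - e)[None])[0]) / (2 * h)
                assert f[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestTraining:
    def test_loss_decreases(self, trained_committee):
        for hist in trained_committee.histories:
            assert hist[-1] <= hist[0]

    def test_fit_quality_on_left_basin(self, trained_committee):
        # converged members reproduce their training energies closely
        assert (trained_committee.rmse("train") < 0.1).all()

    def test_default_committee_size(self, trained_committee):
        assert trained_committee.n_members == 5

    def test_determinism(self, left_basin_dataset):
        cfg = TrainConfig(seed=3, epochs=40, max_steps=40, hidden=(16, 16))
        a = CommitteeModel(left_basin_dataset, cfg).fit()
        b = CommitteeModel(left_basin_dataset, cfg).fit()
        X = left_basin_dataset.coords_matrix()
        assert np.array_equal(a.member_energies(X), b.member_energies(X))

    def test_epistemic_contrast_between_basins(self, trained_committee, left_basin_dataset):
        # the unexplored right basin carries higher force variance than the
        # training points: the premise of uncertainty-driven sampling
        gx = np.linspace(0.3, 1.1, 15)
        gy = np.linspace(-0.5, 0.5, 15)
        GX, GY = np.meshgrid(gx, gy)
        right = np.stack([GX.ravel(), GY.ravel()], axis=1)
        v_right = trained_committee.variance_statistic(right).mean()
        v_train = trained_committee.variance_statistic(left_basin_dataset.coords_matrix()).mean()
        assert v_right > v_train

    def test_different_splits_mode(self, left_basin_dataset):
        cfg = TrainConfig(
            seed=5, epochs=50, max_steps=50, hidden=(16,), diversity="different-splits"
        )
        res = CommitteeModel(left_basin_dataset, cfg).fit()
        trains = [tuple(split[0]) for split in res.splits]
        assert len(set(trains)) > 1

    def test_force_matching_training_reduces_loss(self, left_basin_dataset):
        # alpha_F > 0 exercises the reverse-over-forward parameter gradients
        cfg = TrainConfig(
            seed=5, epochs=150, max_steps=150, hidden=(24, 24), alpha_E=1.0, alpha_F=1.0
        )
        res = CommitteeModel(left_basin_dataset, cfg).fit()
        for hist in res.histories:
            assert hist[-1] < hist[0]
        # forces improved too, not just energies
        X = left_basin_dataset.coords_matrix()
        F = np.array([s.forces for s in left_basin_dataset])
        pred_F = -res.member_grads(X).mean(axis=0)
        fresh = CommitteeModel(
            left_basin_dataset,
            TrainConfig(seed=5, epochs=1, max_steps=1, hidden=(24, 24), alpha_F=1.0),
        ).fit()
        fresh_F = -fresh.member_grads(X).mean(axis=0)
        assert np.mean((pred_F - F) ** 2) < np.mean((fresh_F - F) ** 2)

    def test_rejects_empty_dataset(self):
        from advpes.data import Dataset

        with pytest.raises(ValueError):
            CommitteeModel(Dataset([]), TrainConfig())

    def test_summary_mentions_members(self, trained_committee):
        text = trained_committee.summary()
        assert "members: 5" in text
        assert "RMSE" in text


class TestCalibration:
    def test_percentile_marks_expected_fraction(self, trained_committee, left_basin_dataset):
        clf = trained_committee.calibrate_threshold(percentile=80.0)
        X = left_basin_dataset.coords_matrix()
        values = trained_committee.variance_statistic(X)
        out = sum(clf.classify_value(v) == 0 for v in values)
        expected = int(np.ceil(0.2 * len(values)))
        assert abs(out - expected) <= 1

    def test_boundary_is_out_of_domain(self):
        clf = InDomainClassifier(threshold=0.5)
        assert clf.classify_value(0.5) == 0
        assert clf.classify_value(0.499999) == 1

    def test_monotone_in_variance(self):
        clf = InDomainClassifier(threshold=0.3)
        values = np.linspace(0, 1, 50)
        flags = [clf.classify_value(v) for v in values]
        assert sorted(flags, reverse=True) == flags

    def test_high_percentile_keeps_all_in_domain(self, trained_committee, left_basin_dataset):
        clf = trained_committee.calibrate_threshold(percentile=99.9)
        X = left_basin_dataset.coords_matrix()
        values = trained_committee.variance_statistic(X)
        assert sum(clf.classify_value(v) for v in values) >= len(values) - 1

    def test_zero_variance_committee(self, left_basin_dataset):
        cfg = TrainConfig(seed=3, epochs=1, max_steps=1, hidden=(8,))
        res = CommitteeModel(left_basin_dataset, cfg).fit()
        # make members identical
        ref = res.members[0]
        for m in range(1, len(res.members)):
            res.members[m].set_params([p.copy() for p in ref.get_params()])
        with pytest.warns(UserWarning):
            clf = res.calibrate_threshold(percentile=80.0)
        # threshold collapses to zero (up to summation roundoff of identical
        # member predictions)
        assert clf.threshold == pytest.approx(0.0, abs=1e-20)


class TestSerialization:
    def test_checkpoint_roundtrip(self, trained_committee, left_basin_dataset, tmp_path):
        trained_committee.save(tmp_path / "ckpt")
        loaded = CommitteeResults.load(tmp_path / "ckpt", left_basin_dataset)
        X = left_basin_dataset.coords_matrix()[:5]
        assert np.array_equal(trained_committee.member_energies(X), loaded.member_energies(X))
        assert loaded.model.config == trained_committee.model.config
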