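"""Likelihood-weighted uncertainty loss: identities, gradients, ascent."""

import numpy as np
import pytest

from advpes import (
    AttackConfig,
    Configuration,
    Dataset,
    LabeledSample,
    adversarial_loss,
    batch_attacks,
    boltzmann_likelihood,
    init_delta,
    partition_normalizer,
    run_attack,
)
from advpes.adversarial import adversarial_loss_and_grad, adversarial_loss_terms


def _vec_dataset(energies):
    samples = [
        LabeledSample(Configuration(np.array([float(i), 0.0])), e, np.zeros(2))
        for i, e in enumerate(energies)
    ]
    return Dataset(samples, ["initial"] * len(samples))


class TestNormalizer:
    def test_single_zero_energy_sample(self):
        norm = partition_normalizer(_vec_dataset([0.0]), kT=1.0)
        assert norm.q == pytest.approx(1.0)

    def test_two_zero_energy_samples(self):
        norm = partition_normalizer(_vec_dataset([0.0, 0.0]), kT=1.0)
        assert norm.q == pytest.approx(2.0)

    def test_energy_shift_identity(self):
        kT = 2.5
        e = [0.3, -1.2, 4.0]
        c = 7.0
        q0 = partition_normalizer(_vec_dataset(e), kT).q
        q1 = partition_normalizer(_vec_dataset([x + c for x in e]), kT).q
        assert q1 == pytest.approx(q0 * np.exp(-c / kT))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            partition_normalizer(Dataset([]), kT=1.0)

    def test_large_energies_stay_finite(self):
        norm = partition_normalizer(_vec_dataset([-5000.0, -4999.0]), kT=1.0)
        assert np.isfinite(norm.log_q)
        p = boltzmann_likelihood(-5000.0, norm, kT=1.0)
        assert 0 < p < 1


class TestBoltzmannLikelihood:
    def test_single_sample_identity(self):
        norm = partition_normalizer(_vec_dataset([0.0]), kT=1.0)
        assert boltzmann_likelihood(0.0, norm, kT=1.0) == pytest.approx(1.0)

    def test_quarter_identity(self):
        # dataset E = {0, 0}, kT = 1, Ebar = ln 2: p = (1/2) e^{-ln 2} = 1/4
        norm = partition_normalizer(_vec_dataset([0.0, 0.0]), kT=1.0)
        assert boltzmann_likelihood(np.log(2.0), norm, kT=1.0) == pytest.approx(0.25)

    def test_monotone_decreasing_in_energy(self):
        norm = partition_normalizer(_vec_dataset([0.0, 1.0]), kT=1.0)
        p = boltzmann_likelihood(np.linspace(-2, 2, 20), norm, kT=1.0)
        assert (np.diff(p) < 0).all()

    def test_kt_mismatch_rejected(self):
        norm = partition_normalizer(_vec_dataset([0.0]), kT=1.0)
        with pytest.raises(ValueError):
            boltzmann_likelihood(0.0, norm, kT=2.0)


class TestAdversarialLoss:
    def test_identical_members_zero_everywhere(self, left_basin_dataset, toy_normalizer):
        from advpes import CommitteeModel, TrainConfig

        res = CommitteeModel(left_basin_dataset, TrainConfig(seed=1, epochs=2, max_steps=2, hidden=(8,))).fit()
        ref = res.members[0]
        for m in res.members[1:]:
            m.set_params([p.copy() for p in ref.get_params()])
        rng = np.random.default_rng(0)
        for p in rng.uniform(-1.5, 1.5, (10, 2)):
            assert adversarial_loss(res, Configuration(p), toy_normalizer) == pytest.approx(0.0)

    def test_product_of_worked_factors(self):
        # p = 1/4 and sigma_F^2 = 2/3 combine to L_adv = 1/6
        assert 0.25 * (2.0 / 3.0) == pytest.approx(1.0 / 6.0)

    def test_nonnegative(self, trained_committee, toy_normalizer):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1.5, 1.5, (50, 2))
        loss, _ = adversarial_loss_and_grad(trained_committee, X, toy_normalizer)
        assert (loss >= 0).all()

    def test_gradient_matches_finite_differences(self, trained_committee, toy_normalizer):
        rng = np.random.default_rng(20)
        X = rng.uniform(-1.4, 1.4, (20, 2))
        loss, grad = adversarial_loss_and_grad(trained_committee, X, toy_normalizer)
        h = 1e-5
        for n in range(20):
            for j in range(2):
                Xp, Xm = X.copy(), X.copy()
                Xp[n, j] += h
                Xm[n, j] -= h
                lp, _ = adversarial_loss_and_grad(trained_committee, Xp, toy_normalizer)
                lm, _ = adversarial_loss_and_grad(trained_committee, Xm, toy_normalizer)
                fd = (lp[n] - lm[n]) / (2 * h)
                assert grad[n, j] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_tiny_exact_step_never_decreases(self, trained_committee, toy_normalizer):
        rng = np.random.default_rng(21)
        X = rng.uniform(-1.2, 1.2, (20, 2))
        loss, grad = adversarial_loss_and_grad(trained_committee, X, toy_normalizer)
        stepped, _ = adversarial_loss_and_grad(trained_committee, X + 1e-6 * grad, toy_normalizer)
        assert (stepped >= loss - 1e-12).all()

    def test_shift_invariance(self, trained_committee, left_basin_dataset):
        # adding a constant to all dataset energies and to the committee
        # output cancels between p's numerator and Q
        c = 3.7
        kT = 5.0
        rng = np.random.default_rng(22)
        X = rng.uniform(-1.2, 1.2, (5, 2))
        norm0 = partition_normalizer(left_basin_dataset, kT)
        p0, v0 = adversarial_loss_terms(trained_committee, X, norm0)

        shifted = Dataset(
            [LabeledSample(s.config, s.energy + c, s.forces) for s in left_basin_dataset],
            list(left_basin_dataset.provenance),
        )
        norm1 = partition_normalizer(shifted, kT)
        for m in trained_committee.members:
            m.b[-1] = m.b[-1] + c
        try:
            p1, v1 = adversarial_loss_terms(trained_committee, X, norm1)
        finally:
            for m in trained_committee.members:
                m.b[-1] = m.b[-1] - c
        assert p0 * v0 == pytest.approx(p1 * v1, rel=1e-10)


class TestInitDelta:
    def test_zero_sigma_gives_exact_zeros(self):
        assert np.array_equal(init_delta((4, 3), 0.0, seed=1), np.zeros((4, 3)))

    def test_seed_reproducibility(self):
        a = init_delta(10, 0.5, seed=3)
        b = init_delta(10, 0.5, seed=3)
        assert np.array_equal(a, b)

    def test_sample_std(self):
        d = init_delta(100000, 0.2, seed=4)
        assert d.std() == pytest.approx(0.2, rel=0.02)
        assert d.mean() == pytest.approx(0.0, abs=0.01)


class TestRunAttack:
    def test_deterministic_degenerate_case(self, trained_committee, toy_normalizer):
        cfg = AttackConfig(sigma_delta=0.0, kT=5.0, lr=3e-3, n_steps=50, seed=9)
        seed_cfg = Configuration(np.array([-0.75, 0.1]))
        a = run_attack(trained_committee, seed_cfg, cfg, toy_normalizer)
        b = run_attack(trained_committee, seed_cfg, cfg, toy_normalizer)
        assert np.array_equal(a.delta_history, b.delta_history)
        assert np.array_equal(a.loss_history, b.loss_history)
        assert np.array_equal(a.final_config.coords, b.final_config.coords)

    def test_histories_have_expected_length(self, trained_committee, toy_normalizer):
        cfg = AttackConfig(n_steps=25, seed=2)
        r = run_attack(trained_committee, Configuration(np.array([-0.7, 0.0])), cfg, toy_normalizer)
        assert r.delta_history.shape == (26, 2)
        assert r.loss_history.shape == (26,)
        assert r.final_config.coords == pytest.approx(
            r.seed_config.coords + r.delta_history[-1]
        )

    def test_ascent_increases_loss(self, trained_committee, toy_normalizer, left_basin_dataset):
        cfg = AttackConfig(sigma_delta=0.01, kT=5.0, lr=3e-3, n_steps=600, seed=5)
        seeds = [left_basin_dataset[i].config for i in range(5)]
        for r in batch_attacks(trained_committee, seeds, cfg, toy_normalizer):
            assert r.loss_history[-1] >= r.loss_history[0]

    def test_identical_members_keep_delta_zero(self, left_basin_dataset, toy_normalizer):
        from advpes import CommitteeModel, TrainConfig

        res = CommitteeModel(left_basin_dataset, TrainConfig(seed=1, epochs=2, max_steps=2, hidden=(8,))).fit()
        ref = res.members[0]
        for m in res.members[1:]:
            m.set_params([p.copy() for p in ref.get_params()])
        cfg = AttackConfig(sigma_delta=0.0, n_steps=20, seed=0)
        r = run_attack(res, Configuration(np.array([-0.7, 0.0])), cfg, toy_normalizer)
        assert np.array_equal(r.delta_history[-1], np.zeros(2))
        assert r.loss_history == pytest.approx(np.zeros(21))


class TestBatchAttacks:
    def test_batch_of_one_equals_run_attack(self, trained_committee, toy_normalizer):
        cfg = AttackConfig(n_steps=30, seed=7)
        seed_cfg = Configuration(np.array([-0.8, -0.2]))
        single = run_attack(trained_committee, seed_cfg, cfg, toy_normalizer)
        batch = batch_attacks(trained_committee, [seed_cfg], cfg, toy_normalizer)
        assert np.array_equal(single.delta_history, batch[0].delta_history)
        assert np.array_equal(single.loss_history, batch[0].loss_history)

    def test_permutation_equivariance(self, trained_committee, toy_normalizer, left_basin_dataset):
        cfg = AttackConfig(n_steps=30, seed=8)
        seeds = [left_basin_dataset[i].config for i in range(4)]
        fwd = batch_attacks(trained_committee, seeds, cfg, toy_normalizer)
        rev = batch_attacks(trained_committee, seeds[::-1], cfg, toy_normalizer)
        for a, b in zip(fwd, rev[::-1]):
            assert np.array_equal(a.delta_history, b.delta_history)

    def test_twenty_seeds_give_twenty_results(self, trained_committee, toy_normalizer, left_basin_dataset):
        cfg = AttackConfig(n_steps=5, seed=9)
        seeds = [left_basin_dataset[i].config for i in range(20)]
        results = batch_attacks(trained_committee, seeds, cfg, toy_normalizer)
        assert len(results) == 20
        for r in results:
            assert r.final_config.numbers is None
            assert r.final_config.dof == 2

    def test_empty_batch_rejected(self, trained_committee, toy_normalizer):
        with pytest.raises(ValueError):
            batch_attacks(trained_committee, [], AttackConfig(), toy_normalizer)
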