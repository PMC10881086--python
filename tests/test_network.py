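"""Training, prediction and evaluation of the proportion network."""

import numpy as np
import pytest

import spotdeconv as sd
from spotdeconv.network import uniform_predictor_loss


class TestFit:
    def test_beats_uniform_predictor(self, trained_model, test_mixtures):
        pred = trained_model.predict_mixture_set(test_mixtures)
        truth = test_mixtures.proportions
        eps = 1e-12
        model_loss = np.sum(
            truth * (np.log(truth + eps) - np.log(pred + eps))) / len(truth)
        assert model_loss < uniform_predictor_loss(truth)

    def test_single_epoch_history(self, train_mixtures, norm_spec):
        cfg = sd.ModelConfig(hidden_sizes=(16,), max_epochs=1, seed=0)
        model = sd.train(train_mixtures, norm_spec, cfg)
        assert len(model.training_history) == 1

    def test_early_stopping_restores_best(self, train_mixtures, norm_spec):
        cfg = sd.ModelConfig(hidden_sizes=(32,), max_epochs=30,
                             early_stop_patience=3, seed=1)
        model = sd.train(train_mixtures, norm_spec, cfg)
        hist = model.training_history
        assert model.net.best_epoch_ == hist["val_loss"].idxmin()

    def test_separable_fixture_recovered(self, trained_model, test_mixtures):
        report = trained_model.evaluate(test_mixtures)
        assert report.overall["mean_pcc"] >= 0.95
        assert report.overall["mean_ccc"] >= 0.95

    def test_prelu_and_alternative_losses_train(self, train_mixtures,
                                                norm_spec):
        for loss, act in [("mse", "prelu"), ("mae", "relu")]:
            cfg = sd.ModelConfig(hidden_sizes=(16,), max_epochs=3,
                                 activation=act, loss=loss, seed=2)
            model = sd.train(train_mixtures, norm_spec, cfg)
            pred = model.predict_mixture_set(train_mixtures)
            np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.ModelConfig(hidden_sizes=())
        with pytest.raises(ValueError):
            sd.ModelConfig(loss="huber")


class TestPredict:
    def test_rows_on_simplex_including_zero_input(self, trained_model):
        n_genes = len(trained_model.gene_space)
        X = np.zeros((3, n_genes))
        p = trained_model.net.predict(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all()

    def test_pure_profile_argmax(self, trained_model, small_ref, small_split):
        # a pure mixture of each type must be assigned to that type
        types = small_ref.cell_type_order
        pure = np.eye(len(types))
        ms = sd.synthesize_mixtures(small_ref, small_split[1], pure, 25,
                                    seed=3)
        pred = trained_model.predict_mixture_set(ms)
        assert np.argmax(pred, axis=1).tolist() == list(range(len(types)))

    def test_duplicated_input_rows_identical(self, trained_model, small_ref):
        counts = np.asarray(small_ref.counts)[:, :1]
        dup = np.repeat(counts, 3, axis=1)
        pred = trained_model.predict(dup, small_ref.gene_ids)
        assert (pred[0] == pred[1]).all() and (pred[1] == pred[2]).all()

    def test_partial_overlap_warns_zero_overlap_errors(self, trained_model,
                                                       small_ref):
        counts = np.asarray(small_ref.counts)[:40, :2]
        with pytest.warns(UserWarning, match="zero-filled"):
            pred = trained_model.predict(counts, small_ref.gene_ids[:40])
        np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-6)
        with pytest.raises(ValueError, match="no genes"):
            trained_model.predict(counts, [f"unknown{i}" for i in range(40)])


class TestInputGradient:
    def test_matches_finite_differences(self, trained_model):
        rng = np.random.default_rng(4)
        x = rng.random((1, len(trained_model.gene_space))) * 2
        net = trained_model.net
        grad = net.input_gradient(x, target_index=0)[0]
        eps = 1e-6
        for g in rng.choice(len(x[0]), size=10, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[0, g] += eps
            xm[0, g] -= eps
            numeric = (net.predict(xp)[0, 0] - net.predict(xm)[0, 0]) / (2 * eps)
            assert grad[g] == pytest.approx(numeric, abs=1e-5)


class TestEvaluate:
    def test_perfect_prediction_limits(self):
        rng = np.random.default_rng(6)
        truth = rng.dirichlet(np.ones(3), size=50)
        rows_pcc = [sd.pcc(truth[:, i], truth[:, i]) for i in range(3)]
        rows_ccc = [sd.ccc(truth[:, i], truth[:, i]) for i in range(3)]
        np.testing.assert_allclose(rows_pcc, 1.0, atol=1e-12)
        np.testing.assert_allclose(rows_ccc, 1.0, atol=1e-12)
        assert sd.rmse(truth.ravel(), truth.ravel()) == 0.0
        assert sd.jsd(truth[0], truth[0]) == 0.0

    def test_shuffled_truth_has_near_zero_ccc(self):
        rng = np.random.default_rng(7)
        truth = rng.dirichlet(np.ones(4), size=200)
        cccs = []
        for _ in range(100):
            perm = rng.permutation(len(truth))
            cccs.append(np.mean([sd.ccc(truth[:, i], truth[perm, i])
                                 for i in range(4)]))
        assert abs(np.mean(cccs)) < 0.05

    def test_invariant_to_profile_order(self, trained_model, test_mixtures):
        report1 = trained_model.evaluate(test_mixtures)
        perm = np.random.default_rng(8).permutation(test_mixtures.n_profiles)
        shuffled = sd.MixtureSet(
            profiles=test_mixtures.profiles[:, perm],
            proportions=test_mixtures.proportions[perm],
            cell_type_order=test_mixtures.cell_type_order,
            gene_ids=test_mixtures.gene_ids, partition="test")
        report2 = trained_model.evaluate(shuffled)
        for k in report1.overall:
            assert report1.overall[k] == pytest.approx(report2.overall[k],
                                                       abs=1e-9)


class TestPersistence:
    def test_save_load_round_trip(self, trained_model, small_ref, tmp_path):
        trained_model.save(tmp_path / "model")
        loaded = sd.DeconvolutionModel.load(tmp_path / "model")
        assert loaded.gene_space == trained_model.gene_space
        assert loaded.cell_type_order == trained_model.cell_type_order
        counts = np.asarray(small_ref.counts)[:, :5]
        p1 = trained_model.predict(counts, small_ref.gene_ids)
        p2 = loaded.predict(counts, small_ref.gene_ids)
        np.testing.assert_array_equal(p1, p2)

    def test_missing_contract_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="contract.json"):
            sd.DeconvolutionModel.load(tmp_path)


def test_training_is_deterministic_given_seed(train_mixtures, norm_spec):
    cfg = sd.ModelConfig(hidden_sizes=(16,), max_epochs=3, seed=42)
    m1 = sd.train(train_mixtures, norm_spec, cfg)
    m2 = sd.train(train_mixtures, norm_spec, cfg)
    for l1, l2 in zip(m1.net.weights_, m2.net.weights_):
        for a, b in zip(l1, l2):
            np.testing.assert_array_equal(a, b)
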