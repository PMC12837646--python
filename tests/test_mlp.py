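"""Forward pass, data splitting, training and grid prediction."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from uaeopt import data as dio
from uaeopt import mlp
from uaeopt.scaling import fit_scaler


def loop_forward(params, X):
    """Independent element-by-element evaluation of the network."""
    import math
    act = {"tanh": math.tanh,
           "logistic": lambda z: 1.0 / (1.0 + math.exp(-z)),
           "identity": lambda z: z}
    fh = act[params.hidden_activation]
    fo = act[params.output_activation]
    out = []
    for x in np.atleast_2d(X):
        hidden = []
        for i in range(params.n_hidden):
            z = params.B1[i]
            for j in range(params.n_inputs):
                z += params.W1[i, j] * x[j]
            hidden.append(fh(z))
        row = []
        for k in range(params.n_outputs):
            z = params.B2[k]
            for i in range(params.n_hidden):
                z += params.W2[k, i] * hidden[i]
            row.append(fo(z))
        out.append(row)
    return np.array(out)


def random_params(rng, n_in=3, n_hidden=None, n_out=None):
    n_hidden = n_hidden or int(rng.integers(1, 12))
    n_out = n_out or int(rng.integers(1, 7))
    acts = ["tanh", "logistic", "identity"]
    return mlp.MLPParameters(
        W1=rng.normal(size=(n_hidden, n_in)), B1=rng.normal(size=n_hidden),
        W2=rng.normal(size=(n_out, n_hidden)), B2=rng.normal(size=n_out),
        hidden_activation=acts[int(rng.integers(0, 3))],
        output_activation=acts[int(rng.integers(0, 3))])


class TestForward:
    def test_zero_weights_collapse_to_output_bias(self, rng):
        params = mlp.MLPParameters(
            W1=np.zeros((4, 3)), B1=np.zeros(4), W2=np.zeros((2, 4)),
            B2=np.array([1.5, -2.0]), output_activation="identity")
        Y = mlp.forward_scaled(params, rng.normal(size=(6, 3)))
        np.testing.assert_allclose(Y, np.tile([1.5, -2.0], (6, 1)))

    def test_toy_1_1_1_network_by_hand(self):
        params = mlp.MLPParameters(W1=[[1.0]], B1=[0.0], W2=[[2.0]],
                                   B2=[1.0], hidden_activation="tanh",
                                   output_activation="identity")
        value = mlp.forward_scaled(params, [[0.5]])[0, 0]
        assert value == pytest.approx(2 * np.tanh(0.5) + 1, abs=1e-12)
        assert value == pytest.approx(1.92423431, abs=1e-7)

    def test_odd_symmetry_with_zero_biases(self, rng):
        params = mlp.MLPParameters(
            W1=rng.normal(size=(5, 3)), B1=np.zeros(5),
            W2=rng.normal(size=(2, 5)), B2=np.zeros(2),
            hidden_activation="tanh", output_activation="identity")
        X = rng.normal(size=(8, 3))
        np.testing.assert_allclose(mlp.forward_scaled(params, -X),
                                   -mlp.forward_scaled(params, X),
                                   atol=1e-12)

    def test_matches_loop_oracle_on_random_networks(self, rng):
        for _ in range(100):
            params = random_params(rng)
            X = rng.normal(size=(5, 3))
            np.testing.assert_allclose(mlp.forward_scaled(params, X),
                                       loop_forward(params, X), atol=1e-12)

    def test_shape_mismatch_names_dimension(self, rng):
        params = random_params(rng)
        with pytest.raises(ValueError, match="3"):
            mlp.forward_scaled(params, rng.normal(size=(4, 2)))

    def test_tanh_output_bounded_before_inverse_scaling(self, rng):
        params = mlp.MLPParameters(
            W1=rng.normal(size=(6, 3)), B1=rng.normal(size=6),
            W2=rng.uniform(-1, 1, size=(3, 6)), B2=rng.uniform(-1, 1, 3),
            hidden_activation="tanh", output_activation="tanh")
        Y = mlp.forward_scaled(params, rng.normal(size=(50, 3)))
        assert (np.abs(Y) < 1).all()


class TestSplit:
    def test_15_samples_give_9_3_3(self):
        split = mlp.split_dataset(15, seed=0)
        assert (np.sum(split == "train"), np.sum(split == "test"),
                np.sum(split == "valid")) == (9, 3, 3)

    def test_partitions_disjoint_and_exhaustive(self):
        split = mlp.split_dataset(20, seed=3)
        assert split.size == 20
        assert set(split) == {"train", "test", "valid"}

    def test_same_seed_reproduces_partition(self):
        np.testing.assert_array_equal(mlp.split_dataset(15, seed=7),
                                      mlp.split_dataset(15, seed=7))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mlp.split_dataset(3, seed=0)


class TestTrain:
    def test_noiseless_linear_response_fit_nearly_exactly(self, rng):
        X = rng.uniform([10, 25, 10], [30, 75, 20], size=(20, 3))
        y = 0.3 * X[:, 0] - 0.1 * X[:, 1] + 0.5 * X[:, 2] + 2.0
        fit = mlp.train(X, y, hidden_size=2,
                        config=mlp.TrainConfig(restarts=10, seed=0))
        assert fit.performance["train"] > 0.9999

    def test_best_of_restarts_never_degrades_training_loss(self, paper_X,
                                                           paper_responses):
        Y = paper_responses.subset(["TPC", "TFC"]).means
        losses = []
        for restarts in (1, 5, 15):
            fit = mlp.train(paper_X, Y, 4,
                            mlp.TrainConfig(restarts=restarts, seed=11))
            losses.append(fit.errors["train"])
        assert losses[1] <= losses[0] + 1e-12
        assert losses[2] <= losses[1] + 1e-12

    def test_predictions_return_in_original_units(self, paper_X,
                                                  paper_responses):
        sub = paper_responses.subset(["TPC", "TFC"])
        fit = mlp.train(paper_X, sub.means, 9,
                        mlp.TrainConfig(restarts=30, seed=1),
                        response_names=["TPC", "TFC"])
        pred = fit.predict(paper_X)
        assert pred.shape == (15, 2)
        # interpolating fit: predictions live on the measured scale
        assert abs(pred[:, 0].mean() - sub.means[:, 0].mean()) < 2.0

    def test_save_load_round_trip_preserves_predictions(
            self, paper_X, paper_responses, tmp_path):
        sub = paper_responses.subset(["TPC", "TFC"])
        fit = mlp.train(paper_X, sub.means, 5,
                        mlp.TrainConfig(restarts=5, seed=2))
        path = mlp.save_model(fit, tmp_path / "model.json")
        clone = mlp.load_model(path)
        np.testing.assert_allclose(clone.predict(paper_X),
                                   fit.predict(paper_X), rtol=1e-12)


class TestSweep:
    def test_single_candidate_is_returned(self, paper_X, paper_responses):
        Y = paper_responses.subset(["TPC"]).means
        table, size = mlp.sweep_hidden_sizes(
            paper_X, Y, [9], mlp.TrainConfig(restarts=3, seed=0))
        assert size == 9 and len(table) == 1

    def test_linear_target_needs_one_hidden_unit(self, rng):
        X = rng.uniform([10, 25, 10], [30, 75, 20], size=(25, 3))
        y = 2.0 + 0.1 * X[:, 0] + 0.02 * X[:, 1] + 0.05 * X[:, 2]
        table, _ = mlp.sweep_hidden_sizes(
            X, y, [1, 10], mlp.TrainConfig(restarts=10, seed=4))
        r2 = table.set_index("hidden_size")["train_r2"]
        assert r2[1] >= r2[10] - 1e-3

    def test_capacity_saturates_on_paper_data(self, paper_X,
                                              paper_responses):
        Y = paper_responses.subset(["TPC", "TFC"]).means
        table, _ = mlp.sweep_hidden_sizes(
            paper_X, Y, [2, 6, 9], mlp.TrainConfig(restarts=15, seed=5))
        r2 = table.set_index("hidden_size")["train_r2"]
        assert r2.max() >= r2[2]
        assert r2.max() > 0.99


@pytest.fixture(scope="module")
def surrogate(paper_X, paper_responses):
    sub = paper_responses.subset(["TPC", "TFC"])
    return mlp.train(paper_X, sub.means, 5,
                     mlp.TrainConfig(restarts=10, seed=6),
                     response_names=["TPC", "TFC"])


class TestPredictGrid:

    def test_grid_at_design_points_matches_forward(self, surrogate,
                                                   paper_X):
        bounds = {"time": (10, 30), "temperature": (25, 75),
                  "ratio": (10, 20)}
        step = {"time": 10, "temperature": 25, "ratio": 5}
        grid = mlp.predict_grid(surrogate, bounds, step)
        assert np.isfinite(grid[["TPC", "TFC"]].to_numpy()).all()
        row = grid[(grid.time == 20) & (grid.temperature == 50) &
                   (grid.ratio == 20)]
        direct = surrogate.predict([[20, 50, 20]])
        assert row["TPC"].iloc[0] == pytest.approx(direct[0, 0])

    def test_step_equal_to_box_width_gives_8_corners(self, surrogate):
        bounds = {"time": (10, 30), "temperature": (25, 75),
                  "ratio": (10, 20)}
        step = {"time": 20, "temperature": 50, "ratio": 10}
        assert len(mlp.predict_grid(surrogate, bounds, step)) == 8

    def test_far_extrapolation_refused(self, surrogate):
        bounds = {"time": (10, 300), "temperature": (25, 75),
                  "ratio": (10, 20)}
        with pytest.raises(ValueError, match="design box"):
            mlp.predict_grid(surrogate, bounds,
                             {"time": 10, "temperature": 25, "ratio": 5})


class TestPublishedWeights:
    def test_forward_finite_on_design_and_tpc_rank_correlated(
            self, paper_X, paper_responses):
        input_scaler = fit_scaler(paper_X, "minmax", interval=(0, 1))
        for model_id in ("ANN1", "ANN2", "ANN3"):
            model = dio.load_published_model(model_id)
            Y = mlp.forward_scaled(model.parameters,
                                   input_scaler.apply(paper_X))
            assert np.isfinite(Y).all()
        ann1 = dio.load_published_model("ANN1")
        pred_tpc = mlp.forward_scaled(ann1.parameters,
                                      input_scaler.apply(paper_X))[:, 0]
        rho = spearmanr(pred_tpc, paper_responses.column("TPC")).statistic
        assert rho > 0
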