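"""Pareto filtering, the genetic search and standard-score ranking."""

import numpy as np
import pytest

from uaeopt import optimize as opt
from uaeopt import synthetic as syn
from uaeopt.data import ResponseMatrix, design_matrix
from uaeopt.mlp import TrainConfig, train


def brute_force_front(F):
    """Double-loop dominance oracle (maximization)."""
    keep = []
    for i in range(len(F)):
        dominated = any(
            (F[j] >= F[i]).all() and (F[j] > F[i]).any()
            for j in range(len(F)) if j != i)
        duplicate = any((F[j] == F[i]).all() for j in range(i))
        if not dominated and not duplicate:
            keep.append(i)
    return keep


def make_matrix(X, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"y{j + 1}" for j in range(X.shape[1])]
    return ResponseMatrix(sample_ids=list(range(1, X.shape[0] + 1)),
                          response_names=names, means=X,
                          sds=np.zeros_like(X))


class TestParetoFront:
    def test_single_objective_front_is_the_argmax(self, rng):
        F = rng.normal(size=(20, 1))
        front = opt.pareto_front(F)
        assert list(front) == [int(np.argmax(F))]

    def test_worked_four_point_example(self):
        F = np.array([[1, 1], [2, 0.5], [0.5, 2], [0.9, 0.9]])
        front = opt.pareto_front(F)
        assert set(front) == {0, 1, 2}        # D dominated by A

    def test_duplicates_leave_the_front_unchanged_as_a_set(self, rng):
        F = rng.uniform(size=(30, 3))
        doubled = np.vstack([F, F])
        a = {tuple(F[i]) for i in opt.pareto_front(F)}
        b = {tuple(doubled[i]) for i in opt.pareto_front(doubled)}
        assert a == b

    def test_minimize_sense_flips_orientation(self):
        F = np.array([[1.0], [3.0], [2.0]])
        assert list(opt.pareto_front(F, senses=["min"])) == [0]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            F = rng.uniform(size=(50, 3))
            assert sorted(opt.pareto_front(F)) == brute_force_front(F)

    def test_cap_keeps_extremes_and_honours_size(self, rng):
        # dense 2-D front: points on a descending curve, all non-dominated
        x = np.linspace(0, 1, 200)
        F = np.column_stack([x, 1 - x ** 2])
        front = opt.pareto_front(F, cap=50)
        assert len(front) == 50
        assert 0 in front and 199 in front


@pytest.fixture(scope="module")
def monotone_surrogate():
    # linear increasing response: optimum at the box's upper corner
    design = syn.generate_design()
    X = design_matrix(design)
    y = 0.2 * X[:, 0] + 0.1 * X[:, 1] + 0.5 * X[:, 2]
    return train(X, y, 2, TrainConfig(restarts=15, seed=0),
                 response_names=["lin"])


class TestGAOptimize:

    def test_monotone_objective_drives_to_upper_bound(
            self, monotone_surrogate):
        result = opt.ga_optimize([monotone_surrogate], syn.DESIGN_BOX,
                                 {"lin": "max"}, population=40,
                                 max_generations=40, seed=1)
        top = result.front.sort_values("lin", ascending=False).iloc[0]
        grid = np.array(np.meshgrid(
            np.arange(10, 30.5, 1), np.arange(25, 75.5, 2.5),
            np.arange(10, 20.5, 0.5), indexing="ij")).reshape(3, -1).T
        best = grid[np.argmax(monotone_surrogate.predict(grid)[:, 0])]
        assert abs(top["time"] - best[0]) <= 1.0
        assert abs(top["temperature"] - best[1]) <= 2.5
        assert abs(top["ratio"] - best[2]) <= 0.5

    def test_same_seed_gives_identical_result(self, monotone_surrogate):
        kwargs = dict(population=30, max_generations=20, seed=9)
        a = opt.ga_optimize([monotone_surrogate], syn.DESIGN_BOX,
                            {"lin": "max"}, **kwargs)
        b = opt.ga_optimize([monotone_surrogate], syn.DESIGN_BOX,
                            {"lin": "max"}, **kwargs)
        assert a.front.equals(b.front)
        assert a.generations == b.generations

    def test_front_cap_honoured_and_points_inside_bounds(
            self, paper_X, paper_responses):
        sub = paper_responses.subset(["TPC", "TFC"])
        surrogate = train(paper_X, sub.means, 5,
                          TrainConfig(restarts=10, seed=3),
                          response_names=["TPC", "TFC"])
        result = opt.ga_optimize([surrogate], syn.DESIGN_BOX,
                                 {"TPC": "max", "TFC": "max"},
                                 population=100, max_generations=30,
                                 front_cap=50, seed=2)
        assert len(result.front) <= 50
        front = result.front
        assert front["time"].between(10, 30).all()
        assert front["temperature"].between(25, 75).all()
        assert front["ratio"].between(10, 20).all()

    def test_unresolvable_objective_rejected(self, monotone_surrogate):
        with pytest.raises(ValueError, match="nope"):
            opt.ga_optimize([monotone_surrogate], syn.DESIGN_BOX,
                            {"nope": "max"}, seed=0)


class TestStandardScoreRank:
    def test_paper_campaign_puts_run_6_first(self, paper_responses):
        ranking = opt.standard_score_rank(paper_responses)
        assert ranking.index[0] == 6
        assert ranking["mean_score"].iloc[0] == pytest.approx(0.8003,
                                                              abs=5e-4)

    def test_hand_computed_zscore_toy(self):
        table = make_matrix([[1.0, 2.0], [2.0, 4.0], [3.0, 9.0]])
        ranking = opt.zscore_rank(table, convention="zscore-sample")
        # col1 z3 = 1; col2: mean 5, sd sqrt(13), z3 = 4/sqrt(13)
        expected = (1.0 + 4.0 / np.sqrt(13.0)) / 2
        assert ranking.loc[3, "mean_score"] == pytest.approx(expected)

    def test_z_columns_standardized_under_both_sd_conventions(
            self, paper_responses):
        for conv, ddof in (("zscore-sample", 1), ("zscore-population", 0)):
            ranking = opt.standard_score_rank(paper_responses,
                                              convention=conv)
            cols = ranking[list(paper_responses.response_names)]
            np.testing.assert_allclose(cols.mean(), 0, atol=1e-9)
            np.testing.assert_allclose(cols.to_numpy().std(axis=0,
                                                           ddof=ddof),
                                       1, atol=1e-9)

    def test_identical_samples_all_score_zero(self):
        table = make_matrix(np.ones((4, 3)))
        with pytest.warns(UserWarning, match="constant"):
            ranking = opt.zscore_rank(table)
        np.testing.assert_allclose(ranking["mean_score"], 0.0)

    def test_invariant_under_positive_affine_rescaling(self,
                                                       paper_responses):
        scaled = make_matrix(paper_responses.means * 3.7 + 11.0,
                             list(paper_responses.response_names))
        a = opt.standard_score_rank(paper_responses)["mean_score"]
        b = opt.standard_score_rank(scaled)["mean_score"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_minimize_sense_reverses_a_column(self):
        table = make_matrix([[1.0], [2.0], [3.0]], ["y"])
        ranking = opt.standard_score_rank(table, senses={"y": "min"})
        assert ranking.index[0] == 1


class TestSelectOptimum:
    def test_paper_campaign_selects_run_6_conditions(
            self, paper_design, paper_responses):
        best = opt.select_optimum(paper_responses, designs=paper_design)
        assert best["sample_id"] == 6
        assert best["conditions"] == {"time": 20.0, "temperature": 50.0,
                                      "ratio": 20.0}
        assert best["responses"]["TPC"] == 16.494
        assert best["responses"]["TFC"] == 2.103

    def test_single_candidate_returned_unchanged(self):
        table = make_matrix([[5.0, 1.0]])
        best = opt.select_optimum(table)
        assert best["sample_id"] == 1
        assert best["responses"] == {"y1": 5.0, "y2": 1.0}

    def test_dominant_candidate_wins(self):
        table = make_matrix([[1.0, 1.0], [2.0, 3.0], [1.5, 2.0]])
        assert opt.select_optimum(table)["sample_id"] == 2

    def test_empty_input_rejected(self):
        with pytest.raises((ValueError, TypeError)):
            opt.select_optimum(None)
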