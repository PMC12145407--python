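"""Scoring-rule tests: worked angular examples, oracle comparisons, and
similarity invariances of the bidimensional map regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navfactor.scoring import (
    CategoricalPointingTrial,
    MapPlacementSet,
    PathTrace,
    PointingTrial,
    ProtractorTrial,
    ScoringError,
    bidimensional_regression,
    bidimensional_regression_r2,
    chirality_correct,
    fold_angular_difference,
    reverse_score,
    score_mrt,
    score_nsq,
    score_ptta,
    score_sbsod,
    score_silcton_pointing,
    score_squaretown_efficiency,
    score_squaretown_pointing,
    score_temple_efficiency,
    score_temple_pointing,
    trace_length,
)


class TestAngularOps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(100, 295, 165), (0, 180, 180), (10, 350, 20), (90, 90, 0), (359, 0, 1)],
    )
    def test_fold_examples(self, a, b, expected):
        assert fold_angular_difference(a, b) == pytest.approx(expected)

    def test_fold_exhaustive_integer_oracle(self):
        # agrees with min(d, 360 - d) for every integer degree pair
        a = np.arange(360)
        for b in range(0, 360, 7):
            d = np.abs(a - b)
            oracle = np.minimum(d, 360 - d)
            ours = np.array([fold_angular_difference(float(x), float(b)) for x in a])
            assert np.array_equal(ours, oracle)

    @given(st.floats(0, 359.999), st.floats(0, 359.999))
    @settings(max_examples=200, deadline=None)
    def test_fold_symmetric_and_bounded(self, a, b):
        d = fold_angular_difference(a, b)
        assert 0 <= d <= 180
        assert d == pytest.approx(fold_angular_difference(b, a))

    def test_fold_rejects_out_of_range(self):
        with pytest.raises(ScoringError):
            fold_angular_difference(361, 0)

    @pytest.mark.parametrize(
        "indicated,turn,expected",
        [(315, "left", 45), (45, "right", 45), (0, "left", 0), (180, "left", 180)],
    )
    def test_chirality(self, indicated, turn, expected):
        assert chirality_correct(indicated, turn) == pytest.approx(expected)

    def test_chirality_rejects_unknown_turn(self):
        with pytest.raises(ScoringError):
            chirality_correct(90, "up")


class TestPointingScores:
    def test_temple_worked_example(self):
        # rightward 100 deg against actual 295: folded error 165, reversed
        t = ProtractorTrial(indicated_angle=100, turn_direction="right", actual_angle=295)
        assert score_temple_pointing([t]) == pytest.approx(-165)

    def test_temple_perfect(self):
        trials = [
            ProtractorTrial(indicated_angle=(360 - a) % 360, turn_direction="left", actual_angle=a)
            for a in (10.0, 100.0, 250.0)
        ]
        assert score_temple_pointing(trials) == pytest.approx(0.0)

    def test_temple_empty_signals(self):
        with pytest.raises(ScoringError):
            score_temple_pointing([])

    def test_silcton_group_means_match_hand_computation(self, spec, rng):
        # 4 stations x known offsets; manual group means
        trials = []
        errs = {"within": [], "between": []}
        for i in range(8):
            sroute = "A" if i < 4 else "B"
            for j in range(7):
                troute = "A" if (i + j) % 2 else "B"
                true = float(rng.uniform(0, 360))
                err = float(rng.uniform(0, 180))
                ind = (true + err) % 360
                trials.append(
                    PointingTrial(
                        station_id=f"s{i}",
                        target_id=f"t{i}_{j}",
                        station_route=sroute,
                        target_route=troute,
                        true_bearing=true,
                        indicated_bearing=ind,
                    )
                )
                errs["within" if sroute == troute else "between"].append(err)
        within, between = score_silcton_pointing(trials)
        assert within == pytest.approx(-np.mean(errs["within"]))
        assert between == pytest.approx(-np.mean(errs["between"]))

    def test_silcton_design_counts(self, small_cohort):
        _, raw = small_cohort
        trials = raw[0].silcton_pointing
        assert len(trials) == 56
        within = [t for t in trials if t.station_route == t.target_route]
        assert len(within) == 24 and len(trials) - len(within) == 32

    def test_squaretown_categorical(self):
        trials = [
            CategoricalPointingTrial(90, 90),
            CategoricalPointingTrial(180, 0),
            CategoricalPointingTrial(0, 90),
        ]
        assert score_squaretown_pointing(trials) == pytest.approx(-(0 + 180 + 90) / 3)

    def test_squaretown_rejects_bad_category(self):
        with pytest.raises(ScoringError):
            CategoricalPointingTrial(45, 90)


class TestMapRegression:
    GRID = np.array([(float(i % 4), float(i // 4)) for i in range(16)])

    def test_identity_is_perfect(self):
        ms = MapPlacementSet([f"o{i}" for i in range(16)], self.GRID.copy(), self.GRID.copy())
        assert bidimensional_regression_r2(ms) == pytest.approx(1.0)

    @given(
        theta=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 5.0),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_similarity_invariance(self, theta, scale, tx, ty):
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        placed = scale * self.GRID @ rot.T + np.array([tx, ty])
        ms = MapPlacementSet([f"o{i}" for i in range(16)], placed, self.GRID.copy())
        assert bidimensional_regression_r2(ms) == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equation_oracle(self, rng):
        placed = self.GRID + rng.normal(0, 0.8, self.GRID.shape)
        res = bidimensional_regression(placed, self.GRID)
        # independent oracle: solve the 4-parameter normal equations directly
        x, y = placed[:, 0], placed[:, 1]
        n = len(x)
        A = np.zeros((2 * n, 4))
        A[:n, 0] = 1
        A[:n, 2] = x
        A[:n, 3] = -y
        A[n:, 1] = 1
        A[n:, 2] = y
        A[n:, 3] = x
        b = np.concatenate([self.GRID[:, 0], self.GRID[:, 1]])
        coef = np.linalg.solve(A.T @ A, A.T @ b)
        sse = float(np.sum((b - A @ coef) ** 2))
        sst = float(np.sum((self.GRID - self.GRID.mean(axis=0)) ** 2))
        assert res["r2"] == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_affine_no_worse_than_euclidean(self, rng):
        placed = self.GRID @ np.array([[1.3, 0.4], [0.1, 0.8]]) + rng.normal(0, 0.3, self.GRID.shape)
        r2_e = bidimensional_regression(placed, self.GRID, "euclidean")["r2"]
        r2_a = bidimensional_regression(placed, self.GRID, "affine")["r2"]
        assert r2_a >= r2_e - 1e-12

    def test_degenerate_inputs_signal(self):
        with pytest.raises(ScoringError):
            bidimensional_regression(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ScoringError):
            bidimensional_regression(np.ones((5, 2)), self.GRID[:5])


class TestEfficiency:
    @staticmethod
    def _line_trace(route, block, length, shortest):
        s = np.linspace(0, length, 50)
        return PathTrace(route, block, np.column_stack([s, np.zeros_like(s)]), shortest)

    def test_trace_length(self):
        tr = PathTrace("r", 1, np.array([[0.0, 0.0], [3.0, 4.0]]), 5.0)
        assert trace_length(tr) == pytest.approx(5.0)

    def test_trace_length_random_oracle(self, rng):
        xy = rng.normal(size=(100, 2))
        tr = PathTrace("r", 1, xy, 1.0)
        oracle = sum(
            float(np.hypot(*(xy[i + 1] - xy[i]))) for i in range(len(xy) - 1)
        )
        assert trace_length(tr) == pytest.approx(oracle)

    def test_perfect_navigator_scores_minus_one(self):
        traces = [
            self._line_trace(f"r{i}", b, 100.0 + 10 * i, 100.0 + 10 * i)
            for i in range(8)
            for b in (1, 2)
        ]
        assert score_squaretown_efficiency(traces) == pytest.approx(-1.0)

    def test_doubling_gives_two(self):
        traces = [
            self._line_trace(f"r{i}", b, 2 * (100.0 + 10 * i), 100.0 + 10 * i)
            for i in range(8)
            for b in (1, 2)
        ]
        assert score_squaretown_efficiency(traces) == pytest.approx(-2.0)

    def test_corner_cutting_below_one(self):
        traces = [
            self._line_trace(f"r{i}", b, 0.98 * (100.0 + 10 * i), 100.0 + 10 * i)
            for i in range(8)
            for b in (1, 2)
        ]
        assert score_squaretown_efficiency(traces) == pytest.approx(-0.98)

    def test_literal_sum_variant(self):
        traces = [self._line_trace(f"r{i}", 1, 100.0, 100.0) for i in range(8)]
        assert score_squaretown_efficiency(traces, literal_sum=True) == pytest.approx(-8.0)

    def test_temple_ratio(self):
        legs = [(3, 2), (2, 2), (4, 2), (3, 2), (2, 2), (4, 2)]
        assert score_temple_efficiency(legs) == pytest.approx(-18 / 12)
        assert score_temple_efficiency([(m, m) for m in (2, 1, 3)]) == pytest.approx(-1.0)

    def test_temple_shortcut_impossible(self):
        with pytest.raises(ScoringError):
            score_temple_efficiency([(1, 2)])


class TestQuestionnaires:
    def test_sbsod_midpoint_and_extremes(self):
        assert score_sbsod([4] * 15) == pytest.approx(4.0)
        # all items negatively phrased at 7 -> 7.0
        assert score_sbsod([7] * 15, positive_items=()) == pytest.approx(7.0)

    def test_sbsod_mixed_hand_computed(self):
        items = [1, 7, 2, 6, 3, 5, 4, 1, 7, 2, 6, 3, 5, 4, 1]
        pos = (1, 3, 4, 5, 7, 9, 14)
        expected = np.mean([8 - r if i + 1 in pos else r for i, r in enumerate(items)])
        assert score_sbsod(items, pos) == pytest.approx(expected)

    def test_sbsod_rejects_bad_item(self):
        with pytest.raises(ScoringError):
            score_sbsod([0] + [4] * 14)

    @pytest.mark.parametrize(
        "counts,expected",
        [((7, 7, 0), 0), ((14, 0, 0), 14), ((5, 3, 6), 2), ((0, 14, 0), -14)],
    )
    def test_nsq(self, counts, expected):
        n_map, n_scene, n_alt = counts
        items = ["map"] * n_map + ["scene"] * n_scene + ["alternative"] * n_alt
        assert score_nsq(items) == expected

    def test_mrt_rules(self):
        both_right = ([0, 1], [0, 1])
        one_each = ([0, 2], [0, 1])
        both_wrong = ([2, 3], [0, 1])
        assert score_mrt([both_right]) == 4
        assert score_mrt([one_each]) == 0
        assert score_mrt([both_wrong]) == -4
        assert score_mrt([both_right] * 20) == 80
        assert score_mrt([([], [0, 1])]) == 0

    def test_mrt_rejects_three_picks(self):
        with pytest.raises(ScoringError):
            score_mrt([([0, 1, 2], [0, 1])])

    def test_ptta(self):
        assert score_ptta(15, 0.0, 180.0) == pytest.approx(5.0)
        assert score_ptta(0, 0.0, 60.0) == pytest.approx(0.0)
        assert score_ptta(17, 0.0, 185.0) == pytest.approx(17 / (185 / 60))
        with pytest.raises(ScoringError):
            score_ptta(5, 10.0, 10.0)

    def test_reverse_score(self):
        assert reverse_score(90) == -90
        assert reverse_score(-1.36) == 1.36
        assert reverse_score(0) == 0
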