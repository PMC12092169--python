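"""Metrics and tuning: AUC oracle, Boyce limits, sensitivity, one-SE rule."""

import numpy as np
import pytest

from mtenm.exceptions import DegenerateSuitabilityError, EmptyInputError
from mtenm.model_selection import (
    TuningResult,
    continuous_boyce,
    cross_validate,
    results_frame,
    roc_auc,
    select_one_se,
    sensitivity,
)


def brute_force_auc(pres, bg):
    wins = sum((p > b) + 0.5 * (p == b) for p in pres for b in bg)
    return wins / (len(pres) * len(bg))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_hand_example(self):
        assert roc_auc([0.9, 0.8], [0.7, 0.85]) == 0.75

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_p, n_b = rng.integers(1, 30, 2)
            # discrete values force ties to exercise the 0.5 convention
            pres = rng.integers(0, 10, n_p) / 10.0
            bg = rng.integers(0, 10, n_b) / 10.0
            assert roc_auc(pres, bg) == brute_force_auc(pres, bg)

    def test_exchangeable_inputs_average_half(self):
        rng = np.random.default_rng(1)
        aucs = [
            roc_auc(rng.uniform(size=50), rng.uniform(size=50)) for _ in range(100)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_empty_inputs_raise(self):
        with pytest.raises(EmptyInputError):
            roc_auc([], [0.5])


class TestBoyce:
    def test_monotone_increasing_ratio_gives_one(self):
        avail = np.linspace(0, 1, 1001)
        pres = np.repeat(avail, np.round(100 * avail).astype(int))
        assert continuous_boyce(pres, avail) == pytest.approx(1.0)

    def test_monotone_decreasing_ratio_gives_minus_one(self):
        avail = np.linspace(0, 1, 1001)
        pres = np.repeat(avail, np.round(100 * (1 - avail)).astype(int))
        assert continuous_boyce(pres, avail) == pytest.approx(-1.0)

    def test_null_resampling_is_unbiased(self):
        # presences drawn from the available set: the index has no
        # systematic sign (its mean over repeats is near zero)
        vals = []
        for r in range(50):
            rng = np.random.default_rng((3, r))
            avail = rng.uniform(0, 1, 3000)
            pres = rng.choice(avail, 300)
            vals.append(continuous_boyce(pres, avail))
        assert abs(np.mean(vals)) < 0.1

    def test_rank_invariance_under_monotone_maps(self):
        for r in range(10):
            rng = np.random.default_rng((4, r))
            avail = rng.uniform(0, 1, 3000)
            pres = avail[avail + rng.normal(0, 0.3, 3000) > 0.8][:400]
            b0 = continuous_boyce(pres, avail)
            knots = np.linspace(0, 1, 12)
            vals = np.cumsum(rng.uniform(0.05, 1, 12))
            vals = (vals - vals[0]) / (vals[-1] - vals[0])
            b1 = continuous_boyce(np.interp(pres, knots, vals), np.interp(avail, knots, vals))
            assert abs(b1 - b0) < 0.15

    def test_constant_suitability_raises(self):
        with pytest.raises(DegenerateSuitabilityError):
            continuous_boyce([0.5], np.full(10, 0.5))


class TestSensitivity:
    def test_threshold_below_minimum(self):
        assert sensitivity([0.2, 0.3], 0.1) == 1.0

    def test_threshold_above_maximum(self):
        assert sensitivity([0.2, 0.3], 0.9) == 0.0

    def test_tenth_percentile_of_own_presences(self):
        vals = np.arange(1, 101) / 100.0  # 100 distinct values
        thr = np.percentile(vals, 10, method="lower")
        assert sensitivity(vals, thr) == pytest.approx(0.90, abs=0.011)

    def test_weighted_fraction(self):
        assert sensitivity([0.1, 0.9], 0.5, weights=[1.0, 3.0]) == 0.75


@pytest.fixture(scope="module")
def cv_setup():
    rng = np.random.default_rng(10)
    center = np.array([20.0, 5.0, 31.0, 200.0])
    spread = np.array([8.0, 2.0, 1.0, 120.0])
    X = rng.normal(center, spread, (150, 4))
    avail = rng.uniform(center - 4 * spread, center + 4 * spread, (800, 4))
    folds = np.arange(150) % 5 + 1
    return X, avail, folds


class TestCrossValidate:
    config = {"bandwidth_mult": 1.5, "sd_count": 3, "quantile": 0.95,
              "edges_zero_distance_factor": 2.0, "weight_exponent": -2,
              "n_boundary": 2000}

    def test_well_specified_data_scores_high(self, cv_setup):
        X, avail, folds = cv_setup
        res = cross_validate(X, None, folds, self.config, avail, seed=1)
        assert res.means["auc"] >= 0.7
        assert res.means["sensitivity"] > 0.5
        assert all(res.ses[m] >= 0 for m in res.ses)

    def test_invariant_to_fold_relabeling(self, cv_setup):
        X, avail, folds = cv_setup
        r1 = cross_validate(X, None, folds, self.config, avail, seed=2)
        relabeled = ((folds + 2) % 5) + 1  # permute fold labels
        r2 = cross_validate(X, None, relabeled, self.config, avail, seed=2)
        for m in r1.means:
            assert r1.means[m] == pytest.approx(r2.means[m])


def make_result(config, means, ses=None):
    r = TuningResult(config=config)
    r.means = dict(zip(("auc", "boyce", "sensitivity"), means))
    r.ses = dict(zip(("auc", "boyce", "sensitivity"), ses or (0.0, 0.0, 0.0)))
    return r


class TestOneSERule:
    def test_clear_winner(self):
        rs = [
            make_result({"bandwidth_mult": 1.0}, (0.9, 0.9, 0.9), (0.01, 0.01, 0.01)),
            make_result({"bandwidth_mult": 2.0}, (0.5, 0.5, 0.5), (0.01, 0.01, 0.01)),
        ]
        assert select_one_se(rs).config["bandwidth_mult"] == 1.0

    def test_parsimony_prefers_larger_bandwidth_on_ties(self):
        rs = [
            make_result({"bandwidth_mult": 1.0, "quantile": 0.95, "sd_count": 3}, (0.8, 0.8, 0.8)),
            make_result({"bandwidth_mult": 2.0, "quantile": 0.95, "sd_count": 3}, (0.8, 0.8, 0.8)),
        ]
        assert select_one_se(rs).config["bandwidth_mult"] == 2.0

    def test_identical_metrics_fall_back_to_grid_order(self):
        rs = [
            make_result({"bandwidth_mult": 1.0}, (0.7, 0.7, 0.7)),
            make_result({"bandwidth_mult": 1.0}, (0.7, 0.7, 0.7)),
        ]
        winner = select_one_se(rs)
        assert winner is rs[0]

    def test_near_best_parsimonious_config_wins_within_one_se(self):
        rs = [
            make_result({"bandwidth_mult": 1.0}, (0.82, 0.80, 0.80), (0.05, 0.05, 0.05)),
            make_result({"bandwidth_mult": 2.5}, (0.80, 0.80, 0.80), (0.05, 0.05, 0.05)),
            make_result({"bandwidth_mult": 0.5}, (0.40, 0.40, 0.40), (0.05, 0.05, 0.05)),
        ]
        assert select_one_se(rs).config["bandwidth_mult"] == 2.5

    def test_results_frame_marks_selection(self):
        rs = [
            make_result({"bandwidth_mult": 1.0}, (0.9, 0.9, 0.9)),
            make_result({"bandwidth_mult": 2.0}, (0.5, 0.5, 0.5)),
        ]
        select_one_se(rs)
        tab = results_frame(rs)
        assert tab["selected"].sum() == 1
        assert set(tab.columns) >= {"bandwidth_mult", "auc_mean", "combined"}
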