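"""Linear max-margin electrode classification and its permutation test."""

import numpy as np
import pandas as pd
import pytest

import mttpipe as m
from mttpipe.classify import loo_predictions

from conftest import small_config
from oracles import (
    naive_loo_accuracy,
    naive_permutation_pvalue,
    naive_zscore,
)


def _features_frame(X, labels, hemisphere="L", task="time"):
    return pd.DataFrame(
        {
            "electrode_id": [f"e{i}" for i in range(len(labels))],
            "region": labels,
            "hemisphere": hemisphere,
            "patient": "sim",
            "task": task,
            "early": X[:, 0],
            "late": X[:, 1],
        }
    )


class TestZscore:
    def test_closed_form_three_points(self):
        out = m.zscore_features(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_idempotent_on_scaled_column(self):
        x = np.array([[-1.2247448], [0.0], [1.2247448]])
        np.testing.assert_allclose(m.zscore_features(x), x, atol=1e-12)

    def test_constant_column_becomes_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = m.zscore_features(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert np.all(out[:, 1] == 0.0)

    def test_matches_naive_population_zscore(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        np.testing.assert_allclose(m.zscore_features(X), naive_zscore(X), atol=1e-12)


class TestLooAccuracy:
    def test_far_separated_clusters_classified_perfectly(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-10, 0.5, (4, 2)), rng.normal(10, 0.5, (4, 2))])
        y = np.array(["A"] * 4 + ["B"] * 4)
        assert m.loo_accuracy(X, y, C=1.0) == 1.0

    def test_identical_points_carry_no_information(self):
        X = np.ones((8, 2))
        y = np.array(["A"] * 4 + ["B"] * 4)
        assert m.loo_accuracy(X, y, C=1.0) <= 0.5

    def test_complement_labelling_gives_same_accuracy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2))
        y = np.array(["A"] * 5 + ["B"] * 5)
        y_swapped = np.where(y == "A", "B", "A")
        for C in (0.01, 1.0, 100.0):
            assert m.loo_accuracy(X, y, C) == m.loo_accuracy(X, y_swapped, C)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_naive_qp_oracle_fold_by_fold(self, seed):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(-1.0, 1.0, (3, 2)), rng.normal(1.0, 1.0, (3, 2))])
        y = np.array(["A"] * 3 + ["B"] * 3)
        y_pm = np.where(y == "A", -1.0, 1.0)
        for C in (0.1, 1.0, 10.0):
            assert m.loo_accuracy(X, y, C) == pytest.approx(naive_loo_accuracy(X, y_pm, C))

    def test_one_class_training_fold_predicts_majority(self):
        # 2 vs 2: leaving out one of a pair can never empty a class, so use
        # the internal predictor directly on a degenerate labelling
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        pred = loo_predictions(X, np.array(["A", "A", "A"]), C=1.0)
        assert list(pred) == ["A", "A", "A"]


class TestSelectC:
    def test_grid_endpoints_are_exact(self):
        grid = m.default_c_grid()
        assert len(grid) == 10
        assert grid[0] == pytest.approx(0.001, rel=1e-12)
        assert grid[-1] == pytest.approx(1000.0, rel=1e-12)
        np.testing.assert_allclose(np.diff(np.log10(grid)), 6.0 / 9.0)

    def test_separable_data_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(-5, 0.3, (4, 2)), rng.normal(5, 0.3, (4, 2))])
        y = np.array(["A"] * 4 + ["B"] * 4)
        C, cv = m.select_C(X, y)
        assert cv.max() == 1.0
        assert cv[C] == 1.0

    def test_flat_accuracy_ties_break_to_smallest_C(self):
        X = np.ones((8, 2))  # no information: accuracy identical across grid
        y = np.array(["A"] * 4 + ["B"] * 4)
        C, cv = m.select_C(X, y)
        assert C == pytest.approx(0.001)
        assert cv.nunique() == 1


class TestPermutationTest:
    def test_four_points_two_per_class_enumerates_six_labelings(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array(["A", "A", "B", "B"])
        p, dist = m.permutation_test(X, y, C=1.0)
        assert len(dist) == 6
        assert p >= 1.0 / 6.0

    def test_identical_features_give_large_p(self):
        X = np.zeros((8, 2))
        y = np.array(["A"] * 4 + ["B"] * 4)
        p, _ = m.permutation_test(X, y, C=1.0)
        assert p >= 0.5

    def test_non_binary_labels_rejected(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError):
            m.permutation_test(X, np.array(["A", "B", "C"] * 2), C=1.0)

    def test_separated_6v6_null_matches_exhaustive_oracle(self):
        """924 labelings; the oracle recounts how many reach the observed
        accuracy (expected: the true labelling and its complement)."""
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(-3, 0.4, (6, 2)), rng.normal(3, 0.4, (6, 2))])
        Xs = m.zscore_features(X)
        y = np.array(["A"] * 6 + ["B"] * 6)
        p, dist = m.permutation_test(Xs, y, C=1.0)
        assert len(dist) == 924
        y_pm = np.where(y == "A", -1.0, 1.0)
        p_oracle, dist_oracle, obs = naive_permutation_pvalue(Xs, y_pm, C=1.0)
        assert obs == 1.0
        assert int(np.sum(dist_oracle >= obs)) == 2
        assert p == pytest.approx(p_oracle)
        assert p == pytest.approx(2.0 / 924.0)

    def test_monte_carlo_fallback_is_seeded(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(16, 2))
        y = np.array(["A"] * 8 + ["B"] * 8)  # C(16,8)=12870 labelings
        p1, d1 = m.permutation_test(X, y, C=1.0, max_exhaustive=1000, n_montecarlo=200, seed=5)
        p2, d2 = m.permutation_test(X, y, C=1.0, max_exhaustive=1000, n_montecarlo=200, seed=5)
        assert p1 == p2
        np.testing.assert_array_equal(d1, d2)
        assert len(d1) == 200
        assert p1 >= 1.0 / 201.0


class TestElectrodeClassifier:
    def test_study_conditions_give_perfect_left_time_separation(self, default_features):
        res = m.ElectrodeClassifier(default_features, hemisphere="L", task="time").fit()
        assert res.loo_accuracy == 1.0
        assert res.n_permutations == 924
        assert res.exhaustive
        assert res.p_value < 0.005
        assert res.n_per_class == {"LTC": 6, "HIPP": 6}

    def test_full_pipeline_matches_naive_reimplementation_small_n(self):
        """Scaling + LOO + exhaustive permutations vs the from-scratch
        oracle, exact agreement, for 4 vs 4 electrodes."""
        for seed in (11, 12):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(-1.2, 0.8, (4, 2)), rng.normal(1.2, 0.8, (4, 2))])
            frame = _features_frame(X, ["LTC"] * 4 + ["HIPP"] * 4)
            res = m.ElectrodeClassifier(frame).fit()
            Xs = naive_zscore(X)
            y_pm = np.where(frame["region"] == "LTC", -1.0, 1.0)
            assert res.loo_accuracy == pytest.approx(
                naive_loo_accuracy(Xs, y_pm, res.selected_C)
            )
            p_oracle, dist_oracle, _ = naive_permutation_pvalue(Xs, y_pm, res.selected_C)
            assert res.n_permutations == 70 == len(dist_oracle)
            assert res.p_value == pytest.approx(p_oracle)

    def test_fewer_than_two_electrodes_per_class_rejected(self, default_features):
        sub = default_features[default_features["electrode_id"] != "l_ltc01"]
        sub = sub[~sub["electrode_id"].isin(["l_ltc02", "l_ltc03", "l_ltc04", "l_ltc05"])]
        with pytest.raises(ValueError, match="2 electrodes"):
            m.ElectrodeClassifier(sub, hemisphere="L", task="time")

    def test_summary_reports_key_quantities(self, default_features):
        res = m.ElectrodeClassifier(default_features, hemisphere="L", task="time").fit()
        text = res.summary()
        assert "LOO accuracy: 1.0000" in text
        assert "924 labelings" in text
        assert "exhaustive" in text

    def test_fold_safe_scaling_mode_runs_and_is_reported(self, default_features):
        res = m.ElectrodeClassifier(
            default_features, hemisphere="L", task="time", fold_safe_scaling=True
        ).fit()
        assert res.fold_safe_scaling
        assert 0.0 <= res.loo_accuracy <= 1.0


class TestNullCalibration:
    def test_pvalues_superuniform_and_accuracy_degrades_with_noise(self):
        """Effect-free datasets: P(p <= alpha) <= alpha + 3 MC-sd.

        Also checks the monotone trend: mean LOO accuracy at high noise does
        not exceed mean accuracy at low noise on effect-bearing data.
        """
        n_seeds = 40
        ps = []
        for seed in range(n_seeds):
            cfg = small_config(
                seed=seed, early_effect=0.0, late_effect=0.0,
                n_ltc_left=4, n_hipp_left=4, trials_per_condition=15,
            )
            epochs, meta = m.generate_dataset(cfg)
            f = m.features_for_dataset(m.average_evoked(m.bandpass(epochs)), meta)
            res = m.ElectrodeClassifier(f, hemisphere="L", task="time").fit()
            ps.append(res.p_value)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1):
            mc_sd = np.sqrt(alpha * (1 - alpha) / n_seeds)
            assert np.mean(ps <= alpha) <= alpha + 3 * mc_sd
        assert np.mean(ps > 0.05) >= 0.85

        accs = {sd: [] for sd in (0.5, 6.0)}
        for sd in accs:
            for seed in range(25):
                cfg = small_config(
                    seed=seed, noise_sd=sd, n_ltc_left=4, n_hipp_left=4,
                    trials_per_condition=15,
                )
                epochs, meta = m.generate_dataset(cfg)
                f = m.features_for_dataset(m.average_evoked(m.bandpass(epochs)), meta)
                sel = f[f["hemisphere"] == "L"]
                X = m.zscore_features(sel[["early", "late"]].to_numpy())
                accs[sd].append(m.loo_accuracy(X, sel["region"].to_numpy(), C=1.0))
        assert np.mean(accs[6.0]) <= np.mean(accs[0.5])
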