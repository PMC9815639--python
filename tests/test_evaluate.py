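import math

import numpy as np
import pandas as pd
import pytest

import penwatch as pw
from penwatch.bench import ResamplingProfile
from penwatch.errors import ConfigurationError
from penwatch.evaluate import (
    compare_models,
    confusion_report,
    results_table,
    run_benchmark,
    sensitivity_sweep,
    split_cv,
    split_loop,
)
from penwatch.windows import WindowConfig


def label_frame(n, tb_frac=0.2, n_pens=4, seed=0):
    rng = np.random.default_rng(seed)
    pens = [f"pen{i}" for i in range(n_pens)]
    return pd.DataFrame({
        "pen_id": rng.choice(pens, n),
        "herd_id": "h1",
        "a_date": pd.Timestamp("2019-01-01"),
        "label": np.where(rng.random(n) < tb_frac, "TB", "CTL"),
    })


class TestSplitCV:
    def test_75_25_partition(self):
        win = label_frame(100)
        plan = split_cv(win, 0.25, seed=0)
        assert len(plan.train_idx) == 75 and len(plan.test_idx) == 25
        assert len(np.intersect1d(plan.train_idx, plan.test_idx)) == 0

    def test_deterministic_per_seed(self):
        win = label_frame(60)
        a, b = split_cv(win, 0.25, seed=5), split_cv(win, 0.25, seed=5)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_stratification_preserves_class_share(self):
        win = label_frame(200, tb_frac=0.2, seed=1)
        plan = split_cv(win, 0.25, seed=1)
        n_tb = (win["label"] == "TB").sum()
        tb_in_test = (win.iloc[plan.test_idx]["label"] == "TB").sum()
        assert abs(tb_in_test - 0.25 * n_tb) <= 1

    def test_rare_class_falls_back_unstratified(self):
        win = label_frame(20, tb_frac=0.0)
        win.loc[0, "label"] = "TB"
        with pytest.warns(UserWarning, match="unstratified"):
            split_cv(win, 0.25, seed=0)


class TestSplitLOOP:
    def pens_frame(self, pen_ids, statuses):
        return pd.DataFrame({
            "pen_id": pen_ids, "herd_id": "h1", "status": statuses,
            "tb_date": pd.NaT, "rec_start": pd.Timestamp("2019-01-01"),
            "rec_end": pd.Timestamp("2019-02-01"),
        })

    def test_single_pen_held_out_of_four(self):
        win = label_frame(80, n_pens=4, seed=2)
        pens = self.pens_frame([f"pen{i}" for i in range(4)], ["CTL"] * 4)
        plan = split_loop(win, pens, 0.25, seed=0)
        assert len(plan.held_out_pens) == 1
        held = plan.held_out_pens[0]
        assert (win.iloc[plan.test_idx]["pen_id"] == held).all()
        assert (win.iloc[plan.train_idx]["pen_id"] != held).all()

    def test_no_pen_on_both_sides_across_seeds(self):
        win = label_frame(150, n_pens=8, seed=3)
        pens = self.pens_frame([f"pen{i}" for i in range(8)], ["TB"] * 4 + ["CTL"] * 4)
        for seed in range(25):
            plan = split_loop(win, pens, 0.25, seed=seed)
            train_pens = set(win.iloc[plan.train_idx]["pen_id"])
            test_pens = set(win.iloc[plan.test_idx]["pen_id"])
            assert not train_pens & test_pens

    def test_every_pen_eventually_held_out(self):
        win = label_frame(100, n_pens=4, seed=4)
        pens = self.pens_frame([f"pen{i}" for i in range(4)], ["CTL"] * 4)
        held = set()
        for seed in range(60):
            held.update(split_loop(win, pens, 0.25, seed=seed).held_out_pens)
        assert held == {"pen0", "pen1", "pen2", "pen3"}

    def test_one_pen_mode(self):
        win = label_frame(100, n_pens=5, seed=5)
        pens = self.pens_frame([f"pen{i}" for i in range(5)], ["CTL"] * 5)
        plan = split_loop(win, pens, seed=3, one_pen=True)
        assert len(plan.held_out_pens) == 1


class TestConfusionReport:
    def test_hand_computed_metrics(self):
        y_true = np.array(["TB"] * 100 + ["CTL"] * 100)
        y_pred = np.array(["TB"] * 80 + ["CTL"] * 20 + ["CTL"] * 95 + ["TB"] * 5)
        r = confusion_report(y_pred, y_true)
        assert (r.tp, r.fn, r.tn, r.fp) == (80, 20, 95, 5)
        assert r.tpr == pytest.approx(0.80)
        assert r.tnr == pytest.approx(0.95)
        assert r.ppv == pytest.approx(0.9412, abs=1e-4)
        assert r.acc == pytest.approx(0.875)
        assert r.kappa == pytest.approx(0.75)  # pe = 0.5
        assert r.kappa_band == "substantial"

    def test_constant_predictor_has_zero_kappa(self):
        y_true = np.array(["TB"] * 30 + ["CTL"] * 70)
        y_pred = np.array(["CTL"] * 100)
        r = confusion_report(y_pred, y_true)
        assert r.tpr == 0.0 and r.tnr == 1.0
        assert r.kappa == pytest.approx(0.0)
        assert r.acc == pytest.approx(r.nir)
        assert r.p_value > 0.5
        assert math.isnan(r.ppv)  # 0/0 reported missing, never 0

    def test_perfect_predictions(self):
        y = np.array(["TB"] * 10 + ["CTL"] * 40)
        r = confusion_report(y, y)
        assert r.acc == 1.0 and r.kappa == 1.0
        assert r.kappa_band == "almost perfect"
        assert r.p_value < 1e-4  # exact binomial vs NIR 0.8 at n=50

    def test_mismatched_lengths_and_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_report(["TB"], ["TB", "CTL"])
        with pytest.raises(ValueError, match="unknown labels"):
            confusion_report(["yes"], ["TB"])

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(2, 60))
            y_true = rng.choice(["TB", "CTL"], n)
            y_pred = rng.choice(["TB", "CTL"], n)
            r = confusion_report(y_pred, y_true)
            # independent tally by explicit enumeration
            tp = sum(p == "TB" and t == "TB" for p, t in zip(y_pred, y_true))
            fp = sum(p == "TB" and t == "CTL" for p, t in zip(y_pred, y_true))
            fn = sum(p == "CTL" and t == "TB" for p, t in zip(y_pred, y_true))
            tn = sum(p == "CTL" and t == "CTL" for p, t in zip(y_pred, y_true))
            assert (r.tp, r.fp, r.fn, r.tn) == (tp, fp, fn, tn)
            assert r.acc == pytest.approx((tp + tn) / n)


class TestCompareModels:
    def profile(self, name, values):
        return ResamplingProfile(model=name, tpr=np.asarray(values, dtype=float), params={})

    def test_self_comparison_is_null(self):
        p = self.profile("a", [0.5, 0.6, 0.7, 0.4])
        out = compare_models([p, self.profile("b", [0.5, 0.6, 0.7, 0.4])])
        row = out.iloc[0]
        assert row["mean_tpr_diff"] == 0.0
        assert row["p_raw"] == 1.0

    def test_seven_models_give_21_bonferroni_pairs(self):
        rng = np.random.default_rng(0)
        profiles = [self.profile(f"m{i}", rng.random(10)) for i in range(7)]
        out = compare_models(profiles)
        assert len(out) == 21
        np.testing.assert_allclose(
            out["p_adj"], np.minimum(1.0, out["p_raw"] * 21)
        )

    def test_missing_folds_dropped_listwise(self):
        a = self.profile("a", [0.5, np.nan, 0.7, 0.4])
        b = self.profile("b", [0.4, 0.6, np.nan, 0.5])
        out = compare_models([a, b])
        assert out.iloc[0]["n_folds_used"] == 2

    def test_mismatched_fold_counts_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            compare_models([self.profile("a", [0.1, 0.2]), self.profile("b", [0.1])])

    def test_null_profiles_control_type_one_error(self):
        """Same-distribution profiles are rarely declared different."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = self.profile("a", rng.normal(0.5, 0.1, 20))
            b = self.profile("b", rng.normal(0.5, 0.1, 20))
            if compare_models([a, b]).iloc[0]["p_adj"] < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.08  # nominal 5% plus Monte-Carlo slack


def test_sweep_default_cell_reproduces_base_run(sim_dataset, sim_observations):
    cfg = WindowConfig()
    tune = pw.TuneConfig(resampling_folds=3, budget=1, seed=0)
    base = run_benchmark(
        sim_observations, sim_dataset.pens, cfg, ["knn"], tune,
        regime="CV", split_seed=0,
    )["knn"]
    out = sensitivity_sweep(
        sim_observations, sim_dataset.pens, cfg, tune,
        window_days_grid=(14,), tb_window_grid=((-35, 10),),
        model="knn", seeds=(0,), regimes=("CV",),
    )
    assert len(out) == 1
    assert out.iloc[0]["acc"] == pytest.approx(base.report.acc)
    assert out.iloc[0]["kappa"] == pytest.approx(base.report.kappa)


def test_results_table_layout(sim_dataset, sim_observations):
    cfg = WindowConfig()
    tune = pw.TuneConfig(resampling_folds=3, budget=1, seed=1)
    res = run_benchmark(sim_observations, sim_dataset.pens, cfg, ["knn"], tune,
                        regime="LOOP", split_seed=1)
    table = results_table({"LOOP": res})
    assert set(["model", "regime", "herd_subset", "acc", "tpr", "tnr", "ppv",
                "kappa", "nir", "p_value"]).issubset(table.columns)
    assert table.iloc[0]["regime"] == "LOOP"
    assert table.iloc[0]["herd_subset"] == "all"


def test_merged_herds_get_per_herd_subset_rows():
    """A two-herd run reports metrics on each herd's test subset too."""
    herds = [pw.scaled_profile(pw.swedish_profile(), n_pens=2, tb_pen_count=1,
                               halfspan=20, pigs_per_pen=(10, 10)),
             pw.scaled_profile(pw.swiss_profile(), n_pens=2, tb_pen_count=1,
                               halfspan=20, pigs_per_pen=(11, 12))]
    data = pw.simulate_herds(herds, pw.DriftModel(onset_day=-15), seed=7)
    obs = pw.daily_observations(data)
    res = run_benchmark(obs, data.pens, WindowConfig(), ["knn"],
                        pw.TuneConfig(resampling_folds=3, budget=1, seed=7),
                        regime="CV", split_seed=7)
    table = results_table({"CV": res})
    assert set(table["herd_subset"]) == {"all", "swedish", "swiss"}
    # subset counts add up to the full test set
    n_all = table[table["herd_subset"] == "all"][["tp", "fp", "fn", "tn"]].sum(axis=1).iloc[0]
    n_sub = table[table["herd_subset"] != "all"][["tp", "fp", "fn", "tn"]].sum().sum()
    assert n_all == n_sub


def test_unknown_regime_rejected(sim_dataset, sim_observations):
    with pytest.raises(ConfigurationError, match="regime"):
        run_benchmark(sim_observations, sim_dataset.pens, WindowConfig(), ["knn"],
                      pw.TuneConfig(resampling_folds=3, budget=1, seed=0),
                      regime="bootstrap")
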