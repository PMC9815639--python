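"""Split regimes, confusion-matrix reporting and model comparison.

Two train/test regimes with opposite leakage behaviour:

* **CV** — a random, class-stratified window-level 75/25 split.  Windows
  of the same pen (largely overlapping in time) can land on both sides,
  so this measures performance when the model is continuously updated
  with the pen's own history.
* **LOOP** — a pen-held-out split: ~25% of pens (stratified by herd and
  outbreak status) contribute *all* their windows to the test side, none
  to training.  This measures performance on a pen the model has never
  seen — the deployment-on-a-new-pen scenario.

Reports carry the full confusion matrix with TB as the positive class,
TPR/TNR/PPV/accuracy, an exact (Clopper-Pearson) 95% CI on accuracy,
Cohen's kappa with its Landis-Koch band, the no-information rate (NIR,
accuracy of always predicting the majority class) and a one-sided exact
binomial p-value for accuracy exceeding the NIR.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from . import bench
from .bench import NEGATIVE, POSITIVE, ResamplingProfile, TuneConfig
from .errors import ConfigurationError
from .windows import WindowConfig, build_windows, make_preprocessor


@dataclass
class SplitPlan:
    """Train/test assignment of window row indices."""

    mode: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    held_out_pens: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.train_idx, self.test_idx)
        if overlap.size:
            raise ConfigurationError("train and test sets overlap")


def split_cv(windows: pd.DataFrame, test_fraction: float = 0.25, seed: int = 0) -> SplitPlan:
    """Random window-level split, stratified by class when possible."""
    if len(windows) < 2:
        raise ConfigurationError("need at least 2 windows to split")
    idx = np.arange(len(windows))
    labels = windows["label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    stratify = labels
    if (counts < 2).any():
        warnings.warn("a class has fewer than 2 windows; falling back to unstratified split")
        stratify = None
    train, test = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=stratify
    )
    return SplitPlan("CV", np.sort(train), np.sort(test), None, seed)


def split_loop(
    windows: pd.DataFrame,
    pens: pd.DataFrame,
    pen_test_fraction: float = 0.25,
    seed: int = 0,
    one_pen: bool = False,
) -> SplitPlan:
    """Pen-held-out split: test pens sampled per (herd, status) stratum.

    ``one_pen=True`` holds out a single random pen (strict
    leave-one-pen-out fold)."""
    pen_ids = windows["pen_id"].unique()
    if len(pen_ids) < 2:
        raise ConfigurationError("need at least 2 pens for a LOOP split")
    meta = pens[pens["pen_id"].isin(pen_ids)][["pen_id", "herd_id", "status"]]
    rng = np.random.default_rng(seed)

    if one_pen:
        test_pens = [str(rng.choice(np.sort(pen_ids)))]
    else:
        test_pens = []
        for (_, _), group in meta.groupby(["herd_id", "status"]):
            ids = np.sort(group["pen_id"].to_numpy())
            if len(ids) < 2:
                warnings.warn(
                    f"stratum with a single pen ({ids[0]}); assigned to training"
                )
                continue
            n_test = max(1, round(pen_test_fraction * len(ids)))
            n_test = min(n_test, len(ids) - 1)
            test_pens.extend(rng.choice(ids, size=n_test, replace=False).tolist())

    in_test = windows["pen_id"].isin(test_pens).to_numpy()
    plan = SplitPlan(
        "LOOP",
        np.flatnonzero(~in_test),
        np.flatnonzero(in_test),
        held_out_pens=sorted(test_pens),
        seed=seed,
    )
    _assert_pen_disjoint(windows, plan)
    return plan


def _assert_pen_disjoint(windows: pd.DataFrame, plan: SplitPlan) -> None:
    train_pens = set(windows.iloc[plan.train_idx]["pen_id"])
    test_pens = set(windows.iloc[plan.test_idx]["pen_id"])
    if train_pens & test_pens:
        raise ConfigurationError(
            f"LOOP split leaks pens across sides: {sorted(train_pens & test_pens)}"
        )


# --------------------------------------------------------------------------
# confusion reporting

KAPPA_BANDS = [
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


@dataclass
class ConfusionReport:
    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float
    tnr: float
    ppv: float
    acc: float
    acc_ci: tuple[float, float]
    kappa: float
    nir: float
    p_value: float
    kappa_band: str

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "tpr": self.tpr, "tnr": self.tnr, "ppv": self.ppv, "acc": self.acc,
            "acc_lo": self.acc_ci[0], "acc_hi": self.acc_ci[1],
            "kappa": self.kappa, "nir": self.nir, "p_value": self.p_value,
            "kappa_band": self.kappa_band,
        }
        return d


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion_report(y_pred, y_true) -> ConfusionReport:
    """All performance measures from a pair of label vectors.

    TB is the positive class.  Ratios with a zero denominator are
    reported as missing (NaN), never as 0.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if len(y_pred) != len(y_true):
        raise ValueError("prediction and truth vectors differ in length")
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    valid = {POSITIVE, NEGATIVE}
    bad = set(np.unique(np.concatenate([y_pred, y_true]))) - valid
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected {sorted(valid)}")

    tp = int(np.sum((y_pred == POSITIVE) & (y_true == POSITIVE)))
    fp = int(np.sum((y_pred == POSITIVE) & (y_true == NEGATIVE)))
    fn = int(np.sum((y_pred == NEGATIVE) & (y_true == POSITIVE)))
    tn = int(np.sum((y_pred == NEGATIVE) & (y_true == NEGATIVE)))
    n = tp + fp + fn + tn

    tpr = _safe_ratio(tp, tp + fn)
    tnr = _safe_ratio(tn, tn + fp)
    ppv = _safe_ratio(tp, tp + fp)
    acc = (tp + tn) / n

    pe = ((tp + fn) * (tp + fp) + (fn + tn) * (fp + tn)) / n**2
    kappa = (acc - pe) / (1 - pe) if pe < 1.0 else math.nan

    correct = tp + tn
    test = stats.binomtest(correct, n, p=0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    nir = max(tp + fn, tn + fp) / n
    p_value = stats.binomtest(correct, n, p=nir, alternative="greater").pvalue

    band = "slight"
    for cut, name in KAPPA_BANDS:
        band = name
        if (kappa if not math.isnan(kappa) else 0.0) <= cut:
            break

    return ConfusionReport(
        tp=tp, fp=fp, fn=fn, tn=tn, tpr=tpr, tnr=tnr, ppv=ppv, acc=acc,
        acc_ci=(float(ci.low), float(ci.high)), kappa=kappa, nir=nir,
        p_value=float(p_value), kappa_band=band,
    )


def compare_models(profiles: list[ResamplingProfile]) -> pd.DataFrame:
    """Pairwise paired t-tests on fold-wise TPR, Bonferroni-adjusted.

    All profiles must share the fold structure (trained with the same
    resampling seed); folds missing a TPR in either member of a pair are
    dropped listwise.
    """
    lengths = {len(p.tpr) for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"profiles have mismatched fold counts: {sorted(lengths)}")
    pairs = list(itertools.combinations(range(len(profiles)), 2))
    n_pairs = len(pairs)
    rows = []
    for i, j in pairs:
        a, b = profiles[i], profiles[j]
        mask = ~(np.isnan(a.tpr) | np.isnan(b.tpr))
        da, db = a.tpr[mask], b.tpr[mask]
        diff = da - db
        mean_diff = float(diff.mean()) if diff.size else math.nan
        if diff.size < 2 or np.allclose(diff, diff[0]):
            # identical profiles (or a single usable fold): no evidence
            t_stat = 0.0 if diff.size and np.allclose(diff, 0.0) else math.nan
            p_raw = 1.0
        else:
            t_stat, p_raw = stats.ttest_rel(da, db)
        rows.append(
            {
                "model_a": a.model, "model_b": b.model,
                "mean_tpr_diff": mean_diff, "t_stat": float(t_stat),
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, p_raw * n_pairs)),
                "n_folds_used": int(diff.size),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# end-to-end benchmark run and sensitivity sweep


@dataclass
class BenchmarkResult:
    model: str
    regime: str
    report: ConfusionReport
    train_report: ConfusionReport
    profile: ResamplingProfile
    plan: SplitPlan
    fitted: object = None
    preprocessor: object = None
    subset_reports: dict | None = None  # per-herd test-set breakdown


def run_benchmark(
    obs: pd.DataFrame,
    pens: pd.DataFrame,
    window_cfg: WindowConfig,
    model_names: list[str],
    tune_cfg: TuneConfig,
    regime: str = "CV",
    split_seed: int = 0,
    test_fraction: float = 0.25,
    windows: pd.DataFrame | None = None,
    space_overrides: dict | None = None,
) -> dict[str, BenchmarkResult]:
    """Windows -> split -> preprocess -> tune -> test-set report.

    Preprocessing (imputation, scaling, PCA) is fitted on the training
    windows only unless ``window_cfg.preprocessing_fit == 'global'``.
    """
    if windows is None:
        windows = build_windows(obs, pens, window_cfg)
    if regime == "CV":
        plan = split_cv(windows, test_fraction, seed=split_seed)
    elif regime == "LOOP":
        plan = split_loop(windows, pens, test_fraction, seed=split_seed)
        _assert_pen_disjoint(windows, plan)
    else:
        raise ConfigurationError(f"unknown regime {regime!r}")

    train = windows.iloc[plan.train_idx]
    test = windows.iloc[plan.test_idx]
    prep = make_preprocessor(window_cfg)
    fit_on = windows if window_cfg.preprocessing_fit == "global" else train
    prep.fit(fit_on)
    X_train = prep.transform(train)
    X_test = prep.transform(test)
    y_train = train["label"].to_numpy()
    y_test = test["label"].to_numpy()

    results: dict[str, BenchmarkResult] = {}
    for name in model_names:
        spec = bench.get_model_spec(name, (space_overrides or {}).get(name))
        fitted, profile = bench.tune_and_fit(spec, X_train, y_train, tune_cfg)
        pred_test = bench.predict_labels(fitted, X_test)
        pred_train = bench.predict_labels(fitted, X_train)
        herds = test["herd_id"].to_numpy()
        subset_reports = {}
        if len(np.unique(herds)) > 1:
            for herd in np.unique(herds):
                m = herds == herd
                subset_reports[str(herd)] = confusion_report(pred_test[m], y_test[m])
        results[name] = BenchmarkResult(
            model=name,
            regime=regime,
            report=confusion_report(pred_test, y_test),
            train_report=confusion_report(pred_train, y_train),
            profile=profile,
            plan=plan,
            fitted=fitted,
            preprocessor=prep,
            subset_reports=subset_reports,
        )
    return results


def results_table(results: dict[str, dict[str, BenchmarkResult]]) -> pd.DataFrame:
    """Tidy test metrics: one row per model x regime ('all'), plus one per
    herd subset of the test windows in merged-herd runs."""
    rows = []
    for regime, by_model in results.items():
        for name, res in by_model.items():
            row = {"model": name, "regime": regime, "herd_subset": "all"}
            row.update(res.report.to_dict())
            rows.append(row)
            for herd, rep in (res.subset_reports or {}).items():
                row = {"model": name, "regime": regime, "herd_subset": herd}
                row.update(rep.to_dict())
                rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_sweep(
    obs: pd.DataFrame,
    pens: pd.DataFrame,
    base_cfg: WindowConfig,
    tune_cfg: TuneConfig,
    window_days_grid: tuple[int, ...] = (7, 14, 21),
    tb_window_grid: tuple[tuple[int, int], ...] = ((-35, 10), (-49, 10), (-10, 5)),
    model: str = "rf",
    seeds: tuple[int, ...] = (0,),
    regimes: tuple[str, ...] = ("CV", "LOOP"),
    space_overrides: dict | None = None,
) -> pd.DataFrame:
    """Re-run the full pipeline over a grid of framing choices.

    One row per (window size, TB window, regime, seed) with the test-set
    metrics of ``model``.  The default grid cell with the base seeds
    reproduces a base run exactly.
    """
    from dataclasses import replace

    rows = []
    for w_days in window_days_grid:
        for tb_win in tb_window_grid:
            cfg = replace(base_cfg, window_days=w_days, tb_window=tuple(tb_win))
            max_span = max(
                (pd.Timestamp(p.rec_end) - pd.Timestamp(p.rec_start)).days + 1
                for p in pens.itertuples(index=False)
            )
            if w_days > max_span:
                warnings.warn(f"window of {w_days} d exceeds every recording; cell skipped")
                continue
            windows = build_windows(obs, pens, cfg)
            for regime in regimes:
                for seed in seeds:
                    res = run_benchmark(
                        obs, pens, cfg, [model], tune_cfg, regime=regime,
                        split_seed=seed, windows=windows,
                        space_overrides=space_overrides,
                    )[model]
                    row = {
                        "window_days": w_days,
                        "tb_window_lo": tb_win[0],
                        "tb_window_hi": tb_win[1],
                        "regime": regime,
                        "seed": seed,
                        "model": model,
                    }
                    row.update(res.report.to_dict())
                    rows.append(row)
    return pd.DataFrame(rows)
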