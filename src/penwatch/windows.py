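"""Sliding analysis windows and their preprocessing.

An *analysis window* is a fixed-size block of consecutive per-pig daily
observations for one pen: ``|variables| x pigs_per_window x window_days``
cells flattened variable-major (variable, then pig slot, then day
offset) — 3 x 10 x 14 = 420 cells at defaults.  The window's ``a_date``
is its first day and decides its class: windows of control pens are
always CTL; windows of a TB pen are TB exactly when ``a_date`` lies in
the TB window around the pen's TB date (inclusive bounds, default
[-35, +10] days).

Preprocessing follows standard leak-free practice: per-herd median
imputation, per-herd centering/scaling, then PCA, each fitted on a
designated subset (the training windows) and applied unchanged
elsewhere.  The transformers are sklearn-compatible and compose with
:class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.pipeline import Pipeline

from .errors import ConfigurationError, ImputationError, StructuralError

META_COLUMNS = ["pen_id", "herd_id", "a_date", "label"]


@dataclass(frozen=True)
class WindowConfig:
    """Window framing and preprocessing parameters."""

    window_days: int = 14
    tb_window: tuple[int, int] = (-35, 10)
    pigs_per_window: int = 10
    variables: tuple[str, ...] = ("dfv", "dfc", "stdfc")
    stride_days: int = 1
    pca_variance_retained: float = 0.95
    preprocessing_fit: str = "train_only"

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ConfigurationError("window_days must be >= 1")
        if self.tb_window[0] > self.tb_window[1]:
            raise ConfigurationError("tb_window lower bound must be <= upper bound")
        if self.pigs_per_window < 1:
            raise ConfigurationError("pigs_per_window must be >= 1")
        if self.stride_days < 1:
            raise ConfigurationError("stride_days must be >= 1")
        if not (0.0 < self.pca_variance_retained <= 1.0):
            raise ConfigurationError("pca_variance_retained must be in (0, 1]")
        if self.preprocessing_fit not in ("train_only", "global"):
            raise ConfigurationError("preprocessing_fit must be 'train_only' or 'global'")

    @property
    def n_features(self) -> int:
        return len(self.variables) * self.pigs_per_window * self.window_days


def feature_names(cfg: WindowConfig) -> list[str]:
    """``f_0001..f_NNNN`` in the documented cell order."""
    n = cfg.n_features
    width = max(4, len(str(n)))
    return [f"f_{i + 1:0{width}d}" for i in range(n)]


def feature_variables(cfg: WindowConfig) -> list[str]:
    """Variable owning each feature column (variable-major layout)."""
    per_var = cfg.pigs_per_window * cfg.window_days
    out: list[str] = []
    for var in cfg.variables:
        out.extend([var] * per_var)
    return out


def expected_window_count(recorded_days: int, window_days: int, stride_days: int = 1) -> int:
    """Number of windows a pen contributes: max(0, floor((D-w)/s) + 1)."""
    if recorded_days < window_days:
        return 0
    return (recorded_days - window_days) // stride_days + 1


# --------------------------------------------------------------------------
# window construction


def select_pigs(pen_obs: pd.DataFrame, k: int) -> list[str | None]:
    """Deterministic choice of the ``k`` pig slots for one pen.

    Pigs are ranked by their number of non-missing observation days
    (descending), ties broken by pig id; pens with fewer than ``k`` pigs
    are padded with ``None`` placeholder slots whose cells stay missing.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if pen_obs.empty or pen_obs["pig_id"].nunique() == 0:
        raise StructuralError("pen has no pigs")
    counts = (
        pen_obs.assign(_obs=pen_obs["dfv"].notna())
        .groupby("pig_id")["_obs"]
        .sum()
        .reset_index()
        .sort_values(["_obs", "pig_id"], ascending=[False, True])
    )
    chosen = counts["pig_id"].head(k).tolist()
    chosen.sort()  # stable slot order by id among the selected pigs
    return chosen + [None] * (k - len(chosen))


def assign_label(pen, a_date: pd.Timestamp, cfg: WindowConfig) -> str:
    """Class of the window starting at ``a_date`` for this pen."""
    status = pen["status"] if isinstance(pen, (dict, pd.Series)) else pen.status
    tb_date = pen["tb_date"] if isinstance(pen, (dict, pd.Series)) else pen.tb_date
    if status == "CTL":
        return "CTL"
    if status == "TB":
        if pd.isna(tb_date):
            raise StructuralError("TB pen has no TB date")
        rel = (pd.Timestamp(a_date) - pd.Timestamp(tb_date)).days
        lo, hi = cfg.tb_window
        return "TB" if lo <= rel <= hi else "CTL"
    raise StructuralError(f"unknown pen status {status!r}")


def build_windows(
    obs: pd.DataFrame, pens: pd.DataFrame, cfg: WindowConfig | None = None
) -> pd.DataFrame:
    """Slide a window over each pen's recording and flatten the cells.

    Returns one row per window: ``pen_id, herd_id, a_date, label`` plus
    the feature columns.  Cells of placeholder pig slots and of missing
    observations are NaN (imputed later).  Pens recorded for fewer days
    than the window contribute nothing (with a warning).
    """
    if cfg is None:
        cfg = WindowConfig()
    cols = feature_names(cfg)
    V, K, W = len(cfg.variables), cfg.pigs_per_window, cfg.window_days
    frames: list[pd.DataFrame] = []

    for pen in pens.itertuples(index=False):
        rec_start = pd.Timestamp(pen.rec_start)
        rec_end = pd.Timestamp(pen.rec_end)
        n_days = (rec_end - rec_start).days + 1
        if n_days < W:
            warnings.warn(
                f"pen {pen.pen_id}: recording ({n_days} d) shorter than window "
                f"({W} d); contributes no windows"
            )
            continue
        pen_obs = obs[obs["pen_id"] == pen.pen_id]
        if pen_obs.empty:
            warnings.warn(f"pen {pen.pen_id}: no observations; skipped")
            continue
        slots = select_pigs(pen_obs, K)
        dates = pd.date_range(rec_start, rec_end, freq="D")

        cube = np.full((V, K, n_days), np.nan)
        for s, pig in enumerate(slots):
            if pig is None:
                continue
            sub = pen_obs[pen_obs["pig_id"] == pig].set_index("date").reindex(dates)
            for v, var in enumerate(cfg.variables):
                cube[v, s, :] = sub[var].to_numpy(dtype=float)

        starts = list(range(0, n_days - W + 1, cfg.stride_days))
        feats = np.empty((len(starts), V * K * W))
        a_dates = []
        labels = []
        for j, i in enumerate(starts):
            feats[j] = cube[:, :, i : i + W].reshape(-1)
            a_date = rec_start + pd.Timedelta(days=i)
            a_dates.append(a_date)
            labels.append(assign_label(pen, a_date, cfg))
        frame = pd.DataFrame(feats, columns=cols)
        frame.insert(0, "label", labels)
        frame.insert(0, "a_date", a_dates)
        frame.insert(0, "herd_id", pen.herd_id)
        frame.insert(0, "pen_id", pen.pen_id)
        frames.append(frame)

    if not frames:
        return pd.DataFrame(columns=META_COLUMNS + cols)
    return pd.concat(frames, ignore_index=True)


def feature_matrix(windows: pd.DataFrame) -> pd.DataFrame:
    """The feature block of a window table (columns ``f_*``)."""
    return windows[[c for c in windows.columns if c.startswith("f_")]]


# --------------------------------------------------------------------------
# preprocessing transformers


class StratifiedMedianImputer(TransformerMixin, BaseEstimator):
    """Median imputation per herd x variable stratum.

    Fitted medians are reused unchanged on unseen windows, so fitting on
    the training portion leaks nothing from the test portion.
    """

    def __init__(self, feature_vars: list[str] | None = None):
        self.feature_vars = feature_vars

    def fit(self, X: pd.DataFrame, y=None):
        fvars = self._resolve_vars(X)
        cols = [c for c in X.columns if c.startswith("f_")]
        self.medians_ = {}
        for herd in sorted(X["herd_id"].unique()):
            block = X.loc[X["herd_id"] == herd, cols].to_numpy(dtype=float)
            for var in dict.fromkeys(fvars):
                sel = [i for i, v in enumerate(fvars) if v == var]
                vals = block[:, sel].ravel()
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    raise ImputationError(
                        f"herd {herd!r}, variable {var!r}: no observed values to impute from"
                    )
                self.medians_[(herd, var)] = float(np.median(vals))
        self.columns_ = cols
        self.feature_vars_ = fvars
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        arr = out[self.columns_].to_numpy(dtype=float)
        for herd in out["herd_id"].unique():
            rows = (out["herd_id"] == herd).to_numpy()
            for j, var in enumerate(self.feature_vars_):
                key = (herd, var)
                if key not in self.medians_:
                    raise ImputationError(f"herd {herd!r} was not seen during fit")
                col = arr[rows, j]
                col[np.isnan(col)] = self.medians_[key]
                arr[rows, j] = col
        out[self.columns_] = arr
        return out

    def _resolve_vars(self, X: pd.DataFrame) -> list[str]:
        if self.feature_vars is not None:
            return list(self.feature_vars)
        # fall back: treat every column as one stratum variable
        return ["all"] * sum(c.startswith("f_") for c in X.columns)


class StratifiedScaler(TransformerMixin, BaseEstimator):
    """Center and scale each cell by its herd x variable stratum moments."""

    def __init__(self, feature_vars: list[str] | None = None):
        self.feature_vars = feature_vars

    def fit(self, X: pd.DataFrame, y=None):
        fvars = (
            list(self.feature_vars)
            if self.feature_vars is not None
            else ["all"] * sum(c.startswith("f_") for c in X.columns)
        )
        cols = [c for c in X.columns if c.startswith("f_")]
        self.center_, self.scale_ = {}, {}
        for herd in sorted(X["herd_id"].unique()):
            block = X.loc[X["herd_id"] == herd, cols].to_numpy(dtype=float)
            for var in dict.fromkeys(fvars):
                sel = [i for i, v in enumerate(fvars) if v == var]
                vals = block[:, sel].ravel()
                vals = vals[~np.isnan(vals)]
                mean = float(vals.mean()) if vals.size else 0.0
                sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                if sd == 0.0:
                    warnings.warn(
                        f"herd {herd!r}, variable {var!r}: zero variance; scale set to 1"
                    )
                    sd = 1.0
                self.center_[(herd, var)] = mean
                self.scale_[(herd, var)] = sd
        self.columns_ = cols
        self.feature_vars_ = fvars
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        arr = out[self.columns_].to_numpy(dtype=float)
        for herd in out["herd_id"].unique():
            rows = (out["herd_id"] == herd).to_numpy()
            for j, var in enumerate(self.feature_vars_):
                key = (herd, var)
                if key not in self.center_:
                    raise ImputationError(f"herd {herd!r} was not seen during fit")
                arr[rows, j] = (arr[rows, j] - self.center_[key]) / self.scale_[key]
        out[self.columns_] = arr
        return out


class WindowPCA(TransformerMixin, BaseEstimator):
    """PCA on the feature block, keeping the smallest leading component
    set reaching the requested cumulative explained variance.

    ``variance_retained=1`` keeps a full-rank rotation (invertible up to
    numerical precision)."""

    def __init__(self, variance_retained: float = 0.95):
        self.variance_retained = variance_retained

    def fit(self, X, y=None):
        arr = self._as_array(X)
        if arr.shape[0] < 2:
            raise ConfigurationError("PCA needs more than one window to fit")
        if np.allclose(arr.var(axis=0), 0.0):
            raise ConfigurationError("degenerate (zero-variance) input for PCA")
        n_components = None if self.variance_retained >= 1.0 else self.variance_retained
        self.pca_ = PCA(n_components=n_components, svd_solver="full")
        self.pca_.fit(arr)
        self.n_components_ = self.pca_.n_components_
        return self

    def transform(self, X) -> np.ndarray:
        return self.pca_.transform(self._as_array(X))

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self.pca_.inverse_transform(scores)

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = [c for c in X.columns if c.startswith("f_")]
            return X[cols].to_numpy(dtype=float) if cols else X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


def make_preprocessor(cfg: WindowConfig) -> Pipeline:
    """Impute -> scale -> PCA as one sklearn pipeline for this config."""
    fvars = feature_variables(cfg)
    return Pipeline(
        [
            ("impute", StratifiedMedianImputer(feature_vars=fvars)),
            ("scale", StratifiedScaler(feature_vars=fvars)),
            ("pca", WindowPCA(variance_retained=cfg.pca_variance_retained)),
        ]
    )


# thin wrappers over the transformers, for script use ----------------------


def impute_median(windows: pd.DataFrame, cfg: WindowConfig, fit_on: pd.DataFrame | None = None):
    imp = StratifiedMedianImputer(feature_vars=feature_variables(cfg))
    imp.fit(windows if fit_on is None else fit_on)
    return imp.transform(windows), imp


def standardize(windows: pd.DataFrame, cfg: WindowConfig, fit_on: pd.DataFrame | None = None):
    sc = StratifiedScaler(feature_vars=feature_variables(cfg))
    sc.fit(windows if fit_on is None else fit_on)
    return sc.transform(windows), sc


def pca_reduce(
    windows: pd.DataFrame,
    variance_retained: float = 0.95,
    fit_on: pd.DataFrame | None = None,
):
    pca = WindowPCA(variance_retained=variance_retained)
    pca.fit(windows if fit_on is None else fit_on)
    return pca.transform(windows), pca


# --------------------------------------------------------------------------
# CSV round-trip


def write_windows_csv(windows: pd.DataFrame, path: str) -> None:
    out = windows.copy()
    out["a_date"] = pd.to_datetime(out["a_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.17g")


def read_windows_csv(path: str) -> pd.DataFrame:
    win = pd.read_csv(path, dtype={"pen_id": str, "herd_id": str, "label": str},
                      parse_dates=["a_date"])
    return win
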