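"""Classifier benchmark: seven model families, TPR-optimized tuning.

The benchmark trains the model families commonly used for this kind of
tabular early-warning problem — elastic-net logistic regression
(``glmnet``), random forest (``rf``), RBF-kernel SVM (``svmRadial``),
weak-prior (heavily regularized) Bayesian-style logistic regression
(``bayesglm``), a single-hidden-layer neural network (``nn``),
k-nearest neighbours (``knn``) and PLS discriminant analysis (``pls``).
Hyperparameters are tuned by uniform random search, capped at a small
budget (default 10 points), scored by the mean fold-wise true positive
rate (TPR, positive class "TB") under k-fold resampling of the training
windows (default k=200).  The selected point is refit on the full
training set; the fold-wise TPR vector of the winning point (its
*resampling profile*) is kept for model-to-model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError

POSITIVE = "TB"
NEGATIVE = "CTL"

#: forest size is held fixed (not tuned); mtry-like fraction is tuned.
RF_N_TREES = 300


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS discriminant analysis: PLS regression on a 0/1 class coding,
    thresholded at 0.5."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("PLSDAClassifier requires exactly two classes")
        pos = POSITIVE if POSITIVE in self.classes_ else self.classes_[1]
        self.positive_ = pos
        target = (y == pos).astype(float)
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pls_ = PLSRegression(n_components=max(1, k))
        self.pls_.fit(X, target)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pls_")
        score = self.pls_.predict(np.asarray(X, dtype=float)).ravel()
        neg = [c for c in self.classes_ if c != self.positive_][0]
        return np.where(score >= 0.5, self.positive_, neg)


@dataclass(frozen=True)
class ModelSpec:
    """One benchmark entry: name, estimator factory, search space.

    Space entries are ``("loguniform", lo, hi)``, ``("uniform", lo, hi)``,
    ``("int", lo, hi)`` (inclusive), ``("odd_int", lo, hi)`` or
    ``("choice", [...])``.
    """

    name: str
    factory: callable
    space: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> dict:
        params = {}
        for key, spec in self.space.items():
            kind = spec[0]
            if kind == "loguniform":
                params[key] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
            elif kind == "uniform":
                params[key] = float(rng.uniform(spec[1], spec[2]))
            elif kind == "int":
                params[key] = int(rng.integers(spec[1], spec[2] + 1))
            elif kind == "odd_int":
                lo, hi = spec[1], spec[2]
                odds = [v for v in range(lo, hi + 1) if v % 2 == 1]
                params[key] = int(rng.choice(odds))
            elif kind == "choice":
                params[key] = spec[1][int(rng.integers(len(spec[1])))]
            else:
                raise ConfigurationError(f"unknown space entry {kind!r}")
        return params

    def space_size(self) -> float:
        """Number of distinct points; inf for continuous spaces."""
        size = 1.0
        for spec in self.space.values():
            if spec[0] in ("loguniform", "uniform"):
                return float("inf")
            if spec[0] == "int":
                size *= spec[2] - spec[1] + 1
            elif spec[0] == "odd_int":
                size *= len([v for v in range(spec[1], spec[2] + 1) if v % 2 == 1])
            elif spec[0] == "choice":
                size *= len(spec[1])
        return size if self.space else 1.0


def _registry() -> dict[str, ModelSpec]:
    return {
        "glmnet": ModelSpec(
            "glmnet",
            lambda p: LogisticRegression(solver="saga", max_iter=5000, **p),
            {"C": ("loguniform", 1e-3, 1e2), "l1_ratio": ("uniform", 0.0, 1.0)},
        ),
        "rf": ModelSpec(
            "rf",
            lambda p: RandomForestClassifier(
                n_estimators=p.pop("n_estimators", RF_N_TREES), random_state=0, **p
            ),
            {"max_features": ("uniform", 0.05, 1.0)},
        ),
        "svmRadial": ModelSpec(
            "svmRadial",
            lambda p: SVC(kernel="rbf", **p),
            {"C": ("loguniform", 1e-2, 1e3), "gamma": ("loguniform", 1e-4, 1.0)},
        ),
        "bayesglm": ModelSpec(
            # weak-prior Bayesian logistic regression approximated by a
            # strongly L2-regularized MAP fit; nothing to tune
            "bayesglm",
            lambda p: LogisticRegression(C=1.0, max_iter=5000),
            {},
        ),
        "nn": ModelSpec(
            "nn",
            lambda p: MLPClassifier(
                hidden_layer_sizes=(p.pop("units"),),
                max_iter=400,
                random_state=0,
                **p,
            ),
            {"units": ("int", 2, 16), "alpha": ("loguniform", 1e-4, 1.0)},
        ),
        "knn": ModelSpec(
            "knn",
            lambda p: KNeighborsClassifier(n_neighbors=p["n_neighbors"]),
            {"n_neighbors": ("odd_int", 3, 31)},
        ),
        "pls": ModelSpec(
            "pls",
            lambda p: PLSDAClassifier(n_components=p["n_components"]),
            {"n_components": ("int", 1, 10)},
        ),
    }


MODEL_NAMES = ("glmnet", "rf", "svmRadial", "bayesglm", "nn", "knn", "pls")


def get_model_spec(name: str, space_overrides: dict | None = None) -> ModelSpec:
    reg = _registry()
    if name not in reg:
        raise ConfigurationError(f"unknown model {name!r}; choose from {sorted(reg)}")
    spec = reg[name]
    if space_overrides:
        space = dict(spec.space)
        fixed = {}
        for key, val in space_overrides.items():
            if isinstance(val, tuple):
                space[key] = val
            else:
                fixed[key] = val
                space.pop(key, None)
        if fixed:
            base_factory = spec.factory
            spec = ModelSpec(spec.name, lambda p, _f=base_factory, _x=fixed: _f({**_x, **p}), space)
        else:
            spec = ModelSpec(spec.name, spec.factory, space)
    return spec


@dataclass(frozen=True)
class TuneConfig:
    """Resampling and random-search settings."""

    resampling_folds: int = 200
    search: str = "random"
    budget: int = 10
    metric: str = "TPR"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resampling_folds < 2:
            raise ConfigurationError("resampling_folds must be >= 2")
        if self.budget < 1:
            raise ConfigurationError("budget must be >= 1")
        if self.search != "random":
            raise ConfigurationError("only random search is supported")
        if self.metric != "TPR":
            raise ConfigurationError("only TPR optimization is supported")


@dataclass
class ResamplingProfile:
    """Fold-wise TPR of the selected hyperparameter point."""

    model: str
    tpr: np.ndarray
    params: dict

    def mean_tpr(self) -> float:
        return float(np.nanmean(self.tpr)) if np.any(~np.isnan(self.tpr)) else float("nan")


def _fold_tpr(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == POSITIVE
    if not pos.any():
        return np.nan
    return float(np.mean(y_pred[pos] == POSITIVE))


def tune_and_fit(
    model: str | ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TuneConfig | None = None,
):
    """Random-search tune on k-fold TPR, then refit on the full set.

    Returns ``(fitted_estimator, ResamplingProfile)``.  Folds without a
    positive example contribute a missing TPR and are excluded from the
    candidate's mean.  Everything is a pure function of (data, config,
    seed).
    """
    if cfg is None:
        cfg = TuneConfig()
    spec = get_model_spec(model) if isinstance(model, str) else model
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class; cannot tune")

    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    k = cfg.resampling_folds
    if k > n:
        warnings.warn(f"resampling_folds={k} clamped to training size {n}")
        k = n
    fold_seed = int(np.random.default_rng(cfg.seed + 17).integers(2**31 - 1))
    splitter = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
    folds = list(splitter.split(X))

    # sample candidate points; finite spaces are deduplicated
    candidates: list[dict] = []
    seen: set = set()
    finite = np.isfinite(spec.space_size())
    attempts = 0
    while len(candidates) < cfg.budget and attempts < cfg.budget * 20:
        attempts += 1
        p = spec.sample(rng)
        key = tuple(sorted(p.items()))
        if finite and key in seen:
            continue
        seen.add(key)
        candidates.append(p)
        if not spec.space:
            break
    if finite and len(candidates) < cfg.budget and spec.space:
        warnings.warn(
            f"{spec.name}: search budget {cfg.budget} exceeds the finite space; "
            f"evaluating {len(candidates)} distinct points"
        )

    best_score, best_params, best_profile = -np.inf, None, None
    for params in candidates:
        tprs = np.full(len(folds), np.nan)
        for i, (tr, va) in enumerate(folds):
            if len(np.unique(y[tr])) < 2:
                continue
            est = spec.factory(dict(params))
            est.fit(X[tr], y[tr])
            tprs[i] = _fold_tpr(y[va], est.predict(X[va]))
        score = np.nanmean(tprs) if np.any(~np.isnan(tprs)) else -np.inf
        if score > best_score:
            best_score, best_params, best_profile = score, params, tprs

    if best_params is None:  # no fold ever saw a positive; keep the first point
        best_params, best_profile = candidates[0], np.full(len(folds), np.nan)
    fitted = spec.factory(dict(best_params))
    fitted.fit(X, y)
    profile = ResamplingProfile(model=spec.name, tpr=best_profile, params=best_params)
    return fitted, profile


def save_fitted(path: str, fitted, preprocessor=None) -> None:
    """Serialize a fitted classifier together with its preprocessing
    pipeline, so prediction on new windows is a standalone step."""
    import joblib

    joblib.dump({"model": fitted, "preprocessor": preprocessor}, path)


def load_fitted(path: str):
    """Counterpart of :func:`save_fitted`; returns (model, preprocessor)."""
    import joblib

    blob = joblib.load(path)
    return blob["model"], blob["preprocessor"]


def predict_labels(fitted, X: np.ndarray) -> np.ndarray:
    """Hard TB/CTL labels for a window feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0, dtype=object)
    expected = getattr(fitted, "n_features_in_", None)
    if expected is not None and X.shape[1] != expected:
        raise ValueError(f"feature-dimension mismatch: expected {expected}, got {X.shape[1]}")
    return np.asarray(fitted.predict(X))
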