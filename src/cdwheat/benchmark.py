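"""Eight-algorithm machine-learning comparison for grain-Cd prediction.

Reproduces the comparison protocol around standard scikit-learn /
xgboost implementations: repeated seeded 4:1 train/test splits; inside
each training set a 9:1 pre-train/validation split and 10-fold
cross-validation drive hyperparameter choice from a small documented
grid; final metrics come from the untouched test split.  The label is
log10 grain Cd and the default features are soil total Cd (log10), pH,
CEC, clay, SOM, DCB-Fe and ox-Fe — the bioavailable pools are excluded
because of their strong correlation with total Cd.

Hyperparameter grids (deliberately small, fully enumerated here):
trees in {100}; tree depth in {None, 10} for single trees and
bagging-style ensembles; k in {3, 5, 7} for k-nearest neighbours; ridge
penalty in {0.1, 1, 10}; SVR C in {1, 10} with an RBF kernel; boosted
models use 100 trees at library-default depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .dataset import Dataset, SplitSpec, split_dataset
from .equations import CD_POOL_FEATURES
from .regression import FitMetrics

__all__ = [
    "ALGORITHMS",
    "ENSEMBLE_ALGORITHMS",
    "BenchmarkSpec",
    "BenchmarkResult",
    "run_benchmark",
    "rank_feature_importance",
]

#: default feature set: total Cd plus the six soil properties
DEFAULT_FEATURES = ("cd_total", "ph", "cec", "clay", "som", "fe_dcb", "fe_ox")

#: canonical algorithm names (aliases in _ALIASES)
ALGORITHMS = (
    "ridge", "decision_tree", "svr", "knn",
    "random_forest", "extra_trees", "gradient_boosting", "xgboost",
)

ENSEMBLE_ALGORITHMS = (
    "random_forest", "extra_trees", "gradient_boosting", "xgboost",
)

_ALIASES = {
    "rf": "random_forest", "ert": "extra_trees", "et": "extra_trees",
    "gbdt": "gradient_boosting", "gbrt": "gradient_boosting",
    "xgb": "xgboost", "dt": "decision_tree",
}


def _canonical(name: str) -> str:
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    key = _ALIASES.get(key, key)
    if key not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {name!r}; choose from {ALGORITHMS}")
    return key


def _estimator_and_grid(name: str, n_trees: int, seed: int):
    depth_grid = [None, 10]
    if name == "ridge":
        return Ridge(), {"alpha": [0.1, 1.0, 10.0]}
    if name == "decision_tree":
        return (DecisionTreeRegressor(random_state=seed),
                {"max_depth": depth_grid})
    if name == "svr":
        return SVR(kernel="rbf"), {"C": [1.0, 10.0]}
    if name == "knn":
        return KNeighborsRegressor(), {"n_neighbors": [3, 5, 7]}
    if name == "random_forest":
        return (RandomForestRegressor(n_estimators=n_trees, random_state=seed),
                {"max_depth": depth_grid})
    if name == "extra_trees":
        return (ExtraTreesRegressor(n_estimators=n_trees, random_state=seed),
                {"max_depth": depth_grid})
    if name == "gradient_boosting":
        return (GradientBoostingRegressor(n_estimators=n_trees,
                                          random_state=seed), {})
    if name == "xgboost":
        return (XGBRegressor(n_estimators=n_trees, random_state=seed,
                             verbosity=0, n_jobs=1), {})
    raise AssertionError(name)


@dataclass(frozen=True)
class BenchmarkSpec:
    """What to benchmark: algorithms, features, splitting protocol."""

    algorithms: tuple[str, ...] = ALGORITHMS
    split: SplitSpec = field(default_factory=SplitSpec)
    features: tuple[str, ...] = DEFAULT_FEATURES
    n_trees: int = 100

    def __post_init__(self):
        if not self.algorithms:
            raise ValueError("algorithms must be non-empty")
        object.__setattr__(
            self, "algorithms",
            tuple(_canonical(a) for a in self.algorithms))
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class BenchmarkResult:
    """Per-repeat metrics, cross-repeat summary and feature importances."""

    per_repeat: pd.DataFrame            # one row per (algorithm, repeat)
    summary: pd.DataFrame               # mean/sd per algorithm
    importances: dict                    # ensemble name -> pd.Series (sums to 1)
    split_ids: list                      # (train_ids, test_ids) per repeat

    def metrics(self, algorithm: str) -> list[FitMetrics]:
        rows = self.per_repeat[self.per_repeat["algorithm"]
                               == _canonical(algorithm)]
        return [FitMetrics(r.r2_train, r.r2_test, r.rmse_test, r.mae_test)
                for r in rows.itertuples()]


def _design(data: Dataset, features: Sequence[str]):
    df = data.df
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise ValueError(f"dataset lacks feature(s): {missing}")
    cols = df[list(features) + ["cd_wheat"]].dropna()
    X = np.empty((len(cols), len(features)))
    for j, f in enumerate(features):
        x = cols[f].to_numpy(dtype=float)
        X[:, j] = np.log10(x) if f in CD_POOL_FEATURES else x
    y = np.log10(cols["cd_wheat"].to_numpy(dtype=float))
    return X, y


def run_benchmark(data: Dataset, spec: Optional[BenchmarkSpec] = None
                  ) -> BenchmarkResult:
    """Run the repeated-split benchmark; fixed seed gives fixed results."""
    spec = spec or BenchmarkSpec()
    if len(data) < 30:
        raise ValueError(f"need >= 30 records to benchmark, got {len(data)}")
    if len(data) < spec.split.cv_folds:
        raise ValueError("dataset smaller than the fold count")

    splits = split_dataset(data, spec.split)
    rows = []
    imp_acc: dict[str, list[np.ndarray]] = {a: [] for a in spec.algorithms
                                            if a in ENSEMBLE_ALGORITHMS}
    split_ids = []
    for rep, (train, test) in enumerate(splits):
        split_ids.append((train.record_ids, test.record_ids))
        X_tr, y_tr = _design(train, spec.features)
        X_te, y_te = _design(test, spec.features)
        rep_seed = (int(spec.split.seed) * 1009 + rep) & 0x7FFFFFFF
        for alg in spec.algorithms:
            est, grid = _estimator_and_grid(alg, spec.n_trees, rep_seed)
            cv = KFold(n_splits=spec.split.cv_folds, shuffle=True,
                       random_state=rep_seed)
            if grid:
                search = GridSearchCV(est, grid, cv=cv, scoring="r2",
                                      n_jobs=1)
                search.fit(X_tr, y_tr)
                best = search.best_estimator_
                best_params = search.best_params_
            else:
                best = est.fit(X_tr, y_tr)
                best_params = {}
            # 9:1 pre-train/validation check inside the training set
            X_pre, X_val, y_pre, y_val = train_test_split(
                X_tr, y_tr, test_size=1 - spec.split.pretrain_fraction,
                random_state=rep_seed)
            val_est, _ = _estimator_and_grid(alg, spec.n_trees, rep_seed)
            val_est.set_params(**best_params)
            val_est.fit(X_pre, y_pre)
            r2_val = float(val_est.score(X_val, y_val))

            best.fit(X_tr, y_tr)
            resid = y_te - best.predict(X_te)
            rows.append({
                "algorithm": alg, "repeat": rep,
                "r2_train": float(best.score(X_tr, y_tr)),
                "r2_validation": r2_val,
                "r2_test": float(best.score(X_te, y_te)),
                "rmse_test": float(np.sqrt(np.mean(resid ** 2))),
                "mae_test": float(np.mean(np.abs(resid))),
                "best_params": repr(best_params),
            })
            if alg in imp_acc:
                shares = np.asarray(best.feature_importances_, dtype=float)
                total = shares.sum()
                if total > 0:
                    imp_acc[alg].append(shares / total)

    per_repeat = pd.DataFrame(rows)
    summary = (per_repeat
               .groupby("algorithm")[["r2_train", "r2_validation", "r2_test",
                                      "rmse_test", "mae_test"]]
               .agg(["mean", "std"]))
    importances = {}
    for alg, stacks in imp_acc.items():
        if stacks:
            mean_shares = np.mean(stacks, axis=0)
            mean_shares = mean_shares / mean_shares.sum()
            importances[alg] = pd.Series(
                mean_shares, index=list(spec.features)
            ).sort_values(ascending=False)
    return BenchmarkResult(per_repeat=per_repeat, summary=summary,
                           importances=importances, split_ids=split_ids)


def rank_feature_importance(fitted_estimator,
                            feature_names: Sequence[str]
                            ) -> list[tuple[str, float]]:
    """Impurity-based importance shares of a fitted tree ensemble,
    descending and normalized to sum to 1."""
    shares = getattr(fitted_estimator, "feature_importances_", None)
    if shares is None:
        raise TypeError(
            f"{type(fitted_estimator).__name__} exposes no impurity-based "
            "feature importances (not a tree ensemble?)")
    shares = np.asarray(shares, dtype=float)
    if len(shares) != len(feature_names):
        raise ValueError("feature_names must align with the fitted design")
    shares = shares / shares.sum()
    order = np.argsort(shares)[::-1]
    return [(feature_names[i], float(shares[i])) for i in order]
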