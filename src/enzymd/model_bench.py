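"""Model benchmarking: metrics, default-parameter screening with exclusion
rules, random hyperparameter search, and the 500-iteration bootstrap
comparison across feature-block datasets with ANOVA + Tukey HSD.

The module owns the protocol, not the learners: estimators come from
scikit-learn and LightGBM, with the gradient-boosted decision-tree ensemble
as the headline regressor.  Metrics follow the standard definitions
RMSE = sqrt(mean((yhat - y)^2)), R^2 = 1 - SSres/SStot, MAE = mean|yhat - y|.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_assembly import FeatureTable, minmax_scale

__all__ = [
    "RegressionMetrics",
    "BenchResult",
    "regression_metrics",
    "response_distribution_check",
    "default_roster",
    "screen_models",
    "make_boosted_tree",
    "default_search_space",
    "tune_random_search",
    "prepare_xy",
    "bootstrap_compare",
    "anova_tukey",
]


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    mae: float
    fit_seconds: float = 0.0


@dataclass
class BenchResult:
    model_name: str
    metrics: RegressionMetrics
    excluded: bool = False
    exclusion_reason: str = "none"  # negative_r2 | distribution_mismatch |
    #                                 fit_failure | none

    def __post_init__(self) -> None:
        assert self.excluded == (self.exclusion_reason != "none")


def regression_metrics(y_true, y_pred, fit_seconds: float = 0.0) -> RegressionMetrics:
    """RMSE, R^2 and MAE of predictions.  Zero-variance y_true makes R^2
    undefined (returned as NaN)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0:
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return RegressionMetrics(r2, rmse, mae, fit_seconds)


def response_distribution_check(y) -> dict:
    """Shape diagnostics of the response: Fisher-Pearson skewness, excess
    kurtosis, normal Q-Q points, and domain feasibility flags for Poisson
    (non-negative) and Gamma (strictly positive) regression."""
    y = np.asarray(y, dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 observations")
    m = y - y.mean()
    m2 = np.mean(m**2)
    g1 = float(np.mean(m**3) / m2**1.5)
    g2 = float(np.mean(m**4) / m2**2 - 3.0)
    order = np.sort((y - y.mean()) / y.std(ddof=0))
    theo = stats.norm.ppf((np.arange(y.size) + 0.5) / y.size)
    return {
        "skewness": g1,
        "kurtosis": g2,
        "qq_points": np.column_stack((theo, order)),
        "poisson_ok": bool((y >= 0).all()),
        "poisson_integer": bool(np.allclose(y, np.round(y))),
        "gamma_ok": bool((y > 0).all()),
    }


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def default_roster() -> dict[str, dict]:
    """Default-parameter screening roster covering the standard regression
    families.  Each entry: factory plus the response-domain requirement
    ('none', 'nonneg' or 'positive')."""
    from lightgbm import LGBMRegressor
    from sklearn.dummy import DummyRegressor
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.kernel_ridge import KernelRidge
    from sklearn.linear_model import (GammaRegressor, Lasso, LinearRegression,
                                      PoissonRegressor, Ridge)
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeRegressor

    return {
        "Dummy (mean)": {"factory": DummyRegressor, "requires": "none"},
        "LinearRegression": {"factory": LinearRegression, "requires": "none"},
        "Ridge": {"factory": Ridge, "requires": "none"},
        "Lasso": {"factory": Lasso, "requires": "none"},
        "KernelRidge": {"factory": KernelRidge, "requires": "none"},
        "SVR": {"factory": SVR, "requires": "none"},
        "KNeighbors": {"factory": KNeighborsRegressor, "requires": "none"},
        "DecisionTree": {
            "factory": lambda: DecisionTreeRegressor(random_state=0),
            "requires": "none",
        },
        "RandomForest": {
            "factory": lambda: RandomForestRegressor(random_state=0, n_jobs=1),
            "requires": "none",
        },
        "GradientBoosting": {
            "factory": lambda: GradientBoostingRegressor(random_state=0),
            "requires": "none",
        },
        "LightGBM": {
            "factory": lambda: make_boosted_tree(),
            "requires": "none",
        },
        "MLP": {
            "factory": lambda: MLPRegressor(random_state=0, max_iter=500),
            "requires": "none",
        },
        "PoissonRegressor": {"factory": PoissonRegressor, "requires": "nonneg"},
        "GammaRegressor": {"factory": GammaRegressor, "requires": "positive"},
    }


def screen_models(
    X_train, y_train, X_test, y_test, roster: dict[str, dict] | None = None
) -> list[BenchResult]:
    """Fit every roster model with default parameters, score on the test
    set, exclude models with negative test R^2 or a response-distribution
    mismatch, and rank survivors by R^2 (desc), RMSE (asc), time (asc).
    A model that raises during fitting is recorded, never fatal."""
    roster = default_roster() if roster is None else roster
    if not roster:
        raise ValueError("empty model roster")
    check = response_distribution_check(np.concatenate([y_train, y_test]))
    results: list[BenchResult] = []
    for name, entry in roster.items():
        req = entry.get("requires", "none")
        if (req == "nonneg" and not check["poisson_ok"]) or (
            req == "positive" and not check["gamma_ok"]
        ):
            results.append(BenchResult(
                name, RegressionMetrics(np.nan, np.nan, np.nan), True,
                "distribution_mismatch",
            ))
            continue
        try:
            model = entry["factory"]()
            t0 = time.perf_counter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_train, y_train)
            elapsed = time.perf_counter() - t0
            metrics = regression_metrics(y_test, model.predict(X_test), elapsed)
        except Exception:
            results.append(BenchResult(
                name, RegressionMetrics(np.nan, np.nan, np.nan), True,
                "fit_failure",
            ))
            continue
        if metrics.r2 < 0:
            results.append(BenchResult(name, metrics, True, "negative_r2"))
        else:
            results.append(BenchResult(name, metrics))
    survivors = [r for r in results if not r.excluded]
    excluded = [r for r in results if r.excluded]
    survivors.sort(key=lambda r: (-r.metrics.r2, r.metrics.rmse,
                                  r.metrics.fit_seconds))
    return survivors + excluded


# ---------------------------------------------------------------------------
# Headline model + tuning
# ---------------------------------------------------------------------------

def make_boosted_tree(seed: int = 0, **params):
    """The headline gradient-boosted decision-tree regressor."""
    from lightgbm import LGBMRegressor

    defaults = dict(random_state=seed, n_jobs=1, verbose=-1)
    defaults.update(params)
    return LGBMRegressor(**defaults)


def default_search_space() -> dict[str, list]:
    return {
        "n_estimators": [100, 200, 300, 500],
        "num_leaves": [7, 15, 31],
        "learning_rate": [0.03, 0.05, 0.1, 0.2],
        "min_child_samples": [5, 10, 20],
        "subsample": [0.7, 0.9, 1.0],
        "colsample_bytree": [0.6, 0.8, 1.0],
    }


def tune_random_search(
    X_train,
    y_train,
    search_space: dict[str, list] | None = None,
    n_iter: int = 20,
    folds: int = 5,
    seed: int = 0,
    model_factory=make_boosted_tree,
) -> dict:
    """Random hyperparameter search with k-fold CV scored by negative MAE.
    Deterministic under ``seed``; returns the best parameters and score."""
    from sklearn.model_selection import RandomizedSearchCV

    space = default_search_space() if search_space is None else search_space
    if not space:
        raise ValueError("empty search space")
    n_comb = int(np.prod([len(v) for v in space.values()]))
    search = RandomizedSearchCV(
        model_factory(seed=seed),
        space,
        n_iter=min(n_iter, n_comb),
        cv=folds,
        scoring="neg_mean_absolute_error",
        random_state=seed,
        n_jobs=1,
        error_score=np.nan,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(np.asarray(X_train), np.asarray(y_train))
    return {
        "best_params": search.best_params_,
        "cv_neg_mae": float(search.best_score_),
    }


def prepare_xy(
    train: FeatureTable, test: FeatureTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Min-max scale with extrema fitted on the training rows only and
    return (X_train, y_train, X_test, y_test) arrays."""
    if train.response is None or test.response is None:
        raise ValueError("feature tables must carry the response")
    combined = pd.concat([train.values, test.values])
    full = FeatureTable(combined, dict(train.blocks))
    scaled, _ = minmax_scale(full, fit_rows=np.arange(len(train.values)))
    X = scaled.values.to_numpy()
    n_train = len(train.values)
    return X[:n_train], train.response, X[n_train:], test.response


# ---------------------------------------------------------------------------
# Bootstrap comparison
# ---------------------------------------------------------------------------

def bootstrap_compare(
    datasets: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    tuned_params: dict[str, dict],
    n_boot: int = 500,
    seed: int = 0,
    model_factory=make_boosted_tree,
) -> dict[str, pd.DataFrame]:
    """Per dataset: ``n_boot`` bootstrap resamples of the training set, a
    fit with the dataset's tuned parameters, and metrics on the fixed test
    set.  Each dataset consumes an independent seed substream."""
    out: dict[str, pd.DataFrame] = {}
    for d_idx, (name, (X_tr, y_tr, X_te, y_te)) in enumerate(datasets.items()):
        rng = np.random.default_rng(np.random.SeedSequence((seed, d_idx)))
        rows = np.zeros((n_boot, 3))
        params = tuned_params.get(name, {})
        n = len(y_tr)
        for b in range(n_boot):
            for attempt in range(3):
                idx = rng.integers(0, n, size=n)
                try:
                    model = model_factory(seed=seed + b, **params)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model.fit(X_tr[idx], y_tr[idx])
                    m = regression_metrics(y_te, model.predict(X_te))
                    break
                except Exception:
                    if attempt == 2:
                        raise
            rows[b] = (m.r2, m.rmse, m.mae)
        out[name] = pd.DataFrame(rows, columns=["r2", "rmse", "mae"])
    return out


def anova_tukey(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict:
    """One-way ANOVA across equally sized groups followed by Tukey HSD
    pairwise comparisons (studentized-range distribution)."""
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    sizes = {a.size for a in arrays}
    if len(sizes) != 1:
        raise ValueError("groups must have equal sizes")
    if np.ptp(np.concatenate(arrays)) == 0:
        anova_p = 1.0
        pairs = [
            {"group_a": names[i], "group_b": names[j], "p_adj": 1.0,
             "significant": False}
            for i in range(len(names)) for j in range(i + 1, len(names))
        ]
        return {"anova_p": anova_p, "tukey": pd.DataFrame(pairs)}
    _, anova_p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            pairs.append({"group_a": names[i], "group_b": names[j],
                          "p_adj": p, "significant": p < alpha})
    return {"anova_p": float(anova_p), "tukey": pd.DataFrame(pairs)}
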