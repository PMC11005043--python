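"""Model interpretation and error-enrichment diagnostics.

Feature attribution comes through three routes: permutation importance
(performance drop under column shuffling), the tree ensemble's internal
gain/split rankings, and Shapley values.  Shapley values for the boosted
tree are obtained from LightGBM's native TreeSHAP (``pred_contrib``); an
exact coalition-enumeration Shapley computation for small feature counts
serves as the independent check.

The error diagnostic labels predictions in the 5%/95% residual tails as
poor and asks, with a hypergeometric test, whether a case flag (by default
">= 5 co-occurring mutations") is over-enriched among them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "permutation_importance",
    "tree_importances",
    "shapley_exact_small",
    "shap_summary",
    "error_threshold_labels",
    "hypergeometric_enrichment",
]


# ---------------------------------------------------------------------------
# Importance rankings
# ---------------------------------------------------------------------------

def permutation_importance(
    model, X, y, metric: str = "r2", n_repeats: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Permutation feature importance: mean +- sd drop in the score when a
    column is shuffled.  ``metric`` is 'r2', 'neg_mae' or 'neg_rmse'."""
    from sklearn.inspection import permutation_importance as _sk_pi

    scoring = {
        "r2": "r2",
        "neg_mae": "neg_mean_absolute_error",
        "neg_rmse": "neg_root_mean_squared_error",
    }.get(metric)
    if scoring is None:
        raise ValueError(f"unknown metric {metric!r}")
    X = pd.DataFrame(X)
    res = _sk_pi(model, X, np.asarray(y), scoring=scoring,
                 n_repeats=n_repeats, random_state=seed, n_jobs=1)
    out = pd.DataFrame(
        {"importance": res.importances_mean, "sd": res.importances_std},
        index=X.columns,
    )
    return out.sort_values("importance", ascending=False)


def tree_importances(model) -> dict[str, pd.Series]:
    """Gain and split-count rankings of a fitted LightGBM ensemble; unused
    features rank last with zeros."""
    try:
        booster = model.booster_
    except AttributeError as exc:
        raise ValueError(
            "tree_importances requires a fitted LightGBM model"
        ) from exc
    names = booster.feature_name()
    gain = pd.Series(booster.feature_importance("gain"), index=names)
    split = pd.Series(booster.feature_importance("split"), index=names)
    return {
        "gain": gain.sort_values(ascending=False),
        "split": split.sort_values(ascending=False),
    }


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

def shapley_exact_small(
    predict, instance: np.ndarray, background: np.ndarray, max_features: int = 12
) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^d coalitions.

    The value of a coalition S is the interventional expectation
    mean_b f(x_S, b_{~S}) over background rows (pass a single row for plain
    reference substitution).  Values satisfy local accuracy: they sum to
    f(x) - mean_b f(b).
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = instance.size
    if d > max_features:
        raise ValueError(
            f"{d} features exceed max_features={max_features}; use the "
            "tree-path (shap_summary) route instead"
        )
    from math import factorial

    n_bg = background.shape[0]
    # v(S) for every coalition, batched into one predict call
    coalitions = []
    for size in range(d + 1):
        coalitions.extend(combinations(range(d), size))
    rows = np.tile(background, (len(coalitions), 1))
    for c_idx, coal in enumerate(coalitions):
        rows[c_idx * n_bg : (c_idx + 1) * n_bg, list(coal)] = instance[list(coal)]
    preds = np.asarray(predict(rows), dtype=float)
    v = preds.reshape(len(coalitions), n_bg).mean(axis=1)
    v_map = {coal: v[i] for i, coal in enumerate(coalitions)}

    phi = np.zeros(d)
    fact = [factorial(k) for k in range(d + 1)]
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for size in range(d):
            w = fact[size] * fact[d - size - 1] / fact[d]
            for coal in combinations(others, size):
                with_j = tuple(sorted(coal + (j,)))
                phi[j] += w * (v_map[with_j] - v_map[coal])
    return phi


def shap_summary(model, X) -> dict:
    """Per-instance Shapley attribution matrix from the fitted boosted-tree
    ensemble (LightGBM TreeSHAP), with the mean-|value| feature ranking and
    a helper ranking interaction partners of a named feature."""
    try:
        booster = model.booster_
    except AttributeError as exc:
        raise ValueError(
            "shap_summary requires a LightGBM model; use permutation "
            "importance for other estimators"
        ) from exc
    X = pd.DataFrame(X)
    contrib = booster.predict(X.to_numpy(), pred_contrib=True)
    values = pd.DataFrame(contrib[:, :-1], columns=X.columns, index=X.index)
    base = float(contrib[0, -1])
    ranking = values.abs().mean(axis=0).sort_values(ascending=False)

    def interaction_strength(feature: str) -> pd.Series:
        """Partners ranked by |corr| between the feature's attribution and
        the partner's values (a screening proxy for interaction)."""
        sj = values[feature]
        out = {}
        for other in X.columns:
            if other == feature:
                continue
            x = X[other]
            if x.std(ddof=0) == 0 or sj.std(ddof=0) == 0:
                out[other] = 0.0
            else:
                out[other] = abs(float(np.corrcoef(sj, x)[0, 1]))
        return pd.Series(out).sort_values(ascending=False)

    return {
        "values": values,
        "base_value": base,
        "ranking": ranking,
        "interaction_strength": interaction_strength,
    }


# ---------------------------------------------------------------------------
# Error-enrichment diagnostic
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Hypergeometric over-enrichment of flagged cases among poor
    predictions: k flagged poor cases among s poor predictions, with K
    flagged cases in a population of N."""

    k: int
    s: int
    K: int
    N: int
    fold: float
    p_value: float
    lower_thr: float = float("nan")
    upper_thr: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.s, self.K) and self.s <= self.N
                and self.K <= self.N):
            raise ValueError("inconsistent contingency counts")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def error_threshold_labels(
    y_true, y_pred, lower_q: float = 0.05, upper_q: float = 0.95
) -> tuple[np.ndarray, float, float]:
    """Label each prediction by its residual (yhat - y) against the
    empirical lower/upper quantile thresholds: 'poor_low', 'ok' or
    'poor_high'.  Returns (labels, lower_thr, upper_thr)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size != y_pred.size or y_true.size < 20:
        raise ValueError("need equal-length arrays with at least 20 cases")
    resid = y_pred - y_true
    lo = float(np.quantile(resid, lower_q))
    hi = float(np.quantile(resid, upper_q))
    labels = np.where(resid < lo, "poor_low",
                      np.where(resid > hi, "poor_high", "ok"))
    return labels, lo, hi


def hypergeometric_enrichment(
    labels: np.ndarray,
    flags: np.ndarray,
    lower_thr: float = float("nan"),
    upper_thr: float = float("nan"),
) -> EnrichmentResult:
    """One-sided (over-enrichment) hypergeometric test of a case flag among
    the poor predictions; p = P(X >= k) under Hypergeometric(N, K, s)."""
    labels = np.asarray(labels)
    flags = np.asarray(flags, dtype=bool)
    if labels.size != flags.size:
        raise ValueError("labels and flags must align")
    poor = labels != "ok"
    N = int(labels.size)
    s = int(poor.sum())
    K = int(flags.sum())
    k = int((poor & flags).sum())
    if s == 0:
        return EnrichmentResult(0, 0, K, N, float("nan"), 1.0,
                                lower_thr, upper_thr)
    p = float(stats.hypergeom.sf(k - 1, N, K, s))
    fold = (k / s) / (K / N) if K > 0 else float("nan")
    return EnrichmentResult(k, s, K, N, fold, p, lower_thr, upper_thr)
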