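"""End-to-end validation experiments on synthetic data.

These are the package's own study-condition checks, shared by the test
suite and the reproduction script: schema conformance of the featurization,
type-I-error calibration of the chunk ANOVA, null calibration of the
bootstrap + Tukey comparison, parameter recovery of the planted response
(model quality plus importance-ranking hits), and the structural statistics
of the emulated variant library.

Problem sizes are chosen for single-core desk-scale runs and stated
explicitly in each function's signature.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import (
    dataset_assembly,
    interpretation,
    model_bench,
    robustness_stats,
    sequence_layer,
    synthetic_data,
    trajectory_features,
)

__all__ = [
    "schema_summary",
    "chunk_anova_type1",
    "tukey_null_calibration",
    "recovery_library",
    "recovery_run",
    "library_statistics",
]


def schema_summary(seed: int = 0, n_variants: int = 20) -> dict:
    """Featurize a small synthetic library with all blocks and report the
    block widths of the assembled table."""
    import warnings

    spec = synthetic_data.default_spec(seed=seed, n_variants=n_variants)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, variants, truth = synthetic_data.build_synthetic_dataset(spec)
    subsets = dataset_assembly.block_subsets(table)
    return {
        "table": table,
        "variants": variants,
        "truth": truth,
        "seq_width": table.block_width("SEQ"),
        "md_width": table.block_width("MD"),
        "pocket_width": table.block_width("POCKET"),
        "total_width": table.n_features,
        "subset_widths": {name: t.n_features for name, t in subsets.items()},
    }


def chunk_anova_type1(
    n_variants: int = 200,
    seed: int = 0,
    n_replicates: int = 2,
    frames: int = 300,
    frames_per_chunk: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Observed type-I error of the chunk-vs-first ANOVA on stationary
    trajectories (white-noise fluctuations, so chunk RMSD values are iid
    and the nominal level should be recovered)."""
    template, seq = synthetic_data.make_template(12, seed=seed)
    spec = synthetic_data.SynthSpec(
        n_variants=n_variants, hot_positions=[1], max_mutations=0,
        replicates=n_replicates, frames_per_traj=frames, dt_ps=100.0,
        flexibility_base=0.3, noise_sd=0.0, seed=seed, ou_rho=0.0,
    )
    variants = synthetic_data.make_variant_library(spec, seq)
    series = {}
    for i, v in enumerate(variants):
        reps = synthetic_data.simulate_replicates(v, template, spec, i)
        series[v.id] = [
            trajectory_features.rmsd_series(t, template) for t in reps
        ]
    p_df, sig = robustness_stats.chunk_anova_matrix(
        series, frames_per_chunk=frames_per_chunk, alpha=alpha
    )
    n_tests = p_df.size
    rate = float(sig.to_numpy().mean())
    se = float(np.sqrt(alpha * (1 - alpha) / n_tests))
    # tests within a variant share the first chunk, so they are positively
    # correlated; the variant-level (cluster) SE is the honest yardstick
    per_variant = sig.to_numpy().mean(axis=0)
    cluster_se = float(per_variant.std(ddof=1) / np.sqrt(len(per_variant)))
    return {"rate": rate, "n_tests": int(n_tests), "alpha": alpha,
            "binomial_se": se, "cluster_se": cluster_se, "p_matrix": p_df}


def tukey_null_calibration(
    n_seeds: int = 20,
    seed: int = 0,
    n_boot: int = 50,
    n_obs: int = 120,
    n_features: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Bootstrap + Tukey comparison of two *identical* datasets (independent
    resampling streams): the fraction of seeds declaring any significant
    difference should stay at or below the nominal level."""
    from sklearn.linear_model import Ridge

    def ridge_factory(seed: int = 0, **params):
        return Ridge(**params)

    false_pos = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence((seed, s)))
        X = rng.standard_normal((n_obs, n_features))
        w = rng.standard_normal(n_features)
        y = X @ w + 0.5 * rng.standard_normal(n_obs)
        n_tr = int(0.8 * n_obs)
        data = (X[:n_tr], y[:n_tr], X[n_tr:], y[n_tr:])
        boot = model_bench.bootstrap_compare(
            {"a": data, "b": data}, {"a": {}, "b": {}},
            n_boot=n_boot, seed=seed * 1000 + s, model_factory=ridge_factory,
        )
        res = model_bench.anova_tukey(
            {k: v["r2"].to_numpy() for k, v in boot.items()}, alpha=alpha
        )
        if bool(res["tukey"]["significant"].any()):
            false_pos += 1
    return {"n_seeds": n_seeds, "false_positive_seeds": false_pos,
            "no_difference_fraction": 1.0 - false_pos / n_seeds}


# ---------------------------------------------------------------------------
# Planted-response recovery
# ---------------------------------------------------------------------------

def recovery_library(
    seed: int = 0, n_variants: int = 300
) -> tuple[dataset_assembly.FeatureTable, synthetic_data.SynthSpec]:
    """Featurize the recovery library (SEQ + MD blocks, study-condition
    defaults: 5 replicates, noise sd 0.5) without planting a response."""
    spec = synthetic_data.default_spec(seed=seed, n_variants=n_variants)
    table, _, _ = synthetic_data.build_synthetic_dataset(
        spec, blocks=("SEQ", "MD"), plant=False
    )
    return table, spec


def recovery_run(
    table: dataset_assembly.FeatureTable,
    spec: synthetic_data.SynthSpec,
    run_seed: int,
    n_iter: int = 10,
    top_k: int = 5,
) -> dict:
    """One seeded recovery experiment: plant the response, split 80/20,
    tune and fit the boosted tree, and check that the planted drivers are
    recovered by the permutation and SHAP rankings."""
    run_spec = dataclasses.replace(spec, seed=run_seed)
    fca, truth = synthetic_data.plant_response(table.values, run_spec)
    planted = table.with_response(fca)
    train_t, test_t = dataset_assembly.train_test_split(planted, seed=run_seed)
    X_tr, y_tr, X_te, y_te = model_bench.prepare_xy(train_t, test_t)
    cols = table.feature_names
    X_tr = pd.DataFrame(X_tr, columns=cols)
    X_te = pd.DataFrame(X_te, columns=cols)

    tuned = model_bench.tune_random_search(
        X_tr, y_tr, n_iter=n_iter, seed=run_seed
    )
    model = model_bench.make_boosted_tree(seed=run_seed, **tuned["best_params"])
    model.fit(X_tr, y_tr)
    metrics = model_bench.regression_metrics(y_te, model.predict(X_te))

    # importance rankings are measured on the full dataset: both methods
    # probe the same fitted model, and more instances/repeats reduce the
    # ranking noise that otherwise dominates beyond the true drivers
    X_all = pd.concat([X_tr, X_te])
    y_all = np.concatenate([y_tr, y_te])
    perm = interpretation.permutation_importance(
        model, X_all, y_all, n_repeats=20, seed=run_seed
    )
    shap = interpretation.shap_summary(model, X_all)
    drivers = set(truth["coefs"])
    perm_top = list(perm.index[:top_k])
    shap_top = list(shap["ranking"].index[:top_k])
    top20_perm = set(perm.index[:20])
    top20_shap = set(shap["ranking"].index[:20])
    return {
        "r2": metrics.r2,
        "rmse": metrics.rmse,
        "mae": metrics.mae,
        "perm_hit": drivers.issubset(perm_top),
        "shap_hit": drivers.issubset(shap_top),
        "overlap_top20": len(top20_perm & top20_shap) / 20.0,
        "perm_top": perm_top,
        "shap_top": shap_top,
        "tuned_params": tuned["best_params"],
    }


# ---------------------------------------------------------------------------
# Library structure statistics
# ---------------------------------------------------------------------------

def library_statistics(seed: int = 0, n_variants: int = 312) -> dict:
    """Structural statistics of the emulated epPCR library: pairwise
    identity, fraction of positions mutated at least once, and the
    prevalence of heavily mutated variants."""
    spec = synthetic_data.default_spec(seed=seed, n_variants=n_variants)
    _, seq = synthetic_data.default_template(seed=seed)
    variants = synthetic_data.make_variant_library(spec, seq)
    ident = sequence_layer.identity_matrix(variants)
    off = ident[~np.eye(len(variants), dtype=bool)]
    _, mutated_fraction = sequence_layer.mutation_site_occurrence(variants)
    n_mut = np.array([v.n_mutations for v in variants])
    return {
        "identity_min": float(off.min()),
        "identity_mean": float(off.mean()),
        "mutated_position_fraction": float(mutated_fraction),
        "fraction_gt5_mutations": float((n_mut > 5).mean()),
        "variants": variants,
    }
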