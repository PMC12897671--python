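"""Nested LOOCV machinery: scaling, tuning, AUC, bootstrap, leakage."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import mirprobe as mp
from mirprobe.nested_eval import (
    EvaluationError,
    FoldRecord,
    ModelSpec,
    _fold_seed,
    default_model_specs,
    mann_whitney_auc,
    scale_train_apply,
)


def _records(labels, scores):
    return [
        FoldRecord(sample_id=f"s{i}", true_label=int(l), score=float(s),
                   selected_features=(), hyperparams={})
        for i, (l, s) in enumerate(zip(labels, scores))
    ]


def _fast_specs(n_estimators=40):
    return default_model_specs(
        n_estimators=n_estimators,
        en_c_grid=(0.01, 0.1, 1.0),
        en_l1_grid=(0.1, 0.5, 1.0),
        svm_c_grid=(0.03125, 0.25, 1.0, 4.0, 32.0),
    )


# ---------------------------------------------------------------- scaling


def test_scale_train_apply_contract():
    rng = np.random.default_rng(0)
    train = rng.normal(5, 3, size=(10, 4))
    train[:, 2] = 7.0  # constant column
    test = train.mean(axis=0, keepdims=True)
    tr, te, stats = scale_train_apply(train, test)
    np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(tr[:, [0, 1, 3]].std(axis=0, ddof=1), 1.0, atol=1e-12)
    assert stats.zero_variance.tolist() == [False, False, True, False]
    np.testing.assert_allclose(tr[:, 2], 0.0)
    # a test row equal to the train mean maps to the origin
    np.testing.assert_allclose(te, 0.0, atol=1e-12)


# ---------------------------------------------------------------- AUC


def test_auc_basics_and_tie_convention():
    assert mp.compute_auc(_records([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])) == 1.0
    assert mp.compute_auc(_records([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])) == 0.5
    # 3 of 4 pairs concordant
    assert mp.compute_auc(_records([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])) == 0.75
    with pytest.raises(EvaluationError):
        mann_whitney_auc(np.array([1, 1]), np.array([0.5, 0.2]))


def test_auc_matches_pairwise_concordance_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(4, 30))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        pairs = [
            (1.0 if sp > sn else 0.5 if sp == sn else 0.0)
            for sp in s[y == 1]
            for sn in s[y == 0]
        ]
        oracle = float(np.mean(pairs))
        assert mann_whitney_auc(y, s) == pytest.approx(oracle)
        assert mann_whitney_auc(y, s) == pytest.approx(roc_auc_score(y, s))


def test_auc_equals_trapezoidal_roc_area():
    """Mann-Whitney AUC equals the trapezoidal area under the ROC staircase."""
    from mirprobe.plotting import roc_points

    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(5, 25))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.normal(size=n), 1)
        recs = _records(y, s)
        fpr, tpr = roc_points(recs)
        assert np.trapezoid(tpr, fpr) == pytest.approx(mp.compute_auc(recs))


def test_bootstrap_ci_degenerate_and_deterministic():
    recs = _records([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0])
    assert mp.bootstrap_auc_ci(recs, n_boot=200, seed=1) == (1.0, 1.0)
    rng_recs = _records([1, 0, 1, 0, 1, 0], [0.7, 0.4, 0.9, 0.6, 0.2, 0.3])
    a = mp.bootstrap_auc_ci(rng_recs, n_boot=500, seed=7)
    b = mp.bootstrap_auc_ci(rng_recs, n_boot=500, seed=7)
    assert a == b
    lo, hi = a
    assert 0.0 <= lo <= hi <= 1.0
    # percentile interval brackets the point estimate on these sizes
    assert lo <= mp.compute_auc(rng_recs) <= hi


# ---------------------------------------------------------------- tuning


def test_inner_tune_single_point_and_tie_rule():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 3))
    y = np.r_[np.zeros(6), np.ones(6)].astype(int)
    X[y == 1] += 4.0  # linearly separable
    single = ModelSpec("svm", "linear_svm", ({"C": 2.0},))
    params, _ = mp.inner_tune(X, y, single)
    assert params == {"C": 2.0}
    # separable data: every cost reaches inner AUC 1.0, tie -> smallest cost
    grid = ModelSpec("svm", "linear_svm", tuple({"C": c} for c in (8.0, 0.5, 2.0)))
    params, auc = mp.inner_tune(X, y, grid)
    assert auc == 1.0
    assert params == {"C": 0.5}


def test_inner_tune_rf_grid_collapses_when_one_feature():
    X = np.random.default_rng(1).normal(size=(10, 1))
    y = np.r_[np.zeros(5), np.ones(5)].astype(int)
    spec = default_model_specs(n_estimators=20)["rf"]
    params, auc = mp.inner_tune(X, y, spec)
    # all variables-per-split choices resolve to 1: no tuning needed
    assert np.isnan(auc)


# ---------------------------------------------------------------- outer loop


@pytest.fixture(scope="module")
def planted_run():
    cfg = mp.SimulationConfig(
        n_features=25,
        group_sizes={"HC": 6, "LC_BM": 6},
        planted_effects=(
            mp.EffectSpec("miR-sim-001", "LC_BM", 6.0),
            mp.EffectSpec("miR-sim-002", "LC_BM", 6.0),
        ),
        seed=21,
    )
    matrix, _ = mp.generate_cp_matrix(cfg)
    expr = mp.log_ratio(matrix, "HC")
    y = expr.labels_for(["LC_BM"], ["HC"])
    X = expr.to_feature_table().loc[y.index]
    params = mp.ProbeSelectionParams(n_repeats=10, seed=4)
    run = mp.run_outer_loocv(
        X, y, select_params=params, model_specs=_fast_specs(), seed=4, n_boot=300
    )
    return X, y, params, run


def test_outer_loocv_shape_and_signal(planted_run):
    X, y, _, run = planted_run
    for name, res in run.results.items():
        assert len(res.fold_records) == len(y)  # one record per sample
        assert res.auc >= 0.9  # strong planted two-feature signal
        lo, hi = res.ci
        assert 0.0 <= lo <= res.auc + 1e-9 and lo <= hi <= 1.0
    assert len(run.manifest["fold_seeds"]) == len(y)


def test_outer_loocv_deterministic(planted_run):
    X, y, params, run = planted_run
    again = mp.run_outer_loocv(
        X, y, select_params=params, model_specs=_fast_specs(), seed=4, n_boot=300
    )
    assert again.to_dict() == run.to_dict()


def test_held_out_sample_cannot_leak(planted_run):
    """Mutating the held-out sample's features leaves that fold's selection,
    scaling statistics and chosen hyperparameters untouched."""
    X, y, params, run = planted_run
    victim = X.index[3]
    X_mut = X.copy()
    X_mut.loc[victim] = X_mut.loc[victim] + 50.0
    mutated = mp.run_outer_loocv(
        X_mut, y, select_params=params, model_specs=_fast_specs(), seed=4, n_boot=300
    )
    fold = next(f for f in run.folds if f.sample_id == victim)
    fold_mut = next(f for f in mutated.folds if f.sample_id == victim)
    assert fold.selected_features == fold_mut.selected_features
    assert fold.scale_mean == fold_mut.scale_mean
    assert fold.scale_sd == fold_mut.scale_sd
    for name in run.results:
        rec = next(r for r in run.results[name].fold_records if r.sample_id == victim)
        rec_mut = next(
            r for r in mutated.results[name].fold_records if r.sample_id == victim
        )
        assert rec.hyperparams == rec_mut.hyperparams


def test_outer_loocv_rejects_tiny_or_one_class():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
    with pytest.raises(mp.ConfigurationError):
        mp.run_outer_loocv(X, np.array([0, 1, 0]))
    X6 = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 4)))
    with pytest.raises(mp.ConfigurationError):
        mp.run_outer_loocv(X6, np.array([0, 0, 0, 0, 0, 1]))


def test_fold_seed_stability():
    assert _fold_seed(7, 3) == _fold_seed(7, 3)
    assert _fold_seed(7, 3) != _fold_seed(7, 4)
    assert 0 <= _fold_seed(123, 456) < 2**31
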