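"""Probe-based selection: prefix-rule oracle, probes, stability, estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.pipeline import Pipeline
from sklearn.linear_model import LogisticRegression

import mirprobe as mp
from mirprobe.probe_select import (
    RankedItem,
    make_probes,
    near_zero_variance_filter,
    one_selection_run,
    rank_features,
    select_prefix,
    stability_selection,
)


def brute_force_prefix(flags, max_ratio):
    """Oracle: test every prefix length explicitly."""
    best_k = 0
    for k in range(1, len(flags) + 1):
        probes = sum(flags[:k])
        originals = k - probes
        if originals >= 1 and probes / originals <= max_ratio:
            best_k = k
    return best_k


def _items(flags):
    return [
        RankedItem(name=f"f{i:03d}", is_probe=bool(fl), score=i * 0.001)
        for i, fl in enumerate(flags)
    ]


def test_select_prefix_examples():
    # eleven originals then a probe: ratio 1/11 <= 0.1 keeps all eleven
    flags = [0] * 11 + [1] + [0] * 5
    selected = select_prefix(_items(flags), 0.1)
    assert len(selected) >= 11
    # probe first with only 5 originals: nothing admissible
    assert select_prefix(_items([1, 0, 0, 0, 0, 0]), 0.1) == []
    # no probes at all: everything selected
    assert len(select_prefix(_items([0] * 7), 0.1)) == 7


@given(
    flags=st.lists(st.booleans(), min_size=0, max_size=200),
    ratio=st.sampled_from([0.05, 0.1, 0.2, 0.5]),
)
@settings(max_examples=300, deadline=None)
def test_select_prefix_matches_brute_force(flags, ratio):
    items = _items(flags)
    selected = select_prefix(items, ratio)
    k_star = brute_force_prefix([int(f) for f in flags], ratio)
    assert selected == [it.name for it in items[:k_star] if not it.is_probe]
    # post-hoc: the selected prefix satisfies the bound exactly
    if selected:
        probes = sum(1 for it in items[:k_star] if it.is_probe)
        assert probes / len(selected) <= ratio


def test_nzv_rules():
    n = 40
    X = pd.DataFrame(
        {
            "constant": np.zeros(n),
            "continuous": np.linspace(0, 1, n),
            # ratio 39/1 >= 19 and unique fraction 2/40 <= 0.1: removed
            "nzv": np.r_[np.zeros(n - 1), 1.0],
        }
    )
    surviving = near_zero_variance_filter(X)
    assert "constant" not in surviving
    assert "continuous" in surviving
    assert "nzv" not in surviving
    # ratio exactly 18 < 19 stays, despite the low unique fraction
    almost = pd.DataFrame({"almost": np.r_[np.zeros(18), [5.0]]})
    assert near_zero_variance_filter(almost) == ["almost"]


def test_make_probes_are_permutations_and_deterministic():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(np.random.default_rng(1).normal(size=(12, 4)), columns=list("abcd"))
    probes = make_probes(X, 6, rng)
    assert probes.shape == (12, 6)
    for name in probes.columns:
        src = name.split("__", 1)[1]
        assert sorted(probes[name]) == pytest.approx(sorted(X[src]))
    again = make_probes(X, 6, np.random.default_rng(0))
    pd.testing.assert_frame_equal(probes, again)
    assert make_probes(X, 0, rng).shape == (12, 0)


def test_one_selection_run_finds_separating_feature():
    rng = np.random.default_rng(3)
    n = 20
    y = np.r_[np.zeros(10), np.ones(10)].astype(int)
    X = pd.DataFrame(rng.normal(size=(n, 30)), columns=[f"g{i:02d}" for i in range(30)])
    X["g00"] = np.r_[rng.normal(0, 0.3, 10), rng.normal(5, 0.3, 10)]  # separated
    params = mp.ProbeSelectionParams(n_repeats=10, seed=0)
    selected = one_selection_run(X, y, params, repeat_seed=123)
    assert "g00" in selected
    assert selected == one_selection_run(X, y, params, repeat_seed=123)


def test_one_selection_run_rejects_degenerate_labels():
    X = pd.DataFrame(np.zeros((4, 3)))
    with pytest.raises(mp.ConfigurationError):
        one_selection_run(X, np.zeros(4, dtype=int), mp.ProbeSelectionParams(), 0)


def test_stability_frequencies_and_monotone_threshold():
    rng = np.random.default_rng(9)
    n = 24
    y = np.r_[np.zeros(12), np.ones(12)].astype(int)
    X = pd.DataFrame(rng.normal(size=(n, 25)), columns=[f"g{i:02d}" for i in range(25)])
    X["g01"] += y * 4.0
    params = mp.ProbeSelectionParams(n_repeats=20, seed=5)
    table = stability_selection(X, y, params)
    assert ((table.frequencies >= 0) & (table.frequencies <= 1)).all()
    assert table.frequencies.loc["g01"] >= 0.9
    assert "g01" in table.retained
    # lowering the threshold never shrinks the retained set
    lowered = mp.StabilityTable(
        table.frequencies, table.n_repeats, 0.2, table.high_stability_threshold
    )
    assert set(table.retained) <= set(lowered.retained)
    # tiers are consistent with frequencies
    tiers = table.tiers()
    assert (tiers[table.frequencies >= 0.70] == "high").all()


def test_probes_and_originals_exchangeable_under_null():
    """With labels independent of the data, a probe is as likely as an
    original to head the ranking, in proportion to their counts."""
    n_orig, n_probe = 15, 15
    top_is_probe = 0
    runs = 200
    for s in range(runs):
        rng = np.random.default_rng(s)
        X = pd.DataFrame(
            rng.normal(size=(16, n_orig)), columns=[f"g{i:02d}" for i in range(n_orig)]
        )
        y = np.r_[np.zeros(8), np.ones(8)].astype(int)
        probes = make_probes(X, n_probe, rng)
        ranked = rank_features(X, y, probes)
        top_is_probe += ranked[0].is_probe
    # expectation 0.5; binomial(200, .5) 4-sigma band
    assert abs(top_is_probe / runs - 0.5) < 4 * 0.5 / np.sqrt(runs)


def test_selector_estimator_in_pipeline(small_cohort):
    _, matrix, truth = small_cohort
    expr = mp.log_ratio(matrix, "HC")
    y = expr.labels_for(["LC_BM"], ["HC", "LC"])
    X = expr.to_feature_table().loc[y.index]
    selector = mp.ProbeStabilitySelector(n_repeats=15, random_state=0, fallback_top_k=1)
    pipe = Pipeline([("select", selector), ("clf", LogisticRegression(max_iter=1000))])
    pipe.fit(X, y)
    fitted = pipe.named_steps["select"]
    assert set(truth.planted_feature_ids) <= set(fitted.retained_features_)
    assert fitted.frequencies_.index.tolist() == list(X.columns)
    assert pipe.predict(X).shape == (len(y),)


def test_selector_fallback_on_pure_noise():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(10, 6)), columns=list("abcdef"))
    y = np.r_[np.zeros(5), np.ones(5)].astype(int)
    sel = mp.ProbeStabilitySelector(
        n_repeats=5, stability_threshold=1.01 - 1e-9, fallback_top_k=1, random_state=1
    )
    # threshold above 1 is unreachable -> fallback must fire
    with pytest.raises(mp.ConfigurationError):
        sel.fit(X, y)  # invalid threshold rejected
    sel = mp.ProbeStabilitySelector(n_probes=200, max_probe_ratio=0.01,
                                    n_repeats=5, fallback_top_k=1, random_state=1)
    sel.fit(X, y)
    if sel.fallback_used_:
        assert len(sel.retained_features_) == 1
    assert sel.get_support().sum() == len(sel.retained_features_)
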