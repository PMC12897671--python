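"""Permutation-probe feature ranking with stability selection.

The core selection procedure:

1. remove near-zero-variance features (caret-style rule);
2. generate ``n_probes`` probe variables, each a permuted copy of a randomly
   chosen original feature — the permutation destroys any association with
   the outcome while preserving the marginal distribution;
3. jointly rank originals and probes by their two-sided Wilcoxon p-value
   (ascending, name-tie-broken);
4. keep the largest top-ranked prefix whose running probe:original ratio does
   not exceed ``max_probe_ratio`` — the ratio bounds the expected proportion
   of null selections among the kept originals;
5. repeat the whole procedure over ``n_repeats`` derived seeds and retain
   features selected in at least ``stability_threshold`` of the repeats
   (``high_stability_threshold`` marks the high-stability tier).

Steps 1-5 are exposed both as functions and as sklearn-compatible selector
estimators (:class:`NearZeroVarianceFilter`, :class:`ProbeStabilitySelector`)
so they compose with pipelines and cross-validation utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import ConfigurationError
from .diffexpr import rank_sum_p_matrix


@dataclass
class ProbeSelectionParams:
    """Tunables of the probe-based stability selection.

    ``n_probes`` permuted decoys per repeat, prefix ratio bound
    ``max_probe_ratio``, ``n_repeats`` derived seeds, retention threshold
    ``stability_threshold`` and high-stability tier ``high_stability_threshold``.
    The near-zero-variance parameters follow the common preprocessing
    convention (frequency ratio 19 = 95/5, unique-value fraction 10%).
    ``bootstrap_subjects`` additionally resamples samples with replacement in
    each repeat (exploratory full-dataset mode); the default repeats only the
    probe re-permutation.
    """

    n_probes: int = 50
    max_probe_ratio: float = 0.1
    n_repeats: int = 100
    stability_threshold: float = 0.45
    high_stability_threshold: float = 0.70
    nzv_freq_ratio: float = 19.0
    nzv_unique_frac: float = 0.10
    bootstrap_subjects: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.max_probe_ratio < 1:
            raise ConfigurationError("max_probe_ratio must be in (0, 1)")
        for thr in (self.stability_threshold, self.high_stability_threshold):
            if not 0 <= thr <= 1:
                raise ConfigurationError("stability thresholds must be in [0, 1]")
        if self.n_probes < 0 or self.n_repeats < 1:
            raise ConfigurationError("n_probes >= 0 and n_repeats >= 1 required")


@dataclass(frozen=True)
class RankedItem:
    """One entry of the joint original+probe ranking."""

    name: str
    is_probe: bool
    score: float
    source: str | None = None


@dataclass
class StabilityTable:
    """Per-feature selection frequency over the seeded repeats."""

    frequencies: pd.Series
    n_repeats: int
    stability_threshold: float
    high_stability_threshold: float

    @property
    def retained(self) -> list[str]:
        keep = self.frequencies[self.frequencies >= self.stability_threshold]
        return list(keep.sort_values(ascending=False, kind="mergesort").index)

    def tiers(self) -> pd.Series:
        f = self.frequencies
        return pd.Series(
            np.where(
                f >= self.high_stability_threshold,
                "high",
                np.where(f >= self.stability_threshold, "medium", "below"),
            ),
            index=f.index,
            name="tier",
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "mirna": self.frequencies.index,
                "frequency": self.frequencies.to_numpy(),
                "tier": self.tiers().to_numpy(),
                "retained": (self.frequencies >= self.stability_threshold).to_numpy(),
            }
        )
        return out.sort_values(
            ["frequency", "mirna"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# functional core


def near_zero_variance_filter(
    X: pd.DataFrame, freq_ratio: float = 19.0, unique_frac: float = 0.10
) -> list[str]:
    """Feature names surviving the near-zero-variance rule.

    A feature is removed if it is constant, or if (most frequent value count /
    second most frequent value count) >= ``freq_ratio`` while its fraction of
    unique values is <= ``unique_frac``.
    """
    if X.shape[1] == 0:
        return []
    n = len(X)
    surviving = []
    for name in X.columns:
        counts = X[name].value_counts(dropna=False).to_numpy()
        if counts.size <= 1:
            continue  # constant
        ratio = counts[0] / counts[1]
        u_frac = counts.size / n
        if ratio >= freq_ratio and u_frac <= unique_frac:
            continue
        surviving.append(name)
    return surviving


def make_probes(X: pd.DataFrame, n_probes: int, rng: np.random.Generator) -> pd.DataFrame:
    """Permuted-copy probe variables drawn (with replacement) from ``X``.

    Probe names encode the repeat-local index and the source feature.
    """
    if X.shape[1] < 1:
        raise ConfigurationError("need at least one feature to build probes")
    names = list(X.columns)
    cols: dict[str, np.ndarray] = {}
    for i in range(n_probes):
        src = names[int(rng.integers(len(names)))]
        cols[f"probe{i + 1:03d}__{src}"] = rng.permutation(X[src].to_numpy())
    return pd.DataFrame(cols, index=X.index)


def select_prefix(ranked: Sequence[RankedItem], max_probe_ratio: float) -> list[str]:
    """Original names in the largest prefix with probe:original ratio <= bound.

    Scans every prefix length ``k`` of the ranking (best first); a prefix is
    admissible when it contains at least one original and its probe count
    divided by its original count does not exceed ``max_probe_ratio``.  The
    largest admissible ``k`` wins even when smaller prefixes transiently
    violate the bound; with no admissible prefix the selection is empty.
    """
    best_k = 0
    probes = originals = 0
    for k, item in enumerate(ranked, start=1):
        if item.is_probe:
            probes += 1
        else:
            originals += 1
        if originals >= 1 and probes / originals <= max_probe_ratio:
            best_k = k
    return [item.name for item in ranked[:best_k] if not item.is_probe]


def rank_features(
    X: pd.DataFrame, y: np.ndarray, probes: pd.DataFrame | None = None
) -> list[RankedItem]:
    """Joint Wilcoxon-p ranking of original features and (optional) probes."""
    blocks = [X] if probes is None or probes.empty else [X, probes]
    joint = pd.concat(blocks, axis=1)
    pvals = rank_sum_p_matrix(joint.to_numpy(), y)
    items = []
    n_orig = X.shape[1]
    for j, name in enumerate(joint.columns):
        is_probe = j >= n_orig
        items.append(
            RankedItem(
                name=name,
                is_probe=is_probe,
                score=float(pvals[j]),
                source=name.split("__", 1)[1] if is_probe else None,
            )
        )
    items.sort(key=lambda it: (it.score, it.name))
    return items


def one_selection_run(
    X: pd.DataFrame,
    y: np.ndarray,
    params: ProbeSelectionParams,
    repeat_seed: int,
) -> list[str]:
    """One probe-generation + ranking + prefix-selection pass.

    Deterministic for a fixed ``repeat_seed``.  ``X`` must already be
    NZV-filtered; ``y`` must contain both classes.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ConfigurationError("y must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence(repeat_seed))
    Xr, yr = X, y
    if params.bootstrap_subjects:
        for _ in range(100):  # redraw degenerate resamples
            idx = rng.integers(len(y), size=len(y))
            if np.unique(y[idx]).size == 2:
                break
        else:
            raise ConfigurationError("could not draw a two-class bootstrap resample")
        Xr = X.iloc[idx].reset_index(drop=True)
        yr = y[idx]
    probes = make_probes(Xr, params.n_probes, rng)
    ranked = rank_features(Xr, yr, probes)
    return select_prefix(ranked, params.max_probe_ratio)


def repeat_seed_for(seed: int, repeat_index: int) -> int:
    """Counter-based derived seed for one repeat (stable across runs)."""
    return int(np.random.SeedSequence([seed, repeat_index]).generate_state(1)[0])


def stability_selection(
    X: pd.DataFrame, y: np.ndarray, params: ProbeSelectionParams
) -> StabilityTable:
    """Selection frequency of every feature over ``n_repeats`` seeded runs."""
    counts = pd.Series(0.0, index=X.columns)
    for r in range(params.n_repeats):
        for name in one_selection_run(X, y, params, repeat_seed_for(params.seed, r)):
            counts[name] += 1.0
    return StabilityTable(
        frequencies=counts / params.n_repeats,
        n_repeats=params.n_repeats,
        stability_threshold=params.stability_threshold,
        high_stability_threshold=params.high_stability_threshold,
    )


# ---------------------------------------------------------------------------
# sklearn estimator surface


class NearZeroVarianceFilter(SelectorMixin, BaseEstimator):
    """Drop constant and near-constant features (caret-style rule).

    Parameters
    ----------
    freq_ratio : float, default=19.0
        Removal requires (top value count / runner-up count) >= this ratio.
    unique_frac : float, default=0.10
        ... together with a unique-value fraction <= this bound.
    """

    def __init__(self, freq_ratio: float = 19.0, unique_frac: float = 0.10):
        self.freq_ratio = freq_ratio
        self.unique_frac = unique_frac

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_features=1)
        names = getattr(self, "feature_names_in_", None)
        cols = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
        df = pd.DataFrame(X, columns=cols)
        surviving = set(near_zero_variance_filter(df, self.freq_ratio, self.unique_frac))
        self.support_ = np.array([c in surviving for c in cols])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


class ProbeStabilitySelector(SelectorMixin, BaseEstimator):
    """Sklearn-compatible permutation-probe stability selector.

    Runs the NZV filter followed by seeded probe-based stability selection
    and exposes the retained features via the standard ``get_support`` /
    ``transform`` selector API.  When nothing reaches the stability
    threshold, the ``fallback_top_k`` best Wilcoxon-ranked originals are
    selected instead (set to 0 to allow an empty selection).

    Attributes
    ----------
    frequencies_ : pandas.Series
        Selection frequency per input feature (0 for NZV-removed features).
    stability_table_ : StabilityTable
        Frequencies/tiers over NZV-surviving features.
    retained_features_ : list of str
        Final selected feature names.
    fallback_used_ : bool
        True when the threshold retained nothing and the fallback applied.
    """

    def __init__(
        self,
        n_probes: int = 50,
        max_probe_ratio: float = 0.1,
        n_repeats: int = 100,
        stability_threshold: float = 0.45,
        high_stability_threshold: float = 0.70,
        nzv_freq_ratio: float = 19.0,
        nzv_unique_frac: float = 0.10,
        bootstrap_subjects: bool = False,
        fallback_top_k: int = 0,
        random_state: int | None = None,
    ):
        self.n_probes = n_probes
        self.max_probe_ratio = max_probe_ratio
        self.n_repeats = n_repeats
        self.stability_threshold = stability_threshold
        self.high_stability_threshold = high_stability_threshold
        self.nzv_freq_ratio = nzv_freq_ratio
        self.nzv_unique_frac = nzv_unique_frac
        self.bootstrap_subjects = bootstrap_subjects
        self.fallback_top_k = fallback_top_k
        self.random_state = random_state

    def _params(self) -> ProbeSelectionParams:
        return ProbeSelectionParams(
            n_probes=self.n_probes,
            max_probe_ratio=self.max_probe_ratio,
            n_repeats=self.n_repeats,
            stability_threshold=self.stability_threshold,
            high_stability_threshold=self.high_stability_threshold,
            nzv_freq_ratio=self.nzv_freq_ratio,
            nzv_unique_frac=self.nzv_unique_frac,
            bootstrap_subjects=self.bootstrap_subjects,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_features=1)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ConfigurationError("y must contain both classes")
        names = getattr(self, "feature_names_in_", None)
        cols = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
        df = pd.DataFrame(X, columns=cols)
        params = self._params()

        surviving = near_zero_variance_filter(df, params.nzv_freq_ratio, params.nzv_unique_frac)
        if not surviving:
            raise ConfigurationError("no features survive the near-zero-variance filter")
        table = stability_selection(df[surviving], y, params)

        retained = table.retained
        self.fallback_used_ = False
        if not retained and self.fallback_top_k > 0:
            ranked = rank_features(df[surviving], y, probes=None)
            retained = [it.name for it in ranked[: self.fallback_top_k]]
            self.fallback_used_ = True

        freq = pd.Series(0.0, index=cols)
        freq.loc[table.frequencies.index] = table.frequencies
        self.frequencies_ = freq
        self.stability_table_ = table
        self.retained_features_ = retained
        retained_set = set(retained)
        self.support_ = np.array([c in retained_set for c in cols])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
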