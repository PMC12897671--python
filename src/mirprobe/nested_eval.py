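"""Fully nested leave-one-out cross-validation evaluation.

For each outer fold (one held-out sample), the entire feature-selection
workflow — near-zero-variance filtering, probe-based stability selection,
centering/scaling, and inner-LOOCV hyperparameter tuning for each classifier
family — runs on the training fold only; the held-out sample is scored by a
model that never saw it at any stage.  Outer-fold scores are summarized by
the Mann-Whitney AUC with percentile bootstrap confidence intervals over
subjects.

Classifier families: elastic-net-regularized logistic regression, linear
support vector machine, and random forest.  Continuous scores are class
probabilities for the logistic and forest models and the signed decision
value for the SVM (probability calibration is unstable at these sample
sizes).  Inner tuning maximizes the AUC of predictions aggregated over all
inner leave-one-out folds (a per-fold AUC is undefined with a single held-out
sample); ties go to the most regularized grid point.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .containers import ConfigurationError, MirprobeError
from .probe_select import ProbeSelectionParams, ProbeStabilitySelector

logger = logging.getLogger(__name__)

ELASTIC_NET = "elastic_net_logistic"
LINEAR_SVM = "linear_svm"
RANDOM_FOREST = "random_forest"


class EvaluationError(MirprobeError):
    pass


@dataclass(frozen=True)
class ContrastSpec:
    """A binary contrast over cohort groups (positive class first)."""

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ConfigurationError("contrast classes must be disjoint")

    def labels(self, groups: pd.Series) -> pd.Series:
        keep = groups.isin(set(self.positive) | set(self.negative))
        y = groups[keep].isin(set(self.positive)).astype(int)
        y.name = "label"
        return y


#: Primary contrast: brain-metastasis cases against everything else.
BM_VS_REST = ContrastSpec("BM_vs_REST", ("LC_BM",), ("HC", "LC"))
BM_VS_LC = ContrastSpec("BM_vs_LC", ("LC_BM",), ("LC",))
BM_VS_HC = ContrastSpec("BM_vs_HC", ("LC_BM",), ("HC",))


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameter grid."""

    name: str
    family: str
    grid: tuple[dict, ...]
    n_estimators: int = 500  # random forest only

    def __post_init__(self) -> None:
        if not self.grid:
            raise ConfigurationError("hyperparameter grid must be non-empty")


def default_model_specs(
    n_estimators: int = 500,
    en_c_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    en_l1_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1)),
    svm_c_grid: Sequence[float] = tuple(2.0 ** np.arange(-5, 6)),
    rf_mtry_grid: Sequence = (1, "sqrt", "third"),
) -> dict[str, ModelSpec]:
    """Conventional grids: elastic-net mixing x log-spaced penalty, SVM cost
    over powers of two, forest variables-per-split in {1, sqrt(p), p/3}."""
    en = tuple({"C": c, "l1_ratio": l1} for c in en_c_grid for l1 in en_l1_grid)
    svm = tuple({"C": float(c)} for c in svm_c_grid)
    rf = tuple({"max_features": m} for m in rf_mtry_grid)
    return {
        "glmnet": ModelSpec("glmnet", ELASTIC_NET, en),
        "svm": ModelSpec("svm", LINEAR_SVM, svm),
        "rf": ModelSpec("rf", RANDOM_FOREST, rf, n_estimators=n_estimators),
    }


@dataclass
class FoldRecord:
    """Prediction for one held-out sample, with its fold-local provenance."""

    sample_id: str
    true_label: int
    score: float
    selected_features: tuple[str, ...]
    hyperparams: dict


@dataclass
class FoldInfo:
    """Fold-internal state shared across models (for audit/leakage checks)."""

    fold_index: int
    sample_id: str
    seed: int
    selected_features: tuple[str, ...]
    fallback_used: bool
    scale_mean: tuple[float, ...]
    scale_sd: tuple[float, ...]


@dataclass
class EvaluationResult:
    model_name: str
    fold_records: list[FoldRecord]
    auc: float
    ci: tuple[float, float] | None = None
    ci_level: float = 0.95
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "auc": self.auc,
            "ci": list(self.ci) if self.ci is not None else None,
            "ci_level": self.ci_level,
            "warnings": self.warnings,
            "folds": [
                {
                    "sample_id": r.sample_id,
                    "true_label": int(r.true_label),
                    "score": float(r.score),
                    "selected_features": list(r.selected_features),
                    "hyperparams": {k: _jsonable(v) for k, v in r.hyperparams.items()},
                }
                for r in self.fold_records
            ],
        }


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


@dataclass
class EvaluationRun:
    """All per-model results plus the replay manifest."""

    results: dict[str, EvaluationResult]
    folds: list[FoldInfo]
    manifest: dict

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "models": {name: res.to_dict() for name, res in self.results.items()},
        }


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalingStats:
    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray  # flags for constant train columns


def scale_train_apply(
    train_X: np.ndarray, test_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, ScalingStats]:
    """Center/scale with statistics from the training fold only.

    Train columns end with mean 0 and (sample, ddof=1) sd 1; constant train
    columns are mapped to 0 and flagged, with the test value shifted by the
    train mean but left unscaled.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[0] < 2:
        raise ConfigurationError("need at least two training samples to scale")
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=1)
    zero = ~(sd > 0)
    safe_sd = np.where(zero, 1.0, sd)
    return (
        (train_X - mean) / safe_sd,
        (test_X - mean) / safe_sd,
        ScalingStats(mean=mean, sd=sd, zero_variance=zero),
    )


# ---------------------------------------------------------------------------
# AUC


def mann_whitney_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 * P(equal), via mid-ranks."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC undefined: only one class present")
    ranks = stats.rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_auc(fold_records: Iterable[FoldRecord]) -> float:
    """Outer-fold AUC from held-out predictions."""
    records = list(fold_records)
    return mann_whitney_auc(
        np.array([r.true_label for r in records]),
        np.array([r.score for r in records]),
    )


def bootstrap_auc_ci(
    fold_records: Sequence[FoldRecord],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUC, resampling subjects with replacement.

    Replicates in which only one class is drawn are skipped; if more than
    half of the replicates are degenerate a warning is issued.
    """
    records = list(fold_records)
    if len(records) < 4:
        raise EvaluationError("need at least 4 records for a bootstrap CI")
    y = np.array([r.true_label for r in records])
    s = np.array([r.score for r in records])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    aucs = []
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(len(y), size=len(y))
        yb = y[idx]
        if yb.min() == yb.max():
            degenerate += 1
            continue
        aucs.append(mann_whitney_auc(yb, s[idx]))
    if degenerate > n_boot / 2:
        warnings.warn(
            f"{degenerate}/{n_boot} bootstrap replicates had a single class",
            stacklevel=2,
        )
    if not aucs:
        raise EvaluationError("all bootstrap replicates degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# models


def _resolve_max_features(value, p: int) -> int:
    if value == "sqrt":
        return max(1, int(round(np.sqrt(p))))
    if value == "third":
        return max(1, int(round(p / 3.0)))
    return min(int(value), p)


def _build_estimator(spec: ModelSpec, params: dict, p: int, random_state: int):
    if spec.family == ELASTIC_NET:
        return LogisticRegression(
            solver="saga",
            C=params["C"],
            l1_ratio=params["l1_ratio"],
            max_iter=5000,
            tol=1e-4,
            random_state=random_state,
        )
    if spec.family == LINEAR_SVM:
        return SVC(kernel="linear", C=params["C"])
    if spec.family == RANDOM_FOREST:
        return RandomForestClassifier(
            n_estimators=spec.n_estimators,
            max_features=_resolve_max_features(params["max_features"], p),
            random_state=random_state,
            n_jobs=1,
        )
    raise ConfigurationError(f"unknown model family {spec.family!r}")


def _score_samples(est, spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    if spec.family == LINEAR_SVM:
        return est.decision_function(X)
    return est.predict_proba(X)[:, 1]


def _regularization_order(spec: ModelSpec, p: int) -> list[dict]:
    """Grid sorted most-regularized first, so stable tie-breaking favors it."""
    grid = list(spec.grid)
    if spec.family == ELASTIC_NET:
        # smaller C = stronger penalty; secondary: larger l1 mixing (sparser)
        grid.sort(key=lambda g: (g["C"], -g["l1_ratio"]))
    elif spec.family == LINEAR_SVM:
        grid.sort(key=lambda g: g["C"])  # smaller cost = more regularized
    elif spec.family == RANDOM_FOREST:
        grid.sort(key=lambda g: _resolve_max_features(g["max_features"], p))
    return grid


def inner_tune(
    train_X: np.ndarray,
    train_y: np.ndarray,
    model: ModelSpec,
    random_state: int = 0,
) -> tuple[dict, float]:
    """Inner-LOOCV grid search maximizing the aggregated-prediction AUC.

    Every grid point is evaluated by leave-one-out over the training fold;
    the held-out scores are pooled and a single AUC computed.  Ties (and the
    no-usable-point edge) resolve to the most regularized point.  Inner folds
    whose training part is single-class are skipped for all points; a grid
    point that fails to fit is skipped with a log entry.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y).astype(int)
    n, p = train_X.shape
    if np.unique(train_y).size < 2:
        raise EvaluationError("inner tuning needs both classes")
    ordered = _regularization_order(model, p)
    # drop grid points that resolve to the same fitted model (e.g. every
    # variables-per-split choice collapses to 1 when few features survive
    # selection); keeps the most-regularized representative
    seen: set = set()
    deduped = []
    for g in ordered:
        if model.family == RANDOM_FOREST:
            key = (_resolve_max_features(g["max_features"], p),)
        else:
            key = tuple(sorted(g.items()))
        if key not in seen:
            seen.add(key)
            deduped.append(g)
    ordered = deduped
    if len(ordered) == 1:
        return ordered[0], float("nan")

    usable_folds = [
        i for i in range(n) if np.unique(np.delete(train_y, i)).size == 2
    ]
    best_params, best_auc = ordered[0], -np.inf
    for params in ordered:
        scores, labels = [], []
        failed = False
        for i in usable_folds:
            Xi = np.delete(train_X, i, axis=0)
            yi = np.delete(train_y, i)
            try:
                est = _build_estimator(model, params, p, random_state)
                est.fit(Xi, yi)
                scores.append(float(_score_samples(est, model, train_X[i : i + 1])[0]))
            except Exception as exc:  # degenerate fit for this grid point
                logger.info("inner grid point %s skipped: %s", params, exc)
                failed = True
                break
            labels.append(train_y[i])
        if failed or not labels:
            continue
        labels_arr = np.array(labels)
        if labels_arr.min() == labels_arr.max():
            continue
        auc = mann_whitney_auc(labels_arr, np.array(scores))
        if auc > best_auc + 1e-12:
            best_params, best_auc = params, auc
    return best_params, best_auc


# ---------------------------------------------------------------------------
# the outer loop


def _fold_seed(seed: int, fold_index: int) -> int:
    return int(np.random.SeedSequence([seed, fold_index]).generate_state(1)[0] % (2**31))


def run_outer_loocv(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    select_params: ProbeSelectionParams | None = None,
    model_specs: dict[str, ModelSpec] | None = None,
    seed: int = 0,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    compute_ci: bool = True,
) -> EvaluationRun:
    """Nested LOOCV over ``X`` (samples x features) and binary ``y``.

    Per fold: NZV filter -> probe stability selection (empty selection falls
    back to the single top-ranked original) -> train-only centering/scaling ->
    inner-LOOCV tuning -> fit -> score the held-out sample.  All stochastic
    stages derive their seeds from ``seed`` and the fold index; the manifest
    records every fold seed for replay.
    """
    X = pd.DataFrame(X)
    y_arr = np.asarray(y).astype(int)
    n = len(X)
    if n != len(y_arr):
        raise ConfigurationError("X and y length mismatch")
    if n < 4 or (y_arr == 1).sum() < 2 or (y_arr == 0).sum() < 2:
        raise ConfigurationError("need n >= 4 with at least 2 samples per class")
    select_params = select_params or ProbeSelectionParams()
    model_specs = model_specs or default_model_specs()

    sample_ids = [str(s) for s in X.index]
    fold_infos: list[FoldInfo] = []
    records: dict[str, list[FoldRecord]] = {name: [] for name in model_specs}
    skipped: list[str] = []

    for i, sample in enumerate(sample_ids):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_X = X.iloc[mask]
        train_y = y_arr[mask]
        if np.unique(train_y).size < 2:
            skipped.append(sample)
            logger.warning("fold %d (%s) skipped: one-class training fold", i, sample)
            continue
        fseed = _fold_seed(seed, i)

        selector = ProbeStabilitySelector(
            n_probes=select_params.n_probes,
            max_probe_ratio=select_params.max_probe_ratio,
            n_repeats=select_params.n_repeats,
            stability_threshold=select_params.stability_threshold,
            high_stability_threshold=select_params.high_stability_threshold,
            nzv_freq_ratio=select_params.nzv_freq_ratio,
            nzv_unique_frac=select_params.nzv_unique_frac,
            bootstrap_subjects=select_params.bootstrap_subjects,
            fallback_top_k=1,
            random_state=fseed,
        ).fit(train_X, train_y)
        selected = tuple(selector.retained_features_)
        if selector.fallback_used_:
            logger.info("fold %d (%s): empty selection, fallback to %s", i, sample, selected)

        train_sel = train_X[list(selected)].to_numpy()
        test_sel = X.iloc[[i]][list(selected)].to_numpy()
        train_s, test_s, scale_stats = scale_train_apply(train_sel, test_sel)
        fold_infos.append(
            FoldInfo(
                fold_index=i,
                sample_id=sample,
                seed=fseed,
                selected_features=selected,
                fallback_used=selector.fallback_used_,
                scale_mean=tuple(scale_stats.mean),
                scale_sd=tuple(scale_stats.sd),
            )
        )
        for name, spec in model_specs.items():
            best_params, _ = inner_tune(train_s, train_y, spec, random_state=fseed)
            est = _build_estimator(spec, best_params, train_s.shape[1], fseed)
            est.fit(train_s, train_y)
            score = float(_score_samples(est, spec, test_s)[0])
            records[name].append(
                FoldRecord(
                    sample_id=sample,
                    true_label=int(y_arr[i]),
                    score=score,
                    selected_features=selected,
                    hyperparams=dict(best_params),
                )
            )

    results: dict[str, EvaluationResult] = {}
    for name in model_specs:
        recs = records[name]
        auc = compute_auc(recs)
        ci = None
        if compute_ci:
            boot_seed = _fold_seed(seed, 10_000 + zlib.crc32(name.encode()) % 1000)
            ci = bootstrap_auc_ci(recs, n_boot=n_boot, level=ci_level, seed=boot_seed)
        results[name] = EvaluationResult(
            model_name=name, fold_records=recs, auc=auc, ci=ci, ci_level=ci_level
        )

    manifest = {
        "seed": seed,
        "fold_seeds": {fi.sample_id: fi.seed for fi in fold_infos},
        "skipped_folds": skipped,
        "n_samples": n,
        "selection_params": {
            k: getattr(select_params, k)
            for k in (
                "n_probes",
                "max_probe_ratio",
                "n_repeats",
                "stability_threshold",
                "high_stability_threshold",
                "nzv_freq_ratio",
                "nzv_unique_frac",
                "bootstrap_subjects",
            )
        },
        "models": {name: spec.family for name, spec in model_specs.items()},
        "n_boot": n_boot if compute_ci else None,
        "ci_level": ci_level if compute_ci else None,
    }
    return EvaluationRun(results=results, folds=fold_infos, manifest=manifest)
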