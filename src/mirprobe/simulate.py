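"""Synthetic Cp-matrix generator.

Emulates the statistical structure of a serum-miRNA focus-panel qPCR study:
179 target assays measured in three small cohorts (healthy controls, lung
cancer without brain metastases, lung cancer with brain metastases), plus
spike-in controls and hemolysis markers, with an analytic detection limit at
Cp 37 that right-censors late-amplifying targets.

The measurement model is additive on the Cp scale:

    Cp[f, s] = baseline(f) + shift(s) + effect(f, group(s)) + eps[f, s]

with ``shift ~ N(0, sample_shift_sd)`` a per-sample technical offset (library
yield / input variation), ``eps ~ N(0, noise_sd)`` well noise, and planted
group effects in cycles (positive delta_cp = later amplification = lower
abundance = downregulation).  Target rows are right-censored at the detection
limit and flagged; control rows are reported uncensored so that quality rules
defined above the limit (spike-in Cp > 37) remain observable.

Random streams are derived per (seed, purpose) so that, e.g., adding a
hemolysis injection does not perturb the noise draws of unrelated cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    CONTROL_ASSAYS,
    HEMOLYSIS_MARKERS,
    SPIKEIN_CONTROLS,
    ConfigurationError,
    CpMatrix,
)

#: Fixed control-assay baselines (cycles).  Spike-ins are added at known
#: amounts so their Cp is tight across samples; the hemolysis pair is set so
#: that the clean-serum delta Cp(23a) - Cp(451) = 3, well under the 7-cycle
#: hemolysis threshold.
CONTROL_BASELINES: dict[str, float] = {
    "UniSp2": 20.0,
    "UniSp4": 26.5,
    "UniSp6": 19.0,
    "miR-23a": 24.0,
    "miR-451": 21.0,
}

_STREAMS = {"baseline": 0, "shift": 1, "noise": 2, "failure": 3}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[purpose],)))


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect: ``delta_cp`` cycles added to one group's mean.

    Positive ``delta_cp`` delays amplification, i.e. downregulation; the true
    log ratio of the affected group versus any unaffected control group is
    ``-delta_cp`` when no censoring occurs.
    """

    feature_id: str
    group: str
    delta_cp: float


@dataclass
class SimulationConfig:
    """Study geometry and noise model for the generator.

    Defaults reproduce the cohort the analysis assumes: 179 miRNA assays over
    groups HC=6 / LC=7 / LC_BM=6 with detection limit 37 cycles.
    """

    n_features: int = 179
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 6, "LC": 7, "LC_BM": 6}
    )
    baseline_cp_range: tuple[float, float] = (20.0, 33.0)
    noise_sd: float = 0.8
    sample_shift_sd: float = 0.5
    detection_limit: float = 37.0
    planted_effects: tuple[EffectSpec, ...] = ()
    hemolysis_samples: tuple[tuple[int, float], ...] = ()
    spikein_failure_samples: tuple[int, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if not self.group_sizes or any(n < 1 for n in self.group_sizes.values()):
            raise ConfigurationError("all group sizes must be >= 1")
        lo, hi = self.baseline_cp_range
        if not (0 < lo <= hi < self.detection_limit):
            raise ConfigurationError(
                "baseline_cp_range must lie within (0, detection_limit)"
            )
        if self.noise_sd < 0 or self.sample_shift_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        feature_ids = set(self.feature_ids())
        for eff in self.planted_effects:
            if eff.group not in self.group_sizes:
                raise ConfigurationError(f"effect targets unknown group {eff.group!r}")
            if eff.feature_id not in feature_ids:
                raise ConfigurationError(
                    f"effect targets unknown feature {eff.feature_id!r}"
                )
        n_samples = sum(self.group_sizes.values())
        for idx, _ in self.hemolysis_samples:
            if not 0 <= idx < n_samples:
                raise ConfigurationError(f"hemolysis sample index {idx} out of range")
        for idx in self.spikein_failure_samples:
            if not 0 <= idx < n_samples:
                raise ConfigurationError(f"spike-in failure index {idx} out of range")

    def feature_ids(self) -> list[str]:
        return [f"miR-sim-{i + 1:03d}" for i in range(self.n_features)]

    def sample_ids(self) -> list[str]:
        ids = []
        for group, n in self.group_sizes.items():
            ids.extend(f"{group}_{i + 1:02d}" for i in range(n))
        return ids

    def sample_groups(self) -> pd.Series:
        labels = []
        for group, n in self.group_sizes.items():
            labels.extend([group] * n)
        return pd.Series(labels, index=self.sample_ids(), name="group")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_feature_ids: frozenset[str]
    #: feature x group table of true log ratios (0 where nothing was planted;
    #: -delta_cp for a planted feature in its target group, pre-censoring).
    true_log_ratios: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "planted_feature_ids": sorted(self.planted_feature_ids),
            "true_log_ratios": {
                g: self.true_log_ratios[g].to_dict() for g in self.true_log_ratios.columns
            },
        }


def generate_cp_matrix(config: SimulationConfig) -> tuple[CpMatrix, GroundTruth]:
    """Draw one Cp matrix (targets + control rows) and its ground truth.

    Deterministic for a fixed ``config.seed``: the same config yields
    bit-identical output on every call.
    """
    config.validate()
    features = config.feature_ids()
    if CONTROL_ASSAYS & set(features):
        raise ConfigurationError("feature ids collide with reserved control names")
    samples = config.sample_ids()
    groups = config.sample_groups()
    control_rows = list(SPIKEIN_CONTROLS) + list(HEMOLYSIS_MARKERS)
    assays = features + control_rows

    baseline = pd.Series(
        np.concatenate(
            [
                _rng(config.seed, "baseline").uniform(
                    *config.baseline_cp_range, size=config.n_features
                ),
                [CONTROL_BASELINES[c] for c in control_rows],
            ]
        ),
        index=assays,
    )
    shift = _rng(config.seed, "shift").normal(0.0, config.sample_shift_sd, len(samples))
    noise = _rng(config.seed, "noise").normal(
        0.0, config.noise_sd, size=(len(assays), len(samples))
    )

    cp = baseline.to_numpy()[:, None] + shift[None, :] + noise
    values = pd.DataFrame(cp, index=assays, columns=samples)

    truth_lr = pd.DataFrame(0.0, index=features, columns=list(config.group_sizes))
    for eff in config.planted_effects:
        cols = groups.index[groups == eff.group]
        values.loc[eff.feature_id, cols] += eff.delta_cp
        truth_lr.loc[eff.feature_id, eff.group] += -eff.delta_cp

    # right-censor target rows only; control rows stay observable above 37
    censored = pd.DataFrame(False, index=assays, columns=samples)
    target_block = values.loc[features]
    over = target_block > config.detection_limit
    censored.loc[features] = over.to_numpy()
    values.loc[features] = target_block.where(~over, config.detection_limit)

    for idx in config.spikein_failure_samples:
        values.loc[list(SPIKEIN_CONTROLS), samples[idx]] = config.detection_limit + 1.5

    matrix = CpMatrix(values=values, groups=groups, censored=censored)
    for idx, delta in config.hemolysis_samples:
        matrix = inject_hemolysis(matrix, samples[idx], delta)

    truth = GroundTruth(
        planted_feature_ids=frozenset(e.feature_id for e in config.planted_effects),
        true_log_ratios=truth_lr,
    )
    return matrix, truth


def inject_hemolysis(matrix: CpMatrix, sample_id: str, delta: float) -> CpMatrix:
    """Return a copy with red-cell contamination injected into one sample.

    Hemolysis releases erythrocyte miR-451 into serum, which advances its
    amplification: the miR-451 Cp drops by ``delta`` cycles, raising the
    Cp(miR-23a) - Cp(miR-451) quality delta by the same amount.  Every other
    cell is untouched.
    """
    marker_23a, marker_451 = HEMOLYSIS_MARKERS
    if marker_451 not in matrix.values.index or marker_23a not in matrix.values.index:
        raise ConfigurationError("hemolysis marker rows missing from matrix")
    if not matrix.has_sample(sample_id):
        raise ConfigurationError(f"unknown sample {sample_id!r}")
    out = matrix.copy()
    out.values.loc[marker_451, sample_id] -= delta
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: same study conditions, different random draw."""
    return replace(config, seed=seed)
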