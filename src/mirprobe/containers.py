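"""In-memory containers for qPCR panel data.

The raw measurement object is a quantification-cycle (Cp) matrix: one row per
assay (miRNA targets plus exogenous spike-in controls and hemolysis marker
assays), one column per serum sample.  Lower Cp means higher abundance.
Control assays live in the same matrix as the miRNA targets, distinguished by
a reserved name set, mirroring how focus-panel exports lay out their plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: Exogenous spike-ins monitoring RNA extraction (UniSp2/4) and cDNA
#: synthesis (UniSp6) efficiency.
SPIKEIN_CONTROLS: tuple[str, ...] = ("UniSp2", "UniSp4", "UniSp6")

#: Hemolysis markers: miR-451 is erythrocyte-enriched, so red-cell
#: contamination lowers its Cp and inflates Cp(miR-23a) - Cp(miR-451).
HEMOLYSIS_MARKERS: tuple[str, str] = ("miR-23a", "miR-451")

#: All control-assay rows excluded from relative quantification.
CONTROL_ASSAYS: frozenset[str] = frozenset(SPIKEIN_CONTROLS) | frozenset(HEMOLYSIS_MARKERS)

#: Canonical cohort labels: healthy controls, lung cancer without brain
#: metastases, lung cancer with brain metastases.
GROUP_LABELS: tuple[str, ...] = ("HC", "LC", "LC_BM")


class MirprobeError(Exception):
    """Base error for this package."""


class ConfigurationError(MirprobeError):
    """Invalid configuration or malformed input structure."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise ConfigurationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class CpMatrix:
    """Assay x sample quantification-cycle matrix with group labels.

    Parameters
    ----------
    values
        Cp values, index = assay ids, columns = sample ids.  ``NaN`` marks a
        missing/undetermined well.
    groups
        Sample id -> group label, aligned with ``values.columns``.
    censored
        Boolean mask of the same shape as ``values``; ``True`` where the
        measurement hit the detection limit and was right-censored.
    """

    values: pd.DataFrame
    groups: pd.Series
    censored: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "assay id")
        _check_unique(self.values.columns, "sample id")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ConfigurationError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        else:
            if not (
                self.censored.index.equals(self.values.index)
                and self.censored.columns.equals(self.values.columns)
            ):
                raise ConfigurationError("censored mask not aligned with values")
            self.censored = self.censored.astype(bool)

    # -- basic views ------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def mirna_assays(self) -> list[str]:
        """Target assays, i.e. every row that is not a reserved control."""
        return [a for a in self.values.index if a not in CONTROL_ASSAYS]

    def has_sample(self, sample_id: str) -> bool:
        return sample_id in self.values.columns

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    # -- restricted copies ------------------------------------------------

    def select_samples(self, sample_ids: Iterable[str]) -> "CpMatrix":
        ids = list(sample_ids)
        unknown = [s for s in ids if s not in self.values.columns]
        if unknown:
            raise ConfigurationError(f"unknown sample ids: {unknown}")
        return CpMatrix(
            values=self.values[ids].copy(),
            groups=self.groups.loc[ids].copy(),
            censored=self.censored[ids].copy(),
        )

    def copy(self) -> "CpMatrix":
        return CpMatrix(self.values.copy(), self.groups.copy(), self.censored.copy())


@dataclass
class ExpressionMatrix:
    """Per-miRNA, per-sample base-2 log ratios after comparative-Cp normalization.

    Each cell is LR = -(Cp_sample - mean Cp over the control group), so the
    fold change relative to the control group is ``2**LR``.
    """

    values: pd.DataFrame
    groups: pd.Series
    control_group: str
    censored: pd.DataFrame | None = None
    dropped_features: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def to_feature_table(self) -> pd.DataFrame:
        """Samples x features table in the orientation sklearn expects."""
        return self.values.T.copy()

    def labels_for(self, positive: Iterable[str], negative: Iterable[str]) -> pd.Series:
        """Binary labels (1 = positive) restricted to the named groups."""
        pos, neg = set(positive), set(negative)
        overlap = pos & neg
        if overlap:
            raise ConfigurationError(f"contrast classes overlap: {sorted(overlap)}")
        keep = self.groups.isin(pos | neg)
        y = self.groups[keep].isin(pos).astype(int)
        y.name = "label"
        return y


def validate_groups(groups: pd.Series, allowed: Iterable[str] | None = None) -> None:
    allowed_set = set(GROUP_LABELS if allowed is None else allowed)
    bad = sorted(set(groups.dropna().unique()) - allowed_set)
    if bad:
        raise ConfigurationError(
            f"unknown group labels {bad}; expected subset of {sorted(allowed_set)}"
        )
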