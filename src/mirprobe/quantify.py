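"""Comparative-Cp relative quantification.

For each miRNA target the per-sample delta Cp is taken against the mean Cp of
the control group:

    dCp[f, s] = Cp[f, s] - mean(Cp[f, control samples])
    LR[f, s]  = -dCp[f, s]          (base-2 log ratio)
    FC        = 2**LR               (fold change)

The sign convention follows the comparative-Cp method: late amplification
(higher Cp) means lower abundance, so downregulated targets carry negative
log ratios.  An LR above +1 is called upregulation and below -1
downregulation; both calls are strict.

Group-level logFC is the difference of group mean log ratios (equivalently
the log of the geometric-mean fold change), the standard choice on the Cp
scale.  Censored Cp values are used at the detection limit by default
("use-at-limit"); pass ``censored_policy="drop"`` to treat them as missing.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .containers import ConfigurationError, CpMatrix, ExpressionMatrix

CensoredPolicy = Literal["use-at-limit", "drop"]


def control_means(
    matrix: CpMatrix,
    control_group: str,
    censored_policy: CensoredPolicy = "use-at-limit",
) -> pd.Series:
    """Per-feature arithmetic mean Cp across the control group's samples.

    Missing wells are skipped; a feature with no non-missing control value
    yields NaN (flagged and excluded downstream).
    """
    controls = matrix.group_samples(control_group)
    if not controls:
        raise ConfigurationError(f"control group {control_group!r} has no samples")
    features = matrix.mirna_assays
    block = matrix.values.loc[features, controls]
    if censored_policy == "drop":
        block = block.where(~matrix.censored.loc[features, controls])
    elif censored_policy != "use-at-limit":
        raise ConfigurationError(f"unknown censored_policy {censored_policy!r}")
    return block.mean(axis=1, skipna=True)


def log_ratio(
    matrix: CpMatrix,
    control_group: str,
    censored_policy: CensoredPolicy = "use-at-limit",
) -> ExpressionMatrix:
    """Comparative-Cp normalization of every target against the control mean."""
    means = control_means(matrix, control_group, censored_policy)
    features = matrix.mirna_assays
    block = matrix.values.loc[features]
    if censored_policy == "drop":
        block = block.where(~matrix.censored.loc[features])
    dropped = tuple(means.index[means.isna()])
    keep = [f for f in features if f not in set(dropped)]
    lr = -(block.loc[keep].sub(means.loc[keep], axis=0))
    return ExpressionMatrix(
        values=lr,
        groups=matrix.groups.copy(),
        control_group=control_group,
        censored=matrix.censored.loc[keep].copy(),
        dropped_features=dropped,
    )


def fold_change(lr):
    """Fold change 2**LR (scalar, array or Series)."""
    return 2.0 ** np.asarray(lr) if not np.isscalar(lr) else 2.0 ** lr


def regulation_call(lr) -> str | np.ndarray:
    """Classify a log ratio: 'up' iff LR > 1, 'down' iff LR < -1, else 'none'."""
    arr = np.asarray(lr, dtype=float)
    out = np.where(arr > 1.0, "up", np.where(arr < -1.0, "down", "none"))
    return out.item() if out.ndim == 0 else out


def group_logfc(expr: ExpressionMatrix, group_a: str, group_b: str) -> pd.Series:
    """Per-feature logFC = mean LR in ``group_a`` minus mean LR in ``group_b``.

    Because both groups share the same control-group reference this equals
    minus the difference of group mean Cps; features all-missing in either
    group get NaN.
    """
    a = expr.group_samples(group_a)
    b = expr.group_samples(group_b)
    if not a or not b:
        raise ConfigurationError("both contrast groups must be non-empty")
    logfc = expr.values[a].mean(axis=1, skipna=True) - expr.values[b].mean(axis=1, skipna=True)
    logfc.name = f"logFC[{group_a}-{group_b}]"
    return logfc


# report rounding mirrors the conventional table layout: FC to 6 decimals,
# logFC to 2, p-values to 3
ROUNDING = {"fc": 6, "log_fc": 2, "p_value": 3}


def round_report(table: pd.DataFrame, rounding: dict[str, int] | None = None) -> pd.DataFrame:
    rounding = rounding or ROUNDING
    out = table.copy()
    for col, nd in rounding.items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    return out
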