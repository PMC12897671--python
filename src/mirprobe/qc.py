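"""Sample-level quality control for serum qPCR panels.

Two rules, both strict inequalities as worded in standard panel protocols:

* a spike-in control (UniSp2/UniSp4 for RNA extraction, UniSp6 for cDNA
  synthesis) with Cp exceeding 37 indicates poor sample quality or low yield;
* a hemolysis delta Cp(miR-23a) - Cp(miR-451) greater than 7 indicates
  significant red-cell contamination.

Boundary values (Cp exactly 37, delta exactly 7) pass.  Failing samples are
excluded outright, never imputed, and QC precedes every statistical step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import HEMOLYSIS_MARKERS, SPIKEIN_CONTROLS, CpMatrix, MirprobeError


class QCError(MirprobeError):
    """Raised for unanswerable QC queries or when no sample survives QC."""


@dataclass(frozen=True)
class QCThresholds:
    max_control_cp: float = 37.0
    max_hemolysis_delta: float = 7.0
    spikein_names: tuple[str, ...] = SPIKEIN_CONTROLS
    hemolysis_pair: tuple[str, str] = HEMOLYSIS_MARKERS

    def __post_init__(self) -> None:
        if not (np.isfinite(self.max_control_cp) and self.max_control_cp > 0):
            raise QCError("max_control_cp must be finite and positive")
        if not (np.isfinite(self.max_hemolysis_delta) and self.max_hemolysis_delta > 0):
            raise QCError("max_hemolysis_delta must be finite and positive")


@dataclass
class SampleQCRecord:
    sample_id: str
    spikein_cps: dict[str, float]
    hemolysis_delta: float
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # invariant: pass status and reasons agree
        assert self.passed == (len(self.fail_reasons) == 0)


@dataclass
class QCReport:
    records: list[SampleQCRecord]
    thresholds: QCThresholds

    @property
    def passing_samples(self) -> list[str]:
        return [r.sample_id for r in self.records if r.passed]

    @property
    def failing_samples(self) -> list[str]:
        return [r.sample_id for r in self.records if not r.passed]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"sample_id": r.sample_id}
            row.update({name: r.spikein_cps.get(name, np.nan) for name in self.thresholds.spikein_names})
            row["hemolysis_delta"] = r.hemolysis_delta
            row["passed"] = r.passed
            row["fail_reasons"] = ";".join(r.fail_reasons)
            rows.append(row)
        return pd.DataFrame(rows)


def hemolysis_delta(
    matrix: CpMatrix, sample_id: str, pair: tuple[str, str] = HEMOLYSIS_MARKERS
) -> float:
    """Cp(miR-23a) - Cp(miR-451) for one sample.

    Hemolysis lowers the miR-451 Cp, so larger deltas mean worse
    contamination.
    """
    marker_23a, marker_451 = pair
    for marker in pair:
        if marker not in matrix.values.index:
            raise QCError(f"hemolysis marker row {marker!r} missing")
        value = matrix.values.loc[marker, sample_id]
        if pd.isna(value):
            raise QCError(f"hemolysis marker {marker!r} missing for sample {sample_id!r}")
    return float(matrix.values.loc[marker_23a, sample_id] - matrix.values.loc[marker_451, sample_id])


def evaluate_sample(
    matrix: CpMatrix, sample_id: str, thresholds: QCThresholds | None = None
) -> SampleQCRecord:
    """Apply both QC rules to one sample; missing controls count as failures."""
    thresholds = thresholds or QCThresholds()
    if not matrix.has_sample(sample_id):
        raise QCError(f"unknown sample {sample_id!r}")

    reasons: list[str] = []
    spikein_cps: dict[str, float] = {}
    for name in thresholds.spikein_names:
        if name not in matrix.values.index:
            spikein_cps[name] = np.nan
            reasons.append(f"spike-in {name} missing")
            continue
        cp = matrix.values.loc[name, sample_id]
        spikein_cps[name] = float(cp) if pd.notna(cp) else np.nan
        if pd.isna(cp):
            reasons.append(f"spike-in {name} missing")
        elif cp > thresholds.max_control_cp:  # strict: exactly 37 passes
            reasons.append(
                f"spike-in {name} Cp {float(cp):.2f} exceeds {thresholds.max_control_cp:g}"
            )

    try:
        delta = hemolysis_delta(matrix, sample_id, thresholds.hemolysis_pair)
    except QCError as exc:
        delta = np.nan
        reasons.append(str(exc))
    else:
        if delta > thresholds.max_hemolysis_delta:  # strict: exactly 7 passes
            reasons.append(
                f"hemolysis delta {delta:.2f} exceeds {thresholds.max_hemolysis_delta:g}"
            )

    return SampleQCRecord(
        sample_id=sample_id,
        spikein_cps=spikein_cps,
        hemolysis_delta=delta,
        passed=not reasons,
        fail_reasons=reasons,
    )


def apply_qc(
    matrix: CpMatrix, thresholds: QCThresholds | None = None
) -> tuple[CpMatrix, QCReport]:
    """Evaluate every sample and return the matrix restricted to passers.

    Control rows are retained in the filtered matrix (they are dropped later,
    at quantification).  Raises :class:`QCError` if nothing survives.
    """
    thresholds = thresholds or QCThresholds()
    if not matrix.samples:
        raise QCError("empty matrix")
    records = [evaluate_sample(matrix, s, thresholds) for s in matrix.samples]
    report = QCReport(records=records, thresholds=thresholds)
    passing = report.passing_samples
    if not passing:
        raise QCError("no samples passed QC; pipeline halted")
    return matrix.select_samples(passing), report
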