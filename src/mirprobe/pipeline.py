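"""End-to-end pipeline: QC -> quantification -> DE -> selection -> evaluation.

A :class:`RunConfig` (YAML or JSON) names the input tables, thresholds,
selection parameters, contrasts, models and the global seed; ``run_pipeline``
executes the stages in order and writes every artifact plus a replay manifest
(config hash, per-fold seeds, package/library versions).  Reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .plotting import roc_points
from .containers import ConfigurationError, GROUP_LABELS, validate_groups
from .diffexpr import de_table
from .io import (
    read_cp_table,
    write_expression,
    write_json,
)
from .nested_eval import (
    ContrastSpec,
    default_model_specs,
    run_outer_loocv,
)
from .probe_select import (
    ProbeSelectionParams,
    near_zero_variance_filter,
    stability_selection,
)
from .qc import QCThresholds, apply_qc
from .quantify import log_ratio, round_report

logger = logging.getLogger(__name__)


def parse_contrast(text: str, groups: tuple[str, ...] = GROUP_LABELS) -> ContrastSpec:
    """Parse ``"POS:NEG"`` where each side joins groups with ``+``; ``REST``
    on the negative side means every other group."""
    try:
        pos_txt, neg_txt = text.split(":")
    except ValueError as exc:
        raise ConfigurationError(f"contrast {text!r} must be 'POS:NEG'") from exc
    positive = tuple(pos_txt.split("+"))
    if neg_txt == "REST":
        negative = tuple(g for g in groups if g not in positive)
    else:
        negative = tuple(neg_txt.split("+"))
    name = f"{'+'.join(positive)}_vs_{'+'.join(negative)}"
    return ContrastSpec(name=name, positive=positive, negative=negative)


@dataclass
class RunConfig:
    cp_table: str
    metadata: str
    output_dir: str
    control_group: str = "HC"
    qc: QCThresholds = field(default_factory=QCThresholds)
    selection: ProbeSelectionParams = field(default_factory=ProbeSelectionParams)
    de_contrasts: tuple[tuple[str, str], ...] = (("LC", "HC"), ("LC_BM", "HC"))
    eval_contrast: str = "LC_BM:REST"
    models: tuple[str, ...] = ("glmnet", "svm", "rf")
    rf_n_estimators: int = 500
    n_boot: int = 2000
    ci_level: float = 0.95
    seed: int = 0
    alpha: float = 0.05
    censored_policy: str = "use-at-limit"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        qc_cfg = QCThresholds(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in data.pop("qc", {}).items()
        })
        sel_cfg = ProbeSelectionParams(**data.pop("selection", {}))
        for key in ("de_contrasts",):
            if key in data:
                data[key] = tuple(tuple(c) for c in data[key])
        if "models" in data:
            data["models"] = tuple(data["models"])
        cfg = cls(qc=qc_cfg, selection=sel_cfg, **data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("cp_table", "metadata"):
            if not Path(getattr(self, attr)).exists():
                raise ConfigurationError(f"{attr} path does not exist: {getattr(self, attr)}")
        unknown = set(self.models) - {"glmnet", "svm", "rf"}
        if unknown:
            raise ConfigurationError(f"unknown models: {sorted(unknown)}")

    def to_payload(self) -> dict:
        return {
            **{k: v for k, v in asdict(self).items() if k not in ("qc", "selection")},
            "qc": asdict(self.qc) if not isinstance(self.qc, dict) else self.qc,
            "selection": asdict(self.selection),
        }

    def digest(self) -> str:
        payload = self.to_payload()
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest.  Partial artifacts are kept
    on stage failure, with the manifest noting the failing stage."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": config.digest(),
        "config": json.loads(json.dumps(config.to_payload(), default=str)),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    manifest_path = out / "manifest.json"
    try:
        # QC
        matrix = read_cp_table(config.cp_table, config.metadata)
        validate_groups(matrix.groups)
        matrix, report = apply_qc(matrix, config.qc)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        write_json(
            {
                "passing": report.passing_samples,
                "failing": report.failing_samples,
                "records": [
                    {
                        "sample_id": r.sample_id,
                        "spikein_cps": r.spikein_cps,
                        "hemolysis_delta": None if r.hemolysis_delta != r.hemolysis_delta else r.hemolysis_delta,
                        "passed": r.passed,
                        "fail_reasons": r.fail_reasons,
                    }
                    for r in report.records
                ],
            },
            out / "qc_report.json",
        )
        manifest["stages"].append("qc")
        manifest["n_samples_passed"] = len(report.passing_samples)

        # quantification
        expr = log_ratio(matrix, config.control_group, config.censored_policy)
        write_expression(expr, out / "log_ratios.tsv")
        manifest["stages"].append("quantify")

        # differential expression per contrast
        for a, b in config.de_contrasts:
            table = de_table(expr, (a, b), alpha=config.alpha)
            round_report(table).to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t", index=False)
        manifest["stages"].append("diffexpr")

        # exploratory full-dataset stability selection
        contrast = parse_contrast(config.eval_contrast)
        y = contrast.labels(expr.groups)
        X = expr.to_feature_table().loc[y.index]
        surviving = near_zero_variance_filter(
            X, config.selection.nzv_freq_ratio, config.selection.nzv_unique_frac
        )
        sel_params = replace(config.selection, seed=config.seed)
        table = stability_selection(X[surviving], y.to_numpy(), sel_params)
        table.to_frame().to_csv(out / "stability.tsv", sep="\t", index=False)
        manifest["stages"].append("select")

        # nested evaluation
        specs = {
            k: v
            for k, v in default_model_specs(n_estimators=config.rf_n_estimators).items()
            if k in config.models
        }
        run = run_outer_loocv(
            X,
            y,
            select_params=sel_params,
            model_specs=specs,
            seed=config.seed,
            n_boot=config.n_boot,
            ci_level=config.ci_level,
        )
        write_json(run.to_dict(), out / "evaluation.json")
        for name, res in run.results.items():
            fpr, tpr = roc_points(res.fold_records)
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                out / f"roc_{name}.tsv", sep="\t", index=False
            )
        manifest["stages"].append("evaluate")
        manifest["fold_seeds"] = run.manifest["fold_seeds"]
        manifest["auc"] = {name: res.auc for name, res in run.results.items()}
    except Exception as exc:
        manifest["failed_stage"] = _next_stage(manifest["stages"])
        manifest["error"] = str(exc)
        write_json(manifest, manifest_path)
        raise
    write_json(manifest, manifest_path)
    return manifest


_STAGE_ORDER = ["qc", "quantify", "diffexpr", "select", "evaluate"]


def _next_stage(done: list[str]) -> str:
    for stage in _STAGE_ORDER:
        if stage not in done:
            return stage
    return "finalize"
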