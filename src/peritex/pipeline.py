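"""Cohort-level orchestration: manifest -> features -> study report.

``run_pipeline`` reads a cohort manifest (CSV with columns ``subject_id,
image_path, mask_path, label`` and optional ``age, sex``), extracts the full
texture profile per subject, runs the selection/screening/prediction workflow
and writes all artifacts (wide and tidy feature CSVs, selection JSON,
univariate/ROC/regression tables, prediction-ROC curve points, and a
structured log with a config hash).  Identical config and seed give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import ExtractionProfile, extract_all
from .imaging import read_image, read_mask
from .selection import FeatureMatrix
from .stats import StudyReport, run_study

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("peritex")


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    positive_label: str = "A"
    selection_k: int = 10
    alpha: float = 0.05
    covariate_columns: tuple[str, ...] = ()
    extended_percentiles: bool = False
    log_level: str = "INFO"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: StudyReport
    features: pd.DataFrame
    labels: np.ndarray
    excluded: list[dict]
    config_hash: str


def run_pipeline(config: RunConfig) -> PipelineResult:
    logging.basicConfig(level=config.log_level)
    manifest = pd.read_csv(config.manifest)
    required = {"subject_id", "image_path", "mask_path", "label"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    profile = (
        ExtractionProfile.extended() if config.extended_percentiles else ExtractionProfile()
    )
    base = Path(config.manifest).parent
    rows, ids, labels, excluded = [], [], [], []
    for rec in manifest.to_dict(orient="records"):
        try:
            image = read_image(_resolve(rec["image_path"], base))
            mask = read_mask(_resolve(rec["mask_path"], base))
            fv = extract_all(image, mask, profile=profile)
        except Exception as exc:
            log.warning("excluding subject %s: %s", rec["subject_id"], exc)
            excluded.append({"subject_id": rec["subject_id"], "reason": str(exc)})
            continue
        rows.append(fv.to_dict())
        ids.append(str(rec["subject_id"]))
        labels.append(rec["label"] == config.positive_label)

    labels = np.array(labels, dtype=bool)
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise RuntimeError(
            f"fewer than 3 subjects per class survived extraction "
            f"({int(labels.sum())} positive / {int((~labels).sum())} negative)"
        )
    wide = pd.DataFrame(rows, index=ids)
    # features with any missing value are dropped from statistics (logged)
    n_nan = int(wide.isna().any(axis=0).sum())
    if n_nan:
        log.info("dropping %d features undefined for at least one subject", n_nan)
    usable = wide.dropna(axis=1)
    M = FeatureMatrix(
        subjects=ids,
        features=list(usable.columns),
        values=usable.to_numpy(),
        labels=labels,
    )
    covariates = None
    if config.covariate_columns:
        covariates = manifest.set_index(manifest["subject_id"].astype(str)).loc[
            ids, list(config.covariate_columns)
        ]
    report = run_study(M, covariates=covariates, k=config.selection_k, alpha=config.alpha)
    result = PipelineResult(
        report=report,
        features=wide,
        labels=labels,
        excluded=excluded,
        config_hash=config.hash(),
    )
    _write_artifacts(result, config)
    return result


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _resolve(path: str, base: Path) -> Path:
    p = Path(path)
    return p if p.is_absolute() else base / p


def _write_artifacts(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep = result.report

    result.features.rename_axis("subject_id").to_csv(out / "features_wide.csv")
    tidy = result.features.rename_axis("subject_id").reset_index().melt(
        id_vars="subject_id", var_name="feature", value_name="value"
    )
    tidy.to_csv(out / "features_tidy.csv", index=False)

    (out / "selection.json").write_text(
        json.dumps(
            {
                "fisher": [list(t) for t in rep.fisher.ranked],
                "poe_acc": [list(t) for t in rep.poe_acc.ranked],
                "union": rep.union,
                "overlap": rep.overlap,
            },
            indent=2,
        )
    )
    rep.univariate.to_csv(out / "univariate.csv")
    if rep.roc_per_feature:
        pd.DataFrame(
            {
                "feature": name,
                "auc": r.auc,
                "auc_ci_low": r.auc_ci[0],
                "auc_ci_high": r.auc_ci[1],
                "p_vs_half": r.p_vs_half,
                "youden": r.youden,
                "criterion": r.criterion,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for name, r in rep.roc_per_feature.items()
        ).to_csv(out / "roc_per_feature.csv", index=False)
    if rep.regression is not None:
        rep.regression.table.to_csv(out / "regression.csv")
        _roc_curve_csv(
            rep.regression.predicted, result.labels, out / "prediction_roc_curve.csv"
        )

    payload = rep.to_dict()
    payload["config"] = asdict(config)
    payload["config_hash"] = result.config_hash
    payload["software_version"] = __version__
    payload["excluded"] = result.excluded
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=_jsonable))


def _roc_curve_csv(scores: np.ndarray, labels: np.ndarray, path: Path) -> None:
    """Operating points ("positive if score > t") of the combined model."""
    thresholds = np.unique(scores)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    rows = [
        {
            "threshold": float(t),
            "sensitivity": float((scores[labels] > t).sum() / n_pos),
            "specificity": float((scores[~labels] <= t).sum() / n_neg),
        }
        for t in thresholds
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
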