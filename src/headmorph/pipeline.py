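"""End-to-end orchestration: per-subject measurement and cohort study runs.

`run_measure` turns a manifest of per-subject tissue maps plus a ventricle
mask into one metrics row per subject (the 11-metric battery plus the 2D
plane measurements).  `run_study` turns a metrics table with group/age
columns into the full statistical report: demographics, the primary
head-circumference ANCOVA with effect size and required sample size, the
MANCOVA with post hocs, absolute-difference ANCOVAs, the stepwise regression
path, and the SVM classification block.  Every report embeds the
configuration hash and seed, so equal configs reproduce byte-identical
results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, cohort_stats, planimetry, volumetry
from .errors import HeadmorphError
from .phantom import METRIC_COLUMNS
from .volume_io import TissueSet, canonicalize, read_mask, read_volume

logger = logging.getLogger("headmorph")

#: Secondary morphological outcomes entering the MANCOVA by default (all
#: metrics except the primary outcome, head circumference).
DEFAULT_MANCOVA_OUTCOMES = tuple(m for m in METRIC_COLUMNS if m != "head_circumference_cm")


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run; defaults are the reference settings."""

    manifest: str | None = None
    mask_path: str | None = None
    output_dir: str = "."
    fwhm_mm: float = 4.0
    threshold: float = 0.5
    plane_z: float = 0.0
    p_enter: float = 0.05
    p_remove: float = 0.10
    svm_c: float = 1.0
    train_fraction: float = 0.8
    seed: int = 0
    canonicalize_inputs: bool = True
    mancova_outcomes: tuple[str, ...] = DEFAULT_MANCOVA_OUTCOMES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mancova_outcomes"] = list(self.mancova_outcomes)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if "mancova_outcomes" in d:
            d["mancova_outcomes"] = tuple(d["mancova_outcomes"])
        return cls(**d)


MANIFEST_COLUMNS = ("subject_id", "gm", "wm", "csf", "bone", "soft")


def measure_subject(ts: TissueSet, ventricle_mask, config: RunConfig) -> dict:
    """All 11 cohort metrics plus plane metrics for one subject."""
    comp = volumetry.compartment_volumes(ts, ventricle_mask)
    lat = volumetry.laterality_metrics(ts, ventricle_mask)
    mesh = volumetry.ventricular_surface_area(ts.csf, ventricle_mask)
    plane = planimetry.measure_plane_metrics(
        ts, target_world_z=config.plane_z, fwhm_mm=config.fwhm_mm, threshold=config.threshold
    )
    return {
        "head_circumference_cm": plane.circumference_cm,
        "icv_ml": comp.icv,
        "brain_ml": comp.brain,
        "gm_ml": comp.gm,
        "wm_ml": comp.wm,
        "csf_total_ml": comp.csf_total,
        "csf_subarachnoid_ml": comp.csf_subarachnoid,
        "csf_ventricular_ml": comp.csf_ventricular,
        "ventricular_sa_cm2": mesh.area_cm2,
        "ventricular_ai": lat.ventricular.ai,
        "total_csf_ai": lat.total_csf.ai,
        "ventricular_absdiff_ml": lat.ventricular.absdiff_ml,
        "total_csf_absdiff_ml": lat.total_csf.absdiff_ml,
        "length_cm": plane.length_cm,
        "width_cm": plane.width_cm,
        "cephalic_index": plane.cephalic_index,
        "shape_class": plane.shape_class.value,
        "head_area_cm2": plane.head_area_cm2,
        "icv_area_cm2": plane.icv_area_cm2,
        "brain_area_cm2": plane.brain_area_cm2,
        "plane_world_z": plane.world_z,
    }


def run_measure(config: RunConfig, out_csv=None) -> pd.DataFrame:
    """Measure every subject in the manifest; failures are logged, not fatal."""
    if config.manifest is None or config.mask_path is None:
        raise HeadmorphError("run_measure needs both a manifest and a ventricle mask path")
    manifest = pd.read_csv(config.manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise HeadmorphError(f"manifest is missing columns: {missing}")
    mask = read_mask(config.mask_path)
    rows = []
    for _, entry in manifest.iterrows():
        sid = entry["subject_id"]
        try:
            vols = {}
            for tissue in ("gm", "wm", "csf", "bone", "soft"):
                vol = read_volume(entry[tissue], probability=True)
                vols[tissue] = canonicalize(vol) if config.canonicalize_inputs else vol
            ts = TissueSet(**vols)
            row = {"subject_id": sid}
            for col in ("group", "age", "iq", "handedness"):
                if col in manifest.columns:
                    row[col] = entry[col]
            row |= measure_subject(ts, mask, config)
            rows.append(row)
        except Exception as exc:
            logger.error("subject %s failed: %s", sid, exc)
    if not rows:
        raise HeadmorphError("no subject could be measured")
    table = pd.DataFrame(rows)
    table.attrs["config_hash"] = config.config_hash()
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def run_study(config: RunConfig, table: pd.DataFrame, out_json=None) -> dict:
    """Full cohort statistics + classification report on a metrics table."""
    required = {"group", "age", "head_circumference_cm"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise HeadmorphError(f"metrics table is missing columns: {missing}")

    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n": {g: int((table["group"] == g).sum()) for g in pd.unique(table["group"])},
    }

    demo: dict = {"age": cohort_stats.two_sample_t(table["age"], table["group"])}
    if "iq" in table.columns and table["iq"].notna().sum() >= 4:
        ok = table["iq"].notna()
        demo["iq"] = cohort_stats.two_sample_t(table.loc[ok, "iq"], table.loc[ok, "group"])
    if "handedness" in table.columns and table["handedness"].notna().any():
        counts = pd.crosstab(table["group"], table["handedness"])
        chi2, df, p = cohort_stats.chi_square_independence(counts.to_numpy())
        demo["handedness"] = {"chi2": chi2, "df": df, "p_value": p}
    report["demographics"] = demo

    primary = cohort_stats.ancova_group(table, "head_circumference_cm", covariates=["age"])
    report["primary_ancova"] = primary
    if primary.cohens_d is not None and np.isfinite(primary.cohens_d) and primary.cohens_d != 0:
        report["required_n_per_group"] = cohort_stats.required_sample_size(
            abs(primary.cohens_d), alpha=0.05, power=0.80
        )

    for col in ("cephalic_index", "head_area_cm2", "icv_area_cm2", "brain_area_cm2"):
        if col in table.columns:
            report.setdefault("plane_t_tests", {})[col] = cohort_stats.two_sample_t(
                table[col], table["group"]
            )

    outcomes = [m for m in config.mancova_outcomes if m in table.columns]
    if outcomes:
        report["mancova"] = cohort_stats.mancova(table, outcomes, covariates=["age"])

    for absdiff, volume in (
        ("ventricular_absdiff_ml", "csf_ventricular_ml"),
        ("total_csf_absdiff_ml", "csf_total_ml"),
    ):
        if absdiff in table.columns and volume in table.columns:
            report.setdefault("absdiff_ancova", {})[absdiff] = cohort_stats.ancova_group(
                table, absdiff, covariates=["age"], extra_covariates=[volume]
            )

    candidates = [m for m in METRIC_COLUMNS if m != "head_circumference_cm" and m in table.columns]
    report["stepwise"] = cohort_stats.stepwise_regression(
        table, "head_circumference_cm", candidates, p_enter=config.p_enter, p_remove=config.p_remove
    )

    features = [m for m in METRIC_COLUMNS if m in table.columns]
    if len(features) >= 2 and table["group"].nunique() == 2:
        train, test = classifier.stratified_split(
            table, train_fraction=config.train_fraction, seed=config.seed
        )
        ftrain, ftest = classifier.prepare_features(train, test, feature_cols=features)
        model = classifier.fit_linear_svm(ftrain, C=config.svm_c)
        rep = classifier.evaluate(model, ftest)
        report["svm"] = {
            "train_n": len(train),
            "test_n": len(test),
            "report": rep,
            "weight_contributions_pct": classifier.weight_contributions(model),
        }

    report = _jsonify(report)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
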