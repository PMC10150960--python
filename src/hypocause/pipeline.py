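"""End-to-end pipeline: simulate -> featurize -> associate -> classify -> report.

Every stage persists its intermediates under the output directory (diaries/,
features.csv, assoc/, report/) along with ``manifest.json`` recording all
seeds and stage parameters; a rerun with the same config reproduces the same
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import AssociationConfig, multiple_regression_report, single_variable_scan
from .classify import ClassifierSpec, run_cv_experiment
from .diary import read_diary_tables, write_diary_tables
from .features import WindowConfig, featurize_cohort, registry_schema
from .report import render_text
from .simulate import CohortConfig, EffectProfile, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    classifier_specs: tuple[ClassifierSpec, ...] = (
        ClassifierSpec(scenario="ovr:ACTIVITY"),
    )
    run_association: bool = True
    out_dir: str = "hypocause_run"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cohort = d.get("cohort", {})
        if "effect_profile" in cohort:
            ep = cohort.pop("effect_profile")
            cohort["effect_profile"] = (
                EffectProfile.zeroed() if ep == "null" else EffectProfile(**ep)
                if isinstance(ep, dict) else EffectProfile()
            )
        from .classify import SFFSConfig
        from .nn import NNConfig

        def spec_of(s: dict) -> ClassifierSpec:
            s = dict(s)
            if isinstance(s.get("sffs"), dict):
                s["sffs"] = SFFSConfig(**s["sffs"])
            if isinstance(s.get("nn"), dict):
                s["nn"] = NNConfig(**s["nn"])
            return ClassifierSpec(**s)

        specs = tuple(
            spec_of(s) for s in d.get("classifier_specs", [{"scenario": "ovr:ACTIVITY"}])
        )
        return cls(
            cohort=CohortConfig(**cohort),
            window=WindowConfig(**d.get("window", {})),
            association=AssociationConfig(**d.get("association", {})),
            classifier_specs=specs,
            run_association=d.get("run_association", True),
            out_dir=d.get("out_dir", "hypocause_run"),
        )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the artifact directory.

    Stage failures propagate with stage context; partial outputs are left in
    place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/4: simulate cohort (n=%d)", config.cohort.n_subjects)
    diaries, truth = generate_cohort(config.cohort)
    write_diary_tables(diaries, out / "diaries")
    truth.to_csv(out / "diaries" / "ground_truth.csv")

    log.info("stage 2/4: featurize")
    diaries = read_diary_tables(out / "diaries")  # read back: exercises the I/O contract
    features = featurize_cohort(diaries, config.window)
    features.to_csv(out / "features.csv", index=False)
    (out / "features_schema.json").write_text(json.dumps(registry_schema(), indent=2))

    assoc_multiple = None
    if config.run_association:
        log.info("stage 3/4: association analysis")
        assoc_dir = out / "assoc"
        assoc_dir.mkdir(exist_ok=True)
        scans = [
            single_variable_scan(features, cat, config.association)
            for cat in ("ACTIVITY", "FOOD", "MEDICATION")
        ]
        pd.concat(scans, ignore_index=True).to_csv(assoc_dir / "single_scan.csv", index=False)
        assoc_multiple = multiple_regression_report(features, config.association)
        assoc_multiple.to_csv(assoc_dir / "multiple_regression.csv", index=False)

    log.info("stage 4/4: classification experiments (%d specs)", len(config.classifier_specs))
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    summaries = []
    for spec in config.classifier_specs:
        cv = run_cv_experiment(features, spec)
        tag = f"{spec.scenario.replace(':', '_')}_{spec.feature_space}_{spec.objective}"
        cv.fold_metrics.to_csv(report_dir / f"cv_report_{tag}.csv", index=False)
        (report_dir / f"selected_features_{tag}.json").write_text(
            json.dumps(cv.selected_features, indent=2)
        )
        summaries.append(cv.summary())
    cv_summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    cv_summary.to_csv(report_dir / "cv_summary.csv", index=False)

    (out / "summary.txt").write_text(render_text(assoc_multiple, cv_summary))
    manifest = {
        "hypocause_version": __version__,
        "config": _jsonable(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
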