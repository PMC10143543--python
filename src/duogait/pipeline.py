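"""End-to-end orchestration: simulate -> extract -> compare -> classify.

Every stage writes its tables under the output directory and logs its
parameter provenance; all randomness flows from the single config seed,
so identical config + seed runs produce byte-identical reports (the log
file is the only per-run artifact outside that contract).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import agreement, classify, imu, insole
from .config import RunConfig
from .io import write_feature_table
from .simulate import CohortBundle, generate_cohort

log = logging.getLogger("duogait")


def extract_cohort_features(cohort: CohortBundle, config: RunConfig
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both pipelines over every session; one feature row per session."""
    ins_rows, imu_rows = [], []
    for s in cohort.sessions:
        sid = s.session_id
        try:
            _, feats = insole.extract_insole_features(
                s.insole, thresholds=config.thresholds,
                preprocess_config=config.preprocess,
                printed_formula=config.printed_formula)
            ins_rows.append({"session_id": sid, **feats.session.to_dict()})
        except insole.NoStepsError:
            log.warning("insole: no steps detected in %s", sid)
            ins_rows.append({"session_id": sid})
        _, feats = imu.extract_imu_features(
            s.imu_left, s.imu_right, params=config.peaks,
            bout_config=config.bouts)
        imu_rows.append({"session_id": sid, **feats.session.to_dict()})
    return pd.DataFrame(ins_rows), pd.DataFrame(imu_rows)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns the artifact paths.

    Stages: cohort simulation (raw recordings + manifest), feature
    extraction for both systems, cross-system agreement report, and
    impairment classification over the three feature sets.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if config.verbosity else logging.WARNING)
    artifacts: dict[str, str] = {}
    try:
        log.info("simulate: seed=%d subjects=%d", config.simulation.seed,
                 config.simulation.n_subjects)
        cohort = generate_cohort(config.simulation, out_dir=out / "cohort")
        artifacts["manifest"] = str(out / "cohort" / "manifest.csv")

        log.info("extract: %d sessions", len(cohort.sessions))
        ins_feat, imu_feat = extract_cohort_features(cohort, config)
        artifacts["insole_features"] = str(
            write_feature_table(ins_feat, out / "insole_features.csv"))
        artifacts["imu_features"] = str(
            write_feature_table(imu_feat, out / "imu_features.csv"))

        log.info("compare: cross-system agreement")
        paired = agreement.build_paired_table(ins_feat.dropna(), imu_feat,
                                              cohort.manifest)
        result = agreement.compare_systems(paired)
        artifacts["agreement_report"] = str(write_feature_table(
            result.to_frame(), out / "agreement_report.csv"))
        if config.make_plots:
            agreement.save_agreement_plots(paired, result, out / "plots")

        log.info("classify: %s", ", ".join(classify.FEATURE_SETS))
        reports = classify.run_all_feature_sets(
            ins_feat.dropna(), imu_feat, cohort.manifest, config.ml)
        metric_frames, importance_frames = [], []
        for fs, rep in reports.items():
            m = rep.metrics.copy()
            m.insert(0, "classifier", m.index)
            m.insert(0, "feature_set", fs)
            metric_frames.append(m.reset_index(drop=True))
            if rep.importances is not None:
                imp = rep.importances.head(20).copy()
                imp.insert(0, "rank", range(1, len(imp) + 1))
                imp.insert(0, "feature_set", fs)
                importance_frames.append(imp)
        artifacts["classification_report"] = str(write_feature_table(
            pd.concat(metric_frames, ignore_index=True),
            out / "classification_report.csv"))
        if importance_frames:
            artifacts["importance_report"] = str(write_feature_table(
                pd.concat(importance_frames, ignore_index=True),
                out / "importance_report.csv"))

        with open(out / "provenance.json", "w") as fh:
            json.dump(config.provenance(), fh, indent=2, sort_keys=True)
        artifacts["provenance"] = str(out / "provenance.json")
        log.info("done")
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts
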