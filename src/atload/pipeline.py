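"""Pipeline orchestration: simulate -> QC -> estimate -> summarize ->
subsample -> correlate.

Two execution paths share the same stage logic:

* :func:`run_pipeline` runs file-based stages under an output directory,
  each re-runnable from the previous stage's CSVs, with a run manifest
  (config hash + seed) and a plain-text log naming every dropped
  recording and excluded participant.
* :func:`analyze_cohort` streams an in-memory synthetic cohort through
  QC, estimation and summarization without touching disk — the practical
  path for large cohorts, since a multi-day cohort is tens of millions of
  samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .cohort_stats import correlation_table
from .config import RunConfig
from .cumulative_load import (
    CumulativeLoadSummary,
    LoadThresholds,
    ParticipantLoadSummary,
    aggregate_participant,
    combine_summaries,
    summarize_series,
)
from .insole_io import (
    CohortManifest,
    InsoleRecording,
    read_manifest,
    read_clinical_table,
    read_recording,
    write_manifest,
    write_recording,
)
from .signal_qc import QCReport, check_adherence, qc_recording
from .subsampling import subsampling_curve
from .synthetic_data import (
    Artifact,
    CohortBundle,
    EffectSpec,
    simulate_cohort,
    write_cohort,
)
from .tendon_load import GRAVITY_N_PER_KG, SensorGeometry, estimate_tendon_load

__all__ = ["run_pipeline", "analyze_cohort", "CohortAnalysis", "PipelineResult"]

logger = logging.getLogger(__name__)

ArtifactFn = Callable[[str, int, int], Sequence[Artifact]]


@dataclass
class CohortAnalysis:
    """Summaries and QC outcomes of one cohort pass."""

    day_summaries: dict[str, list[CumulativeLoadSummary]]
    participant_summaries: list[ParticipantLoadSummary]
    qc_reports: list[QCReport]
    dropped_recordings: list[str]
    excluded_participants: list[str]

    @property
    def kept_participants(self) -> list[ParticipantLoadSummary]:
        return [
            s
            for s in self.participant_summaries
            if s.participant_id not in self.excluded_participants
        ]

    def participant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "participant_id": s.participant_id,
                    "l_overall": s.l_overall,
                    "l_high": s.l_high,
                    "t_load_h": s.t_load_h,
                    "n_days": s.n_summaries,
                    "defined": s.defined,
                    "excluded": s.participant_id in self.excluded_participants,
                }
                for s in self.participant_summaries
            ]
        )


def _summarize_recordings(
    recordings: Sequence[InsoleRecording],
    bw_n: float,
    geometry: SensorGeometry,
    thresholds: LoadThresholds,
    qc_enabled: bool,
    qc_kwargs: dict,
    qc_reports: list[QCReport],
    dropped: list[str],
    participant_id: str,
) -> CumulativeLoadSummary:
    """QC + estimate + summarize one day's sessions into a day summary."""
    per_session: list[CumulativeLoadSummary] = []
    for rec in recordings:
        if qc_enabled:
            rec, report = qc_recording(rec, bw_n, geometry=geometry, **qc_kwargs)
            qc_reports.append(report)
            if report.disposition == "drop":
                dropped.append(report.recording_id)
                logger.info(
                    "dropped %s: %s", report.recording_id, ",".join(report.flags)
                )
                continue
        series = estimate_tendon_load(rec, geometry, bw_n)
        per_session.append(
            summarize_series(series, thresholds, participant_id=participant_id)
        )
    return combine_summaries(per_session, scope="day")


def analyze_cohort(
    bundle: CohortBundle,
    qc_enabled: bool = True,
    adherence_min_h: float = 1.0,
    artifact_fn: ArtifactFn | None = None,
    qc_kwargs: dict | None = None,
) -> CohortAnalysis:
    """Stream a synthetic cohort through QC, estimation and aggregation.

    ``artifact_fn(pid, day, session) -> [Artifact, ...]`` lets callers
    corrupt selected sessions on the way in (for QC studies); the clean
    generator output is unaffected.
    """
    qc_kwargs = qc_kwargs or {}
    day_summaries: dict[str, list[CumulativeLoadSummary]] = {}
    qc_reports: list[QCReport] = []
    dropped: list[str] = []
    for profile, day, recordings in bundle.iter_days():
        pid = profile.participant_id
        if artifact_fn is not None:
            recordings = [
                bundle_inject(bundle, rec, artifact_fn(pid, day, rec.session))
                for rec in recordings
            ]
        day_summary = _summarize_recordings(
            recordings,
            profile.bw_n,
            bundle.geometry,
            bundle.thresholds,
            qc_enabled,
            qc_kwargs,
            qc_reports,
            dropped,
            pid,
        )
        day_summary.participant_id = pid
        day_summaries.setdefault(pid, []).append(day_summary)

    participant_summaries = [
        aggregate_participant(days, participant_id=pid)
        for pid, days in day_summaries.items()
    ]
    excluded = []
    for pid, days in day_summaries.items():
        verdict = check_adherence(
            [d.t_load_h for d in days], min_median_daily_loading_h=adherence_min_h
        )
        if verdict == "exclude":
            excluded.append(pid)
            logger.info("excluded %s: median daily loading below threshold", pid)
    return CohortAnalysis(
        day_summaries=day_summaries,
        participant_summaries=participant_summaries,
        qc_reports=qc_reports,
        dropped_recordings=dropped,
        excluded_participants=excluded,
    )


def bundle_inject(
    bundle: CohortBundle, rec: InsoleRecording, artifacts: Sequence[Artifact]
) -> InsoleRecording:
    from .synthetic_data import inject_artifacts

    if not artifacts:
        return rec
    profile = bundle.profile(rec.participant_id)
    return inject_artifacts(rec, artifacts, bundle.geometry, profile.bw_n)


# --------------------------------------------------------------------------
# File-based stages
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    outdir: Path
    paths: dict[str, Path] = field(default_factory=dict)


def _bw_lookup(clinical: pd.DataFrame) -> dict[str, float]:
    return {
        row["participant_id"]: row["mass_kg"] * GRAVITY_N_PER_KG
        for _, row in clinical.iterrows()
    }


def stage_simulate(config: RunConfig, outdir: Path) -> Path:
    """Generate the synthetic cohort and write it under outdir/cohort."""
    cohort_dir = outdir / "cohort"
    spec = EffectSpec().scaled_noise(config.cohort.noise_scale)
    bundle = simulate_cohort(
        n_participants=config.cohort.n_participants,
        n_days=config.cohort.n_days,
        effect_spec=spec,
        seed=config.seed,
        geometry=config.geometry.to_geometry(),
        thresholds=config.thresholds.to_thresholds(),
        sample_rate_hz=config.sample_rate_hz,
        volume_range=(config.cohort.volume_min, config.cohort.volume_max),
        day_scale=config.cohort.day_scale,
    )
    write_cohort(bundle, cohort_dir)
    logger.info("simulate: wrote cohort to %s", cohort_dir)
    return cohort_dir


def stage_qc(config: RunConfig, outdir: Path) -> Path:
    """Drift-correct and screen every manifest session; write kept copies."""
    cohort_dir = outdir / "cohort"
    qc_dir = outdir / "qc"
    (qc_dir / "sessions").mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(cohort_dir / "manifest.csv")
    clinical = read_clinical_table(cohort_dir / "clinical.csv")
    bw = _bw_lookup(clinical)
    geometry = config.geometry.to_geometry()
    rules = config.qc.to_rules()
    thresholds = config.thresholds.to_thresholds()

    kept_rows, report_rows = [], []
    for _, row in manifest.table.iterrows():
        rec = read_recording(cohort_dir / row["path"])
        corrected, report = qc_recording(
            rec,
            bw[row["participant_id"]],
            geometry=geometry,
            window_s=config.qc.window_s,
            tolerance_bw=config.qc.tolerance_bw,
            rules=rules,
            thresholds=thresholds,
        )
        report_rows.append(
            {
                "recording_id": report.recording_id,
                "offset_heel_n": report.offsets_n[0],
                "offset_mid_n": report.offsets_n[1],
                "offset_fore_n": report.offsets_n[2],
                "corrected": report.corrected,
                "flags": "|".join(report.flags),
                "disposition": report.disposition,
            }
        )
        if report.disposition == "drop":
            logger.info("qc: dropped %s (%s)", report.recording_id, report.flags)
            continue
        out_path = f"sessions/{corrected.session_id}.csv"
        write_recording(corrected, qc_dir / out_path)
        kept_rows.append({**row.to_dict(), "path": out_path})
    write_manifest(
        CohortManifest(pd.DataFrame(kept_rows, columns=list(CohortManifest.COLUMNS))),
        qc_dir / "manifest.csv",
    )
    pd.DataFrame(report_rows).to_csv(qc_dir / "qc_report.csv", index=False)
    logger.info("qc: kept %d / %d sessions", len(kept_rows), len(manifest))
    return qc_dir


def stage_summarize(config: RunConfig, outdir: Path) -> Path:
    """Estimate tendon load and write recording/day/participant summaries."""
    qc_dir = outdir / "qc"
    cohort_dir = outdir / "cohort"
    summaries_dir = outdir / "summaries"
    summaries_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(qc_dir / "manifest.csv")
    clinical = read_clinical_table(cohort_dir / "clinical.csv")
    bw = _bw_lookup(clinical)
    geometry = config.geometry.to_geometry()
    thresholds = config.thresholds.to_thresholds()

    rec_rows = []
    day_map: dict[str, dict[int, list[CumulativeLoadSummary]]] = {}
    for _, row in manifest.table.iterrows():
        rec = read_recording(qc_dir / row["path"])
        pid = rec.participant_id
        series = estimate_tendon_load(rec, geometry, bw[pid])
        s = summarize_series(series, thresholds, participant_id=pid)
        rec_rows.append(
            {
                "participant_id": pid,
                "day": rec.day,
                "session": rec.session,
                "t_load_h": s.t_load_h,
                "i_overall": s.i_overall,
                "t_high_h": s.t_high_h,
                "i_high": s.i_high,
            }
        )
        day_map.setdefault(pid, {}).setdefault(rec.day, []).append(s)
    pd.DataFrame(rec_rows).to_csv(summaries_dir / "recording_summaries.csv", index=False)

    day_rows = []
    participant_rows = []
    for pid in sorted(day_map):
        days = []
        for day in sorted(day_map[pid]):
            d = combine_summaries(day_map[pid][day], scope="day")
            d.participant_id = pid
            days.append((day, d))
            day_rows.append(
                {
                    "participant_id": pid,
                    "day": day,
                    "t_load_h": d.t_load_h,
                    "i_overall": d.i_overall,
                    "t_high_h": d.t_high_h,
                    "i_high": d.i_high,
                }
            )
        summary = aggregate_participant([d for _, d in days], participant_id=pid)
        verdict = check_adherence(
            [d.t_load_h for _, d in days],
            min_median_daily_loading_h=config.qc.adherence_min_h,
        )
        if verdict == "exclude":
            logger.info("summarize: excluded %s (low median daily loading)", pid)
        participant_rows.append(
            {
                "participant_id": pid,
                "l_overall": summary.l_overall,
                "l_high": summary.l_high,
                "t_load_h": summary.t_load_h,
                "n_days": summary.n_summaries,
                "defined": summary.defined,
                "excluded": verdict == "exclude",
            }
        )
    pd.DataFrame(day_rows).to_csv(summaries_dir / "day_summaries.csv", index=False)
    pd.DataFrame(participant_rows).to_csv(
        summaries_dir / "participant_summaries.csv", index=False
    )
    return summaries_dir


def _day_summaries_from_csv(path: Path) -> dict[str, list[CumulativeLoadSummary]]:
    table = pd.read_csv(path, dtype={"participant_id": str})
    out: dict[str, list[CumulativeLoadSummary]] = {}
    for _, row in table.sort_values(["participant_id", "day"]).iterrows():
        out.setdefault(row["participant_id"], []).append(
            CumulativeLoadSummary(
                t_load_h=row["t_load_h"],
                i_overall=row["i_overall"],
                t_high_h=row["t_high_h"],
                i_high=row["i_high"],
                scope="day",
                participant_id=row["participant_id"],
            )
        )
    return out


def stage_subsample(config: RunConfig, outdir: Path) -> Path:
    """Day-subsampling MAPE/r curves from the day summaries."""
    summaries_dir = outdir / "summaries"
    sub_dir = outdir / "subsampling"
    sub_dir.mkdir(parents=True, exist_ok=True)
    participants = pd.read_csv(
        summaries_dir / "participant_summaries.csv", dtype={"participant_id": str}
    )
    keep = set(participants[~participants["excluded"]]["participant_id"])
    day_summaries = {
        pid: days
        for pid, days in _day_summaries_from_csv(
            summaries_dir / "day_summaries.csv"
        ).items()
        if pid in keep
    }
    result = subsampling_curve(day_summaries)
    result.to_frame().to_csv(sub_dir / "subsampling.csv", index=False)
    return sub_dir


def stage_correlate(config: RunConfig, outdir: Path) -> Path:
    """Correlation grid of load measures vs clinical measures."""
    summaries_dir = outdir / "summaries"
    corr_dir = outdir / "correlations"
    corr_dir.mkdir(parents=True, exist_ok=True)
    participants = pd.read_csv(
        summaries_dir / "participant_summaries.csv", dtype={"participant_id": str}
    )
    clinical = read_clinical_table(outdir / "cohort" / "clinical.csv")
    kept = participants[~participants["excluded"] & participants["defined"]]
    summaries = [
        ParticipantLoadSummary(
            participant_id=row["participant_id"],
            l_overall=row["l_overall"],
            l_high=row["l_high"],
            t_load_h=row["t_load_h"],
            n_summaries=int(row["n_days"]),
        )
        for _, row in kept.iterrows()
    ]
    table = correlation_table(summaries, clinical, alpha=config.alpha)
    table.to_csv(corr_dir / "correlations.csv", index=False)
    return corr_dir


_STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "summarize": stage_summarize,
    "subsample": stage_subsample,
    "correlate": stage_correlate,
}


def run_pipeline(
    config: RunConfig,
    outdir: Path | str | None = None,
    stages: Sequence[str] = ("simulate", "qc", "summarize", "subsample", "correlate"),
) -> PipelineResult:
    """Run the requested stages in order under one output directory.

    Writes ``run.json`` (config hash, seed, stages) and appends to
    ``run.log``.  Reruns with the same config and seed reproduce
    identical outputs.
    """
    if config.cohort.n_participants < 1:
        raise ValueError("config requires at least one participant")
    outdir = Path(outdir) if outdir is not None else Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("atload")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        result = PipelineResult(outdir=outdir)
        for name in stages:
            if name not in _STAGES:
                raise ValueError(f"unknown stage {name!r}")
            logger.info("stage %s: start", name)
            result.paths[name] = _STAGES[name](config, outdir)
        (outdir / "run.json").write_text(
            json.dumps(
                {
                    "config_hash": config.config_hash(),
                    "seed": config.seed,
                    "stages": list(stages),
                    "config": config.model_dump(),
                },
                indent=2,
                sort_keys=True,
            )
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return result
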