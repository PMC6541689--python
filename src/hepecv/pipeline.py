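"""End-to-end orchestration of the synthetic ECV experiment.

One call runs: cohort generation → bolus kinetics → MOLLI phantoms at the
pre-contrast and three post-contrast acquisitions → T1 map fitting → ROI
means → ECV records → cohort statistics → report bundle.  Every stage is
also callable on its own (and exposed as a CLI subcommand) so real T1
maps and haematocrit values can reuse the downstream chain.

Randomness is controlled by one master seed; per-subject, per-stage seeds
are derived by stable hashing of ``(master_seed, purpose, subject,
time label)``, so adding a subject or time point never reshuffles the
noise of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig, config_hash
from .ecv import ECVRecord, records_to_frame, subject_ecv_records
from .kinetics import SubjectGroundTruth, cohort_to_frame, generate_cohort
from .molli import (
    PhantomImageSeries,
    label_for_time,
    parse_scheme,
    simulate_phantom,
)
from .stats import CohortSummary, summarize_cohort, summary_table
from .t1fit import RelaxationMap, fit_t1_map

__all__ = ["run_experiment", "run_stage", "derive_seed", "ExperimentResult"]

logger = logging.getLogger(__name__)

#: Fixed rendering used for all CSV output, so runs are byte-comparable.
CSV_FLOAT_FORMAT = "%.6g"


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable sub-seed from the master seed and a purpose path."""
    payload = "|".join([str(master_seed), *map(str, tokens)])
    digest = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class ExperimentResult:
    """Outputs of one full experiment run."""

    ground_truth: pd.DataFrame
    records: pd.DataFrame
    summary: CohortSummary
    outputs: dict[str, Path]


def _scheme_for(config: ExperimentConfig, time_label: str):
    text = config.scheme_pre if time_label == "pre" else config.scheme_post
    return parse_scheme(text, initial_ti=config.initial_ti, base_interval=config.base_interval)


def simulate_subject_series(
    subject: SubjectGroundTruth, config: ExperimentConfig
) -> dict[str, PhantomImageSeries]:
    """All four acquisitions (pre + post times) for one subject."""
    labels = ["pre"] + [label_for_time(t) for t in config.acquisition_times]
    series = {}
    for label in labels:
        series[label] = simulate_phantom(
            subject,
            config.kinetics,
            label,
            scheme=_scheme_for(config, label),
            snr=config.snr,
            seed=derive_seed(config.master_seed, "noise", subject.subject_id, label),
            geometry=config.geometry,
            readout_factor=config.readout_factor,
            noise_model=config.noise_model,
        )
    return series


def measure_subject(
    subject: SubjectGroundTruth, config: ExperimentConfig
) -> list[ECVRecord]:
    """Simulate, fit and extract the ECV records for one subject."""
    series = simulate_subject_series(subject, config)
    maps: dict[str, RelaxationMap] = {
        label: fit_t1_map(s, residual_threshold=config.residual_threshold)
        for label, s in series.items()
    }
    pre_map = maps.pop("pre")
    return subject_ecv_records(
        subject.subject_id,
        pre_map,
        maps,
        config.liver_roi,
        config.blood_roi,
        subject.haematocrit,
        expected_times=tuple(label_for_time(t) for t in config.acquisition_times),
    )


def _fig2_table(records: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Group-mean ECV (percent) per acquisition time."""
    merged = records.merge(truth[["subject_id", "group"]], on="subject_id")
    merged["time_min"] = [
        float(lbl.removeprefix("post")) for lbl in merged["time_label"]
    ]
    out = (
        merged.groupby(["group", "time_min"], sort=True)["ecv"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out["mean_ecv_pct"] = out.pop("mean") * 100.0
    out["sd_ecv_pct"] = out.pop("std") * 100.0
    out = out.rename(columns={"count": "n"})
    return out[["group", "time_min", "n", "mean_ecv_pct", "sd_ecv_pct"]]


def _fig3_tables(records: pd.DataFrame, truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Scatter data: per-subject ECV (percent) vs histology / portal pressure."""
    merged = records.merge(
        truth[["subject_id", "group", "sirius_red_pct", "portal_pressure_mmhg"]],
        on="subject_id",
    )
    merged["ecv_pct"] = merged["ecv"] * 100.0
    cols = ["subject_id", "group", "time_label", "ecv_pct"]
    return {
        "scatter_ecv_vs_sirius_red": merged[cols + ["sirius_red_pct"]],
        "scatter_ecv_vs_portal_pressure": merged[cols + ["portal_pressure_mmhg"]],
    }


def run_experiment(
    config: ExperimentConfig, out_dir: Path | str | None = None
) -> ExperimentResult:
    """Run the full synthetic study; optionally write the report bundle.

    Deterministic for a fixed configuration (the master seed reseeds each
    cohort spec and every phantom's noise).  When ``out_dir`` is given the
    bundle holds: the ground-truth and ECV-record CSVs, the group summary
    table, the group-mean-ECV-vs-time table, the correlation scatter CSVs,
    a markdown report and a provenance JSON.
    """
    subjects: list[SubjectGroundTruth] = []
    for spec in config.cohorts:
        seeded = dataclasses.replace(
            spec, seed=derive_seed(config.master_seed, "cohort", spec.group_label)
        )
        cohort = generate_cohort(seeded)
        logger.info("stage=simulate-cohort group=%s n=%d", spec.group_label, len(cohort))
        subjects.extend(cohort)

    records: list[ECVRecord] = []
    for subject in subjects:
        recs = measure_subject(subject, config)
        records.extend(recs)
    logger.info("stage=measure subjects=%d records=%d", len(subjects), len(records))

    truth_frame = cohort_to_frame(subjects)
    record_frame = records_to_frame(records)
    summary = summarize_cohort(
        record_frame, truth_frame, group_order=tuple(s.group_label for s in config.cohorts)
    )

    outputs: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

        def _write(name: str, frame: pd.DataFrame) -> None:
            path = out_dir / f"{name}.csv"
            frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
            outputs[name] = path

        _write("ground_truth", truth_frame)
        _write("ecv_records", record_frame)
        _write("group_summary", summary_table(summary))
        _write("ecv_vs_time", _fig2_table(record_frame, truth_frame))
        for name, frame in _fig3_tables(record_frame, truth_frame).items():
            _write(name, frame)
        report_path = out_dir / "report.md"
        report_path.write_text(summary.to_markdown())
        outputs["report"] = report_path
        prov_path = out_dir / "provenance.json"
        prov_path.write_text(
            json.dumps(
                {
                    "package_version": __version__,
                    "config_hash": config_hash(config),
                    "master_seed": config.master_seed,
                    "n_subjects": len(subjects),
                    "n_records": len(records),
                },
                indent=2,
            )
        )
        outputs["provenance"] = prov_path
        logger.info("stage=report out_dir=%s files=%d", out_dir, len(outputs))

    return ExperimentResult(
        ground_truth=truth_frame, records=record_frame, summary=summary, outputs=outputs
    )


def replicate_group_mean_ecv(
    spec,
    time_label: str,
    seeds,
    kinetics=None,
    snr: float = 40.0,
    config: ExperimentConfig | None = None,
) -> float:
    """Average recovered group-mean ECV (fraction) over seed replicates.

    Runs the full generate → simulate → fit → ECV chain once per seed for a
    single cohort spec and returns the mean over replicates of the group-mean
    ECV at ``time_label``.  This is the end-to-end parameter-recovery
    protocol used to validate the pipeline against its calibration targets.
    """
    base = config if config is not None else ExperimentConfig()
    means = []
    for seed in seeds:
        cfg = dataclasses.replace(
            base,
            cohorts=(spec,),
            master_seed=int(seed),
            **({"kinetics": kinetics} if kinetics is not None else {}),
            snr=snr,
        )
        result = run_experiment(cfg)
        sub = result.records[result.records["time_label"] == time_label]
        means.append(float(sub["ecv"].mean()))
    return float(np.mean(means))


# ---------------------------------------------------------------------------
# Individual stages (CLI backends, real-data reuse)
# ---------------------------------------------------------------------------


def stage_simulate_cohort(config: ExperimentConfig, out_csv: Path | str) -> pd.DataFrame:
    """Generate all cohorts and write the ground-truth CSV."""
    subjects = []
    for spec in config.cohorts:
        seeded = dataclasses.replace(
            spec, seed=derive_seed(config.master_seed, "cohort", spec.group_label)
        )
        subjects.extend(generate_cohort(seeded))
    frame = cohort_to_frame(subjects)
    Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    return frame


def stage_simulate_scan(
    config: ExperimentConfig,
    truth_csv: Path | str,
    subject_id: str,
    time_label: str,
    out_stem: Path | str,
):
    """Simulate one subject/time-point acquisition and write NIfTI + sidecar."""
    from .kinetics import cohort_from_frame
    from .molli import save_series

    frame = pd.read_csv(truth_csv)
    match = [s for s in cohort_from_frame(frame) if s.subject_id == subject_id]
    if not match:
        raise ValueError(f"subject {subject_id!r} not present in {truth_csv}")
    series = simulate_phantom(
        match[0],
        config.kinetics,
        time_label,
        scheme=_scheme_for(config, time_label),
        snr=config.snr,
        seed=derive_seed(config.master_seed, "noise", subject_id, time_label),
        geometry=config.geometry,
        readout_factor=config.readout_factor,
        noise_model=config.noise_model,
    )
    return save_series(series, out_stem)


def stage_fit(series_stem: Path | str, out_stem: Path | str,
              residual_threshold: float = 0.15):
    """Fit a T1 map from a saved series and write it as NIfTI."""
    from .molli import load_series
    from .t1fit import save_map

    series = load_series(series_stem)
    t1_map = fit_t1_map(series, residual_threshold=residual_threshold)
    return save_map(t1_map, out_stem)


def stage_ecv(in_csv: Path | str, out_csv: Path | str) -> pd.DataFrame:
    """Compute ECV for a table of T1 quadruples + haematocrit.

    The input CSV needs columns ``t1_liver_pre, t1_liver_post,
    t1_blood_pre, t1_blood_post, haematocrit``; an ``ecv`` column is
    appended.
    """
    from .ecv import compute_ecv

    frame = pd.read_csv(in_csv)
    frame["ecv"] = [
        compute_ecv(
            row.t1_liver_pre, row.t1_liver_post, row.t1_blood_pre,
            row.t1_blood_post, row.haematocrit,
        )
        for row in frame.itertuples(index=False)
    ]
    Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    return frame


def stage_stats(
    records_csv: Path | str, truth_csv: Path | str, out_dir: Path | str
) -> CohortSummary:
    """Summarise an ECV-record table against its ground-truth covariates."""
    records = pd.read_csv(records_csv)
    truth = pd.read_csv(truth_csv)
    summary = summarize_cohort(records, truth)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_table(summary).to_csv(
        out_dir / "group_summary.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    (out_dir / "report.md").write_text(summary.to_markdown())
    return summary


_STAGES = {
    "simulate-cohort": stage_simulate_cohort,
    "simulate-scan": stage_simulate_scan,
    "fit-t1": stage_fit,
    "ecv": stage_ecv,
    "stats": stage_stats,
    "run-all": run_experiment,
}


def run_stage(name: str, /, *args, **kwargs):
    """Dispatch one pipeline stage by name (see CLI subcommands)."""
    try:
        fn = _STAGES[name]
    except KeyError:
        raise ValueError(
            f"unknown stage {name!r}; choose from {sorted(_STAGES)}"
        ) from None
    return fn(*args, **kwargs)
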