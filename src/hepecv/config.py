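"""Experiment configuration: one object describing the full synthetic study.

The configuration nests the cohort sampling specs, the kinetic model, the
MOLLI schemes and timing, phantom geometry, ROI placement, acquisition
times and the master seed.  It round-trips through YAML so experiments
are reproducible from a single file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ecv import ROISpec
from .kinetics import CohortSpec, KineticsParams, default_cohort_specs
from .molli import SCHEME_POST, SCHEME_PRE, PhantomGeometry

__all__ = ["ExperimentConfig", "load_config", "save_config", "config_hash"]


def _default_liver_roi() -> ROISpec:
    return ROISpec(center=(32, 22), radius=10.0, region_role="liver")


def _default_blood_roi() -> ROISpec:
    return ROISpec(center=(32, 52), radius=3.0, region_role="blood")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run the synthetic experiment end to end."""

    cohorts: tuple[CohortSpec, ...] = field(
        default_factory=lambda: tuple(default_cohort_specs())
    )
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    scheme_pre: str = SCHEME_PRE
    scheme_post: str = SCHEME_POST
    initial_ti: float = 100.0  # ms
    base_interval: float = 1000.0  # ms
    snr: float = 40.0
    readout_factor: float = 0.8  # T1*/T1 perturbation of the readout train
    noise_model: str = "gaussian"
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    liver_roi: ROISpec = field(default_factory=_default_liver_roi)
    blood_roi: ROISpec = field(default_factory=_default_blood_roi)
    acquisition_times: tuple[float, ...] = (5.0, 15.0, 25.0)  # minutes
    residual_threshold: float = 0.15
    master_seed: int = 0

    def __post_init__(self) -> None:
        times = self.acquisition_times
        if not times:
            raise ValueError("need at least one post-contrast acquisition time")
        if any(t <= 0 for t in times) or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise ValueError("acquisition times must be strictly increasing and positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive (inf for noiseless)")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, float) and np.isinf(obj):
        return ".inf"
    return obj


def _tuple2(v):
    return tuple(int(x) for x in v)


def config_from_dict(data: dict) -> ExperimentConfig:
    """Rebuild an :class:`ExperimentConfig` from a plain (YAML) mapping."""
    data = dict(data)
    cohorts = tuple(CohortSpec(**c) for c in data.pop("cohorts", []))
    if not cohorts:
        cohorts = tuple(default_cohort_specs())
    kinetics = KineticsParams(**data.pop("kinetics", {}))
    geom_d = data.pop("geometry", None)
    geometry = (
        PhantomGeometry(
            shape=_tuple2(geom_d["shape"]),
            liver_center=_tuple2(geom_d["liver_center"]),
            liver_radius=float(geom_d["liver_radius"]),
            aorta_center=_tuple2(geom_d["aorta_center"]),
            aorta_radius=float(geom_d["aorta_radius"]),
        )
        if geom_d
        else PhantomGeometry()
    )

    def _roi(d, fallback):
        if not d:
            return fallback()
        return ROISpec(
            center=_tuple2(d["center"]), radius=float(d["radius"]),
            region_role=d["region_role"],
        )

    liver_roi = _roi(data.pop("liver_roi", None), _default_liver_roi)
    blood_roi = _roi(data.pop("blood_roi", None), _default_blood_roi)
    times = tuple(float(t) for t in data.pop("acquisition_times", (5.0, 15.0, 25.0)))
    snr = data.pop("snr", 40.0)
    snr = np.inf if snr in (".inf", None, "inf") else float(snr)
    return ExperimentConfig(
        cohorts=cohorts,
        kinetics=kinetics,
        geometry=geometry,
        liver_roi=liver_roi,
        blood_roi=blood_roi,
        acquisition_times=times,
        snr=snr,
        **data,
    )


def load_config(path: Path | str) -> ExperimentConfig:
    """Read an experiment configuration from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: ExperimentConfig, path: Path | str) -> None:
    """Write an experiment configuration to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def config_hash(config: ExperimentConfig) -> str:
    """Stable hex digest of the full configuration (for provenance records)."""
    payload = json.dumps(_to_plain(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
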