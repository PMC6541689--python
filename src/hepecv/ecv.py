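"""Extracellular volume fraction from pre-/post-contrast T1 maps.

The ECV fraction is computed from the contrast-induced change in
longitudinal relaxation rate (R1 = 1/T1) of liver tissue relative to the
blood pool, scaled to whole blood by the haematocrit:

    ECV = (1/T1_liver_post - 1/T1_liver_pre)
          / (1/T1_blood_post - 1/T1_blood_pre) * (1 - haematocrit)

ROI protocol: a single circular region in the liver parenchyma (excluding
vasculature via the map's validity mask) and a circular blood-pool region
in the abdominal aorta; the same regions are propagated across all of a
subject's maps, and each post-contrast time point uses its own blood-pool
T1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .t1fit import RelaxationMap

__all__ = [
    "ROISpec",
    "ECVRecord",
    "EquilibriumViolationError",
    "EmptyROIError",
    "compute_ecv",
    "roi_mean",
    "subject_ecv_records",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

ECV_RECORD_COLUMNS = (
    "subject_id",
    "time_label",
    "t1_liver_pre",
    "t1_liver_post",
    "t1_blood_pre",
    "t1_blood_post",
    "haematocrit",
    "ecv",
    "flags",
)


class EquilibriumViolationError(ValueError):
    """Blood pool shows no contrast enhancement; the ECV ratio is undefined."""


class EmptyROIError(ValueError):
    """No valid voxel lies inside the region of interest."""


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest on the map lattice (0-based row/col)."""

    center: tuple[int, int]
    radius: float
    region_role: str  # "liver" or "blood"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("ROI radius must be at least 1 voxel")
        if self.region_role not in ("liver", "blood"):
            raise ValueError("region_role must be 'liver' or 'blood'")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Disc mask: a voxel belongs iff its centre lies within the radius."""
        r0, c0 = self.center
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise ValueError("ROI centre lies outside the image")
        rows, cols = np.indices(shape)
        inside = (rows - r0) ** 2 + (cols - c0) ** 2 <= self.radius**2
        if (
            r0 - self.radius < -0.5
            or c0 - self.radius < -0.5
            or r0 + self.radius > shape[0] - 0.5
            or c0 + self.radius > shape[1] - 0.5
        ):
            raise ValueError("ROI extends outside the image bounds")
        return inside


@dataclass(frozen=True)
class ECVRecord:
    """One subject's T1 quadruple and derived ECV at one post-contrast time."""

    subject_id: str
    time_label: str
    t1_liver_pre: float
    t1_liver_post: float
    t1_blood_pre: float
    t1_blood_post: float
    haematocrit: float
    ecv: float
    flags: tuple[str, ...] = ()


def compute_ecv(
    t1_liver_pre: float,
    t1_liver_post: float,
    t1_blood_pre: float,
    t1_blood_post: float,
    haematocrit: float,
) -> float:
    """ECV fraction from the four T1 values (any single unit) and haematocrit.

    Raises :class:`EquilibriumViolationError` when the blood pool shows no
    enhancement; a negative liver enhancement is reported as a warning and
    the (negative) value returned, so bad fits remain auditable.
    """
    for name, t1 in (
        ("t1_liver_pre", t1_liver_pre),
        ("t1_liver_post", t1_liver_post),
        ("t1_blood_pre", t1_blood_pre),
        ("t1_blood_post", t1_blood_post),
    ):
        if not t1 > 0:
            raise ValueError(f"{name} must be positive, got {t1}")
    if not 0.0 <= haematocrit < 1.0:
        raise ValueError("haematocrit must lie in [0, 1)")
    delta_r1_liver = 1.0 / t1_liver_post - 1.0 / t1_liver_pre
    delta_r1_blood = 1.0 / t1_blood_post - 1.0 / t1_blood_pre
    if delta_r1_blood <= 0:
        raise EquilibriumViolationError(
            "blood-pool T1 did not shorten after contrast; no enhancement to normalise by"
        )
    if delta_r1_liver < 0:
        warnings.warn(
            "negative liver enhancement (post-contrast T1 above pre-contrast); "
            "returning the negative ECV for audit",
            stacklevel=2,
        )
    return delta_r1_liver / delta_r1_blood * (1.0 - haematocrit)


def roi_mean(t1_map: RelaxationMap, roi: ROISpec) -> tuple[float, int]:
    """Mean T1 over the valid voxels of a circular ROI.

    Returns ``(mean_ms, n_voxels)``; invalid voxels are excluded, and an
    ROI with no valid voxel raises :class:`EmptyROIError`.
    """
    inside = roi.mask(t1_map.t1_values.shape)
    use = inside & t1_map.validity_mask
    n = int(use.sum())
    if n == 0:
        raise EmptyROIError(f"ROI at {roi.center} contains no valid voxel")
    return float(t1_map.t1_values[use].mean()), n


def subject_ecv_records(
    subject_id: str,
    pre_map: RelaxationMap,
    post_maps: dict[str, RelaxationMap],
    liver_roi: ROISpec,
    blood_roi: ROISpec,
    haematocrit: float,
    expected_times: tuple[str, ...] = ("post5", "post15", "post25"),
) -> list[ECVRecord]:
    """One :class:`ECVRecord` per post-contrast time point.

    The same two ROIs are reused on every map; each record takes its
    blood-pool T1 from its own time point's map.  A missing time point is
    logged and skipped; physiologically implausible values (no T1
    shortening, ECV outside (0, 1)) are flagged, never silently dropped.
    """
    t1_liver_pre, _ = roi_mean(pre_map, liver_roi)
    t1_blood_pre, _ = roi_mean(pre_map, blood_roi)
    records = []
    for label in expected_times:
        post = post_maps.get(label)
        if post is None:
            logger.warning("subject %s: missing post-contrast map %s; record omitted",
                           subject_id, label)
            continue
        t1_liver_post, _ = roi_mean(post, liver_roi)
        t1_blood_post, _ = roi_mean(post, blood_roi)
        flags = []
        if t1_liver_post >= t1_liver_pre:
            flags.append("no_liver_t1_shortening")
        if t1_blood_post >= t1_blood_pre:
            flags.append("no_blood_t1_shortening")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ecv = compute_ecv(
                    t1_liver_pre, t1_liver_post, t1_blood_pre, t1_blood_post, haematocrit
                )
        except EquilibriumViolationError:
            ecv = float("nan")
        if not 0.0 < ecv < 1.0:
            flags.append("ecv_out_of_range")
        records.append(
            ECVRecord(
                subject_id=subject_id,
                time_label=label,
                t1_liver_pre=t1_liver_pre,
                t1_liver_post=t1_liver_post,
                t1_blood_pre=t1_blood_pre,
                t1_blood_post=t1_blood_post,
                haematocrit=haematocrit,
                ecv=ecv,
                flags=tuple(flags),
            )
        )
    return records


def records_to_frame(records: list[ECVRecord]) -> pd.DataFrame:
    """Tabulate ECV records with the canonical CSV column names."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "time_label": r.time_label,
                "t1_liver_pre": r.t1_liver_pre,
                "t1_liver_post": r.t1_liver_post,
                "t1_blood_pre": r.t1_blood_pre,
                "t1_blood_post": r.t1_blood_post,
                "haematocrit": r.haematocrit,
                "ecv": r.ecv,
                "flags": ";".join(r.flags),
            }
            for r in records
        ],
        columns=list(ECV_RECORD_COLUMNS),
    )
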