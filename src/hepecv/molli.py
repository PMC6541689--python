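"""MOLLI-style inversion-recovery signal and digital phantom simulation.

A modified Look-Locker inversion recovery (MOLLI) acquisition samples the
inversion-recovery curve in grouped readouts.  Schemes are written in the
usual ``n(m)p`` shorthand — readout counts outside parentheses, recovery
pauses inside — e.g. ``4(10)10`` pre-contrast and ``3(6)2(6)8``
post-contrast.  Each voxel's magnitude signal follows the standard
three-parameter model

    S(TI) = | A - B * exp(-TI / T1*) |

where the apparent relaxation time T1* is shortened by the repeated
readouts and related to the true T1 by the Look-Locker correction
T1 = T1* (B/A - 1).  The simulator chooses T1* and B self-consistently
from a configurable readout-perturbation factor so that a correct fitter
recovers the ground-truth T1 exactly in the noiseless case.

Phantoms are small 2-D grids with a liver region and an aortic blood-pool
disc whose ground-truth T1s come from the kinetic model at the acquisition
time; they stand in for the transversal T1 maps of a real scan.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .kinetics import KineticsParams, SubjectGroundTruth, relaxation_rates

__all__ = [
    "MOLLIScheme",
    "IRSignal",
    "PhantomGeometry",
    "PhantomImageSeries",
    "parse_scheme",
    "inversion_times",
    "simulate_signal",
    "simulate_phantom",
    "save_series",
    "load_series",
    "TIME_LABELS",
    "SCHEME_PRE",
    "SCHEME_POST",
]

#: Canonical acquisition time labels and their post-injection minutes.
TIME_LABELS: dict[str, float] = {"pre": 0.0, "post5": 5.0, "post15": 15.0, "post25": 25.0}

_TIME_LABEL_RE = re.compile(r"post(\d+(?:\.\d+)?)")


def time_from_label(label: str) -> float:
    """Minutes post-injection encoded by a time label ('pre' or 'post<min>')."""
    if label == "pre":
        return 0.0
    m = _TIME_LABEL_RE.fullmatch(label)
    if not m:
        raise ValueError(f"unknown time label {label!r}; expected 'pre' or 'post<minutes>'")
    return float(m.group(1))


def label_for_time(t: float) -> str:
    """Inverse of :func:`time_from_label` for post-injection times."""
    if t <= 0:
        raise ValueError("post-injection time must be positive")
    return f"post{t:g}"

SCHEME_PRE = "4(10)10"
SCHEME_POST = "3(6)2(6)8"

#: Region codes in phantom label maps.
LABEL_BACKGROUND, LABEL_LIVER, LABEL_AORTA = 0, 1, 2


@dataclass(frozen=True)
class MOLLIScheme:
    """Inversion-group structure of a MOLLI acquisition.

    ``groups`` is an ordered list of ``(n_readouts, pause)`` with the pause
    (seconds of free recovery after the group) ``None`` for the final group.
    ``initial_ti`` and ``base_interval`` (ms) place the readouts of each
    group on an arithmetic TI ladder; each group is treated as an
    independent inversion experiment.
    """

    groups: tuple[tuple[int, float | None], ...]
    initial_ti: float = 100.0
    base_interval: float = 1000.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("scheme needs at least one inversion group")
        for n, pause in self.groups:
            if n < 1:
                raise ValueError("each group needs at least one readout")
            if pause is not None and pause <= 0:
                raise ValueError("pauses must be positive")
        if self.initial_ti <= 0 or self.base_interval <= 0:
            raise ValueError("timing values must be positive")
        if self.total_readouts < 5:
            raise ValueError(
                "need at least 5 readouts for a stable three-parameter fit"
            )

    @property
    def total_readouts(self) -> int:
        return sum(n for n, _ in self.groups)


_SCHEME_RE = re.compile(r"^\d+(?:\(\d+\)\d+)*$")


def parse_scheme(text: str, initial_ti: float = 100.0, base_interval: float = 1000.0) -> MOLLIScheme:
    """Parse ``n(m)p...`` shorthand into a :class:`MOLLIScheme`.

    ``"4(10)10"`` → two groups of 4 and 10 readouts separated by a 10-s
    pause; ``"3(6)2(6)8"`` → three groups of 3, 2 and 8 readouts.
    """
    text = text.strip()
    if not _SCHEME_RE.match(text):
        bad = re.search(r"[^\d()]", text)
        token = bad.group(0) if bad else text
        raise ValueError(f"malformed MOLLI scheme {text!r} (offending token {token!r})")
    counts = [int(c) for c in re.findall(r"(?:^|\))(\d+)", text)]
    pauses = [float(p) for p in re.findall(r"\((\d+)\)", text)]
    groups = tuple(
        (counts[i], pauses[i] if i < len(pauses) else None) for i in range(len(counts))
    )
    return MOLLIScheme(groups=groups, initial_ti=initial_ti, base_interval=base_interval)


def inversion_times(scheme: MOLLIScheme) -> tuple[np.ndarray, np.ndarray]:
    """Inversion times (ms) and their group indices for all readouts.

    Group ``g`` with ``n`` readouts contributes
    ``initial_ti + j * base_interval`` for ``j = 0..n-1``; groups are
    independent inversion experiments, so their TI ladders restart.
    """
    tis, gidx = [], []
    for g, (n, _pause) in enumerate(scheme.groups):
        for j in range(n):
            tis.append(scheme.initial_ti + j * scheme.base_interval)
            gidx.append(g)
    return np.asarray(tis, dtype=float), np.asarray(gidx, dtype=int)


@dataclass(frozen=True)
class IRSignal:
    """Sampled inversion-recovery magnitudes with their inversion times."""

    inversion_times: np.ndarray  # ms
    magnitudes: np.ndarray
    group_index: np.ndarray
    snr: float
    truth_t1: float | None = None  # ms, simulation only

    def __post_init__(self) -> None:
        if len(self.inversion_times) != len(self.magnitudes):
            raise ValueError("inversion_times and magnitudes must have equal length")


def _model_params(truth_t1: float, readout_factor: float) -> tuple[float, float, float]:
    """(A, B, T1*) self-consistent with the Look-Locker relation."""
    a = 1.0
    t1_star = readout_factor * truth_t1
    b = a * (1.0 + truth_t1 / t1_star)  # so that T1 = T1*(B/A - 1)
    return a, b, t1_star


def signed_recovery(tis: np.ndarray, truth_t1: float, readout_factor: float = 0.8) -> np.ndarray:
    """Noiseless signed recovery curve A - B exp(-TI/T1*)."""
    a, b, t1_star = _model_params(truth_t1, readout_factor)
    return a - b * np.exp(-np.asarray(tis, dtype=float) / t1_star)


def simulate_signal(
    truth_t1: float,
    scheme: MOLLIScheme,
    snr: float = np.inf,
    seed: int | np.random.Generator | None = None,
    readout_factor: float = 0.8,
    noise_model: str = "gaussian",
) -> IRSignal:
    """Simulate one voxel's MOLLI magnitude samples.

    Gaussian noise of SD ``A/snr`` is added to the signed signal before the
    magnitude operation (``snr = inf`` gives exact model samples); the
    ``"rician"`` model adds an independent quadrature noise channel, for
    robustness experiments at low SNR.
    """
    if truth_t1 <= 0:
        raise ValueError("truth_t1 must be positive")
    if not snr > 0:
        raise ValueError("snr must be positive (use inf for noiseless)")
    tis, gidx = inversion_times(scheme)
    signed = signed_recovery(tis, truth_t1, readout_factor)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isinf(snr):
        mags = np.abs(signed)
    else:
        sigma = 1.0 / snr  # A is fixed at 1 signal unit
        if noise_model == "gaussian":
            mags = np.abs(signed + rng.normal(0.0, sigma, signed.shape))
        elif noise_model == "rician":
            mags = np.hypot(
                signed + rng.normal(0.0, sigma, signed.shape),
                rng.normal(0.0, sigma, signed.shape),
            )
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return IRSignal(
        inversion_times=tis, magnitudes=mags, group_index=gidx, snr=snr, truth_t1=truth_t1
    )


# ---------------------------------------------------------------------------
# Digital phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomGeometry:
    """Layout of the 2-D phantom: a liver disc and an aortic disc."""

    shape: tuple[int, int] = (64, 64)
    liver_center: tuple[int, int] = (32, 22)
    liver_radius: float = 14.0
    aorta_center: tuple[int, int] = (32, 52)
    aorta_radius: float = 5.0

    def __post_init__(self) -> None:
        labels = self.label_map()
        # label_map raises on overlap; also require both regions in-bounds
        for center, radius, name in (
            (self.liver_center, self.liver_radius, "liver"),
            (self.aorta_center, self.aorta_radius, "aorta"),
        ):
            r, c = center
            if (
                r - radius < 0
                or c - radius < 0
                or r + radius >= self.shape[0]
                or c + radius >= self.shape[1]
            ):
                raise ValueError(f"{name} region extends outside the image bounds")
        if not labels.any():
            raise ValueError("phantom has no tissue voxels")

    def label_map(self) -> np.ndarray:
        rows, cols = np.indices(self.shape)
        liver = (rows - self.liver_center[0]) ** 2 + (cols - self.liver_center[1]) ** 2 <= (
            self.liver_radius**2
        )
        aorta = (rows - self.aorta_center[0]) ** 2 + (cols - self.aorta_center[1]) ** 2 <= (
            self.aorta_radius**2
        )
        if (liver & aorta).any():
            raise ValueError("liver and aorta regions overlap")
        labels = np.zeros(self.shape, dtype=np.int16)
        labels[liver] = LABEL_LIVER
        labels[aorta] = LABEL_AORTA
        return labels


@dataclass(frozen=True)
class PhantomImageSeries:
    """Per-TI magnitude images of one acquisition plus ground-truth metadata."""

    images: np.ndarray  # (n_ti, rows, cols)
    inversion_times: np.ndarray  # ms
    group_index: np.ndarray
    labels: np.ndarray  # (rows, cols) region codes
    truth_t1: np.ndarray  # (rows, cols) ms, 0 in background
    time_label: str
    scheme_text: str
    snr: float

    def __post_init__(self) -> None:
        if self.images.shape[0] != len(self.inversion_times):
            raise ValueError("one image per inversion time required")
        if self.images.shape[1:] != self.labels.shape:
            raise ValueError("image and label dimensions differ")


def simulate_phantom(
    subject: SubjectGroundTruth,
    params: KineticsParams,
    time_label: str,
    scheme: MOLLIScheme | None = None,
    snr: float = 40.0,
    seed: int | np.random.Generator | None = None,
    geometry: PhantomGeometry | None = None,
    readout_factor: float = 0.8,
    noise_model: str = "gaussian",
) -> PhantomImageSeries:
    """Simulate one subject's T1-mapping acquisition at one time point.

    Region ground-truth T1s come from the kinetic model at the acquisition
    time; the pre-contrast scan defaults to the 4(10)10 scheme and
    post-contrast scans to 3(6)2(6)8.  Background voxels carry zero signal
    (they are masked invalid downstream); tissue voxels get independent
    noise.
    """
    t = time_from_label(time_label)
    if scheme is None:
        scheme = parse_scheme(SCHEME_PRE if time_label == "pre" else SCHEME_POST)
    scheme_text = _scheme_to_text(scheme)
    geometry = geometry or PhantomGeometry()
    labels = geometry.label_map()

    r1_liver, r1_blood = relaxation_rates(t, subject, params)
    truth = np.zeros(geometry.shape, dtype=float)
    truth[labels == LABEL_LIVER] = 1.0 / r1_liver
    truth[labels == LABEL_AORTA] = 1.0 / r1_blood

    tis, gidx = inversion_times(scheme)
    images = np.zeros((len(tis), *geometry.shape), dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for code, t1 in (
        (LABEL_LIVER, 1.0 / r1_liver),
        (LABEL_AORTA, 1.0 / r1_blood),
    ):
        mask = labels == code
        signed = signed_recovery(tis, t1, readout_factor)[:, None]
        signed = np.broadcast_to(signed, (len(tis), int(mask.sum()))).copy()
        if np.isinf(snr):
            mags = np.abs(signed)
        elif noise_model == "gaussian":
            mags = np.abs(signed + rng.normal(0.0, 1.0 / snr, signed.shape))
        elif noise_model == "rician":
            mags = np.hypot(
                signed + rng.normal(0.0, 1.0 / snr, signed.shape),
                rng.normal(0.0, 1.0 / snr, signed.shape),
            )
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
        images[:, mask] = mags

    return PhantomImageSeries(
        images=images,
        inversion_times=tis,
        group_index=gidx,
        labels=labels,
        truth_t1=truth,
        time_label=time_label,
        scheme_text=scheme_text,
        snr=snr,
    )


def _scheme_to_text(scheme: MOLLIScheme) -> str:
    parts = []
    for n, pause in scheme.groups:
        parts.append(str(n))
        if pause is not None:
            parts.append(f"({pause:g})")
    return "".join(parts)


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------


def save_series(series: PhantomImageSeries, stem: Path | str) -> tuple[Path, Path, Path]:
    """Write a series as NIfTI volumes plus a JSON sidecar.

    ``<stem>.nii.gz`` holds one volume per TI (rows × cols × 1 × n_ti),
    ``<stem>_labels.nii.gz`` the region label map, and ``<stem>.json`` the
    inversion times and acquisition metadata.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    img_path = stem.with_suffix(".nii.gz")
    lbl_path = stem.parent / f"{stem.name}_labels.nii.gz"
    json_path = stem.with_suffix(".json")
    data = np.transpose(series.images, (1, 2, 0))[:, :, None, :]
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(img_path))
    nib.save(nib.Nifti1Image(series.labels.astype(np.int16)[:, :, None], np.eye(4)), str(lbl_path))
    sidecar = {
        "inversion_times_ms": series.inversion_times.tolist(),
        "group_index": series.group_index.tolist(),
        "time_label": series.time_label,
        "scheme": series.scheme_text,
        "snr": None if np.isinf(series.snr) else series.snr,
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return img_path, lbl_path, json_path


def load_series(stem: Path | str) -> PhantomImageSeries:
    """Read a series written by :func:`save_series`."""
    stem = Path(stem)
    img = nib.load(str(stem.with_suffix(".nii.gz")))
    lbl_path = stem.parent / f"{stem.name}_labels.nii.gz"
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.asarray(img.dataobj, dtype=float)[:, :, 0, :]
    images = np.transpose(data, (2, 0, 1))
    labels = (
        np.asarray(nib.load(str(lbl_path)).dataobj, dtype=np.int16)[:, :, 0]
        if lbl_path.exists()
        else np.ones(images.shape[1:], dtype=np.int16)
    )
    snr = sidecar.get("snr")
    return PhantomImageSeries(
        images=images,
        inversion_times=np.asarray(sidecar["inversion_times_ms"], dtype=float),
        group_index=np.asarray(
            sidecar.get("group_index", [0] * images.shape[0]), dtype=int
        ),
        labels=labels,
        truth_t1=np.zeros(images.shape[1:]),
        time_label=sidecar.get("time_label", "pre"),
        scheme_text=sidecar.get("scheme", ""),
        snr=np.inf if snr is None else float(snr),
    )
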