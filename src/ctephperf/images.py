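"""Image containers and NIfTI round-trip I/O.

All volumes live on a regular voxel grid with physical spacing in mm.
Axis convention is (x, y, z) = (left-right, anterior-posterior,
inferior-superior); 4D dynamic series carry time as the last axis, the
NIfTI convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError

#: Lobe label coding shared across the package.
LOBE_LABELS: dict[int, str] = {1: "RUL", 2: "RML", 3: "RLL", 4: "LUL", 5: "LLL"}
LOBE_IDS: dict[str, int] = {name: lab for lab, name in LOBE_LABELS.items()}
LOBE_NAMES: tuple[str, ...] = tuple(LOBE_LABELS[k] for k in sorted(LOBE_LABELS))
WHOLE_LUNG = "whole_lung"
ROI_NAMES: tuple[str, ...] = (WHOLE_LUNG,) + LOBE_NAMES


def _affine(spacing) -> np.ndarray:
    return np.diag([float(spacing[0]), float(spacing[1]), float(spacing[2]), 1.0])


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise DataError(f"spacing must be three positive mm values, got {spacing}")
    return spacing


@dataclass
class ScalarMap3D:
    """A 3D scalar image (PBF, PBV or iodine map) with spacing and units.

    Parameters
    ----------
    values : (nx, ny, nz) float array. NaN marks missing voxels.
    spacing : voxel size in mm per axis.
    units : free-text physical units, e.g. ``"mL/100mL/min"``.
    mask : optional boolean volume of valid voxels; defaults to finite values.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DataError(f"expected a 3D volume, got shape {self.values.shape}")
        self.spacing = _check_spacing(self.spacing)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DataError("mask shape does not match values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Voxels that carry a finite value (intersected with `mask`)."""
        finite = np.isfinite(self.values)
        return finite if self.mask is None else (finite & self.mask)

    def save(self, path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.float32), _affine(self.spacing))
        img.header["descrip"] = self.units.encode()[:79]
        nib.save(img, str(path))
        return path

    @classmethod
    def load(cls, path, units: str | None = None) -> "ScalarMap3D":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if units is None:
            units = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
        return cls(np.asarray(img.dataobj, dtype=float), spacing, units=units)


@dataclass
class LobeSegmentation:
    """Integer label volume: 0 background, 1..5 the five lung lobes."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise DataError("label volume must be integer-typed")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def lung_mask(self) -> np.ndarray:
        return self.labels > 0

    def lobe_mask(self, roi: int | str) -> np.ndarray:
        lab = LOBE_IDS[roi] if isinstance(roi, str) else int(roi)
        return self.labels == lab

    def present_lobes(self) -> list[str]:
        present = np.unique(self.labels)
        return [LOBE_LABELS[int(l)] for l in present if int(l) in LOBE_LABELS]

    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def save(self, path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.labels.astype(np.int16), _affine(self.spacing))
        nib.save(img, str(path))
        return path

    @classmethod
    def load(cls, path) -> "LobeSegmentation":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj).astype(np.int16), spacing)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


@dataclass
class DceSeries:
    """A 4D dynamic contrast-enhanced series with per-frame times.

    ``signal`` has shape (nx, ny, nz, n_frames); ``frame_times`` are the
    acquisition times in seconds, strictly increasing. The first
    ``n_baseline`` frames precede contrast arrival and define the signal
    baseline.
    """

    signal: np.ndarray
    frame_times: np.ndarray
    n_baseline: int = 3
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.signal.ndim != 4:
            raise DataError(f"expected a 4D series, got shape {self.signal.shape}")
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.signal.shape[-1]:
            raise DataError("frame_times length must match the number of frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise DataError("frame_times must be strictly increasing")
        if not (1 <= int(self.n_baseline) <= self.signal.shape[-1]):
            raise DataError("n_baseline must be in [1, n_frames]")
        self.n_baseline = int(self.n_baseline)
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_frames(self) -> int:
        return self.signal.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def save(self, path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.signal.astype(np.float32), _affine(self.spacing))
        nib.save(img, str(path))
        sidecar = {"frame_times_s": self.frame_times.tolist(), "n_baseline": self.n_baseline}
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def load(cls, path) -> "DceSeries":
        path = Path(path)
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        meta = json.loads(_sidecar_path(path).read_text())
        return cls(
            np.asarray(img.dataobj, dtype=float),
            np.asarray(meta["frame_times_s"], dtype=float),
            n_baseline=int(meta["n_baseline"]),
            spacing=spacing,
        )
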