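"""Perfusion defect maps (QDM) and defect percentages (QDP).

A binary defect map is obtained by thresholding a perfusion map at
0.7 times the 75th percentile of its in-lung values. The threshold is
computed independently for every subject, modality, scan session and
perfusion parameter — thresholds are never shared across maps. Defect
percentages are reported per lobe (against the lobe volume, or against
the whole-lung volume to express each lobe's contribution) and for the
whole lung.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, DegenerateMapError, ParameterError
from .images import LOBE_NAMES, WHOLE_LUNG, LobeSegmentation, ScalarMap3D, _affine

DEFAULT_QUANTILE = 0.75
DEFAULT_FACTOR = 0.7

REFERENCES = ("lobe_volume", "whole_lung_volume")


def compute_threshold(
    map_: ScalarMap3D,
    lung_mask: np.ndarray,
    quantile: float = DEFAULT_QUANTILE,
    factor: float = DEFAULT_FACTOR,
) -> float:
    """Subject-specific defect threshold: Q75 of in-lung values × 0.7.

    The quantile uses linear interpolation between order statistics.
    Missing (NaN) voxels inside the mask are dropped. A non-positive
    upper quartile makes the threshold meaningless and raises
    :class:`DegenerateMapError`.
    """
    if not (0 < quantile < 1):
        raise ParameterError("quantile must be in (0, 1)")
    if factor <= 0:
        raise ParameterError("threshold factor must be positive")
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.shape != map_.shape:
        raise DataError("lung mask grid does not match the map")
    vals = map_.values[lung_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DataError("lung mask selects no finite voxels")
    q = float(np.quantile(vals, quantile))  # linear interpolation (type 7)
    if q <= 0:
        raise DegenerateMapError(
            f"{quantile:.0%} percentile of in-lung values is {q:.3g} <= 0"
        )
    return factor * q


@dataclass
class DefectMap:
    """Binary defect/healthy classification of lung voxels (QDM).

    ``qdm`` is True where a voxel is classified as perfusion defect;
    it is meaningful only inside ``mask`` (lung voxels with a finite
    map value). ``threshold`` is the map-unit cutoff that produced it.
    """

    qdm: np.ndarray
    mask: np.ndarray
    threshold: float
    source_parameter: str = ""

    def __post_init__(self) -> None:
        self.qdm = np.asarray(self.qdm, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.qdm.shape != self.mask.shape:
            raise DataError("qdm and mask shapes differ")
        if np.any(self.qdm & ~self.mask):
            raise DataError("defect voxels outside the valid mask")

    def save(self, path, spacing=(1.0, 1.0, 1.0)) -> Path:
        """Write as int8 NIfTI (0 outside mask, 1 defect, 2 healthy) + sidecar."""
        path = Path(path)
        coded = np.zeros(self.qdm.shape, dtype=np.int8)
        coded[self.mask] = 2
        coded[self.qdm] = 1
        nib.save(nib.Nifti1Image(coded, _affine(spacing)), str(path))
        meta = {"threshold": self.threshold, "source_parameter": self.source_parameter}
        from .images import _sidecar_path

        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
        return path

    @classmethod
    def load(cls, path) -> "DefectMap":
        from .images import _sidecar_path

        path = Path(path)
        coded = np.asarray(nib.load(str(path)).dataobj).astype(np.int8)
        meta = json.loads(_sidecar_path(path).read_text())
        return cls(
            qdm=coded == 1,
            mask=coded > 0,
            threshold=float(meta["threshold"]),
            source_parameter=str(meta.get("source_parameter", "")),
        )


def make_qdm(
    map_: ScalarMap3D,
    lung_mask: np.ndarray,
    threshold: float | None = None,
    source_parameter: str = "",
    strict: bool = True,
    quantile: float = DEFAULT_QUANTILE,
    factor: float = DEFAULT_FACTOR,
) -> DefectMap:
    """Threshold a perfusion map into a defect map.

    A voxel is defect iff its value is strictly below the threshold
    (``strict=False`` switches to <=). When ``threshold`` is None it is
    computed from this map via :func:`compute_threshold`. Voxels with
    missing (non-finite) values inside the lung are excluded from the
    map's valid mask entirely — they count in neither numerator nor
    denominator downstream.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if threshold is None:
        threshold = compute_threshold(map_, lung_mask, quantile=quantile, factor=factor)
    valid = lung_mask & np.isfinite(map_.values)
    below = map_.values < threshold if strict else map_.values <= threshold
    return DefectMap(
        qdm=below & valid, mask=valid, threshold=float(threshold),
        source_parameter=source_parameter,
    )


def compute_qdp(
    qdm: DefectMap,
    labels: LobeSegmentation,
    reference: str = "lobe_volume",
) -> pd.DataFrame:
    """Defect percentage per ROI as a tidy table.

    With ``reference="lobe_volume"`` each lobe's QDP is the percentage
    of that lobe's voxels classified defect; with
    ``"whole_lung_volume"`` it is the lobe's defect count as a
    percentage of all lung voxels (its contribution to the whole-lung
    QDP). The whole-lung row is always referenced to the whole lung.
    A lobe absent from the segmentation is reported with NaN, not zero.
    """
    if reference not in REFERENCES:
        raise ParameterError(f"reference must be one of {REFERENCES}")
    if labels.shape != qdm.qdm.shape:
        raise DataError("label grid does not match the defect map")
    valid = qdm.mask & labels.lung_mask
    n_lung = int(valid.sum())
    if n_lung == 0:
        raise DataError("no valid lung voxels under the defect map mask")
    n_lung_defect = int((qdm.qdm & valid).sum())

    rows = [
        {
            "roi": WHOLE_LUNG,
            "reference": reference,
            "n_roi": n_lung,
            "n_defect": n_lung_defect,
            "qdp_percent": 100.0 * n_lung_defect / n_lung,
        }
    ]
    for roi in LOBE_NAMES:
        roi_valid = labels.lobe_mask(roi) & qdm.mask
        n_roi = int(roi_valid.sum())
        n_def = int((qdm.qdm & roi_valid).sum())
        denom = n_roi if reference == "lobe_volume" else n_lung
        rows.append(
            {
                "roi": roi,
                "reference": reference,
                "n_roi": n_roi,
                "n_defect": n_def,
                "qdp_percent": 100.0 * n_def / denom if denom > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def qdp_long(
    qdm: DefectMap,
    labels: LobeSegmentation,
    subject_id: str = "",
    phase: str = "",
    modality: str = "",
    parameter: str = "",
) -> pd.DataFrame:
    """Both reference conventions stacked, annotated with cohort keys."""
    tables = [compute_qdp(qdm, labels, reference=ref) for ref in REFERENCES]
    out = pd.concat(tables, ignore_index=True)
    out.insert(0, "subject_id", subject_id)
    out.insert(1, "phase", phase)
    out.insert(2, "modality", modality)
    out.insert(3, "parameter", parameter)
    return out
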