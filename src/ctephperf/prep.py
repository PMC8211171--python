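"""CT iodine-map preprocessing and grid-consistency checks.

The dual-energy CT pulmonary-blood-volume (iodine) maps are denoised
with a 3D Gaussian filter before thresholding. All volumes entering the
defect comparison must be co-registered; this package performs no
registration, it only verifies the grids match.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, ParameterError
from .images import LobeSegmentation, ScalarMap3D

#: spacing agreement tolerance between co-registered volumes, in mm
SPACING_TOL_MM = 1e-3


def smooth_map(
    map_: ScalarMap3D, sigma: float = 2.0, sigma_in_mm: bool = False
) -> ScalarMap3D:
    """Isotropic 3D Gaussian smoothing (default sd 2 voxels).

    ``sigma`` is the kernel standard deviation in voxel units, or in mm
    when ``sigma_in_mm`` (converted per axis through the spacing).
    ``sigma = 0`` is the identity. The boundary is handled by
    nearest-neighbour replication so lung edges are not artificially
    darkened; the mask is carried over unchanged.
    """
    if sigma < 0:
        raise ParameterError("smoothing sigma must be >= 0")
    if sigma == 0:
        return ScalarMap3D(
            map_.values.copy(), map_.spacing, units=map_.units, mask=map_.mask
        )
    sig = [sigma / s for s in map_.spacing] if sigma_in_mm else sigma
    smoothed = ndimage.gaussian_filter(map_.values, sigma=sig, mode="nearest")
    return ScalarMap3D(smoothed, map_.spacing, units=map_.units, mask=map_.mask)


def _grid_of(vol) -> tuple[tuple[int, ...], tuple[float, ...]]:
    if isinstance(vol, ScalarMap3D):
        return vol.values.shape, vol.spacing
    if isinstance(vol, LobeSegmentation):
        return vol.labels.shape, vol.spacing
    raise TypeError(f"unsupported volume type {type(vol).__name__}")


def harmonize(map_a: ScalarMap3D, map_b: ScalarMap3D, labels: LobeSegmentation):
    """Assert all three volumes share one grid; return them unchanged.

    Shapes must be identical and spacings agree within 1e-3 mm on every
    axis. Any mismatch raises :class:`GridMismatchError` naming the
    offending volume and axis — the inputs would need registration,
    which is outside this pipeline.
    """
    ref_shape, ref_spacing = _grid_of(map_a)
    for name, vol in (("map_b", map_b), ("labels", labels)):
        shape, spacing = _grid_of(vol)
        if shape != ref_shape:
            raise GridMismatchError(
                f"{name} grid shape {shape} != reference {ref_shape}; "
                "volumes must be co-registered"
            )
        for ax, (s, r) in enumerate(zip(spacing, ref_spacing)):
            if abs(s - r) > SPACING_TOL_MM:
                raise GridMismatchError(
                    f"{name} spacing on axis {ax} ({s} mm) differs from "
                    f"reference ({r} mm) by more than {SPACING_TOL_MM} mm"
                )
    return map_a, map_b, labels
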