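"""Voxelwise PBF/PBV quantification by regularized deconvolution.

The tissue concentration curve in bolus-tracking perfusion imaging is the
convolution of the arterial input function (AIF) with the flow-scaled
residue function, C(t) = ∫₀ᵗ AIF(τ) h(t−τ) dτ with h(t) = F·R(t),
R(0) = 1 and R non-increasing. Discretizing the Volterra integral
equation of the first kind with trapezoidal quadrature weights yields a
lower-triangular linear system C = L·h, which is inverted per voxel with
truncated-SVD regularization. Perfusion indices follow from h:

* PBF = max(h) (tolerant to a small bolus delay),
* PBV = ∫ h dt (central volume theorem),
* MTT = PBV / PBF.

Flow is carried internally in 1/s; reported PBF is scaled to
mL/100mL/min, PBV to mL/100mL, MTT in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError
from .images import DceSeries, ScalarMap3D

#: conversion between per-second flow units (internal) and per-minute (reported)
SECONDS_PER_MINUTE = 60.0

#: relative frame-spacing jitter tolerated before resampling is required
UNIFORM_TOL = 0.05


@dataclass
class Aif:
    """Arterial input function sampled on the series' frame times."""

    concentration: np.ndarray
    frame_times: np.ndarray | None = None
    source: str = "supplied"  # "roi" | "supplied" | "truth"

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.ndim != 1:
            raise DataError("AIF must be a 1D concentration curve")
        if np.any(self.concentration < 0):
            raise DataError("AIF concentrations must be nonnegative")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != self.concentration.shape:
                raise DataError("AIF time and concentration lengths differ")

    @classmethod
    def load_csv(cls, path, source: str = "supplied") -> "Aif":
        arr = np.genfromtxt(path, delimiter=",", names=True)
        return cls(
            np.atleast_1d(arr["concentration"]).astype(float),
            np.atleast_1d(arr["t_seconds"]).astype(float),
            source=source,
        )


@dataclass
class ImpulseResponse:
    """Flow-scaled residue recovered for one voxel, with perfusion indices.

    ``h`` is in 1/s (flow-scaled residue); ``pbf`` is max(h) expressed in
    mL/100mL/min, ``pbv`` the trapezoidal time-integral of h in mL/100mL,
    and ``mtt = pbv / (pbf/60)`` in seconds (NaN and flagged when
    pbf = 0, where transit time is undefined).
    """

    h: np.ndarray
    times: np.ndarray
    pbf: float = field(init=False)
    pbv: float = field(init=False)
    mtt: float = field(init=False)
    mtt_defined: bool = field(init=False)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        peak = float(np.max(self.h)) if self.h.size else 0.0
        self.pbf = SECONDS_PER_MINUTE * peak
        self.pbv = float(np.trapezoid(self.h, self.times))
        self.mtt_defined = peak > 0
        self.mtt = self.pbv / peak if self.mtt_defined else float("nan")


def check_uniform_spacing(times: np.ndarray, tol: float = UNIFORM_TOL) -> float:
    """Return the mean frame interval; raise if jitter exceeds ``tol``."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise DataError("need at least two frame times")
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        raise DataError("frame times must be strictly increasing")
    dt = float(diffs.mean())
    if np.max(np.abs(diffs - dt)) > tol * dt:
        raise DataError(
            "frame spacing varies by more than "
            f"{tol:.0%}; resample the series to a uniform grid first"
        )
    return dt


def resample_uniform(series: DceSeries) -> DceSeries:
    """Linearly resample a jittered series onto a uniform time grid."""
    t = series.frame_times
    dt = float(np.diff(t).mean())
    new_t = t[0] + dt * np.arange(series.n_frames)
    flat = series.signal.reshape(-1, series.n_frames)
    out = np.empty_like(flat)
    for i, curve in enumerate(flat):
        out[i] = np.interp(new_t, t, curve)
    return DceSeries(
        out.reshape(series.signal.shape), new_t,
        n_baseline=series.n_baseline, spacing=series.spacing,
    )


def signal_to_concentration(series: DceSeries) -> np.ndarray:
    """Linear signal model: concentration = S(t) − mean baseline signal.

    The mean over the ``n_baseline`` pre-contrast frames is subtracted
    per voxel, so baseline frames average to zero by construction.
    """
    base = series.signal[..., : series.n_baseline].mean(axis=-1, keepdims=True)
    return series.signal - base


def build_convolution_operator(aif: Aif | np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    """Lower-triangular Volterra operator with trapezoidal weights.

    ``L[i, j] = dt · w · AIF(t_i − t_j)`` for j ≤ i, with w = 1/2 at the
    ends of the quadrature band (j = 0 and j = i) and 1 in the interior,
    so that ``(L h)_i`` is the trapezoid-rule discretization of
    ``∫₀^{t_i} AIF(τ) h(t_i − τ) dτ`` — second-order accurate in dt.
    Requires (near-)uniform frame spacing.
    """
    curve = aif.concentration if isinstance(aif, Aif) else np.asarray(aif, dtype=float)
    times = np.asarray(frame_times, dtype=float)
    if curve.shape != times.shape:
        raise DataError("AIF curve and frame_times must have equal length")
    dt = check_uniform_spacing(times)
    if not np.any(curve > 0):
        raise DataError("AIF is identically zero; operator would be singular")
    n = len(times)
    i, j = np.indices((n, n))
    lag = i - j
    w = np.where((j == 0) | (j == i), 0.5, 1.0)
    L = np.where(lag >= 0, dt * w * curve[np.clip(lag, 0, n - 1)], 0.0)
    return L


class TsvdDeconvolver:
    """Batched truncated-SVD solver for the Volterra system C = L·h.

    Singular values below ``lam`` times the largest are discarded
    (``lam = 0`` falls back to a numerical-rank pseudoinverse, for
    noiseless data). The pseudoinverse is precomputed once per AIF, so
    whole-volume deconvolution is a single matrix product.
    """

    def __init__(self, aif, frame_times, lam: float = 0.15):
        if lam < 0 or lam >= 1:
            raise ParameterError("regularization cutoff lam must be in [0, 1)")
        self.frame_times = np.asarray(frame_times, dtype=float)
        self.operator = build_convolution_operator(aif, self.frame_times)
        self.lam = float(lam)
        U, s, Vt = np.linalg.svd(self.operator)
        cutoff = max(self.lam, 1e-12) * s[0]
        keep = s >= cutoff
        self.rank_ = int(keep.sum())
        self.pinv_ = (Vt[keep].T / s[keep]) @ U[:, keep].T

    def solve(self, conc: np.ndarray) -> np.ndarray:
        """Solve for h (clipped at 0); ``conc`` is (n_frames,) or (n_frames, n)."""
        conc = np.asarray(conc, dtype=float)
        h = self.pinv_ @ conc
        return np.clip(h, 0.0, None)


def deconvolve_voxel(
    conc: np.ndarray,
    operator: np.ndarray | TsvdDeconvolver,
    reg: float = 0.15,
    frame_times: np.ndarray | None = None,
) -> ImpulseResponse:
    """Recover the impulse response of a single voxel curve.

    ``operator`` may be a prebuilt :class:`TsvdDeconvolver` (``reg`` is
    then ignored) or the raw lower-triangular matrix from
    :func:`build_convolution_operator` together with ``frame_times``.
    An all-zero concentration yields h = 0 (pbf = pbv = 0), which is a
    valid result, not an error.
    """
    conc = np.asarray(conc, dtype=float)
    if isinstance(operator, TsvdDeconvolver):
        solver = operator
    else:
        if frame_times is None:
            raise DataError("frame_times required when passing a raw operator")
        solver = object.__new__(TsvdDeconvolver)
        solver.frame_times = np.asarray(frame_times, dtype=float)
        solver.operator = np.asarray(operator, dtype=float)
        solver.lam = float(reg)
        U, s, Vt = np.linalg.svd(solver.operator)
        if s[0] == 0:
            raise DataError("singular operator: AIF is identically zero")
        keep = s >= max(solver.lam, 1e-12) * s[0]
        solver.rank_ = int(keep.sum())
        solver.pinv_ = (Vt[keep].T / s[keep]) @ U[:, keep].T
    if conc.shape != solver.frame_times.shape:
        raise DataError("concentration curve and operator time grid differ")
    h = solver.solve(conc)
    return ImpulseResponse(h, solver.frame_times)


def map_perfusion(
    series: DceSeries,
    aif: Aif | np.ndarray,
    mask: np.ndarray,
    reg: float = 0.15,
    emit_mtt: bool = False,
):
    """Deconvolve every masked voxel of a DCE series into PBF/PBV maps.

    Non-uniform frame times (jitter above 5%) are first resampled to a
    uniform grid by linear interpolation. Voxels outside the mask are
    set to NaN. Returns ``(pbf_map, pbv_map)`` or
    ``(pbf_map, pbv_map, mtt_map)`` when ``emit_mtt``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise DataError(
            f"mask grid {mask.shape} does not match series grid {series.grid_shape}"
        )
    try:
        check_uniform_spacing(series.frame_times)
    except DataError:
        series = resample_uniform(series)
    solver = TsvdDeconvolver(aif, series.frame_times, lam=reg)
    conc = signal_to_concentration(series)
    H = solver.solve(conc[mask].T)  # (n_frames, n_mask)

    peak = H.max(axis=0)
    pbf = np.full(mask.shape, np.nan)
    pbv = np.full(mask.shape, np.nan)
    pbf[mask] = SECONDS_PER_MINUTE * peak
    pbv[mask] = np.trapezoid(H, series.frame_times, axis=0)
    pbf_map = ScalarMap3D(pbf, series.spacing, units="mL/100mL/min", mask=mask)
    pbv_map = ScalarMap3D(pbv, series.spacing, units="mL/100mL", mask=mask)
    if not emit_mtt:
        return pbf_map, pbv_map
    mtt = np.full(mask.shape, np.nan)
    pos = mask.copy()
    pos[mask] = peak > 0
    mtt[pos] = pbv[pos] / (pbf[pos] / SECONDS_PER_MINUTE)
    return pbf_map, pbv_map, ScalarMap3D(mtt, series.spacing, units="s", mask=mask)
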