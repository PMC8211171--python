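"""Synthetic paired-modality lung phantom cohort with known ground truth.

The generator builds a five-lobe lung label map from two analytic
ellipsoids, plants contiguous wedge-like perfusion defects with exact
per-lobe fractions, and produces a co-registered pair of modality maps
per subject: a CT pulmonary-blood-volume (iodine-surrogate) map and a
dynamic contrast-enhanced MRI series obtained by forward convolution of
a gamma-variate arterial input function with a mono-exponential residue.
Both modalities share the same planted defect geometry, so cross-modality
agreement is high by construction; noise realisations are independent.

Everything is deterministic given a seed: identical seeds produce
bit-identical outputs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, ParameterError, SizingError
from .images import (
    LOBE_IDS,
    LOBE_LABELS,
    LOBE_NAMES,
    DceSeries,
    LobeSegmentation,
    ScalarMap3D,
)

LOWER_LOBES = ("RLL", "LLL")

# Cohort regime defaults: healthy perfusion levels and the defect contrast
# chosen so that planted defects fall well below the Q75 x 0.7 threshold.
DEFAULT_PBF_HEALTHY = 60.0  # mL/100mL/min
DEFAULT_MTT = 4.0  # s
DEFAULT_CONTRAST_RATIO = 0.3
DEFAULT_SNR = 10.0


# ---------------------------------------------------------------------------
# Arterial input function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AifModel:
    """Gamma-variate arterial input function model.

    ``aif(t) = A * (t - t0)**alpha * exp(-(t - t0)/beta)`` for t > t0,
    zero otherwise. ``recirculation_gain`` > 0 adds a delayed, scaled
    copy of the first pass (delay ``recirculation_delay`` seconds).
    """

    amplitude: float = 1.0
    t0: float = 0.0
    alpha: float = 3.0
    beta: float = 1.5
    recirculation_gain: float = 0.0
    recirculation_delay: float = 12.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("gamma-variate shape alpha and scale beta must be > 0")
        if self.recirculation_gain < 0:
            raise ParameterError("recirculation_gain must be >= 0")

    @property
    def peak_time(self) -> float:
        """First-pass peak location t0 + alpha*beta."""
        return self.t0 + self.alpha * self.beta

    def peak_normalized(self) -> "AifModel":
        """Rescale amplitude so the first-pass peak equals 1."""
        peak = (self.alpha * self.beta) ** self.alpha * np.exp(-self.alpha)
        return replace(self, amplitude=self.amplitude / (self.amplitude * peak))


def gamma_variate_aif(model: AifModel, times: np.ndarray) -> np.ndarray:
    """Sample the gamma-variate AIF on an ascending time grid (seconds)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise DataError("times must be a 1D vector")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise DataError("times must be ascending with first time >= 0")

    def first_pass(t0: float) -> np.ndarray:
        s = t - t0
        out = np.zeros_like(s)
        pos = s > 0
        out[pos] = model.amplitude * s[pos] ** model.alpha * np.exp(-s[pos] / model.beta)
        return out

    curve = first_pass(model.t0)
    if model.recirculation_gain > 0:
        curve = curve + model.recirculation_gain * first_pass(
            model.t0 + model.recirculation_delay
        )
    return curve


def default_aif(n_baseline: int = 3, dt: float = 1.0) -> AifModel:
    """Peak-normalised AIF whose onset follows the baseline frames."""
    return AifModel(t0=n_baseline * dt).peak_normalized()


# ---------------------------------------------------------------------------
# Lung geometry
# ---------------------------------------------------------------------------


def generate_lobe_labelmap(
    shape: Sequence[int] = (64, 64, 64),
    spacing: Sequence[float] = (3.0, 3.0, 3.0),
    seed: int = 0,
) -> LobeSegmentation:
    """Two ellipsoidal lungs split into five lobes by oblique planes.

    Labels: 0 background, 1 RUL, 2 RML, 3 RLL, 4 LUL, 5 LLL. The right
    lung is cut into three lobes, the left into two, by planes tilted in
    the anterior-posterior direction (a crude oblique fissure). Sizes and
    cut positions are jittered per seed so that lobe volumes vary across
    subjects while the label topology is fixed.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise SizingError(f"grid {shape} too small; need at least 32 voxels per axis")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise DataError("spacing must be positive")

    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    ix, iy, iz = np.indices(shape)
    labels = np.zeros(shape, dtype=np.int16)

    for side, cx_frac in (("right", 0.28), ("left", 0.72)):
        jit = np.clip(rng.normal(1.0, 0.03, size=3), 0.91, 1.09)
        a = 0.16 * nx * jit[0]
        b = 0.30 * ny * jit[1]
        c = 0.38 * nz * jit[2]
        cx, cy, cz = cx_frac * nx, 0.5 * ny, 0.5 * nz
        if cx - a < 1 or cx + a > nx - 1 or cy - b < 1 or cz - c < 1:
            raise SizingError("lungs do not fit inside the requested grid")
        inside = ((ix - cx) / a) ** 2 + ((iy - cy) / b) ** 2 + ((iz - cz) / c) ** 2 <= 1.0
        z0, zext = cz - c, 2.0 * c
        slope = rng.normal(0.18, 0.02)
        if side == "right":
            f1 = 0.40 + rng.normal(0.0, 0.01)
            f2 = 0.62 + rng.normal(0.0, 0.01)
            cut1 = z0 + f1 * zext + slope * (iy - cy)
            cut2 = z0 + f2 * zext + slope * (iy - cy)
            labels[inside & (iz < cut1)] = LOBE_IDS["RLL"]
            labels[inside & (iz >= cut1) & (iz < cut2)] = LOBE_IDS["RML"]
            labels[inside & (iz >= cut2)] = LOBE_IDS["RUL"]
        else:
            f1 = 0.45 + rng.normal(0.0, 0.01)
            cut1 = z0 + f1 * zext + slope * (iy - cy)
            labels[inside & (iz < cut1)] = LOBE_IDS["LLL"]
            labels[inside & (iz >= cut1)] = LOBE_IDS["LUL"]

    present = set(np.unique(labels).tolist())
    missing = [LOBE_LABELS[l] for l in LOBE_LABELS if l not in present]
    if missing:
        raise SizingError(f"grid too small: lobes {missing} came out empty")
    return LobeSegmentation(labels, spacing)


def plant_defects(
    seg: LobeSegmentation,
    fractions: Mapping[str, float],
    seed: int = 0,
) -> np.ndarray:
    """Plant one contiguous wedge-like defect per lobe with exact fractions.

    For each lobe, a seed voxel is drawn from the peripheral 30% of the
    lobe (by distance from the lobe centroid) and the defect is the set of
    ``round(fraction * lobe_size)`` lobe voxels closest to it in physical
    distance — a contiguous cap, mimicking the wedge-shaped perfusion
    defects of vascular occlusion. The realised per-lobe fraction equals
    the requested one to within a single voxel of rounding.
    """
    rng = np.random.default_rng(seed)
    spacing = np.asarray(seg.spacing)
    defect = np.zeros(seg.shape, dtype=bool)
    for roi, frac in fractions.items():
        if not (0.0 <= frac <= 1.0):
            raise ParameterError(f"defect fraction for {roi} must be in [0, 1]")
        mask = seg.lobe_mask(roi)
        idx = np.argwhere(mask)
        if idx.size == 0:
            raise DataError(f"lobe {roi} is empty in the segmentation")
        n_target = int(round(frac * len(idx)))
        if n_target == 0:
            continue
        phys = idx * spacing
        d_cent = np.linalg.norm(phys - phys.mean(axis=0), axis=1)
        peripheral = idx[d_cent >= np.quantile(d_cent, 0.7)]
        seed_vox = peripheral[rng.integers(len(peripheral))]
        d = np.linalg.norm(phys - seed_vox * spacing, axis=1)
        order = np.argsort(d, kind="stable")
        chosen = idx[order[:n_target]]
        defect[tuple(chosen.T)] = True
    return defect


# ---------------------------------------------------------------------------
# Ground truth and paired maps
# ---------------------------------------------------------------------------


@dataclass
class CohortTruth:
    """Ground truth for one subject/phase: perfusion maps and defect geometry."""

    subject_id: str
    phase: str  # "pre_op" | "post_op"
    labels: LobeSegmentation
    pbf_truth: ScalarMap3D  # mL/100mL/min, defect contrast applied
    pbv_truth: ScalarMap3D  # mL/100mL
    defect_truth: np.ndarray  # boolean volume, subset of the lung mask
    lobar_defect_fraction: dict[str, float]  # realised per-lobe fractions
    seed: int
    mtt_s: float = DEFAULT_MTT
    contrast_ratio: float = DEFAULT_CONTRAST_RATIO

    def whole_lung_defect_fraction(self) -> float:
        lung = self.labels.lung_mask
        return float(self.defect_truth[lung].mean())


def make_truth(
    labels: LobeSegmentation,
    fractions: Mapping[str, float],
    subject_id: str = "S0",
    phase: str = "pre_op",
    contrast_ratio: float = DEFAULT_CONTRAST_RATIO,
    pbf_healthy: float = DEFAULT_PBF_HEALTHY,
    mtt_s: float = DEFAULT_MTT,
    seed: int = 0,
) -> CohortTruth:
    """Build ground-truth PBF/PBV maps with planted defects.

    Healthy lung voxels carry ``pbf_healthy``; defect voxels carry
    ``contrast_ratio * pbf_healthy`` (exact suppression, no noise — noise
    belongs to the modality maps). PBV follows the central volume theorem,
    PBV = PBF * MTT / 60 with MTT in seconds and PBF per minute.
    """
    if not (0.0 < contrast_ratio < 1.0):
        raise ParameterError("contrast_ratio must be in (0, 1)")
    if mtt_s <= 0:
        raise ParameterError("mean transit time must be positive")
    defect = plant_defects(labels, fractions, seed=seed)
    lung = labels.lung_mask
    if np.any(defect & ~lung):
        raise DataError("planted defect escaped the lung mask")

    pbf = np.zeros(labels.shape, dtype=float)
    pbf[lung] = pbf_healthy
    pbf[defect] = contrast_ratio * pbf_healthy
    pbv = pbf * mtt_s / 60.0

    realised = {
        roi: float(defect[labels.lobe_mask(roi)].mean()) for roi in LOBE_NAMES
    }
    return CohortTruth(
        subject_id=subject_id,
        phase=phase,
        labels=labels,
        pbf_truth=ScalarMap3D(pbf, labels.spacing, units="mL/100mL/min", mask=lung),
        pbv_truth=ScalarMap3D(pbv, labels.spacing, units="mL/100mL", mask=lung),
        defect_truth=defect,
        lobar_defect_fraction=realised,
        seed=seed,
        mtt_s=mtt_s,
        contrast_ratio=contrast_ratio,
    )


def simulate_dce_series(
    labels: LobeSegmentation,
    pbf_truth: ScalarMap3D,
    mtt_map: float | np.ndarray,
    aif: AifModel | np.ndarray,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int = 60,
    n_baseline: int = 3,
    baseline_signal: float = 50.0,
) -> DceSeries:
    """Forward-simulate a DCE series: C(t) = PBF * (AIF ⊛ R)(t) + noise.

    The tissue residue is mono-exponential, R(t) = exp(-t/MTT), and the
    convolution is evaluated with the same trapezoidal Volterra
    discretization the quantification stage inverts, so a noiseless
    series is exactly consistent with the forward operator. Flow enters
    in per-second units (PBF/60); the signal is a constant baseline plus
    the concentration curve (linear signal model).
    """
    from .perfusion import build_convolution_operator  # local import: no cycle at load

    if not (0.8 <= dt <= 1.1):
        raise ParameterError("frame interval dt must lie in [0.8, 1.1] s")
    pbf = np.asarray(pbf_truth.values, dtype=float)
    if np.any(pbf[np.isfinite(pbf)] < 0):
        raise ParameterError("pbf_truth must be nonnegative")
    lung = labels.lung_mask
    mtt = np.broadcast_to(np.asarray(mtt_map, dtype=float), pbf.shape)
    if np.any(mtt[lung] <= 0):
        raise ParameterError("mean transit time must be positive throughout the lung")

    times = np.arange(n_frames) * dt
    aif_curve = gamma_variate_aif(aif, times) if isinstance(aif, AifModel) else np.asarray(aif, float)
    if aif_curve.shape != times.shape:
        raise DataError("AIF curve length must match the number of frames")
    L = build_convolution_operator(aif_curve, times)

    # h(t) = (PBF/60) * exp(-t/MTT), one column per lung voxel
    f_per_s = pbf[lung] / 60.0
    residue = np.exp(-np.outer(times, 1.0 / mtt[lung]))
    conc = L @ (residue * f_per_s)  # (n_frames, n_lung)

    signal = np.full(pbf.shape + (n_frames,), baseline_signal, dtype=float)
    signal[lung] = baseline_signal + conc.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal += rng.normal(0.0, noise_sd, size=signal.shape)
    return DceSeries(signal, times, n_baseline=n_baseline, spacing=labels.spacing)


def generate_paired_maps(
    truth: CohortTruth,
    snr_ct: float = DEFAULT_SNR,
    snr_mri: float = DEFAULT_SNR,
    seed: int = 0,
    mri: str = "series",
    dt: float = 1.0,
    n_frames: int = 60,
    n_baseline: int = 3,
):
    """Paired co-registered modality data for one subject/phase.

    CT: ``pbv_truth`` plus i.i.d. Gaussian noise with sd = healthy PBV /
    ``snr_ct``. MRI: either a simulated DCE series (``mri="series"``,
    noise sd = peak tissue concentration / ``snr_mri``) to be quantified
    by the deconvolution stage, or direct noisy PBF/PBV maps
    (``mri="maps"``). Noise realisations of the two modalities are
    independent; an SNR of ``inf`` (or <= 0) disables noise.

    Returns ``(ct_pbv_map, mri_data)``.
    """
    rng = np.random.default_rng(seed)
    ct_seed, mri_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    lung = truth.labels.lung_mask
    pbv = truth.pbv_truth.values.copy()
    healthy_pbv = float(np.max(pbv[lung]))
    if np.isfinite(snr_ct) and snr_ct > 0:
        ct_rng = np.random.default_rng(ct_seed)
        pbv = pbv + ct_rng.normal(0.0, healthy_pbv / snr_ct, size=pbv.shape)
    ct_map = ScalarMap3D(pbv, truth.labels.spacing, units="mL/100mL", mask=lung)

    if mri == "series":
        aif = default_aif(n_baseline=n_baseline, dt=dt)
        clean = simulate_dce_series(
            truth.labels, truth.pbf_truth, truth.mtt_s, aif,
            dt=dt, noise_sd=0.0, n_frames=n_frames, n_baseline=n_baseline,
        )
        peak = float(np.max(clean.signal[lung]) - clean.signal[lung].min())
        noise_sd = peak / snr_mri if (np.isfinite(snr_mri) and snr_mri > 0) else 0.0
        series = simulate_dce_series(
            truth.labels, truth.pbf_truth, truth.mtt_s, aif,
            dt=dt, noise_sd=noise_sd, seed=mri_seed,
            n_frames=n_frames, n_baseline=n_baseline,
        )
        aif_curve = gamma_variate_aif(aif, series.frame_times)
        return ct_map, (series, aif_curve)
    if mri == "maps":
        mri_rng = np.random.default_rng(mri_seed)
        pbf = truth.pbf_truth.values.copy()
        pbv_m = truth.pbv_truth.values.copy()
        healthy_pbf = float(np.max(pbf[lung]))
        if np.isfinite(snr_mri) and snr_mri > 0:
            pbf = pbf + mri_rng.normal(0.0, healthy_pbf / snr_mri, size=pbf.shape)
            pbv_m = pbv_m + mri_rng.normal(0.0, healthy_pbv / snr_mri, size=pbv_m.shape)
        pbf_map = ScalarMap3D(pbf, truth.labels.spacing, units="mL/100mL/min", mask=lung)
        pbv_map = ScalarMap3D(pbv_m, truth.labels.spacing, units="mL/100mL", mask=lung)
        return ct_map, (pbf_map, pbv_map)
    raise ParameterError(f"unknown mri mode {mri!r}; use 'series' or 'maps'")


# ---------------------------------------------------------------------------
# Cohort scenarios
# ---------------------------------------------------------------------------


def sample_lobar_fractions(rng: np.random.Generator) -> dict[str, float]:
    """Pre-operative per-lobe defect fractions (CTEPH cohort regime).

    Drawn per lobe from a clipped normal centred at 0.5 (whole-lung
    defect burden about half the lung, with realistic between-subject
    spread in the 0.4-0.7 band).
    """
    return {
        roi: float(np.clip(rng.normal(0.5, 0.1), 0.4, 0.7)) for roi in LOBE_NAMES
    }


def post_op_fractions(
    pre: Mapping[str, float],
    rng: np.random.Generator,
    lower_lobe_improvement: float = 0.20,
) -> dict[str, float]:
    """Post-endarterectomy fractions: improvement concentrated in lower lobes.

    Lower lobes improve by ``lower_lobe_improvement`` (mean, sd 0.05) in
    absolute defect fraction; RUL/RML improve marginally; the left upper
    lobe gets a zero-mean between-subject perturbation (sd 0.05) — no
    systematic change, but the biological variability without which a
    paired test on it would be degenerate.
    """
    post = dict(pre)
    for roi in LOWER_LOBES:
        delta = float(np.clip(rng.normal(lower_lobe_improvement, 0.05), 0.02, 0.5))
        post[roi] = float(np.clip(pre[roi] - delta, 0.02, 1.0))
    for roi in ("RUL", "RML"):
        delta = float(np.clip(rng.normal(0.04, 0.03), 0.0, 0.15))
        post[roi] = float(np.clip(pre[roi] - delta, 0.02, 1.0))
    post["LUL"] = float(np.clip(pre["LUL"] + rng.normal(0.0, 0.05), 0.02, 1.0))
    return post


@dataclass
class SubjectData:
    """All simulated inputs for one subject/phase."""

    truth: CohortTruth
    ct_map: ScalarMap3D
    mri_data: object  # (DceSeries, aif curve) or (pbf_map, pbv_map)
    mri_mode: str


def simulate_subject(
    subject_id: str,
    phase: str,
    seed: int,
    shape=(64, 64, 64),
    spacing=(3.0, 3.0, 3.0),
    fractions: Mapping[str, float] | None = None,
    snr_ct: float = DEFAULT_SNR,
    snr_mri: float = DEFAULT_SNR,
    mri: str = "series",
    labels: LobeSegmentation | None = None,
    **truth_kwargs,
) -> SubjectData:
    """Generate one subject/phase end to end (geometry, truth, paired maps)."""
    rng = np.random.default_rng(seed)
    geo_seed, defect_seed, noise_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    if labels is None:
        labels = generate_lobe_labelmap(shape, spacing, seed=geo_seed)
    if fractions is None:
        fractions = sample_lobar_fractions(rng)
    truth = make_truth(
        labels, fractions, subject_id=subject_id, phase=phase,
        seed=defect_seed, **truth_kwargs,
    )
    ct_map, mri_data = generate_paired_maps(
        truth, snr_ct=snr_ct, snr_mri=snr_mri, seed=noise_seed, mri=mri
    )
    return SubjectData(truth=truth, ct_map=ct_map, mri_data=mri_data, mri_mode=mri)


def iter_cohort(
    n_subjects: int = 5,
    seed: int = 0,
    shape=(64, 64, 64),
    spacing=(3.0, 3.0, 3.0),
    scenario: str = "single",
    snr_ct: float = DEFAULT_SNR,
    snr_mri: float = DEFAULT_SNR,
    mri: str = "series",
    lower_lobe_improvement: float = 0.20,
):
    """Yield :class:`SubjectData` for a whole cohort, one session at a time.

    ``scenario="single"`` yields one pre-op session per subject;
    ``"pre_post_pea"`` yields a pre-op and a post-op session sharing the
    subject's lung geometry, with the post-op defect burden reduced
    mainly in the lower lobes. Deterministic in ``seed``.
    """
    master = np.random.default_rng(seed)
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        geo_seed = int(rng.integers(0, 2**31 - 1))
        labels = generate_lobe_labelmap(shape, spacing, seed=geo_seed)
        pre_frac = sample_lobar_fractions(rng)
        phases = [("pre_op", pre_frac)]
        if scenario == "pre_post_pea":
            phases.append(
                ("post_op", post_op_fractions(pre_frac, rng, lower_lobe_improvement))
            )
        elif scenario != "single":
            raise ParameterError(f"unknown scenario {scenario!r}")
        for phase, frac in phases:
            phase_seed = int(rng.integers(0, 2**31 - 1))
            yield simulate_subject(
                sid, phase, phase_seed, shape=shape, spacing=spacing,
                fractions=frac, snr_ct=snr_ct, snr_mri=snr_mri, mri=mri,
                labels=labels,
            )


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------


def write_subject(outdir: Path, data: SubjectData) -> dict:
    """Write one subject/phase to NIfTI/CSV and return its manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = data.truth
    tag = f"{truth.subject_id}_{truth.phase}"
    entry: dict = {"subject_id": truth.subject_id, "phase": truth.phase, "seed": truth.seed}

    entry["labels"] = str(truth.labels.save(outdir / f"{tag}_lobes.nii.gz"))
    entry["ct_pbv"] = str(data.ct_map.save(outdir / f"{tag}_ct_pbv.nii.gz"))
    if data.mri_mode == "series":
        series, aif_curve = data.mri_data
        entry["mri_series"] = str(series.save(outdir / f"{tag}_mri_dce.nii.gz"))
        aif_path = outdir / f"{tag}_aif.csv"
        with open(aif_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_seconds", "concentration"])
            for t, c in zip(series.frame_times, aif_curve):
                w.writerow([f"{t:.6g}", f"{c:.10g}"])
        entry["aif"] = str(aif_path)
    else:
        pbf_map, pbv_map = data.mri_data
        entry["mri_pbf"] = str(pbf_map.save(outdir / f"{tag}_mri_pbf.nii.gz"))
        entry["mri_pbv"] = str(pbv_map.save(outdir / f"{tag}_mri_pbv.nii.gz"))

    truth_rows = [
        {
            "subject_id": truth.subject_id,
            "phase": truth.phase,
            "roi": roi,
            "defect_fraction": truth.lobar_defect_fraction.get(roi, np.nan)
            if roi != "whole_lung"
            else truth.whole_lung_defect_fraction(),
            "mean_pbf": float(truth.pbf_truth.values[truth.labels.lobe_mask(roi)].mean())
            if roi != "whole_lung"
            else float(truth.pbf_truth.values[truth.labels.lung_mask].mean()),
            "mean_pbv": float(truth.pbv_truth.values[truth.labels.lobe_mask(roi)].mean())
            if roi != "whole_lung"
            else float(truth.pbv_truth.values[truth.labels.lung_mask].mean()),
        }
        for roi in ("whole_lung",) + LOBE_NAMES
    ]
    truth_path = outdir / f"{tag}_truth.csv"
    with open(truth_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(truth_rows[0]))
        w.writeheader()
        w.writerows(truth_rows)
    entry["truth_table"] = str(truth_path)
    return entry


def simulate_cohort_to_dir(
    outdir,
    n_subjects: int = 5,
    seed: int = 0,
    shape=(64, 64, 64),
    spacing=(3.0, 3.0, 3.0),
    scenario: str = "single",
    snr_ct: float = DEFAULT_SNR,
    snr_mri: float = DEFAULT_SNR,
    mri: str = "series",
) -> Path:
    """Simulate a cohort and write it with a manifest JSON.

    ``scenario="single"`` writes one pre-op session per subject;
    ``"pre_post_pea"`` writes paired pre/post sessions with post-op
    improvement concentrated in the lower lobes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = [
        write_subject(outdir, data)
        for data in iter_cohort(
            n_subjects=n_subjects, seed=seed, shape=shape, spacing=spacing,
            scenario=scenario, snr_ct=snr_ct, snr_mri=snr_mri, mri=mri,
        )
    ]
    manifest = {
        "seed": seed,
        "scenario": scenario,
        "shape": list(shape),
        "spacing": list(spacing),
        "snr_ct": snr_ct,
        "snr_mri": snr_mri,
        "mri_mode": mri,
        "subjects": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
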