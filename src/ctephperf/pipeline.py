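"""End-to-end orchestration: simulate → quantify → prep → defects → agree → report.

A run is driven by a config mapping (usually a YAML file) and writes a
self-contained run directory: per-subject defect maps, tidy QDP and
agreement tables, cohort report tables, and a JSON run log recording
every parameter, the package version and input checksums. Deterministic
stages are bit-reproducible for identical config and seed.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_report, cohort_report
from .defects import make_qdm, qdp_long
from .errors import ConfigError, DataError
from .images import DceSeries, LobeSegmentation, ScalarMap3D
from .perfusion import Aif, map_perfusion
from .prep import harmonize, smooth_map
from .synthetic import SubjectData, simulate_cohort_to_dir

DEFAULTS = {
    "lam": 0.15,          # TSVD relative singular-value cutoff
    "sigma": 2.0,         # CT Gaussian smoothing sd (voxels, or mm with sigma_in_mm)
    "sigma_in_mm": False,
    "percentile": 75.0,   # defect threshold percentile
    "factor": 0.7,        # defect threshold factor
    "n_baseline": None,  # None: use the series' own sidecar value
    "strict": True,       # defect iff value < threshold
}


@dataclass
class SubjectInputs:
    """Loaded inputs for one subject/phase, ready for analysis."""

    subject_id: str
    phase: str
    labels: LobeSegmentation
    ct_map: ScalarMap3D
    mri_data: object
    mri_mode: str  # "series" | "maps"


def _inputs_from(data) -> SubjectInputs:
    if isinstance(data, SubjectInputs):
        return data
    if isinstance(data, SubjectData):
        return SubjectInputs(
            subject_id=data.truth.subject_id,
            phase=data.truth.phase,
            labels=data.truth.labels,
            ct_map=data.ct_map,
            mri_data=data.mri_data,
            mri_mode=data.mri_mode,
        )
    raise TypeError(f"cannot analyze {type(data).__name__}")


def analyze_subject(
    data,
    lam: float = DEFAULTS["lam"],
    sigma: float = DEFAULTS["sigma"],
    sigma_in_mm: bool = DEFAULTS["sigma_in_mm"],
    percentile: float = DEFAULTS["percentile"],
    factor: float = DEFAULTS["factor"],
    strict: bool = DEFAULTS["strict"],
    n_baseline: int | None = DEFAULTS["n_baseline"],
):
    """Run the per-subject analysis chain on in-memory inputs.

    Smooths the CT map, quantifies the MRI series (or accepts ready MRI
    maps), verifies grid consistency, thresholds each map independently
    into a defect map, and computes QDP and cross-modality agreement.

    Returns ``(qdp_df, agree_df, qdms)`` where ``qdms`` maps parameter
    name (CT_PBV / MRI_PBF / MRI_PBV) to its :class:`DefectMap`.
    """
    sub = _inputs_from(data)
    labels = sub.labels
    lung = labels.lung_mask
    quantile = percentile / 100.0

    ct_prepped = smooth_map(sub.ct_map, sigma, sigma_in_mm=sigma_in_mm)
    if sub.mri_mode == "series":
        series, aif_curve = sub.mri_data
        if n_baseline is not None:
            series.n_baseline = int(n_baseline)
        aif = aif_curve.concentration if isinstance(aif_curve, Aif) else aif_curve
        pbf_map, pbv_map = map_perfusion(series, aif, lung, reg=lam)
    else:
        pbf_map, pbv_map = sub.mri_data
    harmonize(ct_prepped, pbf_map, labels)

    maps = {
        "CT_PBV": (ct_prepped, "CT"),
        "MRI_PBF": (pbf_map, "MRI"),
        "MRI_PBV": (pbv_map, "MRI"),
    }
    qdms = {}
    qdp_frames = []
    for param, (map_, modality) in maps.items():
        qdm = make_qdm(
            map_, lung, source_parameter=param,
            strict=strict, quantile=quantile, factor=factor,
        )
        qdms[param] = qdm
        qdp_frames.append(
            qdp_long(qdm, labels, sub.subject_id, sub.phase, modality, param)
        )
    agree_frames = [
        agreement_report(
            qdms["CT_PBV"], qdms[p], labels,
            subject_id=sub.subject_id, phase=sub.phase, pair=f"CT_PBV_vs_{p}",
        )
        for p in ("MRI_PBF", "MRI_PBV")
    ]
    return pd.concat(qdp_frames, ignore_index=True), pd.concat(agree_frames, ignore_index=True), qdms


def _load_entry(entry: dict) -> SubjectInputs:
    labels = LobeSegmentation.load(entry["labels"])
    ct_map = ScalarMap3D.load(entry["ct_pbv"])
    ct_map.mask = labels.lung_mask
    if "mri_series" in entry:
        series = DceSeries.load(entry["mri_series"])
        aif = Aif.load_csv(entry["aif"])
        return SubjectInputs(entry["subject_id"], entry["phase"], labels, ct_map,
                             (series, aif.concentration), "series")
    pbf = ScalarMap3D.load(entry["mri_pbf"])
    pbv = ScalarMap3D.load(entry["mri_pbv"])
    pbf.mask = labels.lung_mask
    pbv.mask = labels.lung_mask
    return SubjectInputs(entry["subject_id"], entry["phase"], labels, ct_map,
                         (pbf, pbv), "maps")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Fill defaults and sanity-check a run configuration."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    if "out_dir" not in cfg:
        raise ConfigError("config must name an out_dir")
    if ("simulate" not in cfg) == ("manifest" not in cfg):
        raise ConfigError("config must contain exactly one of 'simulate' or 'manifest'")
    params = {**DEFAULTS, **cfg.get("params", {})}
    unknown = set(params) - set(DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown analysis parameters: {sorted(unknown)}")
    if not (0 <= params["lam"] < 1):
        raise ConfigError("lam must be in [0, 1)")
    if not (0 < params["percentile"] < 100):
        raise ConfigError("percentile must be in (0, 100)")
    if params["factor"] <= 0:
        raise ConfigError("threshold factor must be positive")
    if params["sigma"] < 0:
        raise ConfigError("sigma must be >= 0")
    cfg["params"] = params
    return cfg


def run_pipeline(config: dict) -> Path:
    """Execute a full cohort run; returns the run directory.

    The config either requests simulation (``simulate: {n_subjects,
    shape, spacing, scenario, snr_ct, snr_mri, mri_mode}``) or points at
    an existing cohort ``manifest`` JSON. Per-subject failures abort the
    run with an explicit error naming the subject.
    """
    cfg = validate_config(config)
    params = cfg["params"]
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", cfg["seed"])
        mri_mode = sim.pop("mri_mode", "series")
        manifest_path = simulate_cohort_to_dir(out / "data", mri=mri_mode, **sim)
    else:
        manifest_path = Path(cfg["manifest"])
        if not manifest_path.exists():
            raise DataError(f"manifest not found: {manifest_path}")
    manifest = json.loads(Path(manifest_path).read_text())

    qdm_dir = out / "qdm"
    qdm_dir.mkdir(exist_ok=True)
    qdp_frames, agree_frames = [], []
    checksums = {}
    skipped = []
    for entry in manifest["subjects"]:
        tag = f"{entry['subject_id']}_{entry['phase']}"
        missing = [k for k in ("labels", "ct_pbv") if not Path(entry[k]).exists()]
        if missing:
            skipped.append({"subject": tag, "missing": missing})
            continue
        for key in ("labels", "ct_pbv", "mri_series", "mri_pbf", "mri_pbv", "aif"):
            if key in entry:
                checksums[f"{tag}:{key}"] = _sha256(Path(entry[key]))
        sub = _load_entry(entry)
        qdp_df, agree_df, qdms = analyze_subject(sub, **params)
        qdp_frames.append(qdp_df)
        agree_frames.append(agree_df)
        for param, qdm in qdms.items():
            qdm.save(qdm_dir / f"{tag}_{param.lower()}_qdm.nii.gz",
                     spacing=sub.labels.spacing)

    if not qdp_frames:
        raise DataError("no analyzable subjects in the manifest")
    qdp_all = pd.concat(qdp_frames, ignore_index=True)
    agree_all = pd.concat(agree_frames, ignore_index=True)
    qdp_all.to_csv(out / "qdp.csv", index=False)
    agree_all.to_csv(out / "agreement.csv", index=False)

    report_dir = out / "report"
    tables = cohort_report(qdp_all, agree_all, report_dir, seed=cfg["seed"],
                           plots=bool(cfg.get("plots", False)))

    log = {
        "version": __version__,
        "python": platform.python_version(),
        "config": {k: v for k, v in cfg.items() if k != "params"},
        "params": params,
        "manifest": str(manifest_path),
        "n_subject_sessions": len(qdp_frames),
        "skipped": skipped,
        "report_tables": sorted(tables),
        "input_checksums": checksums,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return out
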