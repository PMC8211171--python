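"""Spatial agreement of defect maps and cohort-level statistics.

Voxel-level agreement between two binary defect maps is summarised by a
spatial overlap metric (percentage of ROI voxels on which the two maps
agree, counting matching defect plus matching healthy voxels) and by
Dice coefficients computed separately for the defect and the healthy
label. Cohort-level comparisons use Pearson product-moment correlation,
Bland–Altman limits of agreement and lobe-based paired t-tests, with
unadjusted p-values at α = 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UndefinedStatisticError
from .images import LOBE_NAMES, WHOLE_LUNG, LobeSegmentation
from .defects import DefectMap

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Voxel-level agreement
# ---------------------------------------------------------------------------


def _common_mask(qdm_a: DefectMap, qdm_b: DefectMap, roi_mask: np.ndarray) -> np.ndarray:
    if qdm_a.qdm.shape != qdm_b.qdm.shape:
        raise DataError("defect maps are on different grids")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != qdm_a.qdm.shape:
        raise DataError("ROI mask grid does not match the defect maps")
    return roi_mask & qdm_a.mask & qdm_b.mask


def overlap_metric(qdm_a: DefectMap, qdm_b: DefectMap, roi_mask: np.ndarray) -> float:
    """Percent of ROI voxels on which both maps agree (defect or healthy).

    overlap = 100 · (both-defect + both-healthy) / ROI voxels. NaN for
    an empty ROI.
    """
    roi = _common_mask(qdm_a, qdm_b, roi_mask)
    n = int(roi.sum())
    if n == 0:
        return float("nan")
    a, b = qdm_a.qdm[roi], qdm_b.qdm[roi]
    agree = int(np.count_nonzero(a == b))
    return 100.0 * agree / n


def dice(
    qdm_a: DefectMap, qdm_b: DefectMap, label: str, roi_mask: np.ndarray
) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) for one label within the ROI.

    ``label`` is ``"defect"`` or ``"healthy"``. Returns NaN when both
    label sets are empty (reporting 1 there would inflate agreement in
    degenerate lobes).
    """
    if label not in ("defect", "healthy"):
        raise DataError("label must be 'defect' or 'healthy'")
    roi = _common_mask(qdm_a, qdm_b, roi_mask)
    a, b = qdm_a.qdm[roi], qdm_b.qdm[roi]
    if label == "healthy":
        a, b = ~a, ~b
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        return float("nan")
    return 2.0 * int(np.count_nonzero(a & b)) / size


def agreement_report(
    qdm_a: DefectMap,
    qdm_b: DefectMap,
    labels: LobeSegmentation,
    subject_id: str = "",
    phase: str = "",
    pair: str = "",
) -> pd.DataFrame:
    """Overlap and Dice per ROI (whole lung and each lobe) as a tidy table."""
    rows = []
    for roi in (WHOLE_LUNG,) + LOBE_NAMES:
        mask = labels.lung_mask if roi == WHOLE_LUNG else labels.lobe_mask(roi)
        if not mask.any():
            continue  # empty ROI: missing row
        rows.append(
            {
                "subject_id": subject_id,
                "phase": phase,
                "pair": pair,
                "roi": roi,
                "overlap_percent": overlap_metric(qdm_a, qdm_b, mask),
                "dice_defect": dice(qdm_a, qdm_b, "defect", mask),
                "dice_healthy": dice(qdm_a, qdm_b, "healthy", mask),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment r with two-sided p from the t(n−2) law."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pearson requires two equal-length vectors")
    if len(x) < 3:
        raise DataError("pearson requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("pearson requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


class PairedResult(NamedTuple):
    mean_delta: float
    t: float
    p: float
    n: int


def paired_delta_test(pre: np.ndarray, post: np.ndarray) -> PairedResult:
    """Two-sided paired t-test on post − pre differences.

    ``mean_delta`` is mean(post − pre), so a perfusion improvement
    (QDP decrease) appears as a negative delta. When all differences
    are identical the t statistic has zero denominator; by convention
    t = 0 and p = NaN are returned (flagging an undefined test) unless
    the common difference is nonzero, in which case the effect is
    certain but untestable and p is still NaN.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise DataError("paired test requires two equal-length vectors")
    if len(pre) < 2:
        raise DataError("paired test requires n >= 2")
    diff = post - pre
    mean_delta = float(diff.mean())
    if np.ptp(diff) == 0:
        return PairedResult(mean_delta, 0.0 if mean_delta == 0 else float("inf"),
                            float("nan"), len(pre))
    res = stats.ttest_rel(post, pre)
    return PairedResult(mean_delta, float(res.statistic), float(res.pvalue), len(pre))


class BlandAltman(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Bland–Altman agreement: bias = mean(x−y), LoA = bias ± 1.96·sd(x−y).

    Returns per-pair means and differences alongside, ready for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise DataError("bland_altman requires paired vectors with n >= 2")
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, (x + y) / 2.0, diffs)


def bland_altman_plot(x, y, out_path, title: str = "") -> Path:
    """Write an SVG Bland–Altman plot (mean vs difference with LoA lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(x, y)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(ba.means, ba.diffs, s=18, color="tab:blue")
    for val, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(val, linestyle=style, color="tab:gray", linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------


def select_single_sessions(
    qdp_df: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Keep one session per subject for cross-sectional analyses.

    Subjects present with both pre- and post-op sessions contribute a
    single, seeded random choice of phase, avoiding double counting.
    Returns the filtered table and the chosen phase per subject.
    """
    rng = np.random.default_rng(seed)
    chosen: dict[str, str] = {}
    for sid in sorted(qdp_df["subject_id"].unique()):
        phases = sorted(qdp_df.loc[qdp_df["subject_id"] == sid, "phase"].unique())
        chosen[sid] = phases[int(rng.integers(len(phases)))] if len(phases) > 1 else phases[0]
    keep = qdp_df.apply(lambda r: chosen[r["subject_id"]] == r["phase"], axis=1)
    return qdp_df[keep].copy(), chosen


def cross_modality_table(
    qdp_df: pd.DataFrame,
    agree_df: pd.DataFrame | None,
    param_a: str,
    param_b: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-ROI cross-modality comparison of lobe-referenced QDP.

    For each ROI: mean (SD) QDP of each parameter, Pearson r and p over
    subjects, and — when an agreement table is supplied — mean (SD)
    overlap and Dice coefficients. One session per subject enters
    (seeded random choice for dual-session subjects).
    """
    df = qdp_df[qdp_df["reference"] == "lobe_volume"]
    df = df[df["parameter"].isin([param_a, param_b])]
    df, chosen = select_single_sessions(df, seed=seed)
    rows = []
    for roi in (WHOLE_LUNG,) + LOBE_NAMES:
        sub = df[df["roi"] == roi].pivot_table(
            index="subject_id", columns="parameter", values="qdp_percent"
        )
        if param_a not in sub or param_b not in sub:
            continue
        sub = sub.dropna(subset=[param_a, param_b])
        a, b = sub[param_a].to_numpy(), sub[param_b].to_numpy()
        row = {
            "roi": roi,
            "n": len(sub),
            f"{param_a}_mean": a.mean() if len(a) else np.nan,
            f"{param_a}_sd": a.std(ddof=1) if len(a) > 1 else np.nan,
            f"{param_b}_mean": b.mean() if len(b) else np.nan,
            f"{param_b}_sd": b.std(ddof=1) if len(b) > 1 else np.nan,
        }
        if len(sub) >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
            row["pearson_r"], row["p_value"] = pearson(a, b)
        else:
            row["pearson_r"], row["p_value"] = np.nan, np.nan
        if len(sub) >= 2:
            ba = bland_altman(a, b)
            row["ba_bias"], row["ba_loa_low"], row["ba_loa_high"] = (
                ba.bias, ba.loa_low, ba.loa_high,
            )
        if agree_df is not None and len(agree_df):
            pair = f"{param_a}_vs_{param_b}"
            keep = agree_df.apply(
                lambda r: r["subject_id"] in chosen
                and chosen[r["subject_id"]] == r["phase"], axis=1,
            )
            sel = agree_df[keep]
            sel = sel[(sel["roi"] == roi) & (sel["pair"] == pair)]
            for col in ("overlap_percent", "dice_defect", "dice_healthy"):
                vals = sel[col].dropna().to_numpy()
                row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
                row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def pre_post_table(qdp_df: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per-ROI paired pre/post comparison of lobe-referenced QDP.

    Only subjects with both phases for ``parameter`` enter; each ROI row
    reports pre and post mean (SD), the mean paired change Δ = post −
    pre with its SD, and the two-sided paired t-test p-value.
    """
    df = qdp_df[(qdp_df["reference"] == "lobe_volume") & (qdp_df["parameter"] == parameter)]
    rows = []
    for roi in (WHOLE_LUNG,) + LOBE_NAMES:
        sub = df[df["roi"] == roi].pivot_table(
            index="subject_id", columns="phase", values="qdp_percent"
        )
        if "pre_op" not in sub or "post_op" not in sub:
            continue
        sub = sub.dropna(subset=["pre_op", "post_op"])
        if len(sub) < 2:
            continue
        pre, post = sub["pre_op"].to_numpy(), sub["post_op"].to_numpy()
        res = paired_delta_test(pre, post)
        rows.append(
            {
                "roi": roi,
                "n": res.n,
                "pre_mean": pre.mean(),
                "pre_sd": pre.std(ddof=1),
                "post_mean": post.mean(),
                "post_sd": post.std(ddof=1),
                "delta_mean": res.mean_delta,
                "delta_sd": float((post - pre).std(ddof=1)),
                "t_statistic": res.t,
                "p_value": res.p,
                "significant": bool(res.p < ALPHA) if np.isfinite(res.p) else False,
            }
        )
    return pd.DataFrame(rows)


def cohort_report(
    qdp_df: pd.DataFrame,
    agree_df: pd.DataFrame | None,
    outdir,
    seed: int = 0,
    plots: bool = False,
) -> dict[str, pd.DataFrame]:
    """Write the full set of cohort tables as CSV; return them as frames.

    Cross-modality tables are produced for CT_PBV against each MRI
    parameter present; pre/post tables for every parameter with both
    phases. Absent modalities simply produce no table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = set(qdp_df["parameter"].unique())
    tables: dict[str, pd.DataFrame] = {}

    for mri_param in ("MRI_PBF", "MRI_PBV"):
        if "CT_PBV" in params and mri_param in params:
            name = f"cross_ct_vs_{mri_param.lower()}"
            tab = cross_modality_table(qdp_df, agree_df, "CT_PBV", mri_param, seed=seed)
            if len(tab):
                tables[name] = tab
                tab.to_csv(outdir / f"{name}.csv", index=False)
                if plots:
                    df, chosen = select_single_sessions(
                        qdp_df[(qdp_df["reference"] == "lobe_volume")
                               & (qdp_df["roi"] == WHOLE_LUNG)
                               & (qdp_df["parameter"].isin(["CT_PBV", mri_param]))],
                        seed=seed,
                    )
                    wide = df.pivot_table(index="subject_id", columns="parameter",
                                          values="qdp_percent").dropna()
                    if len(wide) >= 2:
                        bland_altman_plot(
                            wide["CT_PBV"].to_numpy(), wide[mri_param].to_numpy(),
                            outdir / f"{name}_bland_altman_whole_lung.svg",
                            title=f"CT-QDP vs {mri_param}-QDP (whole lung)",
                        )
    for param in sorted(params):
        tab = pre_post_table(qdp_df, param)
        if len(tab):
            name = f"prepost_{param.lower()}"
            tables[name] = tab
            tab.to_csv(outdir / f"{name}.csv", index=False)
    return tables
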