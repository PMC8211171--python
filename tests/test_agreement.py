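"""Agreement metrics, cohort statistics and report tables."""

import numpy as np
import pandas as pd
import pytest

import ctephperf as cp
from ctephperf.agreement import (
    BlandAltman,
    cross_modality_table,
    pre_post_table,
    select_single_sessions,
)
from ctephperf.defects import DefectMap
from ctephperf.errors import DataError, UndefinedStatisticError

from conftest import random_defect_pair


def brute_force_overlap(a, b, roi):
    match = total = 0
    for idx in np.ndindex(roi.shape):
        if roi[idx]:
            total += 1
            if a.qdm[idx] == b.qdm[idx]:
                match += 1
    return 100.0 * match / total


def brute_force_dice(a, b, roi, label):
    qa = a.qdm if label == "defect" else ~a.qdm
    qb = b.qdm if label == "defect" else ~b.qdm
    na = nb = ni = 0
    for idx in np.ndindex(roi.shape):
        if roi[idx]:
            na += bool(qa[idx])
            nb += bool(qb[idx])
            ni += bool(qa[idx] and qb[idx])
    return float("nan") if na + nb == 0 else 2.0 * ni / (na + nb)


class TestOverlapAndDice:
    def test_identical_maps_full_agreement(self):
        rng = np.random.default_rng(0)
        a, _, roi = random_defect_pair(rng)
        assert cp.overlap_metric(a, a, roi) == 100.0
        assert cp.dice(a, a, "defect", roi) == 1.0
        assert cp.dice(a, a, "healthy", roi) == 1.0

    def test_complementary_maps_zero_overlap(self):
        rng = np.random.default_rng(1)
        a, _, roi = random_defect_pair(rng)
        comp = DefectMap(qdm=~a.qdm & roi, mask=roi, threshold=1.0)
        assert cp.overlap_metric(a, comp, roi) == 0.0

    def test_disjoint_defects_zero_dice(self):
        roi = np.ones((4, 4, 4), dtype=bool)
        qa = np.zeros_like(roi)
        qb = np.zeros_like(roi)
        qa[0], qb[1] = True, True
        a = DefectMap(qdm=qa, mask=roi, threshold=1.0)
        b = DefectMap(qdm=qb, mask=roi, threshold=1.0)
        assert cp.dice(a, b, "defect", roi) == 0.0

    def test_dice_constructed_60_40_30(self):
        """|A|=60, |B|=40, |A∩B|=30 -> Dice = 0.6."""
        roi = np.ones((100, 1, 1), dtype=bool)
        qa = np.zeros_like(roi)
        qb = np.zeros_like(roi)
        qa[:60] = True
        qb[30:70] = True  # overlap = indices 30..59 -> 30 voxels
        a = DefectMap(qdm=qa, mask=roi, threshold=1.0)
        b = DefectMap(qdm=qb, mask=roi, threshold=1.0)
        assert cp.dice(a, b, "defect", roi) == pytest.approx(0.6, abs=1e-14)

    def test_empty_empty_label_is_missing_not_one(self):
        roi = np.ones((3, 3, 3), dtype=bool)
        empty = DefectMap(qdm=np.zeros_like(roi), mask=roi, threshold=1.0)
        assert np.isnan(cp.dice(empty, empty, "defect", roi))

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b, roi = random_defect_pair(rng, shape=(5, 5, 4))
            assert cp.overlap_metric(a, b, roi) == pytest.approx(
                brute_force_overlap(a, b, roi), abs=1e-12
            )
            for label in ("defect", "healthy"):
                assert cp.dice(a, b, label, roi) == pytest.approx(
                    brute_force_dice(a, b, roi, label), abs=1e-12
                )

    def test_overlap_dice_linkage_identity(self):
        """overlap = (dice_d·(|A_d|+|B_d|)/2 + dice_h·(|A_h|+|B_h|)/2)/|ROI|."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b, roi = random_defect_pair(rng)
            n = roi.sum()
            nd = a.qdm[roi].sum() + b.qdm[roi].sum()
            nh = 2 * n - nd
            dd = cp.dice(a, b, "defect", roi)
            dh = cp.dice(a, b, "healthy", roi)
            dd = 0.0 if np.isnan(dd) else dd
            dh = 0.0 if np.isnan(dh) else dh
            linked = 100.0 * (dd * nd / 2 + dh * nh / 2) / n
            assert cp.overlap_metric(a, b, roi) == pytest.approx(linked, abs=1e-9)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(5.0)
        r, _ = cp.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0, abs=1e-12)
        r, _ = cp.pearson(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_from_definition_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 4.1, 3.9, 8.0, 6.5])
        r, p = cp.pearson(x, y)
        r_def = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(r_def, abs=1e-12)
        from scipy import stats

        t = r_def * np.sqrt(3 / (1 - r_def**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=3), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cp.pearson(np.ones(5), np.arange(5.0))
        with pytest.raises(DataError):
            cp.pearson(np.arange(2.0), np.arange(2.0))


class TestPairedDeltaTest:
    def test_no_change_flagged(self):
        pre = np.array([3.0, 4.0, 5.0])
        res = cp.paired_delta_test(pre, pre)
        assert res.mean_delta == 0.0 and res.t == 0.0 and np.isnan(res.p)

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(40, 60, 12)
        post = pre - 8.0 + rng.normal(0, 1, 12)
        res = cp.paired_delta_test(pre, post)
        assert res.mean_delta == pytest.approx(-8.0, abs=1.5)
        assert res.p < 0.01

    def test_antisymmetric_in_order(self):
        rng = np.random.default_rng(1)
        pre = rng.uniform(0, 1, 8)
        post = pre + rng.normal(0, 1, 8)
        f, b = cp.paired_delta_test(pre, post), cp.paired_delta_test(post, pre)
        assert f.mean_delta == pytest.approx(-b.mean_delta, abs=1e-14)
        assert f.t == pytest.approx(-b.t, abs=1e-12)


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = cp.bland_altman(x, x)
        assert (ba.bias, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)

    def test_hand_computed_limits(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([2.0, 1.0, 0.0])  # diffs -2, 0, 2; sd = 2
        ba = cp.bland_altman(x, y)
        assert ba.bias == pytest.approx(0.0, abs=1e-14)
        assert ba.loa_high == pytest.approx(1.96 * 2.0, abs=1e-12)
        assert ba.loa_low == pytest.approx(-1.96 * 2.0, abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert cp.bland_altman(x + 5.0, y).bias == pytest.approx(
            cp.bland_altman(x, y).bias + 5.0, abs=1e-12
        )


def _toy_qdp_df():
    """Three subjects, two parameters, lobe-referenced whole-lung rows only."""
    rows = []
    values = {
        "S1": {"CT_PBV": 40.0, "MRI_PBF": 42.0},
        "S2": {"CT_PBV": 50.0, "MRI_PBF": 49.0},
        "S3": {"CT_PBV": 60.0, "MRI_PBF": 63.0},
    }
    for sid, params in values.items():
        for param, qdp in params.items():
            for roi in ("whole_lung",) + cp.LOBE_NAMES:
                rows.append(
                    {
                        "subject_id": sid,
                        "phase": "pre_op",
                        "modality": param.split("_")[0],
                        "parameter": param,
                        "roi": roi,
                        "reference": "lobe_volume",
                        "qdp_percent": qdp,  # same value in every ROI
                    }
                )
    return pd.DataFrame(rows)


class TestCohortReport:
    def test_cross_modality_means_match_hand_computation(self):
        tab = cross_modality_table(_toy_qdp_df(), None, "CT_PBV", "MRI_PBF").set_index("roi")
        assert len(tab) == 6  # whole lung + 5 lobes
        assert tab.loc["whole_lung", "CT_PBV_mean"] == pytest.approx(50.0)
        assert tab.loc["whole_lung", "MRI_PBF_mean"] == pytest.approx((42 + 49 + 63) / 3)
        assert tab.loc["whole_lung", "n"] == 3
        r_hand, _ = cp.pearson(np.array([40.0, 50, 60]), np.array([42.0, 49, 63]))
        assert tab.loc["whole_lung", "pearson_r"] == pytest.approx(r_hand, abs=1e-12)

    def test_dual_session_subject_deduplicated_with_seed(self):
        df = _toy_qdp_df()
        extra = df[df["subject_id"] == "S1"].copy()
        extra["phase"] = "post_op"
        df = pd.concat([df, extra], ignore_index=True)
        kept, chosen = select_single_sessions(df, seed=0)
        assert (kept[kept["subject_id"] == "S1"]["phase"] == chosen["S1"]).all()
        assert len(kept[kept["subject_id"] == "S1"]) == len(
            df[(df["subject_id"] == "S1") & (df["phase"] == chosen["S1"])]
        )
        # same seed -> same choice
        _, chosen2 = select_single_sessions(df, seed=0)
        assert chosen == chosen2

    def test_pre_post_table_paired_stats(self):
        rows = []
        rng = np.random.default_rng(0)
        deltas = []
        for i in range(6):
            pre = 50.0 + rng.normal(0, 3)
            delta = -10.0 + rng.normal(0, 1)
            deltas.append(delta)
            for phase, qdp in (("pre_op", pre), ("post_op", pre + delta)):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "phase": phase,
                        "modality": "CT",
                        "parameter": "CT_PBV",
                        "roi": "whole_lung",
                        "reference": "lobe_volume",
                        "qdp_percent": qdp,
                    }
                )
        tab = pre_post_table(pd.DataFrame(rows), "CT_PBV").set_index("roi")
        assert tab.loc["whole_lung", "delta_mean"] == pytest.approx(np.mean(deltas), abs=1e-9)
        assert tab.loc["whole_lung", "n"] == 6
        assert tab.loc["whole_lung", "p_value"] < 0.001
        assert bool(tab.loc["whole_lung", "significant"])

    def test_absent_modality_produces_no_table(self, tmp_path):
        df = _toy_qdp_df()
        df = df[df["parameter"] == "CT_PBV"]
        tables = cp.cohort_report(df, None, tmp_path)
        assert not any("cross" in name for name in tables)
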