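import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from perfmap.evaluate import (
    MetricRecord,
    compare_models,
    dsc,
    error_stats,
    evaluate_case,
    iou,
    itpc,
    surface_distance_metrics,
)

from conftest import make_mask


def brute_force_overlap(a, b):
    """Set-arithmetic Dice/IoU oracle."""
    pa = {tuple(p) for p in np.argwhere(a)}
    pb = {tuple(p) for p in np.argwhere(b)}
    if not pa and not pb:
        return 1.0, 1.0
    inter = len(pa & pb)
    d = 2 * inter / (len(pa) + len(pb)) if (pa or pb) else 1.0
    j = inter / len(pa | pb)
    return d, j


def brute_force_surface(a, b, spacing):
    """All-pairs surface-distance oracle (pad-and-check surface extraction)."""

    def surface(m):
        pad = np.pad(m, 1)
        pts = []
        for z, y, x in np.argwhere(m):
            zz, yy, xx = z + 1, y + 1, x + 1
            nb = [pad[zz - 1, yy, xx], pad[zz + 1, yy, xx], pad[zz, yy - 1, xx],
                  pad[zz, yy + 1, xx], pad[zz, yy, xx - 1], pad[zz, yy, xx + 1]]
            if not all(nb):
                pts.append((z, y, x))
        return np.asarray(pts, dtype=float) * np.asarray(spacing)

    sa, sb = surface(a), surface(b)
    d = cdist(sa, sb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return pooled.mean(), pooled.max(), np.percentile(pooled, 95)


def random_mask_pair(rng, shape=(12, 12, 12)):
    while True:
        a = rng.random(shape) > 0.75
        b = rng.random(shape) > 0.75
        if a.any() and b.any():
            return a, b


class TestOverlapMetrics:
    def test_identical_masks(self):
        m = make_mask(np.ones((3, 3, 3)))
        assert dsc(m, m) == 1.0 and iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((2, 2, 4)); a[..., :2] = 1
        b = np.zeros((2, 2, 4)); b[..., 2:] = 1
        assert dsc(make_mask(a), make_mask(b)) == 0.0
        assert iou(make_mask(a), make_mask(b)) == 0.0

    def test_two_voxel_overlap_case(self):
        a = np.zeros((1, 1, 3)); a[0, 0, :2] = 1
        b = np.zeros((1, 1, 3)); b[0, 0, 1:] = 1
        assert dsc(make_mask(a), make_mask(b)) == pytest.approx(0.5)
        assert iou(make_mask(a), make_mask(b)) == pytest.approx(1.0 / 3.0)

    def test_both_empty_convention(self):
        e = make_mask(np.zeros((2, 2, 2)))
        assert dsc(e, e) == 1.0 and iou(e, e) == 1.0

    def test_jaccard_dice_identity_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a, b = random_mask_pair(rng)
            d = dsc(make_mask(a), make_mask(b))
            j = iou(make_mask(a), make_mask(b))
            assert j == pytest.approx(d / (2 - d), abs=1e-12)
            assert d >= j


class TestSurfaceMetrics:
    def test_identical_masks_zero_distances(self):
        m = make_mask(np.pad(np.ones((2, 2, 2)), 1))
        assert surface_distance_metrics(m, m) == (0.0, 0.0, 0.0)

    def test_two_single_voxels(self):
        a = np.zeros((1, 1, 12)); a[0, 0, 0] = 1
        b = np.zeros((1, 1, 12)); b[0, 0, 10] = 1
        asd, hd, hd95 = surface_distance_metrics(
            make_mask(a, spacing=(1, 1, 0.7)), make_mask(b, spacing=(1, 1, 0.7))
        )
        assert asd == hd == hd95 == pytest.approx(7.0)

    def test_hd_symmetric_and_hd95_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = random_mask_pair(rng)
            ma, mb = make_mask(a, (1.0, 0.8, 0.8)), make_mask(b, (1.0, 0.8, 0.8))
            asd1, hd1, hd951 = surface_distance_metrics(ma, mb)
            asd2, hd2, hd952 = surface_distance_metrics(mb, ma)
            assert hd1 == pytest.approx(hd2, abs=1e-12)
            assert hd951 <= hd1 + 1e-12

    def test_empty_mask_flagged_undefined(self):
        with pytest.raises(ValueError):
            surface_distance_metrics(make_mask(np.zeros((2, 2, 2))), make_mask(np.ones((2, 2, 2))))

    def test_evaluate_case_flags_empty_prediction(self):
        rec = evaluate_case(make_mask(np.zeros((2, 2, 2))), make_mask(np.ones((2, 2, 2))))
        assert rec.dsc == 0.0 and rec.asd_mm is None and not rec.complete()


class TestItpc:
    def test_mean_and_single_and_order(self):
        assert itpc([("a", 2.0), ("b", 4.0)]) == 3.0
        assert itpc([("a", 2.5)]) == 2.5
        assert itpc([("b", 4.0), ("a", 2.0)]) == 3.0
        with pytest.raises(ValueError):
            itpc([])


class TestErrorStats:
    def test_identical_lists_all_zero(self):
        s = error_stats([1.0, 2.0], [1.0, 2.0])
        assert s.mae_mm == s.mdae_mm == s.rmse_mm == 0.0

    def test_constant_offset(self):
        s = error_stats([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert s.mae_mm == s.mdae_mm == s.rmse_mm == pytest.approx(2.0)

    def test_hand_case_1234(self):
        s = error_stats([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])
        assert s.mae_mm == pytest.approx(2.5)
        assert s.mdae_mm == pytest.approx(2.5)
        assert s.rmse_mm == pytest.approx(np.sqrt(7.5))
        assert s.iqr_mm == pytest.approx((1.75, 3.25))

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p, r = rng.normal(size=15), rng.normal(size=15)
            s = error_stats(p, r)
            assert s.rmse_mm >= s.mae_mm >= 0
            assert s.iqr_mm[0] <= s.iqr_mm[1]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            error_stats([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            error_stats([], [])


def _records_from(rng, model_ids, shift=0.0):
    recs = []
    for m in model_ids:
        for i in range(10):
            d = float(np.clip(rng.uniform(0.3, 0.7) + (shift if m == model_ids[-1] else 0), 0, 1))
            recs.append(
                MetricRecord(
                    case_id=f"c{i}", model_id=m, dsc=d, iou=d / (2 - d),
                    asd_mm=float(rng.uniform(0.5, 2)), hd_mm=float(rng.uniform(4, 8)),
                    hd95_mm=float(rng.uniform(2, 4)),
                )
            )
    return recs


class TestCompareModels:
    def test_identical_groups_show_no_effect(self):
        rng = np.random.default_rng(3)
        base = _records_from(rng, ["A"])
        recs = []
        for m in ("A", "B", "C"):
            for r in base:
                recs.append(MetricRecord(r.case_id, m, r.dsc, r.iou, r.asd_mm, r.hd_mm, r.hd95_mm))
        res = compare_models(recs)
        assert res.manova["wilks_lambda"] == pytest.approx(1.0)
        assert not any(t["significant"] for t in res.tukey)

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(12)
        recs = []
        for m, mu in (("A", 0.0), ("B", 10.0)):
            for i in range(20):
                v = float(rng.normal(mu, 1.0))
                recs.append(
                    MetricRecord(f"c{i}", m, dsc=float(rng.uniform(.4,.6)), iou=.4,
                                 asd_mm=v, hd_mm=v + 5, hd95_mm=v + 4)
                )
        res = compare_models(recs)
        assert res.per_metric_anova["asd_mm"]["p_value"] < 1e-3
        assert any(t["significant"] and t["metric"] == "asd_mm" for t in res.tukey)

    def test_tukey_covers_all_pairs_per_metric(self):
        rng = np.random.default_rng(4)
        res = compare_models(_records_from(rng, ["A", "B", "C"], shift=0.05))
        per_metric = {}
        for t in res.tukey:
            per_metric.setdefault(t["metric"], []).append(t["pair"])
        k = 3
        for pairs in per_metric.values():
            assert len(pairs) == k * (k - 1) // 2
            assert len(set(pairs)) == len(pairs)

    def test_insufficient_groups_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            compare_models(_records_from(rng, ["A"]))


class TestBruteForceEquivalence:
    def test_metrics_match_brute_force_oracles(self):
        rng = np.random.default_rng(21)
        spacing = (1.0, 0.8, 0.8)
        for _ in range(30):
            a, b = random_mask_pair(rng)
            ma, mb = make_mask(a, spacing), make_mask(b, spacing)
            d_exp, j_exp = brute_force_overlap(a, b)
            assert dsc(ma, mb) == pytest.approx(d_exp, abs=1e-12)
            assert iou(ma, mb) == pytest.approx(j_exp, abs=1e-12)
            asd_e, hd_e, hd95_e = brute_force_surface(a, b, spacing)
            asd, hd, hd95 = surface_distance_metrics(ma, mb)
            assert asd == pytest.approx(asd_e, abs=1e-9)
            assert hd == pytest.approx(hd_e, abs=1e-9)
            assert hd95 == pytest.approx(hd95_e, abs=1e-9)
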