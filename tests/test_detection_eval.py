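"""COCO AP/AR metrics, sieving correlation, and run comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from silageqc.core import AnnotationSet, Calibration, Instance
from silageqc.detection_eval import (
    compare_runs,
    evaluate_detections,
    pearson_correlation,
)
from silageqc.quality import QualityEstimate
from silageqc.synthetic import (
    DetectorProfile,
    HarvestSimConfig,
    SievingRecord,
    generate_harvest,
    simulate_detector,
)

from conftest import make_image, make_set, random_convex_polygon, square
from oracles import coco_oracle


def _perfect_detections(gt):
    return AnnotationSet(
        source_id="det", images=dict(gt.images),
        instances=[
            dataclasses.replace(i, instance_id=i.instance_id + "d", score=1.0)
            for i in gt.instances
        ],
    )


def _random_scene(rng, n_gt, n_det, image_id="img0"):
    rec = make_image(image_id=image_id)
    gt_polys = [
        random_convex_polygon(rng, rng.uniform(100, 900, 2), 60.0) for _ in range(n_gt)
    ]
    gt = AnnotationSet(
        source_id="gt", images={image_id: rec},
        instances=[
            Instance(f"g{k}", image_id, "kernel_fragment", p)
            for k, p in enumerate(gt_polys)
        ],
    )
    det_polys = []
    for k in range(n_det):
        if k < n_gt and rng.random() < 0.7:  # jittered copy of a gt polygon
            from shapely.geometry import Polygon as SP

            p = gt_polys[k] + rng.normal(0, rng.uniform(1, 12), size=gt_polys[k].shape)
            det_polys.append(np.asarray(SP(p).convex_hull.exterior.coords[:-1]))
        else:
            det_polys.append(random_convex_polygon(rng, rng.uniform(100, 900, 2), 60.0))
    det = AnnotationSet(
        source_id="det", images={image_id: rec},
        instances=[
            Instance(f"d{k}", image_id, "kernel_fragment", p,
                     score=float(rng.uniform(0.05, 1.0)))
            for k, p in enumerate(det_polys)
        ],
    )
    return gt, det


class TestEvaluateDetections:
    def test_perfect_detections_score_100(self):
        gt = generate_harvest(HarvestSimConfig(n_images=4, seed=61))
        res = evaluate_detections(gt, _perfect_detections(gt))
        for m in ("AP", "AP50", "AP75", "AR100"):
            assert res.overall[m] == pytest.approx(100.0)

    def test_low_iou_detection_scores_zero_at_half(self):
        gt = make_set([square(0, 0, 100)])
        # shifted square: IoU = 40000/... = (100-60)*100 / (2*10000 - 4000) = 0.25
        det = make_set([square(60, 0, 100)], source_id="det", scores=[0.9])
        res = evaluate_detections(gt, det)
        assert res.overall["AP50"] == 0.0

    def test_unscored_detection_rejected(self):
        gt = make_set([square(0, 0, 100)])
        det = make_set([square(0, 0, 100)], source_id="det")
        with pytest.raises(ValueError, match="score"):
            evaluate_detections(gt, det)

    def test_class_missing_from_gt_rejected(self):
        gt = make_set([square(0, 0, 100)], label="accepted_leaf")
        det = make_set([square(0, 0, 100)], source_id="det",
                       label="inner_stalk", scores=[0.9])
        with pytest.raises(ValueError, match="taxonomy"):
            evaluate_detections(gt, det)

    def test_invariants_on_simulated_detector(self):
        gt = generate_harvest(HarvestSimConfig(n_images=6, seed=67))
        det = simulate_detector(gt, DetectorProfile(seed=3))
        res = evaluate_detections(gt, det)
        o = res.overall
        assert 0 <= o["AP"] <= o["AP50"] <= 100
        assert o["AR1"] <= o["AR10"] <= o["AR100"] <= 100

    def test_matches_brute_force_oracle_on_random_scenes(self):
        rng = np.random.default_rng(71)
        for s in range(30):
            gt, det = _random_scene(
                rng, n_gt=int(rng.integers(1, 8)), n_det=int(rng.integers(1, 12))
            )
            res = evaluate_detections(gt, det)
            ora = coco_oracle(gt, det)
            for m, v in res.overall.items():
                assert v == pytest.approx(ora["overall"][m], abs=1e-9), (s, m)

    def test_ap_decreases_with_localization_jitter(self):
        gt = generate_harvest(HarvestSimConfig(n_images=4, seed=73))
        aps = []
        for jitter in (0.5, 6.0, 14.0):
            vals = [
                evaluate_detections(
                    gt,
                    simulate_detector(
                        gt,
                        DetectorProfile(localization_jitter_px=jitter, fp_rate=0.0,
                                        seed=seed),
                    ),
                ).overall["AP"]
                for seed in range(8)
            ]
            aps.append(np.mean(vals))
        assert aps[0] > aps[1] > aps[2]

    def test_score_tie_break_is_order_invariant(self):
        gt = make_set([square(0, 0, 100), square(300, 300, 100)])
        rec = gt.images["img0"]
        dets = [
            Instance("d0", "img0", "kernel_fragment", square(2, 0, 100), score=0.8),
            Instance("d1", "img0", "kernel_fragment", square(302, 300, 100), score=0.8),
        ]
        r1 = evaluate_detections(
            gt, AnnotationSet(source_id="d", images={"img0": rec}, instances=dets)
        )
        r2 = evaluate_detections(
            gt, AnnotationSet(source_id="d", images={"img0": rec},
                              instances=list(reversed(dets)))
        )
        assert r1.overall == r2.overall


class TestPearsonCorrelation:
    def _records(self, vals, week="CW40"):
        return [
            SievingRecord(sample_id=f"s{k}", calendar_week=week, csps_percent=v)
            for k, v in enumerate(vals)
        ]

    def _estimates(self, vals, week="CW40"):
        return [
            QualityEstimate(sample_id=f"s{k}", calendar_week=week, csps_percent=v,
                            n_fragments=10, n_passing=5, weighting="area")
            for k, v in enumerate(vals)
        ]

    def test_perfect_agreement_r_one(self):
        vals = [20.0, 45.0, 70.0, 95.0]
        res = pearson_correlation(self._estimates(vals), self._records(vals))
        assert res[0].pcc == pytest.approx(1.0)
        assert res[0].n == 4

    def test_anticorrelated_r_minus_one(self):
        vals = [20.0, 45.0, 70.0, 95.0]
        flipped = [100.0 - v for v in vals]
        res = pearson_correlation(self._estimates(vals), self._records(flipped))
        assert res[0].pcc == pytest.approx(-1.0)

    def test_noise_attenuation_within_3_se(self):
        rng = np.random.default_rng(79)
        n, sigma = 50, 5.0
        truth = rng.uniform(20, 90, n)
        noisy = truth + rng.normal(0, sigma, n)
        ests = [
            QualityEstimate(sample_id=f"s{k}", calendar_week="CW40",
                            csps_percent=float(np.clip(v, 0, 100)),
                            n_fragments=1, n_passing=1, weighting="area")
            for k, v in enumerate(noisy)
        ]
        recs = [
            SievingRecord(sample_id=f"s{k}", calendar_week="CW40",
                          csps_percent=float(truth[k]))
            for k in range(n)
        ]
        r = pearson_correlation(ests, recs)[0].pcc
        sd = truth.std()
        expected = sd / np.sqrt(sd**2 + sigma**2)  # analytic attenuation
        se = (1 - expected**2) / np.sqrt(n - 3)
        assert abs(r - expected) < 3 * se

    def test_pooled_group_over_two_weeks(self):
        e = self._estimates([20.0, 50.0, 80.0], "CW40") + self._estimates(
            [30.0, 60.0, 90.0], "CW43"
        )
        # re-key the second week's ids to keep sample ids unique
        e = e[:3] + [dataclasses.replace(x, sample_id=x.sample_id + "b") for x in e[3:]]
        s = self._records([22.0, 49.0, 78.0], "CW40") + [
            dataclasses.replace(x, sample_id=x.sample_id + "b")
            for x in self._records([33.0, 58.0, 88.0], "CW43")
        ]
        res = pearson_correlation(e, s)
        groups = {r.group for r in res}
        assert groups == {"CW40", "CW43", "CW40+CW43"}
        pooled = next(r for r in res if r.group == "CW40+CW43")
        assert pooled.n == 6

    def test_unpaired_ids_listed(self):
        with pytest.raises(ValueError, match="s9"):
            pearson_correlation(
                self._estimates([1.0, 2.0, 3.0]),
                self._records([1.0, 2.0, 3.0])[:2]
                + [SievingRecord("s9", "CW40", 5.0)],
            )

    def test_zero_variance_reports_absent(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = pearson_correlation(
                self._estimates([50.0, 50.0, 50.0]), self._records([1.0, 2.0, 3.0])
            )
        assert res[0].pcc is None


class TestCompareRuns:
    def test_published_delta_arithmetic(self):
        table = pd.DataFrame(
            {"AP": [17.20, 20.75], "AP50": [32.15, 38.35]},
            index=["baseline", "best"],
        )
        (cmp,) = compare_runs(table, baseline="baseline")
        assert cmp.deltas_pp["AP"] == pytest.approx(3.55)
        assert cmp.deltas_pp["AP50"] == pytest.approx(6.20)

    def test_identical_run_zero_deltas(self):
        table = pd.DataFrame({"AP": [10.0, 10.0]}, index=["baseline", "same"])
        (cmp,) = compare_runs(table, baseline="baseline")
        assert cmp.deltas_pp["AP"] == 0.0
        assert cmp.ratios["AP"] == 1.0

    def test_large_ratio_flagged_best(self):
        table = pd.DataFrame(
            {"AP": [4.97, 17.66, np.nan]}, index=["baseline", "ssl", "diverged"]
        )
        results = {c.run_id: c for c in compare_runs(table, baseline="baseline")}
        assert results["ssl"].deltas_pp["AP"] == pytest.approx(12.69)
        assert results["ssl"].ratios["AP"] > 3
        assert "AP" in results["ssl"].best_for
        assert np.isnan(results["diverged"].deltas_pp["AP"])
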