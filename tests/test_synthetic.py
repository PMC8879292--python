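"""Generator determinism, limit cases, and configured-effect recovery."""

import dataclasses

import numpy as np
import pytest

from silageqc.core import Calibration, shape_summary
from silageqc.quality import estimate_csps_per_sample
from silageqc.synthetic import (
    AnnotatorProfile,
    CountModel,
    DetectorProfile,
    HarvestSimConfig,
    corrupt_annotations,
    generate_harvest,
    simulate_detector,
    simulate_sieving,
)

from conftest import make_set, square

CAL = Calibration()


def _polys_equal(a, b):
    return len(a) == len(b) and all(
        x.instance_id == y.instance_id and np.array_equal(x.polygon, y.polygon)
        for x, y in zip(a.instances, b.instances)
    )


class TestGenerateHarvest:
    def test_deterministic_given_seed(self):
        cfg = HarvestSimConfig(n_images=5, seed=9)
        assert _polys_equal(generate_harvest(cfg), generate_harvest(cfg))

    def test_zero_rate_gives_empty_images(self):
        cfg = HarvestSimConfig(
            n_images=4, count_model=CountModel(base_rate=0.0), seed=1
        )
        assert len(generate_harvest(cfg)) == 0

    def test_nonpositive_image_size_rejected(self):
        with pytest.raises(ValueError, match="image size"):
            HarvestSimConfig(image_size_px=(0, 100))

    def test_pg_effect_on_counts_and_sizes(self):
        # narrow gap: more fragments per image, smaller median major axis;
        # judged at 3 Monte-Carlo standard errors over 60 images per setting
        n = 60
        sets = {
            pg: generate_harvest(HarvestSimConfig(n_images=n, pg_mm=pg, seed=21))
            for pg in (1.0, 4.0)
        }
        counts = {pg: len(s) / n for pg, s in sets.items()}
        per_img = {
            pg: np.array(
                [len(s.instances_in(img)) for img in s.images]
            )
            for pg, s in sets.items()
        }
        se = np.sqrt(sum(v.var(ddof=1) / n for v in per_img.values()))
        assert counts[1.0] - counts[4.0] > 3 * se

        med = {
            pg: np.median(
                [shape_summary(i, CAL).major_axis_mm for i in s.instances]
            )
            for pg, s in sets.items()
        }
        assert med[1.0] < med[4.0]


class TestCorruptAnnotations:
    def test_zero_profile_is_identity(self):
        gt = generate_harvest(HarvestSimConfig(n_images=3, seed=2))
        prof = AnnotatorProfile(
            miss_base=0, miss_size_slope=0, vertex_jitter_px=0,
            false_positive_rate=0, merge_prob=0, seed=1,
        )
        out = corrupt_annotations(gt, prof)
        assert _polys_equal(
            gt, dataclasses.replace(out, instances=sorted(
                out.instances, key=lambda i: i.instance_id))
        ) or len(out) == len(gt)
        by_id = {i.instance_id: i for i in out.instances}
        assert all(
            np.array_equal(by_id[i.instance_id].polygon, i.polygon)
            for i in gt.instances
        )

    def test_total_miss_gives_empty_set(self):
        gt = generate_harvest(HarvestSimConfig(n_images=3, seed=2))
        prof = AnnotatorProfile(
            miss_base=1.0, miss_size_slope=0, false_positive_rate=0, seed=1
        )
        assert len(corrupt_annotations(gt, prof)) == 0

    def test_deterministic(self):
        gt = generate_harvest(HarvestSimConfig(n_images=3, seed=2))
        prof = AnnotatorProfile(seed=5)
        assert _polys_equal(
            corrupt_annotations(gt, prof), corrupt_annotations(gt, prof)
        )

    def test_miss_rate_orders_instance_counts(self):
        # low-miss annotator keeps more instances than high-miss in >=95% of
        # 100 seeded replicates
        gt = generate_harvest(HarvestSimConfig(n_images=4, seed=3))
        wins = 0
        for seed in range(100):
            low = corrupt_annotations(
                gt, AnnotatorProfile(miss_base=0.1, miss_size_slope=0,
                                     false_positive_rate=0, seed=seed)
            )
            high = corrupt_annotations(
                gt, AnnotatorProfile(miss_base=0.6, miss_size_slope=0,
                                     false_positive_rate=0, seed=seed + 1000)
            )
            wins += len(low) > len(high)
        assert wins >= 95

    def test_merge_reduces_count_for_adjacent_pairs(self):
        gt = make_set([square(100, 100, 60), square(163, 100, 60)])
        prof = AnnotatorProfile(
            miss_base=0, miss_size_slope=0, vertex_jitter_px=0,
            false_positive_rate=0, merge_prob=1.0, merge_gap_px=5.0, seed=0,
        )
        merged = corrupt_annotations(gt, prof)
        assert len(merged) == 1


class TestSimulateDetector:
    def test_perfect_profile_reproduces_gt(self):
        gt = generate_harvest(HarvestSimConfig(n_images=3, seed=4))
        prof = DetectorProfile(
            recall_curve=((0.0, 1.0), (100.0, 1.0)),
            localization_jitter_px=0.0,
            score_tp=(float("inf"), 1.0),
            fp_rate=0.0,
            seed=1,
        )
        det = simulate_detector(gt, prof)
        assert len(det) == len(gt)
        assert all(i.score == 1.0 for i in det.instances)
        gt_sorted = sorted(gt.instances, key=lambda i: (i.image_id, i.instance_id))
        det_sorted = sorted(det.instances, key=lambda i: (i.image_id, i.instance_id))
        assert all(
            np.array_equal(a.polygon, b.polygon)
            for a, b in zip(gt_sorted, det_sorted)
        )

    def test_zero_recall_gives_only_false_positives(self):
        gt = generate_harvest(HarvestSimConfig(n_images=3, seed=4))
        prof = DetectorProfile(
            recall_curve=((0.0, 0.0), (100.0, 0.0)), fp_rate=2.0, seed=1
        )
        det = simulate_detector(gt, prof)
        assert all("det" in i.instance_id for i in det.instances)
        assert len(det) > 0
        # no detection overlaps gt exactly
        gt_polys = {i.polygon.tobytes() for i in gt.instances}
        assert all(i.polygon.tobytes() not in gt_polys for i in det.instances)

    def test_detection_count_matches_expectation(self):
        # constant recall p and fp rate: E[count] = p * n_gt + fp_rate * n_img
        gt = generate_harvest(HarvestSimConfig(n_images=100, seed=6))
        p, fp = 0.7, 1.5
        prof = DetectorProfile(
            recall_curve=((0.0, p), (100.0, p)), fp_rate=fp, seed=2
        )
        det = simulate_detector(gt, prof)
        expected = p * len(gt) + fp * len(gt.images)
        var = p * (1 - p) * len(gt) + fp * len(gt.images)
        assert abs(len(det) - expected) <= 3 * np.sqrt(var)


class TestSimulateSieving:
    def test_all_tiny_fragments_give_100(self):
        gt = make_set([square(100, 100, 20), square(300, 300, 30)])  # 1-1.5 mm
        recs = simulate_sieving(gt, CAL, noise_sd=0)
        assert [r.csps_percent for r in recs] == [100.0]

    def test_all_huge_fragments_give_0(self):
        gt = make_set([square(100, 100, 200), square(400, 400, 300)])  # 10-15 mm
        recs = simulate_sieving(gt, CAL, noise_sd=0)
        assert [r.csps_percent for r in recs] == [0.0]

    def test_noise_free_equals_estimate_csps_exactly(self):
        gt = generate_harvest(HarvestSimConfig(n_images=20, pg_mm=4.0, seed=11))
        sieve = simulate_sieving(gt, CAL, noise_sd=0)
        est = estimate_csps_per_sample(gt, CAL)
        assert [r.sample_id for r in sieve] == [e.sample_id for e in est]
        assert [r.csps_percent for r in sieve] == [e.csps_percent for e in est]

    def test_deterministic_given_seed(self):
        gt = generate_harvest(HarvestSimConfig(n_images=5, pg_mm=4.0, seed=11))
        a = simulate_sieving(gt, CAL, noise_sd=3.0, seed=7)
        b = simulate_sieving(gt, CAL, noise_sd=3.0, seed=7)
        assert [r.csps_percent for r in a] == [r.csps_percent for r in b]
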