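"""IoU matching, overlap counts, and Cohen's kappa between annotators."""

import dataclasses

import numpy as np
import pytest

from silageqc.agreement import (
    KappaReport,
    cohen_kappa,
    match_instances,
    overlap_counts,
    pairwise_agreement_report,
)
from silageqc.core import AnnotationSet, Instance
from silageqc.synthetic import AnnotatorProfile, HarvestSimConfig, corrupt_annotations, generate_harvest

from conftest import make_image, make_set, random_convex_polygon, square
from oracles import hand_cohen_kappa, max_cardinality_matching


def _copy_with_ids(aset, suffix, shift=0.0):
    return AnnotationSet(
        source_id=aset.source_id + suffix,
        images=dict(aset.images),
        instances=[
            Instance(i.instance_id + suffix, i.image_id, i.label, i.polygon + shift)
            for i in aset.instances
        ],
    )


class TestMatchInstances:
    def test_identical_sets_match_fully_at_iou_one(self):
        a = make_set([square(10, 10, 40), square(200, 200, 80)], source_id="a")
        b = _copy_with_ids(a, "b")
        m = match_instances(a, b)
        assert len(m.pairs) == 2
        assert all(iou == pytest.approx(1.0) for _, _, iou in m.pairs)
        assert overlap_counts(m) == (2, 2, 2)

    def test_translated_beyond_overlap_matches_nothing(self):
        a = make_set([square(10, 10, 40)], source_id="a")
        b = _copy_with_ids(a, "b", shift=500.0)
        m = match_instances(a, b)
        assert m.pairs == ()
        assert overlap_counts(m) == (1, 1, 0)

    def test_threshold_outside_open_interval_rejected(self):
        a = make_set([square(10, 10, 40)])
        with pytest.raises(ValueError, match="iou_threshold"):
            match_instances(a, a, iou_threshold=1.0)

    def test_raising_threshold_never_increases_agreement(self):
        gt = generate_harvest(HarvestSimConfig(n_images=4, seed=13))
        noisy = corrupt_annotations(gt, AnnotatorProfile(vertex_jitter_px=4.0, seed=5))
        agreed = [
            overlap_counts(match_instances(gt, noisy, iou_threshold=t))[2]
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        assert agreed == sorted(agreed, reverse=True)

    def test_greedy_vs_hungarian_on_random_scenes(self):
        """Greedy one-to-one matching never exceeds the maximum-cardinality
        assignment and equals it on non-adversarial random scenes."""
        rng = np.random.default_rng(99)
        equal = 0
        n_scenes = 100
        for s in range(n_scenes):
            rec = make_image()
            n = int(rng.integers(3, 7))
            polys = [
                random_convex_polygon(rng, rng.uniform(100, 900, 2), 60.0)
                for _ in range(n)
            ]
            a = AnnotationSet(
                source_id="a", images={rec.image_id: rec},
                instances=[
                    Instance(f"a{k}", rec.image_id, "kernel_fragment", p)
                    for k, p in enumerate(polys)
                ],
            )
            jitter = [p + rng.normal(0, 3.0, size=p.shape) for p in polys]
            from shapely.geometry import Polygon as SP
            jitter = [np.asarray(SP(p).convex_hull.exterior.coords[:-1]) for p in jitter]
            b = AnnotationSet(
                source_id="b", images={rec.image_id: rec},
                instances=[
                    Instance(f"b{k}", rec.image_id, "kernel_fragment", p)
                    for k, p in enumerate(jitter)
                ],
            )
            greedy = len(match_instances(a, b).pairs)
            from silageqc.core import polygon_iou

            iou = np.array(
                [[polygon_iou(p, q) for q in jitter] for p in polys]
            )
            optimal = max_cardinality_matching(iou, 0.5)
            assert greedy <= optimal
            equal += greedy == optimal
        assert equal == n_scenes


class TestCohenKappa:
    def test_identical_sets_kappa_one(self):
        a = make_set([square(10, 10, 40), square(200, 200, 80)], source_id="a")
        b = _copy_with_ids(a, "b")
        rep = cohen_kappa(a, b)
        assert rep.kappa_reported == 1.0

    def test_disjoint_sets_reported_zero_raw_negative(self):
        a = make_set([square(10, 10, 40), square(300, 300, 40)], source_id="a")
        b = _copy_with_ids(a, "b", shift=500.0)
        rep = cohen_kappa(a, b)
        assert rep.kappa_reported == 0.0
        assert rep.kappa_raw < 0.0

    def test_hand_built_contingency(self):
        """10 units, both annotate 6, 4 matched: kappa = 1/6 by hand."""
        shared = [square(100 * k, 100 * k, 50) for k in range(4)]
        a_only = [square(600, 100 * k, 50) for k in range(2)]
        b_only = [square(800, 100 * k, 50) for k in range(2)]
        a = make_set(shared + a_only, source_id="a")
        b_set = make_set(shared + b_only, source_id="b")
        rep = cohen_kappa(a, b_set, background_budget=10)
        assert rep.contingency == ((4, 2), (2, 2))
        assert rep.kappa_raw == pytest.approx(hand_cohen_kappa(4, 2, 2, 2))
        assert rep.kappa_raw == pytest.approx(1 / 6)

    def test_symmetry_under_annotator_swap(self):
        gt = generate_harvest(HarvestSimConfig(n_images=3, seed=17))
        noisy = corrupt_annotations(gt, AnnotatorProfile(seed=4))
        r1 = cohen_kappa(gt, noisy)
        r2 = cohen_kappa(noisy, gt)
        assert r1.kappa_raw == pytest.approx(r2.kappa_raw)
        assert r1.n_agreed == r2.n_agreed

    def test_no_shared_images_raises(self):
        a = make_set([square(10, 10, 40)], source_id="a")
        rec = make_image(image_id="other")
        b = AnnotationSet(source_id="b", images={"other": rec}, instances=[])
        with pytest.raises(ValueError, match="no shared images"):
            cohen_kappa(a, b)

    def test_kappa_decreases_with_miss_rate(self):
        """Expectation over seeds: heavier misses lower the agreement."""
        gt = generate_harvest(HarvestSimConfig(n_images=3, seed=19))
        means = []
        for miss in (0.1, 0.4, 0.7):
            vals = []
            for seed in range(50):
                noisy = corrupt_annotations(
                    gt,
                    AnnotatorProfile(
                        miss_base=miss, miss_size_slope=0, vertex_jitter_px=1.0,
                        false_positive_rate=0.5, seed=seed,
                    ),
                )
                vals.append(cohen_kappa(gt, noisy).kappa_raw)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestPairwiseReport:
    def test_report_combinatorics_and_na_cells(self):
        gt = generate_harvest(HarvestSimConfig(n_images=2, seed=23))
        sets = {}
        for src in ("A1", "A2", "A3"):
            for seq in ("Seq1", "Seq2"):
                if (src, seq) == ("A3", "Seq2"):
                    continue  # missing combination -> na
                prof = AnnotatorProfile(seed=hash((src, seq)) % 1000)
                s = corrupt_annotations(gt, prof)
                sets[(src, seq)] = dataclasses.replace(s, source_id=src)
        reports = pairwise_agreement_report(sets)
        assert len(reports) == 12  # 6 ordered pairs x 2 sequences
        na = [r for r in reports if not r.available]
        assert len(na) == 4  # pairs touching (A3, Seq2), both directions
        for rep in reports:
            if rep.available:
                assert 0.0 <= rep.kappa_reported <= 1.0
                assert -1.0 <= rep.kappa_raw <= 1.0

    def test_self_pair_kappa_one(self):
        gt = generate_harvest(HarvestSimConfig(n_images=2, seed=29))
        a = dataclasses.replace(gt, source_id="A1")
        b = _copy_with_ids(gt, "x")
        b = dataclasses.replace(b, source_id="A2")
        reports = pairwise_agreement_report({("A1", "S"): a, ("A2", "S"): b})
        assert all(r.kappa_reported == 1.0 for r in reports)
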