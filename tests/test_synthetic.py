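"""Scene generator and observer simulator: determinism, geometry, recovery."""

import numpy as np
import pytest

import mosaicount as mc
from mosaicount.errors import CapacityError, ObserverModelError

from conftest import make_set


def grid_truth(n, label="adult", box=40, pitch=60, mosaic_id="m1"):
    """Lay n boxes on a grid — truth for observer simulations without rendering."""
    per_row = int(np.ceil(np.sqrt(n)))
    boxes = []
    for k in range(n):
        x = (k % per_row) * pitch
        y = (k // per_row) * pitch
        boxes.append((x, y, x + box, y + box))
    return make_set(boxes, [label] * n, mosaic_id=mosaic_id, source_id="truth")


class TestGenerateScene:
    def test_empty_spec_gives_blank_truth(self):
        spec = mc.SceneSpec(width=600, height=400, n_adult=0, n_calf=0,
                            n_ghost=0, n_rock=0, n_bird=0, n_trunk=0, seed=1)
        scene = mc.generate_scene(spec)
        assert len(scene.truth) == 0
        assert scene.raster.shape == (400, 600)
        assert scene.raster.dtype == np.uint8

    def test_same_seed_bit_identical(self):
        spec = mc.SceneSpec(width=800, height=600, n_adult=6, n_calf=2,
                            n_ghost=2, n_rock=2, n_bird=1, n_trunk=1, seed=9)
        s1, s2 = mc.generate_scene(spec), mc.generate_scene(spec)
        assert np.array_equal(s1.raster, s2.raster)
        assert s1.truth.annotations == s2.truth.annotations
        assert s1.distractors.items == s2.distractors.items

    def test_counts_bounds_and_separation(self, small_scene):
        spec, scene = small_scene
        counts = scene.truth.counts_by_label()
        assert counts[mc.Label.ADULT] == spec.n_adult
        assert counts[mc.Label.CALF] == spec.n_calf
        assert counts[mc.Label.GHOST] == spec.n_ghost
        scene.truth.check_bounds(scene.meta)
        centers = [a.bbox.center for a in scene.truth]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(centers[i][0] - centers[j][0],
                             centers[i][1] - centers[j][1])
                # centers were placed >= min_separation apart; boxes tighten
                # toward sprite pixels so allow a small placement slack
                assert d >= spec.min_separation_px - 10

    def test_truth_boxes_are_tight(self, small_scene):
        """Every box edge touches rendered sprite pixels (background-subtracted)."""
        spec, scene = small_scene
        blank = mc.generate_scene(
            mc.SceneSpec(**{**spec.__dict__, "n_adult": 0, "n_calf": 0,
                            "n_ghost": 0, "n_rock": 0, "n_bird": 0,
                            "n_trunk": 0}))
        diff = np.abs(scene.raster.astype(int) - blank.raster.astype(int)) >= 1
        for a in scene.truth:
            b = a.bbox
            sub = diff[b.y0:b.y1, b.x0:b.x1]
            assert sub[0, :].any() and sub[-1, :].any()
            assert sub[:, 0].any() and sub[:, -1].any()

    def test_ghosts_have_lower_contrast_than_adults(self, small_scene):
        spec, scene = small_scene
        img = scene.raster.astype(float)

        def mean_contrast(label):
            vals = []
            for a in scene.truth:
                if a.label is not label:
                    continue
                b = a.bbox
                patch = img[b.y0:b.y1, b.x0:b.x1]
                ring = np.median(img[max(0, b.y0 - 15):b.y1 + 15,
                                     max(0, b.x0 - 15):b.x1 + 15])
                vals.append(patch.mean() - ring)
            return np.mean(vals)

        assert mean_contrast(mc.Label.GHOST) < mean_contrast(mc.Label.ADULT)

    def test_infeasible_placement_raises_capacity(self):
        spec = mc.SceneSpec(width=500, height=400, n_adult=200, n_calf=0,
                            n_ghost=0, n_rock=0, n_bird=0, n_trunk=0,
                            min_separation_px=100, seed=0)
        with pytest.raises(CapacityError) as exc:
            mc.generate_scene(spec)
        assert exc.value.achieved < 200


class TestObserverModel:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ObserverModelError):
            mc.ObserverModel(miss_prob={"adult": 0.5},
                             confusion={"adult": {"adult": 0.9},
                                        "calf": {"calf": 1.0},
                                        "ghost": {"ghost": 1.0}})

    def test_probabilities_in_range(self):
        with pytest.raises(ObserverModelError):
            mc.ObserverModel(miss_prob={"adult": -0.1},
                             confusion={"adult": {"adult": 1.1},
                                        "calf": {"calf": 1.0},
                                        "ghost": {"ghost": 1.0}})


class TestSimulateObserver:
    def test_zero_error_model_is_identity(self):
        truth = grid_truth(30)
        out = mc.simulate_observer(truth, mc.DistractorSet("m1"),
                                   mc.ObserverModel(seed=4))
        assert out.annotations == truth.annotations

    def test_ghost_only_blackout(self):
        truth = make_set([(0, 0, 20, 20), (40, 0, 60, 20), (80, 0, 100, 20)],
                         ["adult", "calf", "ghost"], source_id="truth")
        model = mc.ObserverModel(miss_prob={"ghost": 1.0},
                                 confusion={"adult": {"adult": 1.0},
                                            "calf": {"calf": 1.0},
                                            "ghost": {}}, seed=1)
        out = mc.simulate_observer(truth, mc.DistractorSet("m1"), model)
        labs = [a.label for a in out]
        assert mc.Label.GHOST not in labs
        assert labs == [mc.Label.ADULT, mc.Label.CALF]

    def test_seeded_miss_count_reproducible(self):
        truth = grid_truth(500)
        model = mc.ObserverModel(
            miss_prob={"adult": 0.2},
            confusion={"adult": {"adult": 0.8}, "calf": {"calf": 1.0},
                       "ghost": {"ghost": 1.0}}, seed=77)
        n1 = len(mc.simulate_observer(truth, mc.DistractorSet("m1"), model))
        n2 = len(mc.simulate_observer(truth, mc.DistractorSet("m1"), model))
        assert n1 == n2
        assert 500 - n1 == pytest.approx(100, abs=4 * np.sqrt(500 * 0.2 * 0.8))

    def test_miss_rate_recovered_across_seeds(self):
        """Mean missing proportion over 200 seeds within 3 binomial SEs of 0.2."""
        truth = grid_truth(500)
        p, n_seeds = 0.2, 200
        missed = []
        for seed in range(n_seeds):
            model = mc.ObserverModel(
                miss_prob={"adult": p},
                confusion={"adult": {"adult": 1 - p}, "calf": {"calf": 1.0},
                           "ghost": {"ghost": 1.0}}, seed=seed)
            out = mc.simulate_observer(truth, mc.DistractorSet("m1"), model)
            missed.append((len(truth) - len(out)) / len(truth))
        se = np.sqrt(p * (1 - p) / (len(truth) * n_seeds))
        assert abs(np.mean(missed) - p) < 3 * se

    def test_object_false_positives_only_with_rate(self):
        truth = grid_truth(5)
        distractors = mc.DistractorSet("m1", [
            mc.synthetic.Distractor("rock", mc.BoundingBox(500 + 30 * k, 500,
                                                           520 + 30 * k, 520))
            for k in range(50)])
        quiet = mc.simulate_observer(truth, distractors,
                                     mc.ObserverModel(seed=3))
        assert len(quiet) == 5
        noisy_model = mc.ObserverModel(object_fp_rate={"adult": 100.0}, seed=3)
        noisy = mc.simulate_observer(truth, distractors, noisy_model)
        assert len(noisy) == 55  # rate 100 per 100 distractors -> all marked

    def test_jitter_keeps_positive_area_in_bounds(self):
        truth = grid_truth(100, box=5, pitch=8)
        model = mc.ObserverModel(bbox_jitter_sd_px=6.0, seed=2)
        out = mc.simulate_observer(truth, mc.DistractorSet("m1"), model,
                                   bounds=(100, 100))
        for a in out:
            assert a.bbox.area >= 1
            assert 0 <= a.bbox.x0 < a.bbox.x1 <= 100
            assert 0 <= a.bbox.y0 < a.bbox.y1 <= 100


class TestFixtureSuite:
    def test_suite_reproducible_and_complete(self, tmp_path):
        out1, man1 = mc.build_fixture_suite(tmp_path / "a", seed=5)
        out2, man2 = mc.build_fixture_suite(tmp_path / "b", seed=5)
        assert man1 == man2
        assert len(man1["scenes"]) == 4
        scene_dir = out1 / man1["scenes"][0]["mosaic_id"]
        for name in ["mosaic.png", "meta.yaml", "truth.csv", "expert.csv",
                     "detector.csv", "distractors.csv"]:
            assert (scene_dir / name).exists()
        for k in range(1, 6):
            assert (scene_dir / f"naive-{k}.csv").exists()
        # byte-for-byte reproducibility of one annotation file and the raster
        assert ((out1 / "mosaic-75a" / "truth.csv").read_bytes()
                == (out2 / "mosaic-75a" / "truth.csv").read_bytes())
        assert ((out1 / "mosaic-75a" / "mosaic.png").read_bytes()
                == (out2 / "mosaic-75a" / "mosaic.png").read_bytes())

    def test_expert_source_scores_perfectly(self, tmp_path):
        out, man = mc.build_fixture_suite(tmp_path / "s", seed=5)
        sid = man["scenes"][0]["mosaic_id"]
        truth = mc.read_annotations(out / sid / "truth.csv", source_id="truth")
        expert = mc.read_annotations(out / sid / "expert.csv", source_id="expert")
        s = mc.evaluate_source(truth, expert)
        assert s.stats["species"].accuracy == 1.0
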