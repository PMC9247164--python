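"""Synthetic generators: determinism, degenerate configs, generative checks."""

import numpy as np
import pytest

from polypcadx.datamodel import Histology, RawCall, map_vienna
from polypcadx.io import StreamHeader, write_detection_stream
from polypcadx.synthetic import (
    GroupBehavior,
    PanelConfig,
    SceneConfig,
    ScoreModel,
    generate_cohort,
    generate_panel,
    generate_scene,
)


class TestCohort:
    def test_zero_prevalence(self):
        cohort = generate_cohort(50, 0.0, seed=1)
        assert all(p.histology is Histology.NON_ADENOMA for p in cohort)

    def test_label_counts_near_prevalence(self):
        n, prev = 513, 198 / 513
        cohort = generate_cohort(n, prev, seed=2)
        k = sum(p.histology is Histology.ADENOMA for p in cohort)
        # binomial 99% interval around 198
        sd = np.sqrt(n * prev * (1 - prev))
        assert abs(k - n * prev) < 2.58 * sd

    def test_label_consistent_with_vienna(self):
        for p in generate_cohort(100, 0.5, seed=3):
            assert p.histology is map_vienna(p.vienna_category)


class TestScene:
    def test_same_seed_byte_identical_stream(self, tmp_path):
        scene = SceneConfig(n_frames_wl=20, n_frames_bl=5, descriptor_dim=8)
        cohort = generate_cohort(1, 1.0, seed=4)
        paths = []
        for name in ("a.jsonl", "b.jsonl"):
            frames, _ = generate_scene(scene, cohort, ScoreModel(), seed=11)
            p = tmp_path / name
            write_detection_stream(
                p, StreamHeader("c", scene.frame_width, scene.frame_height, 8), frames
            )
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_no_occlusion_means_detection_every_frame(self):
        scene = SceneConfig(n_frames_wl=30, n_frames_bl=0, miss_prob=0.0,
                            descriptor_dim=4)
        cohort = generate_cohort(1, 0.0, seed=5)
        frames, truth = generate_scene(scene, cohort, ScoreModel(), seed=6)
        assert all(len(f.detections) == 1 for f in frames)
        assert len(truth) == 30

    def test_adenoma_score_means_match_model(self):
        model = ScoreModel(adenoma_mean=0.78)
        rng = np.random.default_rng(7)
        means = np.array(
            [model.sample_polyp_mean(Histology.ADENOMA, rng) for _ in range(10_000)]
        )
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 0.78) < 3 * se
        frames = model.sample_frame_scores(0.35, rng, 10_000)
        se_f = frames.std(ddof=1) / np.sqrt(frames.size)
        assert abs(frames.mean() - 0.35) < 3 * se_f

    def test_boxes_stay_inside_frame(self):
        scene = SceneConfig(n_frames_wl=40, n_frames_bl=0, step_sd=30.0,
                            descriptor_dim=8)
        cohort = generate_cohort(3, 0.5, seed=8)
        frames, _ = generate_scene(scene, cohort, ScoreModel(), seed=9)
        for f in frames:
            for det in f.detections:
                assert 0 <= det.box.x_min < det.box.x_max <= scene.frame_width
                assert 0 <= det.box.y_min < det.box.y_max <= scene.frame_height

    def test_infeasible_geometry_rejected(self):
        scene = SceneConfig(frame_width=100, frame_height=100, box_size_min=90,
                            box_size_max=95)
        cohort = generate_cohort(4, 0.5, seed=10)
        with pytest.raises(ValueError):
            generate_scene(scene, cohort, ScoreModel(), seed=1)

    def test_descriptor_dim_must_host_clusters(self):
        scene = SceneConfig(descriptor_dim=2)
        cohort = generate_cohort(3, 0.5, seed=10)
        with pytest.raises(ValueError, match="descriptor_dim"):
            generate_scene(scene, cohort, ScoreModel(), seed=1)


def test_separated_scores_give_perfect_clip_decisions():
    """With strongly separated score distributions and all frames valid,
    every clip decision matches histology."""
    from polypcadx.pipeline import run_pipeline

    model = ScoreModel(
        adenoma_mean=0.9, non_adenoma_mean=0.1,
        polyp_concentration=400.0, frame_concentration=50.0,
        quality_probs=(0.0, 0.0, 1.0),
    )
    scene = SceneConfig(n_frames_wl=30, n_frames_bl=0, miss_prob=0.0,
                        descriptor_dim=8)
    cohort = generate_cohort(30, 0.4, seed=17)
    for i, polyp in enumerate(cohort):
        frames, _ = generate_scene(scene, [polyp], model, seed=200 + i)
        res = run_pipeline(frames)
        wl = res.clip_summary[res.clip_summary["light_mode"] == "WL"]
        assert len(wl) == 1
        assert wl.iloc[0]["call"] == polyp.histology.value


class TestPanel:
    def test_perfect_accuracy(self):
        cfg = PanelConfig(
            expert=GroupBehavior(1.0, 1.0, 0.0),
            non_expert=GroupBehavior(1.0, 1.0, 0.0),
            reader_sd=0.0,
        )
        cohort = generate_cohort(40, 0.5, seed=11)
        truth = {p.polyp_id: p.histology for p in cohort}
        for r in generate_panel(cfg, cohort, seed=12):
            is_adenoma_call = r.raw_call in (RawCall.ADENOMA, RawCall.CARCINOMA)
            assert is_adenoma_call == (truth[r.polyp_id] is Histology.ADENOMA)

    def test_undetermined_rate_near_configured(self):
        cfg = PanelConfig(
            expert=GroupBehavior(0.8, 0.8, 0.02),
            non_expert=GroupBehavior(0.8, 0.8, 0.02),
        )
        cohort = generate_cohort(200, 0.4, seed=13)
        panel = generate_panel(cfg, cohort, seed=14)
        n = len(panel)
        k = sum(r.raw_call is RawCall.UNCERTAIN for r in panel)
        sd = np.sqrt(n * 0.02 * 0.98)
        assert abs(k - 0.02 * n) < 2.58 * sd

    def test_determinism(self):
        cohort = generate_cohort(10, 0.5, seed=15)
        a = generate_panel(PanelConfig(), cohort, seed=16)
        b = generate_panel(PanelConfig(), cohort, seed=16)
        assert a == b
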