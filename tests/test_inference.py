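"""Sliding-window inference: coverage, averaging, thresholding, reporting."""

import numpy as np
import pytest

from canalseg.inference import (SlidingSpec, evaluate_cases, predict_volume,
                                window_starts)
from canalseg.nn import Tensor
from canalseg.phantoms import LabeledVolume


class ConstModel:
    """Stub emitting a constant logit everywhere."""

    def __init__(self, c):
        self.c = c

    def eval(self):
        return self

    def __call__(self, x):
        return Tensor(np.full(x.shape, self.c, dtype=np.float32))


class EchoModel:
    """Stub mapping intensities to logits: +10 where input > 0.5, else -10."""

    def eval(self):
        return self

    def __call__(self, x):
        return Tensor(np.where(x.data > 0.5, 10.0, -10.0).astype(np.float32))


class TestWindowStarts:
    def test_paper_xy_axis_alignment(self):
        starts = window_starts(512, 64, 28)
        assert len(starts) == 17
        assert starts[-1] == 448          # 448 + 64 == 512, no clamp needed

    def test_paper_z_axis(self):
        assert window_starts(64, 32, 8) == [0, 8, 16, 24, 32]

    def test_single_window_when_patch_equals_extent(self):
        assert window_starts(32, 32, 8) == [0]

    def test_clamped_final_window_covers_tail(self):
        starts = window_starts(50, 16, 12)
        assert starts == [0, 12, 24, 34]
        assert starts[-1] + 16 == 50

    def test_patch_larger_than_extent_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            window_starts(16, 32, 8)


class TestPredictVolume:
    def test_full_sweep_counts_on_study_geometry(self):
        grid = np.zeros((64, 512, 512), dtype=np.float32)
        spec = SlidingSpec()     # patch (32,64,64), steps (8,28,28)
        n_eval = np.prod([len(window_starts(e, p, s)) for e, p, s in
                          zip(grid.shape, spec.patch_size, spec.steps)])
        assert n_eval == 5 * 17 * 17 == 1445
        _, counts, _ = predict_volume(ConstModel(0.3), grid, spec, normalize=False)
        assert counts.min() >= 1

    def test_constant_model_gives_bit_constant_probability_map(self):
        grid = np.random.default_rng(0).normal(size=(16, 40, 40)).astype(np.float32)
        spec = SlidingSpec(patch_size=(8, 16, 16), steps=(5, 7, 7))
        probs, counts, mask = predict_volume(ConstModel(0.7), grid, spec)
        expected = 1.0 / (1.0 + np.exp(-0.7))
        assert np.unique(probs).size == 1
        assert probs.flat[0] == pytest.approx(expected, abs=1e-7)
        assert mask.all()       # sigma(0.7) > 0.5

    def test_count_matrix_matches_brute_force_coverage(self):
        shape = (10, 12, 9)
        spec = SlidingSpec(patch_size=(4, 5, 3), steps=(3, 4, 2))
        _, counts, _ = predict_volume(ConstModel(0.0), np.zeros(shape, np.float32),
                                      spec, normalize=False)
        ref = np.zeros(shape, dtype=int)
        for sd in window_starts(shape[0], 4, 3):
            for sh in window_starts(shape[1], 5, 4):
                for sw in window_starts(shape[2], 3, 2):
                    ref[sd:sd + 4, sh:sh + 5, sw:sw + 3] += 1
        np.testing.assert_array_equal(counts, ref)
        assert counts.min() >= 1

    def test_window_order_does_not_change_average(self):
        rng = np.random.default_rng(1)
        grid = rng.normal(size=(12, 20, 20)).astype(np.float32)
        spec = SlidingSpec(patch_size=(8, 8, 8), steps=(4, 6, 6))

        class NoisyEcho:
            def eval(self):
                return self

            def __call__(self, x):
                return Tensor(np.tanh(x.data))

        probs, counts, _ = predict_volume(NoisyEcho(), grid, spec, normalize=False)
        # reference accumulation over shuffled window order
        windows = [(sd, sh, sw)
                   for sd in window_starts(12, 8, 4)
                   for sh in window_starts(20, 8, 6)
                   for sw in window_starts(20, 8, 6)]
        rng.shuffle(windows)
        acc = np.zeros(grid.shape)
        for sd, sh, sw in windows:
            patch = grid[sd:sd + 8, sh:sh + 8, sw:sw + 8]
            acc[sd:sd + 8, sh:sh + 8, sw:sw + 8] += np.tanh(patch)
        ref = 1.0 / (1.0 + np.exp(-acc / counts))
        assert np.abs(probs - ref).max() < 1e-6

    def test_threshold_monotonicity(self):
        grid = np.random.default_rng(2).normal(size=(8, 16, 16)).astype(np.float32)

        class Echo:
            def eval(self):
                return self

            def __call__(self, x):
                return Tensor(x.data)

        masks = []
        for thr in (0.3, 0.5, 0.7):
            spec = SlidingSpec(patch_size=(8, 8, 8), steps=(4, 4, 4), threshold=thr)
            masks.append(predict_volume(Echo(), grid, spec, normalize=False)[2])
        assert np.all(masks[1] <= masks[0]) and np.all(masks[2] <= masks[1])

    def test_volume_smaller_than_patch_names_axis(self):
        spec = SlidingSpec(patch_size=(32, 64, 64), steps=(8, 28, 28))
        with pytest.raises(ValueError, match="axis 0"):
            predict_volume(ConstModel(0.0), np.zeros((16, 64, 64), np.float32), spec)

    def test_prob_accumulation_mode_agrees_for_constant_model(self):
        grid = np.zeros((8, 16, 16), np.float32)
        a = predict_volume(ConstModel(1.2), grid,
                           SlidingSpec(patch_size=(8, 8, 8), steps=(4, 4, 4)),
                           normalize=False)[0]
        b = predict_volume(ConstModel(1.2), grid,
                           SlidingSpec(patch_size=(8, 8, 8), steps=(4, 4, 4),
                                       accumulate="probs"),
                           normalize=False)[0]
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestEvaluateCases:
    def make_cases(self, n=3):
        rng = np.random.default_rng(7)
        cases = []
        for _ in range(n):
            labels = (rng.random((8, 16, 16)) > 0.9).astype(np.uint8)
            labels[4, 8, 8] = 1     # never empty
            cases.append(LabeledVolume(intensities=labels.astype(np.float32),
                                       labels=labels))
        return cases

    def test_perfect_stub_scores_perfectly(self):
        cases = self.make_cases()
        spec = SlidingSpec(patch_size=(8, 8, 8), steps=(4, 8, 8))
        report = evaluate_cases(EchoModel(), cases, spec, normalize=False)
        body = report[report["case"] != "Mean"]
        assert np.allclose(body["dsc"], 1.0)
        assert np.allclose(body["avd_mm"], 0.0)
        assert np.allclose(body["asd_mm"], 0.0)

    def test_report_layout_rows_and_mean(self):
        cases = self.make_cases(6)
        spec = SlidingSpec(patch_size=(8, 8, 8), steps=(4, 8, 8))
        report = evaluate_cases(EchoModel(), cases, spec, normalize=False)
        assert len(report) == 7
        assert report["case"].tolist()[-1] == "Mean"
        body = report[report["case"] != "Mean"]
        assert report.iloc[-1]["dsc"] == pytest.approx(body["dsc"].mean())

    def test_empty_prediction_marked_not_fatal(self):
        cases = self.make_cases(2)
        spec = SlidingSpec(patch_size=(8, 8, 8), steps=(4, 8, 8))
        report = evaluate_cases(ConstModel(-10.0), cases, spec, normalize=False)
        body = report[report["case"] != "Mean"]
        # empty prediction vs non-empty truth: DSC defined (0), surfaces not
        assert np.allclose(body["dsc"], 0.0)
        assert body["note"].str.contains("non-empty").all()
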