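"""Rule-based classification and the trainable image classifier."""

import numpy as np
import pytest

from usvkit.classify import (ClassLabel, ClassPosterior, TrainingConfig,
                             classify_track, decide_usv_vs_noise,
                             predict_posterior, train_classifier)
from usvkit.segmentation import CandidateImage
from usvkit.synth import ideal_track, make_template

TRACK_DT_S = 0.0005


def track_ms(freqs_khz, dt_ms=0.5):
    f = np.asarray(freqs_khz, float) * 1000.0
    t = np.arange(f.size) * dt_ms / 1000.0
    return f, t


class TestClassifyTrackExamples:
    def test_step_up_jump_with_gap(self):
        # one upward 8 kHz jump across a 5 ms unobserved gap
        f = np.r_[np.full(20, 60.0), np.full(10, 64.0), np.full(20, 68.0)]
        f, t = track_ms(f)
        obs = np.ones(f.size, bool)
        obs[20:30] = False  # 5 ms silent gap; interpolated ramp in between
        assert classify_track(f, t, obs) is ClassLabel.STEP_UP

    def test_step_down_instantaneous(self):
        f, t = track_ms(np.r_[np.full(20, 75.0), np.full(20, 66.0)])
        assert classify_track(f, t) is ClassLabel.STEP_DOWN

    def test_constant_70k_10ms_is_short(self):
        f, t = track_ms(np.full(20, 70.0))  # 10 ms
        assert classify_track(f, t) is ClassLabel.SHORT

    def test_constant_30ms_is_flat(self):
        f, t = track_ms(np.full(60, 70.0))
        assert classify_track(f, t) is ClassLabel.FLAT

    def test_chevron_inverted_u(self):
        # rise 10 kHz then fall 10 kHz over 40 ms
        up = np.linspace(60, 70, 40)
        f, t = track_ms(np.r_[up, up[::-1]])
        assert classify_track(f, t) is ClassLabel.CHEVRON

    def test_reverse_chevron(self):
        down = np.linspace(80, 70, 40)
        f, t = track_ms(np.r_[down, down[::-1]])
        assert classify_track(f, t) is ClassLabel.REV_CHEVRON

    def test_up_fm(self):
        f, t = track_ms(np.linspace(55, 70, 60))
        assert classify_track(f, t) is ClassLabel.UP_FM

    def test_down_fm(self):
        f, t = track_ms(np.linspace(80, 65, 60))
        assert classify_track(f, t) is ClassLabel.DOWN_FM

    def test_complex_two_directional_changes(self):
        wave = np.r_[np.linspace(65, 73, 20), np.linspace(73, 64, 20),
                     np.linspace(64, 72, 20), np.linspace(72, 65, 20)]
        f, t = track_ms(wave)
        assert classify_track(f, t) is ClassLabel.COMPLEX

    def test_two_steps(self):
        f, t = track_ms(np.r_[np.full(20, 50.0), np.full(20, 60.0),
                              np.full(20, 70.0)])
        assert classify_track(f, t) is ClassLabel.TWO_STEPS

    def test_multiple_steps(self):
        f, t = track_ms(np.r_[np.full(12, 50.0), np.full(12, 60.0),
                              np.full(12, 70.0), np.full(12, 80.0)])
        assert classify_track(f, t) is ClassLabel.MULTIPLE_STEPS

    def test_broadband_track_is_noise(self):
        f, t = track_ms(np.full(30, 70.0))
        bw = np.full(30, 40_000.0)
        assert classify_track(f, t, bandwidth_hz=bw) is ClassLabel.NOISE

    def test_empty_track_error(self):
        with pytest.raises(ValueError, match="empty"):
            classify_track(np.empty(0))


class TestClassifierProperties:
    def test_total_and_deterministic(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 120))
            f = rng.uniform(46_000, 110_000, n)
            t = np.arange(n) * TRACK_DT_S
            first = classify_track(f, t)
            assert first in ClassLabel
            assert classify_track(f.copy(), t.copy()) is first

    @pytest.mark.parametrize("label", [lab for lab in ClassLabel
                                       if lab is not ClassLabel.NOISE])
    def test_generator_classifier_consistency(self, label, rng):
        """100 random noiseless templates per class are all recovered."""
        harmonic_ok = label in (ClassLabel.FLAT, ClassLabel.SHORT)
        for i in range(100):
            tpl = make_template(label, 0.0, rng,
                                harmonic=harmonic_ok and i % 5 == 0)
            t, f, obs = ideal_track(tpl)
            assert classify_track(f, t, obs) is label, f"template {i}"


def shape_image(kind, rng):
    """227x227 images of distinct synthetic ridge shapes."""
    img = rng.normal(0.05, 0.02, (227, 227)).clip(0, 1)
    cols = np.arange(60, 160)
    if kind == "rising":
        rows = np.linspace(160, 60, cols.size)
    elif kind == "falling":
        rows = np.linspace(60, 160, cols.size)
    elif kind == "flat":
        rows = np.full(cols.size, 110.0)
    elif kind == "vee":
        rows = np.r_[np.linspace(60, 160, 50), np.linspace(160, 60, 50)]
    elif kind == "hump":
        rows = np.r_[np.linspace(160, 60, 50), np.linspace(60, 160, 50)]
    else:  # noise: no coherent ridge
        rows = rng.uniform(40, 180, cols.size)
    for c, r in zip(cols, rows):
        img[int(r) - 2:int(r) + 3, c] = 1.0
    return CandidateImage(pixels227=img, candidate_id=0)


KINDS = ["rising", "falling", "flat", "vee", "hump", "noise"]
KIND_LABELS = {
    "rising": ClassLabel.UP_FM, "falling": ClassLabel.DOWN_FM,
    "flat": ClassLabel.FLAT, "vee": ClassLabel.REV_CHEVRON,
    "hump": ClassLabel.CHEVRON, "noise": ClassLabel.NOISE,
}
DESK_CFG = dict(learning_rate=0.05, batch_size=32, hidden_units=48,
                input_size=24, seed=5)


@pytest.fixture(scope="module")
def trained_toy():
    rng = np.random.default_rng(42)
    images, labels = [], []
    for kind in KINDS:
        for _ in range(100):
            images.append(shape_image(kind, rng))
            labels.append(KIND_LABELS[kind])
    cfg = TrainingConfig(max_epochs=10, **DESK_CFG)
    model = train_classifier(images, labels, cfg)
    return model, images, labels


class TestTrainClassifier:
    def test_synthetic_separability(self, trained_toy):
        """Six noiselessly distinct shape classes reach >= 90% validation
        accuracy within 10 epochs at desk scale."""
        model, _, _ = trained_toy
        assert max(model.validation_accuracy) >= 0.90

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(1)
        images = [shape_image(k, rng) for k in KINDS for _ in range(20)]
        labels = [KIND_LABELS[k] for k in KINDS for _ in range(20)]
        cfg = TrainingConfig(max_epochs=4, **DESK_CFG)
        trace1 = train_classifier(images, labels, cfg).validation_accuracy
        trace2 = train_classifier(images, labels, cfg).validation_accuracy
        assert trace1 == trace2

    def test_patience_halts_training(self):
        rng = np.random.default_rng(2)
        # two interleaved identical classes: validation accuracy cannot
        # improve, so training must stop after patience epochs
        images = [shape_image("flat", rng) for _ in range(40)]
        labels = [ClassLabel.FLAT, ClassLabel.UP_FM] * 20
        cfg = TrainingConfig(max_epochs=50, patience_epochs=3, **DESK_CFG)
        model = train_classifier(images, labels, cfg)
        assert len(model.validation_accuracy) < 50

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_classifier([], [], TrainingConfig())


class TestPredictPosterior:
    def test_posterior_normalised(self, trained_toy):
        model, images, _ = trained_toy
        post = predict_posterior(model, images[0])
        assert sum(post.probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 0 for p in post.probs.values())

    def test_memorised_image_recovered(self, trained_toy):
        model, images, labels = trained_toy
        hits = sum(predict_posterior(model, img).top_label is lab
                   for img, lab in zip(images[::10], labels[::10]))
        assert hits >= 0.8 * len(images[::10])

    def test_uniform_noise_scores_as_noise(self, trained_toy):
        """Incoherent images should mostly favour the noise class."""
        model, _, _ = trained_toy
        rng = np.random.default_rng(9)
        noisy = 0
        for _ in range(100):
            img = CandidateImage(pixels227=rng.random((227, 227)),
                                 candidate_id=0)
            if predict_posterior(model, img).p_usv < 0.5:
                noisy += 1
        assert noisy > 50


class TestDecideUsvVsNoise:
    def _post(self, p_noise, spread_label=ClassLabel.FLAT):
        probs = {lab: 0.0 for lab in ClassLabel}
        probs[ClassLabel.NOISE] = p_noise
        probs[spread_label] = 1.0 - p_noise
        return ClassPosterior(probs=probs)

    def test_high_noise_probability(self):
        is_usv, flagged = decide_usv_vs_noise(self._post(0.9))
        assert not is_usv

    def test_boundary_with_low_confidence_flag(self):
        is_usv, flagged = decide_usv_vs_noise(self._post(0.49))
        assert is_usv and flagged

    def test_confident_usv_unflagged(self):
        is_usv, flagged = decide_usv_vs_noise(self._post(0.01))
        assert is_usv and not flagged
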