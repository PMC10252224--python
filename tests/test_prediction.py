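"""Prediction stage: per-organ outputs, loss identities, end-to-end contract."""

import numpy as np
import pytest

from facemark3d import prediction as pr
from facemark3d import detection as det
from facemark3d.geometry import VoxelGrid
from facemark3d.registry import ORGAN_ORDER, Organ, landmark_names, organ_spec


def scalar_loop_mean(p, t):
    total = 0.0
    for i in range(len(p)):
        total += sum((p[i][j] - t[i][j]) ** 2 for j in range(3))
    return total / len(p)


def scalar_loop_max(p, t):
    return max(sum((p[i][j] - t[i][j]) ** 2 for j in range(3))
               for i in range(len(p)))


# ---------------------------------------------------------------------------
# Structure


@pytest.mark.parametrize("organ,out_dim", [(Organ.EYES, 24), (Organ.CHIN, 12)])
def test_output_dimension_is_3N(organ, out_dim, rng):
    cfg = pr.PredictionNetConfig(organ=organ, M=16, n_blocks=2, channels=(2, 4),
                                 n_residual_blocks=2)
    model = pr.build_prediction_net(cfg, seed=0)
    x = rng.random((2, 1, 16, 16, 16)).astype(np.float32)
    model.net.eval()
    assert model.net.forward(x).shape == (2, out_dim)


def test_config_landmark_count_follows_registry():
    for organ in ORGAN_ORDER:
        cfg = pr.PredictionNetConfig(organ=organ, M=8, n_blocks=2, channels=(2, 2))
        assert cfg.n_landmarks == organ_spec(organ).n_landmarks


# ---------------------------------------------------------------------------
# Losses


def test_losses_zero_at_identity(rng):
    p = rng.normal(size=(5, 3))
    assert pr.loss_mean(p, p) == 0.0
    assert pr.loss_max(p, p) == 0.0
    assert pr.loss_combined(p, p) == 0.0


def test_two_point_worked_example():
    t = np.zeros((2, 3))
    p = np.array([[0.1, 0, 0], [0.2, 0, 0]])  # squared distances 0.01, 0.04
    assert pr.loss_mean(p, t) == pytest.approx(0.025)
    assert pr.loss_max(p, t) == pytest.approx(0.04)
    assert pr.loss_combined(p, t, 0.5, 0.5) == pytest.approx(0.0325)
    assert pr.loss_combined(p, t, 1.0, 0.0) == pytest.approx(pr.loss_mean(p, t))
    assert pr.loss_combined(p, t, 0.0, 1.0) == pytest.approx(pr.loss_max(p, t))


def test_losses_match_scalar_oracles(rng):
    for _ in range(100):
        n = rng.integers(1, 9)
        p = rng.normal(size=(n, 3))
        t = rng.normal(size=(n, 3))
        assert pr.loss_mean(p, t) == pytest.approx(scalar_loop_mean(p, t), abs=1e-9)
        assert pr.loss_max(p, t) == pytest.approx(scalar_loop_max(p, t), abs=1e-9)
        lam = float(rng.uniform())
        want = lam * scalar_loop_mean(p, t) + (1 - lam) * scalar_loop_max(p, t)
        assert pr.loss_combined(p, t, lam, 1 - lam) == pytest.approx(want, abs=1e-9)


def test_loss_ordering_mean_combined_max(rng):
    for _ in range(50):
        p = rng.normal(size=(6, 3))
        t = rng.normal(size=(6, 3))
        lam = float(rng.uniform())
        lm, lx = pr.loss_mean(p, t), pr.loss_max(p, t)
        lc = pr.loss_combined(p, t, lam, 1 - lam)
        assert 0 <= lm <= lc + 1e-12
        assert lc <= lx + 1e-12


def test_combined_monotone_in_lambda2(rng):
    p = rng.normal(size=(4, 3))
    t = rng.normal(size=(4, 3))
    values = [pr.loss_combined(p, t, 1 - l2, l2) for l2 in (0.0, 0.25, 0.5, 1.0)]
    assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))


def test_loss_shape_mismatch_rejected(rng):
    with pytest.raises(pr.PredictionError):
        pr.loss_mean(rng.normal(size=(3, 3)), rng.normal(size=(4, 3)))
    with pytest.raises(pr.PredictionError):
        pr.loss_combined(np.zeros((2, 3)), np.zeros((2, 3)), 0.8, 0.8)


def test_batch_loss_gradient_matches_finite_difference(rng):
    from facemark3d import nn
    p = rng.normal(size=(3, 5, 3))
    t = rng.normal(size=(3, 5, 3))
    _, grad = pr._combined_loss_batch_grad(p, t, 0.3, 0.7)
    num = nn.numeric_gradient(
        lambda: pr._combined_loss_batch_grad(p, t, 0.3, 0.7)[0], p, eps=1e-5)
    assert np.abs(grad - num).max() < 1e-6


# ---------------------------------------------------------------------------
# Training


def toy_dataset(rng, organ, n=2, M=8):
    N = organ_spec(organ).n_landmarks
    return [(VoxelGrid((rng.random((M, M, M)) < 0.1).astype(np.uint8)),
             rng.uniform(-1, 1, size=(N, 3))) for _ in range(n)]


def test_zero_lr_training_is_noop(rng):
    cfg = pr.PredictionNetConfig(organ=Organ.CHIN, M=8, n_blocks=2,
                                 channels=(2, 2), n_residual_blocks=1)
    model = pr.build_prediction_net(cfg, seed=1)
    w0 = [p.copy() for p, _ in model.net.parameters()]
    pr.train_predictor(Organ.CHIN, model, toy_dataset(rng, Organ.CHIN),
                       det.OptimizerConfig(lr=0.0), epochs=1, seed=0)
    for (p, _), w in zip(model.net.parameters(), w0):
        np.testing.assert_array_equal(p, w)


def test_training_deterministic_and_organ_mismatch_rejected(rng):
    cfg = pr.PredictionNetConfig(organ=Organ.CHIN, M=8, n_blocks=2,
                                 channels=(2, 2), n_residual_blocks=1)
    data = toy_dataset(np.random.default_rng(3), Organ.CHIN)
    hs = []
    for _ in range(2):
        model = pr.build_prediction_net(cfg, seed=1)
        hs.append(pr.train_predictor(Organ.CHIN, model, data,
                                     det.OptimizerConfig(lr=1e-3),
                                     epochs=3, seed=5))
    assert hs[0] == hs[1]
    model = pr.build_prediction_net(cfg, seed=1)
    with pytest.raises(pr.PredictionError):
        pr.train_predictor(Organ.NOSE, model, data, det.OptimizerConfig(),
                           epochs=1, seed=0)


# ---------------------------------------------------------------------------
# End-to-end pipeline contract (stub-scale networks, untrained)


@pytest.fixture(scope="module")
def tiny_models():
    detector = det.build_detection_net(
        det.DetectionNetConfig(M=16, n_blocks=2, channels=(2, 4)), seed=0)
    # untrained stub: bias the half-extent outputs up so the predicted boxes
    # cover the whole domain and every organ crop is non-empty
    head = detector.net.layers[-1]
    head.b[[i for i in range(36) if i % 6 >= 3]] = 3.0
    detector.net.eval()
    predictors = {}
    for k, organ in enumerate(ORGAN_ORDER):
        m = pr.build_prediction_net(
            pr.PredictionNetConfig(organ=organ, M=16, n_blocks=2,
                                   channels=(2, 4), n_residual_blocks=1),
            seed=k)
        m.net.eval()
        predictors[organ] = m
    return detector, predictors


def test_pipeline_outputs_all_32_names(tiny_models, small_face):
    detector, predictors = tiny_models
    out = pr.predict_landmarks_mm(detector, predictors, small_face.cloud,
                                  boxes=small_face.true_boxes)
    assert set(out) == set(landmark_names())


def test_pipeline_translation_equivariance(tiny_models, small_face):
    """A rigidly translated cloud yields translated landmarks."""
    from facemark3d.geometry import PointCloud
    detector, predictors = tiny_models
    shift = np.array([12.0, -7.0, 3.0])
    a = pr.predict_landmarks_mm(detector, predictors, small_face.cloud)
    moved = PointCloud(small_face.cloud.points + shift)
    b = pr.predict_landmarks_mm(detector, predictors, moved)
    for name in a:
        np.testing.assert_allclose(b[name], a[name] + shift, atol=1e-6)


def test_pipeline_deterministic_under_fixed_weights(tiny_models, small_face):
    detector, predictors = tiny_models
    a = pr.predict_landmarks_mm(detector, predictors, small_face.cloud)
    b = pr.predict_landmarks_mm(detector, predictors, small_face.cloud)
    for name in a:
        np.testing.assert_array_equal(a[name], b[name])


def test_missing_predictor_rejected(tiny_models, small_face):
    detector, predictors = tiny_models
    partial = {o: m for o, m in predictors.items() if o is not Organ.CHIN}
    with pytest.raises(pr.PredictionError, match="chin"):
        pr.predict_landmarks_mm(detector, partial, small_face.cloud)


def test_organ_independence_under_retraining(small_face, rng):
    """Retraining one organ leaves the other organs' outputs bit-identical."""
    detector = det.build_detection_net(
        det.DetectionNetConfig(M=16, n_blocks=2, channels=(2, 4)), seed=0)
    predictors = {}
    for k, organ in enumerate(ORGAN_ORDER):
        m = pr.build_prediction_net(
            pr.PredictionNetConfig(organ=organ, M=16, n_blocks=2,
                                   channels=(2, 4), n_residual_blocks=1),
            seed=k)
        m.net.eval()
        predictors[organ] = m
    before = pr.predict_landmarks_mm(detector, predictors, small_face.cloud,
                                     boxes=small_face.true_boxes)
    pr.train_predictor(Organ.LIPS, predictors[Organ.LIPS],
                       toy_dataset(rng, Organ.LIPS, M=16),
                       det.OptimizerConfig(lr=1e-3), epochs=2, seed=0)
    after = pr.predict_landmarks_mm(detector, predictors, small_face.cloud,
                                    boxes=small_face.true_boxes)
    lips = set(organ_spec(Organ.LIPS).landmark_names)
    for name in before:
        if name in lips:
            continue
        np.testing.assert_array_equal(before[name], after[name])
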