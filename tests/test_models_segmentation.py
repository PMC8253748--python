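"""Segmentation architecture contracts and small training behaviours."""

import numpy as np
import pytest

from spinevc.errors import ConfigurationError, ValidationError
from spinevc.metrics import dice
from spinevc.models_segmentation import (SegModelConfig, TrainParams,
                                         VertebralSegmenter,
                                         build_segmentation_model,
                                         load_segmentation_model, predict_mask,
                                         save_segmentation_model,
                                         train_segmentation)
from spinevc.training_data import segmentation_corpus, small_phantom_spec

TINY = dict(depth=2, base_filters=4, input_size=(32, 32))


@pytest.mark.parametrize("variant", ["unet", "resunet", "r2unet"])
def test_forward_is_input_shaped_sigmoid_map(variant, rng):
    model = build_segmentation_model(SegModelConfig(variant=variant, seed=1, **TINY))
    out = model.forward_array(rng.uniform(0, 1, (2, 32, 32)))
    assert out.shape == (2, 32, 32)
    assert out.min() > 0 and out.max() < 1


def test_r2unet_single_step_matches_resunet_parameter_count():
    kw = dict(depth=2, base_filters=4, input_size=(16, 16))
    r2 = build_segmentation_model(SegModelConfig(variant="r2unet", time_steps=1, **kw))
    res = build_segmentation_model(SegModelConfig(variant="resunet", **kw))
    assert r2.n_parameters() == res.n_parameters()


def test_recurrent_block_reduces_to_plain_unet(rng):
    """With one time step and shortcuts disabled, the recurrent network is
    the plain U-Net: identical weights give identical outputs."""
    kw = dict(depth=2, base_filters=4, input_size=(16, 16), seed=3)
    unet = build_segmentation_model(SegModelConfig(variant="unet", **kw))
    reduced = build_segmentation_model(
        SegModelConfig(variant="r2unet", time_steps=1, residual=False, **kw))
    reduced.load_state_dict(unet.state_dict())
    unet.eval(), reduced.eval()
    x = rng.uniform(0, 1, (16, 16))
    np.testing.assert_allclose(unet.forward_array(x), reduced.forward_array(x))


def test_time_steps_change_output(rng):
    kw = dict(depth=2, base_filters=4, input_size=(16, 16), seed=3)
    t1 = build_segmentation_model(SegModelConfig(variant="r2unet", time_steps=1, **kw))
    t2 = build_segmentation_model(SegModelConfig(variant="r2unet", time_steps=2, **kw))
    t2.load_state_dict(t1.state_dict())
    t1.eval(), t2.eval()
    x = rng.uniform(0, 1, (16, 16))
    assert not np.allclose(t1.forward_array(x), t2.forward_array(x))


def test_parameter_count_is_pure_function_of_config():
    cfg = SegModelConfig(variant="r2unet", seed=0, **TINY)
    a = build_segmentation_model(cfg).n_parameters()
    b = build_segmentation_model(SegModelConfig(variant="r2unet", seed=99, **TINY)).n_parameters()
    assert a == b


@pytest.mark.parametrize("cfg_kwargs", [
    dict(variant="vnet"),
    dict(depth=0),
    dict(time_steps=0),
    dict(input_size=(100, 100), depth=4),
])
def test_invalid_configs_rejected(cfg_kwargs):
    base = dict(variant="unet", depth=2, base_filters=4, input_size=(32, 32))
    base.update(cfg_kwargs)
    with pytest.raises(ConfigurationError):
        build_segmentation_model(SegModelConfig(**base))


def test_zero_epochs_leaves_model_unchanged(rng):
    model = build_segmentation_model(SegModelConfig(variant="unet", seed=5, **TINY))
    before = model.state_dict()
    imgs = rng.uniform(0, 1, (2, 32, 32)).astype(np.float32)
    _, history = train_segmentation(model, imgs, (imgs > 0.5), TrainParams(epochs=0))
    assert history == []
    for k, v in model.state_dict().items():
        np.testing.assert_array_equal(v, before[k])


def test_untrained_prediction_deterministic_and_binary(rng):
    model = build_segmentation_model(SegModelConfig(variant="r2unet", seed=2, **TINY))
    x = rng.uniform(0, 1, (32, 32))
    m1, m2 = predict_mask(model, x), predict_mask(model, x)
    np.testing.assert_array_equal(m1, m2)
    assert set(np.unique(m1)) <= {0, 1}
    assert np.isfinite(dice(m1, m1)) or m1.sum() == 0  # metrics interface


def test_training_shape_validation(rng):
    model = build_segmentation_model(SegModelConfig(variant="unet", **TINY))
    with pytest.raises(ValidationError):
        train_segmentation(model, rng.uniform(0, 1, (2, 16, 16)),
                           rng.integers(0, 2, (2, 16, 16)), TrainParams(epochs=1))


def test_loss_decreases_and_overfits_single_phantom():
    imgs, masks = segmentation_corpus(1, seed=3, spec=small_phantom_spec(64))
    model = build_segmentation_model(
        SegModelConfig(variant="unet", depth=2, base_filters=4,
                       input_size=(64, 64), seed=0))
    _, history = train_segmentation(
        model, imgs, masks,
        TrainParams(batch_size=1, epochs=80, learning_rate=0.002, seed=0))
    assert history[-1] < history[0]
    assert dice(predict_mask(model, imgs[0]), masks[0]) > 0.95


def test_training_on_empty_masks_predicts_empty():
    imgs, _ = segmentation_corpus(2, seed=8, spec=small_phantom_spec(32))
    masks = np.zeros_like(imgs)
    model = build_segmentation_model(
        SegModelConfig(variant="unet", depth=2, base_filters=4,
                       input_size=(32, 32), seed=0))
    train_segmentation(model, imgs, masks,
                       TrainParams(batch_size=2, epochs=30,
                                   learning_rate=0.01, seed=0))
    assert predict_mask(model, imgs[0]).sum() == 0


def test_checkpoint_roundtrip(tmp_path, rng):
    model = build_segmentation_model(SegModelConfig(variant="r2unet", seed=4, **TINY))
    path = tmp_path / "seg.npz"
    save_segmentation_model(model, path)
    loaded = load_segmentation_model(path)
    x = rng.uniform(0, 1, (32, 32))
    model.eval()
    np.testing.assert_allclose(model.forward_array(x), loaded.forward_array(x))


def test_estimator_is_sklearn_compatible():
    from sklearn.base import clone

    est = VertebralSegmenter(variant="unet", depth=2, base_filters=4,
                             input_size=(32, 32), epochs=1)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    est.set_params(epochs=3)
    assert est.epochs == 3
    with pytest.raises(ValueError):
        est.set_params(bogus=1)
    with pytest.raises(ValidationError):
        est.predict(np.zeros((32, 32)))
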