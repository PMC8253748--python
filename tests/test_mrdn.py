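"""MRDN regressor: block structure, training behaviours, estimator API."""

import numpy as np
import pytest

from spinevc.errors import ConfigurationError, ValidationError
from spinevc.mrdn import (CompressionRegressor, MRDBConfig, MRDNConfig,
                          MRDNTrainParams, build_mrdn, load_mrdn, predict_vc,
                          prepare_crop, save_mrdn, train_mrdn)
from spinevc.training_data import triplet_crops_from_phantoms

TINY = MRDNConfig(stem_channels=4, mrdb=MRDBConfig(bottleneck_channels=4),
                  input_size=(64, 64), seed=0)


@pytest.fixture(scope="module")
def tiny_crop_set():
    crops, targets = triplet_crops_from_phantoms(4, seed=9, size=(64, 64))
    return crops[:5], targets[:5]


def test_forward_yields_finite_scalars(rng):
    net = build_mrdn(TINY)
    out = net.forward_array(rng.uniform(0, 1, (3, 64, 64)))
    assert out.shape == (3,)
    assert np.isfinite(out).all()


def test_batch_predictions_match_single(rng):
    net = build_mrdn(TINY)
    net.eval()
    crops = rng.uniform(0, 1, (4, 64, 64))
    batch = net.forward_array(crops)
    singles = [net.forward_array(c[None])[0] for c in crops]
    np.testing.assert_allclose(batch, singles, rtol=1e-5)


def test_mrdb_concat_width_is_four_branches():
    net = build_mrdn(TINY)
    block = net.mrdbs[0]
    assert block.concat_width == len(TINY.mrdb.dilation_rates) * TINY.mrdb.bottleneck_channels
    assert len(block.branches) == 4


def test_residual_add_changes_output(rng):
    net = build_mrdn(TINY)
    net.eval()
    x = rng.uniform(0, 1, (1, 64, 64))
    with_add = net.forward_array(x)
    net.mrdbs[0].use_residual = False
    without = net.forward_array(x)
    assert not np.allclose(with_add, without)


def test_parameter_count_deterministic():
    a = build_mrdn(MRDNConfig(stem_channels=4, input_size=(64, 64), seed=1))
    b = build_mrdn(MRDNConfig(stem_channels=4, input_size=(64, 64), seed=7))
    assert a.n_parameters() == b.n_parameters()


@pytest.mark.parametrize("cfg", [
    MRDNConfig(mrdb=MRDBConfig(dilation_rates=(4, 2))),
    MRDNConfig(mrdb=MRDBConfig(dilation_rates=(2, 2, 4))),
    MRDNConfig(mrdb=MRDBConfig(dilation_rates=(-1, 2))),
    MRDNConfig(input_size=(100, 100)),
    MRDNConfig(n_stem_layers=0),
])
def test_invalid_configs_rejected(cfg):
    with pytest.raises(ConfigurationError):
        build_mrdn(cfg)


def test_stem_width_progression_capped():
    cfg = MRDNConfig(stem_channels=16, channel_cap=64)
    assert cfg.stem_widths() == [16, 32, 64, 64, 64, 64]


def test_prepare_crop_pads_to_square_binary():
    crop = np.ones((40, 20), dtype=np.uint8)
    out = prepare_crop(crop, (64, 64))
    assert out.shape == (64, 64)
    assert set(np.unique(out)) <= {0.0, 1.0}


def test_zero_epochs_and_validation(tiny_crop_set, rng):
    crops, targets = tiny_crop_set
    net = build_mrdn(TINY)
    _, history = train_mrdn(net, crops, targets, MRDNTrainParams(epochs=0))
    assert history == []
    with pytest.raises(ValidationError):
        train_mrdn(net, crops, targets[:-1], MRDNTrainParams(epochs=1))
    with pytest.raises(ValidationError):
        net.forward_array(rng.uniform(0, 1, (1, 32, 32)))


def test_overfits_five_crops_to_half_point(tiny_crop_set):
    crops, targets = tiny_crop_set
    net = build_mrdn(TINY)
    mean, scale = targets.mean(), targets.std() or 1.0
    train_mrdn(net, crops, (targets - mean) / scale,
               MRDNTrainParams(batch_size=5, epochs=300,
                               learning_rate=0.005, seed=0))
    pred = net.forward_array(crops) * scale + mean
    assert np.abs(pred - targets).max() <= 0.5


def test_constant_targets_learned_as_constant(tiny_crop_set):
    crops, _ = tiny_crop_set
    targets = np.full(len(crops), 12.5, dtype=np.float32)
    reg = CompressionRegressor(stem_channels=4, bottleneck_channels=4,
                               input_size=(64, 64), batch_size=5, epochs=60,
                               learning_rate=0.005, seed=0)
    reg.fit(crops, targets)
    pred = reg.predict(crops)
    assert np.ptp(pred) < 1.0
    assert np.abs(pred - 12.5).max() < 1.0


def test_predict_vc_is_deterministic_and_tagged(tiny_crop_set):
    crops, _ = tiny_crop_set
    net = build_mrdn(TINY)
    m1 = predict_vc(net, crops[0], target_label=3)
    m2 = predict_vc(net, crops[0], target_label=3)
    assert m1.vc_pct == m2.vc_pct
    assert m1.method == "mrdn" and m1.target_label == 3
    batch = predict_vc(net, crops)
    assert len(batch) == len(crops)


def test_checkpoint_roundtrip(tmp_path, tiny_crop_set):
    crops, _ = tiny_crop_set
    net = build_mrdn(TINY)
    net.eval()
    save_mrdn(net, tmp_path / "mrdn.npz", y_mean=5.0, y_scale=2.0)
    loaded, y_mean, y_scale = load_mrdn(tmp_path / "mrdn.npz")
    assert (y_mean, y_scale) == (5.0, 2.0)
    np.testing.assert_allclose(net.forward_array(crops[0]),
                               loaded.forward_array(crops[0]))


def test_estimator_is_sklearn_compatible():
    from sklearn.base import clone

    est = CompressionRegressor(stem_channels=4, epochs=2)
    assert clone(est).get_params() == est.get_params()
    with pytest.raises(ValueError):
        est.set_params(nope=1)
    with pytest.raises(ValidationError):
        est.predict(np.zeros((64, 64)))
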