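"""Multi-scale residual dilated network (MRDN): a CNN regressor mapping a
three-vertebral-body segmentation crop directly to a compression
percentage.

A six-layer convolutional stem (3x3 conv, BN, ReLU, 2x2 max pooling per
layer) extracts a low-level feature map.  The multi-scale residual
dilated block (MRDB) then applies a 1x1 bottleneck, four parallel 3x3
dilated convolutions (dilation rates 2, 4, 8 and 16 — receptive spans of
5 to 33 pixels), concatenates the four branch maps, closes with a 3x3
convolution back to the stem width, and adds the block input at the very
end (single residual addition).  Global average pooling and a linear unit
produce the scalar compression estimate, in percent; negative outputs are
legitimate (target taller than its neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError
from .geometry import VCMeasurement
from .nn import Tensor
from .preprocess import standardize

__all__ = [
    "MRDBConfig",
    "MRDNConfig",
    "MRDNTrainParams",
    "MRDB",
    "MRDN",
    "build_mrdn",
    "train_mrdn",
    "predict_vc",
    "prepare_crop",
    "CompressionRegressor",
]


@dataclass
class MRDBConfig:
    dilation_rates: tuple[int, ...] = (2, 4, 8, 16)
    bottleneck_channels: int = 32

    def validate(self) -> None:
        rates = tuple(self.dilation_rates)
        if not rates or any(r <= 0 for r in rates):
            raise ConfigurationError(f"dilation rates must be positive, got {rates}")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ConfigurationError(
                f"dilation rates must be strictly increasing, got {rates}")
        if self.bottleneck_channels < 1:
            raise ConfigurationError(
                f"bottleneck_channels must be >= 1, got {self.bottleneck_channels}")


@dataclass
class MRDNConfig:
    n_stem_layers: int = 6
    stem_channels: int = 16
    channel_cap: int = 128
    n_mrdb: int = 1
    mrdb: MRDBConfig = field(default_factory=MRDBConfig)
    input_size: tuple[int, int] = (128, 128)
    seed: int = 0

    def validate(self) -> None:
        self.mrdb.validate()
        if self.n_stem_layers < 1 or self.n_mrdb < 1:
            raise ConfigurationError("n_stem_layers and n_mrdb must be >= 1")
        div = 2 ** self.n_stem_layers
        h, w = self.input_size
        if h % div or w % div:
            raise ConfigurationError(
                f"input size {h}x{w} not divisible by 2^{self.n_stem_layers} = {div}")

    def stem_widths(self) -> list[int]:
        """Channel progression: doubling from ``stem_channels``, capped."""
        widths = []
        c = self.stem_channels
        for _ in range(self.n_stem_layers):
            widths.append(min(c, self.channel_cap))
            c *= 2
        return widths


@dataclass
class MRDNTrainParams:
    batch_size: int = 8
    epochs: int = 150
    learning_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ConfigurationError(
                "batch_size must be >= 1, epochs >= 0 and learning_rate > 0 "
                f"(got {self.batch_size}, {self.epochs}, {self.learning_rate})")


class MRDB(nn.Module):
    """Bottleneck -> parallel dilated branches -> concat -> 3x3 conv -> add."""

    def __init__(self, channels: int, cfg: MRDBConfig, rng: np.random.Generator):
        super().__init__()
        b = cfg.bottleneck_channels
        self.bottleneck = nn.ConvBNRelu(channels, b, rng, kernel=1)
        self.branches = [nn.ConvBNRelu(b, b, rng, dilation=d)
                         for d in cfg.dilation_rates]
        self.close = nn.ConvBNRelu(len(cfg.dilation_rates) * b, channels, rng)
        self.concat_width = len(cfg.dilation_rates) * b
        self.use_residual = True

    def __call__(self, x: Tensor) -> Tensor:
        z = self.bottleneck(x)
        cat = nn.concat([branch(z) for branch in self.branches], axis=1)
        y = self.close(cat)
        return nn.add(y, x) if self.use_residual else y


class MRDN(nn.Module):
    def __init__(self, cfg: MRDNConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.stem_widths()
        self.stem = []
        cin = 1
        for c in widths:
            self.stem.append(nn.ConvBNRelu(cin, c, rng))
            cin = c
        self.mrdbs = [MRDB(cin, cfg.mrdb, rng) for _ in range(cfg.n_mrdb)]
        self.fc = nn.Linear(cin, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.stem:
            x = nn.maxpool2x2(layer(x))
        for block in self.mrdbs:
            x = block(x)
        return nn.linear(nn.global_avg_pool(x), self.fc.weight, self.fc.bias)

    def forward_array(self, crops: np.ndarray) -> np.ndarray:
        crops = np.asarray(crops, dtype=np.float32)
        if crops.ndim == 2:
            crops = crops[None]
        if crops.shape[1:] != tuple(self.cfg.input_size):
            raise ValidationError(
                f"crop size {crops.shape[1:]} != model input {self.cfg.input_size}")
        return self(Tensor(crops[:, None])).data[:, 0]


def build_mrdn(cfg: MRDNConfig) -> MRDN:
    return MRDN(cfg)


def prepare_crop(crop: np.ndarray, size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Aspect-preserving resize + pad of a triplet crop to the model input."""
    if size[0] != size[1]:
        raise ConfigurationError("MRDN input must be square")
    out, _ = standardize(np.asarray(crop), target=size[0], is_mask=True)
    return out.astype(np.float32)


def train_mrdn(model: MRDN, crops: np.ndarray, vc_targets: np.ndarray,
               params: MRDNTrainParams) -> tuple[MRDN, list[float]]:
    """Train with Adam on mean squared error against percent targets."""
    params.validate()
    crops = np.asarray(crops, dtype=np.float32)
    targets = np.asarray(vc_targets, dtype=np.float32)
    if crops.ndim != 3 or targets.ndim != 1 or crops.shape[0] != targets.shape[0]:
        raise ValidationError(
            f"crops {crops.shape} and targets {targets.shape} must be "
            "(N, H, W) and (N,) with matching N")
    if params.epochs == 0:
        return model, []
    rng = np.random.default_rng(params.seed)
    opt = nn.Adam(model.parameters(), lr=params.learning_rate)
    model.train()
    history = []
    n = crops.shape[0]
    for _ in range(params.epochs):
        losses = []
        order = rng.permutation(n)
        for start in range(0, n, params.batch_size):
            idx = order[start:start + params.batch_size]
            opt.zero_grad()
            pred = model(Tensor(crops[idx][:, None]))
            loss = nn.mse_loss(pred, targets[idx][:, None])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    model.eval()
    return model, history


def predict_vc(model: MRDN, crop: np.ndarray,
               target_label: int = 2) -> VCMeasurement | list[VCMeasurement]:
    """Predict compression for one crop (or a batch) with the trained MRDN.

    Anterior heights are not observable through the regressor, so they are
    reported as NaN in the returned measurements.
    """
    was_training = model.training
    model.eval()
    vals = model.forward_array(crop)
    if was_training:
        model.train()
    nan = float("nan")
    measurements = [VCMeasurement(target_label=target_label, ha_upper=nan,
                                  ha_target=nan, ha_lower=nan,
                                  vc_pct=float(v), method="mrdn") for v in vals]
    return measurements[0] if np.asarray(crop).ndim == 2 else measurements


def save_mrdn(model: MRDN, path, y_mean: float = 0.0, y_scale: float = 1.0) -> None:
    """Checkpoint weights (npz) plus an architecture sidecar (yaml)."""
    from dataclasses import asdict
    from pathlib import Path

    import yaml

    path = Path(path)
    model.save(path)
    cfg = asdict(model.cfg)
    cfg["input_size"] = list(cfg["input_size"])
    cfg["mrdb"]["dilation_rates"] = list(cfg["mrdb"]["dilation_rates"])
    cfg["target_affine"] = [float(y_mean), float(y_scale)]
    with open(path.with_suffix(".cfg.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)


def load_mrdn(path) -> tuple[MRDN, float, float]:
    """Load a checkpoint; returns (model, y_mean, y_scale) for unscaling."""
    from pathlib import Path

    import yaml

    path = Path(path)
    with open(path.with_suffix(".cfg.yaml")) as fh:
        raw = yaml.safe_load(fh)
    y_mean, y_scale = raw.pop("target_affine", [0.0, 1.0])
    raw["input_size"] = tuple(raw["input_size"])
    raw["mrdb"] = MRDBConfig(dilation_rates=tuple(raw["mrdb"]["dilation_rates"]),
                             bottleneck_channels=raw["mrdb"]["bottleneck_channels"])
    model = MRDN(MRDNConfig(**raw))
    model.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    model.eval()
    return model, float(y_mean), float(y_scale)


class CompressionRegressor:
    """Scikit-learn style estimator around the MRDN.

    ``fit(X, y)`` takes (N, H, W) binary triplet crops at ``input_size``
    and percent compression targets.  Targets are standardized internally
    for optimisation (a reparametrisation of the linear head) and mapped
    back at prediction time.
    """

    def __init__(self, stem_channels: int = 16, channel_cap: int = 128,
                 bottleneck_channels: int = 32,
                 dilation_rates: tuple[int, ...] = (2, 4, 8, 16),
                 n_mrdb: int = 1, input_size: tuple[int, int] = (128, 128),
                 batch_size: int = 8, epochs: int = 150,
                 learning_rate: float = 0.01, seed: int = 0):
        self.stem_channels = stem_channels
        self.channel_cap = channel_cap
        self.bottleneck_channels = bottleneck_channels
        self.dilation_rates = dilation_rates
        self.n_mrdb = n_mrdb
        self.input_size = input_size
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    _PARAM_NAMES = ("stem_channels", "channel_cap", "bottleneck_channels",
                    "dilation_rates", "n_mrdb", "input_size", "batch_size",
                    "epochs", "learning_rate", "seed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAM_NAMES}

    def set_params(self, **params) -> "CompressionRegressor":
        for k, v in params.items():
            if k not in self._PARAM_NAMES:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "CompressionRegressor":
        y = np.asarray(y, dtype=np.float32)
        self.y_mean_ = float(y.mean())
        self.y_scale_ = float(y.std()) or 1.0
        cfg = MRDNConfig(stem_channels=self.stem_channels,
                         channel_cap=self.channel_cap,
                         n_mrdb=self.n_mrdb,
                         mrdb=MRDBConfig(dilation_rates=tuple(self.dilation_rates),
                                         bottleneck_channels=self.bottleneck_channels),
                         input_size=tuple(self.input_size), seed=self.seed)
        self.model_ = build_mrdn(cfg)
        params = MRDNTrainParams(batch_size=self.batch_size, epochs=self.epochs,
                                 learning_rate=self.learning_rate, seed=self.seed)
        scaled = (y - self.y_mean_) / self.y_scale_
        _, self.loss_history_ = train_mrdn(self.model_, X, scaled, params)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValidationError("estimator is not fitted; call fit first")
        was_training = self.model_.training
        self.model_.eval()
        out = self.model_.forward_array(X) * self.y_scale_ + self.y_mean_
        if was_training:
            self.model_.train()
        return out

    def score(self, X, y) -> float:
        """Coefficient of determination (R^2), sklearn convention."""
        y = np.asarray(y, dtype=float)
        pred = self.predict(X)
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
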