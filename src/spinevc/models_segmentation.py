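"""Vertebral-body segmentation networks: U-Net, ResU-Net and R2U-Net.

All three share one encoder/decoder topology; they differ only in the
convolution block.  A block is two 3x3 conv->BN->ReLU units; the residual
variants add a 1x1-projected shortcut from the block input to the block
output, and the recurrent variant applies its second unit's kernel
``time_steps`` times, re-adding the unit input at each step
(x_t = f(w * x_{t-1} + x_0), weights and BN shared across steps).  With
``time_steps=1`` and the shortcut disabled the recurrent block reduces
exactly to the plain block, which is used as an architecture oracle in
the tests.

Each encoder level halves the grid with 2x2 max pooling; each decoder
level upsamples 2x, halves the channels with a 3x3 "up-conv" unit and
concatenates the matching encoder feature map.  A 1x1 convolution and a
sigmoid produce the per-pixel foreground probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError
from .nn import Tensor

__all__ = [
    "SegModelConfig",
    "TrainParams",
    "SegBlock",
    "SegNet",
    "build_segmentation_model",
    "train_segmentation",
    "predict_mask",
    "VertebralSegmenter",
]

VARIANTS = ("unet", "resunet", "r2unet")


@dataclass
class SegModelConfig:
    """Architecture hyperparameters for the segmentation networks.

    ``residual`` normally follows the variant (shortcuts for resunet and
    r2unet); it can be forced for architecture-equivalence experiments.
    """

    variant: str = "r2unet"
    depth: int = 4
    base_filters: int = 32
    time_steps: int = 2
    input_size: tuple[int, int] = (512, 512)
    seed: int = 0
    residual: bool | None = None

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.depth < 1:
            raise ConfigurationError(f"depth must be >= 1, got {self.depth}")
        if self.time_steps < 1:
            raise ConfigurationError(f"time_steps must be >= 1, got {self.time_steps}")
        div = 2 ** self.depth
        h, w = self.input_size
        if h % div or w % div:
            raise ConfigurationError(
                f"input size {h}x{w} not divisible by 2^depth = {div}")

    @property
    def effective_time_steps(self) -> int:
        return self.time_steps if self.variant == "r2unet" else 1

    @property
    def effective_residual(self) -> bool:
        if self.residual is not None:
            return self.residual
        return self.variant in ("resunet", "r2unet")


@dataclass
class TrainParams:
    batch_size: int = 5
    epochs: int = 200
    learning_rate: float = 0.001
    loss: str = "bce"
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ConfigurationError(
                "batch_size must be >= 1, epochs >= 0 and learning_rate > 0 "
                f"(got {self.batch_size}, {self.epochs}, {self.learning_rate})")
        if self.loss != "bce":
            raise ConfigurationError(f"unsupported loss {self.loss!r}")


class SegBlock(nn.Module):
    """Two conv units with optional recurrence (second unit) and shortcut."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 time_steps: int = 1, residual: bool = False):
        super().__init__()
        self.unit1 = nn.ConvBNRelu(cin, cout, rng)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.time_steps = time_steps
        self.proj = nn.Conv2d(cin, cout, 1, rng) if residual else None

    def __call__(self, x: Tensor) -> Tensor:
        x0 = self.unit1(x)
        h = nn.relu(self.bn2(self.conv2(x0)))
        for _ in range(self.time_steps - 1):
            h = nn.relu(self.bn2(nn.add(self.conv2(h), x0)))
        if self.proj is not None:
            h = nn.add(h, self.proj(x))
        return h


class SegNet(nn.Module):
    """Symmetric encoder/decoder with skip connections and sigmoid head."""

    def __init__(self, cfg: SegModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        t, res = cfg.effective_time_steps, cfg.effective_residual
        chans = [cfg.base_filters * 2 ** i for i in range(cfg.depth + 1)]

        self.encoders = []
        cin = 1
        for c in chans[:-1]:
            self.encoders.append(SegBlock(cin, c, rng, t, res))
            cin = c
        self.bottleneck = SegBlock(chans[-2], chans[-1], rng, t, res)
        self.upconvs = []
        self.decoders = []
        for i in reversed(range(cfg.depth)):
            self.upconvs.append(nn.ConvBNRelu(chans[i + 1], chans[i], rng))
            self.decoders.append(SegBlock(2 * chans[i], chans[i], rng, t, res))
        self.head = nn.Conv2d(chans[0], 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = nn.maxpool2x2(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.upconvs, self.decoders, reversed(skips)):
            x = up(nn.upsample2x(x))
            x = dec(nn.concat([skip, x], axis=1))
        return nn.sigmoid(self.head(x))

    def forward_array(self, batch: np.ndarray) -> np.ndarray:
        """Forward a (N, H, W) float batch, returning (N, H, W) probabilities."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 2:
            batch = batch[None]
        h, w = self.cfg.input_size
        if batch.shape[1:] != (h, w):
            raise ValidationError(
                f"batch spatial size {batch.shape[1:]} != model input {h}x{w}")
        out = self(Tensor(batch[:, None]))
        return out.data[:, 0]


def build_segmentation_model(cfg: SegModelConfig) -> SegNet:
    """Construct a segmentation network; the parameter count depends only
    on the architectural fields of ``cfg``."""
    return SegNet(cfg)


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_segmentation(model: SegNet, images: np.ndarray, masks: np.ndarray,
                       params: TrainParams) -> tuple[SegNet, list[float]]:
    """Train with Adam on pixelwise binary cross-entropy.

    ``images`` and ``masks`` are aligned (N, H, W) arrays at the model's
    input size.  Returns the model and the per-epoch mean loss history;
    ``epochs=0`` leaves the model untouched.
    """
    params.validate()
    images = np.asarray(images, dtype=np.float32)
    masks = (np.asarray(masks) > 0).astype(np.float32)
    if images.shape != masks.shape or images.ndim != 3:
        raise ValidationError(
            f"images {images.shape} and masks {masks.shape} must be aligned "
            "(N, H, W) arrays")
    if images.shape[1:] != tuple(model.cfg.input_size):
        raise ValidationError(
            f"training rasters {images.shape[1:]} != model input size "
            f"{model.cfg.input_size}")
    if params.epochs == 0:
        return model, []

    rng = np.random.default_rng(params.seed)
    opt = nn.Adam(model.parameters(), lr=params.learning_rate)
    model.train()
    history = []
    n = images.shape[0]
    for _ in range(params.epochs):
        losses = []
        for idx in _iter_batches(n, params.batch_size, rng):
            opt.zero_grad()
            pred = model(Tensor(images[idx][:, None]))
            loss = nn.bce_loss(pred, masks[idx][:, None])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    model.eval()
    return model, history


def predict_mask(model: SegNet, img: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize the sigmoid probability map at ``threshold`` (uint8 mask)."""
    was_training = model.training
    model.eval()
    prob = model.forward_array(img)
    if was_training:
        model.train()
    out = (prob > threshold).astype(np.uint8)
    return out[0] if np.asarray(img).ndim == 2 else out


def save_segmentation_model(model: SegNet, path) -> None:
    """Checkpoint weights (npz) plus an architecture sidecar (yaml)."""
    from dataclasses import asdict
    from pathlib import Path

    import yaml

    path = Path(path)
    model.save(path)
    cfg = asdict(model.cfg)
    cfg["input_size"] = list(cfg["input_size"])
    with open(path.with_suffix(".cfg.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)


def load_segmentation_model(path) -> SegNet:
    from pathlib import Path

    import yaml

    path = Path(path)
    with open(path.with_suffix(".cfg.yaml")) as fh:
        raw = yaml.safe_load(fh)
    raw["input_size"] = tuple(raw["input_size"])
    model = SegNet(SegModelConfig(**raw))
    model.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    model.eval()
    return model


class VertebralSegmenter:
    """Scikit-learn style estimator wrapping the segmentation networks.

    ``fit(X, y)`` takes (N, H, W) images and binary masks; ``predict(X)``
    returns binary masks; ``score(X, y)`` is the mean Dice coefficient.
    """

    def __init__(self, variant: str = "r2unet", depth: int = 4,
                 base_filters: int = 32, time_steps: int = 2,
                 input_size: tuple[int, int] = (512, 512),
                 batch_size: int = 5, epochs: int = 200,
                 learning_rate: float = 0.001, seed: int = 0):
        self.variant = variant
        self.depth = depth
        self.base_filters = base_filters
        self.time_steps = time_steps
        self.input_size = input_size
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    # get_params/set_params kept sklearn-compatible without inheriting,
    # so the nn engine stays the only model dependency.
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "variant", "depth", "base_filters", "time_steps", "input_size",
            "batch_size", "epochs", "learning_rate", "seed")}

    def set_params(self, **params) -> "VertebralSegmenter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "VertebralSegmenter":
        cfg = SegModelConfig(variant=self.variant, depth=self.depth,
                             base_filters=self.base_filters,
                             time_steps=self.time_steps,
                             input_size=tuple(self.input_size), seed=self.seed)
        self.model_ = build_segmentation_model(cfg)
        params = TrainParams(batch_size=self.batch_size, epochs=self.epochs,
                             learning_rate=self.learning_rate, seed=self.seed)
        _, self.loss_history_ = train_segmentation(self.model_, X, y, params)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValidationError("estimator is not fitted; call fit first")
        return predict_mask(self.model_, X)

    def score(self, X, y) -> float:
        from .metrics import dice
        pred = self.predict(X)
        y = np.asarray(y)
        if pred.ndim == 2:
            return dice(pred, y)
        return float(np.mean([dice(p, g) for p, g in zip(pred, y)]))
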