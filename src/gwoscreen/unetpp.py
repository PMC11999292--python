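"""UNet++ disc/cup segmenter with GWO-searchable hyperparameters.

The network is the nested-skip encoder-decoder: node X(i, j) at pyramid
level i and skip depth j receives the concatenation of all previous nodes
at its level, X(i, 0..j-1), plus the upsampled X(i+1, j-1), so information
flows through dense "cross-connections" between the downsampling
(exploration) and upsampling (exploitation) paths.  Output head is a 1x1
convolution with a sigmoid, two channels: optic disc and optic cup
probability maps.  At depth 1 the nesting degenerates to a plain U-Net.

Training minimizes binary cross-entropy plus soft-Dice (smoothing eps=1)
averaged over the two channels, with Adam and early stopping on validation
loss.  The hyperparameters a Grey Wolf search tunes are
{log10 learning rate, dropout rate, base filter count, binarization
threshold}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import autograd as ag
from .autograd import Tensor
from .gwo import GWOConfig, OptimizationResult, optimize
from .nn import Adam, ConvBlock, Conv2d, Dropout, Module

__all__ = [
    "SegModelConfig",
    "SegSearchSpace",
    "UNetPlusPlus",
    "UnetPlusPlusSegmenter",
    "build_segmenter",
    "train_segmenter",
    "segment",
    "gwo_tune_segmenter",
    "dice",
    "iou",
]


@dataclass
class SegModelConfig:
    """Segmenter hyperparameters (the GWO search decodes into this)."""

    depth: int = 4
    base_filters: int = 16
    dropout_rate: float = 0.0
    learning_rate: float = 1e-4
    binarize_threshold: float = 0.5
    deep_supervision: bool = False

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must be in (0, 1)")


@dataclass
class SegSearchSpace:
    """Bounds of the 4-D hyperparameter box the wolves roam.

    Axes in order: log10(learning_rate), dropout_rate, base_filters
    (continuous, rounded on decode), binarize_threshold.
    """

    log10_lr: tuple[float, float] = (-5.0, -2.0)
    dropout: tuple[float, float] = (0.0, 0.5)
    base_filters: tuple[float, float] = (8.0, 32.0)
    threshold: tuple[float, float] = (0.2, 0.8)

    @property
    def dim(self) -> int:
        return 4

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.log10_lr[0], self.dropout[0],
                       self.base_filters[0], self.threshold[0]])
        hi = np.array([self.log10_lr[1], self.dropout[1],
                       self.base_filters[1], self.threshold[1]])
        return lo, hi

    def decode(self, vector: np.ndarray, depth: int = 2) -> SegModelConfig:
        return SegModelConfig(
            depth=depth,
            base_filters=int(round(float(vector[2]))),
            dropout_rate=float(vector[1]),
            learning_rate=float(10.0 ** vector[0]),
            binarize_threshold=float(vector[3]),
        )


class UNetPlusPlus(Module):
    """The nested-skip network; NCHW tensors in, per-pixel probabilities out."""

    def __init__(self, config: SegModelConfig, in_channels: int,
                 out_channels: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        d = config.depth
        ch = [config.base_filters * (2 ** i) for i in range(d + 1)]
        self.depth = d
        self.out_channels = out_channels
        self.blocks: dict[tuple[int, int], ConvBlock] = {}
        block_list = []  # for parameter discovery
        for i in range(d + 1):
            in_ch = in_channels if i == 0 else ch[i - 1]
            blk = ConvBlock(in_ch, ch[i], rng)
            self.blocks[(i, 0)] = blk
            block_list.append(blk)
        for j in range(1, d + 1):
            for i in range(d + 1 - j):
                in_ch = ch[i] * j + ch[i + 1]
                blk = ConvBlock(in_ch, ch[i], rng)
                self.blocks[(i, j)] = blk
                block_list.append(blk)
        self.head = Conv2d(ch[0], out_channels, 1, rng)
        # bias toward the background prior (~10-15% foreground) so no init
        # starts in the all-positive basin
        self.head.bias.data[:] = -2.0
        self._block_list = block_list
        self.dropout = Dropout(config.dropout_rate, rng)
        self.config = config

    def forward_logits(self, x: Tensor, training: bool = False) -> Tensor:
        self.dropout.training = training
        d = self.depth
        nodes: dict[tuple[int, int], Tensor] = {}
        cur = x * 2.0 - 1.0  # center [0,1] intensities
        for i in range(d + 1):
            if i > 0:
                cur = ag.max_pool2d(nodes[(i - 1, 0)])
            nodes[(i, 0)] = self.dropout(self.blocks[(i, 0)](cur))
        for j in range(1, d + 1):
            for i in range(d + 1 - j):
                skips = [nodes[(i, k)] for k in range(j)]
                up = ag.upsample2x(nodes[(i + 1, j - 1)])
                nodes[(i, j)] = self.blocks[(i, j)](ag.concat(skips + [up], axis=1))
        return self.head(nodes[(0, d)])

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ag.sigmoid(self.forward_logits(x, training=training))


def build_segmenter(config: SegModelConfig, in_channels: int = 3,
                    out_channels: int = 2, seed: int = 0,
                    image_side: int | None = None) -> UNetPlusPlus:
    """Construct the model; fails fast if the spatial side is incompatible."""
    if image_side is not None and image_side % (2 ** config.depth) != 0:
        raise ValueError(
            f"image side {image_side} not divisible by 2^depth = {2 ** config.depth}")
    return UNetPlusPlus(config, in_channels, out_channels, seed=seed)


# ---------------------------------------------------------------------------
# overlap metrics


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); both-empty pairs count as 1."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union; both-empty pairs count as 1."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# training


def _to_nchw(images: np.ndarray) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:  # (N, H, W) grayscale
        arr = arr[:, None, :, :]
    elif arr.ndim == 4:  # (N, H, W, C)
        arr = arr.transpose(0, 3, 1, 2)
    else:
        raise ValueError("images must be (N,H,W) or (N,H,W,C)")
    return arr


def _seg_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """BCE (from logits, stable) + (1 - soft Dice); eps = 1 smoothing."""
    y = Tensor(target)
    bce = ag.bce_with_logits(logits, target)
    probs = ag.sigmoid(logits)
    inter = (probs * y).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + y.sum(axis=(0, 2, 3))
    soft_dice = (inter * 2.0 + 1.0) / (denom + 1.0)
    return bce + (1.0 - soft_dice.mean())


def train_segmenter(model: UNetPlusPlus, images: np.ndarray, masks: np.ndarray,
                    config: SegModelConfig, epochs: int = 30,
                    seed: int = 0, batch_size: int = 8,
                    patience: int = 10, val_fraction: float = 0.2,
                    ) -> list[dict]:
    """Train in place; returns the per-epoch trace.

    images: (N, H, W, C) in [0, 1]; masks: (N, H, W, 2) binary (disc, cup).
    A validation holdout (>= 1 sample) is split off internally for early
    stopping; the best-validation weights are restored at the end.
    """
    x = _to_nchw(images)
    y = np.asarray(masks, dtype=np.float32).transpose(0, 3, 1, 2)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples (one must be held out for "
                         "validation-based early stopping)")
    if not y.any():
        warnings.warn("all-background masks in training set", RuntimeWarning)
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(n * val_fraction)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    xtr, ytr, xval, yval = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    trace: list[dict] = []
    best_val = np.inf
    best_state = None
    since_best = 0
    for epoch in range(epochs):
        order = rng.permutation(len(xtr))
        losses = []
        for start in range(0, len(xtr), batch_size):
            idx = order[start:start + batch_size]
            model.zero_grad()
            logits = model.forward_logits(Tensor(xtr[idx]), training=True)
            loss = _seg_loss(logits, ytr[idx])
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_logits = model.forward_logits(Tensor(xval))
        val_loss = float(_seg_loss(val_logits, yval).data)
        val_probs = ag.sigmoid(val_logits)
        pred = val_probs.data >= config.binarize_threshold
        per_channel = [
            float(np.mean([dice(pred[i, c], yval[i, c] > 0.5)
                           for i in range(len(xval))]))
            for c in range(y.shape[1])]
        val_dice = float(np.mean(per_channel))
        trace.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                      "val_loss": val_loss, "val_dice": val_dice,
                      "val_dice_disc": per_channel[0],
                      "val_dice_cup": per_channel[-1]})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = [p.data.copy() for p in model.parameters()]
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return trace


def segment(model: UNetPlusPlus, image: np.ndarray,
            binarize_threshold: float | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predict binary disc and cup masks for one image.

    The cup mask is intersected with the disc mask: anatomically the cup
    lies inside the disc.
    """
    thr = (model.config.binarize_threshold if binarize_threshold is None
           else binarize_threshold)
    x = _to_nchw(image[None] if image.ndim == 3 or image.ndim == 2 else image)
    probs = model(Tensor(x)).data[0]
    disc = probs[0] > thr if thr > 0 else probs[0] > 0
    cup = probs[1] > thr if thr > 0 else probs[1] > 0
    cup = np.logical_and(cup, disc)
    return disc, cup


# ---------------------------------------------------------------------------
# sklearn-style estimator


class UnetPlusPlusSegmenter(BaseEstimator):
    """Optic disc/cup segmenter with an sklearn fit/predict surface.

    Parameters mirror :class:`SegModelConfig` plus training controls.
    Fitted attributes: ``model_`` (the network), ``history_`` (per-epoch
    trace), ``val_dice_`` (best validation Dice).
    """

    def __init__(self, depth: int = 2, base_filters: int = 8,
                 dropout_rate: float = 0.0, learning_rate: float = 1e-3,
                 binarize_threshold: float = 0.5, deep_supervision: bool = False,
                 epochs: int = 30, batch_size: int = 8, patience: int = 10,
                 val_fraction: float = 0.2, seed: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.binarize_threshold = binarize_threshold
        self.deep_supervision = deep_supervision
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def _config(self) -> SegModelConfig:
        return SegModelConfig(
            depth=self.depth, base_filters=self.base_filters,
            dropout_rate=self.dropout_rate, learning_rate=self.learning_rate,
            binarize_threshold=self.binarize_threshold,
            deep_supervision=self.deep_supervision)

    def fit(self, X, y):
        """X: (N, H, W, C) images in [0,1]; y: (N, H, W, 2) disc/cup masks."""
        X = np.asarray(X, dtype=np.float32)
        cfg = self._config()
        side = X.shape[1]
        if side % (2 ** cfg.depth) != 0:
            raise ValueError(
                f"image side {side} not divisible by 2^depth = {2 ** cfg.depth}")
        in_ch = X.shape[3] if X.ndim == 4 else 1
        self.model_ = build_segmenter(cfg, in_channels=in_ch, out_channels=2,
                                      seed=self.seed, image_side=side)
        self.history_ = train_segmenter(
            self.model_, X, y, cfg, epochs=self.epochs, seed=self.seed,
            batch_size=self.batch_size, patience=self.patience,
            val_fraction=self.val_fraction)
        self.val_dice_ = max(h["val_dice"] for h in self.history_) \
            if self.history_ else 0.0
        return self

    def predict(self, X) -> np.ndarray:
        """Returns (N, H, W, 2) boolean masks (disc, cup), cup within disc."""
        X = np.asarray(X, dtype=np.float32)
        out = np.empty(X.shape[:3] + (2,), dtype=bool)
        for i in range(X.shape[0]):
            d, c = segment(self.model_, X[i])
            out[i, :, :, 0] = d
            out[i, :, :, 1] = c
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Returns (N, H, W, 2) probability maps."""
        X = np.asarray(X, dtype=np.float32)
        probs = self.model_(Tensor(_to_nchw(X))).data
        return probs.transpose(0, 2, 3, 1)

    def score(self, X, y) -> float:
        """Mean Dice over samples and channels against reference masks."""
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([
            dice(pred[i, :, :, c], y[i, :, :, c] > 0.5)
            for i in range(len(y)) for c in range(2)]))


# ---------------------------------------------------------------------------
# GWO hyperparameter search


def gwo_tune_segmenter(images: np.ndarray, masks: np.ndarray,
                       space: SegSearchSpace, gwo_config: GWOConfig,
                       budget_epochs_per_eval: int = 5, depth: int = 2,
                       train_seed: int = 0
                       ) -> tuple[SegModelConfig, OptimizationResult]:
    """Search the hyperparameter box; fitness = 1 - mean validation Dice.

    Every candidate is decoded into a :class:`SegModelConfig`, short-trained
    for ``budget_epochs_per_eval`` epochs from the same seed, and scored on
    the internal validation holdout.  Diverged runs (NaN loss) surface as
    +inf fitness through the optimizer's NaN guard.
    """
    lo, hi = space.bounds()
    if gwo_config.dim != space.dim:
        raise ValueError("gwo_config.dim must equal the search-space dim (4)")
    gwo_config.lower_bounds = lo
    gwo_config.upper_bounds = hi

    def objective(vector: np.ndarray) -> float:
        cfg = space.decode(vector, depth=depth)
        est = UnetPlusPlusSegmenter(
            depth=cfg.depth, base_filters=cfg.base_filters,
            dropout_rate=cfg.dropout_rate, learning_rate=cfg.learning_rate,
            binarize_threshold=cfg.binarize_threshold,
            epochs=budget_epochs_per_eval, patience=budget_epochs_per_eval,
            seed=train_seed)
        try:
            est.fit(images, masks)
        except FloatingPointError:
            return float("nan")
        return 1.0 - est.val_dice_

    result = optimize(objective, gwo_config)
    best_cfg = space.decode(result.best_position, depth=depth)
    return best_cfg, result
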