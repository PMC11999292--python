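"""Capsule-network glaucoma/normal classifier with dynamic routing.

Architecture (printed sizes for the default spec): a 64x64x3 crop passes
through a 9x9 valid convolution (stride 1) to a 56x56 feature stack, then a
9x9 stride-2 "primary capsule" convolution to a 24x24 grid of capsule
types; each primary capsule is an 8-D vector squashed to norm < 1.  With 32
types the conv stack is 256 channels deep and there are 24*24*32 = 18432
primary capsules.  Each primary capsule votes for the two 16-D class
capsules ("glaucoma", "normal") through a learned transform; routing by
agreement iteratively concentrates the softmax-normalized coupling
coefficients on the class whose output the capsule's vote agrees with.
The class capsule norms are the class scores; training uses the capsule
margin loss (m+ = 0.9, m- = 0.1, lambda = 0.5).

Tests and desk-scale runs may shrink ``conv_filters`` and
``primary_caps_types``; the default spec keeps the full printed sizes and
its shape invariants are validated at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autograd as ag
from .autograd import Tensor
from .nn import Adam, Conv2d, Module

__all__ = [
    "CapsNetSpec",
    "CapsOutput",
    "conv_output_side",
    "squash",
    "dynamic_routing",
    "CapsNet",
    "build_capsnet",
    "margin_loss",
    "train_capsnet",
    "CapsNetClassifier",
]

EPS = 1e-9


def conv_output_side(in_side: int, kernel: int, stride: int) -> int:
    """Output side of a valid (unpadded) convolution."""
    if kernel > in_side:
        raise ValueError(f"kernel {kernel} exceeds input side {in_side}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return (in_side - kernel) // stride + 1


@dataclass
class CapsNetSpec:
    """Architecture constants; defaults are the full printed sizes."""

    input_side: int = 64
    input_channels: int = 3
    conv_kernel: int = 9
    conv_filters: int = 256
    conv_stride: int = 1
    primary_kernel: int = 9
    primary_stride: int = 2
    primary_caps_types: int = 32
    primary_caps_dim: int = 8
    class_caps: int = 2
    class_caps_dim: int = 16
    routing_iters: int = 3

    def __post_init__(self):
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        self.conv_side = conv_output_side(self.input_side, self.conv_kernel,
                                          self.conv_stride)
        self.primary_side = conv_output_side(self.conv_side, self.primary_kernel,
                                             self.primary_stride)
        self.primary_channels = self.primary_caps_types * self.primary_caps_dim
        self.num_primary_caps = (self.primary_side ** 2) * self.primary_caps_types

    def validate_printed_shapes(self):
        """Assert the default architecture's printed arithmetic (64->56->24)."""
        if self.conv_side != 56 or self.primary_side != 24:
            raise ValueError(
                f"shape chain {self.input_side}->{self.conv_side}->"
                f"{self.primary_side} differs from the printed 64->56->24")
        if self.primary_channels != 256:
            raise ValueError("primary depth must be 32 x 8 = 256")


@dataclass
class CapsOutput:
    class_vectors: np.ndarray        # (class_caps, class_caps_dim)
    class_probabilities: np.ndarray  # (class_caps,) vector norms in [0, 1)
    predicted_label: str


def squash(vectors: np.ndarray, axis: int = -1) -> np.ndarray:
    """Norm-compressing nonlinearity v -> (|v|^2/(1+|v|^2)) * v/|v|.

    Zero vectors map to zero (the norm is epsilon-guarded); direction is
    preserved and the output norm is strictly below 1.
    """
    v = np.asarray(vectors, dtype=float)
    sq = (v ** 2).sum(axis=axis, keepdims=True)
    norm = np.sqrt(sq + EPS)
    return (sq / (1.0 + sq)) * v / norm


def _squash_t(v: Tensor, axis: int) -> Tensor:
    sq = (v * v).sum(axis=axis, keepdims=True)
    norm = (sq + EPS).sqrt()
    return v * (sq / (1.0 + sq)) / norm


def dynamic_routing(u_hat: np.ndarray, iterations: int,
                    return_history: bool = False):
    """Routing by agreement (numpy reference, one sample).

    u_hat : (num_input_caps, num_class_caps, class_dim) prediction vectors.
    Returns (v, c): class capsule vectors (num_class_caps, class_dim) and
    the final coupling coefficients (num_input_caps, num_class_caps), which
    sum to 1 over classes for every input capsule at every iteration.  With
    ``return_history`` the per-iteration coupling matrices are appended as
    a third return value.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    u_hat = np.asarray(u_hat, dtype=float)
    n_in, n_cls, _ = u_hat.shape
    b = np.zeros((n_in, n_cls))
    history = []
    for _ in range(iterations):
        e = np.exp(b - b.max(axis=1, keepdims=True))
        c = e / e.sum(axis=1, keepdims=True)
        if return_history:
            history.append(c.copy())
        s = (c[:, :, None] * u_hat).sum(axis=0)
        v = squash(s, axis=-1)
        b = b + (u_hat * v[None]).sum(axis=-1)
    if return_history:
        return v, c, history
    return v, c


class CapsNet(Module):
    """The trainable network (autodiff tensors inside)."""

    def __init__(self, spec: CapsNetSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.conv1 = Conv2d(spec.input_channels, spec.conv_filters,
                            spec.conv_kernel, rng, stride=spec.conv_stride)
        self.primary = Conv2d(spec.conv_filters, spec.primary_channels,
                              spec.primary_kernel, rng,
                              stride=spec.primary_stride)
        # vote transform: (num_primary, class_caps, primary_dim, class_dim)
        scale = 0.1
        self.W = Tensor(rng.normal(0.0, scale,
                                   (spec.num_primary_caps, spec.class_caps,
                                    spec.primary_caps_dim, spec.class_caps_dim)),
                        requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C, H, W) -> class capsule vectors (N, class_caps, class_dim)."""
        spec = self.spec
        if x.shape[1:] != (spec.input_channels, spec.input_side, spec.input_side):
            raise ValueError(
                f"expected input (N, {spec.input_channels}, {spec.input_side}, "
                f"{spec.input_side}), got {x.shape}")
        h = ag.relu(self.conv1(x))
        assert h.shape[2] == spec.conv_side, "conv side mismatch vs arithmetic"
        p = self.primary(h)
        assert p.shape[2] == spec.primary_side, "primary side mismatch"
        n = p.shape[0]
        # (N, types*dim, g, g) -> (N, P, dim) with P = g*g*types
        u = p.reshape(n, spec.primary_caps_types, spec.primary_caps_dim,
                      spec.primary_side, spec.primary_side)
        u = u.transpose(0, 1, 3, 4, 2).reshape(n, spec.num_primary_caps,
                                               spec.primary_caps_dim)
        u = _squash_t(u, axis=2)
        # votes: (N, P, 1, 1, dim) @ (P, cls, dim, cd) -> (N, P, cls, 1, cd)
        u5 = u.reshape(n, spec.num_primary_caps, 1, 1, spec.primary_caps_dim)
        u_hat = (u5 @ self.W).reshape(n, spec.num_primary_caps,
                                      spec.class_caps, spec.class_caps_dim)
        return self._route(u_hat)

    def _route(self, u_hat: Tensor) -> Tensor:
        n, P, C, D = u_hat.shape
        b = Tensor(np.zeros((n, P, C, 1), dtype=np.float32))
        v = None
        for _ in range(self.spec.routing_iters):
            c = ag.softmax(b, axis=2)
            s = (c * u_hat).sum(axis=1)            # (N, C, D)
            v = _squash_t(s, axis=2)
            agree = (u_hat * v.reshape(n, 1, C, D)).sum(axis=3, keepdims=True)
            b = b + agree
        return v

    __call__ = forward


def build_capsnet(spec: CapsNetSpec, seed: int = 0) -> CapsNet:
    return CapsNet(spec, seed=seed)


def class_norms(v: Tensor) -> Tensor:
    """Capsule norms (the class scores), shape (N, class_caps)."""
    return ((v * v).sum(axis=2) + EPS).sqrt()


def margin_loss(norms: Tensor, onehot: np.ndarray, m_plus: float = 0.9,
                m_minus: float = 0.1, lam: float = 0.5) -> Tensor:
    """Capsule margin loss averaged over the batch.

    L = sum_k [T_k max(0, m+ - |v_k|)^2 + lam (1-T_k) max(0, |v_k| - m-)^2].
    """
    t = Tensor(onehot.astype(np.float32))
    present = (Tensor(np.float32(m_plus)) - norms).maximum(0.0) ** 2.0
    absent = (norms - Tensor(np.float32(m_minus))).maximum(0.0) ** 2.0
    per_sample = (t * present + lam * (1.0 - t) * absent).sum(axis=1)
    return per_sample.mean()


def _dihedral_augment(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random 90-degree rotations and flips (NCHW); label-preserving for
    fundus crops, where orientation carries no class information."""
    out = batch.copy()
    for i in range(len(out)):
        k = int(rng.integers(4))
        if k:
            out[i] = np.rot90(out[i], k, axes=(1, 2))
        if rng.integers(2):
            out[i] = out[i][:, :, ::-1]
    return np.ascontiguousarray(out)


def train_capsnet(model: CapsNet, images: np.ndarray, labels: np.ndarray,
                  epochs: int, batch_size: int = 32,
                  learning_rate: float = 1e-4, seed: int = 0,
                  patience: int = 10, val_fraction: float = 0.2,
                  augment: bool = True) -> list[dict]:
    """Adam + margin loss with early stopping on validation loss.

    images: (N, side, side, C) in [0, 1]; labels: array of class names.
    Training batches receive random dihedral augmentation (rotations and
    flips) unless ``augment=False``.  Returns the per-epoch trace;
    ``epochs=0`` returns an empty trace and leaves the model untouched.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    if epochs == 0:
        return []
    x = np.asarray(images, dtype=np.float32).transpose(0, 3, 1, 2)
    onehot = (labels[:, None] == classes[None, :]).astype(np.float32)
    rng = np.random.default_rng(seed)
    n = len(x)
    n_val = max(1, int(round(n * val_fraction)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    optimizer = Adam(model.parameters(), lr=learning_rate)
    trace: list[dict] = []
    best_val = np.inf
    best_state = None
    since = 0
    for epoch in range(epochs):
        order = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(tr_idx), batch_size):
            idx = tr_idx[order[start:start + batch_size]]
            model.zero_grad()
            xb = _dihedral_augment(x[idx], rng) if augment else x[idx]
            v = model(Tensor(xb))
            loss = margin_loss(class_norms(v), onehot[idx])
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        vv = model(Tensor(x[val_idx]))
        norms = class_norms(vv)
        val_loss = float(margin_loss(norms, onehot[val_idx]).data)
        pred = norms.data.argmax(axis=1)
        truth = onehot[val_idx].argmax(axis=1)
        val_acc = float((pred == truth).mean())
        trace.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                      "val_loss": val_loss, "val_accuracy": val_acc})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = [p.data.copy() for p in model.parameters()]
            since = 0
        else:
            since += 1
            if since >= patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return trace


class CapsNetClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper: fit on (N, side, side, C) crops and labels.

    ``conv_filters`` and ``primary_caps_types`` may be reduced for desk-scale
    training; the full printed architecture is the default.  Fitted
    attributes: ``model_``, ``classes_``, ``history_``.
    """

    def __init__(self, conv_filters: int = 256, primary_caps_types: int = 32,
                 routing_iters: int = 3, epochs: int = 100,
                 batch_size: int = 32, learning_rate: float = 1e-4,
                 patience: int = 10, val_fraction: float = 0.2,
                 input_side: int = 64, input_channels: int = 3,
                 augment: bool = True, seed: int = 0):
        self.conv_filters = conv_filters
        self.primary_caps_types = primary_caps_types
        self.routing_iters = routing_iters
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.val_fraction = val_fraction
        self.input_side = input_side
        self.input_channels = input_channels
        self.augment = augment
        self.seed = seed

    def _spec(self) -> CapsNetSpec:
        return CapsNetSpec(
            input_side=self.input_side, input_channels=self.input_channels,
            conv_filters=self.conv_filters,
            primary_caps_types=self.primary_caps_types,
            routing_iters=self.routing_iters)

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("exactly two classes are expected")
        self.model_ = build_capsnet(self._spec(), seed=self.seed)
        self.history_ = train_capsnet(
            self.model_, X, y, epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, seed=self.seed,
            patience=self.patience, val_fraction=self.val_fraction,
            augment=self.augment)
        return self

    def _norms(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=np.float32).transpose(0, 3, 1, 2)
        out = []
        for start in range(0, len(x), self.batch_size):
            v = self.model_(Tensor(x[start:start + self.batch_size]))
            out.append(class_norms(v).data)
        return np.concatenate(out, axis=0)

    def decision_norms(self, X) -> np.ndarray:
        """Raw class capsule norms, shape (N, 2), each in [0, 1)."""
        return self._norms(X)

    def predict_proba(self, X) -> np.ndarray:
        norms = self._norms(X)
        return norms / norms.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self._norms(X).argmax(axis=1)]

    def output(self, X) -> list[CapsOutput]:
        """Full capsule outputs (vectors, norms, label) per sample."""
        x = np.asarray(X, dtype=np.float32).transpose(0, 3, 1, 2)
        outs = []
        for start in range(0, len(x), self.batch_size):
            v = self.model_(Tensor(x[start:start + self.batch_size]))
            norms = class_norms(v).data
            for i in range(v.shape[0]):
                outs.append(CapsOutput(
                    class_vectors=v.data[i].copy(),
                    class_probabilities=norms[i].copy(),
                    predicted_label=str(self.classes_[int(norms[i].argmax())])))
        return outs
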