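"""Volumetric CNN regressor mapping five bounding cubes to one scalar score.

The five per-family minimum bounding cubes are stacked as the five input
channels of one ``input_edge``^3 tensor.  The network is three rounds of
[3x3x3 convolution + batch norm + ReLU] with 10, 20 and 1 output channels
(all same-padded, stride 1, so the spatial size is preserved), a flatten, and
fully connected layers whose widths at the published input size of 64^3 are
262,144 -> 4096 -> 64 -> 1, with dropout (rate 0.5) between the FC layers.
Training minimizes mean squared error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm3d,
    Conv3d,
    Dropout,
    Linear,
    Module,
    ReLU,
    Sequential,
    mse_loss,
    new_rng,
)

__all__ = ["RegressorConfig", "Regressor", "build_regressor",
           "train_regressor", "predict_scores", "measure_flattened_length"]


@dataclass
class RegressorConfig:
    input_edge: int = 64
    in_channels: int = 5
    conv_channels: tuple[int, int, int] = (10, 20, 1)
    fc_dims: tuple[int, int, int] = (262144, 4096, 64)
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        flat = self.input_edge ** 3 * self.conv_channels[-1]
        if self.fc_dims[0] != flat:
            raise ValueError(
                f"fc_dims[0]={self.fc_dims[0]} must equal input_edge^3 x "
                f"last conv channels = {flat}")

    @classmethod
    def scaled(cls, input_edge: int, fc_hidden: tuple[int, int] = (256, 32),
               conv_channels: tuple[int, int, int] = (10, 20, 1),
               dropout: float = 0.5, seed: int = 0) -> "RegressorConfig":
        """A reduced configuration for small cubes; keeps the layer pattern."""
        flat = input_edge ** 3 * conv_channels[-1]
        return cls(input_edge=input_edge, conv_channels=conv_channels,
                   fc_dims=(flat, *fc_hidden), dropout=dropout, seed=seed)


def _build_body(cfg: RegressorConfig, rng: np.random.Generator) -> Sequential:
    c0, c1, c2 = cfg.conv_channels
    return Sequential(
        Conv3d(cfg.in_channels, c0, k=3, rng=rng), BatchNorm3d(c0), ReLU(),
        Conv3d(c0, c1, k=3, rng=rng), BatchNorm3d(c1), ReLU(),
        Conv3d(c1, c2, k=3, rng=rng), BatchNorm3d(c2), ReLU(),
    )


def measure_flattened_length(cfg: RegressorConfig) -> int:
    """Trace the convolutional body with a zero input of the configured edge
    and count the flattened features entering the first FC layer."""
    body = _build_body(cfg, new_rng(cfg.seed))
    body.eval()
    x = np.zeros((1, cfg.in_channels) + (cfg.input_edge,) * 3, dtype=np.float32)
    h = body.forward(x)
    return int(np.prod(h.shape[1:]))


class Regressor(Module):
    def __init__(self, cfg: RegressorConfig) -> None:
        self.cfg = cfg
        rng = new_rng(cfg.seed)
        self.body = _build_body(cfg, rng)
        f0, f1, f2 = cfg.fc_dims
        self.fc = Sequential(
            Linear(f0, f1, rng=rng), ReLU(), Dropout(cfg.dropout, rng=rng),
            Linear(f1, f2, rng=rng), ReLU(), Dropout(cfg.dropout, rng=rng),
            Linear(f2, 1, rng=rng),
        )
        self._flat_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 5, E, E, E) -> (N,) predicted scores."""
        if x.shape[1:] != (self.cfg.in_channels,) + (self.cfg.input_edge,) * 3:
            raise ValueError(f"expected input shape (N, {self.cfg.in_channels}, "
                             f"{self.cfg.input_edge}^3), got {x.shape}")
        h = self.body(x)
        self._flat_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        return self.fc(flat)[:, 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.fc.backward(grad[:, None])
        g = g.reshape(self._flat_shape)
        self._flat_shape = None
        return self.body.backward(g)

    @property
    def flattened_feature_length(self) -> int:
        return self.cfg.input_edge ** 3 * self.cfg.conv_channels[-1]


def build_regressor(cfg: RegressorConfig) -> Regressor:
    return Regressor(cfg)


def _random_flips(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip each sample's cubes along a random subset of spatial axes.

    The structures inside the cubes are bilateral, so axis flips are
    label-preserving augmentation."""
    out = x.copy()
    for i in range(len(out)):
        for ax in (1, 2, 3):  # spatial axes of (C, E, E, E)
            if rng.random() < 0.5:
                out[i] = np.flip(out[i], axis=ax)
    return out


def train_regressor(model: Regressor,
                    cubes: np.ndarray, scores: np.ndarray,
                    val_cubes: np.ndarray | None = None,
                    val_scores: np.ndarray | None = None,
                    epochs: int = 60, batch_size: int = 8, lr: float = 1e-3,
                    seed: int = 0, patience: int | None = 15,
                    augment_flips: bool = True,
                    standardize_scores: bool = True,
                    weight_decay: float = 0.0,
                    ) -> dict[str, list[float]]:
    """Minimize MSE with Adam; returns per-epoch train (and validation) MSE.

    Scores are internally z-scored against the training set (the inverse
    transform is stored on the model and applied by :func:`predict_scores`),
    and training cubes are randomly mirror-flipped each epoch unless disabled.
    Early stopping on validation MSE (restoring the best weights) when a
    validation set and ``patience`` are given.  Deterministic under ``seed``.
    """
    n = len(scores)
    if n == 0:
        raise ValueError("empty training set")
    cubes = np.asarray(cubes, dtype=np.float32)
    scores = np.asarray(scores, dtype=np.float64)
    y_mean = float(scores.mean()) if standardize_scores else 0.0
    y_sd = float(scores.std()) if standardize_scores else 1.0
    if y_sd == 0.0:
        y_sd = 1.0
    model.y_mean, model.y_sd = y_mean, y_sd
    y = (scores - y_mean) / y_sd
    y_val = ((np.asarray(val_scores, dtype=np.float64) - y_mean) / y_sd
             if val_scores is not None else None)
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=lr, weight_decay=weight_decay)
    history: dict[str, list[float]] = {"train_mse": []}
    has_val = val_cubes is not None and y_val is not None
    if has_val:
        history["val_mse"] = []
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(n)
        ep_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = cubes[idx]
            if augment_flips:
                xb = _random_flips(xb, rng)
            pred = model.forward(xb)
            loss, dpred = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate")
            opt.zero_grad()
            model.backward(dpred)
            opt.step()
            ep_losses.append(loss * y_sd ** 2)  # report on the score scale
        history["train_mse"].append(float(np.mean(ep_losses)))
        if has_val:
            model.eval()
            vp = np.concatenate([model.forward(val_cubes[s:s + batch_size])
                                 for s in range(0, len(val_cubes), batch_size)])
            v = float(np.mean((vp - y_val) ** 2)) * y_sd ** 2
            history["val_mse"].append(v)
            if v < best_val - 1e-9:
                best_val, best_state, since_best = v, model.state_dict(), 0
            else:
                since_best += 1
                if patience is not None and since_best >= patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def predict_scores(model: Regressor, cubes: np.ndarray, batch_size: int = 8,
                   tta_flips: bool = False) -> np.ndarray:
    """Eval-mode predictions (dropout off, BN running statistics) on the
    original score scale.

    ``tta_flips`` averages the prediction over all eight mirror flips of the
    cubes — the same symmetry used for training augmentation — which lowers
    prediction variance at 8x the forward cost.
    """
    model.eval()
    cubes = np.asarray(cubes, dtype=np.float32)
    variants: list[np.ndarray] = [cubes]
    if tta_flips:
        from itertools import product
        variants = [cubes]
        for fx, fy, fz in product((False, True), repeat=3):
            if not (fx or fy or fz):
                continue
            v = cubes
            for ax, f in zip((2, 3, 4), (fx, fy, fz)):
                if f:
                    v = np.flip(v, axis=ax)
            variants.append(np.ascontiguousarray(v))
    preds = []
    for v in variants:
        out = [model.forward(v[s:s + batch_size])
               for s in range(0, len(v), batch_size)]
        preds.append(np.concatenate(out))
    pred = np.mean(preds, axis=0)
    y_mean = getattr(model, "y_mean", 0.0)
    y_sd = getattr(model, "y_sd", 1.0)
    return pred * y_sd + y_mean
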