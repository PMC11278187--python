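"""Ensemble deep random vector functional link (edRVFL) classifier.

An RVFL layer is a hidden layer with frozen random weights plus direct
links: the design matrix fed to the output layer concatenates the nonlinear
hidden activations, the raw input features, and a constant-1 column (the
output bias). Stacking L such layers — each layer's hidden block receiving
the previous hidden block alongside the raw input — and giving every layer
its own closed-form ridge output head yields the deep ensemble; predictions
aggregate the per-layer heads.

Only the output heads are trained, by solving the regularized normal
equations exactly; the random hidden weights are never updated. With
``n_layers=1, n_nodes=0`` the model collapses to plain ridge regression of
one-hot targets on the standardized input, which serves as an external
correctness anchor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "EdRVFLConfig",
    "RVFLLayer",
    "EdRVFLModel",
    "init_model",
    "hidden_stack",
    "fit",
    "predict_scores",
    "predict",
    "save_model",
    "load_model",
]

_ACTIVATIONS = {
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
}


@dataclass(frozen=True)
class EdRVFLConfig:
    """Hyperparameters of the ensemble.

    ``n_nodes`` enhancement (random hidden) nodes per layer, ``reg_c`` the
    regularization parameter and ``n_layers`` hidden layers; the defaults
    (10, 100, 10) are the operating point used for stroke classification.
    Under the ``inverse_c`` ridge convention the penalty is ``I / reg_c``
    (large ``reg_c`` = weak regularization, the dominant RVFL convention);
    ``direct_lambda`` uses ``reg_c · I``.
    """

    n_nodes: int = 10
    reg_c: float = 100.0
    n_layers: int = 10
    activation: str = "tanh"
    seed: int = 0
    aggregation: str = "mean_score"
    bagging_fraction: float = 1.0
    ridge_convention: str = "inverse_c"

    def __post_init__(self) -> None:
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be >= 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.reg_c <= 0:
            raise ValueError("reg_c must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.aggregation not in ("mean_score", "majority_vote"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if not (0.0 < self.bagging_fraction <= 1.0):
            raise ValueError("bagging_fraction must be in (0, 1]")
        if self.ridge_convention not in ("inverse_c", "direct_lambda"):
            raise ValueError(f"unknown ridge_convention {self.ridge_convention!r}")


@dataclass
class RVFLLayer:
    """Frozen random input-to-hidden weights and biases of one layer."""

    W: np.ndarray  # (d_in, n_nodes)
    b: np.ndarray  # (n_nodes,)


@dataclass
class EdRVFLModel:
    """Random layers, per-layer ridge heads, class order and the feature
    standardizer fitted on the training split."""

    config: EdRVFLConfig
    d: int
    n_classes: int
    layers: list[RVFLLayer]
    classes: list[str] | None = None
    heads: list[np.ndarray] | None = None
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None

    @property
    def is_fitted(self) -> bool:
        return self.heads is not None


def init_model(d: int, n_classes: int, cfg: EdRVFLConfig | None = None) -> EdRVFLModel:
    """Create an unfitted model: ``n_layers`` layers with seeded uniform
    [-1, 1] weights. Layer 1 maps the d input features to ``n_nodes``
    hidden units; deeper layers map [previous hidden | input]."""
    cfg = cfg or EdRVFLConfig()
    if d < 1:
        raise ValueError("d must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    layers = []
    for level in range(cfg.n_layers):
        d_in = d if level == 0 else cfg.n_nodes + d
        layers.append(
            RVFLLayer(
                W=rng.uniform(-1.0, 1.0, size=(d_in, cfg.n_nodes)),
                b=rng.uniform(-1.0, 1.0, size=cfg.n_nodes),
            )
        )
    return EdRVFLModel(config=cfg, d=d, n_classes=n_classes, layers=layers)


def _standardize(model: EdRVFLModel, X: np.ndarray) -> np.ndarray:
    return (X - model.feat_mean) / model.feat_std


def hidden_stack(model: EdRVFLModel, X: np.ndarray) -> list[np.ndarray]:
    """Per-layer design blocks D_l = [H_l | X | 1] for standardized X.

    H_1 = act(X W_1 + b_1); for l >= 2, H_l = act([H_{l-1} | X] W_l + b_l).
    The raw input is concatenated at every level (direct links) and the
    constant column implements the output bias.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.d:
        raise ValueError(f"X must be (n, {model.d}), got {X.shape}")
    act = _ACTIVATIONS[model.config.activation]
    ones = np.ones((X.shape[0], 1))
    designs = []
    h_prev: np.ndarray | None = None
    for level, layer in enumerate(model.layers):
        z_in = X if level == 0 else np.hstack([h_prev, X])
        h = act(z_in @ layer.W + layer.b) if model.config.n_nodes > 0 else np.empty((X.shape[0], 0))
        designs.append(np.hstack([h, X, ones]))
        h_prev = h
    return designs


def _solve_head(D: np.ndarray, Y: np.ndarray, cfg: EdRVFLConfig) -> np.ndarray:
    lam = 1.0 / cfg.reg_c if cfg.ridge_convention == "inverse_c" else cfg.reg_c
    gram = D.T @ D + lam * np.eye(D.shape[1])
    return linalg.solve(gram, D.T @ Y, assume_a="pos")


def fit(model: EdRVFLModel, X: np.ndarray, y: Sequence[str]) -> EdRVFLModel:
    """Fit the standardizer and all per-layer ridge heads in closed form.

    Targets are one-hot encoded over the sorted unique labels. With
    ``bagging_fraction < 1`` each layer's head is solved on its own seeded
    row subsample. The model is modified in place and returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths disagree")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if len(classes) != model.n_classes:
        raise ValueError(f"expected {model.n_classes} classes, found {len(classes)}")

    model.classes = [str(c) for c in classes]
    model.feat_mean = X.mean(axis=0)
    std = X.std(axis=0)
    model.feat_std = np.where(std > 0, std, 1.0)

    Xs = _standardize(model, X)
    class_index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((X.shape[0], len(classes)))
    for i, label in enumerate(y):
        Y[i, class_index[label]] = 1.0

    designs = hidden_stack(model, Xs)
    n = X.shape[0]
    heads = []
    rng = np.random.default_rng(model.config.seed + 1)
    for D in designs:
        if model.config.bagging_fraction < 1.0:
            size = max(2, int(round(model.config.bagging_fraction * n)))
            rows = rng.choice(n, size=size, replace=False)
            heads.append(_solve_head(D[rows], Y[rows], model.config))
        else:
            heads.append(_solve_head(D, Y, model.config))
    model.heads = heads
    return model


def _per_layer_scores(model: EdRVFLModel, X: np.ndarray) -> list[np.ndarray]:
    if not model.is_fitted:
        raise RuntimeError("model is not fitted")
    Xs = _standardize(model, np.asarray(X, dtype=float))
    return [D @ W for D, W in zip(hidden_stack(model, Xs), model.heads)]


def predict_scores(model: EdRVFLModel, X: np.ndarray) -> np.ndarray:
    """Aggregate per-layer head outputs into one (n, n_classes) score matrix.

    ``mean_score`` averages the raw per-layer scores; ``majority_vote``
    takes each layer's argmax and returns per-class vote shares (rows sum
    to 1).
    """
    layer_scores = _per_layer_scores(model, X)
    if model.config.aggregation == "mean_score":
        return np.mean(layer_scores, axis=0)
    votes = np.zeros((layer_scores[0].shape[0], len(model.classes)))
    for scores in layer_scores:
        winners = np.argmax(scores, axis=1)
        votes[np.arange(len(winners)), winners] += 1.0
    return votes / len(layer_scores)


def predict(model: EdRVFLModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the aggregated scores; exact ties break toward the class
    earliest in ``model.classes``."""
    scores = predict_scores(model, X)
    return np.asarray(model.classes, dtype=object)[np.argmax(scores, axis=1)]


def save_model(model: EdRVFLModel, path: str | Path) -> None:
    """Serialize config, class order, standardizer and all weights into one
    portable .npz file (format version 1)."""
    if not model.is_fitted:
        raise RuntimeError("refusing to serialize an unfitted model")
    arrays = {
        "feat_mean": model.feat_mean,
        "feat_std": model.feat_std,
    }
    for i, layer in enumerate(model.layers):
        arrays[f"layer_{i}_W"] = layer.W
        arrays[f"layer_{i}_b"] = layer.b
        arrays[f"head_{i}"] = model.heads[i]
    meta = {
        "format_version": 1,
        "d": model.d,
        "n_classes": model.n_classes,
        "classes": model.classes,
        "config": model.config.__dict__,
    }
    np.savez(Path(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> EdRVFLModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]))
        cfg = EdRVFLConfig(**meta["config"])
        layers = [
            RVFLLayer(W=data[f"layer_{i}_W"], b=data[f"layer_{i}_b"])
            for i in range(cfg.n_layers)
        ]
        heads = [data[f"head_{i}"] for i in range(cfg.n_layers)]
        return EdRVFLModel(
            config=cfg,
            d=meta["d"],
            n_classes=meta["n_classes"],
            layers=layers,
            classes=meta["classes"],
            heads=heads,
            feat_mean=data["feat_mean"],
            feat_std=data["feat_std"],
        )
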