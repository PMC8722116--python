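"""Knowledge-masked feed-forward classifier for cell-type prediction.

The model is a standard fully-connected network, x_i = a(W_i x_{i-1} + b_i)
with a softmax output over cell types, except that the first hidden layer
may carry *biological* nodes: one node per gene set, whose incoming weights
are fixed to zero for every gene outside the set (the prior mask). A first
layer may mix freely-connected dense nodes with biological nodes; the layout
is [dense block | biological block]. Training minimises the multi-class
cross-entropy with mini-batch SGD (momentum, learning-rate decay) or Adam.

Masking is enforced twice: gradients at masked positions are zeroed, and the
weights themselves are re-zeroed after every optimizer step, so the masked
entries are exactly 0.0 at all times. With an all-ones mask the network is
bit-for-bit the dense network of the same widths under shared seeds.

Everything is numpy; training is deterministic given the config seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelVector, PriorMask

ACTIVATIONS = ("tanh", "relu", "sigmoid", "linear")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class LayerSpec:
    """One hidden layer: optional biological nodes plus dense nodes."""

    biological: bool = False
    dense_nodes: int = 0

    def __post_init__(self) -> None:
        if self.dense_nodes < 0:
            raise ValueError("dense_nodes must be non-negative")
        if not self.biological and self.dense_nodes == 0:
            raise ValueError("a layer needs biological nodes and/or dense nodes")


@dataclass
class NetworkConfig:
    input_genes: list[str]
    hidden_layers: list[LayerSpec]
    n_classes: int
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layers:
            raise ValueError("at least one hidden layer is required")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for spec in self.hidden_layers[1:]:
            if spec.biological:
                raise ValueError("only the first hidden layer may carry a mask")


@dataclass
class TrainingConfig:
    optimizer: str = "sgd"
    learning_rate: float = 0.01
    momentum: float = 0.9
    decay: float = 0.0
    epochs: int = 100
    batch_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if min(self.learning_rate, self.momentum, self.decay) < 0:
            raise ValueError("learning_rate, momentum and decay must be >= 0")


def default_training_config(optimizer: str = "sgd", **kwargs) -> TrainingConfig:
    """The defaults used throughout: SGD lr 0.01 / momentum 0.9, Adam lr 0.001."""
    if optimizer == "adam":
        kwargs.setdefault("learning_rate", 0.001)
        kwargs.setdefault("momentum", 0.0)
    return TrainingConfig(optimizer=optimizer, **kwargs)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------


def apply_activation(x: np.ndarray, kind: str) -> np.ndarray:
    """Elementwise activation; softmax acts along the last axis (max-shifted)."""
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        warnings.warn("NaN input to activation; propagating", stacklevel=2)
    if kind == "tanh":
        return np.tanh(x)
    if kind == "relu":
        return np.maximum(0.0, x)
    if kind == "sigmoid":
        # computed via tanh for symmetric overflow behaviour
        return 0.5 * (1.0 + np.tanh(0.5 * x))
    if kind == "linear":
        return x
    if kind == "softmax":
        shifted = x - np.max(x, axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown activation {kind!r}")


def _activation_grad(pre: np.ndarray, post: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - post**2
    if kind == "relu":
        return (pre > 0).astype(float)
    if kind == "sigmoid":
        return post * (1.0 - post)
    if kind == "linear":
        return np.ones_like(pre)
    raise ValueError(f"unknown hidden activation {kind!r}")


def cross_entropy(y_onehot: np.ndarray, p: np.ndarray) -> float:
    """Mean over samples of −Σ_c y_c log p_c, with p clipped to [1e-12, 1]."""
    y_onehot = np.atleast_2d(np.asarray(y_onehot, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if y_onehot.shape != p.shape:
        raise ValueError(f"shape mismatch {y_onehot.shape} vs {p.shape}")
    p = np.clip(p, 1e-12, 1.0)
    return float(-(y_onehot * np.log(p)).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Weights, biases and metadata of a (possibly untrained) network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: NetworkConfig
    mask: PriorMask | None = None
    first_layer_mask: np.ndarray | None = None  # full (genes × width) 0/1
    class_order: list[str] | None = None
    preprocessing: dict | None = None
    history: list[float] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def layer_widths(self) -> list[int]:
        return [w.shape[1] for w in self.weights]

    @property
    def biological_node_names(self) -> list[str] | None:
        return None if self.mask is None else list(self.mask.node_names)

    def forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        """Propagate cells × genes activations through ``upto`` layers.

        ``upto=None`` runs the full network (softmax probabilities);
        ``upto=k`` stops after hidden layer k (1-based), returning its
        post-activation values.
        """
        x = np.asarray(x, dtype=float)
        n_hidden = self.n_layers - 1
        stop = n_hidden if upto is None else upto
        if not 1 <= stop <= n_hidden:
            raise ValueError(f"upto must be in [1, {n_hidden}]")
        for i in range(stop):
            x = apply_activation(
                x @ self.weights[i] + self.biases[i], self.config.activation
            )
        if upto is not None:
            return x
        return apply_activation(x @ self.weights[-1] + self.biases[-1], "softmax")

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Store the model in a single .npz archive."""
        meta = {
            "activation": self.config.activation,
            "n_classes": self.config.n_classes,
            "seed": self.config.seed,
            "input_genes": self.config.input_genes,
            "hidden_layers": [
                {"biological": s.biological, "dense_nodes": s.dense_nodes}
                for s in self.config.hidden_layers
            ],
            "class_order": self.class_order,
            "node_names": self.biological_node_names,
            "history": self.history,
            "preprocessing_method": (self.preprocessing or {}).get("method"),
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        if self.first_layer_mask is not None:
            arrays["first_layer_mask"] = self.first_layer_mask
        if self.mask is not None:
            arrays["mask_matrix"] = self.mask.matrix
        if self.preprocessing:
            for key, value in self.preprocessing.items():
                if key != "method":
                    arrays[f"prep_{key}"] = np.asarray(value)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            weights, biases = [], []
            i = 0
            while f"W{i}" in data:
                weights.append(data[f"W{i}"])
                biases.append(data[f"b{i}"])
                i += 1
            config = NetworkConfig(
                input_genes=list(meta["input_genes"]),
                hidden_layers=[LayerSpec(**s) for s in meta["hidden_layers"]],
                n_classes=meta["n_classes"],
                activation=meta["activation"],
                seed=meta["seed"],
            )
            mask = None
            if "mask_matrix" in data and meta["node_names"]:
                mask = PriorMask(
                    data["mask_matrix"], list(meta["input_genes"]), meta["node_names"]
                )
            flm = data["first_layer_mask"] if "first_layer_mask" in data else None
            prep = None
            if meta["preprocessing_method"]:
                prep = {"method": meta["preprocessing_method"]}
                for key in data.files:
                    if key.startswith("prep_"):
                        prep[key[5:]] = data[key]
        return cls(
            weights=weights,
            biases=biases,
            config=config,
            mask=mask,
            first_layer_mask=flm,
            class_order=meta["class_order"],
            preprocessing=prep,
            history=list(meta["history"]),
        )


def build_network(config: NetworkConfig, mask: PriorMask | None = None) -> TrainedModel:
    """Glorot-initialise a network; masked first-layer weights start at 0.

    The full first-layer matrix is drawn before masking, so an all-ones mask
    yields exactly the same initial weights as the dense network of the same
    widths under the same seed.
    """
    wants_mask = any(s.biological for s in config.hidden_layers)
    if wants_mask and mask is None:
        raise ValueError("config declares biological nodes but no mask was given")
    if not wants_mask and mask is not None:
        raise ValueError("mask given but config declares no biological nodes")
    if mask is not None and mask.gene_ids != list(config.input_genes):
        raise ValueError("mask gene order does not match config.input_genes")

    rng = np.random.default_rng(config.seed)
    widths = [len(config.input_genes)]
    for spec in config.hidden_layers:
        width = spec.dense_nodes + (mask.n_nodes if spec.biological else 0)
        widths.append(width)
    widths.append(config.n_classes)

    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    first_layer_mask = None
    if mask is not None:
        spec = config.hidden_layers[0]
        dense_block = np.ones((len(config.input_genes), spec.dense_nodes))
        first_layer_mask = np.concatenate([dense_block, mask.matrix], axis=1)
        weights[0] = weights[0] * first_layer_mask

    return TrainedModel(
        weights=weights,
        biases=biases,
        config=config,
        mask=mask,
        first_layer_mask=first_layer_mask,
    )


def count_effective_parameters(
    config: NetworkConfig, mask: PriorMask | None = None
) -> int:
    """Free (unmasked) weights plus all biases, output layer included."""
    wants_mask = any(s.biological for s in config.hidden_layers)
    if wants_mask and mask is None:
        raise ValueError("config declares biological nodes but no mask was given")
    n_in = len(config.input_genes)
    total = 0
    fan_in = n_in
    for i, spec in enumerate(config.hidden_layers):
        width = spec.dense_nodes + (mask.n_nodes if spec.biological else 0)
        if i == 0 and spec.biological:
            free = fan_in * spec.dense_nodes + int(mask.matrix.sum())
        else:
            free = fan_in * width
        total += free + width
        fan_in = width
    total += fan_in * config.n_classes + config.n_classes
    return total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _one_hot(codes: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((codes.size, n_classes))
    out[np.arange(codes.size), codes] = 1.0
    return out


def train(
    model: TrainedModel,
    X: ExpressionMatrix | np.ndarray,
    y: LabelVector,
    tcfg: TrainingConfig,
    callback=None,
) -> TrainedModel:
    """Fit the network in place by mini-batch cross-entropy minimisation.

    Runs exactly ``tcfg.epochs`` epochs of seeded shuffled mini-batches (no
    early stopping) and returns the final-epoch model. The per-epoch mean
    training loss is appended to ``model.history``. ``callback(step, model)``,
    if given, is invoked after every optimizer step.
    """
    x = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if isinstance(X, ExpressionMatrix) and X.gene_ids != list(model.config.input_genes):
        raise ValueError("training matrix gene order does not match the model")
    if len(y) != x.shape[0]:
        raise ValueError("label vector not aligned with expression rows")
    if y.n_classes > model.config.n_classes:
        extra = set(y.classes)
        raise ValueError(
            f"labels have {y.n_classes} classes but the model outputs "
            f"{model.config.n_classes}: {sorted(extra)[: y.n_classes]}"
        )
    model.class_order = list(y.classes)
    codes = y.indices()
    onehot = _one_hot(codes, model.config.n_classes)

    n = x.shape[0]
    act = model.config.activation
    flm = model.first_layer_mask
    shuffle_rng = np.random.default_rng(tcfg.seed + 1)

    velocity_w = [np.zeros_like(w) for w in model.weights]
    velocity_b = [np.zeros_like(b) for b in model.biases]
    if tcfg.optimizer == "adam":
        m_w = [np.zeros_like(w) for w in model.weights]
        v_w = [np.zeros_like(w) for w in model.weights]
        m_b = [np.zeros_like(b) for b in model.biases]
        v_b = [np.zeros_like(b) for b in model.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

    step = 0
    for _epoch in range(tcfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            batch = order[start : start + tcfg.batch_size]
            xb, yb = x[batch], onehot[batch]
            bsz = len(batch)

            # forward pass, caching activations
            activations = [xb]
            pre_list = []
            h = xb
            for i in range(model.n_layers - 1):
                pre = h @ model.weights[i] + model.biases[i]
                h = apply_activation(pre, act)
                pre_list.append(pre)
                activations.append(h)
            logits = h @ model.weights[-1] + model.biases[-1]
            probs = apply_activation(logits, "softmax")
            epoch_loss += cross_entropy(yb, probs) * bsz

            # backward pass: softmax + cross-entropy gives delta = p - y
            delta = (probs - yb) / bsz
            grads_w = [None] * model.n_layers
            grads_b = [None] * model.n_layers
            grads_w[-1] = activations[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            for i in range(model.n_layers - 2, -1, -1):
                delta = (delta @ model.weights[i + 1].T) * _activation_grad(
                    pre_list[i], activations[i + 1], act
                )
                grads_w[i] = activations[i].T @ delta
                grads_b[i] = delta.sum(axis=0)
            if flm is not None:
                grads_w[0] *= flm

            lr = tcfg.learning_rate / (1.0 + tcfg.decay * step)
            if tcfg.optimizer == "sgd":
                for i in range(model.n_layers):
                    velocity_w[i] = tcfg.momentum * velocity_w[i] - lr * grads_w[i]
                    velocity_b[i] = tcfg.momentum * velocity_b[i] - lr * grads_b[i]
                    model.weights[i] += velocity_w[i]
                    model.biases[i] += velocity_b[i]
            else:  # adam
                t = step + 1
                for i in range(model.n_layers):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * grads_w[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * grads_w[i] ** 2
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * grads_b[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * grads_b[i] ** 2
                    mhat_w = m_w[i] / (1 - beta1**t)
                    vhat_w = v_w[i] / (1 - beta2**t)
                    mhat_b = m_b[i] / (1 - beta1**t)
                    vhat_b = v_b[i] / (1 - beta2**t)
                    model.weights[i] -= lr * mhat_w / (np.sqrt(vhat_w) + eps)
                    model.biases[i] -= lr * mhat_b / (np.sqrt(vhat_b) + eps)

            if flm is not None:
                model.weights[0] *= flm  # defensive: masked entries exactly 0
            step += 1
            if callback is not None:
                callback(step, model)
        model.history.append(epoch_loss / n)
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


@dataclass
class PredictionOutput:
    probabilities: np.ndarray
    predicted_class: list[str]
    class_order: list[str]


def _aligned_values(model: TrainedModel, X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        expected = list(model.config.input_genes)
        if X.gene_ids != expected:
            missing = sorted(set(expected) - set(X.gene_ids))
            unknown = sorted(set(X.gene_ids) - set(expected))
            if missing or unknown:
                raise ValueError(
                    f"gene space mismatch: missing {missing[:5]}, "
                    f"unknown {unknown[:5]}"
                )
            X = X.subset_genes(expected)
        return X.values
    x = np.asarray(X, dtype=float)
    if x.shape[1] != len(model.config.input_genes):
        raise ValueError("input width does not match model gene count")
    return x


def predict_proba(model: TrainedModel, X) -> PredictionOutput:
    """Row-stochastic class probabilities; argmax ties go to the lowest index."""
    if model.class_order is None:
        raise ValueError("model has not been trained (no class order)")
    probs = model.forward(_aligned_values(model, X))
    # pad class order if the model has more outputs than observed classes
    order = list(model.class_order)
    order += [f"_unused_{i}" for i in range(model.config.n_classes - len(order))]
    codes = probs.argmax(axis=1)  # np.argmax: first (lowest) index wins ties
    return PredictionOutput(
        probabilities=probs,
        predicted_class=[order[c] for c in codes],
        class_order=order,
    )


def predict(model: TrainedModel, X) -> list[str]:
    return predict_proba(model, X).predicted_class
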