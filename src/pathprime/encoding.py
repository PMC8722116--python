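"""Unsupervised reuse of a trained classifier.

Once the network predicts cell types well, its intermediate layers are a
representation of the data in their own right: detaching the output layer
and reading the last hidden layer gives a low-dimensional *encoding* used
for clustering, retrieval and 2-D visualisation, while the first hidden
layer's biological block gives per-cell *pathway activities*. The weights
into the output layer rank which pathways the classifier leans on for each
cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .network import TrainedModel, _aligned_values


@dataclass
class Encoding:
    """Last-hidden-layer activations: cells × H."""

    values: np.ndarray
    cell_ids: list[str] | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class PathwayActivityMatrix:
    """First-hidden-layer activations restricted to the biological nodes."""

    values: np.ndarray
    node_names: list[str]
    cell_ids: list[str] | None = None


@dataclass
class NodeRanking:
    """Per class: nodes ordered by the weight connecting them to that class."""

    per_class: dict[str, list[tuple[str, float]]]

    def top_names(self, cls: str) -> list[str]:
        return [name for name, _ in self.per_class[cls]]


def encode(model: TrainedModel, X) -> Encoding:
    """Activations of the last hidden layer (output layer detached)."""
    x = _aligned_values(model, X)
    values = model.forward(x, upto=model.n_layers - 1)
    cell_ids = X.cell_ids if hasattr(X, "cell_ids") else None
    return Encoding(values=values, cell_ids=cell_ids)


def pathway_activities(model: TrainedModel, X) -> PathwayActivityMatrix:
    """First-hidden-layer activations of the biological block only.

    For hybrid first layers the dense block is excluded, so columns line up
    one-to-one with the prior-mask nodes (pathways).
    """
    if model.mask is None:
        raise ValueError("model has no biological nodes; no pathway activities")
    x = _aligned_values(model, X)
    first = model.forward(x, upto=1)
    n_dense = model.config.hidden_layers[0].dense_nodes
    bio = first[:, n_dense:]
    cell_ids = X.cell_ids if hasattr(X, "cell_ids") else None
    return PathwayActivityMatrix(
        values=bio, node_names=list(model.mask.node_names), cell_ids=cell_ids
    )


def mean_activity_by_class(
    activities: PathwayActivityMatrix, labels
) -> dict[str, np.ndarray]:
    """Per-cell-type mean of each node's activity."""
    arr = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    return {
        cls: activities.values[arr == cls].mean(axis=0) for cls in np.unique(arr)
    }


def top_nodes_per_class(
    model: TrainedModel,
    n: int = 10,
    *,
    strategy: str = "auto",
    orient: str = "input_sign",
    use_abs: bool = False,
) -> NodeRanking:
    """Rank hidden nodes by their weight into each output class.

    For a single-hidden-layer model the node → class weight is read directly
    from the output weight matrix. For deeper models two strategies exist:

    ``path_product`` (the ``auto`` default for 2-layer models)
        score(node, class) = Σ_h |W2[node, h] · W3[h, class]| — the total
        connection strength over all second-layer routes.
    ``last_layer``
        rank the *last* hidden layer's nodes by output weight (which are
        dense nodes, not pathways, in 2-layer designs).

    A symmetric hidden unit (tanh, linear) can encode high member-gene
    expression with either sign, flipping its output weight in tandem, so
    the raw signed output weight of a node is only identified up to that
    orientation. With ``orient="input_sign"`` (default) each ranked node is
    therefore oriented by the sign of its summed incoming weights — making
    the score the weight of the path "elevated member genes → node →
    class" — before signed descending ranking. ``orient="none"`` ranks the
    raw signed weights; ``use_abs`` ranks magnitudes. ``n`` larger than the
    node count is clamped with a warning.
    """
    if model.class_order is None:
        raise ValueError("model has not been trained")
    if orient not in ("input_sign", "none"):
        raise ValueError(f"unknown orient {orient!r}")
    n_hidden = model.n_layers - 1

    if strategy == "auto":
        strategy = "last_layer" if n_hidden == 1 else "path_product"

    def _orientation(incoming: np.ndarray) -> np.ndarray:
        sign = np.sign(incoming.sum(axis=0))
        sign[sign == 0] = 1.0
        return sign

    if strategy == "last_layer" and n_hidden == 1 and model.mask is not None:
        n_dense = model.config.hidden_layers[0].dense_nodes
        node_names = list(model.mask.node_names)
        scores = model.weights[-1][n_dense:, :]  # biological rows only
        if orient == "input_sign":
            scores = scores * _orientation(model.weights[0][:, n_dense:])[:, None]
    elif strategy == "last_layer":
        width = model.weights[-1].shape[0]
        node_names = [f"node_{i}" for i in range(width)]
        scores = model.weights[-1]
        if orient == "input_sign":
            scores = scores * _orientation(model.weights[-2])[:, None]
    elif strategy == "path_product":
        if model.mask is None:
            raise ValueError("path_product ranking requires biological nodes")
        n_dense = model.config.hidden_layers[0].dense_nodes
        node_names = list(model.mask.node_names)
        # accumulate |route| strength from each biological node to each class
        strength = np.abs(model.weights[1][n_dense:, :])
        for w in model.weights[2:-1]:
            strength = strength @ np.abs(w)
        scores = strength @ np.abs(model.weights[-1])
    else:
        raise ValueError(f"unknown ranking strategy {strategy!r}")

    if n > len(node_names):
        warnings.warn(
            f"n={n} exceeds the {len(node_names)} available nodes; clamped",
            stacklevel=2,
        )
        n = len(node_names)

    ranked = np.abs(scores) if use_abs else scores
    per_class: dict[str, list[tuple[str, float]]] = {}
    for c, cls in enumerate(model.class_order):
        col = ranked[:, c]
        # stable sort on -col keeps ties in node order
        order = np.argsort(-col, kind="stable")[:n]
        per_class[cls] = [(node_names[i], float(scores[i, c])) for i in order]
    return NodeRanking(per_class=per_class)


def embed_2d(enc: Encoding, method: str = "tsne", seed: int = 0) -> np.ndarray:
    """Project an encoding to 2-D with t-SNE (seeded) or PCA (deterministic)."""
    x = enc.values
    if method == "pca":
        if x.shape[0] < 2:
            raise ValueError("PCA embedding needs at least 2 cells")
        return PCA(n_components=2, svd_solver="full").fit_transform(x)
    if method == "tsne":
        if x.shape[0] < 3:
            raise ValueError("t-SNE embedding needs at least 3 cells")
        perplexity = min(30.0, max(1.0, (x.shape[0] - 1) / 3))
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            max_iter=1000,
            init="pca",
            random_state=seed,
        )
        return tsne.fit_transform(x)
    raise ValueError(f"unknown embedding method {method!r}")
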