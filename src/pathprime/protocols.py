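"""Validation protocols: repeated stratified holdout, leave-P-groups-out
clustering, reference/query retrieval, and hyperband hyperparameter search.

Each protocol repeatedly (re)trains the network from scratch with seeds
derived from a base seed, always fitting preprocessing statistics on the
training fold only, and returns a :class:`ProtocolReport` whose per-repeat
records make every summary recomputable and every repeat re-runnable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import ExpressionMatrix, LabelVector, PriorMask, preprocess
from .encoding import encode
from .evaluation import (
    RetrievalConfig,
    clustering_metrics,
    kmeans_cluster,
    retrieval_map,
    supervised_metrics,
)
from .network import (
    NetworkConfig,
    TrainedModel,
    TrainingConfig,
    build_network,
    predict,
    train,
)

# ---------------------------------------------------------------------------
# plans and report
# ---------------------------------------------------------------------------


@dataclass
class HoldoutPlan:
    repeats: int = 100
    test_size: float = 0.30
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_size < 1:
            raise ValueError("test_size must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class LPGOPlan:
    P: int = 4
    repeats: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 2:
            raise ValueError("P must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class HyperbandPlan:
    """Search space for SGD tuning: learning rate and decay are sampled
    log-uniformly, momentum uniformly."""

    learning_rate_range: tuple[float, float] = (1e-4, 1e-1)
    momentum_range: tuple[float, float] = (0.0, 0.99)
    decay_range: tuple[float, float] = (1e-6, 1e-2)
    max_resource: int = 27
    eta: int = 3
    objective: str = "accuracy"
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta < 2:
            raise ValueError("eta must be >= 2")
        if self.max_resource < self.eta:
            raise ValueError("max_resource must be >= eta")


@dataclass
class ProtocolReport:
    protocol: str
    records: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    def summary(self, stat: str = "mean") -> dict[str, float]:
        """Aggregate every numeric field across records."""
        if not self.records:
            return {}
        keys = [
            k
            for k, v in self.records[0].items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        ]
        fn = {"mean": np.mean, "median": np.median, "std": np.std}[stat]
        return {
            k: float(fn([r[k] for r in self.records if k in r])) for k in keys
        }


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def stratified_split(
    labels: LabelVector, test_size: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test split with largest-remainder rounding.

    Per-class test counts apportion ``round(test_size · n)`` cells by the
    largest fractional remainder of ``test_size · n_c`` (ties broken by
    class order); every class is guaranteed at least one training cell.
    """
    arr = labels.as_array()
    classes = labels.classes
    counts = {c: int((arr == c).sum()) for c in classes}
    for c, n_c in counts.items():
        if n_c < 2:
            raise ValueError(f"class {c!r} has {n_c} cell(s); cannot stratify")

    quotas = {c: counts[c] * test_size for c in classes}
    take = {c: math.floor(quotas[c]) for c in classes}
    total_target = round(sum(quotas.values()))
    leftovers = sorted(
        classes, key=lambda c: (-(quotas[c] - take[c]), classes.index(c))
    )
    for c in leftovers[: total_target - sum(take.values())]:
        take[c] += 1
    for c in classes:  # keep at least one training cell per class
        if take[c] >= counts[c]:
            take[c] = counts[c] - 1

    rng = np.random.default_rng(seed)
    test_idx, train_idx = [], []
    for c in classes:
        members = np.flatnonzero(arr == c)
        perm = rng.permutation(members)
        test_idx.extend(perm[: take[c]])
        train_idx.extend(perm[take[c] :])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _fit_once(
    X: ExpressionMatrix,
    y: LabelVector,
    net_cfg: NetworkConfig,
    train_cfg: TrainingConfig,
    mask: PriorMask | None,
    preprocess_method: str,
    seed: int,
) -> tuple[TrainedModel, dict]:
    """Preprocess (fit on X), build a fresh seeded network, train."""
    Xp, stats = preprocess(X, preprocess_method)
    cfg = replace(net_cfg, n_classes=y.n_classes, seed=seed)
    model = build_network(cfg, mask)
    model.preprocessing = stats
    train(model, Xp, y, replace(train_cfg, seed=seed))
    return model, stats


def _apply_stats(X: ExpressionMatrix, stats: dict) -> ExpressionMatrix:
    return preprocess(X, stats["method"], fit_stats=stats)[0]


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def repeated_stratified_holdout(
    X: ExpressionMatrix,
    y: LabelVector,
    net_cfg: NetworkConfig,
    train_cfg: TrainingConfig,
    plan: HoldoutPlan,
    mask: PriorMask | None = None,
    preprocess_method: str = "zscore",
) -> ProtocolReport:
    """Repeat: stratified split, train on the training fold, score the test
    fold with the supervised metrics. Preprocessing is fit per repeat on the
    training fold only."""
    report = ProtocolReport(
        protocol="holdout",
        config={
            "repeats": plan.repeats,
            "test_size": plan.test_size,
            "preprocess": preprocess_method,
        },
    )
    for r in range(plan.repeats):
        seed = plan.base_seed + r
        train_idx, test_idx = stratified_split(y, plan.test_size, seed)
        X_tr = ExpressionMatrix(
            X.values[train_idx], X.gene_ids, [X.cell_ids[i] for i in train_idx]
        )
        X_te = ExpressionMatrix(
            X.values[test_idx], X.gene_ids, [X.cell_ids[i] for i in test_idx]
        )
        y_tr, y_te = y.subset(train_idx), y.subset(test_idx)
        model, stats = _fit_once(
            X_tr, y_tr, net_cfg, train_cfg, mask, preprocess_method, seed
        )
        y_hat = predict(model, _apply_stats(X_te, stats))
        record = supervised_metrics(y_te, y_hat).as_dict()
        record["repeat"] = r
        record["seed"] = seed
        report.records.append(record)
        report.seeds.append(seed)
    return report


def lpgo_protocol(
    X: ExpressionMatrix,
    y: LabelVector,
    net_cfg: NetworkConfig,
    train_cfg: TrainingConfig,
    plan: LPGOPlan,
    mask: PriorMask | None = None,
    preprocess_method: str = "zscore",
    kmeans_n_init: int = 10,
) -> ProtocolReport:
    """Leave-P-groups-out: hold out every cell of P randomly drawn cell
    types, train on the complement, encode the held-out cells and cluster
    them with K-Means (K = P), scoring clusters against the true labels.

    The held-out types are never seen during training, so this simulates
    clustering genuinely unknown cell types.
    """
    M = y.n_classes
    if plan.P >= M:
        raise ValueError(f"P={plan.P} must be < number of classes M={M}")
    if M - plan.P < 2:
        raise ValueError("training fold must retain at least 2 classes")

    report = ProtocolReport(
        protocol="lpgo",
        config={"P": plan.P, "repeats": plan.repeats, "preprocess": preprocess_method},
    )
    arr = y.as_array()
    for r in range(plan.repeats):
        seed = plan.base_seed + r
        rng = np.random.default_rng(seed)
        held_out = sorted(str(c) for c in rng.choice(y.classes, size=plan.P, replace=False))
        test_rows = np.flatnonzero(np.isin(arr, held_out))
        train_rows = np.flatnonzero(~np.isin(arr, held_out))
        X_tr = ExpressionMatrix(
            X.values[train_rows], X.gene_ids, [X.cell_ids[i] for i in train_rows]
        )
        X_te = ExpressionMatrix(
            X.values[test_rows], X.gene_ids, [X.cell_ids[i] for i in test_rows]
        )
        y_tr = LabelVector(list(arr[train_rows]))
        y_te = list(arr[test_rows])
        assert not set(y_tr.classes) & set(held_out)

        model, stats = _fit_once(
            X_tr, y_tr, net_cfg, train_cfg, mask, preprocess_method, seed
        )
        enc = encode(model, _apply_stats(X_te, stats))
        clusters = kmeans_cluster(enc, K=plan.P, seed=seed, n_init=kmeans_n_init)
        record = clustering_metrics(y_te, clusters).as_dict()
        record["repeat"] = r
        record["seed"] = seed
        record["held_out"] = held_out
        report.records.append(record)
        report.seeds.append(seed)
    return report


def retrieval_protocol(
    learning: tuple[ExpressionMatrix, LabelVector],
    retrieval: tuple[ExpressionMatrix, LabelVector],
    net_cfg: NetworkConfig,
    train_cfg: TrainingConfig,
    rcfg: RetrievalConfig | None = None,
    mask: PriorMask | None = None,
    preprocess_method: str = "zscore",
    seed: int = 0,
) -> ProtocolReport:
    """Train on the full learning set; annotate the retrieval set by nearest
    neighbours in encoding space, scored by per-class MAP.

    Both sets are restricted to their common genes (in learning-set order),
    which must match the network's input genes. Retrieval classes absent
    from the learning set keep AP = 0 by definition.
    """
    X_learn, y_learn = learning
    X_query, y_query = retrieval
    common = [g for g in X_learn.gene_ids if g in set(X_query.gene_ids)]
    if not common:
        raise ValueError("learning and retrieval sets share no genes")
    X_learn = X_learn.subset_genes(common)
    X_query = X_query.subset_genes(common)
    if list(net_cfg.input_genes) != common:
        raise ValueError(
            "network input genes do not match the common gene space; "
            "intersect gene spaces (and rebuild the mask) before training"
        )

    rcfg = rcfg or RetrievalConfig()
    model, stats = _fit_once(
        X_learn, y_learn, net_cfg, train_cfg, mask, preprocess_method, seed
    )
    enc_ref = encode(model, _apply_stats(X_learn, stats))
    enc_query = encode(model, _apply_stats(X_query, stats))
    result = retrieval_map(enc_ref, y_learn, enc_query, y_query, rcfg)

    report = ProtocolReport(
        protocol="retrieval",
        config={"k": rcfg.k, "preprocess": preprocess_method},
        seeds=[seed],
    )
    for cls, value in result["per_class"].items():
        report.records.append({"cell_type": cls, "map": value})
    report.config["mean_map"] = result["mean"]
    report.config["k_used"] = result["k"]
    return report


# ---------------------------------------------------------------------------
# hyperband
# ---------------------------------------------------------------------------


def hyperband_schedule(max_resource: int, eta: int) -> list[list[tuple[int, int]]]:
    """The (n_configs, resource) rungs of each successive-halving bracket."""
    s_max = int(math.floor(math.log(max_resource) / math.log(eta)))
    budget = (s_max + 1) * max_resource
    brackets = []
    for s in range(s_max, -1, -1):
        n = int(math.ceil(budget / max_resource / (s + 1) * eta**s))
        r = max_resource * eta ** (-s)
        rungs = []
        for i in range(s + 1):
            n_i = int(math.floor(n * eta ** (-i)))
            r_i = max(1, int(round(r * eta**i)))
            rungs.append((n_i, r_i))
        brackets.append(rungs)
    return brackets


def _sample_config(plan: HyperbandPlan, rng: np.random.Generator) -> TrainingConfig:
    def log_uniform(lo: float, hi: float) -> float:
        if lo == hi:
            return lo
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    lo, hi = plan.momentum_range
    return TrainingConfig(
        optimizer="sgd",
        learning_rate=log_uniform(*plan.learning_rate_range),
        momentum=lo if lo == hi else float(rng.uniform(lo, hi)),
        decay=log_uniform(*plan.decay_range),
        epochs=1,  # resource set per rung
        batch_size=10,
    )


def hyperband_tune(
    X: ExpressionMatrix,
    y: LabelVector,
    net_cfg: NetworkConfig,
    plan: HyperbandPlan,
    objective_fn=None,
    mask: PriorMask | None = None,
    preprocess_method: str = "zscore",
) -> tuple[TrainingConfig, list[dict]]:
    """Hyperband search over SGD learning rate, momentum and decay.

    Resource = training epochs. Each candidate is trained on an internal
    stratified split of ``X`` and scored on the held-out part by
    ``objective_fn(model, X_val, y_val)`` (default: validation accuracy,
    higher is better); successive halving keeps the top 1/eta per rung.
    Returns the best configuration (epochs reset to ``max_resource``) and
    the full trial log.
    """
    if objective_fn is None:

        def objective_fn(model, X_val, y_val):
            return supervised_metrics(y_val, predict(model, X_val)).accuracy

    train_idx, val_idx = stratified_split(y, plan.validation_fraction, plan.seed)
    X_tr = ExpressionMatrix(
        X.values[train_idx], X.gene_ids, [X.cell_ids[i] for i in train_idx]
    )
    X_val = ExpressionMatrix(
        X.values[val_idx], X.gene_ids, [X.cell_ids[i] for i in val_idx]
    )
    y_tr, y_val = y.subset(train_idx), y.subset(val_idx)
    Xp_tr, stats = preprocess(X_tr, preprocess_method)
    Xp_val = _apply_stats(X_val, stats)

    log: list[dict] = []
    best: tuple[float, TrainingConfig] | None = None
    brackets = hyperband_schedule(plan.max_resource, plan.eta)
    for b, rungs in enumerate(brackets):
        rng = np.random.default_rng(plan.seed + 1000 * (b + 1))
        candidates = [_sample_config(plan, rng) for _ in range(rungs[0][0])]
        for rung_idx, (n_i, r_i) in enumerate(rungs):
            candidates = candidates[:n_i]
            scored = []
            for c_idx, cand in enumerate(candidates):
                cfg = replace(net_cfg, n_classes=y_tr.n_classes, seed=plan.seed)
                model = build_network(cfg, mask)
                tcfg = replace(cand, epochs=r_i, seed=plan.seed)
                train(model, Xp_tr, y_tr, tcfg)
                score = float(objective_fn(model, Xp_val, y_val))
                scored.append((score, c_idx, cand))
                log.append(
                    {
                        "bracket": b,
                        "rung": rung_idx,
                        "epochs": r_i,
                        "learning_rate": cand.learning_rate,
                        "momentum": cand.momentum,
                        "decay": cand.decay,
                        "objective": score,
                    }
                )
            scored.sort(key=lambda t: (-t[0], t[1]))
            if best is None or scored[0][0] > best[0]:
                best = (scored[0][0], scored[0][2])
            candidates = [cand for _, _, cand in scored]
    assert best is not None
    return replace(best[1], epochs=plan.max_resource, seed=plan.seed), log
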