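"""Independent textbook-formula oracles used to cross-check the metric code.

Everything here is written from contingency tables and first principles,
deliberately sharing no code with the package's metric implementations.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.special import gammaln


def confusion(y_true, y_pred, classes):
    table = {(t, p): 0 for t in classes for p in classes}
    for t, p in zip(y_true, y_pred):
        table[(t, p)] += 1
    return table


def supervised_oracle(y_true, y_pred) -> dict[str, float]:
    y_true = list(y_true)
    y_pred = list(y_pred)
    classes = sorted(set(y_true) | set(y_pred))
    n = len(y_true)

    tp = {c: sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c) for c in classes}
    pred_n = {c: y_pred.count(c) for c in classes}
    true_n = {c: y_true.count(c) for c in classes}

    prec = {c: tp[c] / pred_n[c] if pred_n[c] else 0.0 for c in classes}
    rec = {c: tp[c] / true_n[c] if true_n[c] else 0.0 for c in classes}
    f1 = {
        c: (2 * prec[c] * rec[c] / (prec[c] + rec[c]) if prec[c] + rec[c] else 0.0)
        for c in classes
    }

    accuracy = sum(tp.values()) / n
    support_total = sum(true_n.values())

    def macro(d):
        return sum(d.values()) / len(classes)

    def weighted(d):
        return sum(d[c] * true_n[c] for c in classes) / support_total

    total_tp = sum(tp.values())
    total_pred = sum(pred_n.values())
    total_true = sum(true_n.values())
    micro_p = total_tp / total_pred
    micro_r = total_tp / total_true
    micro_f1 = (
        2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    )

    present = [c for c in classes if true_n[c] > 0]
    balanced = sum(rec[c] for c in present) / len(present)

    return {
        "accuracy": accuracy,
        "balanced_accuracy": balanced,
        "precision_macro": macro(prec),
        "precision_micro": micro_p,
        "precision_weighted": weighted(prec),
        "recall_macro": macro(rec),
        "recall_micro": micro_r,
        "recall_weighted": weighted(rec),
        "f1_macro": macro(f1),
        "f1_micro": micro_f1,
        "f1_weighted": weighted(f1),
    }


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _contingency(y_true, clusters):
    t_classes = sorted(set(y_true))
    c_classes = sorted(set(clusters))
    table = np.zeros((len(t_classes), len(c_classes)), dtype=int)
    for t, c in zip(y_true, clusters):
        table[t_classes.index(t), c_classes.index(c)] += 1
    return table


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    probs = counts[counts > 0] / n
    return float(-(probs * np.log(probs)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    mi = 0.0
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij:
                mi += nij / n * math.log(n * nij / (row[i] * col[j]))
    return mi


def _expected_mi(row: np.ndarray, col: np.ndarray, n: int) -> float:
    """E[MI] under the permutation (hypergeometric) model."""
    emi = 0.0
    lg = gammaln
    for a in row:
        for b in col:
            lo = max(1, a + b - n)
            hi = min(a, b)
            for nij in range(lo, hi + 1):
                term1 = nij / n * math.log(n * nij / (a * b))
                logw = (
                    lg(a + 1)
                    + lg(b + 1)
                    + lg(n - a + 1)
                    + lg(n - b + 1)
                    - lg(n + 1)
                    - lg(nij + 1)
                    - lg(a - nij + 1)
                    - lg(b - nij + 1)
                    - lg(n - a - b + nij + 1)
                )
                emi += term1 * math.exp(logw)
    return emi


def _pair_counts(y_true, clusters):
    """(both same, same true only, same cluster only) over all pairs."""
    ss = st = sc = 0
    for i, j in combinations(range(len(y_true)), 2):
        same_t = y_true[i] == y_true[j]
        same_c = clusters[i] == clusters[j]
        if same_t and same_c:
            ss += 1
        if same_t:
            st += 1
        if same_c:
            sc += 1
    return ss, st, sc


def clustering_oracle(y_true, clusters) -> dict[str, float]:
    y_true = list(y_true)
    clusters = list(clusters)
    n = len(y_true)
    table = _contingency(y_true, clusters)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    h_true = _entropy(row)
    h_clust = _entropy(col)
    mi = _mutual_information(table)

    homogeneity = 1.0 if h_true == 0 else mi / h_true
    completeness = 1.0 if h_clust == 0 else mi / h_clust
    v = (
        0.0
        if homogeneity + completeness == 0
        else 2 * homogeneity * completeness / (homogeneity + completeness)
    )

    # ARI from pair counts
    ss, st, sc = _pair_counts(y_true, clusters)
    total_pairs = n * (n - 1) // 2
    expected = st * sc / total_pairs
    max_index = (st + sc) / 2
    ari = 1.0 if max_index == expected else (ss - expected) / (max_index - expected)

    # Fowlkes-Mallows = geometric mean of pair precision and recall
    fm = 0.0 if st == 0 or sc == 0 else ss / math.sqrt(st * sc)

    emi = _expected_mi(row, col, n)
    denom = (h_true + h_clust) / 2 - emi
    ami = 1.0 if denom == 0 else (mi - emi) / denom

    return {
        "homogeneity": homogeneity,
        "completeness": completeness,
        "v_measure": v,
        "ari": ari,
        "ami": ami,
        "fowlkes_mallows": fm,
    }


def average_precision_oracle(query_class, ranked, k) -> float:
    """AP by direct enumeration of precision@i at each relevant rank."""
    ranked = list(ranked)[:k]
    relevant_ranks = [i for i, r in enumerate(ranked, start=1) if r == query_class]
    if not relevant_ranks:
        return 0.0
    precisions = []
    for rank in relevant_ranks:
        hits_up_to = sum(1 for r in relevant_ranks if r <= rank)
        precisions.append(hits_up_to / rank)
    return sum(precisions) / len(relevant_ranks)


def hypergeom_tail_oracle(overlap: int, N: int, K: int, n: int) -> float:
    """P(X >= overlap) by exhaustive enumeration of the upper tail."""

    def comb(a, b):
        return math.comb(a, b) if 0 <= b <= a else 0

    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(overlap, min(K, n) + 1)) / total


def bh_oracle(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up q-values by the direct definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, p[i] * m / rank_from_end)
        q[i] = running_min
    return q
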