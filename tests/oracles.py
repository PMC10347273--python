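"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the mathematical definitions with
naive loops, deliberately sharing no code with the package, so that
agreement between the two routes is meaningful.
"""

import numpy as np


def dist(a, b, metric):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if metric == "euclidean":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        return float(1.0 - np.dot(a, b) / (na * nb))
    raise ValueError(metric)


def semi_hard_triplets(X, labels, m, metric):
    """All (a, p, n) with d_ap < d_an < d_ap + m, keeping per (a, p) the
    negative with minimal d_an (lowest index on exact ties)."""
    n = len(labels)
    chosen = set()
    for a in range(n):
        for p in range(n):
            if p == a or labels[p] != labels[a]:
                continue
            d_ap = dist(X[a], X[p], metric)
            best, best_d = None, None
            for neg in range(n):
                if labels[neg] == labels[a]:
                    continue
                d_an = dist(X[a], X[neg], metric)
                if d_ap < d_an < d_ap + m:
                    if best is None or d_an < best_d:
                        best, best_d = neg, d_an
            if best is not None:
                chosen.add((a, p, best))
    return chosen


def knn_vote(X_train, y_train, x, k, metric="euclidean"):
    """Majority label among the k nearest training points; distance ties at
    the boundary resolved by training order; vote ties -> malignant."""
    d = [dist(row, x, metric) for row in X_train]
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
    n_benign = sum(y_train[i] == "benign" for i in order)
    return "benign" if 2 * n_benign > k else "malignant"


def auc_by_pairs(y_true_is_positive, scores):
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, y_true_is_positive) if t]
    neg = [s for s, t in zip(scores, y_true_is_positive) if not t]
    if not pos or not neg:
        raise ValueError("AUC needs both classes")
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
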