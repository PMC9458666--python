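"""Independent brute-force reference implementations.

Everything here is written straight from the defining formulas with plain
Python loops, deliberately sharing no code with the package, so that tests
can compare the two routes. Only suitable for tiny inputs.
"""

from __future__ import annotations

import math

F_SENTINEL = 1e12


# -- weighting ----------------------------------------------------------------

def anova_f(columns, labels):
    """One-way ANOVA F per feature column via explicit variance decomposition."""
    out = []
    n = len(labels)
    classes = sorted(set(labels), key=str)
    c = len(classes)
    for col in columns:
        grand = sum(col) / n
        groups = {cls: [x for x, y in zip(col, labels) if y == cls] for cls in classes}
        ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups.values())
        ss_w = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups.values())
        if ss_w == 0.0:
            out.append(0.0 if ss_b == 0.0 else F_SENTINEL)
        else:
            out.append((ss_b / (c - 1)) / (ss_w / (n - c)))
    return out


def normalize_weights(scores):
    total = sum(scores)
    if total == 0:
        return [1.0 / len(scores)] * len(scores)
    return [s / total for s in scores]


def minmax(train_col, value):
    lo, hi = min(train_col), max(train_col)
    if hi == lo:
        return 0.0
    return min(1.0, max(0.0, (value - lo) / (hi - lo)))


# -- distances / similarities -------------------------------------------------

def hybrid_distance(u_num, v_num, w_num, u_cat, v_cat, w_cat):
    l2sq = sum(w * (a - b) ** 2 for a, b, w in zip(u_num, v_num, w_num))
    l0 = sum(w for a, b, w in zip(u_cat, v_cat, w_cat) if a != b)
    return math.sqrt(l2sq + l0 * l0)


def distance_matrix(rows_num, rows_cat, w_num, w_cat):
    n = len(rows_num)
    return [
        [
            hybrid_distance(rows_num[i], rows_num[j], w_num, rows_cat[i], rows_cat[j], w_cat)
            if i != j else 0.0
            for j in range(n)
        ]
        for i in range(n)
    ]


def similarities(D):
    """(upper-triangular similarity dict keyed by (i, j) with i < j, max)."""
    dmax = max(max(row) for row in D)
    sims = {}
    for i in range(len(D)):
        for j in range(i + 1, len(D)):
            sims[(i, j)] = dmax - D[i][j]
    return sims, dmax


# -- graph model --------------------------------------------------------------

def positive_edges(sims, ids):
    return {frozenset((ids[i], ids[j])): s for (i, j), s in sims.items() if s > 0}


def union_top_k(edges, ids, k):
    """Survivors of either-endpoint top-k pruning (lexicographic tie-break)."""
    keep = set()
    for node in ids:
        incident = [
            (w, min(p - {node})) for p, w in edges.items() if node in p
        ]
        incident.sort(key=lambda t: (-t[0], str(t[1])))
        for w, nbr in incident[:k]:
            keep.add(frozenset((node, nbr)))
    return keep


def fortify(edges, classes, alpha):
    out = {}
    for pair, w in edges.items():
        u, v = tuple(pair)
        same = classes[u] == classes[v]
        out[pair] = w * (1 + alpha) if same else w * (1 - alpha)
    return out


# -- prediction ---------------------------------------------------------------

def test_sims(test_num, test_cat, rows_num, rows_cat, w_num, w_cat, ids, dmax):
    return {
        ids[i]: max(
            0.0,
            dmax - hybrid_distance(test_num, rows_num[i], w_num,
                                   test_cat, rows_cat[i], w_cat),
        )
        for i in range(len(ids))
    }


def class_topk_means(values, classes, k):
    """Per-class mean of the k largest values (node-id tie-break)."""
    out = {}
    for cls in sorted(set(classes.values()), key=str):
        vals = sorted(
            ((v, node) for node, v in values.items() if classes[node] == cls),
            key=lambda t: (-t[0], str(t[1])),
        )[:k]
        out[cls] = sum(v for v, _ in vals) / len(vals) if vals else 0.0
    return out


def relative_margin(scores):
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    top = ranked[0][0]
    if len(ranked) == 1:
        return top, 1.0
    s1, s2 = ranked[0][1], ranked[1][1]
    return top, (0.0 if s1 <= 0 else (s1 - s2) / s1)


def cosine(test_vals, edge_weights, v, ids):
    """Cosine between the test profile and v's neighbourhood profile."""
    others = [n for n in ids if n != v]
    t = [test_vals[n] for n in others]
    w = [edge_weights.get(frozenset((v, n)), 0.0) for n in others]
    nt = math.sqrt(sum(x * x for x in t))
    nw = math.sqrt(sum(x * x for x in w))
    if nt == 0 or nw == 0:
        return 0.0
    return sum(a * b for a, b in zip(t, w)) / (nt * nw)


def argmax_classmean(sims, classes, supports=None):
    """Prediction oracle for the no-pruning, no-fortification limit:
    argmax over classes of the mean clipped similarity to all its nodes."""
    means = {}
    for cls in sorted(set(classes.values()), key=str):
        members = [n for n in classes if classes[n] == cls]
        means[cls] = sum(sims[n] for n in members) / len(members)
    supports = supports or {c: sum(1 for n in classes if classes[n] == c) for c in means}
    return sorted(means.items(), key=lambda kv: (-kv[1], -supports[kv[0]], str(kv[0])))[0][0]


# -- scoring ------------------------------------------------------------------

def weighted_f1(y_true, y_pred):
    """Support-weighted F1 from an explicit confusion count."""
    classes = sorted(set(y_true), key=str)
    n = len(y_true)
    total = 0.0
    for cls in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        support = tp + fn
        if tp == 0:
            f1 = 0.0
        else:
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            f1 = 2 * prec * rec / (prec + rec)
        total += f1 * support / n
    return total
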