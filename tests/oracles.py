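"""Independent brute-force oracles used to validate the implementation.

Everything in this module is deliberately slow and simple: pure-Python
voxel loops, exhaustive flood fills, exponential Shapley enumeration and
hand risk-table survival arithmetic.  Nothing here shares code with the
package under test.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np


# ---------------------------------------------------------------------------
# voxel-loop lesion oracles
# ---------------------------------------------------------------------------


def flood_fill_label(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components by explicit stack-based flood fill."""
    if connectivity == 26:
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (
                    0 <= p[0] < mask.shape[0]
                    and 0 <= p[1] < mask.shape[1]
                    and 0 <= p[2] < mask.shape[2]
                    and mask[p]
                    and not labels[p]
                ):
                    labels[p] = current
                    stack.append(p)
    return labels


def pair_overlaps(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Triple-loop intersection voxel counts for every label pair."""
    counts: dict[tuple[int, int], int] = {}
    for x in range(labels_a.shape[0]):
        for y in range(labels_a.shape[1]):
            for z in range(labels_a.shape[2]):
                la, lb = labels_a[x, y, z], labels_b[x, y, z]
                if la > 0 and lb > 0:
                    counts[(la, lb)] = counts.get((la, lb), 0) + 1
    return counts


def adjudicate_by_loops(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    threshold: float = 0.10,
) -> tuple[dict, dict]:
    """Recompute concordance categories with explicit voxel loops.

    Returns (category_a, category_b) mapping label -> 'concordant' or
    'only', using intersection / min(volume) with a strict threshold.
    """
    sizes_a = {l: int((labels_a == l).sum()) for l in np.unique(labels_a) if l > 0}
    sizes_b = {l: int((labels_b == l).sum()) for l in np.unique(labels_b) if l > 0}
    inter = pair_overlaps(labels_a, labels_b)
    cat_a = {l: "only" for l in sizes_a}
    cat_b = {l: "only" for l in sizes_b}
    for (la, lb), n in inter.items():
        frac = n / min(sizes_a[la], sizes_b[lb])
        if frac > threshold:
            cat_a[la] = "concordant"
            cat_b[lb] = "concordant"
    return cat_a, cat_b


def site_by_loops(labels: np.ndarray, bone: np.ndarray, threshold: float = 0.10) -> dict:
    """Medullary/extramedullary per label by explicit voxel counting."""
    out = {}
    for l in np.unique(labels):
        if l <= 0:
            continue
        sel = labels == l
        frac = (bone[sel] > 0).sum() / sel.sum()
        out[l] = "medullary" if frac >= threshold else "extramedullary"
    return out


def suv_stats_by_loops(labels: np.ndarray, pet: np.ndarray, label: int) -> tuple[float, float]:
    total, peak, n = 0.0, -np.inf, 0
    for x in range(labels.shape[0]):
        for y in range(labels.shape[1]):
            for z in range(labels.shape[2]):
                if labels[x, y, z] == label:
                    v = float(pet[x, y, z])
                    total += v
                    peak = max(peak, v)
                    n += 1
    return total / n, peak


# ---------------------------------------------------------------------------
# survival oracles
# ---------------------------------------------------------------------------


def km_by_hand(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate from a hand-built risk table."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    ev_times = np.unique(times[events])
    surv = []
    s = 1.0
    for t in ev_times:
        n = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1 - d / n
        surv.append(s)
    return ev_times, np.array(surv)


def logrank_by_hand(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square from the explicit risk-set table."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    all_t = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e, var = 0.0, 0.0
    for t in all_t:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = ((ta == t) & ea).sum()
        db = ((tb == t) & eb).sum()
        n, d = na + nb, da + db
        if n < 2:
            continue
        e_a = d * na / n
        o_minus_e += da - e_a
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# ---------------------------------------------------------------------------
# Shapley oracle for single CART trees
# ---------------------------------------------------------------------------


def tree_coalition_value(tree, x: np.ndarray, S: set) -> float:
    """Tree-path conditional expectation given the coalition S of features."""
    t = tree.tree_

    def rec(node):
        if t.children_left[node] == -1:
            v = np.asarray(t.value[node]).ravel()
            return v[1] / v.sum() if len(v) == 2 else float(tree.classes_[0])
        d = t.feature[node]
        left, right = t.children_left[node], t.children_right[node]
        if d in S:
            if np.isnan(x[d]):
                return rec(left if t.missing_go_to_left[node] else right)
            return rec(left if x[d] <= t.threshold[node] else right)
        w = t.weighted_n_node_samples
        return (w[left] * rec(left) + w[right] * rec(right)) / w[node]

    return rec(0)


def brute_force_shapley(tree, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact Shapley values by enumerating all 2^p feature coalitions."""
    p = tree.n_features_in_
    phi = np.zeros(p)
    for i in range(p):
        rest = [f for f in range(p) if f != i]
        for k in range(len(rest) + 1):
            for S in combinations(rest, k):
                w = factorial(k) * factorial(p - k - 1) / factorial(p)
                phi[i] += w * (
                    tree_coalition_value(tree, x, set(S) | {i})
                    - tree_coalition_value(tree, x, set(S))
                )
    return phi, tree_coalition_value(tree, x, set())
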