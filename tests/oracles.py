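"""Independent reference implementations used only as test oracles.

Each function here is deliberately written the slow, obvious way —
scalar loops and exhaustive enumeration — and never shares code with the
package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def welch_t_oracle(a, b) -> tuple[float, float]:
    """Closed-form Welch t statistic and two-sided p via the t survival
    function, computed scalar-by-scalar."""
    from scipy.stats import t as t_dist

    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t_stat = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t_stat), df)
    return t_stat, p


def bh_oracle(p_values) -> list[float]:
    """Step-up BH by direct definition: adj(i) = min over p_(j) >= p_i of
    p_(j) * n / rank(j), monotonicity enforced by explicit min-scan."""
    p = list(map(float, p_values))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj_sorted = [0.0] * n
    running = float("inf")
    for pos in range(n - 1, -1, -1):
        running = min(running, p[order[pos]] * n / (pos + 1))
        adj_sorted[pos] = min(running, 1.0)
    out = [0.0] * n
    for pos, i in enumerate(order):
        out[i] = adj_sorted[pos]
    return out


def gated_fusion_oracle(p_a, p_b, W1, b1, W2, b2):
    """Elementwise scalar-loop evaluation of the gating equations."""
    p_a = np.atleast_2d(np.asarray(p_a, dtype=float))
    p_b = np.atleast_2d(np.asarray(p_b, dtype=float))
    B, F = p_a.shape
    H = W1.shape[1]
    fused = np.zeros((B, F))
    g = np.zeros((B, F))
    for s in range(B):
        z = [p_a[s, i] for i in range(F)] + [p_b[s, i] for i in range(F)]
        hidden = []
        for h in range(H):
            acc = b1[h]
            for i in range(2 * F):
                acc += z[i] * W1[i, h]
            hidden.append(max(acc, 0.0))
        for f in range(F):
            acc = b2[f]
            for h in range(H):
                acc += hidden[h] * W2[h, f]
            g[s, f] = 1.0 / (1.0 + math.exp(-acc))
            fused[s, f] = g[s, f] * p_a[s, f] + (1.0 - g[s, f]) * p_b[s, f]
    return fused, g


def betweenness_oracle(graph) -> dict:
    """Normalized betweenness by exhaustive all-pairs shortest-path
    enumeration (BFS levels + path counting by DFS)."""
    import networkx as nx

    nodes = list(graph.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        total = len(paths)
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / total
    if n > 2:
        norm = 2.0 / ((n - 1) * (n - 2))
        for v in nodes:
            score[v] *= norm
    return score


def auc_rank_oracle(y_true, scores) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly,
    ties counting one half."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hypergeom_tail_oracle(k, M, n, N) -> float:
    """P(X >= k) for a hypergeometric(M, n, N) by direct combinatorial
    summation."""
    total = 0.0
    for i in range(k, min(n, N) + 1):
        total += (math.comb(n, i) * math.comb(M - n, N - i)) / math.comb(M, N)
    return total
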