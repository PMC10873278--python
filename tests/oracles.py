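"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit Python loops and ancestor-chain walks, sharing
no code path with the vectorised implementations they validate.
"""

from __future__ import annotations

import numpy as np


def quadratic_index(p, D) -> float:
    """I = sum_i sum_j d_ij p_i p_j via an explicit O(k^2) double loop."""
    p = np.asarray(p, dtype=float)
    D = np.asarray(D, dtype=float)
    total = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            total += D[i, j] * p[i] * p[j]
    return total


def per_cause_contributions(p, D) -> np.ndarray:
    """C_c = p_c * sum_i d_ci p_i, looped."""
    p = np.asarray(p, dtype=float)
    D = np.asarray(D, dtype=float)
    out = np.zeros(len(p))
    for c in range(len(p)):
        mean_dist = 0.0
        for i in range(len(p)):
            mean_dist += D[c, i] * p[i]
        out[c] = p[c] * mean_dist
    return out


def tree_distance(tree, i: str, j: str) -> float:
    """Walk both ancestor chains upward and find the deepest shared ancestor."""

    def chain(cause):
        node = tree.node(cause)
        ids = [node.id]
        while node.parent_id is not None:
            node = tree.node(node.parent_id)
            ids.append(node.id)
        return ids  # deepest first

    ci, cj = chain(i), chain(j)
    L = tree.depth
    shared_levels = set()
    for depth_i, a in enumerate(ci):
        for depth_j, b in enumerate(cj):
            if a == b:
                shared_levels.add(L - depth_i)
    deepest = max(shared_levels) if shared_levels else 0
    return (L - deepest) / L


def kendall_tau_a(x, y) -> float:
    """Tau over all pairs, no tie correction (valid when inputs are tie-free)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    return (concordant - discordant) / (n * (n - 1) / 2)
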