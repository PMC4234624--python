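"""Independent oracles used by the tests.

Everything here is computed straight from definitions — dense linear
algebra for the walk, explicit loops for the map equation, recursive
enumeration of set partitions — deliberately sharing no code with the
package's implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def stationary_dense(nodes, edges, tau):
    """Stationary distribution of the teleporting walk by dense linear solve."""
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    T = np.zeros((n, n))
    out = {i: [] for i in range(n)}
    for a, b in set(edges):
        if a != b:
            out[idx[a]].append(idx[b])
    for i in range(n):
        if not out[i]:
            T[i, :] = 1.0 / n
        else:
            T[i, :] = tau / n
            for j in out[i]:
                T[i, j] += (1.0 - tau) / len(out[i])
    # solve p = p T with sum(p) = 1
    A = np.vstack([T.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    return nodes, p


def transition_dense(nodes, edges, tau):
    nodes_sorted, _ = stationary_dense(nodes, edges, tau)
    idx = {n: i for i, n in enumerate(nodes_sorted)}
    n = len(nodes_sorted)
    T = np.zeros((n, n))
    out = {i: [] for i in range(n)}
    for a, b in set(edges):
        if a != b:
            out[idx[a]].append(idx[b])
    for i in range(n):
        if not out[i]:
            T[i, :] = 1.0 / n
        else:
            T[i, :] = tau / n
            for j in out[i]:
                T[i, j] += (1.0 - tau) / len(out[i])
    return nodes_sorted, T


def _h(x):
    return x * math.log2(x) if x > 0 else 0.0


def codelength_dense(nodes, edges, tau, mapping):
    """Map-equation value from the definition: exit rates from the dense
    transition matrix, codebook entropies spelled out term by term."""
    nodes_sorted, p = stationary_dense(nodes, edges, tau)
    _, T = transition_dense(nodes, edges, tau)
    idx = {n: i for i, n in enumerate(nodes_sorted)}
    modules = {}
    for node, lab in mapping.items():
        modules.setdefault(lab, []).append(idx[node])
    q = {}
    for lab, members in modules.items():
        inside = set(members)
        q[lab] = sum(p[i] * T[i, j] for i in members for j in range(len(nodes_sorted)) if j not in inside)
    q_tot = sum(q.values())
    L = 0.0
    if q_tot > 0:
        L += q_tot * (-sum(_h(q[lab] / q_tot) for lab in modules))
    for lab, members in modules.items():
        tot = q[lab] + sum(p[i] for i in members)
        if tot <= 0:
            continue
        H = -_h(q[lab] / tot) - sum(_h(p[i] / tot) for i in members)
        L += tot * H
    return L


def set_partitions(items):
    """All partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_min_codelength(nodes, edges, tau):
    best_L, best_partition = math.inf, None
    for blocks in set_partitions(sorted(nodes)):
        mapping = {n: k for k, block in enumerate(blocks) for n in block}
        L = codelength_dense(nodes, edges, tau, mapping)
        if L < best_L - 1e-12:
            best_L, best_partition = L, blocks
    return best_L, best_partition


def modularity_direct(nodes, edges, mapping):
    """Directed modularity as the explicit double sum over ordered node pairs."""
    edges = set(edges)
    E = len(edges)
    nodes = sorted(nodes)
    kout = {n: sum(1 for a, b in edges if a == n) for n in nodes}
    kin = {n: sum(1 for a, b in edges if b == n) for n in nodes}
    Q = 0.0
    for i in nodes:
        for j in nodes:
            if mapping[i] == mapping[j]:
                A = 1.0 if (i, j) in edges else 0.0
                Q += A / E - kout[i] * kin[j] / (E * E)
    return Q


def kl_direct(group_counts, global_probs):
    n = sum(group_counts)
    d = 0.0
    for c, pg in zip(group_counts, global_probs):
        if c > 0:
            d += (c / n) * math.log2((c / n) / pg)
    return d
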