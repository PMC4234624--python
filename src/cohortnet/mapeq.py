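"""Two-level map-equation community detection for directed networks.

The map equation scores a partition M of a digraph by the expected per-step
code length of a two-level (index + per-module) Huffman coding of a
teleporting random walk:

    L(M) = q H(Q) + sum_k (q_k + p_k) H(P_k)

where p_i are stationary visit rates of the walk, q_k is the rate at which
the walker exits module k, q = sum_k q_k, H(Q) is the entropy of the
normalized exit rates and H(P_k) the entropy of module k's codebook (its
nodes' visit rates plus the exit rate, normalized).  All logarithms are
base 2, so L is in bits per step.  A partition with lower L exploits more
regularity in the flow; minimizing L over partitions is the community
detection step.

Walk model: with probability 1-tau the walker follows a uniformly chosen
out-link; with probability tau (or always, from a node without out-links)
it teleports to a node chosen uniformly at random.  Exit/enter rates
include teleportation flow, so a one-module partition has exit rate exactly
zero and L equals the entropy of the visit rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from math import log2

from .io import WeeklyNetwork

__all__ = [
    "Partition",
    "VisitDistribution",
    "CodeLengthReport",
    "visit_frequencies",
    "description_length",
    "detect_communities",
    "modularity",
    "run_stability",
    "RunStability",
]

_EPS = 1e-12


def _plogp(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    mask = x > 0
    out[mask] = x[mask] * np.log2(x[mask])
    return out if out.ndim else float(out)


def _plogp_s(x: float) -> float:
    """Scalar x*log2(x) with 0 log 0 = 0 (hot path of the optimizer)."""
    return x * log2(x) if x > 0.0 else 0.0


class Partition:
    """Disjoint, exhaustive assignment of nodes to communities.

    Labels are canonical: communities are numbered 1..m by decreasing size,
    ties broken by the smallest contained node id.
    """

    __slots__ = ("_mapping",)

    def __init__(self, mapping: Mapping):
        groups: dict = {}
        for node, label in mapping.items():
            groups.setdefault(label, []).append(node)
        ordered = sorted(groups.values(), key=lambda ns: (-len(ns), min(ns)))
        self._mapping = {}
        for new_label, nodes in enumerate(ordered, start=1):
            for node in nodes:
                self._mapping[node] = new_label
        self._mapping = dict(sorted(self._mapping.items()))

    @property
    def mapping(self) -> dict:
        return dict(self._mapping)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._mapping)

    @property
    def n_communities(self) -> int:
        return max(self._mapping.values(), default=0)

    def communities(self) -> dict:
        out: dict = {}
        for node, label in self._mapping.items():
            out.setdefault(label, []).append(node)
        return {label: tuple(sorted(nodes)) for label, nodes in sorted(out.items())}

    def sizes(self) -> dict:
        return {label: len(nodes) for label, nodes in self.communities().items()}

    def label_of(self, node) -> int:
        return self._mapping[node]

    def restrict_to(self, nodes: Iterable) -> "Partition":
        nodes = set(nodes)
        return Partition({n: c for n, c in self._mapping.items() if n in nodes})

    def membership(self) -> tuple:
        """(node, label) pairs in sorted node order; canonical identity."""
        return tuple(self._mapping.items())

    def __eq__(self, other):
        return isinstance(other, Partition) and self._mapping == other._mapping

    def __hash__(self):
        return hash(self.membership())

    def __repr__(self):
        return f"Partition({self.n_communities} communities, {len(self._mapping)} nodes)"

    @classmethod
    def singletons(cls, nodes: Iterable) -> "Partition":
        return cls({n: i for i, n in enumerate(sorted(nodes))})

    @classmethod
    def one_module(cls, nodes: Iterable) -> "Partition":
        return cls({n: 1 for n in nodes})


class _CompiledGraph:
    """Index-based digraph view used by the walk and the optimizer."""

    def __init__(self, net: WeeklyNetwork):
        if not net.nodes:
            raise ValueError("empty network")
        if not net.is_simple():
            raise ValueError("network must be simplified first (no self-loops/duplicates)")
        self.nodes = sorted(net.nodes)
        index = {node: i for i, node in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.out: list = [[] for _ in range(self.n)]
        self.inn: list = [[] for _ in range(self.n)]
        for a, b in sorted(net.edge_set):
            self.out[index[a]].append(index[b])
            self.inn[index[b]].append(index[a])
        self.outdeg = np.array([len(t) for t in self.out], dtype=float)
        self.dangling = self.outdeg == 0
        self.src = np.array([i for i in range(self.n) for _ in self.out[i]], dtype=int)
        self.dst = np.array([j for i in range(self.n) for j in self.out[i]], dtype=int)


@dataclass(frozen=True)
class VisitDistribution:
    """Stationary visit rates of the teleporting walk."""

    nodes: tuple
    p: np.ndarray
    tau: float
    tol: float
    n_iter: int

    def as_dict(self) -> dict:
        return dict(zip(self.nodes, self.p.tolist()))


def visit_frequencies(
    net: WeeklyNetwork, tau: float = 0.15, tol: float = 1e-12, max_iter: int = 10_000
) -> VisitDistribution:
    """Power-iterate the teleporting walk to its stationary distribution.

    Raises RuntimeError with convergence diagnostics if the fixed point is
    not reached within ``max_iter`` iterations (L1 change below ``tol``).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    g = _CompiledGraph(net)
    n = g.n
    p = np.full(n, 1.0 / n)
    follow = np.where(g.dangling, 0.0, 1.0 - tau)
    inv_outdeg = np.where(g.dangling, 0.0, 1.0 / np.maximum(g.outdeg, 1.0))
    for it in range(1, max_iter + 1):
        weight = p * follow * inv_outdeg
        new_p = np.zeros(n)
        np.add.at(new_p, g.dst, weight[g.src])
        teleport_mass = 1.0 - (p * follow).sum()
        new_p += teleport_mass / n
        new_p /= new_p.sum()
        delta = np.abs(new_p - p).sum()
        p = new_p
        if delta < tol:
            return VisitDistribution(nodes=tuple(g.nodes), p=p, tau=tau, tol=tol, n_iter=it)
    raise RuntimeError(
        f"visit frequencies did not converge: n={n}, tau={tau}, tol={tol}, "
        f"max_iter={max_iter}, last L1 change={delta:.3e}"
    )


@dataclass(frozen=True)
class CodeLengthReport:
    """Per-step description length of a partition, split into its terms."""

    total: float  # L(M), bits per step
    index_term: float  # q * H(Q)
    module_terms: dict  # community label -> (q_k + p_k) * H(P_k)
    exit_rates: dict  # community label -> q_k
    q_total: float
    tau: float


def _exit_and_within(g: _CompiledGraph, labels: np.ndarray, p: np.ndarray, tau: float):
    """Exit rate and aggregate visit rate per module (teleportation included)."""
    m = labels.max() + 1
    n = g.n
    size = np.bincount(labels, minlength=m).astype(float)
    p_mod = np.bincount(labels, weights=p, minlength=m)
    p_nondangling = np.bincount(labels, weights=np.where(g.dangling, 0.0, p), minlength=m)
    p_dangl = p_mod - p_nondangling
    teleport = (tau * p_nondangling + p_dangl) * (n - size) / n
    link_w = (1.0 - tau) * p[g.src] / g.outdeg[g.src]
    cross = labels[g.src] != labels[g.dst]
    link_out = np.bincount(labels[g.src], weights=link_w * cross, minlength=m)
    return teleport + link_out, p_mod


def description_length(
    net: WeeklyNetwork,
    partition: Partition,
    visit: VisitDistribution | None = None,
    tau: float = 0.15,
) -> CodeLengthReport:
    """Evaluate the map equation L(M) for a given partition.

    ``visit`` may be precomputed (its tau takes precedence); otherwise the
    stationary distribution is computed here.
    """
    g = _CompiledGraph(net)
    if visit is None:
        visit = visit_frequencies(net, tau=tau)
    else:
        tau = visit.tau
        if tuple(visit.nodes) != tuple(g.nodes):
            raise ValueError("visit distribution does not match the network's node set")
    if partition.nodes != frozenset(g.nodes):
        raise ValueError("partition must cover exactly the network's nodes")
    p = visit.p
    label_by_node = partition.mapping
    labels = np.array([label_by_node[nd] - 1 for nd in g.nodes], dtype=int)
    q_k, p_mod = _exit_and_within(g, labels, p, tau)
    m = len(q_k)
    sum_plogp = np.bincount(labels, weights=_plogp(p), minlength=m)
    module_terms = _plogp(q_k + p_mod) - _plogp(q_k) - sum_plogp
    q = float(q_k.sum())
    index_term = float(_plogp(q) - _plogp(q_k).sum())
    total = float(index_term + module_terms.sum())
    labels_present = sorted(set(label_by_node.values()))
    return CodeLengthReport(
        total=total,
        index_term=index_term,
        module_terms={lab: float(module_terms[lab - 1]) for lab in labels_present},
        exit_rates={lab: float(q_k[lab - 1]) for lab in labels_present},
        q_total=q,
        tau=tau,
    )


class _Optimizer:
    """Greedy map-equation minimizer: node moves plus module merges.

    Maintains per-module aggregates so that a candidate move is evaluated in
    O(degree) time.  The trajectory of L within a run is non-increasing.
    """

    def __init__(self, g: _CompiledGraph, p: np.ndarray, tau: float, rng: np.random.Generator):
        self.g = g
        self.p = p
        self.tau = tau
        self.rng = rng
        n = g.n
        self.mod = np.arange(n)
        self.link_w = np.where(g.dangling, 0.0, (1.0 - tau) * p / np.maximum(g.outdeg, 1.0))
        self.pn = np.where(g.dangling, 0.0, p)  # non-dangling visit mass
        self.pd = np.where(g.dangling, p, 0.0)
        self.plogp_node = _plogp(p)
        # per-module aggregates (arrays indexed by module id; empty slots zero)
        self.size = np.ones(n)
        self.sum_p = p.copy()
        self.sum_pn = self.pn.copy()
        self.sum_pd = self.pd.copy()
        self.sum_plogp = self.plogp_node.copy()
        # link_out[k] = sum_{i in k} link_w[i] * (#targets of i outside k)
        self.link_out = np.array(
            [self.link_w[i] * len(self.g.out[i]) for i in range(n)]
        )  # singletons: every target is outside
        self._recompute_totals()

    # -- bookkeeping ---------------------------------------------------
    def _q_of(self, k: int) -> float:
        if self.size[k] == 0:
            return 0.0
        tele = (self.tau * self.sum_pn[k] + self.sum_pd[k]) * (self.g.n - self.size[k]) / self.g.n
        return tele + self.link_out[k]

    def _module_term(self, k: int, q: float) -> float:
        if self.size[k] == 0:
            return 0.0
        return _plogp_s(q + self.sum_p[k]) - _plogp_s(q) - self.sum_plogp[k]

    def _recompute_totals(self):
        self.q_k = np.array([self._q_of(k) for k in range(self.g.n)])
        self.terms = np.array([self._module_term(k, self.q_k[k]) for k in range(self.g.n)])
        self.S_qlogq = float(_plogp(self.q_k).sum())
        self.q_total = float(self.q_k.sum())

    def codelength(self) -> float:
        index = _plogp_s(self.q_total) - self.S_qlogq
        return index + float(self.terms.sum())

    # -- node moves ----------------------------------------------------
    def _move_stats(self, v: int, a: int, b: int):
        """Aggregates of modules a (minus v) and b (plus v); b == -1 means a
        fresh empty module."""
        g, lw = self.g, self.link_w
        out_v, in_v = g.out[v], g.inn[v]
        cnt_to_a = sum(1 for j in out_v if self.mod[j] == a)
        in_from_a = sum(lw[u] for u in in_v if self.mod[u] == a)
        stats_a = (
            self.size[a] - 1,
            self.sum_p[a] - self.p[v],
            self.sum_pn[a] - self.pn[v],
            self.sum_pd[a] - self.pd[v],
            self.sum_plogp[a] - self.plogp_node[v],
            self.link_out[a] - lw[v] * (len(out_v) - cnt_to_a) + in_from_a,
        )
        if b == -1:
            stats_b = (1.0, self.p[v], self.pn[v], self.pd[v], self.plogp_node[v], lw[v] * len(out_v))
        else:
            cnt_to_b = sum(1 for j in out_v if self.mod[j] == b)
            in_from_b = sum(lw[u] for u in in_v if self.mod[u] == b)
            stats_b = (
                self.size[b] + 1,
                self.sum_p[b] + self.p[v],
                self.sum_pn[b] + self.pn[v],
                self.sum_pd[b] + self.pd[v],
                self.sum_plogp[b] + self.plogp_node[v],
                self.link_out[b] + lw[v] * (len(out_v) - cnt_to_b) - in_from_b,
            )
        return stats_a, stats_b

    @staticmethod
    def _q_term(stats, tau, n):
        size, sum_p, sum_pn, sum_pd, sum_plogp, link_out = stats
        if size == 0:
            return 0.0, 0.0
        q = (tau * sum_pn + sum_pd) * (n - size) / n + link_out
        term = _plogp_s(q + sum_p) - _plogp_s(q) - sum_plogp
        return q, term

    def _delta_for(self, v: int, b: int):
        a = self.mod[v]
        stats_a, stats_b = self._move_stats(v, a, b)
        qa_new, term_a_new = self._q_term(stats_a, self.tau, self.g.n)
        qb_new, term_b_new = self._q_term(stats_b, self.tau, self.g.n)
        qa_old, qb_old = self.q_k[a], (0.0 if b == -1 else self.q_k[b])
        term_a_old = self.terms[a]
        term_b_old = 0.0 if b == -1 else self.terms[b]
        S_new = self.S_qlogq - (_plogp_s(qa_old) + _plogp_s(qb_old)) + (_plogp_s(qa_new) + _plogp_s(qb_new))
        q_new = self.q_total - qa_old - qb_old + qa_new + qb_new
        d_index = (_plogp_s(q_new) - S_new) - (_plogp_s(self.q_total) - self.S_qlogq)
        d_terms = (term_a_new + term_b_new) - (term_a_old + term_b_old)
        return d_index + d_terms, (stats_a, stats_b, qa_new, qb_new, term_a_new, term_b_new)

    def _apply_move(self, v: int, b: int, payload):
        a = self.mod[v]
        stats_a, stats_b, qa_new, qb_new, term_a_new, term_b_new = payload
        if b == -1:
            b = int(np.flatnonzero(self.size == 0)[0])
        for arrs, stats in (((a,), stats_a), ((b,), stats_b)):
            k = arrs[0]
            self.size[k], self.sum_p[k], self.sum_pn[k], self.sum_pd[k], self.sum_plogp[k], self.link_out[k] = stats
        self.S_qlogq += (_plogp_s(qa_new) + _plogp_s(qb_new) - _plogp_s(self.q_k[a]) - _plogp_s(self.q_k[b]))
        self.q_total += qa_new + qb_new - self.q_k[a] - self.q_k[b]
        self.q_k[a], self.q_k[b] = qa_new, qb_new
        self.terms[a], self.terms[b] = term_a_new, term_b_new
        self.mod[v] = b

    def _candidates(self, v: int):
        a = self.mod[v]
        cand = {self.mod[u] for u in self.g.out[v]} | {self.mod[u] for u in self.g.inn[v]}
        occupied = np.flatnonzero(self.size > 0)
        if len(occupied) <= 16:  # exhaustive on small module counts
            cand |= set(occupied.tolist())
        cand.discard(a)
        cand = sorted(int(c) for c in cand)
        if self.size[a] > 1:
            cand.append(-1)  # split off into a fresh singleton
        return cand

    def node_move_pass(self) -> bool:
        improved = False
        for v in self.rng.permutation(self.g.n):
            best_delta, best_b, best_payload = -_EPS, None, None
            for b in self._candidates(int(v)):
                delta, payload = self._delta_for(int(v), b)
                if delta < best_delta:
                    best_delta, best_b, best_payload = delta, b, payload
            if best_b is not None:
                self._apply_move(int(v), best_b, best_payload)
                improved = True
        return improved

    # -- module merges -------------------------------------------------
    def _merge_delta(self, a: int, b: int):
        g, lw = self.g, self.link_w
        cross = 0.0
        for k, other in ((a, b), (b, a)):
            for i in np.flatnonzero(self.mod == k):
                cross += lw[i] * sum(1 for j in g.out[i] if self.mod[j] == other)
        stats = (
            self.size[a] + self.size[b],
            self.sum_p[a] + self.sum_p[b],
            self.sum_pn[a] + self.sum_pn[b],
            self.sum_pd[a] + self.sum_pd[b],
            self.sum_plogp[a] + self.sum_plogp[b],
            self.link_out[a] + self.link_out[b] - cross,
        )
        q_new, term_new = self._q_term(stats, self.tau, g.n)
        S_new = self.S_qlogq - (_plogp_s(self.q_k[a]) + _plogp_s(self.q_k[b])) + _plogp_s(q_new)
        q_tot_new = self.q_total - self.q_k[a] - self.q_k[b] + q_new
        d_index = (_plogp_s(q_tot_new) - S_new) - (_plogp_s(self.q_total) - self.S_qlogq)
        d_terms = term_new - self.terms[a] - self.terms[b]
        return d_index + d_terms, (stats, q_new, term_new)

    def _apply_merge(self, a: int, b: int, payload):
        stats, q_new, term_new = payload
        self.S_qlogq += (_plogp_s(q_new) - _plogp_s(self.q_k[a]) - _plogp_s(self.q_k[b]))
        self.q_total += q_new - self.q_k[a] - self.q_k[b]
        (
            self.size[a],
            self.sum_p[a],
            self.sum_pn[a],
            self.sum_pd[a],
            self.sum_plogp[a],
            self.link_out[a],
        ) = stats
        self.q_k[a], self.terms[a] = q_new, term_new
        self.size[b] = 0
        self.sum_p[b] = self.sum_pn[b] = self.sum_pd[b] = self.sum_plogp[b] = self.link_out[b] = 0.0
        self.q_k[b] = 0.0
        self.terms[b] = 0.0
        self.mod[self.mod == b] = a

    def merge_pass(self) -> bool:
        pairs = set()
        for i in range(self.g.n):
            for j in self.g.out[i]:
                a, b = int(self.mod[i]), int(self.mod[j])
                if a != b:
                    pairs.add((min(a, b), max(a, b)))
        best_delta, best_pair, best_payload = -_EPS, None, None
        for a, b in sorted(pairs):
            delta, payload = self._merge_delta(a, b)
            if delta < best_delta:
                best_delta, best_pair, best_payload = delta, (a, b), payload
        if best_pair is not None:
            self._apply_merge(*best_pair, best_payload)
            return True
        return False

    def run(self) -> np.ndarray:
        while True:
            moved = False
            while self.node_move_pass():
                moved = True
            if self.merge_pass():
                moved = True
                continue
            if not moved:
                break
        return self.mod.copy()


def detect_communities(
    net: WeeklyNetwork,
    tau: float = 0.15,
    n_runs: int = 100,
    seed: int = 0,
    visit: VisitDistribution | None = None,
):
    """Best-of-``n_runs`` greedy minimization of the map equation.

    Each run starts from singletons and alternates randomized node-move
    sweeps with module merges until L stops decreasing; the run order is
    randomized per run but fully determined by ``seed``.  Returns the best
    partition (ties broken by the lexicographically smallest canonical
    labeling) together with its code-length report.
    """
    g = _CompiledGraph(net)
    if visit is None:
        visit = visit_frequencies(net, tau=tau)
    else:
        tau = visit.tau
    best = None
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        opt = _Optimizer(g, visit.p, tau, rng)
        labels = opt.run()
        partition = Partition({g.nodes[i]: int(labels[i]) for i in range(g.n)})
        L = opt.codelength()
        key = (round(L, 12), partition.membership())
        if best is None or key < best[0]:
            best = (key, partition)
    partition = best[1]
    report = description_length(net, partition, visit=visit)
    return partition, report


def modularity(net: WeeklyNetwork, partition: Partition) -> float:
    """Directed modularity Q = (1/E) sum_ij [A_ij - k_i^out k_j^in / E] delta(c_i, c_j)."""
    edges = net.edge_set
    e = len(edges)
    if e == 0:
        raise ValueError("modularity is undefined for a network with no edges")
    if partition.nodes != net.nodes:
        raise ValueError("partition must cover exactly the network's nodes")
    mapping = partition.mapping
    kout: dict = {}
    kin: dict = {}
    within = 0
    for a, b in edges:
        kout[a] = kout.get(a, 0) + 1
        kin[b] = kin.get(b, 0) + 1
        if mapping[a] == mapping[b]:
            within += 1
    expected = 0.0
    by_module_out: dict = {}
    by_module_in: dict = {}
    for node in net.nodes:
        lab = mapping[node]
        by_module_out[lab] = by_module_out.get(lab, 0) + kout.get(node, 0)
        by_module_in[lab] = by_module_in.get(lab, 0) + kin.get(node, 0)
    for lab in by_module_out:
        expected += by_module_out[lab] * by_module_in.get(lab, 0)
    return within / e - expected / (e * e)


@dataclass(frozen=True)
class RunStability:
    """Between-run agreement of the detector on one network."""

    vi_mean: float
    vi_sem: float  # NaN when only one consecutive pair was available
    mean_n_communities: float
    mean_modularity: float
    mean_codelength: float
    n_pairs: int


def run_stability(
    net: WeeklyNetwork,
    tau: float = 0.15,
    n_pairs: int = 10,
    seed: int = 0,
) -> RunStability:
    """Variation of information between consecutive single runs.

    Runs the detector ``n_pairs + 1`` times (one greedy run each, differing
    only in random sweep order) and reports the mean and standard error of
    the VI between consecutive runs, along with mean community count,
    directed modularity and code length over all runs.
    """
    from .compare import variation_of_information

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    visit = visit_frequencies(net, tau=tau)
    results = [
        detect_communities(net, tau=tau, n_runs=1, seed=seed + i, visit=visit)
        for i in range(n_pairs + 1)
    ]
    vis = np.array(
        [variation_of_information(results[i][0], results[i + 1][0]) for i in range(n_pairs)]
    )
    sem = float(vis.std(ddof=1) / np.sqrt(n_pairs)) if n_pairs > 1 else float("nan")
    return RunStability(
        vi_mean=float(vis.mean()),
        vi_sem=sem,
        mean_n_communities=float(np.mean([p.n_communities for p, _ in results])),
        mean_modularity=float(np.mean([modularity(net, p) for p, _ in results])),
        mean_codelength=float(np.mean([r.total for _, r in results])),
        n_pairs=n_pairs,
    )
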