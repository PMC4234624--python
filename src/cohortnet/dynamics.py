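"""Link turnover, link-weight and degree statistics for a weekly network sequence.

Terminology for one week t of an ordered sequence of simple digraphs:

* ``E_tot(t)``  — number of links present in week t;
* ``E_new(t)``  — links absent from week t-1 (turnover w.r.t. the previous
  week only; no memory of earlier weeks);
* ``E_re(t)``   — links present in at least one earlier week s < t
  (re-established links);
* ``f_new(t)``  — fraction of week-t links never seen in any earlier week
  (completely new links).

A link can be new relative to t-1 yet re-established relative to an earlier
week, so E_new and E_re do not partition E_tot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import WeeklyNetwork

__all__ = [
    "link_counts",
    "unique_link_count",
    "saturation_percent",
    "link_weight_distribution",
    "degree_stats",
    "diameter",
    "DegreeStats",
    "LinkWeightDistribution",
]


def link_counts(networks: Sequence) -> pd.DataFrame:
    """Per-week link-turnover summary.

    Returns a DataFrame indexed by week with columns E_tot, E_new, E_re,
    f_new, density, diameter, n_nodes, n_active.  First-week convention:
    E_new = E_tot and E_re = 0 (there is no preceding week to compare with).
    """
    if not networks:
        raise ValueError("need at least one weekly network")
    rows = []
    prev_edges: frozenset = frozenset()
    seen: set = set()
    for idx, net in enumerate(networks):
        edges = net.edge_set
        e_tot = len(edges)
        e_new = e_tot if idx == 0 else len(edges - prev_edges)
        e_re = 0 if idx == 0 else len(edges & seen)
        completely_new = e_tot if idx == 0 else len(edges - seen)
        n = net.n_nodes
        rows.append(
            {
                "week": net.week,
                "E_tot": e_tot,
                "E_new": e_new,
                "E_re": e_re,
                "f_new": completely_new / e_tot if e_tot else np.nan,
                "density": e_tot / (n * (n - 1)) if n > 1 else np.nan,
                "diameter": diameter(net),
                "n_nodes": n,
                "n_active": len(net.active_nodes()),
            }
        )
        prev_edges = edges
        seen |= edges
    return pd.DataFrame(rows).set_index("week")


def unique_link_count(networks: Sequence, n_nodes: int | None = None):
    """Distinct directed links used across all weeks, and the percentage of
    the N(N-1) possible directed links this represents.

    ``n_nodes`` defaults to the size of the union of all weekly node sets.
    """
    all_edges = set()
    all_nodes = set()
    for net in networks:
        all_edges |= net.edge_set
        all_nodes |= net.nodes
    n = len(all_nodes) if n_nodes is None else int(n_nodes)
    return len(all_edges), saturation_percent(len(all_edges), n)


def saturation_percent(n_unique: int, n_nodes: int) -> float:
    """Percentage of the N(N-1) possible directed links that were ever used."""
    if n_nodes < 2:
        raise ValueError("need at least two nodes for a directed link")
    return 100.0 * n_unique / (n_nodes * (n_nodes - 1))


@dataclass(frozen=True)
class LinkWeightDistribution:
    """Accumulated link weights w_ij = number of weeks (up to a given week)
    in which the ordered pair (i, j) occurred."""

    upto_week: int
    weights: dict  # (source, target) -> weeks of occurrence
    histogram: pd.Series  # weight value -> number of links with that weight


def link_weight_distribution(networks: Sequence, upto_week: int | None = None) -> LinkWeightDistribution:
    """Cumulative link-weight distribution: how many pairs named each other
    once, twice, thrice, ... in all weeks up to ``upto_week`` (default: the
    last week, integrating the whole sequence)."""
    weeks = [net.week for net in networks]
    if upto_week is None:
        upto_week = weeks[-1]
    if upto_week not in weeks:
        raise ValueError(f"week {upto_week} not in sequence {weeks}")
    weights: dict = {}
    for net in networks:
        if net.week > upto_week:
            break
        for e in net.edge_set:
            weights[e] = weights.get(e, 0) + 1
    hist = pd.Series(weights, dtype=int).value_counts().sort_index() if weights else pd.Series(dtype=int)
    hist.index.name = "weight"
    return LinkWeightDistribution(upto_week=upto_week, weights=weights, histogram=hist)


@dataclass(frozen=True)
class DegreeStats:
    """Cumulative degree distribution and moment-based summary statistics.

    ``cumulative[k]`` is P(K >= k); ``sd`` is the moment-based standard
    deviation sqrt(<k^2> - <k>^2) and ``sem`` its standard error sd/sqrt(n).
    """

    mode: str
    degrees: np.ndarray
    cumulative: pd.Series
    mean: float
    sd: float
    sem: float

    def moment(self, m: int) -> float:
        return float(np.mean(self.degrees.astype(float) ** m))


def degree_stats(net: WeeklyNetwork, mode: str = "total") -> DegreeStats:
    """Degree distribution statistics for one week (mode: in, out or total)."""
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if mode == "in":
        degs = [d for _, d in g.in_degree()]
    elif mode == "out":
        degs = [d for _, d in g.out_degree()]
    elif mode == "total":
        degs = [d for _, d in g.degree()]
    else:
        raise ValueError(f"mode must be in/out/total, got {mode!r}")
    degs = np.asarray(sorted(degs), dtype=int)
    n = len(degs)
    values, counts = np.unique(degs, return_counts=True)
    pk = counts / n
    cumulative = pd.Series(pk[::-1].cumsum()[::-1], index=values, name="P(K>=k)")
    m1 = float(np.mean(degs))
    m2 = float(np.mean(degs.astype(float) ** 2))
    sd = float(np.sqrt(max(m2 - m1 * m1, 0.0)))
    return DegreeStats(mode=mode, degrees=degs, cumulative=cumulative, mean=m1, sd=sd, sem=sd / np.sqrt(n))


def diameter(net: WeeklyNetwork) -> int:
    """Longest shortest directed path over the reachable ordered pairs.

    Unreachable pairs are ignored, so the value is finite on disconnected
    digraphs; a network with no edges has diameter 0.
    """
    g = net.to_networkx()
    best = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        if dists:
            best = max(best, max(dists.values()))
    return best
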