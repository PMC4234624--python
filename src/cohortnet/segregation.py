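"""Kullback-Leibler segregation of network communities by a node attribute.

For a partition into groups C_1..C_m and a categorical attribute with
global distribution p(a) over the partitioned nodes, each group's
segregation is the KL divergence between its attribute distribution and the
global one,

    D_k = sum_a p_k(a) log2( p_k(a) / p(a) )   [bits],

and the network-level segregation is the size-weighted total
S = sum_k (n_k / n) D_k.  S is 0 when every group mirrors the global
distribution and reaches its maximum, the Shannon entropy of p(a), under
perfect segregation (every group pure).  Significance is assessed with a
permutation null: attribute values are randomly re-assigned to the
partitioned nodes (multiset preserved, partition and network fixed) and the
observed S (or D_k) is standardized against the null mean and standard
deviation to give a Z-score; |Z| > 1.96 is flagged as significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AttributeTable
from .mapeq import Partition

__all__ = [
    "DegenerateNullError",
    "SegregationResult",
    "group_divergence",
    "total_segregation",
    "max_segregation",
    "segregation_zscore",
    "weekly_zscore_series",
    "SIGNIFICANCE_THRESHOLD",
]

SIGNIFICANCE_THRESHOLD = 1.96


class DegenerateNullError(ValueError):
    """The permutation null has zero spread, so a Z-score is undefined
    (e.g. a constant attribute, or a single group covering the network)."""


def _plogp(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    mask = x > 0
    out[mask] = x[mask] * np.log2(x[mask])
    return out


def group_divergence(group_counts, global_dist) -> float:
    """KL divergence (bits) of one group's category counts from the global
    category distribution.

    ``group_counts`` and ``global_dist`` are aligned per-category vectors
    (or mappings with identical keys).  Categories present in the group must
    have positive global probability — guaranteed whenever the group is a
    subset of the network the global distribution was computed from.
    """
    if isinstance(group_counts, Mapping):
        keys = list(group_counts)
        group_counts = np.array([group_counts[k] for k in keys], dtype=float)
        global_dist = np.array([global_dist[k] for k in keys], dtype=float)
    counts = np.asarray(group_counts, dtype=float)
    p_global = np.asarray(global_dist, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("group is empty")
    if not np.isclose(p_global.sum(), 1.0):
        raise ValueError("global distribution must sum to 1")
    if np.any((counts > 0) & (p_global <= 0)):
        raise ValueError("group contains a category with zero global probability; inconsistent inputs")
    p_group = counts / counts.sum()
    mask = p_group > 0
    return float(np.sum(p_group[mask] * np.log2(p_group[mask] / p_global[mask])))


def max_segregation(global_dist) -> float:
    """Shannon entropy (bits) of the global category distribution: the value
    S attains under perfect segregation."""
    if isinstance(global_dist, Mapping):
        global_dist = list(global_dist.values())
    p = np.asarray(global_dist, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("global distribution must sum to 1")
    return float(-_plogp(p).sum())


def _counts_by_group(partition: Partition, attrs: AttributeTable, attribute: str):
    """(group labels, category list, counts matrix, node order) for the
    partitioned nodes."""
    nodes = sorted(partition.nodes)
    if not nodes:
        raise ValueError("empty partition")
    values = attrs.values_for(attribute, nodes)
    vocab = [c for c in attrs.vocabulary(attribute) if c in set(values)]
    cat_index = {c: i for i, c in enumerate(vocab)}
    labels = sorted(partition.communities())
    lab_index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(vocab)), dtype=int)
    group_idx = np.array([lab_index[partition.label_of(n)] for n in nodes])
    value_idx = np.array([cat_index[v] for v in values])
    np.add.at(counts, (group_idx, value_idx), 1)
    return labels, vocab, counts, group_idx, value_idx


def _S_from_counts(counts: np.ndarray, p_global: np.ndarray):
    """Vectorized S and per-group D for one or many (stacked) count matrices.

    ``counts`` has shape (..., G, C); returns (S[...], D[..., G]).
    """
    counts = np.asarray(counts, dtype=float)
    n_k = counts.sum(axis=-1)
    n = n_k.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_group = np.where(n_k[..., None] > 0, counts / np.maximum(n_k[..., None], 1), 0.0)
        ratio = np.where((p_group > 0) & (p_global > 0), p_group / p_global, 1.0)
        d = np.sum(p_group * np.log2(ratio), axis=-1)
    s = np.sum(n_k / n * d, axis=-1)
    return s, d


def total_segregation(partition: Partition, attrs: AttributeTable, attribute: str) -> float:
    """Size-weighted total segregation S (bits) of a partition w.r.t. one
    attribute; the global distribution is computed from the partitioned
    nodes themselves (the students present that week)."""
    _, _, counts, _, _ = _counts_by_group(partition, attrs, attribute)
    p_global = counts.sum(axis=0) / counts.sum()
    s, _ = _S_from_counts(counts, p_global)
    return float(s)


@dataclass(frozen=True)
class SegregationResult:
    """Observed segregation with its permutation null summary."""

    attribute: str
    S: float
    S_max: float
    Z: float
    significant: bool
    n_permutations: int
    seed: int
    groups: pd.DataFrame  # per group: size, D (bits), Z, significant, counts per category
    categories: tuple
    global_dist: np.ndarray


def _null_counts(group_idx, value_idx, n_groups, n_cats, m_perms, rng):
    """Category-count tensors (m_perms, G, C) under random re-assignment of
    the observed attribute multiset to nodes."""
    n = len(value_idx)
    order = np.argsort(rng.random((m_perms, n)), axis=1)
    perm_values = value_idx[order]  # (M, n)
    flat = (
        np.repeat(np.arange(m_perms), n) * (n_groups * n_cats)
        + np.tile(group_idx, m_perms) * n_cats
        + perm_values.ravel()
    )
    counts = np.bincount(flat, minlength=m_perms * n_groups * n_cats)
    return counts.reshape(m_perms, n_groups, n_cats)


def segregation_zscore(
    partition: Partition,
    attrs: AttributeTable,
    attribute: str,
    m_perms: int = 1000,
    seed: int = 0,
    level: str = "network",
) -> SegregationResult:
    """Observed S with a permutation Z-score; optionally per-group Z too.

    ``level`` is "network" (group table carries sizes and divergences only)
    or "per_group" (each group additionally gets its own Z from the same
    null re-assignments).  Raises :class:`DegenerateNullError` when the null
    standard deviation of S is zero.
    """
    if m_perms < 2:
        raise ValueError("m_perms must be >= 2")
    if level not in {"network", "per_group"}:
        raise ValueError("level must be 'network' or 'per_group'")
    labels, vocab, counts, group_idx, value_idx = _counts_by_group(partition, attrs, attribute)
    p_global = counts.sum(axis=0) / counts.sum()
    s_obs, d_obs = _S_from_counts(counts, p_global)
    rng = np.random.default_rng(seed)
    null = _null_counts(group_idx, value_idx, len(labels), len(vocab), m_perms, rng)
    s_null, d_null = _S_from_counts(null, p_global)
    sd = s_null.std(ddof=0)
    if sd == 0:
        raise DegenerateNullError(
            f"permutation null for {attribute!r} has zero spread (S always {s_null[0]:.6g}); "
            "Z-score undefined"
        )
    z = float((s_obs - s_null.mean()) / sd)
    rows = {
        "group": labels,
        "size": counts.sum(axis=1),
        "D": d_obs,
    }
    if level == "per_group":
        gsd = d_null.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            gz = (d_obs - d_null.mean(axis=0)) / gsd
        gz = np.where(gsd > 0, gz, np.nan)
        rows["Z"] = gz
        rows["significant"] = np.abs(np.nan_to_num(gz)) > SIGNIFICANCE_THRESHOLD
    groups = pd.DataFrame(rows).set_index("group")
    for i, cat in enumerate(vocab):
        groups[f"n_{cat}"] = counts[:, i]
    return SegregationResult(
        attribute=attribute,
        S=float(s_obs),
        S_max=max_segregation(p_global),
        Z=z,
        significant=abs(z) > SIGNIFICANCE_THRESHOLD,
        n_permutations=m_perms,
        seed=seed,
        groups=groups,
        categories=tuple(vocab),
        global_dist=p_global,
    )


def weekly_zscore_series(
    networks: Sequence,
    partitions: Sequence,
    attrs: AttributeTable,
    attributes: Sequence = ("gender", "section", "grade"),
    m_perms: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-week segregation Z-scores for several attributes.

    Returns a tidy DataFrame (week, attribute, S, S_max, Z, significant).
    Weeks whose null is degenerate for an attribute get Z = NaN rather than
    aborting the series.
    """
    if len(networks) != len(partitions):
        raise ValueError("networks and partitions must be aligned")
    rows = []
    for net, part in zip(networks, partitions):
        for j, attribute in enumerate(attributes):
            try:
                res = segregation_zscore(
                    part, attrs, attribute, m_perms=m_perms, seed=seed + 1000 * net.week + j
                )
                rows.append(
                    {
                        "week": net.week,
                        "attribute": attribute,
                        "S": res.S,
                        "S_max": res.S_max,
                        "Z": res.Z,
                        "significant": res.significant,
                    }
                )
            except DegenerateNullError:
                rows.append(
                    {
                        "week": net.week,
                        "attribute": attribute,
                        "S": total_segregation(part, attrs, attribute),
                        "S_max": float("nan"),
                        "Z": float("nan"),
                        "significant": False,
                    }
                )
    return pd.DataFrame(rows)
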