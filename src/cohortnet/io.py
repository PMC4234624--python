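"""Reading, validating, simplifying, merging and exporting weekly directed networks.

A weekly network records "who named whom" in one course week: a directed
link runs from the namer to the named student.  Networks are kept as simple
digraphs (no self-loops, no parallel links); raw survey exports may contain
both, so :func:`simplify` is applied before any analysis.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeeklyNetwork",
    "AttributeTable",
    "FormatError",
    "ValidationError",
    "read_edge_lists",
    "write_edge_lists",
    "simplify",
    "merge_weeks",
    "read_attributes",
    "write_attributes",
    "export_network",
    "read_network",
]


class FormatError(ValueError):
    """A delimited-text input does not have the expected layout."""


class ValidationError(ValueError):
    """Input content violates a declared contract (vocabulary, coverage)."""


@dataclass(frozen=True)
class WeeklyNetwork:
    """One course week's directed graph of "A named B" links.

    ``edges`` may contain duplicates and self-loops straight after reading;
    :func:`simplify` returns the cleaned network.  Node identifiers are
    opaque, case-sensitive strings that are consistent across weeks.
    """

    week: int
    nodes: frozenset
    edges: tuple

    @classmethod
    def from_edges(cls, week: int, edges: Iterable, extra_nodes: Iterable = ()) -> "WeeklyNetwork":
        edges = tuple((str(a), str(b)) for a, b in edges)
        nodes = frozenset(str(n) for n in extra_nodes)
        nodes |= {a for a, _ in edges} | {b for _, b in edges}
        return cls(week=int(week), nodes=nodes, edges=edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def active_nodes(self) -> frozenset:
        """Nodes that named at least one *other* student this week."""
        return frozenset(a for a, b in self.edges if a != b)

    def is_simple(self) -> bool:
        return len(self.edges) == len(self.edge_set) and all(a != b for a, b in self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(week=self.week)
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(e for e in self.edges if e[0] != e[1])
        return g


def simplify(net: WeeklyNetwork) -> WeeklyNetwork:
    """Strip self-loops and duplicate ordered pairs; keep the node set.

    Nodes whose only incident link was a self-loop remain as isolates (a
    warning is logged, since such rows usually indicate a survey artifact).
    """
    kept = sorted({(a, b) for a, b in net.edges if a != b})
    touched = {a for a, b in kept} | {b for _, b in kept}
    loop_only = {a for a, b in net.edges if a == b} - touched
    if loop_only:
        logger.warning(
            "week %s: %d node(s) kept as isolates after dropping self-loops: %s",
            net.week, len(loop_only), sorted(loop_only),
        )
    return WeeklyNetwork(week=net.week, nodes=net.nodes, edges=tuple(kept))


def merge_weeks(net1: WeeklyNetwork, net2: WeeklyNetwork, new_label: int) -> WeeklyNetwork:
    """Union of two weeks' links (used to pool sparsely answered early weeks)."""
    merged = WeeklyNetwork(
        week=int(new_label),
        nodes=net1.nodes | net2.nodes,
        edges=net1.edges + net2.edges,
    )
    return simplify(merged)


def read_edge_lists(path, sep: str = ",") -> list:
    """Read a (week, source, target) delimited file into per-week networks.

    Returns one :class:`WeeklyNetwork` per distinct week, in ascending week
    order.  Duplicates and self-loops are retained; apply :func:`simplify`
    before analysis.
    """
    path = Path(path)
    by_week: dict = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        cols = [c.strip().lower() for c in header]
        try:
            iw, is_, it = cols.index("week"), cols.index("source"), cols.index("target")
        except ValueError as exc:
            raise FormatError(f"{path}: header must contain week,source,target (got {header})") from exc
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                week = int(row[iw])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: non-parsable week {row!r}") from exc
            src, tgt = row[is_].strip(), row[it].strip()
            if not src or not tgt:
                raise FormatError(f"{path}:{lineno}: empty node id in {row!r}")
            by_week.setdefault(week, []).append((src, tgt))
    return [WeeklyNetwork.from_edges(w, by_week[w]) for w in sorted(by_week)]


def write_edge_lists(networks: Sequence, path, sep: str = ",") -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["week", "source", "target"])
        for net in networks:
            for a, b in sorted(net.edge_set):
                writer.writerow([net.week, a, b])


@dataclass(frozen=True)
class AttributeTable:
    """Per-student categorical attributes with declared, ordered vocabularies.

    The conventional columns are ``gender`` (2 categories), ``section``
    (the pre-assigned recitation/laboratory group) and ``grade`` (ordered,
    including fail categories), but any categorical columns are accepted.
    """

    data: pd.DataFrame  # index: node id (str); columns: attribute names
    vocabularies: Mapping = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate node ids in attribute table: {dupes}")
        for col in df.columns:
            vocab = self.vocabularies.get(col)
            if vocab is None:
                continue
            if not len(vocab):
                raise ValidationError(f"vocabulary for {col!r} is empty")
            bad = set(df[col].astype(str)) - set(vocab)
            if bad:
                raise ValidationError(f"unknown {col!r} categories {sorted(bad)}; vocabulary is {list(vocab)}")

    @property
    def attributes(self) -> tuple:
        return tuple(self.data.columns)

    def vocabulary(self, attribute: str) -> tuple:
        if attribute in self.vocabularies:
            return tuple(self.vocabularies[attribute])
        return tuple(pd.unique(self.data[attribute].astype(str)))

    def values_for(self, attribute: str, nodes: Iterable) -> pd.Series:
        nodes = list(nodes)
        missing = [n for n in nodes if n not in self.data.index]
        if missing:
            raise ValidationError(f"nodes missing from attribute table: {sorted(missing)[:10]}")
        return self.data.loc[nodes, attribute].astype(str)

    def validate_against(self, net: WeeklyNetwork) -> None:
        missing = sorted(set(net.nodes) - set(self.data.index))
        if missing:
            raise ValidationError(
                f"week {net.week}: {len(missing)} network node(s) missing from attribute table: {missing[:10]}"
            )


DEFAULT_VOCABULARIES = {
    "gender": ("F", "M"),
    # Danish 7-step grading scale; -3 and 00 are fail grades.
    "grade": ("-3", "00", "02", "4", "7", "10", "12"),
}


def read_attributes(path, vocabularies: Mapping | None = None, sep: str = ",") -> AttributeTable:
    """Read an (id, attribute...) CSV into an :class:`AttributeTable`.

    When ``vocabularies`` is None, each column's vocabulary is inferred as
    the sorted set of observed values (declared vocabularies are preferred:
    they catch typos and fix category order for downstream statistics).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "id" not in {c.lower() for c in df.columns}:
        raise FormatError(f"{path}: attribute file must have an 'id' column (got {list(df.columns)})")
    df.columns = [c.lower() for c in df.columns]
    df = df.set_index("id")
    if vocabularies is None:
        vocabularies = {col: tuple(sorted(df[col].astype(str).unique())) for col in df.columns}
    return AttributeTable(data=df, vocabularies=vocabularies)


def write_attributes(table: AttributeTable, path, sep: str = ",") -> None:
    table.data.rename_axis("id").to_csv(path, sep=sep)


def export_network(net: WeeklyNetwork, path, fmt: str = "edgelist") -> None:
    """Export one week as edge-list CSV, GraphML, or Pajek ``.net``."""
    path = Path(path)
    if fmt == "edgelist":
        write_edge_lists([net], path)
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "pajek":
        nx.write_pajek(net.to_networkx(), path)
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def read_network(path, fmt: str = "edgelist", week: int | None = None) -> WeeklyNetwork:
    """Inverse of :func:`export_network` (round-trip fidelity is tested)."""
    path = Path(path)
    if fmt == "edgelist":
        nets = read_edge_lists(path)
        if len(nets) != 1:
            raise FormatError(f"{path}: expected a single-week edge list, found {len(nets)} weeks")
        return simplify(nets[0])
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "pajek":
        g = nx.DiGraph(nx.read_pajek(path))
    else:
        raise ValueError(f"unsupported export format {fmt!r}")
    if week is None:
        week = int(g.graph.get("week", 0))
    return simplify(WeeklyNetwork.from_edges(week, g.edges(), extra_nodes=g.nodes()))
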