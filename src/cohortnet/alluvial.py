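"""Alluvial diagrams of community evolution and within-week flow maps.

The alluvial diagram has one column per week; each box is a community with
height proportional to its student count (a single scale factor for the
whole figure) and a color class recording whether the community is
significantly segregated by gender (green), section (dark red), both
(purple) or neither.  The gray streamlines between adjacent columns carry
the entries of the between-week confusion matrix: a streamline from box k
to box l has thickness proportional to the number of students who were in
community k one week and community l the next.

The flow map summarizes one week's walk dynamics at community level: node
size is the community's accumulated visit rate, arrows the inter-community
probability flow (teleportation included, as in the map-equation
accounting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .compare import confusion_matrix
from .io import WeeklyNetwork
from .mapeq import Partition, VisitDistribution, _CompiledGraph

__all__ = [
    "Box",
    "Streamline",
    "AlluvialDiagram",
    "FlowMap",
    "build_alluvial",
    "streamline_count",
    "aggregate_flow",
    "render_svg",
    "COLOR_CLASSES",
]

#: color classes for segregation significance and their render colors
COLOR_CLASSES = {
    "none": "#bbbbbb",
    "gender": "#2e8b57",
    "section": "#8b0000",
    "both": "#800080",
}


@dataclass(frozen=True)
class Box:
    week: int
    community: int
    size: int
    color_class: str = "none"


@dataclass(frozen=True)
class Streamline:
    week_from: int
    week_to: int
    source: int
    target: int
    count: int


@dataclass(frozen=True)
class AlluvialDiagram:
    weeks: tuple
    boxes: dict  # week -> tuple of Box, ordered by decreasing size
    streamlines: dict  # (week_from, week_to) -> tuple of Streamline
    scale: float  # box height units per student


def _color_class(flags: Mapping | None, week: int, community: int) -> str:
    if flags is None:
        return "none"
    cls = flags.get((week, community), "none")
    if cls not in COLOR_CLASSES:
        raise ValueError(f"unknown color class {cls!r}; expected one of {sorted(COLOR_CLASSES)}")
    return cls


def segregation_color_classes(results_by_week: Mapping) -> dict:
    """Turn per-week gender/section SegregationResults (level='per_group')
    into the alluvial color-class mapping (week, community) -> class."""
    flags: dict = {}
    for week, by_attr in results_by_week.items():
        gender = by_attr.get("gender")
        section = by_attr.get("section")
        communities = set()
        for res in (gender, section):
            if res is not None:
                communities |= set(res.groups.index)
        for c in communities:
            g = bool(gender is not None and gender.groups.loc[c].get("significant", False))
            s = bool(section is not None and section.groups.loc[c].get("significant", False))
            flags[(week, c)] = "both" if (g and s) else "gender" if g else "section" if s else "none"
    return flags


def build_alluvial(
    partitions: Sequence,
    weeks: Sequence | None = None,
    color_flags: Mapping | None = None,
    scale: float = 3.0,
) -> AlluvialDiagram:
    """Assemble the diagram from >= 2 ordered partitions.

    ``color_flags`` maps (week, community) to a color class (see
    :data:`COLOR_CLASSES`); missing entries default to "none".  Adjacent
    partitions must share at least one node, otherwise there is nothing for
    the streamlines to carry.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions for an alluvial diagram")
    if weeks is None:
        weeks = list(range(1, len(partitions) + 1))
    if len(weeks) != len(partitions):
        raise ValueError("weeks and partitions must be aligned")
    boxes: dict = {}
    for week, part in zip(weeks, partitions):
        sizes = part.sizes()
        boxes[week] = tuple(
            Box(week=week, community=c, size=sizes[c], color_class=_color_class(color_flags, week, c))
            for c in sorted(sizes, key=lambda c: (-sizes[c], c))
        )
    streamlines: dict = {}
    for (w1, p1), (w2, p2) in zip(zip(weeks, partitions), list(zip(weeks, partitions))[1:]):
        overlap = p1.nodes & p2.nodes
        if not overlap:
            raise ValueError(f"partitions for weeks {w1} and {w2} share no nodes")
        cm = confusion_matrix(p1, p2)
        lines = [
            Streamline(week_from=w1, week_to=w2, source=int(r), target=int(c), count=int(v))
            for (r, c), v in cm.table.stack().items()
            if v > 0
        ]
        lines.sort(key=lambda s: (-s.count, s.source, s.target))
        streamlines[(w1, w2)] = tuple(lines)
    return AlluvialDiagram(weeks=tuple(weeks), boxes=boxes, streamlines=streamlines, scale=float(scale))


def streamline_count(diagram: AlluvialDiagram, between: tuple) -> int:
    """Number of distinct between-week movements (nonzero confusion entries)."""
    key = tuple(between)
    if key not in diagram.streamlines:
        raise ValueError(f"no streamlines between weeks {between}; have {sorted(diagram.streamlines)}")
    return len(diagram.streamlines[key])


@dataclass(frozen=True)
class FlowMap:
    week: int
    community_rate: dict  # community -> accumulated visit rate
    flows: dict  # (source community, target community), source != target -> flow per step
    color_classes: dict = field(default_factory=dict)


def aggregate_flow(
    net: WeeklyNetwork,
    partition: Partition,
    visit: VisitDistribution,
    color_flags: Mapping | None = None,
) -> FlowMap:
    """Community-level walk flow: accumulated visit rate per community and
    the per-step probability flow between ordered community pairs, with
    teleportation flow included (same accounting as the map equation)."""
    g = _CompiledGraph(net)
    if tuple(visit.nodes) != tuple(g.nodes):
        raise ValueError("visit distribution does not match the network")
    if partition.nodes != net.nodes:
        raise ValueError("partition must cover exactly the network's nodes")
    tau = visit.tau
    p = visit.p
    labels = np.array([partition.label_of(nd) for nd in g.nodes])
    communities = sorted(partition.communities())
    n = g.n
    sizes = {c: int((labels == c).sum()) for c in communities}
    rate = {c: float(p[labels == c].sum()) for c in communities}
    flows: dict = {}
    # teleportation flow: from node i, mass tau (or 1 if dangling) spread 1/n per node
    for c in communities:
        mask = labels == c
        tele_mass = float((np.where(g.dangling, 1.0, tau) * p)[mask].sum())
        for c2 in communities:
            if c2 != c:
                flows[(c, c2)] = tele_mass * sizes[c2] / n
    # link-following flow
    link_w = np.where(g.dangling, 0.0, (1.0 - tau) * p / np.maximum(g.outdeg, 1.0))
    for i in range(n):
        ci = labels[i]
        for j in g.out[i]:
            cj = labels[j]
            if ci != cj:
                flows[(int(ci), int(cj))] += float(link_w[i])
    colors = {}
    for c in communities:
        colors[c] = _color_class(color_flags, net.week, c)
    return FlowMap(week=net.week, community_rate=rate, flows=flows, color_classes=colors)


# ---------------------------------------------------------------------------
# SVG rendering (sole render target: geometry is testable without a display)

_COLUMN_WIDTH = 40.0
_COLUMN_GAP = 160.0
_BOX_GAP = 6.0
_MARGIN = 20.0


def _svg_header(width: float, height: float) -> str:
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.1f}" height="{height:.1f}" '
        f'viewBox="0 0 {width:.1f} {height:.1f}">\n'
    )


def _alluvial_svg(diagram: AlluvialDiagram) -> str:
    scale = diagram.scale
    # box geometry per column
    geo: dict = {}  # (week, community) -> (x, y, h)
    col_heights = []
    for ci, week in enumerate(diagram.weeks):
        x = _MARGIN + ci * (_COLUMN_WIDTH + _COLUMN_GAP)
        y = _MARGIN
        for box in diagram.boxes[week]:
            h = box.size * scale
            geo[(week, box.community)] = (x, y, h)
            y += h + _BOX_GAP
        col_heights.append(y)
    width = 2 * _MARGIN + len(diagram.weeks) * _COLUMN_WIDTH + (len(diagram.weeks) - 1) * _COLUMN_GAP
    height = max(col_heights) + _MARGIN
    parts = [_svg_header(width, height)]
    # streamlines first (under the boxes)
    for (w1, w2), lines in sorted(diagram.streamlines.items()):
        out_off = {box.community: 0.0 for box in diagram.boxes[w1]}
        in_off = {box.community: 0.0 for box in diagram.boxes[w2]}
        for line in lines:
            x1, y1, _ = geo[(w1, line.source)]
            x2, y2, _ = geo[(w2, line.target)]
            t = line.count * scale
            ya = y1 + out_off[line.source]
            yb = y2 + in_off[line.target]
            out_off[line.source] += t
            in_off[line.target] += t
            xa = x1 + _COLUMN_WIDTH
            xm = (xa + x2) / 2.0
            parts.append(
                f'<path d="M {xa:.2f} {ya:.2f} C {xm:.2f} {ya:.2f} {xm:.2f} {yb:.2f} {x2:.2f} {yb:.2f} '
                f"L {x2:.2f} {yb + t:.2f} C {xm:.2f} {yb + t:.2f} {xm:.2f} {ya + t:.2f} {xa:.2f} {ya + t:.2f} Z\" "
                f'fill="#999999" fill-opacity="0.45" data-count="{line.count}" '
                f'data-from="{w1}:{line.source}" data-to="{w2}:{line.target}"/>\n'
            )
    for week in diagram.weeks:
        for box in diagram.boxes[week]:
            x, y, h = geo[(week, box.community)]
            parts.append(
                f'<rect x="{x:.2f}" y="{y:.2f}" width="{_COLUMN_WIDTH:.1f}" height="{h:.2f}" '
                f'fill="{COLOR_CLASSES[box.color_class]}" stroke="black" stroke-width="0.5" '
                f'data-week="{week}" data-community="{box.community}" data-size="{box.size}"/>\n'
            )
            parts.append(
                f'<text x="{x + _COLUMN_WIDTH / 2:.2f}" y="{y + h / 2:.2f}" font-size="8" '
                f'text-anchor="middle" dominant-baseline="middle">G{box.community}</text>\n'
            )
    parts.append("</svg>\n")
    return "".join(parts)


def _flowmap_svg(fm: FlowMap) -> str:
    communities = sorted(fm.community_rate)
    m = len(communities)
    radius = 140.0
    cx0 = cy0 = radius + _MARGIN + 40
    pos = {}
    for i, c in enumerate(communities):
        angle = 2 * np.pi * i / max(m, 1)
        pos[c] = (cx0 + radius * np.cos(angle), cy0 + radius * np.sin(angle))
    size = 2 * (radius + _MARGIN + 40)
    parts = [_svg_header(size, size)]
    max_flow = max(fm.flows.values(), default=0.0)
    for (a, b), flow in sorted(fm.flows.items()):
        if flow <= 0:
            continue
        (xa, ya), (xb, yb) = pos[a], pos[b]
        w = 0.5 + (6.0 * flow / max_flow if max_flow > 0 else 0.0)
        parts.append(
            f'<line x1="{xa:.2f}" y1="{ya:.2f}" x2="{xb:.2f}" y2="{yb:.2f}" stroke="#555555" '
            f'stroke-width="{w:.3f}" data-flow="{flow:.8f}" data-from="{a}" data-to="{b}"/>\n'
        )
    for c in communities:
        x, y = pos[c]
        r = 4.0 + 60.0 * np.sqrt(fm.community_rate[c])
        color = COLOR_CLASSES[fm.color_classes.get(c, "none")]
        parts.append(
            f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{r:.2f}" fill="{color}" fill-opacity="0.8" '
            f'stroke="black" stroke-width="0.5" data-community="{c}" data-rate="{fm.community_rate[c]:.8f}"/>\n'
        )
        parts.append(
            f'<text x="{x:.2f}" y="{y:.2f}" font-size="9" text-anchor="middle" '
            f'dominant-baseline="middle">G{c}</text>\n'
        )
    parts.append("</svg>\n")
    return "".join(parts)


def render_svg(obj, path) -> None:
    """Write an :class:`AlluvialDiagram` or :class:`FlowMap` as SVG.

    Geometry is proportional to the underlying counts/flows and annotated
    with ``data-`` attributes so the numbers can be read back from the file.
    """
    if isinstance(obj, AlluvialDiagram):
        if not obj.boxes or all(not b for b in obj.boxes.values()):
            raise ValueError("cannot render an empty alluvial diagram")
        svg = _alluvial_svg(obj)
    elif isinstance(obj, FlowMap):
        if not obj.community_rate:
            raise ValueError("cannot render an empty flow map")
        svg = _flowmap_svg(obj)
    else:
        raise TypeError(f"cannot render object of type {type(obj).__name__}")
    Path(path).write_text(svg, encoding="utf-8")
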