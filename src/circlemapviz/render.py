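"""Deterministic graph layout and SVG scene assembly.

Nodes are placed by a seeded force-directed (Fruchterman-Reingold) layout
followed by a minimum-distance post-pass so CircleMap glyphs never
overlap.  Edges are drawn rim-to-rim with type-specific terminators —
arrowhead for activation, T-bar for inhibition, dashes for structural
component/member links — and stroke colors that identify the source
network track.  The machine-testable contract is the set of stable CSS
classes: ``node``, ``edge``, ``spoke``, ``segment``, ``legend``.

Determinism contract: identical (graph, glyphs, seed, config) produce a
byte-identical SVG document; all coordinates are emitted with fixed
precision and all collections are iterated in insertion order.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import networkx as nx

from .core import CircleMapGlyph, DEFAULT_MISSING_COLOR
from .errors import ConfigurationError, StateError, VocabularyError
from .model import PathwayGraph

#: First two track colors mirror the purple directed / brown undirected
#: convention for curated regulatory links vs protein-protein interactions;
#: the rest is a fixed categorical palette.
DEFAULT_TRACK_PALETTE = [
    "#800080",  # purple
    "#8b4513",  # brown
    "#1f78b4",
    "#33a02c",
    "#e31a1c",
    "#ff7f00",
    "#6a3d9a",
    "#b15928",
]

_FMT = "%.3f"


def _f(x: float) -> str:
    s = _FMT % x
    return "0.000" if s == "-0.000" else s


@dataclass
class SceneConfig:
    """Geometry and style constants for one scene."""

    inner_radius: float = 14.0  # label disc radius
    ring_thickness: float = 9.0
    missing_color: str = DEFAULT_MISSING_COLOR
    font_family: str = "Helvetica, Arial, sans-serif"
    padding: float = 40.0
    edge_width: float = 2.0
    parallel_offset: float = 5.0
    node_gap: float = 18.0  # extra clearance between glyph rims
    layout_iterations: int = 500
    background: str = "#ffffff"

    def glyph_radius(self, n_rings: int) -> float:
        return self.inner_radius + n_rings * self.ring_thickness


@dataclass
class Layout:
    """Node name -> (x, y) plus the scene extent, in abstract units."""

    positions: dict[str, tuple[float, float]]
    width: float
    height: float

    def __getitem__(self, node: str) -> tuple[float, float]:
        return self.positions[node]

    def __contains__(self, node: str) -> bool:
        return node in self.positions


def _enforce_min_distance(
    pos: dict[str, tuple[float, float]], min_dist: float, rounds: int = 200
) -> dict[str, tuple[float, float]]:
    """Push overlapping node pairs apart until all pairwise distances >= min_dist."""
    names = list(pos)
    xy = {n: list(p) for n, p in pos.items()}
    for _ in range(rounds):
        moved = False
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                dx = xy[b][0] - xy[a][0]
                dy = xy[b][1] - xy[a][1]
                d = math.hypot(dx, dy)
                if d >= min_dist:
                    continue
                moved = True
                if d < 1e-9:
                    # coincident: separate along a direction fixed by name order
                    angle = (hash_free_angle(a, b))
                    dx, dy = math.cos(angle), math.sin(angle)
                    d = 1e-9
                push = (min_dist - d) / 2.0
                ux, uy = dx / d, dy / d
                xy[a][0] -= ux * push
                xy[a][1] -= uy * push
                xy[b][0] += ux * push
                xy[b][1] += uy * push
        if not moved:
            break
    return {n: (p[0], p[1]) for n, p in xy.items()}


def hash_free_angle(a: str, b: str) -> float:
    """Deterministic separation angle for coincident nodes (no PYTHONHASHSEED)."""
    acc = 0
    for ch in a + "|" + b:
        acc = (acc * 31 + ord(ch)) % 360
    return math.radians(acc)


def layout_graph(
    graph: PathwayGraph, seed: int, config: SceneConfig | None = None
) -> Layout:
    """Seeded force-directed placement with non-overlap guarantee.

    Runs a Fruchterman-Reingold layout for a fixed iteration budget from a
    seed-determined start, scales to scene units, then enforces a minimum
    pairwise distance of one glyph diameter plus clearance.  Identical
    (graph, seed, config) give identical coordinates.
    """
    config = config or SceneConfig()
    if graph.n_nodes == 0:
        raise ConfigurationError("cannot lay out an empty graph")
    diameter = 2 * config.glyph_radius(_max_rings_hint(graph)) + config.node_gap

    names = sorted(graph.nodes)
    if len(names) == 1:
        half = diameter / 2 + config.padding
        return Layout({names[0]: (half, half)}, 2 * half, 2 * half)

    g = nx.Graph()
    g.add_nodes_from(names)
    for e in graph.edges:
        if e.source != e.target:
            g.add_edge(e.source, e.target)
    span = diameter * max(2.0, math.sqrt(len(names)) * 1.6)
    pos = nx.spring_layout(
        g, seed=seed, iterations=config.layout_iterations, scale=span / 2
    )
    flat = {n: (float(p[0]), float(p[1])) for n, p in sorted(pos.items())}
    # small slack so coordinate rounding cannot drop pairs below the diameter
    flat = _enforce_min_distance(flat, diameter + 0.01)

    xs = [p[0] for p in flat.values()]
    ys = [p[1] for p in flat.values()]
    margin = diameter / 2 + config.padding
    shift_x = margin - min(xs)
    shift_y = margin - min(ys)
    positions = {
        n: (round(x + shift_x, 3), round(y + shift_y, 3)) for n, (x, y) in flat.items()
    }
    width = round(max(xs) - min(xs) + 2 * margin, 3)
    height = round(max(ys) - min(ys) + 2 * margin, 3)
    return Layout(positions, width, height)


def _max_rings_hint(graph: PathwayGraph) -> int:
    # glyph ring count is supplied at scene assembly; layout uses a fixed
    # conservative 4-ring footprint so spacing does not depend on data
    return 4


# ---------------------------------------------------------------------------
# geometry helpers


def _polar(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    """Point at clockwise angle from 12 o'clock (SVG y grows downward)."""
    rad = math.radians(angle_deg)
    return (cx + r * math.sin(rad), cy - r * math.cos(rad))


def _sector_path(
    cx: float, cy: float, r0: float, r1: float, start: float, extent: float
) -> str:
    """SVG path for an annular sector; full-turn cells become a two-arc donut."""
    if extent >= 360.0 - 1e-9:
        halves = []
        for s in (start, start + 180.0):
            x0o, y0o = _polar(cx, cy, r1, s)
            x1o, y1o = _polar(cx, cy, r1, s + 180.0)
            x0i, y0i = _polar(cx, cy, r0, s + 180.0)
            x1i, y1i = _polar(cx, cy, r0, s)
            halves.append(
                f"M {_f(x0o)} {_f(y0o)} A {_f(r1)} {_f(r1)} 0 0 1 {_f(x1o)} {_f(y1o)} "
                f"L {_f(x0i)} {_f(y0i)} A {_f(r0)} {_f(r0)} 0 0 0 {_f(x1i)} {_f(y1i)} Z"
            )
        return " ".join(halves)
    end = start + extent
    large = 1 if extent > 180.0 else 0
    x0i, y0i = _polar(cx, cy, r0, start)
    x0o, y0o = _polar(cx, cy, r1, start)
    x1o, y1o = _polar(cx, cy, r1, end)
    x1i, y1i = _polar(cx, cy, r0, end)
    return (
        f"M {_f(x0i)} {_f(y0i)} L {_f(x0o)} {_f(y0o)} "
        f"A {_f(r1)} {_f(r1)} 0 {large} 1 {_f(x1o)} {_f(y1o)} "
        f"L {_f(x1i)} {_f(y1i)} "
        f"A {_f(r0)} {_f(r0)} 0 {large} 0 {_f(x0i)} {_f(y0i)} Z"
    )


# ---------------------------------------------------------------------------
# element builders


def _marker_id(kind: str, color: str) -> str:
    return f"{kind}-{color.lstrip('#')}"


def _build_markers(parent: ET.Element, colors: list[str]) -> None:
    defs = ET.SubElement(parent, "defs")
    for color in colors:
        arrow = ET.SubElement(
            defs,
            "marker",
            {
                "id": _marker_id("arrow", color),
                "markerWidth": "10",
                "markerHeight": "8",
                "refX": "9",
                "refY": "4",
                "orient": "auto",
                "markerUnits": "userSpaceOnUse",
            },
        )
        ET.SubElement(
            arrow, "path", {"d": "M 0 0 L 10 4 L 0 8 Z", "fill": color}
        )
        tbar = ET.SubElement(
            defs,
            "marker",
            {
                "id": _marker_id("tbar", color),
                "markerWidth": "4",
                "markerHeight": "12",
                "refX": "3",
                "refY": "6",
                "orient": "auto",
                "markerUnits": "userSpaceOnUse",
            },
        )
        ET.SubElement(
            tbar,
            "rect",
            {"x": "1", "y": "0", "width": "2", "height": "12", "fill": color},
        )


def render_edge(
    edge,
    layout: Layout,
    track_colors: dict[str, str],
    config: SceneConfig | None = None,
    offset_index: int = 0,
    n_parallel: int = 1,
    rim_radius: float | None = None,
) -> ET.Element:
    """One edge as a ``<g class="edge">`` fragment.

    Activation ends in an arrowhead, inhibition in a T-bar; component and
    member links are dashed; plain undirected links have no terminator.
    Parallel edges between one pair are offset perpendicular to the
    connecting line so none coincides.  Self-edges render as a small loop.
    """
    config = config or SceneConfig()
    if edge.edge_type not in ("activates", "inhibits", "component", "member", "undirected"):
        raise VocabularyError(f"unknown edge type {edge.edge_type!r}")
    color = track_colors.get(edge.track, "#555555")
    rim = rim_radius if rim_radius is not None else config.glyph_radius(1)
    group = ET.Element(
        "g", {"class": "edge", "data-track": edge.track, "data-type": edge.edge_type}
    )
    attrs = {
        "stroke": color,
        "stroke-width": _f(config.edge_width),
        "fill": "none",
    }
    if edge.edge_type in ("component", "member"):
        attrs["stroke-dasharray"] = "6 3"

    x0, y0 = layout[edge.source]
    x1, y1 = layout[edge.target]
    if edge.source == edge.target:
        # loop: small circle tangent to the rim at 45 degrees
        lx, ly = x0 + rim * 0.85, y0 - rim * 0.85
        loop = ET.SubElement(
            group, "circle",
            {"cx": _f(lx), "cy": _f(ly), "r": _f(rim * 0.5), **attrs},
        )
        _attach_terminator(loop, edge.edge_type, color)
        return group

    dx, dy = x1 - x0, y1 - y0
    dist = math.hypot(dx, dy) or 1e-9
    ux, uy = dx / dist, dy / dist
    # perpendicular offset for parallel edges
    shift = (offset_index - (n_parallel - 1) / 2.0) * config.parallel_offset
    px, py = -uy * shift, ux * shift
    sx, sy = x0 + ux * rim + px, y0 + uy * rim + py
    ex, ey = x1 - ux * rim + px, y1 - uy * rim + py
    line = ET.SubElement(
        group,
        "line",
        {"x1": _f(sx), "y1": _f(sy), "x2": _f(ex), "y2": _f(ey), **attrs},
    )
    _attach_terminator(line, edge.edge_type, color)
    return group


def _attach_terminator(el: ET.Element, edge_type: str, color: str) -> None:
    if edge_type == "activates":
        el.set("marker-end", f"url(#{_marker_id('arrow', color)})")
    elif edge_type == "inhibits":
        el.set("marker-end", f"url(#{_marker_id('tbar', color)})")


_ENTITY_SHAPES = {
    "complex": "hexagon",
    "family": "double-rect",
    "smallmolecule": "circle",
    "process": "rect",
}


def render_node(
    node: str,
    entity_type: str,
    glyph: CircleMapGlyph | None,
    layout: Layout,
    config: SceneConfig | None = None,
) -> ET.Element:
    """One node as a ``<g class="node">`` fragment.

    Nodes with data become CircleMap glyphs: one filled annular-sector
    path per cell (class ``spoke`` in full mode, ``segment`` in
    aggregated mode), rings drawn inner to outer, gene label centered in
    the inner disc.  Nodes without data get an entity-type-specific plain
    shape with a label.
    """
    config = config or SceneConfig()
    cx, cy = layout[node]
    group = ET.Element(
        "g", {"class": "node", "data-name": node, "data-entity": entity_type}
    )
    if glyph is not None:
        cell_class = "spoke" if glyph.mode == "full" else "segment"
        for ring_idx, cells in enumerate(glyph.cells):
            r0 = config.inner_radius + ring_idx * config.ring_thickness
            r1 = r0 + config.ring_thickness
            for cell in cells:
                ET.SubElement(
                    group,
                    "path",
                    {
                        "class": cell_class,
                        "d": _sector_path(cx, cy, r0, r1, cell.start, cell.extent),
                        "fill": cell.color,
                        "stroke": "#ffffff",
                        "stroke-width": "0.3",
                        "data-key": cell.key,
                    },
                )
        ET.SubElement(
            group,
            "circle",
            {
                "cx": _f(cx),
                "cy": _f(cy),
                "r": _f(config.inner_radius),
                "fill": "#ffffff",
                "stroke": "#333333",
                "stroke-width": "0.8",
            },
        )
        font = max(6.0, min(11.0, config.inner_radius * 0.45 + 2))
    else:
        _plain_shape(group, entity_type, cx, cy, config)
        font = 10.0
    label = ET.SubElement(
        group,
        "text",
        {
            "x": _f(cx),
            "y": _f(cy),
            "text-anchor": "middle",
            "dominant-baseline": "central",
            "font-family": config.font_family,
            "font-size": _f(font),
            "fill": "#111111",
        },
    )
    label.text = node
    return group


def _plain_shape(
    group: ET.Element, entity_type: str, cx: float, cy: float, config: SceneConfig
) -> None:
    r = config.inner_radius * 1.4
    shape = _ENTITY_SHAPES.get(entity_type, "circle")
    style = {"fill": "#efefef", "stroke": "#333333", "stroke-width": "1"}
    if shape == "hexagon":
        pts = " ".join(
            f"{_f(cx + r * math.cos(math.radians(60 * i - 30)))},"
            f"{_f(cy + r * math.sin(math.radians(60 * i - 30)))}"
            for i in range(6)
        )
        ET.SubElement(group, "polygon", {"points": pts, **style})
    elif shape == "double-rect":
        for inset in (0.0, 4.0):
            ET.SubElement(
                group,
                "rect",
                {
                    "x": _f(cx - r + inset),
                    "y": _f(cy - r * 0.7 + inset),
                    "width": _f(2 * r - 2 * inset),
                    "height": _f(1.4 * r - 2 * inset),
                    **style,
                },
            )
    elif shape == "rect":
        ET.SubElement(
            group,
            "rect",
            {
                "x": _f(cx - r),
                "y": _f(cy - r * 0.6),
                "width": _f(2 * r),
                "height": _f(1.2 * r),
                "rx": "4",
                **style,
            },
        )
    else:
        ET.SubElement(
            group, "circle", {"cx": _f(cx), "cy": _f(cy), "r": _f(r), **style}
        )


# ---------------------------------------------------------------------------
# scene


@dataclass
class Scene:
    """A fully specified picture: graph, glyphs, layout, colors, legend."""

    graph: PathwayGraph
    glyphs: dict[str, CircleMapGlyph]
    layout: Layout | None
    track_colors: dict[str, str]
    config: SceneConfig = field(default_factory=SceneConfig)

    def validate(self) -> None:
        for gene in self.glyphs:
            if gene not in self.graph.nodes:
                raise ConfigurationError(
                    f"glyph for {gene!r} has no corresponding graph node"
                )
        for e in self.graph.edges:
            if e.track not in self.track_colors:
                raise ConfigurationError(f"track {e.track!r} has no display color")

    def to_svg_element(self) -> ET.Element:
        """Build the SVG element tree: defs, edges, nodes, legend, in order."""
        if self.layout is None:
            raise StateError("scene is not laid out")
        self.validate()
        cfg = self.config
        legend_width = 190.0
        width = self.layout.width + legend_width
        height = max(self.layout.height, 160.0)
        root = ET.Element(
            "svg",
            {
                "xmlns": "http://www.w3.org/2000/svg",
                "version": "1.1",
                "width": _f(width),
                "height": _f(height),
                "viewBox": f"0 0 {_f(width)} {_f(height)}",
            },
        )
        ET.SubElement(
            root,
            "rect",
            {"x": "0", "y": "0", "width": _f(width), "height": _f(height),
             "fill": cfg.background},
        )
        colors = sorted(set(self.track_colors.values()) | {"#555555"})
        _build_markers(root, colors)

        max_rings = max((g.n_rings for g in self.glyphs.values()), default=1)
        rim = cfg.glyph_radius(max_rings)

        # edges under nodes; parallel edges per unordered pair get offsets
        groups: dict[tuple[str, str], list[int]] = {}
        for idx, e in enumerate(self.graph.edges):
            groups.setdefault(e.pair(), []).append(idx)
        edge_layer = ET.SubElement(root, "g", {"id": "edges"})
        for pair_indices in groups.values():
            k = len(pair_indices)
            for j, idx in enumerate(pair_indices):
                e = self.graph.edges[idx]
                edge_layer.append(
                    render_edge(
                        e, self.layout, self.track_colors, cfg,
                        offset_index=j, n_parallel=k, rim_radius=rim,
                    )
                )

        node_layer = ET.SubElement(root, "g", {"id": "nodes"})
        for node, entity_type in self.graph.nodes.items():
            node_layer.append(
                render_node(node, entity_type, self.glyphs.get(node), self.layout, cfg)
            )

        root.append(self._legend(width - legend_width + 14.0, 24.0))
        return root

    def _legend(self, x: float, y: float) -> ET.Element:
        """Legend block: ring order (inner to outer) then track colors."""
        cfg = self.config
        legend = ET.Element("g", {"class": "legend"})
        line_h = 18.0

        def _text(tx: float, ty: float, s: str, bold: bool = False) -> None:
            el = ET.SubElement(
                legend,
                "text",
                {
                    "x": _f(tx),
                    "y": _f(ty),
                    "font-family": cfg.font_family,
                    "font-size": "11",
                    "fill": "#111111",
                    **({"font-weight": "bold"} if bold else {}),
                },
            )
            el.text = s

        _text(x, y, "Rings (inner to outer)", bold=True)
        y += line_h
        ring_specs = []
        for glyph in self.glyphs.values():
            ring_specs = glyph.rings
            break
        for spec in ring_specs:
            scale = spec.scale()
            swatch_color = (
                scale.high_color
                if scale.kind == "continuous"
                else next(iter(scale.categories.values()), "#404040")
            )
            ET.SubElement(
                legend,
                "rect",
                {
                    "x": _f(x),
                    "y": _f(y - 9),
                    "width": "12",
                    "height": "12",
                    "fill": swatch_color,
                    "stroke": "#333333",
                    "stroke-width": "0.5",
                },
            )
            _text(x + 18, y, f"{spec.position}: {spec.matrix.platform_label}")
            y += line_h
        y += 6
        _text(x, y, "Network tracks", bold=True)
        y += line_h
        for track, color in self.track_colors.items():
            ET.SubElement(
                legend,
                "line",
                {
                    "x1": _f(x),
                    "y1": _f(y - 4),
                    "x2": _f(x + 14),
                    "y2": _f(y - 4),
                    "stroke": color,
                    "stroke-width": "3",
                },
            )
            _text(x + 20, y, track or "(display)")
            y += line_h
        return legend


def assemble_scene(
    graph: PathwayGraph,
    glyphs: dict[str, CircleMapGlyph],
    layout: Layout,
    track_colors: dict[str, str],
    config: SceneConfig | None = None,
) -> Scene:
    """Bundle graph + glyphs + layout into a validated Scene."""
    scene = Scene(graph, glyphs, layout, dict(track_colors), config or SceneConfig())
    scene.validate()
    return scene


def track_palette(track_names: list[str]) -> dict[str, str]:
    """Assign the default palette to an ordered list of track names."""
    return {
        name: DEFAULT_TRACK_PALETTE[i % len(DEFAULT_TRACK_PALETTE)]
        for i, name in enumerate(track_names)
    }
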