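"""Layout determinism, edge/node glyph structure, scene combinatorics."""

import math

import pytest
from lxml import etree

from circlemapviz import (
    GroupPartition,
    PathwayGraph,
    RingSpec,
    SampleOrder,
    Scene,
    SceneConfig,
    assemble_scene,
    build_glyph,
    layout_graph,
    render_edge,
    render_node,
    svg_bytes,
)
from circlemapviz.errors import ConfigurationError
from circlemapviz.fixtures import random_graph, random_matrix
from circlemapviz.model import Edge


def glyph_diameter(config=None):
    config = config or SceneConfig()
    return 2 * config.glyph_radius(4) + config.node_gap


class TestLayout:
    def test_empty_graph_rejected(self):
        with pytest.raises(ConfigurationError):
            layout_graph(PathwayGraph(), seed=0)

    def test_single_node_centered(self):
        layout = layout_graph(PathwayGraph({"A": "protein"}), seed=0)
        x, y = layout["A"]
        assert x == pytest.approx(layout.width / 2)
        assert y == pytest.approx(layout.height / 2)

    def test_same_seed_identical_coordinates(self):
        g = random_graph(10, 15, seed=4)
        l1 = layout_graph(g, seed=9)
        l2 = layout_graph(g, seed=9)
        assert l1.positions == l2.positions

    def test_different_seeds_differ(self):
        g = random_graph(10, 15, seed=4)
        assert layout_graph(g, seed=1).positions != layout_graph(g, seed=2).positions

    def test_min_pairwise_distance(self):
        g = random_graph(15, 30, seed=2)
        layout = layout_graph(g, seed=5)
        pts = list(layout.positions.values())
        min_d = glyph_diameter()
        for i, (x0, y0) in enumerate(pts):
            for x1, y1 in pts[i + 1:]:
                assert math.hypot(x1 - x0, y1 - y0) >= min_d - 1e-6


class TestRenderEdge:
    layout = type("L", (), {"__getitem__": lambda self, n: {"A": (0.0, 0.0),
                                                            "B": (200.0, 0.0)}[n]})()
    colors = {"t": "#800080"}

    def _frag(self, edge_type):
        frag = render_edge(Edge("A", "B", edge_type, "t"), self.layout, self.colors)
        return etree.tostring(
            etree.fromstring(etree.tostring(self._to_lxml(frag)))
        ).decode()

    @staticmethod
    def _to_lxml(el):
        import xml.etree.ElementTree as ET

        return etree.fromstring(ET.tostring(el))

    def test_inhibits_has_tbar_not_arrow(self):
        s = self._frag("inhibits")
        assert "tbar-" in s and "arrow-" not in s

    def test_activates_has_arrowhead(self):
        s = self._frag("activates")
        assert "arrow-" in s and "tbar-" not in s

    def test_structural_edges_dashed_plain(self):
        for et_ in ("component", "member"):
            s = self._frag(et_)
            assert "stroke-dasharray" in s and "marker-end" not in s
        s = self._frag("undirected")
        assert "stroke-dasharray" not in s and "marker-end" not in s

    def test_edge_starts_at_rim_not_center(self):
        frag = render_edge(Edge("A", "B", "undirected", "t"), self.layout,
                           self.colors, rim_radius=50.0)
        line = frag.find("line")
        assert float(line.get("x1")) == pytest.approx(50.0)
        assert float(line.get("x2")) == pytest.approx(150.0)

    def test_parallel_edges_distinct_paths_and_colors(self):
        colors = {"t1": "#111111", "t2": "#222222"}
        f1 = render_edge(Edge("A", "B", "undirected", "t1"), self.layout, colors,
                         offset_index=0, n_parallel=2)
        f2 = render_edge(Edge("A", "B", "undirected", "t2"), self.layout, colors,
                         offset_index=1, n_parallel=2)
        l1, l2 = f1.find("line"), f2.find("line")
        assert l1.get("stroke") != l2.get("stroke")
        assert (l1.get("y1"), l1.get("y2")) != (l2.get("y1"), l2.get("y2"))


class TestRenderNode:
    layout = type("L", (), {"__getitem__": lambda self, n: (100.0, 100.0)})()

    def test_full_glyph_sector_count(self):
        m = random_matrix(2, 10, seed=0)
        glyph = build_glyph("G000",
                            [RingSpec(m, 0), RingSpec(random_matrix(2, 10, seed=1,
                                                                    platform_label="r2"), 1)],
                            order=SampleOrder(m.samples))
        frag = render_node("G000", "protein", glyph, self.layout)
        assert len(frag.findall("path[@class='spoke']")) == 20

    def test_complex_without_glyph_is_plain_shape(self):
        frag = render_node("CPLX", "complex", None, self.layout)
        assert len(frag.findall("path")) == 0
        assert len(frag.findall("polygon")) == 1

    def test_aggregated_extents_proportional(self):
        m = random_matrix(1, 4, seed=0)
        p = GroupPartition([("big", m.samples[:3]), ("small", m.samples[3:])])
        glyph = build_glyph("G000", [RingSpec(m, 0)], partition=p)
        (big, small) = glyph.cells[0]
        assert big.extent == pytest.approx(270.0)
        assert small.extent == pytest.approx(90.0)
        frag = render_node("G000", "protein", glyph, self.layout)
        assert len(frag.findall("path[@class='segment']")) == 2


class TestAssembleScene:
    def _toy_scene(self):
        g = PathwayGraph()
        g.add_node("A"), g.add_node("B")
        g.add_edge("A", "B", "inhibits", "bg")
        m = random_matrix(2, 6, seed=0)
        m.data.index = ["A", "B"]
        rings = [RingSpec(m, 0)]
        order = SampleOrder(m.samples)
        glyphs = {n: build_glyph(n, rings, order=order) for n in ("A", "B")}
        layout = layout_graph(g, seed=2)
        return assemble_scene(g, glyphs, layout, {"bg": "#800080"})

    def test_group_counts_and_legend(self):
        root = etree.fromstring(svg_bytes(self._toy_scene()))
        assert len(root.findall(".//*[@class='node']")) == 2
        assert len(root.findall(".//*[@class='edge']")) == 1
        assert len(root.findall(".//*[@class='legend']")) == 1

    def test_legend_lists_rings_in_position_order(self):
        scene = self._toy_scene()
        root = etree.fromstring(svg_bytes(scene))
        ns = "{http://www.w3.org/2000/svg}"
        legend = root.find(f".//{ns}g[@class='legend']")
        texts = [t.text for t in legend.findall(f"{ns}text")]
        ring_lines = [t for t in texts if t and t[0].isdigit()]
        assert ring_lines == ["0: random"]

    def test_glyph_for_missing_node_rejected(self):
        g = PathwayGraph({"A": "protein"})
        m = random_matrix(1, 3, seed=0)
        glyph = build_glyph("G000", [RingSpec(m, 0)],
                            order=SampleOrder(m.samples))
        layout = layout_graph(g, seed=0)
        with pytest.raises(ConfigurationError):
            assemble_scene(g, {"G000": glyph}, layout, {})

    def test_sector_count_formula_over_random_scene(self):
        g = random_graph(5, 8, seed=3)
        m1 = random_matrix(5, 7, seed=1, platform_label="p1")
        m2 = random_matrix(5, 7, seed=2, platform_label="p2")
        rings = [RingSpec(m1, 0), RingSpec(m2, 1)]
        order = SampleOrder(m1.samples)
        glyphs = {n: build_glyph(n, rings, order=order)
                  for n in list(g.nodes)[:4] if n in m1 or n in m2}
        # gene names in matrices are G000.. while nodes are N000..: attach data
        m1.data.index = list(g.nodes)[:5]
        m2.data.index = list(g.nodes)[:5]
        glyphs = {n: build_glyph(n, rings, order=order) for n in list(g.nodes)[:4]}
        layout = layout_graph(g, seed=0)
        scene = assemble_scene(g, glyphs, layout, {"": "#800080"})
        root = etree.fromstring(svg_bytes(scene))
        expected = sum(gl.n_rings * gl.n_cells for gl in glyphs.values())
        assert len(root.findall(".//*[@class='spoke']")) == expected
        assert len(root.findall(".//*[@class='edge']")) == g.n_edges

    def test_byte_determinism_full_scene(self):
        assert svg_bytes(self._toy_scene()) == svg_bytes(self._toy_scene())
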