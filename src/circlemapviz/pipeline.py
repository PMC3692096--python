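"""End-to-end render pipeline shared by the CLI and the HTTP service.

One function, :func:`render_svg_bytes`, takes already-loaded inputs plus
view settings and produces the final SVG bytes, so a command-line run
and a GET request with equivalent parameters are bit-identical by
construction.  :class:`RenderConfig` describes a full run including the
file paths; :func:`load_inputs` materializes it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cio
from .core import (
    GroupPartition,
    RingSpec,
    SampleOrder,
    SortKey,
    build_glyph,
    partition_samples,
    sample_universe,
    sort_samples,
)
from .errors import ConfigurationError
from .model import GeneSet, OmicsMatrix, PathwayGraph, SampleAnnotation, TrackSet
from .network import extract_subnetwork, overlay_tracks
from .render import SceneConfig, assemble_scene, layout_graph, track_palette

log = logging.getLogger("circlemapviz")


def parse_sort_key(spec: str) -> SortKey:
    """Parse a sort-key spec string.

    ``ring:GENE:PLATFORM[:asc|desc]`` sorts by a gene's values in one
    ring; ``annotation:NAME[:asc|desc]`` (or ``ann:...``) sorts by a
    sample annotation.  Direction defaults to ascending.
    """
    parts = spec.split(":")
    directions = {"asc": "ascending", "desc": "descending"}
    if parts[0] == "ring":
        if len(parts) == 3:
            gene, ring, direction = parts[1], parts[2], "ascending"
        elif len(parts) == 4 and parts[3] in directions:
            gene, ring, direction = parts[1], parts[2], directions[parts[3]]
        else:
            raise ConfigurationError(
                f"bad sort key {spec!r}: expected ring:GENE:PLATFORM[:asc|desc]"
            )
        return SortKey("ring_value", gene=gene, ring=ring, direction=direction)
    if parts[0] in ("annotation", "ann"):
        if len(parts) == 2:
            name, direction = parts[1], "ascending"
        elif len(parts) == 3 and parts[2] in directions:
            name, direction = parts[1], directions[parts[2]]
        else:
            raise ConfigurationError(
                f"bad sort key {spec!r}: expected annotation:NAME[:asc|desc]"
            )
        return SortKey("annotation", annotation_name=name, direction=direction)
    raise ConfigurationError(
        f"bad sort key {spec!r}: must start with 'ring:' or 'annotation:'"
    )


@dataclass
class RenderConfig:
    """A full render recipe: input files plus view settings.

    ``matrices`` entries are ``(platform_label, value_kind, path)`` in
    ring order, inner to outer.  ``networks`` entries are ``(name, path)``;
    the first network is the background the gene set filters, the rest
    are overlay tracks.  Files ending in ``.sif`` are parsed as SIF,
    anything else as the typed-node dialect.
    """

    matrices: list[tuple[str, str, str]] = field(default_factory=list)
    networks: list[tuple[str, str]] = field(default_factory=list)
    genes: str = ""
    annotations: list[tuple[str, str]] = field(default_factory=list)
    sort: list[str] = field(default_factory=list)
    group_by: str | None = None
    mode: str = "full"
    seed: int = 0
    out: str = ""

    def validate(self) -> None:
        if not self.matrices:
            raise ConfigurationError("at least one matrix is required")
        labels = [label for label, _, _ in self.matrices]
        if len(labels) != len(set(labels)):
            raise ConfigurationError(f"duplicate platform labels: {labels}")
        kinds = {kind for _, kind, _ in self.matrices}
        bad = kinds - {"continuous", "discrete", "binary"}
        if bad:
            raise ConfigurationError(f"unknown value kinds: {sorted(bad)}")
        if not self.networks:
            raise ConfigurationError("at least one network is required")
        names = [name for name, _ in self.networks]
        if len(names) != len(set(names)):
            raise ConfigurationError(f"duplicate network names: {names}")
        if not self.genes:
            raise ConfigurationError("a gene-set file is required")
        if self.mode not in ("full", "aggregated"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "aggregated" and not self.group_by:
            raise ConfigurationError("mode=aggregated requires group_by")
        if self.group_by and self.group_by not in [n for n, _ in self.annotations]:
            raise ConfigurationError(
                f"group_by names unknown annotation {self.group_by!r}"
            )
        for spec in self.sort:
            parse_sort_key(spec)

    @classmethod
    def from_file(cls, path: str | Path) -> "RenderConfig":
        """Load a declarative JSON config; relative paths resolve against it."""
        path = Path(path)
        raw = json.loads(path.read_text())
        base = path.parent

        def _resolve(p: str) -> str:
            return str((base / p) if not Path(p).is_absolute() else Path(p))

        cfg = cls()
        for entry in raw.get("matrices", []):
            label, kind, mpath = entry.split(":", 2)
            cfg.matrices.append((label, kind, _resolve(mpath)))
        for entry in raw.get("networks", []):
            name, npath = entry.split(":", 1)
            cfg.networks.append((name, _resolve(npath)))
        if raw.get("genes"):
            cfg.genes = _resolve(raw["genes"])
        for entry in raw.get("annotations", []):
            name, apath = entry.split(":", 1)
            cfg.annotations.append((name, _resolve(apath)))
        cfg.sort = list(raw.get("sort", []))
        cfg.group_by = raw.get("group_by")
        cfg.mode = raw.get("mode", "full")
        cfg.seed = int(raw.get("seed", 0))
        cfg.out = raw.get("out", "")
        return cfg


@dataclass
class Inputs:
    """Materialized inputs: parsed matrices, gene set, networks, annotations."""

    matrices: list[OmicsMatrix]
    gene_set: GeneSet
    networks: list[tuple[str, PathwayGraph]]
    annotations: list[SampleAnnotation]


def load_inputs(cfg: RenderConfig) -> Inputs:
    cfg.validate()
    matrices = []
    for label, kind, path in cfg.matrices:
        with open(path, encoding="utf-8") as fh:
            matrices.append(cio.read_matrix(fh, label, kind))
    with open(cfg.genes, encoding="utf-8") as fh:
        gene_set = cio.read_gene_set(fh, Path(cfg.genes).stem)
    networks = []
    for name, path in cfg.networks:
        with open(path, encoding="utf-8") as fh:
            if path.endswith(".sif"):
                graph = cio.read_network_sif(fh, name)
            else:
                graph = cio.read_network_typed(fh, name)
        networks.append((name, graph))
    annotations = []
    for name, path in cfg.annotations:
        with open(path, encoding="utf-8") as fh:
            annotations.append(cio.read_annotation(fh, name))
    return Inputs(matrices, gene_set, networks, annotations)


def render_svg_bytes(
    inputs: Inputs,
    sort: list[str] | None = None,
    group_by: str | None = None,
    mode: str = "full",
    seed: int = 0,
    scene_config: SceneConfig | None = None,
) -> bytes:
    """Run the full pipeline: filter, overlay, sort/partition, glyphs, SVG.

    Stages: the gene set filters the background network (first network)
    to an induced subgraph; the remaining networks overlay as tracks; the
    sample universe (union over matrices) is sorted by the key list; in
    aggregated mode the sorted universe is partitioned by the ``group_by``
    annotation; one glyph per displayed protein node with matrix data;
    seeded layout; scene assembly.  Raises on 0 matched genes.
    """
    matrices = inputs.matrices
    if mode == "aggregated" and not group_by:
        raise ConfigurationError("mode=aggregated requires group_by")

    background_name, background = inputs.networks[0]
    display = extract_subnetwork(background, inputs.gene_set)
    log.info("background %r: %d nodes, %d edges; display: %d nodes, %d edges",
             background_name, background.n_nodes, background.n_edges,
             display.n_nodes, display.n_edges)

    matched = [
        g for g in inputs.gene_set if any(g in m for m in matrices)
    ]
    log.info("%d genes matched against %d matrices", len(matched), len(matrices))
    if not matched:
        raise ConfigurationError("0 genes matched: gene set disjoint from matrices")
    if display.n_nodes == 0:
        raise ConfigurationError(
            "0 genes matched the background network: nothing to display"
        )

    all_names = [background_name] + [n for n, _ in inputs.networks[1:]]
    colors = track_palette(all_names)
    overlay = TrackSet(
        [(name, graph, colors[name]) for name, graph in inputs.networks[1:]]
    )
    graph = overlay_tracks(display, overlay)
    log.info("overlay: %d tracks, %d edges displayed", len(overlay), graph.n_edges)

    universe = sample_universe(matrices, "union")
    keys = [parse_sort_key(s) for s in (sort or [])]
    if keys:
        universe = sort_samples(universe, keys, matrices, inputs.annotations)
    log.info("sample universe: %d samples, %d sort keys", len(universe), len(keys))

    partition: GroupPartition | None = None
    order: SampleOrder | None = universe
    if mode == "aggregated":
        annotation = next(
            a for a in inputs.annotations if a.name == group_by
        )
        partition = partition_samples(universe, annotation)
        order = None
        log.info("aggregated over %r: %d groups %s",
                 group_by, len(partition), partition.sizes)

    rings = [RingSpec(m, i) for i, m in enumerate(matrices)]
    glyphs = {}
    for node, etype in display.nodes.items():
        if etype == "protein" and any(node in m for m in matrices):
            glyphs[node] = build_glyph(node, rings, order=order, partition=partition)

    layout = layout_graph(graph, seed, scene_config)
    scene = assemble_scene(graph, glyphs, layout, colors, scene_config)
    return cio.svg_bytes(scene)


def run_render(cfg: RenderConfig) -> bytes:
    """Load inputs per config, render, and write the output file if set."""
    inputs = load_inputs(cfg)
    payload = render_svg_bytes(
        inputs,
        sort=cfg.sort,
        group_by=cfg.group_by,
        mode=cfg.mode,
        seed=cfg.seed,
    )
    if cfg.out:
        Path(cfg.out).write_bytes(payload)
        log.info("wrote %d bytes to %s", len(payload), cfg.out)
    return payload
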