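"""Readers and writers for the external artifact formats.

Five text formats come in: tab-separated score matrices (header row =
sample ids, first column = gene symbol), two-column sample annotations,
one-symbol-per-line gene sets, SIF interaction lists, and a typed-node
pathway dialect.  One format goes out: SVG 1.1.

Parsing rules that matter:

* missing-value tokens on read are ``NA``, ``nan``, ``NaN`` and the empty
  string; writers emit ``NA``;
* ragged matrix rows are a hard error naming the line, never truncated;
* gene symbols match case-sensitively, no alias resolution;
* UTF-8 text, ``\\n`` or ``\\r\\n`` line endings.
"""

from __future__ import annotations

import io as _io
import xml.etree.ElementTree as ET
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .errors import DuplicateKeyError, FormatError, StateError, VocabularyError
from .model import (
    ENTITY_TYPES,
    Edge,
    GeneSet,
    OmicsMatrix,
    PathwayGraph,
    SampleAnnotation,
    is_missing,
)

MISSING_TOKENS = {"NA", "nan", "NaN", ""}
MISSING_OUT = "NA"

#: SIF relation token -> edge type.  Unknown relations are errors, not
#: silently undirected: the edge type drives the glyph choice downstream.
SIF_RELATIONS = {
    "pp": "undirected",
    "-a>": "activates",
    "-t|": "inhibits",
    "component>": "component",
    "member>": "member",
}

#: Typed-dialect relation token -> edge type (shares the SIF vocabulary).
TYPED_RELATIONS = dict(SIF_RELATIONS)

_EDGE_TO_SIF = {v: k for k, v in SIF_RELATIONS.items()}


def _lines(stream: IO[str]) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, line) with universal newline stripping."""
    for i, raw in enumerate(stream, start=1):
        yield i, raw.rstrip("\r\n")


def _parse_cell(token: str) -> float:
    if token in MISSING_TOKENS:
        return float("nan")
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"cannot parse numeric value {token!r}") from exc


# ---------------------------------------------------------------------------
# matrices


def read_matrix(
    stream: IO[str], platform_label: str, value_kind: str = "continuous"
) -> OmicsMatrix:
    """Parse a tab-separated gene x sample score matrix.

    First row is the header (first field ignored as a corner label, the
    rest are sample identifiers); each following row is a gene symbol and
    its scores.  Row order is preserved.

    Raises
    ------
    FormatError
        On ragged rows (naming the line number), a missing header, or a
        header with zero samples.
    DuplicateKeyError
        On repeated gene symbols.
    """
    it = _lines(stream)
    try:
        _, header = next(it)
    except StopIteration:
        raise FormatError("empty matrix file: no header row") from None
    cols = header.split("\t")
    samples = cols[1:]
    if not samples:
        raise FormatError("header declares zero samples", line=1)
    if len(samples) != len(set(samples)):
        raise DuplicateKeyError(f"duplicate sample identifiers in header: {samples}")

    genes: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in it:
        if line == "":
            continue
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise FormatError(
                f"row has {len(fields)} fields, header has {len(cols)}", line=lineno
            )
        gene = fields[0]
        if gene in seen:
            raise DuplicateKeyError(f"duplicate gene symbol {gene!r}")
        seen.add(gene)
        genes.append(gene)
        rows.append([_parse_cell(tok) for tok in fields[1:]])
    if not genes:
        raise FormatError("matrix has no data rows")
    data = pd.DataFrame(np.asarray(rows, dtype=float), index=genes, columns=samples)
    return OmicsMatrix(platform_label, data, value_kind)


def write_matrix(matrix: OmicsMatrix, stream: IO[str], corner: str = "gene") -> None:
    """Serialize a matrix in the same tab-separated layout ``read_matrix`` accepts."""
    stream.write("\t".join([corner, *matrix.samples]) + "\n")
    for gene in matrix.genes:
        cells = [
            MISSING_OUT if is_missing(v) else repr(float(v))
            for v in matrix.data.loc[gene]
        ]
        stream.write("\t".join([gene, *cells]) + "\n")


# ---------------------------------------------------------------------------
# annotations


def read_annotation(stream: IO[str], name: str = "annotation") -> SampleAnnotation:
    """Parse a two-column ``sample<TAB>category`` table.

    A first line whose first field is ``sample`` (case-insensitive) is
    treated as an optional header.  An empty category field records the
    sample as MISSING.  A sample repeated with a *conflicting* category is
    an error; an exact repeat is tolerated.
    """
    assignments: dict[str, str | None] = {}
    for lineno, line in _lines(stream):
        if line == "" or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"expected 2 tab-separated fields, got {len(fields)}", line=lineno
            )
        sample, category = fields
        if lineno == 1 and sample.lower() == "sample":
            continue
        cat: str | None = category if category not in MISSING_TOKENS else None
        if sample in assignments and assignments[sample] != cat:
            raise DuplicateKeyError(
                f"sample {sample!r} annotated as both "
                f"{assignments[sample]!r} and {cat!r}"
            )
        assignments[sample] = cat
    return SampleAnnotation(name, assignments)


def write_annotation(annotation: SampleAnnotation, stream: IO[str]) -> None:
    for sample, category in annotation.assignments.items():
        stream.write(f"{sample}\t{category if category is not None else ''}\n")


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(stream: IO[str], name: str = "geneset") -> GeneSet:
    """One symbol per line; ``#`` lines are comments; duplicates collapse to first."""
    members: list[str] = []
    for _, line in _lines(stream):
        token = line.strip()
        if token == "" or token.startswith("#"):
            continue
        members.append(token)
    if not members:
        raise FormatError("gene set file contains no symbols")
    return GeneSet(name, members)


def write_gene_set(gene_set: GeneSet, stream: IO[str]) -> None:
    for gene in gene_set.members:
        stream.write(gene + "\n")


# ---------------------------------------------------------------------------
# networks


def read_network_sif(stream: IO[str], track_name: str = "") -> PathwayGraph:
    """Parse ``source<TAB>relation<TAB>target`` lines into a PathwayGraph.

    All nodes default to entity type ``protein``; every edge is tagged
    with ``track_name``.  Unknown relation tokens raise
    :class:`VocabularyError` rather than degrading to undirected.
    """
    graph = PathwayGraph()
    for lineno, line in _lines(stream):
        if line == "" or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(
                f"expected 3 tab-separated fields, got {len(fields)}", line=lineno
            )
        source, relation, target = fields
        if relation not in SIF_RELATIONS:
            raise VocabularyError(
                f"unknown SIF relation {relation!r} (line {lineno}); "
                f"known: {sorted(SIF_RELATIONS)}"
            )
        graph.add_node(source)
        graph.add_node(target)
        graph.add_edge(source, target, SIF_RELATIONS[relation], track_name)
    return graph


def write_network_sif(graph: PathwayGraph, stream: IO[str]) -> None:
    for edge in graph.edges:
        stream.write(f"{edge.source}\t{_EDGE_TO_SIF[edge.edge_type]}\t{edge.target}\n")


def read_network_typed(stream: IO[str], track_name: str = "") -> PathwayGraph:
    """Parse the typed-node pathway dialect.

    Node lines ``entity_type<TAB>name`` must precede edge lines
    ``source<TAB>target<TAB>relation``.  Entity types outside
    {protein, complex, family, smallmolecule, process} and unknown
    relations are vocabulary errors; an edge naming an undeclared node is
    an unknown-node error.
    """
    graph = PathwayGraph()
    for lineno, line in _lines(stream):
        if line == "" or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            entity_type, node = fields
            if entity_type not in ENTITY_TYPES:
                raise VocabularyError(
                    f"unknown entity type {entity_type!r} (line {lineno})"
                )
            graph.add_node(node, entity_type)
        elif len(fields) == 3:
            source, target, relation = fields
            if relation not in TYPED_RELATIONS:
                raise VocabularyError(
                    f"unknown relation {relation!r} (line {lineno})"
                )
            graph.add_edge(source, target, TYPED_RELATIONS[relation], track_name)
        else:
            raise FormatError(
                f"expected 2 (node) or 3 (edge) fields, got {len(fields)}",
                line=lineno,
            )
    return graph


def write_network_typed(graph: PathwayGraph, stream: IO[str]) -> None:
    for node, entity_type in graph.nodes.items():
        stream.write(f"{entity_type}\t{node}\n")
    for edge in graph.edges:
        stream.write(
            f"{edge.source}\t{edge.target}\t{_EDGE_TO_SIF[edge.edge_type]}\n"
        )


# ---------------------------------------------------------------------------
# SVG


def svg_bytes(scene) -> bytes:
    """Serialize a laid-out scene to SVG 1.1 bytes.

    Byte-determinism contract: the element tree is built in a fixed order
    with fixed-precision coordinates, so identical scene + config yields
    identical bytes.
    """
    if getattr(scene, "layout", None) is None:
        raise StateError("scene has no layout; run layout_graph first")
    root = scene.to_svg_element()
    buf = _io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="utf-8", xml_declaration=True)
    return buf.getvalue()


def write_svg(scene, stream: IO[str] | IO[bytes]) -> None:
    """Write a scene as SVG to a text or binary stream."""
    payload = svg_bytes(scene)
    if isinstance(stream, (_io.RawIOBase, _io.BufferedIOBase)) or "b" in getattr(
        stream, "mode", ""
    ):
        stream.write(payload)  # type: ignore[arg-type]
    else:
        stream.write(payload.decode("utf-8"))  # type: ignore[arg-type]
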