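"""Core domain types: omics matrices, annotations, gene sets and pathway graphs.

The in-memory containers mirror the external file formats one-to-one: a
gene x sample score matrix per platform, a two-column sample annotation,
an ordered gene list, and a typed interaction graph whose edges remember
which network "track" they came from.  Missing values are represented as
``float('nan')`` inside a pandas DataFrame and written back out as ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    ConfigurationError,
    DuplicateKeyError,
    UnknownNodeError,
    VocabularyError,
)

#: Value kinds a matrix may declare.
VALUE_KINDS = ("continuous", "discrete", "binary")

#: Entity types the pathway dialect admits.
ENTITY_TYPES = ("protein", "complex", "family", "smallmolecule", "process")

#: Edge types; ``undirected`` pairs are stored with endpoints in
#: lexicographic order so (A, B) and (B, A) denote the same edge.
EDGE_TYPES = ("activates", "inhibits", "component", "member", "undirected")

DIRECTED_EDGE_TYPES = frozenset({"activates", "inhibits", "component", "member"})


def is_missing(value) -> bool:
    """True for the MISSING sentinel (NaN or None)."""
    if value is None:
        return True
    try:
        return math.isnan(value)
    except TypeError:
        return False


MISSING = float("nan")


@dataclass
class OmicsMatrix:
    """One platform's gene x sample score grid.

    Attributes
    ----------
    platform_label:
        Short name shown in ring legends (e.g. ``"expression"``).
    data:
        DataFrame indexed by gene symbol, columns = sample identifiers,
        dtype float; NaN encodes MISSING.
    value_kind:
        ``continuous``, ``discrete`` or ``binary``.  Binary grids may only
        hold 0, 1 and MISSING.
    """

    platform_label: str
    data: pd.DataFrame
    value_kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise VocabularyError(f"unknown value kind {self.value_kind!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateKeyError(f"duplicate gene symbol(s): {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DuplicateKeyError(f"duplicate sample identifier(s): {dupes}")
        if self.value_kind == "binary":
            vals = self.data.to_numpy(dtype=float)
            ok = (vals == 0) | (vals == 1) | (vals != vals)  # NaN != NaN
            if not ok.all():
                raise VocabularyError(
                    "binary matrix contains values outside {0, 1, MISSING}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def value(self, gene: str, sample: str) -> float:
        """Score for (gene, sample); NaN if the sample is absent from this matrix."""
        if gene not in self.data.index or sample not in self.data.columns:
            return MISSING
        return float(self.data.at[gene, sample])

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index


@dataclass
class SampleAnnotation:
    """A named categorical labelling of samples (subtype, phenotype, outcome)."""

    name: str
    assignments: dict[str, str] = field(default_factory=dict)

    def category(self, sample: str) -> str | None:
        """Category for a sample, or None (MISSING) if unannotated."""
        return self.assignments.get(sample)

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for cat in self.assignments.values():
            if cat is not None:
                seen.setdefault(cat)
        return list(seen)


@dataclass
class GeneSet:
    """Ordered, duplicate-free list of gene symbols naming a pathway of interest."""

    name: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        deduped: dict[str, None] = {}
        for g in self.members:
            deduped.setdefault(g)
        self.members = list(deduped)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Edge:
    """One typed interaction, tagged with the network track it came from.

    Undirected edges are canonicalized at construction: endpoints sorted
    lexicographically, so Edge("B", "A", "undirected", t) == Edge("A", "B",
    "undirected", t).  Directed types preserve orientation.
    """

    source: str
    target: str
    edge_type: str
    track: str = ""

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise VocabularyError(f"unknown edge type {self.edge_type!r}")
        if self.edge_type == "undirected" and self.target < self.source:
            s, t = self.source, self.target
            object.__setattr__(self, "source", t)
            object.__setattr__(self, "target", s)

    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair, canonically sorted."""
        a, b = self.source, self.target
        return (a, b) if a <= b else (b, a)


def _canonical_edge(source: str, target: str, edge_type: str, track: str) -> Edge:
    if edge_type == "undirected" and target < source:
        source, target = target, source
    return Edge(source, target, edge_type, track)


@dataclass
class PathwayGraph:
    """Typed nodes plus a multiset of typed, track-tagged edges.

    ``nodes`` maps node name -> entity type.  ``edges`` is an ordered list;
    parallel edges (same endpoints, different track or type) are kept
    distinct because the renderer colors each by its source track.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    def add_node(self, name: str, entity_type: str = "protein") -> None:
        if entity_type not in ENTITY_TYPES:
            raise VocabularyError(f"unknown entity type {entity_type!r}")
        existing = self.nodes.get(name)
        if existing is not None and existing != entity_type:
            raise DuplicateKeyError(
                f"node {name!r} redeclared as {entity_type!r} (was {existing!r})"
            )
        self.nodes[name] = entity_type

    def add_edge(
        self, source: str, target: str, edge_type: str, track: str = ""
    ) -> None:
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise UnknownNodeError(f"edge references undeclared node {endpoint!r}")
        self.edges.append(_canonical_edge(source, target, edge_type, track))

    def has_pair(self, a: str, b: str) -> bool:
        """True if any edge (either orientation, any type) links a and b."""
        want = (a, b) if a <= b else (b, a)
        return any(e.pair() == want for e in self.edges)

    def edge_multiset(self) -> list[tuple[str, str, str, str]]:
        """Sorted multiset view for equality checks in tests."""
        return sorted((e.source, e.target, e.edge_type, e.track) for e in self.edges)

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(dict(self.nodes), list(self.edges))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class TrackSet:
    """Ordered collection of named network tracks with display colors.

    Order defines drawing order and legend order; track names must be
    unique because the per-pair support count is per-track binary.
    """

    tracks: list[tuple[str, PathwayGraph, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.tracks]
        if len(names) != len(set(names)):
            raise ConfigurationError(f"duplicate track names in {names}")

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.tracks]

    @property
    def colors(self) -> dict[str, str]:
        return {name: color for name, _, color in self.tracks}
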