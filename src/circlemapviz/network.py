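"""Network algebra: gene-set filtering, multi-track overlay, support counts.

A large merged background network ("SuperPathway" style) stays out of
view; the displayed graph is the induced subgraph on a query gene set,
optionally keeping complex/family hub nodes whose members are all
selected.  Additional interaction networks are overlaid as tracks: an
edge is drawn only when both endpoints are already displayed, and
parallel edges from different tracks stay distinct so each can be
colored by source.  The per-pair support count — how many tracks agree
that two genes interact — is the confidence readout.
"""

from __future__ import annotations

from .model import GeneSet, PathwayGraph, TrackSet


def extract_subnetwork(
    background: PathwayGraph,
    genes: GeneSet,
    expand_complexes: bool = False,
) -> PathwayGraph:
    """Induced subgraph of ``background`` on the query gene set.

    With ``expand_complexes`` (default off), a complex or family node is
    additionally retained when *all* of its protein neighbors over
    component/member edges belong to the gene set, together with those
    structural edges.  The result never contains an edge absent from the
    background; an empty intersection yields an empty graph, not an error.
    """
    selected = {g for g in genes if g in background.nodes}

    if expand_complexes:
        for node, etype in background.nodes.items():
            if etype not in ("complex", "family") or node in selected:
                continue
            members = set()
            for e in background.edges:
                if e.edge_type not in ("component", "member"):
                    continue
                if e.source == node and background.nodes.get(e.target) == "protein":
                    members.add(e.target)
                elif e.target == node and background.nodes.get(e.source) == "protein":
                    members.add(e.source)
            if members and members <= selected:
                selected.add(node)

    result = PathwayGraph()
    for node in background.nodes:
        if node in selected:
            result.add_node(node, background.nodes[node])
    for e in background.edges:
        if e.source in selected and e.target in selected:
            result.edges.append(e)
    return result


def overlay_tracks(display: PathwayGraph, tracks: TrackSet) -> PathwayGraph:
    """Augment the displayed graph with every track edge internal to it.

    A track edge is added iff both endpoints are display nodes; no nodes
    are ever introduced.  Each added edge is retagged with its track name.
    Duplicate track names are rejected by :class:`TrackSet` itself.
    """
    result = display.copy()
    for track_name, graph, _color in tracks:
        for e in graph.edges:
            if e.source in result.nodes and e.target in result.nodes:
                result.add_edge(e.source, e.target, e.edge_type, track_name)
    return result


def edge_support(pair: tuple[str, str], tracks: TrackSet) -> int:
    """Number of tracks containing any edge between the two genes.

    Orientation and edge type are ignored; a track contributes at most 1
    regardless of how many edge records it holds between the pair, so the
    count measures independent data-set support, bounded by ``len(tracks)``.
    """
    a, b = pair
    return sum(1 for _name, graph, _color in tracks if graph.has_pair(a, b))
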