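"""Directed transformation network, non-redundant pathway extraction, export.

A pathway is a maximal simple directed path: every simple path in the
network is a contiguous sub-path of some returned pathway, and no returned
pathway is a contiguous sub-path of another.  On a chain A->B->C this
yields the single pathway [A, B, C]; shorter windows are redundant and
dropped.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .formula import format_formula
from .matching import Feature, TransformationEdge

__all__ = [
    "TransformationNetwork",
    "Pathway",
    "build_network",
    "enumerate_pathways",
    "filter_pathways",
    "export_pajek",
]

logger = logging.getLogger(__name__)


@dataclass
class TransformationNetwork:
    """Directed multigraph of features (nodes) and rule-matched edges (arcs)."""

    graph: nx.MultiDiGraph
    arcs: list[TransformationEdge]

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass(frozen=True)
class Pathway:
    """An ordered chain of features joined by named transformations."""

    nodes: tuple[str, ...]
    rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 2 or len(self.rules) != len(self.nodes) - 1:
            raise ValueError("a pathway needs >= 2 nodes and one rule per step")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("a pathway must be a simple path (no repeated node)")


def build_network(
    edges: list[TransformationEdge],
    features: list[Feature] | None = None,
) -> TransformationNetwork:
    """Assemble the multigraph; node attributes come from ``features`` if given."""
    graph = nx.MultiDiGraph()
    attrs: dict[str, dict] = {}
    if features:
        for feat in features:
            best = feat.candidates[0].composition if feat.candidates else None
            attrs[feat.id] = {
                "mz": feat.mz.mz,
                "first_time": feat.first_time,
                "time_points": feat.time_points,
                "formula": format_formula(best) if best is not None else "",
            }
    for index, edge in enumerate(edges):
        for node in (edge.source, edge.target):
            if node not in graph:
                graph.add_node(node, **attrs.get(node, {}))
        graph.add_edge(edge.source, edge.target, rule=edge.rule, order=index)
    return TransformationNetwork(graph=graph, arcs=list(edges))


def enumerate_pathways(
    net: TransformationNetwork,
    max_length: int = 20,
    max_paths: int = 100_000,
) -> list[Pathway]:
    """Enumerate maximal simple paths, expanded over parallel-rule arcs.

    ``max_length`` caps nodes per path (paths hitting the cap are emitted
    even if extendable, with a logged warning); ``max_paths`` caps the total
    number of returned pathways (truncation is logged, never silent).
    Output is sorted by length descending, then node ids, then rule names.
    """
    if max_length < 2:
        raise ValueError("max_length must be >= 2 nodes")
    graph = net.graph
    succ = {n: sorted(graph.successors(n)) for n in graph.nodes}
    pred = {n: sorted(graph.predecessors(n)) for n in graph.nodes}

    node_paths: list[tuple[str, ...]] = []
    truncated_length = False

    def extend(path: list[str], members: set[str]) -> None:
        nonlocal truncated_length
        forward = [n for n in succ[path[-1]] if n not in members]
        if forward and len(path) < max_length:
            for nxt in forward:
                members.add(nxt)
                path.append(nxt)
                extend(path, members)
                path.pop()
                members.remove(nxt)
            return
        if len(path) < 2:
            return
        at_cap = len(path) == max_length
        if forward and at_cap:
            truncated_length = True
        backward = any(p not in members for p in pred[path[0]])
        if backward and not at_cap:
            return  # covered by a longer path discovered from an earlier start
        node_paths.append(tuple(path))

    for start in sorted(graph.nodes):
        extend([start], {start})

    if truncated_length:
        logger.warning("pathway enumeration hit the %d-node length cap; paths truncated", max_length)

    pathways: list[Pathway] = []
    overflow = False
    for nodes in node_paths:
        step_rules = []
        for a, b in zip(nodes, nodes[1:]):
            arcs = sorted(graph[a][b].values(), key=lambda d: d["order"])
            step_rules.append([d["rule"] for d in arcs])
        for combo in itertools.product(*step_rules):
            if len(pathways) >= max_paths:
                overflow = True
                break
            pathways.append(Pathway(nodes=nodes, rules=tuple(combo)))
        if overflow:
            break
    if overflow:
        logger.warning("pathway count exceeded cap (%d); output truncated", max_paths)

    pathways.sort(key=lambda p: (-len(p.nodes), p.nodes, p.rules))
    return pathways


def filter_pathways(
    paths: list[Pathway],
    net: TransformationNetwork,
    mz_range: tuple[float, float] | None = None,
    time_points: set[int] | None = None,
) -> list[Pathway]:
    """Keep pathways whose every node passes the m/z and time-point filters.

    A node passes the time filter when its observation times intersect the
    requested set.  An empty filter spec is the identity; filtering never
    splits a path.
    """
    if mz_range is None and time_points is None:
        return list(paths)
    graph = net.graph
    kept = []
    for path in paths:
        ok = True
        for node in path.nodes:
            data = graph.nodes[node]
            if mz_range is not None:
                mz = data.get("mz")
                if mz is None or not (mz_range[0] <= mz <= mz_range[1]):
                    ok = False
                    break
            if time_points is not None:
                observed = data.get("time_points")
                if not observed or not (set(observed) & set(time_points)):
                    ok = False
                    break
        if ok:
            kept.append(path)
    return kept


def export_pajek(net: TransformationNetwork, path: str | Path) -> None:
    """Write the network as a standard Pajek .net file.

    ``*Vertices N`` with 1-based ids and quoted labels, then ``*Arcs`` with
    one ``source target`` line per directed arc.  Node order is sorted by
    id, so identical networks export byte-identically.
    """
    nodes = net.node_ids
    index = {node: i + 1 for i, node in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    lines += [f'{index[node]} "{node}"' for node in nodes]
    lines.append("*Arcs")
    arc_lines = sorted(
        (index[e.source], index[e.target]) for e in net.arcs
    )
    lines += [f"{s} {t}" for s, t in arc_lines]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
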