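"""The link graph: a dependency DAG over vessels.

Edges point from a dependency to its dependents. The graph orders startup
(rank by rank, a vessel only starts once everything it depends on is
online), contains failures by cascading invalidation to all downstream
vessels, and restores repaired segments by reloading cascade victims whose
dependencies are back online. Data-graph connections are deliberately
invisible here: failures never propagate along them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

import networkx as nx

from .errors import ConfigurationError, PreconditionError
from .vessel import InvalidationCause, ReloadReport, Vessel, VesselState

if TYPE_CHECKING:  # pragma: no cover
    from .fleet import Fleet


@dataclass
class LinkGraph:
    graph: nx.DiGraph  # nodes: Vessel; edge u -> v means v depends on u
    ranks: dict[Vessel, int]

    def dependencies(self, vessel: Vessel) -> list[Vessel]:
        return list(self.graph.predecessors(vessel))

    def descendants(self, vessel: Vessel) -> set[Vessel]:
        return set(nx.descendants(self.graph, vessel))

    def start_order(self) -> list[Vessel]:
        """Ascending rank; alphabetical within a rank (deterministic)."""
        return sorted(self.graph.nodes, key=lambda v: (self.ranks[v], v.name))

    def shutdown_order(self) -> list[Vessel]:
        """Descending rank: dependents are torn down before dependencies."""
        return sorted(self.graph.nodes, key=lambda v: (-self.ranks[v], v.name))


@dataclass
class StartReport:
    started: list[Vessel] = field(default_factory=list)
    failed: dict[Vessel, ReloadReport] = field(default_factory=dict)
    skipped: list[Vessel] = field(default_factory=list)  # dependency failed upstream

    @property
    def all_online(self) -> bool:
        return not self.failed and not self.skipped


def build_link_graph(vessels: Iterable[Vessel]) -> LinkGraph:
    """Derive the DAG from each vessel's declared dependencies and assign
    ranks as longest-path depth from the roots. A cycle is a fatal
    configuration error naming the vessels involved."""
    g = nx.DiGraph()
    vessels = list(vessels)
    g.add_nodes_from(vessels)
    for v in vessels:
        for dep in v.spec.dependencies:
            g.add_edge(dep, v)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        names = " -> ".join(u.name for u, _ in cycle) + f" -> {cycle[0][0].name}"
        raise ConfigurationError(f"dependency cycle: {names}")
    ranks: dict[Vessel, int] = {}
    for v in nx.topological_sort(g):
        preds = list(g.predecessors(v))
        ranks[v] = 0 if not preds else 1 + max(ranks[p] for p in preds)
    return LinkGraph(g, ranks)


def start_in_order(graph: LinkGraph) -> StartReport:
    """Reload every vessel in start order. A vessel with a failed or skipped
    dependency is itself skipped: it stays OFFLINE with cause CASCADE, so a
    later repair of the dependency restores it."""
    report = StartReport()
    for vessel in graph.start_order():
        if any(not d.is_online for d in graph.dependencies(vessel)):
            vessel.invalidation_cause = InvalidationCause.CASCADE
            report.skipped.append(vessel)
            continue
        result = vessel.reload()
        if result.success:
            report.started.append(vessel)
        else:
            report.failed[vessel] = result
    return report


def cascade_invalidate(graph: LinkGraph, origin: Vessel,
                       cause: InvalidationCause = InvalidationCause.LOCAL_FAILURE
                       ) -> set[Vessel]:
    """Invalidate the origin with the given cause and every link-graph
    descendant with cause CASCADE, in ascending rank order. Returns the set
    of vessels taken down (vessels already offline keep their prior cause and
    are not included, except the origin itself). Data-graph-only neighbours
    are untouched."""
    affected = sorted(graph.descendants(origin),
                      key=lambda v: (graph.ranks[v], v.name))
    invalidated = {origin}
    origin.invalidate(cause, _propagate=False)
    for vessel in affected:
        if vessel.is_online:
            vessel.invalidate(InvalidationCause.CASCADE, _propagate=False)
            invalidated.add(vessel)
    return invalidated


def restore_segment(graph: LinkGraph, origin: Vessel) -> set[Vessel]:
    """Reload the origin, then every descendant that went down as cascade
    collateral and whose dependencies are all online again, ascending rank
    order. Vessels stopped by the user stay stopped."""
    offline_dep = next((d for d in graph.dependencies(origin) if not d.is_online), None)
    if offline_dep is not None:
        raise PreconditionError(
            f"cannot restore {origin.name!r}: dependency {offline_dep.name!r} is offline")
    reloaded: set[Vessel] = set()
    if origin.reload().success:
        reloaded.add(origin)
    for vessel in sorted(graph.descendants(origin),
                         key=lambda v: (graph.ranks[v], v.name)):
        if vessel.state is not VesselState.OFFLINE:
            continue
        if vessel.invalidation_cause is not InvalidationCause.CASCADE:
            continue
        if any(not d.is_online for d in graph.dependencies(vessel)):
            continue
        if vessel.reload().success:
            reloaded.add(vessel)
    return reloaded


def to_dot(fleet: "Fleet", link_graph: Optional[LinkGraph] = None) -> str:
    """Render the fleet as DOT text: solid edges for link (dependency)
    relations, dashed edges for data routes between vessels."""
    lg = link_graph or fleet.link_graph
    lines = ["digraph fleet {"]
    for v in sorted(fleet.vessels.values(), key=lambda v: v.name):
        lines.append(f'    "{v.name}" [shape=box];')
    if lg is not None:
        for u, v in lg.graph.edges:
            lines.append(f'    "{u.name}" -> "{v.name}" [color=blue];')
    if fleet.data_graph is not None:
        seen = set()
        for p, c in fleet.data_graph.routes:
            key = (p.owner.name, c.owner.name)
            if key not in seen:
                seen.add(key)
                lines.append(f'    "{key[0]}" -> "{key[1]}" [style=dashed, color=purple];')
    lines.append("}")
    return "\n".join(lines)
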