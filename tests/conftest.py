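"""Shared fixtures: counting components, the eight-vessel reference fleet,
and a random-DAG fleet builder used by the ordering/containment property
tests."""

from __future__ import annotations

import numpy as np
import pytest

import fleetkit as fk
from fleetkit import data as fdata


class Counters:
    """Per-vessel invocation counters recorded by the builder/initializer/
    invalidator closures, plus a global event trace."""

    def __init__(self):
        self.built: dict[str, int] = {}
        self.initialized: dict[str, int] = {}
        self.invalidated: dict[str, int] = {}
        self.trace: list[tuple[str, str]] = []  # (event, vessel)

    def make_vessel(self, fleet: fk.Fleet, name: str, deps=(), **kwargs) -> fk.Vessel:
        self.built.setdefault(name, 0)
        self.initialized.setdefault(name, 0)
        self.invalidated.setdefault(name, 0)

        def builder(*handles):
            self.built[name] += 1
            self.trace.append(("build", name))
            return {"name": name, "deps": handles}

        def initializer(*args):
            self.initialized[name] += 1
            self.trace.append(("init", name))

        def invalidator(*args):
            self.invalidated[name] += 1
            self.trace.append(("invalidate", name))

        return fleet.freight(name, builder, initializer=initializer,
                             invalidator=invalidator, dependencies=list(deps),
                             **kwargs)


@pytest.fixture
def counters():
    return Counters()


# Reference eight-vessel fleet: link edges A->B, B->C, B->D, F->G, G->H,
# E isolated in the link graph; one data route H -> E.
FIG3_EDGES = [("A", "B"), ("B", "C"), ("B", "D"), ("F", "G"), ("G", "H")]
FIG3_RANKS = {"A": 0, "E": 0, "F": 0, "B": 1, "G": 1, "C": 2, "D": 2, "H": 2}


class Tick:
    """Payload emitted by vessel H in the reference fleet."""

    def __init__(self, n: int):
        self.n = n


def build_reference_fleet(counters: Counters):
    """The eight-vessel fleet with the H -> E data route. Returns
    (fleet, vessels-by-name)."""
    fleet = fk.Fleet("fig3", settings_path=None)
    vessels: dict[str, fk.Vessel] = {}
    deps_of = {}
    for dep, dependent in FIG3_EDGES:
        deps_of.setdefault(dependent, []).append(dep)
    for name in "ABCDEFGH":
        deps = [vessels[d] for d in deps_of.get(name, [])]
        vessels[name] = counters.make_vessel(fleet, name, deps)

    # H sources Tick payloads; E consumes them (data-only connection)
    counter = {"n": 0, "seen": 0}

    def tick_source(comp):
        counter["n"] += 1
        return Tick(counter["n"]), False

    fdata.add_source(vessels["H"], tick_source, output_type=Tick, name="ticks")

    def absorb(comp, tick, md):
        counter["seen"] += 1

    fdata.add_sink(vessels["E"], absorb, input_type=Tick, name="absorb")
    fleet._tick_counter = counter  # test-side observability
    return fleet, vessels


@pytest.fixture
def reference_fleet(counters):
    fleet, vessels = build_reference_fleet(counters)
    yield fleet, vessels
    fleet.shutdown()


def build_random_dag_fleet(rng: np.random.Generator, n_nodes: int,
                           edge_prob: float = 0.3):
    """A fleet whose link graph is a random DAG (edges only from lower to
    higher node index, so acyclic by construction). Returns
    (fleet, vessels list, dependency-name map)."""
    fleet = fk.Fleet("random", settings_path=None)
    vessels: list[fk.Vessel] = []
    deps_map: dict[str, list[str]] = {}
    order_log: list[str] = []
    fleet._reload_order = order_log  # test-side observability

    def make_builder(name: str):
        def builder(*handles):
            order_log.append(name)
            return {"n": name}

        return builder

    for i in range(n_nodes):
        name = f"v{i:02d}"
        deps = [vessels[j] for j in range(i) if rng.random() < edge_prob]
        deps_map[name] = [d.name for d in deps]
        vessels.append(fleet.freight(name, make_builder(name), dependencies=deps))
    return fleet, vessels, deps_map


def reachability_closure(deps_map: dict[str, list[str]], origin: str) -> set[str]:
    """Brute-force BFS over the dependency lists: every vessel that
    transitively depends on the origin. Independent of the graph library."""
    dependents: dict[str, list[str]] = {n: [] for n in deps_map}
    for node, deps in deps_map.items():
        for d in deps:
            dependents[d].append(node)
    seen = {origin}
    frontier = [origin]
    while frontier:
        node = frontier.pop()
        for nxt in dependents[node]:
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen
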