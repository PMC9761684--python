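"""Polyads: connected clusters of states linked by accepted resonances.

The variational correction operates on the graph whose nodes are the states
of the (up to 2-quanta) VPT2 state space and whose edges are the accepted
Fermi and Darling-Dennison resonances; its connected components are the
polyads, diagonalized as independent blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import networkx as nx

from .resonance import ResonanceDB, two_quanta_states
from .states import VibState


@dataclass
class Polyad:
    states: list[VibState]
    couplings: dict[frozenset, float] = dfield(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.states)


@dataclass
class PolyadDB:
    polyads: list[Polyad]
    singletons: list[VibState]

    def all_states(self) -> list[VibState]:
        out = []
        for p in self.polyads:
            out.extend(p.states)
        out.extend(self.singletons)
        return out

    def polyad_of(self, state: VibState) -> Polyad | None:
        for p in self.polyads:
            if state in p.states:
                return p
        return None

    def to_records(self) -> list[dict]:
        out = []
        for p in self.polyads:
            out.append({
                "size": p.size,
                "states": [s.as_dict() for s in p.states],
                "couplings": [
                    {"pair": [a.as_dict(), b.as_dict()], "value": v}
                    for key, v in p.couplings.items()
                    for a, b in [tuple(key)]
                ],
            })
        return out


def build_polyads(
    resdb: ResonanceDB,
    state_space: list[VibState] | None = None,
    n_modes: int | None = None,
) -> PolyadDB:
    """Partition the state space into polyads using the accepted resonances.

    ``state_space`` defaults to the N + N(N+1)/2 states with up to two
    quanta.  Every accepted resonance connecting two states of the space
    becomes an edge carrying its coupling value; components with >= 2 states
    are polyads, the rest singletons.  The result is a partition: polyads are
    pairwise disjoint and, with the singletons, cover the space.
    """
    if state_space is None:
        if n_modes is None:
            raise ValueError("state_space or n_modes required")
        state_space = two_quanta_states(n_modes)
    space = set(state_space)
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(state_space)
    couplings: dict[frozenset, float] = {}
    for entry in resdb:
        c = entry.candidate
        if c.bra in space and c.ket in space:
            g.add_edge(c.bra, c.ket)
            couplings[frozenset((c.bra, c.ket))] = c.coupling
    polyads: list[Polyad] = []
    singletons: list[VibState] = []
    order = {s: i for i, s in enumerate(state_space)}
    for comp in nx.connected_components(g):
        states = sorted(comp, key=order.get)
        if len(states) == 1:
            singletons.append(states[0])
            continue
        sub = {
            key: v for key, v in couplings.items()
            if all(s in comp for s in key)
        }
        polyads.append(Polyad(states=states, couplings=sub))
    polyads.sort(key=lambda p: order[p.states[0]])
    singletons.sort(key=order.get)
    return PolyadDB(polyads=polyads, singletons=singletons)
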