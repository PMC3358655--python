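"""Alternating Eulerian tours: from edge multiplicities to block reconstructions.

Once every non-telomeric vertex satisfies the copy-number balance
condition, the multigraph in which each edge appears with its multiplicity
decomposes into edge-disjoint *alternating* tours — walks that strictly
alternate interval and non-interval (reference/variant) edges — each
beginning and ending at a telomeric vertex.  Reading off the interval
edges of a tour, with sign for direction of traversal, spells a block
sequence of the rearranged genome (e.g. ``A -B C D C D``).

Extraction is Hierholzer-style: at every balanced vertex each arrival via
a non-interval edge is paired with a departure via the vertex's unique
interval edge and vice versa; unpaired edge stubs at telomeric vertices
seed the open tours.  Closed alternating cycles that share a vertex with a
tour are spliced into it; balanced components containing no telomeric
vertex can only yield closed cycles and are reported as ``leftover_cycles``
(circular or fully amplified structures fall outside the open-tour
guarantee).

Many decompositions are generally consistent with one multiplicity
assignment; pairing order is deterministic (lowest edge id first) unless a
seed requests a randomized tour.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .infer import balance_residuals
from .model import KIND_INTERVAL, IntervalAdjacencyGraph, Vertex

logger = logging.getLogger(__name__)


@dataclass
class Diagnostics:
    """Why a multiplicity assignment is (not) decomposable into open tours."""

    unbalanced: dict = field(default_factory=dict)
    telomere_free_components: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unbalanced


def is_eulerizable(graph: IntervalAdjacencyGraph, mu: dict[int, int]):
    """Check the balance condition; list obstructions to open-tour decomposition.

    Returns ``(ok, diagnostics)``: ``ok`` is true iff every non-telomeric
    vertex is balanced.  Diagnostics additionally report connected
    components of the positive-multiplicity support that contain no
    telomeric vertex; these admit only closed cycles.
    """
    diag = Diagnostics()
    for v, res in balance_residuals(graph, mu).items():
        if res != 0:
            diag.unbalanced[v] = res

    g = nx.Graph()
    for e in graph.edges:
        if mu.get(e.id, 0) > 0:
            g.add_edge(e.u, e.v)
    for comp in nx.connected_components(g):
        if not comp & graph.telomeres:
            diag.telomere_free_components.append(sorted(comp))
    return diag.ok, diag


@dataclass
class BlockSequence:
    """An ordered, signed sequence of reference blocks spelled by one tour."""

    blocks: list[int]
    start_vertex: Vertex
    end_vertex: Vertex
    closed: bool = False
    #: raw traversal: (edge, forward) per step, for conservation checks
    steps: list = field(default_factory=list)

    def edge_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for edge, _fwd in self.steps:
            counts[edge.id] = counts.get(edge.id, 0) + 1
        return counts

    def reverse(self) -> "BlockSequence":
        return BlockSequence([-b for b in reversed(self.blocks)],
                             self.end_vertex, self.start_vertex, self.closed,
                             [(e, not f) for e, f in reversed(self.steps)])


@dataclass
class TourDecomposition:
    tours: list[BlockSequence] = field(default_factory=list)
    leftover_cycles: list[BlockSequence] = field(default_factory=list)

    def edge_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for t in self.tours + self.leftover_cycles:
            for eid, c in t.edge_counts().items():
                counts[eid] = counts.get(eid, 0) + c
        return counts


# A walk is a list of steps; step = (edge, forward) where forward means the
# edge copy is traversed from .u to .v.  The start vertex is kept because
# loops make the vertex sequence ambiguous otherwise.
@dataclass
class _Walk:
    start: Vertex
    steps: list
    closed: bool

    def vertex_after(self, i: int) -> Vertex:
        e, fwd = self.steps[i]
        return e.v if fwd else e.u

    def vertices(self) -> list[Vertex]:
        out = [self.start]
        for i in range(len(self.steps)):
            out.append(self.vertex_after(i))
        return out


def extract_tours(graph: IntervalAdjacencyGraph, mu: dict[int, int],
                  seed: int | None = None) -> TourDecomposition:
    """Decompose the multiplicity multigraph into alternating tours.

    Requires :func:`is_eulerizable` to hold; every edge ``e`` is traversed
    exactly ``mu[e.id]`` times over all tours and leftover cycles.
    """
    ok, diag = is_eulerizable(graph, mu)
    if not ok:
        raise ValueError(f"assignment is not Eulerizable: "
                         f"unbalanced vertices {sorted(diag.unbalanced)}")
    rng = np.random.default_rng(seed) if seed is not None else None

    # Half-stubs: (edge, copy, endindex).  endindex 0 is the stub at e.u,
    # endindex 1 the stub at e.v; a loop has both stubs at the same vertex.
    stubs_at: dict[Vertex, dict[str, list]] = {}
    for e in sorted(graph.edges, key=lambda e: e.id):
        for copy in range(mu.get(e.id, 0)):
            for endidx, v in ((0, e.u), (1, e.v)):
                bucket = stubs_at.setdefault(v, {"I": [], "N": []})
                bucket["I" if e.kind == KIND_INTERVAL else "N"].append(
                    (e, copy, endidx))

    partner: dict[tuple, tuple] = {}
    endpoints: list[tuple] = []
    for v in sorted(stubs_at, key=str):
        iv_stubs = stubs_at[v]["I"]
        ni_stubs = stubs_at[v]["N"]
        if rng is not None:
            rng.shuffle(iv_stubs)
            rng.shuffle(ni_stubs)
        if len(iv_stubs) != len(ni_stubs) and v not in graph.telomeres:
            raise AssertionError(f"unbalanced stub counts at balanced vertex {v}")
        k = min(len(iv_stubs), len(ni_stubs))
        for a, b in zip(iv_stubs[:k], ni_stubs[:k]):
            partner[_sid(a)] = b
            partner[_sid(b)] = a
        endpoints.extend(iv_stubs[k:])
        endpoints.extend(ni_stubs[k:])

    visited: set[tuple] = set()

    def walk_from(stub) -> _Walk:
        e, copy, endidx = stub
        start = e.u if endidx == 0 else e.v
        first = (e.id, copy)
        steps = []
        while True:
            visited.add((e.id, copy))
            steps.append((e, endidx == 0))
            nxt = partner.get((e.id, copy, 1 - endidx))
            if nxt is None:
                return _Walk(start, steps, closed=False)
            e, copy, endidx = nxt
            if (e.id, copy) == first:
                return _Walk(start, steps, closed=True)

    walks: list[_Walk] = []
    for stub in endpoints:
        e, copy, _endidx = stub
        if (e.id, copy) in visited:
            continue  # already traced from this path's other endpoint
        walks.append(walk_from(stub))

    cycles: list[_Walk] = []
    for e in sorted(graph.edges, key=lambda e: e.id):
        for copy in range(mu.get(e.id, 0)):
            if (e.id, copy) not in visited:
                cycles.append(walk_from((e, copy, 0)))

    # Splice cycles into telomere-anchored tours (or into other cycles, so
    # chains of cycles eventually reach a tour) at shared vertices.
    changed = True
    while changed and cycles:
        changed = False
        for cyc in list(cycles):
            host = _find_host(walks, cyc) or \
                _find_host([c for c in cycles if c is not cyc], cyc)
            if host is not None:
                _splice(host, cyc)
                cycles.remove(cyc)
                changed = True

    decomposition = TourDecomposition(
        tours=[_to_blocks(w) for w in walks],
        leftover_cycles=[_to_blocks(w) for w in cycles])
    if cycles:
        logger.warning("%d closed cycle(s) could not be attached to any "
                       "telomere-anchored tour", len(cycles))
    return decomposition


def _sid(stub):
    e, copy, endidx = stub
    return (e.id, copy, endidx)


def _find_host(walks, cyc: _Walk) -> _Walk | None:
    cyc_vs = set(cyc.vertices())
    for w in walks:
        if cyc_vs & set(w.vertices()):
            return w
    return None


def _splice(host: _Walk, cyc: _Walk) -> None:
    """Insert a closed alternating walk into ``host`` at a shared vertex.

    Alternation is preserved by rotating the cycle to the shared vertex and
    reversing it when edge types would clash at a junction; a reversed
    alternating closed walk is still alternating, and a closed alternating
    walk also alternates across its wrap-around, so first and last steps
    always differ in type.
    """
    hv = host.vertices()
    if host.closed:
        hv = hv[:-1]
    cv = cyc.vertices()[:-1]
    share = None
    for hi, v in enumerate(hv):
        if v in cv:
            share = (hi, cv.index(v))
            break
    if share is None:
        raise AssertionError("splice called without a shared vertex")
    hi, ci = share
    rotated = cyc.steps[ci:] + cyc.steps[:ci]

    def is_interval(step):
        return step[0].kind == KIND_INTERVAL

    if host.closed:
        incoming = host.steps[hi - 1]  # wraps via negative index at hi == 0
        outgoing = host.steps[hi % len(host.steps)]
    else:
        incoming = host.steps[hi - 1] if hi > 0 else None
        outgoing = host.steps[hi] if hi < len(host.steps) else None

    clash = (incoming is not None and is_interval(incoming) == is_interval(rotated[0])) \
        or (incoming is None and outgoing is not None
            and is_interval(rotated[-1]) == is_interval(outgoing))
    if clash:
        rotated = [(e, not f) for e, f in reversed(rotated)]
    host.steps[hi:hi] = rotated


def _to_blocks(w: _Walk) -> BlockSequence:
    blocks = []
    for e, fwd in w.steps:
        if e.kind == KIND_INTERVAL:
            blocks.append(e.interval_index if fwd else -e.interval_index)
    end = w.vertex_after(len(w.steps) - 1) if w.steps else w.start
    return BlockSequence(blocks, w.start, end, closed=w.closed, steps=w.steps)


def spell_genome(tour: BlockSequence, names: dict[int, str] | None = None) -> str:
    """Render a block sequence, e.g. ``"A -B C D C D"``.

    ``names`` maps interval index to label; unnamed indices render as the
    index itself.  Reversing a tour renders the sign-flipped mirror image.
    """
    parts = []
    for b in tour.blocks:
        label = names.get(abs(b), str(abs(b))) if names else str(abs(b))
        parts.append(("-" if b < 0 else "") + label)
    return " ".join(parts)


def letter_names(graph: IntervalAdjacencyGraph) -> dict[int, str]:
    """A..Z labels for small graphs (handy for toy examples)."""
    if len(graph.intervals) > 26:
        return {}
    return {iv.index: string.ascii_uppercase[i]
            for i, iv in enumerate(graph.intervals)}
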