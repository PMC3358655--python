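"""Domain model: reference intervals, novel adjacencies, and the interval-adjacency graph.

A rearranged (cancer) genome is described against a reference genome by

* a partition of each reference chromosome into intervals ``I_1 .. I_n``,
  cut at the breakpoints of candidate novel adjacencies;
* a set of novel adjacencies, each joining two oriented interval ends
  (the junctions created by structural variants); and
* a per-interval concordant read-depth profile.

These are assembled into the *interval-adjacency graph*: every interval
contributes two vertices (its start ``s_j`` and end ``t_j``) joined by an
interval edge; reference edges join consecutive intervals on a chromosome
(``t_j`` to ``s_{j+1}``); variant edges encode the novel adjacencies.
Chromosome-terminal vertices form the telomeric set ``T`` and are exempt
from the copy-number balance condition.  An optional artificial vertex
``sigma`` models telomere loss: chromosome ends deleted in the tumor
without any novel adjacency, detected from drops in concordant coverage.

Coordinates are 0-based half-open internally; conversion to/from the
1-based inclusive convention happens only at file boundaries (see
:mod:`prego.fileio`).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sides of an interval an adjacency can attach to.
SIDE_START = "start"
SIDE_END = "end"
_SIDE_RANK = {SIDE_START: 0, SIDE_END: 1}

#: Vertex naming: ("s", j) is the start vertex of interval j, ("t", j) its
#: end vertex.  SIGMA is the artificial telomere-loss vertex.
Vertex = tuple
SIGMA: Vertex = ("sigma", 0)

KIND_INTERVAL = "I"
KIND_REFERENCE = "R"
KIND_VARIANT = "V"

SOURCE_MEASURED = "measured"
SOURCE_TELOMERE_LOSS = "telomere-loss"
SOURCE_SIM_TRUE = "simulated-true"
SOURCE_SIM_FALSE = "simulated-false"


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class CoordinateError(InputError):
    """A breakpoint coordinate falls outside its chromosome."""


class ConsistencyError(InputError):
    """Cross-references between structures do not line up."""


@dataclass(frozen=True)
class Interval:
    """A reference-genome segment ``[start, end)`` with global 1-based index."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(
                f"interval {self.chrom}:{self.start}-{self.end} has non-positive length"
            )
        if self.index < 1:
            raise InputError("interval indices are 1-based")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Adjacency:
    """A novel junction between two oriented interval ends.

    Each end is a pair ``(interval_index, side)`` with side ``"start"`` or
    ``"end"``; side ``"end"`` attaches to the ``t`` vertex, ``"start"`` to
    the ``s`` vertex.  Ends are stored in canonical order so that an
    adjacency has a unique key; ``end1 == end2`` marks an inverted-repeat
    self-junction (a loop in the graph).
    """

    end1: tuple
    end2: tuple
    support: int = 1
    source: str = SOURCE_MEASURED

    def __post_init__(self):
        for end in (self.end1, self.end2):
            if end[1] not in _SIDE_RANK:
                raise InputError(f"bad adjacency side {end[1]!r}")
        if self.source == SOURCE_MEASURED and self.support < 1:
            raise InputError("measured adjacencies need support >= 1")
        if self._key(self.end1) > self._key(self.end2):
            e1, e2 = self.end1, self.end2
            object.__setattr__(self, "end1", e2)
            object.__setattr__(self, "end2", e1)

    @staticmethod
    def _key(end):
        return (end[0], _SIDE_RANK[end[1]])

    @property
    def key(self):
        return (self._key(self.end1), self._key(self.end2))

    @property
    def is_loop(self) -> bool:
        return self.end1 == self.end2


@dataclass(frozen=True)
class Edge:
    """One edge of the interval-adjacency graph."""

    id: int
    kind: str  # "I", "R" or "V"
    u: Vertex
    v: Vertex
    interval_index: int | None = None
    support: int = 0
    source: str = SOURCE_MEASURED

    @property
    def is_loop(self) -> bool:
        return self.u == self.v

    def other(self, vertex: Vertex) -> Vertex:
        return self.v if vertex == self.u else self.u


@dataclass
class DepthProfile:
    """Per-interval concordant-pair counts with the diploid baseline ``tau``."""

    r: np.ndarray
    lengths: np.ndarray
    tau: float = 2.0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.r.shape != self.lengths.shape:
            raise InputError("depth vector and interval lengths differ in size")
        if np.any(self.r < 0):
            raise InputError("negative read counts")
        if np.any(self.lengths <= 0):
            raise InputError("non-positive interval length")

    @property
    def N(self) -> float:
        """Total concordant pairs."""
        return float(self.r.sum())

    @property
    def L_R(self) -> float:
        """Total reference length covered by the intervals."""
        return float(self.lengths.sum())

    @classmethod
    def from_intervals(cls, intervals: Sequence[Interval], counts, tau: float = 2.0):
        return cls(np.asarray(counts, dtype=float),
                   np.array([iv.length for iv in intervals], dtype=float), tau)


class IntervalAdjacencyGraph:
    """The interval-adjacency graph: interval, reference and variant edges.

    Vertices are the interval endpoints ``("s", j)`` / ``("t", j)`` plus,
    after telomere-loss detection, the artificial vertex ``SIGMA``.
    ``telomeres`` collects the vertices exempt from copy-number balance.
    """

    def __init__(self, intervals: Sequence[Interval], edges: Sequence[Edge],
                 telomeres: Iterable[Vertex]):
        self.intervals = list(intervals)
        self.edges = list(edges)
        self.telomeres = set(telomeres)
        self._by_index = {iv.index: iv for iv in self.intervals}
        self._interval_edge: dict[int, Edge] = {}
        self._at: dict[Vertex, list[Edge]] = {}
        for e in self.edges:
            if e.kind == KIND_INTERVAL:
                self._interval_edge[e.interval_index] = e
            self._at.setdefault(e.u, []).append(e)
            if not e.is_loop:
                self._at.setdefault(e.v, []).append(e)

    # -- accessors ---------------------------------------------------------
    @property
    def has_sigma(self) -> bool:
        return SIGMA in self.telomeres

    def interval(self, index: int) -> Interval:
        return self._by_index[index]

    def interval_edge(self, index: int) -> Edge:
        return self._interval_edge[index]

    def edges_at(self, v: Vertex) -> list[Edge]:
        return self._at.get(v, [])

    def interval_edge_at(self, v: Vertex) -> Edge | None:
        for e in self.edges_at(v):
            if e.kind == KIND_INTERVAL:
                return e
        return None

    def reference_edge_at(self, v: Vertex) -> Edge | None:
        for e in self.edges_at(v):
            if e.kind == KIND_REFERENCE:
                return e
        return None

    def variant_edges_at(self, v: Vertex) -> list[Edge]:
        return [e for e in self.edges_at(v) if e.kind == KIND_VARIANT]

    def edges_of_kind(self, kind: str) -> list[Edge]:
        return [e for e in self.edges if e.kind == kind]

    @property
    def vertices(self) -> list[Vertex]:
        out = []
        for iv in self.intervals:
            out.append(("s", iv.index))
            out.append(("t", iv.index))
        if self.has_sigma:
            out.append(SIGMA)
        return out

    def balance_vertices(self) -> list[Vertex]:
        """Vertices subject to the copy-number balance condition."""
        return [v for v in self.vertices if v not in self.telomeres]

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for iv in self.intervals:
            if not seen or seen[-1] != iv.chrom:
                seen.append(iv.chrom)
        return seen

    def chromosome_intervals(self, chrom: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]


@dataclass(frozen=True)
class Cluster:
    """A cluster of discordant read pairs: a candidate novel adjacency.

    Breakpoint positions are internal boundary coordinates (0-based): side
    ``"end"`` at position ``p`` means the junction uses the end of the
    interval finishing at ``p``; side ``"start"`` means it uses the start
    of the interval beginning at ``p``.
    """

    chrom1: str
    pos1: int
    side1: str
    chrom2: str
    pos2: int
    side2: str
    support: int
    source: str = SOURCE_MEASURED

    def ends(self):
        return ((self.chrom1, self.pos1, self.side1),
                (self.chrom2, self.pos2, self.side2))


def filter_adjacencies(clusters: Sequence[Cluster], min_support: int = 5,
                       centromeres: Sequence[tuple] | None = None,
                       centromere_margin: int = 1_000_000,
                       matched_normal_clusters: Sequence[Cluster] | None = None,
                       normal_slack: int = 1000) -> list[Cluster]:
    """Filter candidate adjacency clusters before graph construction.

    Keeps clusters with ``support >= min_support`` whose breakpoints are at
    least ``centromere_margin`` bases from every centromere region
    (``(chrom, start, end)`` triples) and which do not coincide with a
    matched-normal cluster.  Somatic filtering against the normal is done by
    coordinate proximity: a tumor cluster is dropped when a normal cluster
    has the same chromosome pair and both breakpoints within
    ``normal_slack`` bases (upstream read-level matching is the caller's
    job when raw alignments are available).
    """
    cent_by_chrom: dict[str, list[tuple]] = {}
    for chrom, start, end in centromeres or []:
        cent_by_chrom.setdefault(chrom, []).append((start, end))

    def near_centromere(chrom, pos):
        for start, end in cent_by_chrom.get(chrom, []):
            if start - centromere_margin <= pos < end + centromere_margin:
                return True
        return False

    normals = list(matched_normal_clusters or [])

    def in_normal(cl: Cluster) -> bool:
        for nc in normals:
            if (cl.chrom1, cl.side1, cl.chrom2, cl.side2) != \
               (nc.chrom1, nc.side1, nc.chrom2, nc.side2):
                continue
            if abs(cl.pos1 - nc.pos1) <= normal_slack and \
               abs(cl.pos2 - nc.pos2) <= normal_slack:
                return True
        return False

    kept = []
    for cl in clusters:
        if cl.support < min_support:
            logger.info("dropped cluster %s: support %d < %d",
                        _cluster_str(cl), cl.support, min_support)
            continue
        if near_centromere(cl.chrom1, cl.pos1) or near_centromere(cl.chrom2, cl.pos2):
            logger.info("dropped cluster %s: within %d of a centromere",
                        _cluster_str(cl), centromere_margin)
            continue
        if in_normal(cl):
            logger.info("dropped cluster %s: overlaps matched-normal cluster",
                        _cluster_str(cl))
            continue
        kept.append(cl)
    return kept


def _cluster_str(cl: Cluster) -> str:
    return (f"{cl.chrom1}:{cl.pos1}({cl.side1})--"
            f"{cl.chrom2}:{cl.pos2}({cl.side2})x{cl.support}")


@dataclass
class PartitionResult:
    """Intervals tiling the reference plus the index-resolved adjacencies.

    Breakpoint rejection (minimum-interval rule) removes whole adjacencies,
    so partitioning and coordinate-to-index resolution are inseparable;
    ``dropped`` records each removed cluster with the reason.
    """

    intervals: list[Interval]
    adjacencies: list[Adjacency]
    dropped: list[tuple[Cluster, str]] = field(default_factory=list)


def partition_reference(chrom_lengths, clusters: Sequence[Cluster],
                        min_interval_len: int = 8000) -> PartitionResult:
    """Cut the reference genome at adjacency breakpoints.

    ``chrom_lengths`` is an ordered mapping (or sequence of pairs) of
    chromosome name to length.  The sorted breakpoint coordinates of the
    clusters cut each chromosome into consecutive intervals.  A breakpoint
    that would create an interval shorter than ``min_interval_len`` is
    rejected together with its cluster (ties broken left to right along the
    chromosome); removal of a cluster also removes its other breakpoint,
    and acceptance is re-evaluated until stable.
    """
    if isinstance(chrom_lengths, Mapping):
        chrom_items = list(chrom_lengths.items())
    else:
        chrom_items = [(str(c), int(l)) for c, l in chrom_lengths]
    lengths = dict(chrom_items)

    for cl in clusters:
        for chrom, pos, side in cl.ends():
            if chrom not in lengths:
                raise InputError(f"unknown chromosome {chrom!r}")
            L = lengths[chrom]
            if not (0 <= pos <= L):
                raise CoordinateError(
                    f"breakpoint {chrom}:{pos} outside chromosome of length {L}")
            if (pos == 0 and side == SIDE_END) or (pos == L and side == SIDE_START):
                raise CoordinateError(
                    f"breakpoint {chrom}:{pos}({side}) has no interval on that side")

    surviving = list(clusters)
    dropped: list[tuple[Cluster, str]] = []
    while True:
        cuts: dict[str, set[int]] = {c: set() for c in lengths}
        for cl in surviving:
            for chrom, pos, side in cl.ends():
                if 0 < pos < lengths[chrom]:
                    cuts[chrom].add(pos)
        rejected: set[tuple[str, int]] = set()
        for chrom, cset in cuts.items():
            L = lengths[chrom]
            prev = 0
            for c in sorted(cset):
                if c - prev >= min_interval_len and L - c >= min_interval_len:
                    prev = c
                else:
                    rejected.add((chrom, c))
        if not rejected:
            break
        still = []
        for cl in surviving:
            bad = [
                (chrom, pos) for chrom, pos, _side in cl.ends()
                if (chrom, pos) in rejected
            ]
            if bad:
                reason = (f"breakpoint {bad[0][0]}:{bad[0][1]} violates "
                          f"min interval length {min_interval_len}")
                logger.info("dropped cluster %s: %s", _cluster_str(cl), reason)
                dropped.append((cl, reason))
            else:
                still.append(cl)
        surviving = still

    intervals: list[Interval] = []
    index = 0
    boundaries: dict[str, list[int]] = {}
    for chrom, L in chrom_items:
        cset = set()
        for cl in surviving:
            for c2, pos, _side in cl.ends():
                if c2 == chrom and 0 < pos < L:
                    cset.add(pos)
        bounds = [0] + sorted(cset) + [L]
        boundaries[chrom] = bounds
        for a, b in zip(bounds[:-1], bounds[1:]):
            index += 1
            intervals.append(Interval(chrom, a, b, index))

    start_at: dict[tuple[str, int], int] = {}
    end_at: dict[tuple[str, int], int] = {}
    for iv in intervals:
        start_at[(iv.chrom, iv.start)] = iv.index
        end_at[(iv.chrom, iv.end)] = iv.index

    collapsed: dict[tuple, Adjacency] = {}
    for cl in surviving:
        ends = []
        for chrom, pos, side in cl.ends():
            if side == SIDE_END:
                ends.append((end_at[(chrom, pos)], SIDE_END))
            else:
                ends.append((start_at[(chrom, pos)], SIDE_START))
        adj = Adjacency(ends[0], ends[1], support=cl.support, source=cl.source)
        if adj.key in collapsed:
            prev = collapsed[adj.key]
            collapsed[adj.key] = replace(prev, support=prev.support + adj.support)
        else:
            collapsed[adj.key] = adj
    adjacencies = [collapsed[k] for k in sorted(collapsed)]
    return PartitionResult(intervals, adjacencies, dropped)


def build_graph(intervals: Sequence[Interval],
                adjacencies: Sequence[Adjacency]) -> IntervalAdjacencyGraph:
    """Assemble the interval-adjacency graph.

    One interval edge ``(s_j, t_j)`` per interval, reference edges between
    consecutive intervals of the same chromosome, one variant edge per
    adjacency (identical adjacencies collapse with summed support), and the
    telomeric set made of the two terminal vertices of every chromosome.
    """
    ivs = sorted(intervals, key=lambda iv: iv.index)
    if [iv.index for iv in ivs] != list(range(1, len(ivs) + 1)):
        raise ConsistencyError("interval indices must be consecutive from 1")
    known = {iv.index for iv in ivs}

    edges: list[Edge] = []
    eid = 0
    for iv in ivs:
        edges.append(Edge(eid, KIND_INTERVAL, ("s", iv.index), ("t", iv.index),
                          interval_index=iv.index))
        eid += 1
    for a, b in zip(ivs[:-1], ivs[1:]):
        if a.chrom == b.chrom:
            edges.append(Edge(eid, KIND_REFERENCE, ("t", a.index), ("s", b.index)))
            eid += 1

    collapsed: dict[tuple, Adjacency] = {}
    for adj in adjacencies:
        for idx, _side in (adj.end1, adj.end2):
            if idx not in known:
                raise ConsistencyError(
                    f"adjacency references missing interval {idx}")
        if adj.key in collapsed:
            prev = collapsed[adj.key]
            collapsed[adj.key] = replace(prev, support=prev.support + adj.support)
        else:
            collapsed[adj.key] = adj
    for key in sorted(collapsed):
        adj = collapsed[key]
        u = _end_vertex(adj.end1)
        v = _end_vertex(adj.end2)
        edges.append(Edge(eid, KIND_VARIANT, u, v, support=adj.support,
                          source=adj.source))
        eid += 1

    telomeres: set[Vertex] = set()
    for chrom in dict.fromkeys(iv.chrom for iv in ivs):
        chrom_ivs = [iv for iv in ivs if iv.chrom == chrom]
        telomeres.add(("s", chrom_ivs[0].index))
        telomeres.add(("t", chrom_ivs[-1].index))
    return IntervalAdjacencyGraph(ivs, edges, telomeres)


def _end_vertex(end) -> Vertex:
    idx, side = end
    return ("t", idx) if side == SIDE_END else ("s", idx)


def detect_telomere_loss(graph: IntervalAdjacencyGraph, depth: DepthProfile,
                         drop_ratio_threshold: float = 0.5) -> IntervalAdjacencyGraph:
    """Detect telomere loss from drops in normalized concordant coverage.

    Telomere loss leaves no novel adjacency, so it is found from read depth:
    at each reference boundary where the ratio of normalized depths
    ``min(d_j, d_{j+1}) / max(d_j, d_{j+1})`` falls below the threshold and
    the lower-depth side runs to its chromosome end without any variant edge
    that could explain the drop, the artificial telomeric vertex ``sigma``
    is added and joined by a variant edge to the boundary vertex of the
    retained (higher-depth) flank.  Returns the input graph unchanged when
    no qualifying drop exists.
    """
    if len(depth.r) != len(graph.intervals):
        raise InputError("depth profile not aligned with graph intervals")
    d = depth.r / depth.lengths
    by_index = {iv.index: i for i, iv in enumerate(graph.intervals)}

    attach: list[Vertex] = []
    for chrom in graph.chromosomes():
        ivs = graph.chromosome_intervals(chrom)
        for k in range(len(ivs) - 1):
            a, b = ivs[k], ivs[k + 1]
            da, db = d[by_index[a.index]], d[by_index[b.index]]
            hi, lo = max(da, db), min(da, db)
            if hi <= 0:
                continue
            if lo / hi >= drop_ratio_threshold:
                continue
            if da > db:  # loss runs rightwards to the chromosome end
                lost = ivs[k + 1:]
                boundary = ("t", a.index)
                retained = da
            else:
                lost = ivs[:k + 1]
                boundary = ("s", b.index)
                retained = db
            # the depression must persist to the chromosome end: a dip that
            # recovers is a missed internal deletion, not telomere loss
            if any(d[by_index[iv.index]] >= drop_ratio_threshold * retained
                   for iv in lost):
                continue
            explained = bool(graph.variant_edges_at(boundary))
            for iv in lost:
                if graph.variant_edges_at(("s", iv.index)) or \
                   graph.variant_edges_at(("t", iv.index)):
                    explained = True
                    break
            if not explained:
                attach.append(boundary)

    if not attach:
        return graph
    edges = list(graph.edges)
    eid = max(e.id for e in edges) + 1
    for v in attach:
        edges.append(Edge(eid, KIND_VARIANT, SIGMA, v, source=SOURCE_TELOMERE_LOSS))
        eid += 1
    telomeres = set(graph.telomeres) | {SIGMA}
    return IntervalAdjacencyGraph(graph.intervals, edges, telomeres)


def count_concordant(intervals: Sequence[Interval],
                     fragments: Sequence[tuple]) -> np.ndarray:
    """Count fragments fully contained in each interval.

    ``fragments`` are ``(chrom, start, end)`` triples in internal 0-based
    half-open coordinates; a fragment counts toward the unique interval that
    contains it entirely.
    """
    counts = np.zeros(len(intervals), dtype=float)
    starts: dict[str, list[int]] = {}
    idx_of: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        starts.setdefault(iv.chrom, []).append(iv.start)
        ends.setdefault(iv.chrom, []).append(iv.end)
        idx_of.setdefault(iv.chrom, []).append(i)
    for chrom, fstart, fend in fragments:
        if chrom not in starts:
            continue
        pos = bisect_left(starts[chrom], fstart + 1) - 1
        if pos >= 0 and fend <= ends[chrom][pos]:
            counts[idx_of[chrom][pos]] += 1
    return counts
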