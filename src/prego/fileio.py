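"""Readers and writers for the tool's tab-separated interchange formats.

All TSVs open with a ``#prego-format=1`` stamp followed by a header line;
readers reject unstamped or malformed files rather than guessing.  File
coordinates are 1-based inclusive (BED-style files keep BED's 0-based
half-open convention); conversion to the internal 0-based half-open
representation happens here and only here.  Writers emit deterministic
row and column order.

Formats
-------
chrom lengths   name <tab> length (two leading columns of a .fai work)
clusters        chrom1 pos1 side1 chrom2 pos2 side2 support, sides in {s, e}
depth           interval index <tab> concordant count
centromeres     BED (chrom, start, end)
graph           edge list: type in {I, R, V}, id, endpoints, interval
                coordinates (I rows), support/source (V rows)
multiplicities  edge id, edge type, mu
"""

from __future__ import annotations

import csv
from typing import Iterable, Sequence

import numpy as np

from .model import (KIND_INTERVAL, KIND_REFERENCE, KIND_VARIANT, SIGMA,
                    Cluster, DepthProfile, InputError, Interval,
                    IntervalAdjacencyGraph, Edge)

FORMAT_STAMP = "#prego-format=1"

_SIDE_IN = {"s": "start", "e": "end"}
_SIDE_OUT = {"start": "s", "end": "e"}


class FormatError(InputError):
    """A file does not conform to its declared format."""


def _open_rows(path):
    with open(path, newline="") as fh:
        first = fh.readline().rstrip("\n")
        if first != FORMAT_STAMP:
            raise FormatError(f"{path}: missing '{FORMAT_STAMP}' stamp "
                              f"(got {first!r})")
        reader = csv.reader(fh, delimiter="\t")
        return list(reader)


def _write_rows(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(FORMAT_STAMP + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def read_chrom_lengths(path) -> dict[str, int]:
    """Chromosome name/length pairs from a plain TSV (no stamp; .fai-like)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: need name and length")
            try:
                out[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length") from exc
    return out


def read_clusters(path) -> list[Cluster]:
    """Discordant-pair clusters from a BEDPE-like TSV.

    Columns: chrom1, pos1, side1, chrom2, pos2, side2, support; positions
    are 1-based and denote the last base of the interval for side ``e``,
    the first base for side ``s``.
    """
    rows = _open_rows(path)
    if not rows or rows[0][:7] != ["chrom1", "pos1", "side1", "chrom2",
                                   "pos2", "side2", "support"]:
        raise FormatError(f"{path}: bad or missing cluster header")
    out = []
    for lineno, row in enumerate(rows[1:], 3):
        if not row:
            continue
        if len(row) < 7:
            raise FormatError(f"{path}:{lineno}: expected 7 columns, "
                              f"got {len(row)}")
        c1, p1, s1, c2, p2, s2, sup = row[:7]
        for s in (s1, s2):
            if s not in _SIDE_IN:
                raise FormatError(f"{path}:{lineno}: side must be s or e, "
                                  f"got {s!r}")
        try:
            p1i, p2i, supi = int(p1), int(p2), int(sup)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer field") from exc
        out.append(Cluster(c1, _pos_to_boundary(p1i, s1), _SIDE_IN[s1],
                           c2, _pos_to_boundary(p2i, s2), _SIDE_IN[s2], supi))
    return out


def write_clusters(path, clusters: Sequence[Cluster]) -> None:
    rows = []
    for cl in clusters:
        rows.append([cl.chrom1, _boundary_to_pos(cl.pos1, _SIDE_OUT[cl.side1]),
                     _SIDE_OUT[cl.side1],
                     cl.chrom2, _boundary_to_pos(cl.pos2, _SIDE_OUT[cl.side2]),
                     _SIDE_OUT[cl.side2], cl.support])
    _write_rows(path, ["chrom1", "pos1", "side1", "chrom2", "pos2", "side2",
                       "support"], rows)


def _pos_to_boundary(pos: int, side: str) -> int:
    # side 'e': pos is the last included base -> half-open end == pos
    # side 's': pos is the first base (1-based) -> 0-based start == pos - 1
    return pos if side == "e" else pos - 1


def _boundary_to_pos(boundary: int, side: str) -> int:
    return boundary if side == "e" else boundary + 1


def read_centromeres(path) -> list[tuple]:
    """Centromere regions from BED (0-based half-open, no stamp)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: need chrom/start/end")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_intervals_bed(path, intervals: Sequence[Interval]) -> None:
    """Intervals as BED with the global index in the name column."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.index}\n")


def read_depth(path, intervals: Sequence[Interval],
               tau: float = 2.0) -> DepthProfile:
    rows = _open_rows(path)
    if not rows or rows[0][:2] != ["interval", "count"]:
        raise FormatError(f"{path}: bad or missing depth header")
    counts = {}
    for lineno, row in enumerate(rows[1:], 3):
        if not row:
            continue
        try:
            counts[int(row[0])] = float(row[1])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: bad depth row") from exc
    missing = [iv.index for iv in intervals if iv.index not in counts]
    if missing:
        raise FormatError(f"{path}: no count for interval(s) {missing[:5]}")
    return DepthProfile.from_intervals(
        intervals, [counts[iv.index] for iv in intervals], tau)


def write_depth(path, intervals: Sequence[Interval], r) -> None:
    _write_rows(path, ["interval", "count"],
                [[iv.index, int(x)] for iv, x in zip(intervals, r)])


_VERTEX_SIGMA = "sigma"


def _vertex_str(v) -> str:
    if v == SIGMA:
        return _VERTEX_SIGMA
    return f"{v[0]}:{v[1]}"


def _parse_vertex(s: str):
    if s == _VERTEX_SIGMA:
        return SIGMA
    side, idx = s.split(":")
    if side not in ("s", "t"):
        raise FormatError(f"bad vertex {s!r}")
    return (side, int(idx))


def write_graph(path, graph: IntervalAdjacencyGraph) -> None:
    """Edge-list TSV; interval rows carry the reference coordinates."""
    rows = []
    order = {KIND_INTERVAL: 0, KIND_REFERENCE: 1, KIND_VARIANT: 2}
    for e in sorted(graph.edges, key=lambda e: (order[e.kind], e.id)):
        if e.kind == KIND_INTERVAL:
            iv = graph.interval(e.interval_index)
            extra = [iv.chrom, iv.start, iv.end]
        else:
            extra = ["", "", ""]
        rows.append([e.kind, e.id, _vertex_str(e.u), _vertex_str(e.v),
                     *extra, e.support, e.source])
    _write_rows(path, ["type", "id", "end1", "end2", "chrom", "start", "end",
                       "support", "source"], rows)


def read_graph(path) -> IntervalAdjacencyGraph:
    rows = _open_rows(path)
    if not rows or rows[0][:4] != ["type", "id", "end1", "end2"]:
        raise FormatError(f"{path}: bad or missing graph header")
    intervals = []
    edges = []
    has_sigma = False
    for lineno, row in enumerate(rows[1:], 3):
        if not row:
            continue
        kind, eid, u, v, chrom, start, end, support, source = row[:9]
        uu, vv = _parse_vertex(u), _parse_vertex(v)
        has_sigma = has_sigma or SIGMA in (uu, vv)
        interval_index = None
        if kind == KIND_INTERVAL:
            interval_index = uu[1]
            intervals.append(Interval(chrom, int(start), int(end),
                                      interval_index))
        elif kind not in (KIND_REFERENCE, KIND_VARIANT):
            raise FormatError(f"{path}:{lineno}: unknown edge type {kind!r}")
        edges.append(Edge(int(eid), kind, uu, vv,
                          interval_index=interval_index,
                          support=int(support) if support else 0,
                          source=source))
    intervals.sort(key=lambda iv: iv.index)
    telomeres = set()
    for chrom in dict.fromkeys(iv.chrom for iv in intervals):
        chrom_ivs = [iv for iv in intervals if iv.chrom == chrom]
        telomeres.add(("s", chrom_ivs[0].index))
        telomeres.add(("t", chrom_ivs[-1].index))
    if has_sigma:
        telomeres.add(SIGMA)
    return IntervalAdjacencyGraph(intervals, edges, telomeres)


def write_mu(path, graph: IntervalAdjacencyGraph, mu: dict[int, int]) -> None:
    order = {KIND_INTERVAL: 0, KIND_REFERENCE: 1, KIND_VARIANT: 2}
    rows = [[e.id, e.kind, mu[e.id]]
            for e in sorted(graph.edges, key=lambda e: (order[e.kind], e.id))]
    _write_rows(path, ["id", "type", "mu"], rows)


def read_mu(path) -> dict[int, int]:
    rows = _open_rows(path)
    if not rows or rows[0][:3] != ["id", "type", "mu"]:
        raise FormatError(f"{path}: bad or missing multiplicity header")
    out = {}
    for lineno, row in enumerate(rows[1:], 3):
        if not row:
            continue
        try:
            out[int(row[0])] = int(row[2])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: bad multiplicity row") from exc
    return out


def write_annotations(path, annotations) -> None:
    rows = [[a.edge_id, a.geometry,
             a.reciprocal_partner if a.reciprocal_partner is not None else "",
             int(a.trivial), int(a.used), a.multiplicity]
            for a in sorted(annotations, key=lambda a: a.edge_id)]
    _write_rows(path, ["edge_id", "geometry", "partner", "trivial", "used",
                       "mu"], rows)


def read_annotations(path):
    from .variants import VariantAnnotation
    rows = _open_rows(path)
    if not rows or rows[0][:6] != ["edge_id", "geometry", "partner",
                                   "trivial", "used", "mu"]:
        raise FormatError(f"{path}: bad or missing annotation header")
    out = []
    for row in rows[1:]:
        if not row:
            continue
        out.append(VariantAnnotation(
            int(row[0]), row[1], int(row[2]) if row[2] else None,
            bool(int(row[3])), bool(int(row[4])), int(row[5])))
    return out


def write_dot(path, graph: IntervalAdjacencyGraph,
              mu: dict[int, int] | None = None) -> None:
    """GraphViz DOT export; interval edges bold, variant edges red."""
    style = {KIND_INTERVAL: 'style=bold',
             KIND_REFERENCE: 'color=gray',
             KIND_VARIANT: 'color=red'}
    with open(path, "w") as fh:
        fh.write("graph interval_adjacency {\n")
        for v in graph.vertices:
            shape = "doublecircle" if v in graph.telomeres else "circle"
            fh.write(f'  "{_vertex_str(v)}" [shape={shape}];\n')
        for e in sorted(graph.edges, key=lambda e: e.id):
            label = e.kind if mu is None else f"{e.kind}:{mu.get(e.id, 0)}"
            fh.write(f'  "{_vertex_str(e.u)}" -- "{_vertex_str(e.v)}" '
                     f'[label="{label}" {style[e.kind]}];\n')
        fh.write("}\n")
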