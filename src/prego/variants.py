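"""Classification of variant edges and the reciprocal-usage association test.

Variant edges are classified by geometry from the interval ends they join:
within a chromosome, a forward junction ``t_p -- s_q`` (p < q) is a
deletion-type edge, a back junction ``s_p -- t_q`` a tandem-duplication-type
edge, and a junction of two same-type ends (t--t or s--s) an inversion-type
edge; a self-junction at one vertex is an inverted-repeat loop, the
signature of breakage/fusion/bridge amplification.  Between chromosomes,
joining opposite end types preserves both chromosome orientations (a
classical translocation) while joining matching end types flips one (a
Robertsonian translocation).

Each adjacency cuts the reference at two breakpoints, freeing the four
interval ends ``t_p, s_{p+1}, t_q, s_{q+1}``.  When a second variant edge
joins the two ends the first one left free — as in an inversion with both
junctions detected, or a reciprocal translocation — the two edges form a
*reciprocal pair*.  A reciprocal pair with equal multiplicities on both
edges and on both flanking interval-edge pairs is *trivial*: zeroing both
variant edges and adding their multiplicity to the two spanned reference
edges changes neither feasibility nor the likelihood, so the pair carries
no copy-number signal.

The association between an edge being used (multiplicity > 0) and being
(non-trivially) reciprocal is scored per geometry class with a two-sided
Fisher exact test (summation of hypergeometric probabilities no larger
than the observed table's).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from .model import (KIND_VARIANT, SIGMA, SOURCE_TELOMERE_LOSS, Edge,
                    IntervalAdjacencyGraph)

GEOM_DELETION = "deletion"
GEOM_TANDEM_DUP = "tandem-duplication"
GEOM_INVERSION = "inversion"
GEOM_CLASSICAL_TRANSLOCATION = "classical-translocation"
GEOM_ROBERTSONIAN_TRANSLOCATION = "robertsonian-translocation"
GEOM_LOOP = "inverted-repeat-loop"
GEOM_TELOMERE_LOSS = "telomere-loss"

#: classes entered into the usage-association test (the reciprocal-capable
#: geometries); deletion- and duplication-type edges are reported as their
#: own classes
TESTED_CLASSES = (GEOM_INVERSION, GEOM_CLASSICAL_TRANSLOCATION,
                  GEOM_ROBERTSONIAN_TRANSLOCATION)


def classify_geometry(graph: IntervalAdjacencyGraph, edge: Edge) -> str:
    """Geometry class of one variant edge (see module docstring)."""
    if edge.kind != KIND_VARIANT:
        raise ValueError("only variant edges are classifiable")
    if SIGMA in (edge.u, edge.v) or edge.source == SOURCE_TELOMERE_LOSS:
        return GEOM_TELOMERE_LOSS
    if edge.is_loop:
        return GEOM_LOOP
    (side_a, ja), (side_b, jb) = sorted((edge.u, edge.v), key=lambda v: v[1])
    chrom_a = graph.interval(ja).chrom
    chrom_b = graph.interval(jb).chrom
    if chrom_a != chrom_b:
        if side_a != side_b:
            return GEOM_CLASSICAL_TRANSLOCATION
        return GEOM_ROBERTSONIAN_TRANSLOCATION
    if side_a == side_b:
        return GEOM_INVERSION
    if side_a == "t":  # forward junction skips [p+1, q-1]
        return GEOM_DELETION
    return GEOM_TANDEM_DUP


def _breakpoint(graph: IntervalAdjacencyGraph, v) -> int | None:
    """Breakpoint index p (between intervals p and p+1) adjacent to vertex v.

    Vertex ``t_p`` sits at breakpoint p; so does vertex ``s_{p+1}``.  Returns
    None at chromosome ends, where only one flanking interval exists.
    """
    side, j = v
    p = j if side == "t" else j - 1
    try:
        left, right = graph.interval(p), graph.interval(p + 1)
    except KeyError:
        return None
    if left.chrom != right.chrom:
        return None
    return p


def find_reciprocal_pairs(graph: IntervalAdjacencyGraph) -> list[tuple[int, int]]:
    """Pair up variant edges that cover the four ends of the same two breakpoints.

    Two variant edges are partners iff they touch the same two breakpoints
    and take complementary ends at each (together covering
    ``{t_p, s_{p+1}, t_q, s_{q+1}}`` with no vertex shared).  When several
    pairings are possible the lexicographically smallest (by edge-id pair)
    is chosen greedily; every edge has at most one partner.
    """
    candidates: dict[tuple, list[Edge]] = {}
    for e in graph.edges_of_kind(KIND_VARIANT):
        if e.is_loop or SIGMA in (e.u, e.v):
            continue
        bu, bv = _breakpoint(graph, e.u), _breakpoint(graph, e.v)
        if bu is None or bv is None or bu == bv:
            continue
        candidates.setdefault(tuple(sorted((bu, bv))), []).append(e)

    pairs: list[tuple[int, int]] = []
    for _bps, edges in sorted(candidates.items()):
        edges = sorted(edges, key=lambda e: e.id)
        taken: set[int] = set()
        for i, a in enumerate(edges):
            if a.id in taken:
                continue
            for b in edges[i + 1:]:
                if b.id in taken:
                    continue
                if {a.u, a.v} & {b.u, b.v}:
                    continue
                # complementary ends at both breakpoints
                if {a.u, a.v} | {b.u, b.v} == _four_ends(graph, a, b):
                    pairs.append((a.id, b.id))
                    taken.update((a.id, b.id))
                    break
    return sorted(pairs)


def _four_ends(graph, a: Edge, b: Edge) -> set:
    ends = set()
    for v in (a.u, a.v):
        p = _breakpoint(graph, v)
        ends.update((("t", p), ("s", p + 1)))
    return ends


def is_trivial(graph: IntervalAdjacencyGraph, pair: tuple[int, int],
               mu: dict[int, int]) -> bool:
    """A reciprocal pair is trivial when zeroing it cannot change the likelihood.

    Requires equal multiplicity on the two variant edges and on each of the
    two flanking interval-edge pairs.
    """
    by_id = {e.id: e for e in graph.edges}
    a, b = by_id[pair[0]], by_id[pair[1]]
    if mu[a.id] != mu[b.id]:
        return False
    for v in (a.u, a.v):
        p = _breakpoint(graph, v)
        if mu[graph.interval_edge(p).id] != mu[graph.interval_edge(p + 1).id]:
            return False
    return True


def zero_trivial_pair(graph: IntervalAdjacencyGraph, pair: tuple[int, int],
                      mu: dict[int, int]) -> dict[int, int]:
    """The triviality transformation: zero the pair, reroute through reference.

    Sets both variant multiplicities to zero and adds their common value to
    the reference edge spanning each of the two breakpoints; on a trivial
    pair this preserves every balance residual and the likelihood exactly.
    """
    by_id = {e.id: e for e in graph.edges}
    a, b = by_id[pair[0]], by_id[pair[1]]
    k = mu[a.id]
    out = dict(mu)
    out[a.id] = 0
    out[b.id] = 0
    for v in (a.u, a.v):
        p = _breakpoint(graph, v)
        ref = graph.reference_edge_at(("t", p))
        out[ref.id] = out[ref.id] + k
    return out


@dataclass(frozen=True)
class VariantAnnotation:
    edge_id: int
    geometry: str
    reciprocal_partner: int | None
    trivial: bool
    used: bool
    multiplicity: int


def annotate_variants(graph: IntervalAdjacencyGraph,
                      mu: dict[int, int]) -> list[VariantAnnotation]:
    """Per-variant-edge annotation: geometry, partnership, triviality, usage."""
    partner_of: dict[int, int] = {}
    for a, b in find_reciprocal_pairs(graph):
        partner_of[a] = b
        partner_of[b] = a
    out = []
    for e in graph.edges_of_kind(KIND_VARIANT):
        partner = partner_of.get(e.id)
        trivial = False
        if partner is not None:
            trivial = is_trivial(graph, tuple(sorted((e.id, partner))), mu)
        out.append(VariantAnnotation(e.id, classify_geometry(graph, e),
                                     partner, trivial,
                                     used=mu.get(e.id, 0) > 0,
                                     multiplicity=mu.get(e.id, 0)))
    return out


def fisher_two_sided(table) -> tuple[float, bool]:
    """Two-sided Fisher exact p on a 2x2 table; degenerate margins give p = 1.

    The two-sided convention sums hypergeometric probabilities of tables
    no more probable than the observed one (conditional on the margins).
    """
    (a, b), (c, d) = table
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if 0 in rows or 0 in cols:
        return 1.0, True
    return float(fisher_exact([[a, b], [c, d]]).pvalue), False


def usage_association_test(annotations,
                           classes=TESTED_CLASSES) -> pd.DataFrame:
    """Per-class usage counts and the reciprocal-vs-non-reciprocal Fisher test.

    For each geometry class the 2x2 table crosses {non-trivial reciprocal,
    non-reciprocal} with {used, unused}; trivial reciprocal edges are
    tallied but excluded from the test, since their usage is likelihood-
    neutral by construction.
    """
    rows = []
    for cls in classes:
        anns = [a for a in annotations if a.geometry == cls]
        recip = [a for a in anns if a.reciprocal_partner is not None]
        nontriv = [a for a in recip if not a.trivial]
        nonrec = [a for a in anns if a.reciprocal_partner is None]
        table = [[sum(a.used for a in nontriv), sum(not a.used for a in nontriv)],
                 [sum(a.used for a in nonrec), sum(not a.used for a in nonrec)]]
        p, degenerate = fisher_two_sided(table)
        rows.append({
            "class": cls,
            "R_all_used": sum(a.used for a in recip),
            "R_all_unused": sum(not a.used for a in recip),
            "R_nontrivial_used": table[0][0],
            "R_nontrivial_unused": table[0][1],
            "NR_used": table[1][0],
            "NR_unused": table[1][1],
            "p_value": p,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)
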