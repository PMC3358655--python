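"""Shared fixtures: toy graphs and random-instance generators.

The four-interval toy ("A -B C D C D") is the canonical worked example: a
single chromosome cut into intervals A..D, with an inverted segment B and
a duplicated tail C D, described by three variant edges and copy numbers
(1, 1, 2, 2).
"""

from __future__ import annotations

import numpy as np
import pytest

from prego import (Adjacency, DepthProfile, Interval, build_graph,
                   LikelihoodParams)


def make_intervals(n, chrom="chr1", length=100, start_index=1):
    return [Interval(chrom, i * length, (i + 1) * length, start_index + i)
            for i in range(n)]


@pytest.fixture
def toy_graph():
    """Four intervals A..D with the inversion pair and the duplication back-edge."""
    ivs = make_intervals(4)
    adjs = [Adjacency((1, "end"), (2, "end")),
            Adjacency((2, "start"), (3, "start")),
            Adjacency((3, "start"), (4, "end"))]
    return build_graph(ivs, adjs)


@pytest.fixture
def toy_counts():
    return [1, 1, 2, 2]


@pytest.fixture
def toy_depth(toy_graph, toy_counts):
    # tau reflects the mean copy number of the toy's rearranged genome
    # (6 blocks over 4 reference intervals -> 1.5), so that depths
    # proportional to copy numbers are exactly the model's expectations
    r = [100 * c for c in toy_counts]
    return DepthProfile.from_intervals(toy_graph.intervals, r, tau=1.5)


def random_small_instance(rng, max_variant_edges=3, mu_max=3):
    """A random interval-adjacency graph with at most 6 edges plus a depth draw.

    Used for solver-versus-oracle equivalence and tour conservation; read
    counts are drawn so that different multiplicities are plausible.
    """
    n = int(rng.integers(2, 4))
    n_chrom = 1 if n == 2 else int(rng.integers(1, 3))
    ivs = []
    idx = 0
    sizes = [n] if n_chrom == 1 else [1, n - 1]
    for ci, size in enumerate(sizes):
        for k in range(size):
            idx += 1
            ivs.append(Interval(f"chr{ci + 1}", k * 100, (k + 1) * 100, idx))
    base_edges = n + (n - len(sizes))
    n_var = int(rng.integers(0, min(max_variant_edges, 6 - base_edges) + 1))
    ends = [(iv.index, side) for iv in ivs for side in ("start", "end")]
    adjs = []
    seen = set()
    for _ in range(n_var):
        e1 = ends[rng.integers(len(ends))]
        e2 = ends[rng.integers(len(ends))]
        adj = Adjacency(e1, e2)
        if adj.key in seen:
            continue
        seen.add(adj.key)
        adjs.append(adj)
    graph = build_graph(ivs, adjs)
    lam = rng.uniform(50, 150, n)
    target = rng.integers(0, mu_max + 1, n)
    r = np.maximum(0, rng.poisson(lam * target / 2.0)).astype(float)
    depth = DepthProfile(r, np.full(n, 100.0), tau=2.0)
    params = LikelihoodParams(lam, tau=2.0, mu_max=mu_max)
    return graph, depth, params
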