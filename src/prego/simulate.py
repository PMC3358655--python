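"""Synthetic deletion-genome generator and the contamination/noise robustness grid.

The generator emulates a tumor resequencing experiment on a diploid
genome: it plants homozygous and heterozygous deletions (lengths drawn
from a normal distribution) across autosome-proportioned chromosomes,
injects additional *false* adjacencies — each splitting an untouched
interval into three and adding a spurious deletion junction with true
multiplicity 0 — and simulates paired-end physical coverage by sampling
read-interval (fragment) start positions uniformly from the rearranged
genome.  Two error processes can be layered on the per-interval counts:

* contamination: a fraction ``rho`` of fragments is drawn from the
  unrearranged diploid reference instead of the tumor genome, as when
  normal cells dilute a tumor sample;
* depth-estimation noise: Gaussian noise ``N(0, phi * r_j)`` (variance
  proportional to the count) added to each count, then rounded and clamped
  at zero.

Because fragments are placed uniformly, per-interval counts are Poisson;
the default "fast" depth mode draws each count directly from the
equivalent Poisson mean, and a "fragments" mode enumerates fragment
placements explicitly for cross-checking.  ``run_grid`` sweeps (rho, phi),
re-infers multiplicities per trial and reports the mean percentage of
edges assigned their true multiplicity, overall and split into interval
versus reference+variant edges, plus the largest drop relative to the
noise-free cell.

Default chromosome lengths are the 22 human autosome proportions scaled to
a 300 Mb genome, which keeps a full grid at desk scale while leaving the
interval count (what the inference actually sees) identical to a
full-size genome with the same number of events.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infer import LikelihoodParams, solve_multiplicities
from .model import (KIND_INTERVAL, SOURCE_SIM_FALSE, SOURCE_SIM_TRUE,
                    Adjacency, DepthProfile, InputError, Interval,
                    IntervalAdjacencyGraph, build_graph)

# hg19 autosome lengths (Mb), used as proportions only
_AUTOSOME_MB = (249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
                115, 107, 103, 90, 81, 78, 59, 63, 48, 51)


def scaled_autosomes(total: float = 300e6) -> dict[str, int]:
    """22 chromosome lengths with human autosome proportions, given total size."""
    s = sum(_AUTOSOME_MB)
    return {f"chr{i + 1}": int(round(mb / s * total))
            for i, mb in enumerate(_AUTOSOME_MB)}


@dataclass
class SimulationParams:
    """Study conditions for the deletion-genome simulation."""

    n_hom_del: int = 100
    n_het_del: int = 100
    del_len_mean: float = 10_000.0
    del_len_sd: float = 1_000.0
    n_false_adjacencies: int = 50
    coverage: float = 30.0
    frag_len_mean: float = 200.0
    frag_len_sd: float = 10.0
    rho: float = 0.0
    phi: float = 0.0
    n_trials: int = 10
    seed: int | None = None
    genome: dict = field(default_factory=scaled_autosomes)

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise InputError("rho must lie in [0, 1]")
        if self.phi < 0:
            raise InputError("phi must be non-negative")
        for name in ("n_hom_del", "n_het_del", "n_false_adjacencies",
                     "n_trials"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")


MU_HOM, MU_HET, MU_FALSE = 2, 1, 0


@dataclass
class GroundTruth:
    """The generated graph with its true multiplicities.

    ``true_mu`` maps edge id to the multiplicity realized by the simulated
    genome; ``false_edge_ids`` are the injected spurious adjacencies (true
    multiplicity 0); ``interval_counts`` is the copy number c_j per
    interval in graph order; ``het_edge_ids`` are the variant edges of
    heterozygous deletions (true multiplicity 1).
    """

    graph: IntervalAdjacencyGraph
    true_mu: dict[int, int]
    interval_counts: np.ndarray
    false_edge_ids: list[int]
    het_edge_ids: list[int]


def simulate_genome(params: SimulationParams,
                    rng: np.random.Generator | None = None):
    """Generate a deletion genome: intervals, adjacencies, and ground truth.

    Events (homozygous, heterozygous, false deletions) are placed by
    rejection sampling until disjoint with at least one fragment length of
    margin between events and from chromosome ends.  Returns
    ``(intervals, adjacencies, GroundTruth)``; the ground truth is asserted
    to satisfy copy-number balance at every non-telomeric vertex.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    chroms = list(params.genome.items())
    lengths = np.array([l for _c, l in chroms], dtype=float)
    margin = int(params.frag_len_mean)
    kinds = (["hom"] * params.n_hom_del + ["het"] * params.n_het_del
             + ["false"] * params.n_false_adjacencies)

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c, _l in chroms}
    events = []  # (chrom, start, end, kind)
    weights = lengths / lengths.sum()
    max_attempts = 1000 * max(1, len(kinds))
    attempts = 0
    for kind in kinds:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise InputError("genome too small for the requested events")
            ci = rng.choice(len(chroms), p=weights)
            chrom, L = chroms[ci]
            ln = int(round(rng.normal(params.del_len_mean, params.del_len_sd)))
            if ln < 1 or L < ln + 2 * margin:
                continue
            start = int(rng.integers(margin, L - ln - margin + 1))
            end = start + ln
            spans = placed[chrom]
            i = bisect_left(spans, (start, end))
            ok = True
            if i > 0 and spans[i - 1][1] + margin > start:
                ok = False
            if i < len(spans) and end + margin > spans[i][0]:
                ok = False
            if ok:
                insort(spans, (start, end))
                events.append((chrom, start, end, kind))
                break

    events.sort(key=lambda ev: ([c for c, _l in chroms].index(ev[0]), ev[1]))

    intervals: list[Interval] = []
    counts: list[int] = []
    adjacencies: list[Adjacency] = []
    event_info = []  # (variant true mu, kind, span interval index)
    index = 0
    for chrom, L in chroms:
        bounds = [0]
        chrom_events = [ev for ev in events if ev[0] == chrom]
        for _c, start, end, _k in chrom_events:
            bounds.extend((start, end))
        bounds.append(L)
        first = index + 1
        for a, b in zip(bounds[:-1], bounds[1:]):
            index += 1
            intervals.append(Interval(chrom, a, b, index))
            counts.append(2)
        for k, (_c, start, end, kind) in enumerate(chrom_events):
            span_idx = first + 1 + 2 * k  # intervals alternate gap/event
            assert intervals[span_idx - 1].start == start
            if kind == "hom":
                counts[span_idx - 1] = 0
                vmu = MU_HOM
            elif kind == "het":
                counts[span_idx - 1] = 1
                vmu = MU_HET
            else:
                vmu = MU_FALSE
            source = SOURCE_SIM_FALSE if kind == "false" else SOURCE_SIM_TRUE
            adjacencies.append(Adjacency((span_idx - 1, "end"),
                                         (span_idx + 1, "start"),
                                         support=10, source=source))
            event_info.append((vmu, kind, span_idx))

    graph = build_graph(intervals, adjacencies)
    counts_arr = np.array(counts, dtype=int)

    true_mu: dict[int, int] = {}
    for iv in graph.intervals:
        true_mu[graph.interval_edge(iv.index).id] = int(counts_arr[iv.index - 1])
    # reference edges: 2 copies traverse each boundary except next to events
    boundary_mu = {}
    for vmu, kind, span_idx in event_info:
        traversals = {"hom": 0, "het": 1, "false": 2}[kind]
        boundary_mu[span_idx - 1] = traversals  # boundary (span-1, span)
        boundary_mu[span_idx] = traversals      # boundary (span, span+1)
    for e in graph.edges:
        if e.kind == "R":
            left_index = e.u[1]
            true_mu[e.id] = boundary_mu.get(left_index, 2)

    false_ids, het_ids = [], []
    variant_edges = graph.edges_of_kind("V")
    # variant edges were built in canonical adjacency order; match by ends
    vmu_by_key = {}
    for (vmu, kind, span_idx) in event_info:
        vmu_by_key[(("t", span_idx - 1), ("s", span_idx + 1))] = (vmu, kind)
    for e in variant_edges:
        vmu, kind = vmu_by_key[(e.u, e.v)]
        true_mu[e.id] = vmu
        if kind == "false":
            false_ids.append(e.id)
        elif kind == "het":
            het_ids.append(e.id)

    truth = GroundTruth(graph, true_mu, counts_arr, false_ids, het_ids)
    _assert_balanced(truth)
    return intervals, adjacencies, truth


def _assert_balanced(truth: GroundTruth) -> None:
    from .infer import balance_residuals
    residuals = balance_residuals(truth.graph, truth.true_mu)
    bad = {v: r for v, r in residuals.items() if r != 0}
    assert not bad, f"generated ground truth violates balance at {bad}"


def simulate_depth(truth: GroundTruth, params: SimulationParams,
                   rng: np.random.Generator | None = None,
                   mode: str = "fast") -> DepthProfile:
    """Simulate per-interval concordant counts for the generated genome.

    The number of read-intervals is ``coverage * genome_length /
    frag_len_mean`` in expectation, where genome length is the total
    (diploid) tumor DNA; a fraction ``rho`` of them is placed on the
    diploid reference instead.  A read-interval counts toward ``r_j`` iff
    it falls entirely within one extant copy of interval ``I_j``.

    Modes: ``"fast"`` draws each count from its Poisson mean directly
    (uniform placement makes counts Poisson); ``"fragments"`` enumerates
    fragment placements; ``"expected"`` returns the rounded means with no
    sampling (useful for perfect-data experiments).  Gaussian depth noise
    ``N(0, phi * r_j)`` is then added, rounded, and clamped at zero.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    graph = truth.graph
    L = np.array([iv.length for iv in graph.intervals], dtype=float)
    c = truth.interval_counts.astype(float)
    f = params.frag_len_mean
    eff = np.maximum(0.0, L - f)  # start positions keeping a fragment inside

    L_tumor = float((c * L).sum())
    M = params.coverage * L_tumor / f
    tumor_w = c * eff
    ref_w = 2.0 * eff
    mean = M * ((1.0 - params.rho) * tumor_w / tumor_w.sum()
                + params.rho * ref_w / ref_w.sum())

    if mode == "expected":
        r = np.round(mean)
    elif mode == "fast":
        r = rng.poisson(mean).astype(float)
    elif mode == "fragments":
        r = _fragment_depth(graph, c, params, rng, M)
    else:
        raise InputError(f"unknown depth mode {mode!r}")

    if params.phi > 0 and mode != "expected":
        noise = rng.normal(0.0, np.sqrt(params.phi * r))
        r = np.maximum(0.0, np.round(r + noise))
    return DepthProfile(r, L, tau=2.0)


def _fragment_depth(graph, c, params, rng, M) -> np.ndarray:
    """Count fully-contained fragments by explicit placement (slow, exact)."""
    L = np.array([iv.length for iv in graph.intervals], dtype=float)

    def concatenation(copies):
        block_iv, block_len = [], []
        for i, k in enumerate(copies.astype(int)):
            block_iv.extend([i] * k)
            block_len.extend([L[i]] * k)
        ends = np.cumsum(block_len)
        return np.array(block_iv), ends

    n_frag = rng.poisson(M)
    from_ref = rng.random(n_frag) < params.rho
    counts = np.zeros(len(graph.intervals))
    for is_ref, n in ((False, int((~from_ref).sum())), (True, int(from_ref.sum()))):
        if n == 0:
            continue
        copies = np.full(len(L), 2.0) if is_ref else c
        block_iv, ends = concatenation(copies)
        total = ends[-1]
        starts = rng.uniform(0.0, total, n)
        flen = rng.normal(params.frag_len_mean, params.frag_len_sd, n)
        block = np.searchsorted(ends, starts, side="right")
        inside = starts + flen <= ends[block]
        prev_end = np.where(block > 0, ends[block - 1], 0.0)
        inside &= starts >= prev_end  # always true; guards fp edge cases
        np.add.at(counts, block_iv[block[inside]], 1)
    return counts


def score_recovery(truth: GroundTruth, inferred_mu: dict[int, int]) -> dict:
    """Percent of edges with inferred multiplicity equal to the truth.

    Reported overall and separately for interval edges and for
    reference+variant edges, plus the confusion tally of heterozygous-
    deletion variant edges over inferred multiplicities {0, 1, 2, other}.
    """
    if set(inferred_mu) != set(truth.true_mu):
        raise InputError("inferred assignment is not on the ground-truth graph")
    graph = truth.graph
    hits = {"interval": [0, 0], "ref_variant": [0, 0]}
    for e in graph.edges:
        cls = "interval" if e.kind == KIND_INTERVAL else "ref_variant"
        hits[cls][1] += 1
        if inferred_mu[e.id] == truth.true_mu[e.id]:
            hits[cls][0] += 1
    total_hit = hits["interval"][0] + hits["ref_variant"][0]
    total = hits["interval"][1] + hits["ref_variant"][1]
    confusion = {0: 0, 1: 0, 2: 0, "other": 0}
    for eid in truth.het_edge_ids:
        v = inferred_mu[eid]
        confusion[v if v in (0, 1, 2) else "other"] += 1
    return {
        "overall": 100.0 * total_hit / total,
        "interval": 100.0 * hits["interval"][0] / hits["interval"][1],
        "ref_variant": 100.0 * hits["ref_variant"][0] / hits["ref_variant"][1],
        "het_confusion": confusion,
    }


DEFAULT_RHO_GRID = (0.0, 0.1, 0.2, 0.4)
DEFAULT_PHI_GRID = (0.0, 25.0, 100.0, 400.0)


def run_trial(params: SimulationParams, rng: np.random.Generator,
              truth: GroundTruth | None = None,
              depth_mode: str = "fast") -> dict:
    """One simulate -> infer -> score run; a pre-built genome may be reused."""
    if truth is None:
        _ivs, _adj, truth = simulate_genome(params, rng)
    depth = simulate_depth(truth, params, rng, mode=depth_mode)
    lparams = LikelihoodParams.from_profile(depth)
    assignment = solve_multiplicities(truth.graph, depth, lparams)
    scores = score_recovery(truth, assignment.mu)
    scores["solver_status"] = assignment.solver_status
    return scores


def run_grid(params: SimulationParams,
             rho_values=DEFAULT_RHO_GRID,
             phi_values=DEFAULT_PHI_GRID,
             depth_mode: str = "fast") -> tuple[pd.DataFrame, dict]:
    """Sweep the (rho, phi) grid, averaging recovery over ``n_trials``.

    One genome is generated per trial index and reused across grid cells
    (so cells differ only in the error process); depth draws use
    independent substreams per cell and trial.  Returns the per-cell mean
    table and a summary with the maximum drop, in percentage points of the
    overall edge accuracy, relative to the (rho=0, phi=0) cell.
    """
    root = np.random.SeedSequence(params.seed)
    genome_seeds, depth_root = root.spawn(2)
    genome_streams = genome_seeds.spawn(params.n_trials)
    truths = []
    for t in range(params.n_trials):
        gparams = SimulationParams(**{**params.__dict__, "rho": 0.0, "phi": 0.0})
        _ivs, _adj, truth = simulate_genome(
            gparams, np.random.default_rng(genome_streams[t]))
        truths.append(truth)

    rows = []
    cell_streams = depth_root.spawn(len(rho_values) * len(phi_values))
    ci = 0
    for rho in rho_values:
        for phi in phi_values:
            cell = SimulationParams(**{**params.__dict__, "rho": rho,
                                       "phi": phi})
            trial_streams = cell_streams[ci].spawn(params.n_trials)
            ci += 1
            per_trial = []
            for t in range(params.n_trials):
                rng = np.random.default_rng(trial_streams[t])
                per_trial.append(run_trial(cell, rng, truth=truths[t],
                                           depth_mode=depth_mode))
            rows.append({
                "rho": rho,
                "phi": phi,
                "overall": float(np.mean([s["overall"] for s in per_trial])),
                "interval": float(np.mean([s["interval"] for s in per_trial])),
                "ref_variant": float(np.mean([s["ref_variant"]
                                              for s in per_trial])),
            })
    df = pd.DataFrame(rows)
    base = df[(df.rho == rho_values[0]) & (df.phi == phi_values[0])]
    summary = {}
    for col in ("overall", "interval", "ref_variant"):
        drops = float(base[col].iloc[0]) - df[col]
        summary[f"max_drop_{col}"] = float(drops.max())
    summary["baseline_overall"] = float(base["overall"].iloc[0])
    return df, summary
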