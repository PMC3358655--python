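"""Maximum-likelihood integer multiplicity assignment on the interval-adjacency graph.

Under the Lander-Waterman model, the concordant-pair count of interval
``I_j`` present ``mu_j`` times in the tumor genome is Poisson with mean
``lambda_j * mu_j / tau``, where ``lambda_j = N * L_j / L_R`` is the count
expected from a single unrearranged diploid equivalent and ``tau`` is the
copy number of an unrearranged interval (2 for autosomes).  Dropping
constants, the negative log-likelihood is

    L_r(mu) = sum_j [ lambda_j * mu_j / tau  -  r_j * log(lambda_j * mu_j / tau) ]

minimized over non-negative integer edge multiplicities subject to the
copy-number balance condition at every non-telomeric vertex ``v``:

    mu(e_I(v)) = mu(e_R(v)) + sum of mu over variant edges at v
    (a loop at v counts twice)

The discrete problem is solved exactly as an integer linear program: each
interval edge's objective term is tabulated at mu in {0, ..., mu_max} and
selected with one-hot indicator variables, so the piecewise-linear
"approximation" coincides with the true objective at every integer point.
The backend is HiGHS via :func:`scipy.optimize.milp`.  A brute-force
enumeration oracle is provided for testing on tiny graphs.

At ``mu = 0`` the log term is evaluated at a small surrogate copy number
``epsilon_copies`` (default 0.05): residual reads from normal-cell
contamination land on truly deleted intervals, so homozygous deletion must
remain selectable at finite cost rather than being forbidden outright.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import (KIND_INTERVAL, KIND_VARIANT, SIGMA, DepthProfile,
                    InputError, IntervalAdjacencyGraph)

STATUS_OPTIMAL = "optimal"
STATUS_FEASIBLE = "feasible"
STATUS_INFEASIBLE = "infeasible"


@dataclass
class LikelihoodParams:
    """Parameters of the Poisson read-depth likelihood.

    ``lam[i]`` is ``N * L_j / L_R`` for the i-th interval (graph order).
    ``mu_max`` optionally fixes a single upper bound for every edge; when
    ``None`` each interval edge gets ``max(10, ceil(4 * tau * r_j / lambda_j))``,
    generous enough that the bound never binds at the optimum.
    """

    lam: np.ndarray
    tau: float = 2.0
    mu_max: int | None = None
    epsilon_copies: float = 0.05

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        if np.any(self.lam <= 0):
            raise InputError("lambda must be positive for every interval")
        if self.mu_max is not None and self.mu_max < self.tau:
            raise InputError("mu_max must be at least tau")

    @classmethod
    def from_profile(cls, profile: DepthProfile, mu_max: int | None = None,
                     epsilon_copies: float = 0.05) -> "LikelihoodParams":
        if profile.L_R <= 0:
            raise InputError("total reference length is zero")
        if profile.N <= 0:
            raise InputError("no concordant pairs in depth profile")
        lam = profile.N * profile.lengths / profile.L_R
        return cls(lam, tau=profile.tau, mu_max=mu_max,
                   epsilon_copies=epsilon_copies)

    def interval_bounds(self, r: np.ndarray) -> np.ndarray:
        if self.mu_max is not None:
            return np.full(len(self.lam), self.mu_max, dtype=int)
        auto = np.ceil(4.0 * self.tau * np.asarray(r) / self.lam)
        return np.maximum(10, auto.astype(int))


@dataclass
class MultiplicityAssignment:
    """Integer multiplicity per edge id, with the achieved objective value."""

    mu: dict[int, int]
    objective_value: float
    solver_status: str

    def interval_copy_numbers(self, graph: IntervalAdjacencyGraph) -> np.ndarray:
        """Inferred copy number per interval, in graph order."""
        return np.array([self.mu[graph.interval_edge(iv.index).id]
                         for iv in graph.intervals])


def expected_depth(params: LikelihoodParams, j: int, mu_j: float) -> float:
    """Expected concordant-pair count of the j-th interval at multiplicity mu_j."""
    if mu_j < 0:
        raise InputError("negative multiplicity")
    return float(params.lam[j] * mu_j / params.tau)


def _term(params: LikelihoodParams, j: int, mu: int, r_j: float) -> float:
    surrogate = max(mu, params.epsilon_copies)
    return (params.lam[j] * mu / params.tau
            - r_j * math.log(params.lam[j] * surrogate / params.tau))


def neg_log_likelihood(params: LikelihoodParams, mu_intervals, r) -> float:
    """The Poisson negative log-likelihood, constant terms omitted."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InputError("negative read counts")
    mu_intervals = np.asarray(mu_intervals)
    return float(sum(_term(params, j, int(mu_intervals[j]), r[j])
                     for j in range(len(r))))


def _edge_bounds(graph: IntervalAdjacencyGraph, interval_bound: dict[int, int],
                 params: LikelihoodParams) -> dict[int, int]:
    """Upper bound per edge id: interval bound, or max over incident intervals."""
    bounds: dict[int, int] = {}
    default = max(interval_bound.values()) if interval_bound else int(params.tau)
    for e in graph.edges:
        if e.kind == KIND_INTERVAL:
            bounds[e.id] = interval_bound[e.interval_index]
        else:
            incident = [interval_bound[v[1]] for v in (e.u, e.v) if v != SIGMA]
            bounds[e.id] = max(incident) if incident else default
    return bounds


def solve_multiplicities(graph: IntervalAdjacencyGraph, profile: DepthProfile,
                         params: LikelihoodParams | None = None,
                         fixed_interval_counts=None,
                         prefer_sparse: bool = False) -> MultiplicityAssignment:
    """Minimize the Poisson objective over balanced integer multiplicities.

    With ``fixed_interval_counts`` (perfect-data mode) every interval edge
    is pinned to the given copy number and only the reference/variant
    multiplicities are solved for; an inconsistent count vector is reported
    as infeasible, never silently relaxed.  ``prefer_sparse`` adds a
    lexicographic-style secondary objective (weight 1e-6 of the objective
    scale per unit) favoring co-optimal solutions with smaller total
    variant-edge multiplicity.
    """
    if params is None:
        params = LikelihoodParams.from_profile(profile)
    n = len(graph.intervals)
    if len(profile.r) != n:
        raise InputError("depth profile not aligned with graph intervals")

    fixed = None
    if fixed_interval_counts is not None:
        fixed = np.asarray(fixed_interval_counts, dtype=int)
        if len(fixed) != n:
            raise InputError("fixed interval counts not aligned with intervals")

    ivb = {}
    raw = params.interval_bounds(profile.r)
    for i, iv in enumerate(graph.intervals):
        b = int(raw[i])
        if fixed is not None:
            b = max(b, int(fixed[i]))
        ivb[iv.index] = b
    ebound = _edge_bounds(graph, ivb, params)

    # Variable layout: one-hot indicators for each interval edge, then one
    # integer variable per non-interval edge.
    col_of_onehot: dict[int, int] = {}   # interval index -> first column
    col_of_edge: dict[int, int] = {}     # non-interval edge id -> column
    ncols = 0
    for iv in graph.intervals:
        col_of_onehot[iv.index] = ncols
        ncols += ivb[iv.index] + 1
    nonint = [e for e in graph.edges if e.kind != KIND_INTERVAL]
    for e in nonint:
        col_of_edge[e.id] = ncols
        ncols += 1

    cost = np.zeros(ncols)
    idx_of = {iv.index: i for i, iv in enumerate(graph.intervals)}
    for iv in graph.intervals:
        base = col_of_onehot[iv.index]
        i = idx_of[iv.index]
        for m in range(ivb[iv.index] + 1):
            cost[base + m] = _term(params, i, m, profile.r[i])
    if prefer_sparse:
        scale = max(1.0, float(np.max(np.abs(cost)))) if ncols else 1.0
        w = 1e-6 * scale
        for e in nonint:
            if e.kind == KIND_VARIANT:
                cost[col_of_edge[e.id]] += w

    rows, cols, vals, lo, hi = [], [], [], [], []
    nrow = 0

    def add_entry(col, val):
        rows.append(nrow)
        cols.append(col)
        vals.append(val)

    for iv in graph.intervals:
        base = col_of_onehot[iv.index]
        for m in range(ivb[iv.index] + 1):
            add_entry(base + m, 1.0)
        lo.append(1.0)
        hi.append(1.0)
        nrow += 1
        if fixed is not None:
            add_entry(base + int(fixed[idx_of[iv.index]]), 1.0)
            lo.append(1.0)
            hi.append(1.0)
            nrow += 1

    for v in graph.balance_vertices():
        ie = graph.interval_edge_at(v)
        base = col_of_onehot[ie.interval_index]
        for m in range(ivb[ie.interval_index] + 1):
            if m:
                add_entry(base + m, float(m))
        re = graph.reference_edge_at(v)
        if re is not None:
            add_entry(col_of_edge[re.id], -1.0)
        for a in graph.variant_edges_at(v):
            add_entry(col_of_edge[a.id], -2.0 if a.is_loop else -1.0)
        lo.append(0.0)
        hi.append(0.0)
        nrow += 1

    ub = np.empty(ncols)
    for iv in graph.intervals:
        base = col_of_onehot[iv.index]
        ub[base:base + ivb[iv.index] + 1] = 1.0
    for e in nonint:
        ub[col_of_edge[e.id]] = ebound[e.id]

    constraints = []
    if nrow:
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, ncols))
        constraints.append(LinearConstraint(A, np.array(lo), np.array(hi)))
    res = milp(cost, constraints=constraints,
               integrality=np.ones(ncols),
               bounds=Bounds(np.zeros(ncols), ub))

    if res.status == 2 or res.x is None:
        return MultiplicityAssignment({}, math.inf, STATUS_INFEASIBLE)
    status = STATUS_OPTIMAL if res.status == 0 else STATUS_FEASIBLE

    x = np.round(res.x).astype(int)
    mu: dict[int, int] = {}
    for iv in graph.intervals:
        base = col_of_onehot[iv.index]
        block = x[base:base + ivb[iv.index] + 1]
        mu[graph.interval_edge(iv.index).id] = int(np.argmax(block))
    for e in nonint:
        mu[e.id] = int(x[col_of_edge[e.id]])

    obj = neg_log_likelihood(
        params, [mu[graph.interval_edge(iv.index).id] for iv in graph.intervals],
        profile.r)
    return MultiplicityAssignment(mu, obj, status)


def balance_residuals(graph: IntervalAdjacencyGraph,
                      mu: dict[int, int]) -> dict:
    """Copy-number balance residual at every non-telomeric, non-sigma vertex.

    residual(v) = mu(e_I(v)) - mu(e_R(v)) - sum of mu over variant edges at v,
    with a loop at v counted twice; an assignment is feasible iff all
    residuals vanish.
    """
    out = {}
    for v in graph.balance_vertices():
        ie = graph.interval_edge_at(v)
        total = mu[ie.id]
        re = graph.reference_edge_at(v)
        if re is not None:
            total -= mu[re.id]
        for a in graph.variant_edges_at(v):
            total -= (2 if a.is_loop else 1) * mu[a.id]
        out[v] = int(total)
    return out


@dataclass
class OracleResult:
    """Exhaustive-enumeration optimum plus the full co-optimal set."""

    best: MultiplicityAssignment
    co_optimal: list[dict[int, int]] = field(default_factory=list)


def brute_force_oracle(graph: IntervalAdjacencyGraph, profile: DepthProfile,
                       params: LikelihoodParams | None = None,
                       fixed_interval_counts=None,
                       state_guard: int = 10_000_000,
                       tol: float = 1e-9) -> OracleResult:
    """Enumerate every integer assignment within bounds; keep balanced optima.

    Intended as an independent test oracle for tiny graphs; refuses when the
    state space exceeds ``state_guard``.
    """
    if params is None:
        params = LikelihoodParams.from_profile(profile)
    fixed = None
    if fixed_interval_counts is not None:
        fixed = np.asarray(fixed_interval_counts, dtype=int)

    ivb = {}
    raw = params.interval_bounds(profile.r)
    for i, iv in enumerate(graph.intervals):
        b = int(raw[i])
        if fixed is not None:
            b = max(b, int(fixed[i]))
        ivb[iv.index] = b
    ebound = _edge_bounds(graph, ivb, params)

    idx_of = {iv.index: i for i, iv in enumerate(graph.intervals)}
    edge_ids = [e.id for e in graph.edges]
    ranges = []
    states = 1
    for e in graph.edges:
        if e.kind == KIND_INTERVAL and fixed is not None:
            r = [int(fixed[idx_of[e.interval_index]])]
        else:
            r = list(range(ebound[e.id] + 1))
        ranges.append(r)
        states *= len(r)
        if states > state_guard:
            raise InputError(f"state space exceeds guard ({state_guard})")

    best_obj = math.inf
    best_mu = None
    co_opt: list[dict[int, int]] = []
    interval_edge_ids = [graph.interval_edge(iv.index).id for iv in graph.intervals]
    for combo in itertools.product(*ranges):
        mu = dict(zip(edge_ids, combo))
        if any(res != 0 for res in balance_residuals(graph, mu).values()):
            continue
        obj = neg_log_likelihood(params, [mu[i] for i in interval_edge_ids],
                                 profile.r)
        if obj < best_obj - tol:
            best_obj = obj
            best_mu = mu
            co_opt = [mu]
        elif obj <= best_obj + tol:
            co_opt.append(mu)

    if best_mu is None:
        return OracleResult(MultiplicityAssignment({}, math.inf,
                                                   STATUS_INFEASIBLE))
    return OracleResult(
        MultiplicityAssignment(best_mu, best_obj, STATUS_OPTIMAL), co_opt)
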