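# Methods

## Model

A tumor sample is assumed genetically homogeneous: one rearranged genome,
derived from the diploid reference by structural rearrangements of blocks.
The data are (i) an interval partition of the reference cut at candidate
breakpoints, (ii) novel adjacencies between oriented interval ends, and
(iii) per-interval concordant-pair counts. Heterogeneity, allele-specific
copy number and single-nucleotide variation are out of scope.

The interval-adjacency graph has vertices {sⱼ, tⱼ} per interval, one
interval edge (sⱼ, tⱼ) per interval, reference edges (tⱼ, sⱼ₊₁) between
consecutive intervals of a chromosome, and one variant edge per accepted
adjacency (identical adjacencies collapse, summing support; a
self-junction is a loop). Telomeric vertices — chromosome ends, plus the
artificial σ vertex when telomere loss is detected — are exempt from the
copy-number balance condition

    μ(e_I(v)) − μ(e_R(v)) − Σ_{a ∈ E_A(v)} μ(a) = 0,

in which a loop at v counts twice (both of its ends are incident).
Balanced integer multiplicities are exactly the edge usage counts of a
set of edge-disjoint alternating tours between telomeric vertices whose
union covers every edge e exactly μ(e) times, so a solution is always
spellable as block sequences.

Read depth follows a Lander–Waterman Poisson model: the count of interval
Iⱼ present μⱼ times has mean λⱼμⱼ/τ with λⱼ = N·Lⱼ/L_R. Counts are
genuinely over-dispersed in real data; a negative-binomial likelihood
would slot into the same tabulated objective but is not implemented.

## Inference

The negative log-likelihood (constants dropped) is separable over
interval edges; reference and variant edges carry no objective term.
Because multiplicities are integers, the objective can be represented
*exactly* in a linear program: for interval j, binary indicators z_{j,m}
(m = 0..mu_max) select one tabulated value f_j(m) = λⱼm/τ − rⱼ·log(λⱼm/τ),
with Σₘ z_{j,m} = 1 and μⱼ = Σₘ m·z_{j,m}. The MILP (HiGHS via
`scipy.optimize.milp`) therefore returns the true discrete optimum; a
brute-force enumeration oracle cross-checks this exactly on small graphs
in the test suite.

Numerical and formulation choices:

* **Zero-copy surrogate.** log(0) is undefined, so the log term at μ = 0
  is evaluated at `epsilon_copies` (default 0.05 copies). Homozygous
  deletion stays selectable at cost rⱼ·log(τ/(λⱼ·0.05)) relative terms;
  residual contamination reads over a truly deleted interval penalize,
  but do not forbid, the zero call. The default is a compromise: much
  smaller values make μ = 0 unreachable in contaminated samples, much
  larger ones blur the 0-vs-1 decision (see the contamination analysis
  below).
* **Bounds.** Per-interval upper bound max(10, ⌈4·τ·rⱼ/λⱼ⌉) — four times
  the rounded depth ratio — never binds at the optimum in practice; a
  global `mu_max` can override it. Non-interval edges inherit the larger
  bound of their incident intervals.
* **Perfect-data mode.** `fixed_interval_counts` pins every interval edge
  to a given copy number; an inconsistent vector is reported infeasible,
  never relaxed.
* **Tie-breaking.** Co-optimal assignments are common (any trivial
  reciprocal pair creates one). The solver's optimum is reported as-is;
  `prefer_sparse` adds a secondary objective of 1e-6 of the objective
  scale per unit of variant-edge multiplicity to favor sparse usage.
* **Degenerate inputs.** Zero-length intervals are rejected at
  construction, so λⱼ > 0 whenever N > 0; an all-zero depth profile is an
  input error.

## Telomere loss

Telomere loss leaves no discordant-pair signal, so it is detected from
depth: at a reference boundary where min(dⱼ, dⱼ₊₁)/max(dⱼ, dⱼ₊₁) falls
below `drop_ratio_threshold` (default 0.5, normalized depth d = r/L), and
where the depression persists from the boundary to the chromosome end
with no variant edge on the lower side or at the boundary that could
explain it, a variant edge is added from σ to the boundary vertex of the
retained (higher-depth) flank. σ joins the telomeric set once, however
many losses are found; the σ edge enters the balance condition at its
non-σ endpoint only. A dip that recovers before the chromosome end is
treated as a missed internal deletion and left alone. When both flanks of
a boundary are depressed the deeper flank retains the σ edge; attaching
to the shallower flank would instead assert loss of the deeper side,
which the depth contradicts.

## Tours

Extraction pairs, at every balanced vertex, each arrival via a
non-interval edge with a departure via the vertex's unique interval edge
(and vice versa); unpaired stubs at telomeric vertices seed open tours.
Pairing order is lowest-edge-id-first, or shuffled under a seed —
decompositions are not unique and no canonical one is promised. Closed
alternating cycles are spliced into tours at shared vertices (reversing
the cycle when edge types would clash; alternation is preserved because a
closed alternating walk alternates across its wrap-around too). Balanced
components that touch no telomere — circular or fully amplified
structures — cannot join any open tour and are emitted as
`leftover_cycles` with a warning rather than an error.

## Variant classification and the usage test

Within a chromosome, a variant edge tₚ–s_q (p < q) is deletion-type,
sₚ–t_q tandem-duplication-type, two same-type ends inversion-type, and a
self-junction an inverted-repeat loop (the breakage/fusion/bridge
signature). Between chromosomes, opposite end types preserve both
orientations (classical translocation); matching end types flip one
(Robertsonian). Edges into σ are reported as telomere-loss and excluded
from classification and pairing.

Two variant edges are reciprocal partners when they cover the four free
ends {tₚ, sₚ₊₁, t_q, s_q₊₁} of the same two breakpoints with no shared
vertex; with several candidates the lexicographically smallest edge-id
pair wins, and an edge has at most one partner. Loops and edges whose
ends sit at a chromosome terminus (where one flanking interval is
missing) cannot partner. A pair is *trivial* when μ(A) = μ(A′) and both
flanking interval pairs match; zeroing such a pair and adding its
multiplicity to the two spanned reference edges preserves balance and —
because only interval edges carry objective terms — the likelihood,
exactly.

The usage association test builds, per geometry class (inversions and the
two translocation classes; deletion- and duplication-type edges are
tallied as their own classes rather than folded in), the 2×2 table of
{non-trivial reciprocal, non-reciprocal} × {used, unused} and computes
the two-sided Fisher exact p-value by summing hypergeometric
probabilities no greater than the observed table's. Trivial pairs are
excluded from the test because their usage is likelihood-neutral by
construction. A table with an empty margin reports p = 1 with a
degeneracy flag.

## Simulator

The generator emulates a tumor resequencing study at fixed, documented
conditions: 100 homozygous and 100 heterozygous deletions with lengths
N(10 kb, 1 kb), placed disjointly (margin of one fragment length from
each other and from chromosome ends) over 22 chromosomes with human
autosome proportions scaled to 300 Mb total; 50 false adjacencies, each
splitting an intact interval into three with a spurious deletion junction
of true multiplicity 0; fragment coverage of 30× with lengths
N(200 bp, 10 bp). Scaling the genome down keeps a full sweep at desk
scale while leaving what inference actually sees — the number of
intervals and edges, and per-interval depth statistics — identical to a
full-size genome with the same event count; a 3 Gb genome is available
behind `--full-genome`.

Error processes: a fraction ρ of fragments is drawn from the unrearranged
diploid reference (normal-cell contamination); Gaussian noise N(0, φ·rⱼ)
— variance proportional to the count — is added to each count, rounded,
and clamped at zero (counts cannot be negative; the clamp slightly biases
extreme-noise cells upward). Uniform fragment placement makes
per-interval counts Poisson, so the default fast mode draws each count
from its Poisson mean directly; a fragment-enumeration mode exists and
agrees with the fast mode in mean within sampling error (tested), and an
"expected" mode returns rounded means for perfect-data experiments. The
simulator produces deletions only: amplifications, inversions and
translocations are not simulated, no raw sequence is generated, and
fragment mappability/GC structure is absent — passing recovery tests here
demonstrates correctness of the inference machinery under the stated
model, not calling performance on real libraries.

`run_grid` sweeps ρ ∈ {0, 0.1, 0.2, 0.4} × φ ∈ {0, 25, 100, 400}
(defaults), 10 trials per cell, reusing one genome per trial index across
cells so that cells differ only in the error process, and reports mean
percent-correct per edge class plus the largest drop from the (0, 0)
cell.

### Contamination limits homozygous-deletion recovery

A homozygously deleted interval still receives contamination reads at
rate ρ·λⱼ. The objective difference between μ = 1 and μ = 0 for one
interval is λⱼ/τ − rⱼ·ln(1/ε), so the zero call wins iff
rⱼ/λⱼ < 1/(τ·ln(1/ε)); with τ = 2 and ε = 0.05 that is
rⱼ/λⱼ < 1/(2·ln 20) ≈ 0.167, i.e. ρ ≲ 0.17.
Beyond that, *every* homozygous deletion is called at one copy, which
also forces the flanking reference edges and the deletion's variant edge
away from their true values: roughly four miscalled edges per event,
about 31% of all edges at the default event counts, independent of genome
size. The grid's ρ = 0.2 and ρ = 0.4 cells therefore sit past an
identifiability boundary of the likelihood itself, and the measured
maximum drop over the default grid (≈ 45 percentage points, dominated by
those cells) reflects that boundary rather than solver error. At
ρ ≤ 0.1 errors are instead dominated by heterozygous-deletion edges
drifting between multiplicities 0 and 2 as φ grows.

## Known limitations

* Poisson depth only; no over-dispersion, mappability or GC correction.
* One genome per sample: no subclonal mixture deconvolution (ρ models
  normal contamination, not tumor heterogeneity).
* Tour decompositions and ILP optima are generally non-unique; reported
  reconstructions are one consistent choice.
* BAM/CRAM ingestion and discordant-pair clustering are upstream concerns;
  inputs are tabular summaries.
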