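# prego

Reconstruction of the block organization of rearranged (cancer) genomes
from paired-end sequencing summaries: an interval partition of the
reference genome, novel adjacencies from clustered discordant read pairs,
and per-interval concordant read depth.

Cancer genomes are scramblings of intervals ("blocks") of the germline
genome, produced by deletions, duplications, inversions, translocations
and more complex rearrangements. Given

* a partition **I** = (I₁, …, Iₙ) of the reference into intervals cut at
  rearrangement breakpoints,
* a set *A* of novel adjacencies, each joining two oriented interval ends,
* a read-depth vector **r** = (r₁, …, rₙ) of concordant pairs per interval,

`prego` finds the tumor genome(s) most consistent with these data. It
builds the *interval-adjacency graph*: each interval contributes vertices
sⱼ, tⱼ joined by an interval edge; reference edges join consecutive
intervals (tⱼ, sⱼ₊₁); variant edges encode the novel adjacencies.
Chromosome-terminal vertices are *telomeric*; an optional vertex σ models
telomere loss detected from sustained drops in normalized coverage.

Under a Poisson read-depth model the expected count for interval Iⱼ
present μⱼ times is λⱼ μⱼ/τ, with λⱼ = N·Lⱼ/L_R (N total concordant
pairs, Lⱼ interval length, L_R reference length) and τ the ploidy of an
unrearranged interval (2 for autosomes). The tool minimizes the negative
log-likelihood

    L_r(μ) = Σⱼ [ λⱼ μⱼ/τ − rⱼ·log(λⱼ μⱼ/τ) ]

over non-negative **integer** multiplicities μ(e) on all edges, subject to
the copy-number balance condition at every non-telomeric vertex v:

    μ(e_I(v)) = μ(e_R(v)) + Σ_{a ∈ E_A(v)} μ(a)      (loops count twice)

solved exactly as an integer linear program (objective tabulated per
integer copy number and selected by one-hot indicators; HiGHS backend).
By a Kotzig-type argument, any balanced assignment turns the multigraph
into a union of edge-disjoint *alternating Eulerian tours* — walks
alternating interval and non-interval edges between telomeric vertices —
each of which spells a block sequence of the tumor genome. Variant edges
are then classified (deletion-type, tandem-duplication-type,
inversion-type, classical vs Robertsonian translocation, inverted-repeat
loops typical of breakage/fusion/bridge amplification), reciprocal edge
pairs and likelihood-neutral ("trivial") pairs are identified, and the
association between reciprocality and usage is scored with a two-sided
Fisher exact test.

A built-in simulator generates deletion genomes (homozygous and
heterozygous deletions plus false adjacencies on autosome-proportioned
chromosomes), simulates fragment coverage with contamination and
depth-noise processes, and scores how many edges recover their true
multiplicity.

## Worked example

A single chromosome cut into four intervals A–D, with copy numbers
(1, 1, 2, 2), an inverted segment B and a duplicated tail C D:

```python
from prego import *

intervals = [Interval("chr1", i * 100, (i + 1) * 100, i + 1) for i in range(4)]
adjacencies = [Adjacency((1, "end"), (2, "end")),      # inversion junction
               Adjacency((2, "start"), (3, "start")),  # inversion junction
               Adjacency((3, "start"), (4, "end"))]    # duplication back-edge
graph = build_graph(intervals, adjacencies)

# depths proportional to copy number; tau=1.5 is this toy genome's mean
# copy number (6 blocks over 4 reference intervals)
depth = DepthProfile.from_intervals(graph.intervals, [100, 100, 200, 200],
                                    tau=1.5)
result = solve_multiplicities(graph, depth, fixed_interval_counts=[1, 1, 2, 2])
print(result.interval_copy_numbers(graph))   # [1 1 2 2]

decomposition = extract_tours(graph, result.mu)
print(spell_genome(decomposition.tours[0], letter_names(graph)))
# A -B C D C D
```

The spelled tour is one rearranged genome consistent with the data: A,
then B inverted, then C D duplicated. The optimum is not unique — zeroing
the two inversion variant edges and rerouting through reference edges
leaves the likelihood unchanged and spells `A B C D C D`; this is exactly
a *trivial reciprocal pair*, which `annotate_variants` flags.

The Fisher helper reproduces usage-association p-values from a 2×2 table
of (non-trivial reciprocal vs non-reciprocal) × (used vs unused) edges:

```python
from prego import fisher_two_sided
fisher_two_sided([[2, 0], [3, 12]])   # (0.0735..., False)
```

## Command line

```sh
prego simulate --seed 5 -o sim/                 # synthetic deletion genome
prego build --fai genome.tsv --clusters clusters.tsv -o graph.tsv
prego infer --graph graph.tsv --depth depth.tsv -o mu.tsv
prego tours --graph graph.tsv --mu mu.tsv -o tours.txt
prego classify --graph graph.tsv --mu mu.tsv -o annotations.tsv
prego assoc --annotations annotations.tsv -o assoc.tsv
prego grid --seed 1 -o grid.tsv                 # robustness sweep
```

Exit codes: 0 success, 2 input error, 3 infeasible.

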