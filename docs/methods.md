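# Methods

This note records the models, conventions and numerical choices behind the
package, in the order data flows through it.

## Panel and input contract

A probe panel is an ordered list of probes; the order is the single source of
truth for every copy-number vector (cell rows, signal patterns, clone
genotypes, tree nodes). Exactly two probes must carry the
`centromere_control` role: the per-nucleus ploidy baseline is defined from
their pair of counts, so panels without both controls are rejected outright.
The shipped default is the 10-probe liver panel (MYC 8q24, FHIT 3p14, CCND1
11q13, TERT 5p15, TP53 17p13, MET 7q31, HER2 17q12, WWOX 16q23, CEP3, CEP10).
Each fluor is shared by two probes, which therefore belong to different
hybridization panels; the shipped panel-1/panel-2 assignment follows that
fluor-reuse constraint.

Count tables are UTF-8 TSV with a header (`sample_id`, `cell_id`, one column
per probe, optional `qc`); `.xlsx` with the same columns is accepted because
counting is usually recorded in spreadsheets. Probe columns may appear in any
order and are re-ordered on read. Counts are non-negative integers; an empty
cell marks the nucleus `missing_signal`. Counts above 16 are accepted with a
logged warning — near-16n signal numbers occur, but are rare enough that a
high count more often indicates a counting artifact.

QC is nucleus-level and absolute: a nucleus flagged `overlapping`,
`damaged_or_incomplete` or `missing_signal` contributes to no statistic.
No minimum number of reviewed nuclei is imposed; the instability index is
reported against whatever denominator survives QC.

## Ploidy and coding

Two distinct per-nucleus mappings are kept deliberately separate:

- **ploidy reference** (for gain/loss coding): round-half-up mean of the two
  centromere counts, minimum 1. A 3/3-centromere nucleus is coded against
  ploidy 3, so a triploid-balanced cell shows no spurious gains.
- **ploidy class** (for the 2n/4n/8n grouping used by polyploidy metrics and
  the color charts): nearest of {2, 4, 8} to the centromere mean, ties toward
  the lower class (mean 3.0 → 2n, mean 6.0 → 4n). Means above 6 are all 8n.

A nucleus with both centromere counts zero has no baseline and is excluded
(logged), like a QC failure.

Coding is strict comparison against the reference; centromere probes are
never coded. Patterns are keyed on the *full* count vector including the
centromeres, so balanced diploid and balanced tetraploid nuclei are distinct
patterns — required for grouping clones by ploidy.

## Clonality, instability, modes

The clonality threshold is strictly greater than 2% of analyzed nuclei
(6/300 is not clonal, 7/300 is). The denominator is all QC-passed,
ploidy-assignable nuclei, not the aberrant subset, because the threshold is
defined per nuclei in the sample. The instability index
(patterns per 100 nuclei) likewise uses all analyzed nuclei; it is reported
to one decimal, with the unrounded value kept internally. Low vs high
diversification splits at 6 clonal patterns.

Two analysis modes control only the clone-level *reporting* filter:

- `hcc`: balanced nuclei of class 2n/4n are treated as normal liver or
  stromal cells and excluded from gene-level clone calls (balanced 8n nuclei
  stay in the aberrant pool);
- `nafld`: the ploidy-first screen of biopsies; balanced nuclei of any class
  including 8n count as (polyploid) normals.

Per-gene clone calls take the direction from the most frequent reportable
clonal pattern in which the gene is non-neutral.

NAS scores are binned 1–2 / 3–4 / ≥5; zeros fall outside the published
categories and are reported in a separate bucket with a warning rather than
silently merged.

## Synthetic data

The simulator emulates exactly the structure the analysis assumes: a clone
tree rooted at the all-diploid genotype, children differing from their parent
by single-gene-probe ±1 steps optionally preceded by a whole-genome doubling
(at most two per lineage), supplied clone frequencies, and independent
per-probe miscount noise of at most one unit per probe per cell: −1 with
`p_drop` (floored at zero), +1 with `p_split`. Defaults are `p_drop = 0.05`,
`p_split = 0.02`: hybridization dropout exceeds split-signal artifacts in
interphase FISH, but no measured rates exist for this assay, so both are
conventions and configurable. Frequencies are supplied (or
Dirichlet-distributed by the tree generator), not evolved — the data being
emulated report clone frequencies but no growth model.

What the simulator does **not** emulate: binucleated hepatocytes (the
cytospin preparation captures mononuclear polyploidy only), spatial/zonation
structure, cell-cycle or endoreplication dynamics, probe-specific efficiency
differences, and segmental events spanning multiple probes. Passing recovery
tests therefore demonstrate correctness of the statistics under the stated
noise model, not robustness to every failure mode of real hybridizations.

Everything is reproducible from the config seed via `numpy.random.default_rng`.

## Clone phylogenies

Nodes are genotype vectors; the root is always the all-diploid genotype, kept
as an inferred ancestor even when no diploid clone is observed. An edge
carrying `k` doublings costs `wgd_cost*k + step_cost * Σ|child − 2^k·parent|`
with the doubling applied before the residual steps; defaults cost 1 per step
and 1 per doubling (the relative weighting is a declared convention,
configurable). At most two doublings on any root-to-leaf path; a third
doubling to 16n is excluded by construction, so 16n genotypes are reachable
only by unit steps beyond 8n. There is no ploidy-reduction event by default —
the data offer no support for evolution from polyploid back to diploid
clones — but a halving event can be enabled
(`EditModel.allow_ploidy_reduction`) for experimentation with `edit_cost`.

`build_tree` minimizes total cost over tree topologies, per-edge doubling
counts, and inserted Steiner genotypes:

- per-edge doubling counts are always optimal for a given topology, via a
  dynamic program over the remaining per-path budget;
- the search runs from two deterministic starts (greedy sequential
  attachment, and a star from the root, which favors staged-doubling chains)
  and keeps the cheaper fixpoint;
- local moves: steepest-descent subtree re-attachment and parent/child
  rotations; insertion of Steiner candidates (doubled/halved/quartered images
  of observed patterns, component-wise medians of triples over the observed
  patterns and their doubled images, and pre-doubling staging points derived
  from current doubled edges); coordinate-descent re-positioning of Steiner
  nodes; pruning of Steiner nodes that stop paying for themselves.
  Insertions that leave the cost unchanged (or within one event cost) are
  explored further with a re-attachment pass, since staged-doubling optima
  are often reachable only through cost-neutral intermediates.
- all tie-breaks are deterministic (fewer doublings, lexicographically
  smaller vectors), so results depend only on the input order and model.

`brute_force_tree` is the exact companion: the problem is a minimum Steiner
arborescence in the graph whose vertices are (genotype, doublings-used) pairs
on a bounded grid and whose edges are elementary events; it is solved exactly
with the Dreyfus–Wagner subset dynamic program, using Dijkstra closures on
the sparse event graph. The per-coordinate grid cap is twice the largest
observed value (at most 12): a genotype above that bound is dominated,
because unit steps only ever move toward terminals and doubling from above
the cap overshoots further. Bounds (≤5 distinct patterns, ≤4 probes, counts
≤6) keep the state space small; the solver refuses anything larger. On 1,000
random bounded instances the heuristic matched the exact optimum in every
case; this is a verification result, not a guarantee for arbitrary inputs.

A doubling edge is classified **equivalent** iff the child equals the doubled
parent exactly (zero post-doubling steps), else **accumulated**; a sample
shows polyploidization iff its tree contains a doubling edge, and is labelled
accumulated iff any doubling edge is. When an edge with a residual step ties
with a staged alternative (double an unobserved intermediate, then step), the
pruning rule collapses the cost-neutral intermediate, so the direct
(accumulated) reading is reported.

## Cohort layer

Aggregates are standard pandas statistics (sd with n−1). Percentages are
rounded half-up to integers. Median dichotomization puts samples *strictly
above* the median in the high group, which reproduces the published 5-case
high-instability group on the transcribed case table. The association test
is Fisher's exact (two-sided); the original report does not name its test,
and its p = 0.03 for grade is not reproduced by Fisher's exact on the
transcribed table (p = 0.08) — the package asserts the group structure, not
that p-value. Spearman correlations are provided for continuous
histology-vs-index comparisons but carry no reference values. Gene-level
frequencies are computed from per-sample clone annotations (`MYC+`, `TP53-`
token lists for major/minor clones); a sample counts once per gene-direction
regardless of how many clones carry the change.

The shipped fixtures are transcriptions of the two published case tables.
Two transcription-level discrepancies are documented here rather than
patched: the case table's minimum average ploidy is 2.05 while the narrative
quotes a range from 2.07, and the narrative mean instability 25 ± 11.4
recomputes to 24.18 from the column (the median, 24.08, matches the quoted
24). Tests assert the recomputed values.

## Problem sizes

The test suite and the acceptance script use: 2,000-cell samples for clone
recovery (five clones at 40/25/15/12/8%), 200 random instances for
heuristic-vs-exact tree verification, 1,000 random genotypes for doubling
fidelity, and 40 constructed cases for polyploidization classification.
These sizes give comfortable statistical margins (the smallest clone expects
160 cells, an order of magnitude above the clonality threshold) while
keeping a full run in minutes on one CPU.

## Known limitations

- Counts are treated as exact integers; there is no probabilistic model of
  counting error in the statistics themselves (the noise model lives in the
  simulator and in the interpretation of results).
- The tree search is a verified heuristic, exact only as far as tested;
  instances far outside the verified regime (many probes, counts ≫ 6, many
  patterns) may yield suboptimal trees.
- Gene-level cohort frequencies depend on user-supplied clone annotations,
  not on re-derived per-cell data.
- Single-probe resolution cannot distinguish whole-chromosome from focal
  events except where two probes share a chromosome (3p/3cen, 17p/17q).
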