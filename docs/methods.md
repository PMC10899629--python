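# Methods

This note records what the package computes, the conventions it fixes
where the underlying procedures admit more than one reading, and what the
synthetic data do and do not emulate.

## Connectivity model

A dataset is a directed weighted graph over a fixed roster of 180 neurons
(69 sensory, 73 interneurons, 38 motor neurons; muscles, glia and
unconnected cells are excluded from analysis matrices by default, and
autapses are always dropped).  `W[i, j]` is the summed size of all
synapses from neuron *i* onto neuron *j*; an entry of zero means "no
connection", never "a connection of weight zero".

**Normalisation.** Weights are divided by the population standard
deviation of the dataset's nonzero weights after removing values strictly
above their 95th percentile (linear-interpolation convention).  Fixing
"population SD" and "strictly above the interpolated percentile" makes
the scale factor reproducible; only nonzero weights enter the statistic.
The same trim-SD rule normalizes contact-area matrices (applied to the
nonzero contact areas; a literal connection-weight divisor remains
available through `nervering.core.trimmed_sd` for cross-checks).
Normalisation requires at least two distinct retained weights; anything
less raises a degenerate-scale error rather than silently dividing by
zero.

**Binarisation.** An edge exists where the weight strictly exceeds a
floor (default 0).  Wiring-diagram exports accept a positive floor on
normalized weights to drop the weakest edges, reproducing the diagram
convention of excluding edges below the mean individual synapse weight.

## Graph metrics

Degrees count post-/presynaptic partners on the binarized graph; typed
out-degrees restrict both endpoints to one of the 9 (pre type → post
type) classes, with a cross-ensemble filter that drops neurons silent in
every dataset.  Path lengths are directed shortest paths with unit edge
costs; a source's mean path length averages over the nodes it reaches,
and sources reaching nothing are excluded (the procedure behind
published per-dataset *n* values varying with the network is not spelled
out anywhere we know of; reachability-based exclusion is this package's
documented choice).  Clustering uses the simple undirected projection —
a reciprocal pair collapses to one edge — with neighbor pairs counted as
connected if joined in either direction; nodes of undirected degree < 2
are reported as NaN, never divided by zero.

## Stage comparison

Comparisons operate on binarized matrices.  Connection similarity for
neuron *i* between stages is `exp(−d)` with `d` the Euclidean distance of
the two 180-long binary outgoing rows (for binary vectors, the square
root of the Hamming distance).  Neurons with no outgoing connection in
either dataset of a pair are excluded from that pair; group values
average a neuron over its group's dataset pairs (three adult-adult pairs
versus three dauer-adult pairs in the standard design), and groups are
compared with a two-sided Wilcoxon rank-sum test.  The test uses exact
enumeration for tie-free samples smaller than 25 per side and the normal
approximation with tie correction (no continuity correction) otherwise;
the exact path is validated in the tests against an exhaustive
permutation oracle.

## Motifs

Every unordered neuron triple is classified into one of the 16 directed
triad classes via a 64-entry lookup table built from first principles
(dyad counts plus orientation rules) and cross-checked exhaustively
against an independent graph-library implementation in the tests.
Triangular motifs are the seven classes with no null dyad.  The
triangular proportion defaults to the analyzed subnetwork's own
`C(n, 3)` denominator; a whole-network denominator (e.g. 180) is
available by flag since the alternative reading exists.  Nulls are
directed Erdős–Rényi graphs matched on n and `p = |E| / (n (n−1))`,
self-loops excluded, 1000 repetitions by default; under this null each
unordered pair is connected with probability `q = 1 − (1−p)²` and the
expected triangular proportion is `q³`, which the tests verify by
simulation.

## Topology

**Vulnerability** removes directed edges one at a time in a uniformly
random order, measuring the number of weakly connected components and
the largest component's node count after every removal, averaged over
100 repetitions.  Internally each repetition is computed by adding the
edges back in reverse order with a union-find structure — exactly
equivalent, and linear instead of quadratic in the edge count.

**Modules** are detected on the 97-node graph obtained by merging
left-right homolog pairs (weights summed; intra-pair connections land on
the diagonal and are ignored downstream).  Clauset–Newman–Moore greedy
modularity maximization runs on the undirected projection, binarized by
default with a weighted mode available (which of the two the published
4-module result used is not stated; neither is asserted).  Single-neuron
modules are excluded from the report.  Module similarity is the Jaccard
index.

**Hubs** are neurons whose out-degree strictly exceeds the mean (over
100 repetitions) of the maximum out-degree of matched ER networks.  The
ER maxima are sampled directly as maxima of iid Binomial(n−1, p) draws,
which is exact for directed ER out-degrees.

## Voxel contact areas

Contact is face adjacency (6-connectivity): each voxel pair with labels
(A, B) sharing a face contributes that face's area once — `dy·dz` for
x-neighbors, `dx·dz` for y, `dx·dy` for z.  Default voxel dimensions are
(2, 2, 50) nm, overridable.  Counting per shared face rather than per
voxel is the package's stated convention; the per-voxel alternative
(uniformly doubling) is available by flag.  Label 0 is extracellular and
never counts as contact.  Background masks are completed by repeated
single-voxel 6-neighborhood dilation of the segments, visited in a
freshly shuffled seeded order each round: a voxel strictly closer to one
segment (geodesic taxicab distance through the mask) is claimed by that
segment regardless of order, ties fall to the per-round order, and
unreachable mask voxels raise an error carrying their count.

## Diffusion partner assignment

Particles start at uniformly sampled label-0 voxels 6-adjacent to the
active zone and walk the lattice through extracellular voxels only:
stepping into any cell other than the presynaptic one absorbs the
particle; stepping into the presynaptic cell leaves it in place; leaving
the grid, or surviving `max_steps`, counts it lost.  Defaults are 10,000
particles, 50,000 steps and a 5% partner-acceptance fraction — all
exposed parameters with no claim to match any particular study, since
published descriptions defer these details.  Step directions are
equiprobable by default; an anisotropy-weighted mode (probability ∝
1/spacing², the discretisation of isotropic diffusion on an anisotropic
grid) is provided because 50 nm sections versus 2 nm pixels are extreme.
Accepted partners split the active-zone size proportionally to their
absorbed fractions, renormalised to sum exactly to the size.

## Synthetic data: what is emulated, and what is not

`gen_stage_ensemble` emulates an 11-dataset developmental series: a
conserved core present in every stage (default 317 connections), 499
dauer-specific connections against a ~9% specific rate elsewhere, partial
connections shared by random 2–10 stage subsets, mean per-stage
out-degree ≈ 11, log-normal weights, left-right homolog pairs with
correlated rows (a pair member copies its partner's targets and resamples
10%), plus two planted dauer effects: 60 triangle-closing motor-motor
connections (chosen most-common-neighbors-first so each added edge closes
several triangles) and rewiring of half of each sensory neuron's shared
non-core dauer outputs.  The rewiring rate was set by a power analysis so
the planted effect is detected by the rank-sum design in essentially
every run, mirroring the strong significance of the real effect; the
motor boost similarly clears the ER null's 97.5th percentile by design.

Construction is union-first: per-neuron union out-degrees are geometric
(three hub neurons at 4× the mean by default), and each union edge is
assigned to exactly one category — core, single-stage specific, or
partial.  Stage membership is therefore an independent thinning of a
geometric variable, so per-stage out-degrees are geometric with an
analytically known survival slope, recorded in the planted truth.
Rewiring never touches core edges, and every planted set is derived from
the final per-edge stage-membership map, so recovery checks are exact.

What the generator does **not** emulate: spatial structure (no
distance-dependent wiring), reciprocity statistics, weight correlations
between homologs or across stages, the real 81%/19% polyadic/monadic
split (the generator's partner counts are 1 + Poisson, giving ~70/30 at
the same mean), or any attempt to fit the real connectomes' parameters
beyond the stated counts.  Passing tests therefore demonstrate that the
analysis code recovers planted structure under realistic sizes and
noise — not that the generator reproduces the biology.

`gen_synapse_table` decomposes a weight matrix into active zones whose
partner counts are 1 + Poisson(polyady_mean − 1), capped by the
presynaptic neuron's remaining distinct targets; a proportional feedback
on the running mean compensates for the cap so the realized mean lands
on the configured value (2.26 by default), and synapse sizes partition
each weight exactly, making the matrix → table → matrix round trip
lossless.  Volume generators produce axis-aligned block layouts whose
pairwise contact areas are known in closed form, a mirror-symmetric
twin-partner release fixture (intended fractions exactly ½/½), and a
pair of volumes with a planted 6.32× contact fold change.

## Problem sizes and numerical choices

Default analyses run at the study's natural sizes: 180-neuron rosters,
11 stages, ~2,000 connections per stage, 1000-rep ER nulls, 100-rep
vulnerability and hub ensembles, 10,000-particle diffusion runs on
fixtures of a few thousand voxels; the full test suite and the
acceptance script each complete in well under a minute.  All stochastic
components take explicit seeds and are bit-reproducible.  Degenerate
inputs fail loudly: empty synapse tables, unnormalizable weight sets,
active zones without release sites, non-partitioning pair maps and
unreachable mask voxels all raise typed exceptions rather than
propagating NaNs.
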