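# Methods

This note documents the models implemented in `frudsxnet`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions adopted where the published procedure
leaves room.

## Data model

A connectome is two tables. The neuron table carries one row per cell:
unique integer id, hemisphere (`left/right/center/unknown` — ascending and
descending cells may lack a clean side), coarse superclass, gene label
(`Fru`, `Dsx`, `FruDsx`, `none`), morphology type and connectivity subtype
for labeled cells, soma position in micrometres, neurotransmitter,
descending and Kenyon-cell flags, and optionally a connectome cell type for
every cell. The edge table is the directed synaptic graph, `pre → post`
meaning pre is presynaptic, duplicate pairs summed on load. Cells present
only in the edge table are legitimate background cells: they contribute to
every "all synapses with any partner" denominator. Autapses are flagged
(`io.self_edges`) but never silently dropped. Every connection is
thresholded at ≥ 5 synapses (`AnalysisConfig.min_synapses`) before any
downstream analysis.

## Matched-network null model

Given a reference group, a matched network is drawn by rejection sampling:
(1) sample, per superclass, exactly the group's cell count from the pool of
non-Kenyon cells with a complete soma position (cells lacking somas are
excluded from the pool; the reference's own mean distance is recomputed from
the same coordinate table, never cached); (2) accept iff the sample's mean
pairwise Euclidean soma distance is within ±2% (`distance_tolerance`) of the
reference's. The per-superclass counts are matched over pool-eligible
reference cells, so the constraint is satisfiable by construction. A
configurable attempt budget (default 10 000) turns pathological configs —
e.g. tolerance 0 on continuous coordinates — into a `SamplingError` carrying
the achieved distance distribution. Reference cells remain in the candidate
pool (the null randomizes node identity, not edges; degree-preserving
rewiring is deliberately out of scope).

The group-vs-null comparison uses each cell's within-network synapse
fraction (in-group synapses over all synapses with any partner, computed per
direction), with same-primary-type synapses removed from numerator and
denominator on both sides — the labeled group excluded by its morphology
type, matched networks by each cell's connectome type — and the fraction of
connected cell pairs (unordered by default: a pair counts if an edge exists
in either direction; an ordered variant is a flag).

## Partner bias

For one cell and one direction, let N be its number of in-group partners
(after the 5-synapse threshold) and N_group its total synapses with them.
The null draws `n_bias_draws = 100` subsets of N partners, without
replacement, from **all** partners (in-group included — the statistic only
makes sense against same-cardinality subsets), sums their synapses into
V_rand, and reports `(N_group − mean(V_rand)) / std(V_rand)`. `std` uses
population (divide-by-n) normalization: V_rand is treated as an empirical
null vector; the choice is configurable via the exact path. Cells with N = 0
or with every partner in-group (null variance 0) are reported as undefined
rather than 0 — zero is a meaningful bias value the formula cannot produce
there — and are excluded from type-level means, which report the count of
contributing cells. An exact mode replaces the Monte-Carlo null with the
closed-form simple-random-sampling moments (mean `N·m̄`, variance
`N·(P−N)/(P−1)·σ²`), equivalent to enumerating all C(P, N) subsets; the
test-suite uses explicit enumeration as an independent oracle.

## Symmetric-threshold networks

Pair fractions are synapse-weighted group-level sums: for ordered types
(A, B), `out_fraction` divides the A→B synapse total by all output synapses
of A's cells (to any partner, typed or not) and `in_fraction` by all input
synapses of B's cells. An edge is called at threshold θ iff both fractions
reach θ. Within-type synapses stay in denominators by default (configurable);
self-loop edges are omitted from type graphs. Components are computed on the
undirected skeleton (weak/strong variants available); the largest component
is the core, isolated types are listed separately and counted as neither
core nor components. Two-step neighborhoods add, around seed types, first
the types with a θ₁-symmetric connection to a seed (default 1%), then types
with a θ₂-symmetric connection to that layer (default 3%); edges among added
types are not expanded unless requested. Edge signs follow the source type's
modal neurotransmitter — cholinergic excitatory, GABAergic and glutamatergic
inhibitory, anything else unknown — with explicit per-type overrides winning
(the mechanism used where a transmitter prediction is known to be wrong).
The descending-neuron screen takes each DN type's input-synapse total from
the thresholded edge table as denominator, passes types with ≥ 10% of inputs
from the labeled group, and maps labeled subtypes onto passing DN types at a
1% symmetric threshold.

## Connectivity-fingerprint clustering

Each subtype's fingerprint has length 2T over an ordered universe of T
connectome types (default: every type observed in the edge table): synapses
received from each type, then synapses sent to each type. Distances are
plain L2; clustering is average-linkage with a flat cut at 0.3. A cut at an
absolute height of 0.3 is only meaningful on normalized fingerprints — raw
synapse-count distances are orders of magnitude larger — so the default
normalization divides each half of the vector by its own sum, making input
and output profiles compositions; `raw` and whole-row `total` modes are
selectable and the mode is recorded on the result. Subtypes absent from the
3% symmetric network are excluded from clustering. SciPy's agglomeration is
deterministic for a fixed input; the brute-force oracle in the tests breaks
ties by first-found lowest distance, and instances with tied distances are
avoided in comparisons.

## Information-flow ranking

From a seed pool, the traversal proceeds in synchronous steps: every
not-yet-added cell with pooled input is accepted independently with
probability `min(f / cap, 1)`, where f is the fraction of its input synapses
coming from the pool as of the start of the step (synapse-weighted by
default; a partner-count basis is a flag) and `cap = 0.3`. All acceptances
commit together; a cell that fails keeps being retried on later steps, so a
constant fraction f corresponds to a geometric waiting time with success
probability `min(f/0.3, 1)`. The walk stops when no remaining candidate has
positive pooled input (a max-step guard protects against degenerate
configurations). A cell's distance in one repetition is the step at which it
joined; its rank is 1 + the mean distance over repetitions (10 000 for
sensory seeds, 1 000 for type seeds), so seed cells rank exactly 1. Cells
unreached in a repetition are excluded from that repetition's mean and the
count of reached repetitions is reported; an alternative last-step+1 penalty
is a flag. Ranks are percentile-normalized (average-tie convention) against
a reference population defaulting to all cells in the edge table, and
subtype values are means over member cells. The multisensory screen lists
subtypes with normalized rank strictly below 10% from two seed modalities.

For small graphs an exact oracle computes expected joining steps by
absorbing-Markov-chain analysis on pool states: transitions other than the
no-addition self-loop strictly enlarge the pool, so after absorbing the
self-loop analytically (`E = (1 + Σ P(A)·E') / (1 − P(∅))`) a single
backward pass over states in decreasing pool size suffices. The state space
is capped (default 12 non-seed reachable cells); chain fixtures with exact
rational expectations (`synth.make_chain_fixture`) and this oracle together
validate the Monte-Carlo implementation.

## Synthetic connectome generator

The generator emulates the statistical structure the analyses assume, at
populations of a few thousand cells: a superclass partition with one
Gaussian soma cluster per superclass per hemisphere mirrored across the
x = 0 midline (spread 30 µm by default, so matched-network distance
constraints are non-trivially satisfiable); a type/subtype hierarchy with a
type-level mixing kernel (every pair mixes at weight 1, each type prefers a
handful of downstream types, contrast `kernel_strength`) giving clustering
and network construction planted signal; a contiguous block of types labeled
as the group, with `in_group_lift` multiplying both the probability of
labeled→labeled contacts and, for lift ≥ 1, their expected synapse count
(each in-group contact carries 1 + Poisson(lift−1) independent count draws),
so both the fraction-based and the bias-based analyses see the planted
effect; per-type neurotransmitters; descending and Kenyon minorities
(labeled cells are never Kenyon); and per-contact synapse counts from a
zipf(2.3) law, heavy-tailed with finite mean, so the 5-synapse threshold
removes a large, realistic share of weak connections (~90% of edges at the
defaults). Under a uniform kernel the expected in-group synapse fraction has
a closed form used as a recovery oracle. Determinism is bit-stable for a
fixed seed.

What the generator does **not** emulate: real morphology, neuropil
structure, realistic cell counts (~139k) or degree distributions,
left-right wiring symmetry, and any correlation between soma position and
connectivity beyond superclass membership. Passing calibration tests on
synthetic data therefore demonstrates correctness and statistical behaviour
of the machinery, not agreement with the real snapshot — the latter is
exercised separately by the whole-snapshot integration path, which requires
the real data export.

## Calibration conditions and problem sizes

Null-model calibration runs on 4 000-cell connectomes with a 5% labeled
fraction and a **uniform** kernel: with lift 1 the labels are then provably
independent of connectivity, which is the clean type-I condition (a
structured kernel with lift 1 can correlate labels with connectivity through
the type preferences of whichever types happen to be labeled). Power uses
lift 5 under the same conditions. Structured analyses (network shape,
clustering, screens) use 3 000 cells, 10% labeled, lift 5, kernel contrast 4
and a higher contact density (150) so subtype fingerprints are
well-averaged. Oracle agreement uses 50 random graphs of ≤ 8 cells at 600
repetitions, with per-cell Monte-Carlo standard errors from the traversal's
step variance. These sizes keep the full test suite and the acceptance
script in the minutes range while leaving all statistical checks
well-powered.

## Known limitations

* The published clustering cut (0.3) is defined on an unstated feature
  normalization; the half-sum default here is a reasoned choice, recorded in
  the output provenance, and the exact published cluster count should not be
  expected to reproduce under a different normalization.
* Whether the published traversal re-evaluates acceptance within a step as
  the pool grows is unstated; the synchronous convention here is validated
  against an oracle built on the same convention.
* The percentile-normalization population (whole brain vs central brain) is
  configurable because the published choice is unstated; the default is all
  cells in the edge table.
* The connected-pair metric defaults to unordered pairs; the ordered variant
  is a flag.
* Matched-network sampling requires the candidate pool to dominate the
  reference group per superclass; tiny pools fail loudly rather than
  degrade.
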