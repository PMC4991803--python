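# Methods

## Network model

A connectome is a weighted directed graph over a fixed neuron roster.
Two provenance layers are kept per ordered pair: a chemical layer
(directed synaptic contact counts) and a gap-junction layer, which is
symmetric because an electrical coupling conducts both ways and is
therefore entered for both ordered pairs. The analysis weight of a
pair is the sum of the two layers; self-connections are dropped on
ingestion with a warning. When a metadata table is supplied it defines
the roster: isolated roster neurons are retained with zero degree, and
edge-list names outside the roster are an error.

## Graph measures

All weighted measures follow the standard weighted-connectome
conventions, with one normalization made explicit because it matters:

* **Distances.** The distance along a connection of weight *w* is the
  inverse weight. Weights are first normalized by the network maximum
  *w*<sub>max</sub>, so a single step costs *w*<sub>max</sub>/*w* ≥ 1.
  This is a uniform rescaling of 1/*w*: shortest paths, ties and
  betweenness counts are unchanged, and inverse distances (hence all
  efficiencies) stay within [0, 1] even for raw integer contact
  counts. When attacked copies of a network are measured, the *intact*
  maximum is used as the normalization constant for every copy
  ("normalize once, then attack"). This keeps efficiencies of intact
  and attacked networks on one scale and makes the signed efficiency
  vulnerability provably non-negative; normalizing each attacked copy
  by its own maximum would break that whenever the unique strongest
  connection is the one removed.
* **Global efficiency** E: mean inverse shortest-path distance over
  ordered pairs, with disconnected pairs contributing 0 (required,
  since attacked networks may disconnect).
* **Nodal clustering** C(i): the Fagiolo directed-weighted triangle
  formula — normalized weights are cube-rooted, and with
  S = Ŵ<sup>1/3</sup> + (Ŵ<sup>T</sup>)<sup>1/3</sup>,
  C(i) = (S³)<sub>ii</sub> / (2[d<sub>tot</sub>(d<sub>tot</sub>−1) −
  2d<sub>↔</sub>]). Nodes with fewer than two neighbors score 0. A
  binary directed variant is selectable (`clustering="binary"`)
  because the exact weighted formulation used by any given study is
  often unstated; the toggle allows sensitivity checks.
* **Betweenness** B(i) and edge betweenness EBC: unnormalized Brandes
  path counts with all co-minimal shortest paths counted fractionally
  and no arbitrary tie-breaking. The network summary B averages over
  *all* nodes, including zero-degree ones — an attacked neuron stays
  in the matrix, so it stays in the average. Normalization is
  unnecessary because the vulnerability statistic is a ratio.
* **Degree families.** D counts distinct partners with direction
  collapsed (a reciprocal pair to one partner is one anatomical
  neighbor); D_in/D_out count directed connections; Str sums weights;
  AW = Str/D per direction, with 0/0 undefined (NaN) and out/in ratios
  likewise NaN at 0/0.
* **Nodal efficiency** averages outgoing inverse distances by default;
  incoming and two-sided variants are selectable
  (`efficiency_direction`), since the averaging direction is a
  genuinely open convention.

Implementation: all-pairs shortest paths run through scipy's compiled
Dijkstra and betweenness through igraph's compiled Brandes; both are
cross-checked in the test suite against exhaustive path-enumeration
oracles that accumulate path lengths in exact rational arithmetic
(floating-point sums can break genuine shortest-path ties that differ
only in summation order). Clustering is evaluated with dense matrix
products and cross-checked against a literal triple-loop oracle.

## Attack simulations and the vulnerability statistic

A neuronal attack zeroes the target's row and column in both layers
(node retained); a synaptic attack zeroes one ordered pair in both
layers, leaving the reverse direction untouched even for gap-derived
weight. Every attack starts from the intact network, so records are
independent and order-free; the sweep is serial and deterministic.
For each attack and each property X the absolute and signed relative
changes are stored. If an intact property is 0 (possible on degenerate
synthetic inputs), its vulnerability is reported missing (NaN) rather
than infinite.

A full node + edge sweep over a 279-neuron / ~3,000-connection network
is ~3,300 attacks at roughly 80 ms each (one all-pairs shortest-path
and one betweenness computation per attack) — about 4–5 minutes on one
CPU.

## Criticality criteria

* **Neurons:** critical for a property when V > mean + 3·SD of all
  neuronal attacks. The SD is the sample estimator (ddof = 1 by
  default; configurable). σ grades are floor((V − mean)/SD), clipped
  at 0; rounding is selectable (`grade_method`) because floor vs round
  is not a settled convention.
* **Synapses:** the 3 SD rule flags too many edges, so the multiplier
  is data-derived. Grades ≥ 1 are binned into an integer-SD histogram
  (interior empty bins kept at count 0). The *change point* is
  operationalized as the best two-segment piecewise-linear fit of
  log10(count + 1) against bin index over all admissible splits (≥ 2
  bins per side), ties resolved to the smallest split; a histogram
  spanning fewer than 4 bins has no defined change point. The
  governing multiplier is the maximum change point across C, E and B
  (the most conservative choice). If no property yields a change
  point, the analysis falls back to the neuron multiplier so the edge
  stage still completes; the summary records which multiplier was
  used. On distributions whose background decays smoothly into a
  sparse far tail, this procedure places the threshold at the end of
  the background decay — by design: that is the "first major slope
  change".
* **Statistics:** critical-vs-noncritical comparisons use the
  tie-corrected two-sided Mann-Whitney U; property-vulnerability
  correlations use Spearman rank by default (the distributions are
  heavy-tailed; Pearson is selectable), computed against *signed*
  vulnerabilities because the sign carries information. No multiple-
  testing correction is applied by default, matching the single-table
  reporting style of the analysis this package operationalizes.

## Pathways

Left/right neuron pairs are collapsed to their common stem, using
metadata partnerships first and a suffix heuristic as fallback (a
trailing L/R is stripped only when the opposite-suffix sibling exists
in the roster — string shape alone cannot distinguish AVAL from VD01).
The critical synapses, drawn over collapsed names, form a directed
graph whose weakly connected components are the reported pathways
(largest first); collapsed edges carry their supporting original
synapses with grades, reciprocity flags, and an inhibitory sign when
any supporting synapse originates from a neuron whose
`inhibitory_targets` metadata covers the target (`*` = all chemical
outputs, as for GABAergic classes). Sign is metadata, never inferred
from structure. "Long-range" synapses are those whose straight-line
soma distance exceeds a connectome-wide quantile (default 0.90, so the
baseline long-range fraction is ~10%); the quantile is a parameter
because no absolute length threshold generalizes across coordinate
conventions. The neighbor-function profile maps partners' free-text
function labels onto four categories (movement/locomotion,
pioneering/development, chemical-integration, unknown) through an
editable keyword lexicon and counts them per provenance layer.

## Robustness summaries

Leaves are neurons with exactly one partner (direction-collapsed).
Isolation after a neuronal attack reports both the zero-degree count
and the weakly-connected component size distribution, since an attack
can strand individual neurons or whole subnetworks. Reachability is
the transitive closure per provenance layer (gap, chemical, combined);
a three-level coding marks each ordered pair as unreachable,
combined-only, or reachable through at least one single layer. The
coding is this package's own convention — published color schemes for
such matrices are only partially specified.

## Synthetic connectome generator

The generator emulates the statistical shape of the hermaphrodite
wiring data; defaults are the published scale: 88 sensory, 82 inter-
and 109 motor neurons (279 total), 2,990 ordered connections drawn
with hub-skewed in/out propensities (Pareto tail, interneurons boosted
2×, so interneurons tend to be hubs), geometric contact counts with
mean ≈ 2.4, and a symmetric gap layer carrying 12% of total weight,
preferentially placed on already-connected pairs. Neuron names follow
the field's convention (class prefix + number + L/R); a configurable
fraction (default 0.7) is L/R-paired with shared soma position. Birth
times are a two-component draw — early 250–470 min post-fertilization
(before first twitch), late 800–1500 min — with class-dependent mixing
(interneurons 0.9 early, sensory 0.6, motor 0.5), chosen only to
exercise the birth-time classification logic, not to model
development. Soma positions are 1-D uniform on [0, 1] (an
anterior-posterior axis).

What the generator does *not* emulate: spatial wiring-cost structure
(positions are independent of connectivity, so long-range bias in
synthetic critical sets is null by construction), community/modular
organization, reciprocity statistics of the real network, and the
real correlation between weight and function. Passing tests on
synthetic data therefore demonstrate the pipeline's correctness and
its ability to recover planted structure, not biological conclusions.

Planted structures come with an answer key: `hub` (wired to the top of
the degree distribution), `reciprocal_strong_pair` (mutual weights
~10× median, an AVAL↔AVAR analogue), `bridge_edge` (the sole
connection between two otherwise dense blocks, laid between the block
hubs so the cross-block traffic concentrates on the bridge itself),
and `chain` (a directed path of ~20× median weights acting as a
shortest-path superhighway). The bridge-recovery study fixture uses
two 15-node blocks at 0.5 ordered-pair density with near-uniform
weights (geometric p = 0.75), so the planted bridge is the single
structural anomaly rather than competing with heavy-tailed weight
outliers; recovery means the bridge appears in the critical-synapse
union produced by the change-point criterion.

## Numerical choices and degenerate inputs

* All randomness flows through one `numpy.random.Generator` seeded
  from the generator `SynthSpec`; identical specs give bit-identical
  networks, and pipeline reruns give byte-identical outputs.
* An all-equal vulnerability distribution (SD = 0) yields empty
  critical sets rather than an error at the pipeline level; the
  low-level grading function refuses SD = 0 explicitly.
* Ties in the change-point fit go to the smallest split; ties among
  shortest paths are counted fractionally, never broken.
* Vulnerabilities with zero intact property value are NaN and are
  excluded from moments, histograms and correlations.
* Mann-Whitney requires both groups nonempty; correlations with
  zero-variance inputs return NaN entries.

## Problem sizes used in the shipped checks

The test suite and acceptance script size their computations as
follows: oracle-equivalence sweeps over 100–500 random digraphs of 3–7
nodes (exhaustive path enumeration is exponential); attack
monotonicity over 100 random 5–10-node digraphs; bridge recovery over
200 seeded 30-node two-block networks; the full-scale pipeline run on
one 279-neuron synthetic draw. These sizes keep a complete run in the
minutes range on a single CPU while exercising every stage at the
published network's scale at least once.

## Known limitations

* The exact weighted clustering/efficiency formulations of any given
  published table may differ; the surfaced toggles (`clustering`,
  `efficiency_direction`, `sd_ddof`, `grade_method`) exist so a
  reproduction can be chased by sensitivity sweep.
* The change-point operationalization is one concrete reading of
  "first major change in slope"; other readings (raw-count fits,
  different smoothing) would shift the edge multiplier by ±1–2 SD on
  smooth histograms.
* Attacks are single-component only; simultaneous multi-component
  attacks are out of scope.
* The attack sweep is serial; at ~3,300 attacks per published-scale
  network there has been no need for parallelism, and serial execution
  guarantees bit-identical results.
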