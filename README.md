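# frudsxnet

Network analysis of labeled neuron groups in a whole-brain connectome,
built around the question of how sexually-dimorphic (Fruitless/Doublesex)
neurons are wired into the *Drosophila* brain: are they preferentially
interconnected, which cell types form their "core" circuit, how far are they
from each sensory periphery, and which descending neurons do they drive?

The package takes two plain tables — per-cell annotations (superclass, gene
label, type/subtype, soma position, neurotransmitter, descending/Kenyon
flags) and a directed synapse edge list `(pre, post, syn_count)` — and
implements the full analysis chain:

* **Spatially matched random networks.** The null model for a labeled group
  of cells draws random cell sets with exactly the group's per-superclass
  composition (Kenyon cells excluded) and accepts a draw only if its mean
  pairwise soma distance is within ±2% of the group's own; the group's
  within-network synapse fractions and connected-pair fraction are compared
  against 100 accepted samples.
* **Partner bias.** For each cell and direction, with N in-group partners and
  N_group synapses to them, the bias is
  `(N_group − mean(V_rand)) / std(V_rand)` where `V_rand` collects synapse
  sums over random draws of N partners from all partners (without
  replacement); cell biases are averaged per type.
* **Symmetric-threshold networks.** An edge A→B between cell types is called
  at threshold θ iff the A→B synapses are ≥ θ of all output synapses of A's
  cells *and* ≥ θ of all input synapses of B's cells (θ = 3% for the main
  network, 1%/3% for two-step seed neighborhoods, 1% for the
  descending-neuron map). Edge signs follow the source's neurotransmitter
  (cholinergic → excitatory, GABAergic/glutamatergic → inhibitory,
  overridable). The largest connected component is the core network; hub
  removal reports how it splits.
* **Connectivity-fingerprint clustering.** Each subtype gets a 2T vector of
  synapses received from / sent to every connectome type; L2 distances feed
  average-linkage hierarchical clustering cut at 0.3 (on per-half-normalized
  fingerprints).
* **Information-flow ranking.** From a seed population, cells join a growing
  pool in synchronous steps with probability
  `P = min(fraction_of_inputs_from_pool / 0.3, 1)`; a cell's rank is 1 + its
  mean joining step over repetitions (10000 from sensory seeds, 1000 from
  type seeds), percentile-normalized so seeds rank 1. An exact
  absorbing-Markov-chain oracle validates the Monte-Carlo path on small
  graphs, and a multisensory screen lists subtypes with normalized rank
  < 10% from two modalities.
* **Descending-neuron screen.** DN types with ≥ 10% of their input synapses
  from the labeled group, plus the 1% symmetric edge map onto them.

All connections are thresholded at ≥ 5 synapses before any analysis. A
synthetic-connectome generator (`frudsxnet.synth`) provides populations with
planted group assortativity, spatial soma clusters, type structure and
heavy-tailed synapse counts, so the whole chain is testable without the real
data; tiny chain fixtures carry exact expected traversal ranks.

## Worked example

```python
from frudsxnet.config import GeneratorConfig
from frudsxnet.io import apply_synapse_threshold
from frudsxnet.synth import generate_connectome
from frudsxnet.nullmodels import sample_matched_networks, bias_table, type_bias_summary

cfg = GeneratorConfig(n_cells=4000, labeled_fraction=0.05,
                      in_group_lift=5.0, kernel_strength=0.0, seed=101)
neurons, edges = generate_connectome(cfg)
strong = apply_synapse_threshold(edges, 5)
lab = neurons[neurons.gene_label != "none"]
group = set(lab.cell_id)

samples = sample_matched_networks(neurons, group, n_samples=100, rng=55)
bias = type_bias_summary(
    bias_table(strong, group, n_draws=100, rng=17),
    lab.set_index("cell_id")["fru_dsx_type"].to_dict(),
)
print(len(samples), round(max(s.relative_deviation for s in samples), 3))
print(round(bias["mean_bias"].mean(), 3))
```

With the planted lift of 5 this prints `100 0.02` (all matched networks
within the ±2% distance tolerance) and a positive mean type bias of about
`0.2`; regenerating with `in_group_lift=1.0` gives a mean bias statistically
indistinguishable from 0. The numbered drivers under `analysis/` run the
same chain end to end and narrate their findings, e.g. `02_null_models.py`
prints

```
null: group median within-fraction 0.000 vs matched p95 0.000 -> not flagged; mean type bias +0.038
planted: group median within-fraction 0.717 vs matched p95 0.000 -> FLAGGED; mean type bias +0.212
```

— the planted assortative group is detected by both the matched-network
comparison and the bias statistic, while the null group is not, and
`05_information_flow.py` reports the chain-fixture ranks `[2.0, 3.0, 4.0]`
and the geometric fixture's Monte-Carlo rank `2.99` against its exact value
`3.0`.

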