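#!/usr/bin/env python
"""Symmetric-threshold subtype network: construction, signs, core and hubs.

On the structured connectome: builds the 3% symmetric network over labeled
subtypes, assigns excitatory/inhibitory edge signs from type-level
neurotransmitters, reports the core component and what removing the two
highest-degree hubs does to it, and screens non-group cell types with >= 50%
of their synapses with the labeled group.  Writes results/type_networks/.
"""

import json
from pathlib import Path

from frudsxnet.io import apply_synapse_threshold, load_annotations, load_edges
from frudsxnet.network import (
    assign_edge_sign,
    core_network,
    hub_knockout,
    pair_fractions,
    symmetric_threshold,
    type_neurotransmitters,
    write_type_graph,
)
from frudsxnet.nullmodels import external_candidate_screen

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_data"


def main() -> None:
    d = DATA / "structured"
    neurons = load_annotations(d / "annotations.csv")
    edges = load_edges(d / "edges.csv", columns=("pre_id", "post_id", "syn_count"))
    strong = apply_synapse_threshold(edges, 5)
    lab = neurons.loc[neurons["gene_label"] != "none"]
    group = set(lab["cell_id"])
    sub_map = lab.set_index("cell_id")["subtype"].to_dict()
    ctmap = neurons.set_index("cell_id")["cell_type"].to_dict()
    out = ROOT / "type_networks"
    out.mkdir(parents=True, exist_ok=True)

    pairs = pair_fractions(strong, sub_map)
    pairs.to_csv(out / "pair_fractions.csv", index=False)
    graph = symmetric_threshold(pairs, 0.03)
    assign_edge_sign(graph, type_neurotransmitters(neurons, sub_map))
    write_type_graph(graph, out / "nodes.csv", out / "edges.csv", out / "graph.gexf")

    report = core_network(graph)
    hubs = sorted(graph.degree, key=lambda kv: -kv[1])[:2]
    knocked = hub_knockout(graph, {h for h, _ in hubs})
    candidates = external_candidate_screen(strong, group, ctmap, min_fraction=0.5)
    candidates.to_csv(out / "external_candidates.csv", index=False)

    summary = {
        "n_subtypes_total": len(set(sub_map.values())),
        "n_subtypes_in_network": graph.number_of_nodes(),
        "core_size": len(report.core),
        "n_components": report.n_components,
        "hubs_removed": [h for h, _ in hubs],
        "components_after_knockout": [len(c) for c in knocked.components],
        "n_external_candidates": len(candidates),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(
        f"{summary['n_subtypes_in_network']}/{summary['n_subtypes_total']} "
        f"subtypes in the 3% network; core of {summary['core_size']}; removing "
        f"hubs {summary['hubs_removed']} leaves components "
        f"{summary['components_after_knockout']}; "
        f"{summary['n_external_candidates']} external candidates at >=50%"
    )


if __name__ == "__main__":
    main()
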