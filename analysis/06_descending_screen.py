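#!/usr/bin/env python
"""Descending-neuron input screen and the labeled-subtype -> DN edge map.

Identifies descending-neuron types receiving at least 10% of their input
synapses from the labeled group, then maps every 1% symmetric-threshold
connection from labeled subtypes onto those DN types.
Writes results/dn_screen/.
"""

import json
from pathlib import Path

from frudsxnet.io import apply_synapse_threshold, load_annotations, load_edges
from frudsxnet.network import dn_input_screen

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_data"


def main() -> None:
    d = DATA / "structured"
    neurons = load_annotations(d / "annotations.csv")
    edges = load_edges(d / "edges.csv", columns=("pre_id", "post_id", "syn_count"))
    strong = apply_synapse_threshold(edges, 5)
    group = set(neurons.loc[neurons["gene_label"] != "none", "cell_id"])
    out = ROOT / "dn_screen"
    out.mkdir(parents=True, exist_ok=True)

    tab, dn_edges = dn_input_screen(
        strong, group, neurons, min_input_fraction=0.10, theta=0.01
    )
    tab.to_csv(out / "dn_types.csv", index=False)
    dn_edges.to_csv(out / "dn_edges.csv", index=False)
    summary = {
        "n_dn_types": len(tab),
        "n_dn_passing_10pct": int(tab["passes"].sum()),
        "n_subtype_dn_edges": len(dn_edges),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(
        f"{summary['n_dn_passing_10pct']}/{summary['n_dn_types']} DN types "
        f"pass the 10% labeled-input rule; {summary['n_subtype_dn_edges']} "
        "subtype->DN edges at the 1% symmetric threshold"
    )


if __name__ == "__main__":
    main()
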