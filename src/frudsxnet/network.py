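"""Type-level networks built with the symmetric (bidirectional) threshold.

A directed connection from type A to type B is *called* at threshold theta
iff (i) the synapses from A cells onto B cells make up at least theta of all
output synapses of A's cells and (ii) at least theta of all input synapses of
B's cells.  Denominators are each group's total synapses with any partner in
the connectome, not only partners carrying a type label.  On the resulting
type graph we compute connected components (the largest is the "core"
network), hub-removal splits, two-step seed neighborhoods at two thresholds,
edge signs from the source type's neurotransmitter (cholinergic excitatory,
GABAergic/glutamatergic inhibitory, overridable), and the descending-neuron
input screen (DN types receiving at least a given fraction of their inputs
from the labeled group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "pair_fractions",
    "symmetric_threshold",
    "assign_edge_sign",
    "type_neurotransmitters",
    "core_network",
    "hub_knockout",
    "two_step_neighborhood",
    "dn_input_screen",
    "ComponentReport",
    "write_type_graph",
]


def pair_fractions(
    edges: pd.DataFrame,
    grouping: Mapping,
    target_grouping: Mapping | None = None,
    exclude_within: bool = False,
) -> pd.DataFrame:
    """Synapse totals and in/out fractions for every ordered type pair.

    ``grouping`` maps cell id -> type for sources; ``target_grouping`` (when
    the two sides use different partitions, e.g. labeled subtypes onto
    descending types) maps cell id -> type for targets and defaults to
    ``grouping``.  ``out_fraction`` divides the pair total by all output
    synapses of the source type's cells (to any partner, typed or not);
    ``in_fraction`` by all input synapses of the target type's cells.
    ``exclude_within`` removes same-type synapses from numerators and
    denominators (only meaningful when both sides share one partition).
    """
    if target_grouping is None:
        target_grouping = grouping
    src_t = edges["pre_id"].map(grouping)
    dst_t = edges["post_id"].map(target_grouping)
    work = pd.DataFrame(
        {"source_type": src_t, "target_type": dst_t, "syn_count": edges["syn_count"]}
    )
    if exclude_within:
        same_src = edges["pre_id"].map(grouping)
        same = same_src.notna() & (same_src == edges["post_id"].map(grouping))
        work = work.loc[~same]

    out_tot = work.groupby("source_type", observed=True)["syn_count"].sum()
    in_tot = work.groupby("target_type", observed=True)["syn_count"].sum()

    pairs = (
        work.dropna(subset=["source_type", "target_type"])
        .groupby(["source_type", "target_type"], observed=True, sort=True)["syn_count"]
        .sum()
        .rename("syn_total")
        .reset_index()
    )
    pairs["out_fraction"] = pairs["syn_total"] / pairs["source_type"].map(out_tot)
    pairs["in_fraction"] = pairs["syn_total"] / pairs["target_type"].map(in_tot)
    return pairs


def symmetric_threshold(
    pairs: pd.DataFrame,
    theta: float,
    nodes: Iterable | None = None,
    node_attrs: Mapping | None = None,
    include_self: bool = False,
) -> nx.DiGraph:
    """Build the type graph whose edges pass the symmetric threshold.

    Edge A->B is retained iff out_fraction(A->B) >= theta and
    in_fraction(A->B) >= theta.  ``nodes``, when given, fixes the node
    universe (so isolated types are represented); otherwise only the
    endpoints of retained edges appear.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must be in [0, 1], got {theta!r}")
    g = nx.DiGraph(theta=theta)
    if nodes is not None:
        g.add_nodes_from(nodes)
    kept = pairs.loc[
        (pairs["out_fraction"] >= theta) & (pairs["in_fraction"] >= theta)
    ]
    for row in kept.itertuples(index=False):
        if not include_self and row.source_type == row.target_type:
            continue
        g.add_edge(
            row.source_type,
            row.target_type,
            syn_total=int(row.syn_total),
            out_fraction=float(row.out_fraction),
            in_fraction=float(row.in_fraction),
        )
    if node_attrs:
        for node in g.nodes:
            for key, mapping in node_attrs.items():
                if node in mapping:
                    g.nodes[node][key] = mapping[node]
    return g


def type_neurotransmitters(neurons: pd.DataFrame, grouping: Mapping) -> dict:
    """Modal neurotransmitter per type (ties broken alphabetically)."""
    t = neurons["cell_id"].map(grouping)
    sub = neurons.loc[t.notna()].copy()
    sub["type"] = t.loc[t.notna()]
    modal = (
        sub.groupby("type", observed=True)["neurotransmitter"]
        .agg(lambda s: s.value_counts().sort_index().idxmax())
    )
    return modal.to_dict()


_SIGN_RULE = {
    "acetylcholine": "excitatory",
    "GABA": "inhibitory",
    "glutamate": "inhibitory",
}


def assign_edge_sign(
    graph: nx.DiGraph,
    nt_map: Mapping,
    overrides: Mapping | None = None,
) -> nx.DiGraph:
    """Attach an excitatory/inhibitory/unknown sign to every edge.

    Sign follows the source node's neurotransmitter: cholinergic sources are
    excitatory, GABAergic and glutamatergic sources inhibitory, anything else
    unknown.  ``overrides`` (type -> sign) win over the rule — used e.g. for
    cells whose transmitter prediction is known to be wrong.
    """
    overrides = dict(overrides or {})
    for u, v, data in graph.edges(data=True):
        if u in overrides:
            sign = overrides[u]
        else:
            sign = _SIGN_RULE.get(nt_map.get(u), "unknown")
        data["sign"] = sign
        graph.nodes[u]["neurotransmitter"] = nt_map.get(u, "unknown")
    return graph


@dataclass
class ComponentReport:
    components: list = field(default_factory=list)  # sets, largest first
    core: set = field(default_factory=set)
    isolated: set = field(default_factory=set)

    @property
    def n_components(self) -> int:
        return len(self.components)


def core_network(graph: nx.DiGraph, directed: str = "undirected") -> ComponentReport:
    """Connected components of the type graph; the largest is the core.

    Components are computed on the undirected skeleton by default; weakly or
    strongly connected variants of the directed graph are selectable.
    Isolated nodes (no retained edge at all) are listed separately and do not
    count as components.
    """
    if graph.number_of_nodes() == 0:
        return ComponentReport()
    isolated = {n for n in graph.nodes if graph.degree(n) == 0}
    sub = graph.subgraph(n for n in graph.nodes if n not in isolated)
    if directed == "undirected":
        comps = list(nx.connected_components(sub.to_undirected()))
    elif directed == "weak":
        comps = list(nx.weakly_connected_components(sub))
    elif directed == "strong":
        comps = list(nx.strongly_connected_components(sub))
    else:
        raise ValueError("directed must be 'undirected', 'weak' or 'strong'")
    comps = sorted((set(c) for c in comps), key=lambda c: (-len(c), sorted(map(str, c))))
    core = comps[0] if comps else set()
    return ComponentReport(components=comps, core=core, isolated=isolated)


def hub_knockout(graph: nx.DiGraph, remove: Iterable) -> ComponentReport:
    """Component structure after removing the given nodes (hub analysis)."""
    remove = set(remove)
    missing = remove - set(graph.nodes)
    if missing:
        raise KeyError(f"nodes not in graph: {sorted(map(str, missing))}")
    kept = graph.subgraph(n for n in graph.nodes if n not in remove).copy()
    return core_network(kept)


def two_step_neighborhood(
    pairs: pd.DataFrame,
    seed_types: Iterable,
    theta1: float = 0.01,
    theta2: float = 0.03,
    expand_layers: bool = False,
) -> nx.DiGraph:
    """Two-layer neighborhood of seed types under two symmetric thresholds.

    Layer 1 contains the types with a theta1-symmetric connection to or from
    a seed; layer 2 adds types with a theta2-symmetric connection to or from
    layer 1.  Edges within the added layers are not expanded unless
    ``expand_layers`` is set.  Nodes carry a ``layer`` attribute
    ('seed', 1 or 2).
    """
    seed_types = set(seed_types)
    universe = set(pairs["source_type"]) | set(pairs["target_type"])
    missing = seed_types - universe
    if missing:
        raise KeyError(f"seed types absent from the pair table: {sorted(map(str, missing))}")

    g1 = symmetric_threshold(pairs, theta1)
    g2 = symmetric_threshold(pairs, theta2)

    layer1 = set()
    for s in seed_types:
        if s in g1:
            layer1 |= set(g1.successors(s)) | set(g1.predecessors(s))
    layer1 -= seed_types
    layer2 = set()
    for t in layer1:
        if t in g2:
            layer2 |= set(g2.successors(t)) | set(g2.predecessors(t))
    layer2 -= seed_types | layer1

    out = nx.DiGraph(theta1=theta1, theta2=theta2)
    for s in seed_types:
        out.add_node(s, layer="seed")
    for t in sorted(layer1, key=str):
        out.add_node(t, layer=1)
    for t in sorted(layer2, key=str):
        out.add_node(t, layer=2)

    def _copy_edges(src: nx.DiGraph, keep):
        for u, v, data in src.edges(data=True):
            if keep(u, v):
                out.add_edge(u, v, **data)

    _copy_edges(
        g1,
        lambda u, v: (u in seed_types and v in seed_types | layer1)
        or (v in seed_types and u in seed_types | layer1),
    )
    if expand_layers:
        added = layer1 | layer2
        _copy_edges(g2, lambda u, v: u in added and v in added)
    else:
        _copy_edges(
            g2,
            lambda u, v: (u in layer1 and v in layer2) or (v in layer1 and u in layer2),
        )
    return out


def dn_input_screen(
    edges: pd.DataFrame,
    group_ids: Iterable,
    neurons: pd.DataFrame,
    min_input_fraction: float = 0.10,
    dn_type_map: Mapping | None = None,
    group_subtype_map: Mapping | None = None,
    theta: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen descending-neuron types by labeled-group input, then map edges.

    Returns ``(dn_table, edge_list)``: one row per DN type with its total and
    group input synapses and whether it passes the input-fraction rule, and
    the symmetric-threshold (default 1%) edge list between labeled subtypes
    and the passing DN types.  DN input denominators are each DN type's total
    input synapses from any neuron in the (already thresholded) edge table.
    """
    group_ids = set(group_ids)
    dn = neurons.loc[neurons["is_descending"]]
    if len(dn) == 0:
        import warnings

        warnings.warn("no descending-flagged cells; DN screen is empty", stacklevel=2)
        return (
            pd.DataFrame(
                columns=["dn_type", "n_cells", "group_in", "total_in",
                         "input_fraction", "passes"]
            ),
            pd.DataFrame(columns=["source_type", "target_type", "syn_total",
                                  "out_fraction", "in_fraction"]),
        )
    if dn_type_map is None:
        if "cell_type" not in neurons.columns:
            raise ValueError("dn_type_map required when neurons lack a cell_type column")
        dn_type_map = dn.set_index("cell_id")["cell_type"].to_dict()
    else:
        dn_type_map = {c: t for c, t in dn_type_map.items()
                       if c in set(dn["cell_id"])}
    if group_subtype_map is None:
        lab = neurons.loc[neurons["cell_id"].isin(group_ids)]
        group_subtype_map = lab.set_index("cell_id")["subtype"].dropna().to_dict()

    dst = edges["post_id"].map(dn_type_map)
    tot_in = edges.groupby(dst)["syn_count"].sum()
    from_group = edges["pre_id"].isin(group_ids)
    grp_in = edges.loc[from_group].groupby(dst[from_group])["syn_count"].sum()
    dn_types = sorted(set(dn_type_map.values()))
    tab = pd.DataFrame(index=pd.Index(dn_types, name="dn_type"))
    tab["n_cells"] = pd.Series(dn_type_map).value_counts().reindex(dn_types, fill_value=0)
    tab["group_in"] = grp_in.reindex(dn_types, fill_value=0).astype(int)
    tab["total_in"] = tot_in.reindex(dn_types, fill_value=0).astype(int)
    tab["input_fraction"] = tab["group_in"] / tab["total_in"].where(tab["total_in"] > 0)
    tab["passes"] = tab["input_fraction"] >= min_input_fraction
    tab = tab.sort_values("input_fraction", ascending=False).reset_index()

    passing = set(tab.loc[tab["passes"], "dn_type"])
    target_map = {c: t for c, t in dn_type_map.items() if t in passing}
    pairs = pair_fractions(edges, group_subtype_map, target_grouping=target_map)
    kept = pairs.loc[
        (pairs["out_fraction"] >= theta) & (pairs["in_fraction"] >= theta)
    ].reset_index(drop=True)
    return tab, kept


def write_type_graph(graph: nx.DiGraph, node_path, edge_path, gexf_path=None) -> None:
    """Serialize a type graph as node/edge CSVs (and optionally GEXF XML)."""
    nodes = pd.DataFrame(
        [{"node": n, **graph.nodes[n]} for n in sorted(graph.nodes, key=str)]
    )
    edge_rows = [
        {"source": u, "target": v, **d}
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    edges = pd.DataFrame(edge_rows)
    nodes.to_csv(node_path, index=False)
    edges.to_csv(edge_path, index=False)
    if gexf_path is not None:
        nx.write_gexf(graph, gexf_path)
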