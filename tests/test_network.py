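"""Symmetric-threshold type networks, core/hub structure, neighborhoods and
the descending-neuron screen, checked against brute-force reimplementations.
"""

from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from frudsxnet.network import (
    assign_edge_sign,
    core_network,
    dn_input_screen,
    hub_knockout,
    pair_fractions,
    symmetric_threshold,
    two_step_neighborhood,
    type_neurotransmitters,
)
from frudsxnet.nullmodels import within_network_fractions

from conftest import edge_table, neuron_table, random_edges


# ---------------------------------------------------------------- oracles
def brute_pair_fractions(rows, grouping):
    """Dictionary-based pair fraction computation."""
    out_tot, in_tot, pair = {}, {}, {}
    for pre, post, w in rows:
        w = int(w)
        s, t = grouping.get(int(pre)), grouping.get(int(post))
        if s is not None:
            out_tot[s] = out_tot.get(s, 0) + w
        if t is not None:
            in_tot[t] = in_tot.get(t, 0) + w
        if s is not None and t is not None:
            pair[(s, t)] = pair.get((s, t), 0) + w
    return {
        (s, t): (w, Fraction(w, out_tot[s]), Fraction(w, in_tot[t]))
        for (s, t), w in pair.items()
    }


def brute_symmetric_edges(rows, grouping, theta):
    # float() matches the implementation's comparison semantics at the
    # threshold boundary (fractions are exact, theta is a float)
    return {
        (s, t)
        for (s, t), (_, fo, fi) in brute_pair_fractions(rows, grouping).items()
        if float(fo) >= theta and float(fi) >= theta and s != t
    }


def brute_components(edge_set):
    nodes = {n for e in edge_set for n in e}
    comps, seen = [], set()
    for start in nodes:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            for a, b in edge_set:
                if a == u and b not in comp:
                    stack.append(b)
                if b == u and a not in comp:
                    stack.append(a)
        comps.append(comp)
        seen |= comp
    return sorted(comps, key=len, reverse=True)


# ----------------------------------------------------------- pair fractions
def test_pair_fractions_all_synapses_between_two_types():
    edges = edge_table([(1, 2, 7), (3, 4, 3)])
    grouping = {1: "A", 3: "A", 2: "B", 4: "B"}
    pairs = pair_fractions(edges, grouping).set_index(["source_type", "target_type"])
    assert pairs.loc[("A", "B"), "out_fraction"] == 1.0
    assert pairs.loc[("A", "B"), "in_fraction"] == 1.0


def test_pair_fractions_four_type_toy_hand_computed():
    edges = edge_table(
        [(1, 2, 6), (1, 3, 2), (2, 3, 4), (3, 4, 8), (4, 1, 10), (2, 9, 10)]
    )
    grouping = {1: "A", 2: "B", 3: "C", 4: "D"}  # 9 is untyped background
    pairs = pair_fractions(edges, grouping).set_index(["source_type", "target_type"])
    assert pairs.loc[("A", "B"), "out_fraction"] == pytest.approx(6 / 8)
    assert pairs.loc[("A", "C"), "out_fraction"] == pytest.approx(2 / 8)
    # B's outputs include the untyped partner in the denominator
    assert pairs.loc[("B", "C"), "out_fraction"] == pytest.approx(4 / 14)
    assert pairs.loc[("B", "C"), "in_fraction"] == pytest.approx(4 / 6)
    assert pairs.loc[("D", "A"), "in_fraction"] == pytest.approx(1.0)
    assert ("B", "9") not in pairs.index


def test_identity_grouping_reduces_to_per_cell_fractions(rng):
    edges = random_edges(rng, 8, density=0.4)
    grouping = {c: f"cell{c}" for c in range(8)}
    pairs = pair_fractions(edges, grouping)
    members = set(range(8))
    wf = within_network_fractions(edges, members, "output").set_index("cell_id")
    per_cell = pairs.groupby("source_type")["out_fraction"].sum()
    for c in members:
        if f"cell{c}" in per_cell.index:
            # all partners are members, so the per-cell group fraction is the
            # row sum of that cell's outgoing pair fractions
            assert per_cell[f"cell{c}"] == pytest.approx(wf.loc[c, "fraction"])


def test_pair_fraction_row_sums_bounded_by_one(synth_structured):
    _, neurons, strong = synth_structured
    lab = neurons.loc[neurons["gene_label"] != "none"]
    grouping = lab.set_index("cell_id")["subtype"].to_dict()
    pairs = pair_fractions(strong, grouping)
    assert (pairs.groupby("source_type")["out_fraction"].sum() <= 1 + 1e-12).all()
    assert (pairs.groupby("target_type")["in_fraction"].sum() <= 1 + 1e-12).all()


def test_pair_fractions_and_threshold_match_bruteforce(rng):
    for _ in range(20):
        n_cells = int(rng.integers(4, 12))
        n_types = int(rng.integers(2, 7))
        edges = random_edges(rng, n_cells, density=0.4)
        grouping = {c: f"T{rng.integers(0, n_types)}" for c in range(n_cells)}
        rows = list(map(tuple, edges.to_numpy()))
        want = brute_pair_fractions(rows, grouping)
        got = pair_fractions(edges, grouping).set_index(
            ["source_type", "target_type"]
        )
        assert set(got.index) == set(want)
        for key, (w, fo, fi) in want.items():
            assert got.loc[key, "syn_total"] == w
            assert got.loc[key, "out_fraction"] == pytest.approx(float(fo))
            assert got.loc[key, "in_fraction"] == pytest.approx(float(fi))
        for theta in (0.0, 0.05, 0.2, 0.5):
            g = symmetric_threshold(pair_fractions(edges, grouping), theta)
            assert set(g.edges) == brute_symmetric_edges(rows, grouping, theta)
            report = core_network(g)
            assert {frozenset(c) for c in report.components} == {
                frozenset(c) for c in brute_components(set(g.edges))
            }
            if report.components:
                assert len(report.core) == max(len(c) for c in report.components)


# ------------------------------------------------------- symmetric threshold
def test_symmetric_threshold_zero_retains_all_nonself_pairs(rng):
    edges = random_edges(rng, 6)
    grouping = {c: f"T{c % 3}" for c in range(6)}
    pairs = pair_fractions(edges, grouping)
    g = symmetric_threshold(pairs, 0.0)
    nonself = {
        (s, t)
        for s, t in zip(pairs["source_type"], pairs["target_type"])
        if s != t
    }
    assert set(g.edges) == nonself


def test_symmetric_threshold_monotone_in_theta(rng):
    for _ in range(10):
        edges = random_edges(rng, 10, density=0.3)
        grouping = {c: f"T{rng.integers(0, 4)}" for c in range(10)}
        pairs = pair_fractions(edges, grouping)
        e_hi = set(symmetric_threshold(pairs, 0.05).edges)
        e_lo = set(symmetric_threshold(pairs, 0.01).edges)
        assert e_hi <= e_lo


# ---------------------------------------------------------------- edge sign
def test_edge_sign_rule_and_override():
    edges = edge_table([(1, 2, 9), (2, 3, 9), (3, 1, 9)])
    grouping = {1: "A", 2: "B", 3: "C"}
    g = symmetric_threshold(pair_fractions(edges, grouping), 0.0)
    nt = {"A": "GABA", "B": "serotonin", "C": "acetylcholine"}
    assign_edge_sign(g, nt, overrides={"B": "excitatory"})
    assert g.edges["A", "B"]["sign"] == "inhibitory"
    assert g.edges["B", "C"]["sign"] == "excitatory"  # override beats unknown
    assert g.edges["C", "A"]["sign"] == "excitatory"
    assign_edge_sign(g, nt)
    assert g.edges["B", "C"]["sign"] == "unknown"


def test_type_neurotransmitters_modal():
    neurons = neuron_table(
        [
            {"cell_id": 1, "neurotransmitter": "GABA"},
            {"cell_id": 2, "neurotransmitter": "GABA"},
            {"cell_id": 3, "neurotransmitter": "acetylcholine"},
        ]
    )
    assert type_neurotransmitters(neurons, {1: "A", 2: "A", 3: "A"}) == {"A": "GABA"}


# ----------------------------------------------------------- core and hubs
def _graph_from(edges_list):
    g = nx.DiGraph()
    g.add_edges_from(edges_list)
    return g


def test_core_network_two_disjoint_triangles():
    g = _graph_from([(1, 2), (2, 3), (3, 1), (4, 5), (5, 6), (6, 4)])
    report = core_network(g)
    assert sorted(len(c) for c in report.components) == [3, 3]
    assert report.isolated == set()


def test_core_network_isolated_nodes_listed_separately():
    g = _graph_from([(1, 2)])
    g.add_node(99)
    report = core_network(g)
    assert report.core == {1, 2}
    assert report.isolated == {99}
    assert core_network(nx.DiGraph()).components == []


def test_hub_knockout_cut_vertex_and_cycle():
    path = _graph_from([(1, 2), (2, 3), (3, 4), (4, 5)])
    assert hub_knockout(path, {3}).n_components == 2
    cycle = _graph_from([(1, 2), (2, 3), (3, 4), (4, 1)])
    assert hub_knockout(cycle, {3}).n_components == 1
    with pytest.raises(KeyError):
        hub_knockout(path, {42})


# --------------------------------------------------- two-step neighborhood
def _pairs_from_fraction_rows(rows):
    """Rows of (source, target, syn_total, out_fraction, in_fraction)."""
    return pd.DataFrame(
        rows,
        columns=["source_type", "target_type", "syn_total", "out_fraction",
                 "in_fraction"],
    )


def test_two_step_neighborhood_seeds_only_when_no_qualifying_partner():
    pairs = _pairs_from_fraction_rows([("S", "X", 5, 0.005, 0.005)])
    g = two_step_neighborhood(pairs, {"S"}, theta1=0.01, theta2=0.03)
    assert set(g.nodes) == {"S"}
    with pytest.raises(KeyError, match="Z"):
        two_step_neighborhood(pairs, {"Z"}, 0.01, 0.03)


def test_two_step_neighborhood_layers_hand_derived():
    # S -1%- A -3%- B; C only weakly attached to A; D attached to B only
    pairs = _pairs_from_fraction_rows(
        [
            ("S", "A", 10, 0.02, 0.02),   # qualifies at 1%, not at 3%
            ("A", "B", 10, 0.05, 0.05),   # qualifies at 3%
            ("A", "C", 10, 0.02, 0.005),  # fails symmetric 3% (and 1% in)
            ("B", "D", 10, 0.5, 0.5),     # B-D strong, but D is 3 hops out
        ]
    )
    g = two_step_neighborhood(pairs, {"S"}, theta1=0.01, theta2=0.03)
    layers = nx.get_node_attributes(g, "layer")
    assert layers == {"S": "seed", "A": 1, "B": 2}
    assert set(g.edges) == {("S", "A"), ("A", "B")}


def test_two_step_equal_thetas_matches_ball_restriction(rng):
    for _ in range(10):
        edges = random_edges(rng, 10, density=0.35)
        grouping = {c: f"T{rng.integers(0, 5)}" for c in range(10)}
        pairs = pair_fractions(edges, grouping)
        g = symmetric_threshold(pairs, 0.02)
        seeds = {t for t in ("T0",) if t in g} or set(
            list(pairs["source_type"])[:1]
        )
        nb = two_step_neighborhood(pairs, seeds, 0.02, 0.02, expand_layers=True)
        und = g.to_undirected()
        ball = set(seeds)
        for s in seeds & set(und.nodes):
            ball |= set(nx.single_source_shortest_path_length(und, s, cutoff=2))
        assert set(nb.nodes) <= ball
        expected_edges = {
            (u, v) for u, v in g.edges if u in set(nb.nodes) and v in set(nb.nodes)
        }
        assert set(nb.edges) == expected_edges


def test_two_step_contained_in_min_theta_two_hop_ball(synth_structured):
    _, neurons, strong = synth_structured
    lab = neurons.loc[neurons["gene_label"] != "none"]
    grouping = lab.set_index("cell_id")["subtype"].to_dict()
    pairs = pair_fractions(strong, grouping)
    g_min = symmetric_threshold(pairs, 0.01).to_undirected()
    seeds = sorted(g_min.nodes)[:2]
    nb = two_step_neighborhood(pairs, seeds, 0.01, 0.03)
    ball = set(seeds)
    for s in seeds:
        ball |= set(nx.single_source_shortest_path_length(g_min, s, cutoff=2))
    assert set(nb.nodes) <= ball


# ------------------------------------------------------------- DN screen
def test_dn_screen_synthetic_dn_fully_driven_by_group():
    records = [
        {"cell_id": 1, "gene_label": "Fru", "fru_dsx_type": "FD0",
         "subtype": "FD0-a", "cell_type": "a"},
        {"cell_id": 2, "gene_label": "Fru", "fru_dsx_type": "FD0",
         "subtype": "FD0-a", "cell_type": "a"},
        {"cell_id": 3, "is_descending": True, "superclass": "descending",
         "cell_type": "DNx"},
        {"cell_id": 4, "is_descending": True, "superclass": "descending",
         "cell_type": "DNy"},
        {"cell_id": 5, "cell_type": "bg"},
    ]
    neurons = neuron_table(records)
    edges = edge_table([(1, 3, 50), (2, 3, 30), (5, 4, 100), (1, 4, 5)])
    tab, dn_edges = dn_input_screen(edges, {1, 2}, neurons, 0.10)
    tab = tab.set_index("dn_type")
    assert tab.loc["DNx", "input_fraction"] == pytest.approx(1.0)
    assert tab.loc["DNx", "passes"]
    assert tab.loc["DNy", "input_fraction"] == pytest.approx(5 / 105)
    assert not tab.loc["DNy", "passes"]
    # the 1% symmetric edge list covers only passing DN types
    assert set(dn_edges["target_type"]) == {"DNx"}
    assert set(dn_edges["source_type"]) == {"FD0-a"}


def test_dn_screen_impossible_rule_and_missing_dns(synth_structured):
    cfg, neurons, strong = synth_structured
    lab = set(neurons.loc[neurons["gene_label"] != "none", "cell_id"])
    tab, _ = dn_input_screen(strong, lab, neurons, min_input_fraction=1.0)
    assert tab["passes"].sum() == 0
    no_dn = neurons.copy()
    no_dn["is_descending"] = False
    with pytest.warns(UserWarning, match="no descending"):
        empty, empty_edges = dn_input_screen(strong, lab, no_dn, 0.1)
    assert len(empty) == 0 and len(empty_edges) == 0
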