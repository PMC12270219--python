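"""Matched-network null model and partner-bias statistics.

Brute-force oracles here are independent, dictionary-based reimplementations
used only to check the vectorized code paths.
"""


import numpy as np
import pytest

from frudsxnet.errors import SamplingError
from frudsxnet.nullmodels import (
    bias_table,
    connected_pair_fraction,
    enumerate_partner_bias,
    external_candidate_screen,
    group_superclass_counts,
    mean_pairwise_distance,
    partner_bias,
    sample_matched_network,
    sample_matched_networks,
    type_bias_summary,
    within_network_fractions,
)

from conftest import edge_table, neuron_table, random_edges


# ---------------------------------------------------------------- oracles
def brute_within_fraction(rows, member, direction, exclude=None):
    """Pure-python within-network fraction for one cell set."""
    out = {}
    for c in member:
        grp = tot = 0
        for pre, post, w in rows:
            owner, partner = (post, pre) if direction == "input" else (pre, post)
            if owner != c:
                continue
            if exclude and exclude.get(owner) is not None and (
                exclude.get(owner) == exclude.get(partner)
            ):
                continue
            tot += w
            if partner in member:
                grp += w
        out[c] = (grp, tot, grp / tot if tot else float("nan"))
    return out


def brute_pair_fraction(rows, member):
    connected = set()
    for pre, post, _ in rows:
        if pre in member and post in member and pre != post:
            connected.add(frozenset((pre, post)))
    m = len(member)
    return len(connected) / (m * (m - 1) / 2)


# ------------------------------------------------------- matched networks
def test_reference_group_is_its_own_perfect_match(synth_lift1):
    """The reference set proposed as its own sample deviates by exactly 0,
    regardless of row order of the coordinate table."""
    _, neurons, _ = synth_lift1
    lab = set(neurons.loc[neurons["gene_label"] != "none", "cell_id"])
    d = mean_pairwise_distance(neurons, lab)
    shuffled = neurons.sample(frac=1.0, random_state=3).reset_index(drop=True)
    d2 = mean_pairwise_distance(shuffled, lab)
    assert np.isfinite(d) and d > 0
    assert abs(d - d2) / d < 1e-12
    assert group_superclass_counts(neurons, lab) == group_superclass_counts(
        shuffled, lab
    )


def test_matched_samples_satisfy_constraints_individually(synth_lift1):
    _, neurons, _ = synth_lift1
    lab = set(neurons.loc[neurons["gene_label"] != "none", "cell_id"])
    ref_counts = group_superclass_counts(neurons, lab)
    kenyon = set(neurons.loc[neurons["is_kenyon"], "cell_id"])
    samples = sample_matched_networks(neurons, lab, n_samples=20, rng=7)
    for s in samples:
        assert group_superclass_counts(neurons, s.member_ids) == ref_counts
        assert s.relative_deviation <= 0.02
        assert not (s.member_ids & kenyon)
        assert s.mean_pairwise_distance == pytest.approx(
            mean_pairwise_distance(neurons, s.member_ids)
        )


def test_zero_tolerance_on_continuous_somas_fails(synth_lift1):
    _, neurons, _ = synth_lift1
    lab = set(neurons.loc[neurons["gene_label"] != "none", "cell_id"])
    with pytest.raises(SamplingError, match="attempts"):
        sample_matched_network(neurons, lab, tolerance=0.0, rng=1, max_attempts=20)


def test_kenyon_cells_excluded_from_pool():
    records = []
    for i in range(40):
        records.append(
            {
                "cell_id": i,
                "superclass": "central",
                "soma_x": float(i % 7),
                "soma_y": float(i % 5),
                "soma_z": 0.0,
                "is_kenyon": i >= 30,
                "gene_label": "Fru" if i < 10 else "none",
                "fru_dsx_type": "FD0" if i < 10 else None,
            }
        )
    neurons = neuron_table(records)
    samples = sample_matched_networks(
        neurons, set(range(10)), n_samples=10, tolerance=0.5, rng=0
    )
    for s in samples:
        assert all(m < 30 for m in s.member_ids)


# ------------------------------------------------ within-network fractions
def test_within_fractions_six_cell_toy_hand_computed():
    # members {1,2,3,6}; 4 and 5 are background; 6 has no synapses at all
    edges = edge_table(
        [(1, 2, 10), (2, 1, 5), (3, 1, 5), (4, 1, 20), (2, 3, 6), (2, 5, 9)]
    )
    members = {1, 2, 3, 6}
    rec = within_network_fractions(edges, members, "input").set_index("cell_id")
    assert rec.loc[1, "fraction"] == pytest.approx((5 + 5) / (5 + 5 + 20))
    assert rec.loc[2, "fraction"] == pytest.approx(1.0)  # all partners in-group
    assert rec.loc[3, "fraction"] == pytest.approx(1.0)
    assert np.isnan(rec.loc[6, "fraction"])  # zero qualifying synapses
    rec = within_network_fractions(edges, members, "output").set_index("cell_id")
    assert rec.loc[2, "fraction"] == pytest.approx((5 + 6) / (5 + 6 + 9))
    assert rec.loc[3, "fraction"] == pytest.approx(1.0)  # sole output to 1
    assert np.isnan(rec.loc[6, "fraction"])


def test_within_fraction_exclusion_rule_removes_same_type_synapses():
    edges = edge_table([(1, 2, 10), (3, 2, 10), (4, 2, 20)])
    type_map = {1: "A", 2: "A", 3: "B", 4: None}
    rec = within_network_fractions(
        edges, {1, 2, 3}, "input", exclude_within=type_map
    ).set_index("cell_id")
    # 1->2 shares type A: dropped from numerator and denominator
    assert rec.loc[2, "fraction"] == pytest.approx(10 / 30)


def test_fraction_and_pair_metrics_match_bruteforce_on_small_graphs(rng):
    for _ in range(25):
        n = int(rng.integers(3, 9))
        edges = random_edges(rng, n, density=0.35)
        rows = list(map(tuple, edges.to_numpy()))
        member = set(
            rng.choice(n, size=int(rng.integers(2, n + 1)), replace=False).tolist()
        )
        for direction in ("input", "output"):
            got = within_network_fractions(edges, member, direction).set_index(
                "cell_id"
            )
            want = brute_within_fraction(rows, member, direction)
            for c, (g, t, f) in want.items():
                assert got.loc[c, "group_synapses"] == g
                assert got.loc[c, "total_synapses"] == t
                if t:
                    assert got.loc[c, "fraction"] == pytest.approx(f)
        assert connected_pair_fraction(edges, member) == pytest.approx(
            brute_pair_fraction(rows, member)
        )


def test_connected_pair_fraction_extremes():
    complete = edge_table(
        [(a, b, 5) for a in range(4) for b in range(4) if a != b]
    )
    assert connected_pair_fraction(complete, set(range(4))) == 1.0
    assert connected_pair_fraction(complete, set(range(4)), ordered=True) == 1.0
    sparse = edge_table([(0, 9, 5)])
    assert connected_pair_fraction(sparse, {1, 2, 3}) == 0.0


# ------------------------------------------------------------ partner bias
def test_partner_bias_exact_matches_exhaustive_enumeration():
    # cell 0 with 4 input partners, counts 10/1/2/3; partners 1 and 2 in-group
    edges = edge_table([(1, 0, 10), (2, 0, 1), (3, 0, 2), (4, 0, 3)])
    group = {1, 2}
    exact = partner_bias(0, edges, group, "input", exact=True)
    enum = enumerate_partner_bias(0, edges, group, "input")
    assert exact.null_mean == pytest.approx(enum.null_mean)
    assert exact.null_sd == pytest.approx(enum.null_sd)
    assert exact.bias == pytest.approx(enum.bias)
    assert enum.group_synapses == 11
    assert enum.null_mean == pytest.approx(8.0)  # 2 * mean(10,1,2,3)


def test_partner_bias_monte_carlo_agrees_with_enumeration():
    edges = edge_table(
        [(p, 0, c) for p, c in zip(range(1, 9), (10, 1, 2, 3, 7, 2, 9, 4))]
    )
    group = {1, 5, 7}
    enum = enumerate_partner_bias(0, edges, group, "input")
    n_draws = 4000
    mc = partner_bias(0, edges, group, "input", n_draws=n_draws, rng=3)
    se_mean = enum.null_sd / np.sqrt(n_draws)
    assert abs(mc.null_mean - enum.null_mean) < 3 * se_mean
    assert mc.bias == pytest.approx(enum.bias, abs=0.2)


def test_partner_bias_degenerate_cases():
    edges = edge_table([(1, 0, 5), (2, 0, 7)])
    all_group = partner_bias(0, edges, {1, 2}, "input", rng=0)
    assert not all_group.defined  # every draw equals the group: sd = 0
    no_group = partner_bias(0, edges, {99}, "input", rng=0)
    assert not no_group.defined and no_group.n_group_partners == 0
    with pytest.raises(LookupError):
        partner_bias(42, edges, {1}, "input", rng=0)


def test_bias_expectation_zero_under_random_relabeling(rng):
    """Relabeling group membership among partners (preserving N) keeps the
    expected bias at 0."""
    counts = rng.integers(1, 30, size=10)
    edges = edge_table([(p + 1, 0, int(c)) for p, c in enumerate(counts)])
    biases = []
    for _ in range(400):
        group = set(rng.choice(np.arange(1, 11), size=3, replace=False).tolist())
        biases.append(partner_bias(0, edges, group, "input", exact=True).bias)
    biases = np.asarray(biases)
    se = biases.std(ddof=1) / np.sqrt(len(biases))
    assert abs(biases.mean()) < 3 * se


def test_type_bias_summary_single_cell_type_and_undefined_exclusion():
    edges = edge_table([(1, 0, 10), (2, 0, 1), (3, 0, 2), (4, 0, 3), (1, 9, 4)])
    df = bias_table(edges, {1, 2}, cells=[0, 9], directions=("input",), exact=True)
    summary = type_bias_summary(df, {0: "tA", 9: "tB"})
    row = summary.set_index("type")
    assert row.loc["tA", "mean_bias"] == pytest.approx(
        partner_bias(0, edges, {1, 2}, "input", exact=True).bias
    )
    assert "tB" not in row.index  # single all-group partner -> undefined


def test_bias_calibration_null_and_planted(synth_lift1, synth_lift5):
    """Type-level mean bias centers at 0 without a planted effect and is
    strictly positive with a lift-5 planted group."""
    results = {}
    for name, (cfg, neurons, edges) in (
        ("lift1", synth_lift1), ("lift5", synth_lift5)
    ):
        from frudsxnet.io import apply_synapse_threshold

        strong = apply_synapse_threshold(edges, 5)
        lab = neurons.loc[neurons["gene_label"] != "none"]
        group = set(lab["cell_id"])
        tmap = lab.set_index("cell_id")["fru_dsx_type"].to_dict()
        bt = bias_table(strong, group, n_draws=100, rng=17)
        summary = type_bias_summary(bt, tmap)
        results[name] = summary["mean_bias"]
    null = results["lift1"]
    se = null.std(ddof=1) / np.sqrt(len(null))
    assert abs(null.mean()) < 3 * se
    assert results["lift5"].mean() > 0
    assert results["lift5"].mean() > null.mean()


# --------------------------------------------------- external candidates
def test_external_candidate_screen_finds_fully_embedded_outsider():
    # group {1, 2}; type X = {3, 4} talks only to the group; type Y mixed
    edges = edge_table(
        [(3, 1, 10), (1, 4, 8), (5, 1, 5), (5, 9, 45), (9, 5, 5)]
    )
    type_map = {1: "G", 2: "G", 3: "X", 4: "X", 5: "Y", 9: "Z"}
    hits = external_candidate_screen(edges, {1, 2}, type_map, min_fraction=1.0)
    assert hits["cell_type"].tolist() == ["X"]
    loose = external_candidate_screen(edges, {1, 2}, type_map, min_fraction=0.0)
    assert set(loose["cell_type"]) >= {"X", "Y", "Z"}
    assert "G" not in set(loose["cell_type"])  # group types never candidates
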