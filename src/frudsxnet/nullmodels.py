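"""Spatially matched random-network null model and partner-bias statistics.

The null model for a labeled cell group draws random cell sets with exactly
the group's per-superclass composition (Kenyon cells excluded from the
candidate pool) and accepts a draw only if its mean pairwise soma distance is
within a relative tolerance (default +/-2%) of the group's own mean distance.

The partner-bias statistic asks, for one cell and one direction, whether its
synapse count with in-group partners exceeds what same-cardinality random
subsets of all its partners would give:

    bias = (N_group - mean(V_rand)) / std(V_rand)

where N_group is the cell's total synapse count with its N in-group partners
and V_rand collects the synapse-count sums of random draws of N partners
(without replacement, in-group partners included in the candidate pool).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import SamplingError

__all__ = [
    "MatchedSample",
    "BiasResult",
    "group_superclass_counts",
    "mean_pairwise_distance",
    "sample_matched_network",
    "sample_matched_networks",
    "within_network_fractions",
    "connected_pair_fraction",
    "partner_bias",
    "bias_table",
    "type_bias_summary",
    "external_candidate_screen",
]


@dataclass
class MatchedSample:
    member_ids: frozenset
    superclass_counts: dict
    mean_pairwise_distance: float
    reference_distance: float
    n_rejections_before_acceptance: int

    @property
    def relative_deviation(self) -> float:
        return abs(self.mean_pairwise_distance - self.reference_distance) / (
            self.reference_distance
        )


def group_superclass_counts(neurons: pd.DataFrame, member_ids: Iterable) -> dict:
    sub = neurons.loc[neurons["cell_id"].isin(set(member_ids))]
    return sub.groupby("superclass", observed=True).size().to_dict()


def mean_pairwise_distance(neurons: pd.DataFrame, member_ids: Iterable) -> float:
    """Mean Euclidean distance between the soma positions of the member cells.

    Cells without a soma position are excluded from the computation.
    """
    sub = neurons.loc[neurons["cell_id"].isin(set(member_ids)),
                      ["soma_x", "soma_y", "soma_z"]].dropna()
    if len(sub) < 2:
        return float("nan")
    return float(pdist(sub.to_numpy(dtype=float)).mean())


def _candidate_pool(neurons: pd.DataFrame) -> pd.DataFrame:
    """Non-Kenyon cells with a complete soma position."""
    has_soma = neurons[["soma_x", "soma_y", "soma_z"]].notna().all(axis=1)
    return neurons.loc[~neurons["is_kenyon"] & has_soma]


def sample_matched_network(
    neurons: pd.DataFrame,
    reference_ids: Iterable,
    tolerance: float = 0.02,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 10000,
) -> MatchedSample:
    """Draw one matched network by rejection sampling.

    Repeats (1) draw the reference group's per-superclass cell counts at
    random from the non-Kenyon candidate pool, (2) accept iff the draw's mean
    pairwise soma distance is within ``tolerance`` of the reference group's
    own mean distance (recomputed from the same coordinate table), until
    acceptance or the attempt budget is exhausted.
    """
    rng = np.random.default_rng(rng)
    reference_ids = set(reference_ids)
    ref_dist = mean_pairwise_distance(neurons, reference_ids)
    if not np.isfinite(ref_dist) or ref_dist <= 0:
        raise SamplingError("reference group has no usable soma positions")
    # match superclass counts over cells that are in the candidate pool,
    # so the constraint is satisfiable by construction
    pool = _candidate_pool(neurons)
    ref_counts = (
        pool.loc[pool["cell_id"].isin(reference_ids)]
        .groupby("superclass", observed=True)
        .size()
        .to_dict()
    )
    pool_by_sc = {
        sc: grp["cell_id"].to_numpy()
        for sc, grp in pool.groupby("superclass", observed=True)
    }
    for sc, cnt in ref_counts.items():
        if len(pool_by_sc.get(sc, ())) < cnt:
            raise SamplingError(
                f"candidate pool has fewer {sc} cells than the reference group"
            )
    coords = pool.set_index("cell_id")[["soma_x", "soma_y", "soma_z"]]

    achieved = []
    for attempt in range(max_attempts):
        members = np.concatenate(
            [
                rng.choice(pool_by_sc[sc], size=cnt, replace=False)
                for sc, cnt in sorted(ref_counts.items())
            ]
        )
        d = float(pdist(coords.loc[members].to_numpy(dtype=float)).mean())
        achieved.append(d)
        if abs(d - ref_dist) <= tolerance * ref_dist:
            return MatchedSample(
                member_ids=frozenset(int(m) for m in members),
                superclass_counts=dict(ref_counts),
                mean_pairwise_distance=d,
                reference_distance=ref_dist,
                n_rejections_before_acceptance=attempt,
            )
    achieved = np.asarray(achieved)
    raise SamplingError(
        f"no acceptance in {max_attempts} attempts; reference distance "
        f"{ref_dist:.2f}, achieved mean {achieved.mean():.2f} "
        f"(sd {achieved.std():.2f}, range {achieved.min():.2f}-{achieved.max():.2f})"
    )


def sample_matched_networks(
    neurons: pd.DataFrame,
    reference_ids: Iterable,
    n_samples: int = 100,
    tolerance: float = 0.02,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 10000,
) -> list[MatchedSample]:
    rng = np.random.default_rng(rng)
    reference_ids = set(reference_ids)
    return [
        sample_matched_network(neurons, reference_ids, tolerance, rng, max_attempts)
        for _ in range(n_samples)
    ]


def _direction_cols(direction: str) -> tuple[str, str]:
    if direction == "input":
        return "post_id", "pre_id"  # (owner, partner)
    if direction == "output":
        return "pre_id", "post_id"
    raise ValueError(f"direction must be 'input' or 'output', got {direction!r}")


def within_network_fractions(
    edges: pd.DataFrame,
    member_ids: Iterable,
    direction: str = "input",
    exclude_within: Mapping | None = None,
) -> pd.DataFrame:
    """Per-member fraction of synapses made with other members, out of all
    synapses with any partner in the connectome.

    ``exclude_within`` maps cell ids to a grouping (e.g. primary type or
    subtype); synapses between cells sharing a group are removed from both
    the numerator and the denominator, mirroring the published exclusion of
    within-primary-type synapses.  Members with zero qualifying synapses get
    fraction NaN.
    """
    member_ids = set(member_ids)
    owner, partner = _direction_cols(direction)
    sub = edges.loc[edges[owner].isin(member_ids),
                    [owner, partner, "syn_count"]].copy()
    if exclude_within is not None:
        g_owner = sub[owner].map(exclude_within)
        g_partner = sub[partner].map(exclude_within)
        same = g_owner.notna() & (g_owner == g_partner)
        sub = sub.loc[~same]
    in_group = sub[partner].isin(member_ids)
    total = sub.groupby(owner)["syn_count"].sum()
    group = sub.loc[in_group].groupby(owner)["syn_count"].sum()
    idx = pd.Index(sorted(member_ids), name="cell_id")
    total = total.reindex(idx, fill_value=0)
    group = group.reindex(idx, fill_value=0)
    frac = group / total.where(total > 0)
    return pd.DataFrame(
        {
            "cell_id": idx.to_numpy(),
            "direction": direction,
            "group_synapses": group.to_numpy(),
            "total_synapses": total.to_numpy(),
            "fraction": frac.to_numpy(),
        }
    )


def connected_pair_fraction(
    edges: pd.DataFrame, member_ids: Iterable, ordered: bool = False
) -> float:
    """Fraction of member cell pairs connected by at least one edge.

    Default counts unordered pairs: a pair is connected if an edge exists in
    either direction, out of C(m, 2) possible pairs.  With ``ordered=True``
    each direction counts separately out of m*(m-1) ordered pairs.
    """
    member_ids = set(member_ids)
    m = len(member_ids)
    if m < 2:
        raise ValueError("need at least 2 member cells")
    sub = edges.loc[
        edges["pre_id"].isin(member_ids)
        & edges["post_id"].isin(member_ids)
        & (edges["pre_id"] != edges["post_id"])
    ]
    pairs = set(zip(sub["pre_id"].tolist(), sub["post_id"].tolist()))
    if ordered:
        return len(pairs) / (m * (m - 1))
    unordered = {frozenset(p) for p in pairs}
    return len(unordered) / (m * (m - 1) / 2)


@dataclass
class BiasResult:
    cell_id: int
    direction: str
    n_group_partners: int
    n_partners: int
    group_synapses: int
    null_mean: float
    null_sd: float
    bias: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.bias))


def _partner_counts(
    edges: pd.DataFrame, cell_id: int, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    owner, partner = _direction_cols(direction)
    sub = edges.loc[edges[owner] == cell_id]
    grouped = sub.groupby(partner)["syn_count"].sum()
    return grouped.index.to_numpy(), grouped.to_numpy(dtype=float)


def partner_bias(
    cell_id: int,
    edges: pd.DataFrame,
    group_ids: Iterable,
    direction: str = "input",
    n_draws: int = 100,
    rng: np.random.Generator | int | None = None,
    exact: bool = False,
) -> BiasResult:
    """Bias of one cell toward synapses with in-group partners.

    ``exact=True`` replaces the Monte-Carlo null with the closed-form mean
    and (population) standard deviation of a without-replacement subset sum
    (simple-random-sampling moments), equivalent to enumerating all
    C(P, N) partner subsets.
    """
    group_ids = set(group_ids)
    partners, counts = _partner_counts(edges, cell_id, direction)
    if len(partners) == 0:
        raise LookupError(f"cell {cell_id} has no {direction} partners in the edges")
    in_group = np.array([p in group_ids for p in partners])
    n_grp = int(in_group.sum())
    n_all = len(partners)
    group_syn = int(counts[in_group].sum())
    if n_grp == 0 or n_grp == n_all:
        # no in-group partners, or all partners in-group (every draw equals
        # the group): null sd is 0 or the statistic is vacuous
        null_mean = group_syn if n_grp == n_all else 0.0
        return BiasResult(cell_id, direction, n_grp, n_all, group_syn,
                          float(null_mean), 0.0, float("nan"))
    if exact:
        mean = n_grp * counts.mean()
        var = (
            n_grp
            * (n_all - n_grp)
            / (n_all - 1)
            * counts.var()  # population variance
        )
        sd = math.sqrt(var)
    else:
        rng = np.random.default_rng(rng)
        draws = np.empty(n_draws)
        for i in range(n_draws):
            pick = rng.choice(n_all, size=n_grp, replace=False)
            draws[i] = counts[pick].sum()
        mean = float(draws.mean())
        sd = float(draws.std())  # population (divide-by-n) normalization
    bias = (group_syn - mean) / sd if sd > 0 else float("nan")
    return BiasResult(cell_id, direction, n_grp, n_all, group_syn,
                      float(mean), float(sd), float(bias))


def enumerate_partner_bias(
    cell_id: int, edges: pd.DataFrame, group_ids: Iterable, direction: str = "input"
) -> BiasResult:
    """Exhaustive-subset oracle: the null over ALL C(P, N) partner subsets."""
    group_ids = set(group_ids)
    partners, counts = _partner_counts(edges, cell_id, direction)
    in_group = np.array([p in group_ids for p in partners])
    n_grp = int(in_group.sum())
    n_all = len(partners)
    group_syn = int(counts[in_group].sum())
    if n_grp == 0 or n_grp == n_all:
        return BiasResult(cell_id, direction, n_grp, n_all, group_syn,
                          float(group_syn if n_grp == n_all else 0.0),
                          0.0, float("nan"))
    sums = np.array(
        [sum(c) for c in (counts[list(ix)] for ix in combinations(range(n_all), n_grp))]
    )
    mean, sd = float(sums.mean()), float(sums.std())
    bias = (group_syn - mean) / sd if sd > 0 else float("nan")
    return BiasResult(cell_id, direction, n_grp, n_all, group_syn, mean, sd, bias)


def bias_table(
    edges: pd.DataFrame,
    group_ids: Iterable,
    cells: Iterable | None = None,
    directions: tuple = ("input", "output"),
    n_draws: int = 100,
    rng: np.random.Generator | int | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Partner bias for many cells; one row per (cell, direction)."""
    rng = np.random.default_rng(rng)
    group_ids = set(group_ids)
    if cells is None:
        cells = sorted(group_ids)
    rows = []
    for direction in directions:
        owner, _ = _direction_cols(direction)
        present = set(edges[owner].unique())
        for c in cells:
            if c not in present:
                continue
            r = partner_bias(c, edges, group_ids, direction, n_draws, rng, exact)
            rows.append(r.__dict__)
    return pd.DataFrame(rows)


def type_bias_summary(bias_results: pd.DataFrame, type_map: Mapping) -> pd.DataFrame:
    """Average per-cell biases within each type and direction.

    Cells with an undefined bias are excluded from the means; the count of
    contributing cells is reported alongside.
    """
    df = bias_results.copy()
    df["type"] = df["cell_id"].map(type_map)
    df = df.loc[df["type"].notna()]
    defined = df.loc[np.isfinite(df["bias"])]
    out = (
        defined.groupby(["type", "direction"], observed=True)["bias"]
        .agg(mean_bias="mean", n_cells="count")
        .reset_index()
    )
    return out


def external_candidate_screen(
    edges: pd.DataFrame,
    group_ids: Iterable,
    type_map: Mapping,
    min_fraction: float = 0.50,
) -> pd.DataFrame:
    """Rank non-group cell types by their synapse fraction with the group.

    For each cell type containing no group member, computes the fraction of
    the type's input synapses coming from group cells and of its output
    synapses going to group cells; types whose input or output fraction
    reaches ``min_fraction`` are returned, sorted descending by the larger
    of the two.  These are candidates for belonging to the labeled group.
    """
    group_ids = set(group_ids)
    tm = pd.Series(type_map)
    group_types = set(tm.loc[tm.index.isin(group_ids)].unique())

    pre_t = edges["pre_id"].map(type_map)
    post_t = edges["post_id"].map(type_map)
    pre_in_group = edges["pre_id"].isin(group_ids)
    post_in_group = edges["post_id"].isin(group_ids)

    tot_in = edges.groupby(post_t)["syn_count"].sum()
    grp_in = edges.loc[pre_in_group].groupby(post_t[pre_in_group])["syn_count"].sum()
    tot_out = edges.groupby(pre_t)["syn_count"].sum()
    grp_out = edges.loc[post_in_group].groupby(pre_t[post_in_group])["syn_count"].sum()

    types = sorted(set(tot_in.index) | set(tot_out.index))
    df = pd.DataFrame(index=pd.Index(types, name="cell_type"))
    df["total_in"] = tot_in.reindex(types, fill_value=0)
    df["group_in"] = grp_in.reindex(types, fill_value=0)
    df["total_out"] = tot_out.reindex(types, fill_value=0)
    df["group_out"] = grp_out.reindex(types, fill_value=0)
    df["input_fraction"] = df["group_in"] / df["total_in"].where(df["total_in"] > 0)
    df["output_fraction"] = df["group_out"] / df["total_out"].where(df["total_out"] > 0)
    df = df.drop(index=[t for t in types if t in group_types], errors="ignore")
    best = df[["input_fraction", "output_fraction"]].max(axis=1)
    df["best_fraction"] = best
    df = df.loc[best >= min_fraction].sort_values("best_fraction", ascending=False)
    return df.reset_index()
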