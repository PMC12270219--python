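"""Synthetic connectomes and exact small fixtures.

``generate_connectome`` draws a population with the statistical structure the
downstream analyses assume: cells partitioned into superclasses with
spatially clustered somas mirrored across a midline, a type/subtype
hierarchy with a type-level connectivity kernel (so connectivity clustering
has planted signal), a labeled block of types whose in-group connection
probability carries a tunable multiplicative lift, neurotransmitter labels
shared within a type, minorities of descending and Kenyon cells, and
heavy-tailed per-connection synapse counts.

``make_chain_fixture`` builds tiny directed chains whose traversal-rank
expectations are exact rationals (geometric waiting times composed along the
chain), used as oracles for the probabilistic information-flow ranking.

``make_label_table_standin`` builds a SYNTHETIC stand-in for the study's
cell-label spreadsheet, reproducing only its printed marginal counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .errors import ConfigError
from .io import validate_edges, validate_neurons

__all__ = [
    "generate_connectome",
    "expected_in_group_fraction",
    "make_chain_fixture",
    "make_label_table_standin",
    "FixtureGraph",
    "LABEL_STANDIN_SCHEMA_MAP",
]


def _allocate(n: int, proportions: dict, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n items over the proportion keys."""
    keys = list(proportions)
    raw = np.array([proportions[k] for k in keys], dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_connectome(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a (neuron table, edge table) pair; deterministic for a fixed seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    n_types = cfg.n_types

    # --- types nested in superclasses, shuffled so the labeled block of
    # types (a prefix in shuffled order) spans several superclasses
    sc_names = list(cfg.superclass_proportions)
    types_per_sc = _allocate(n_types, cfg.superclass_proportions, rng)
    type_superclass = np.repeat(np.arange(len(sc_names)), types_per_sc)
    type_superclass = rng.permutation(type_superclass)

    # cell -> type, weighted so realized superclass proportions track config
    type_weights = np.array(
        [
            cfg.superclass_proportions[sc_names[type_superclass[t]]]
            / max(1, types_per_sc[type_superclass[t]])
            for t in range(n_types)
        ]
    )
    type_weights = type_weights / type_weights.sum()
    cell_type_idx = rng.choice(n_types, size=n, p=type_weights)

    # --- labeled block: the prefix of types covering ~labeled_fraction cells
    target_labeled = cfg.labeled_fraction * n
    counts = np.bincount(cell_type_idx, minlength=n_types)
    cum = np.cumsum(counts)
    n_labeled_types = 0
    if cfg.labeled_fraction > 0:
        n_labeled_types = max(1, int(np.searchsorted(cum, target_labeled) + 1))
        n_labeled_types = min(n_labeled_types, n_types)
    labeled_type = np.zeros(n_types, dtype=bool)
    labeled_type[:n_labeled_types] = True
    labeled = labeled_type[cell_type_idx]

    # --- subtype within type
    sub_idx = rng.integers(0, cfg.subtypes_per_type, size=n)
    cell_type_names = np.array(
        [f"C{t:03d}.{k}" for t, k in zip(cell_type_idx, sub_idx)]
    )
    fru_dsx_type = np.where(labeled, [f"FD{t:03d}" for t in cell_type_idx], None)
    subtype = np.where(
        labeled,
        [f"FD{t:03d}-C{t:03d}.{k}" for t, k in zip(cell_type_idx, sub_idx)],
        None,
    )

    # gene label per labeled type
    gene_keys = list(cfg.gene_label_proportions)
    gene_p = np.array([cfg.gene_label_proportions[k] for k in gene_keys])
    type_gene = rng.choice(gene_keys, size=n_types, p=gene_p / gene_p.sum())
    gene_label = np.where(labeled, type_gene[cell_type_idx], "none")

    # --- hemisphere and somas: one Gaussian cluster per superclass per side,
    # mirrored across the x = 0 midline
    hemi_draw = rng.random(n)
    hemisphere = np.where(
        hemi_draw < cfg.center_fraction,
        "center",
        np.where(rng.random(n) < 0.5, "left", "right"),
    )
    centers = rng.uniform(
        low=[80.0, 100.0, 100.0], high=[220.0, 500.0, 500.0],
        size=(len(sc_names), 3),
    )
    sc_idx = type_superclass[cell_type_idx]
    soma = centers[sc_idx] + rng.normal(scale=cfg.soma_cluster_spread, size=(n, 3))
    side_sign = np.where(
        hemisphere == "left", -1.0, np.where(hemisphere == "right", 1.0, 0.0)
    )
    soma[:, 0] = soma[:, 0] * side_sign  # center cells sit on the midline

    # neurotransmitter shared within a type
    nt_keys = list(cfg.nt_proportions)
    nt_p = np.array([cfg.nt_proportions[k] for k in nt_keys])
    type_nt = rng.choice(nt_keys, size=n_types, p=nt_p / nt_p.sum())

    is_descending = np.array([sc_names[s] == "descending" for s in sc_idx])
    # Kenyon cells: unlabeled central cells only (labeled set excludes them)
    central = np.array([sc_names[s] == "central" for s in sc_idx])
    kenyon_pool = np.flatnonzero(central & ~labeled)
    n_kenyon = int(round(cfg.kenyon_fraction * n))
    kenyon_ids = rng.choice(kenyon_pool, size=min(n_kenyon, len(kenyon_pool)),
                            replace=False)
    is_kenyon = np.zeros(n, dtype=bool)
    is_kenyon[kenyon_ids] = True

    neurons = pd.DataFrame(
        {
            "cell_id": np.arange(n, dtype=np.int64),
            "hemisphere": hemisphere,
            "superclass": [sc_names[s] for s in sc_idx],
            "gene_label": gene_label,
            "fru_dsx_type": fru_dsx_type,
            "subtype": subtype,
            "soma_x": soma[:, 0],
            "soma_y": soma[:, 1],
            "soma_z": soma[:, 2],
            "neurotransmitter": type_nt[cell_type_idx],
            "is_descending": is_descending,
            "is_kenyon": is_kenyon,
            "cell_type": cell_type_names,
        }
    )

    # --- type-to-type kernel: every pair mixes at weight 1; each type
    # additionally prefers `kernel_targets` downstream types
    kernel = np.ones((n_types, n_types))
    if cfg.kernel_strength > 0 and cfg.kernel_targets > 0:
        for s in range(n_types):
            prefs = rng.choice(n_types, size=min(cfg.kernel_targets, n_types),
                               replace=False)
            kernel[s, prefs] += cfg.kernel_strength

    # --- synaptic contact events, sampled by (source type, labeled) group
    lift = cfg.in_group_lift
    events_per_cell = rng.poisson(cfg.edge_density, size=n)
    pre_list, post_list = [], []
    for s in range(n_types):
        base_w = kernel[s][cell_type_idx].astype(float)
        for lab in (False, True):
            sources = np.flatnonzero((cell_type_idx == s) & (labeled == lab))
            if len(sources) == 0:
                continue
            w = base_w.copy()
            if lab and lift != 1.0:
                w[labeled] *= lift
            total = w.sum()
            if total <= 0:
                continue
            k_events = events_per_cell[sources]
            m = int(k_events.sum())
            if m == 0:
                continue
            targets = rng.choice(n, size=m, p=w / total)
            pre_list.append(np.repeat(sources, k_events))
            post_list.append(targets)
    pre = np.concatenate(pre_list) if pre_list else np.empty(0, dtype=np.int64)
    post = np.concatenate(post_list) if post_list else np.empty(0, dtype=np.int64)
    keep = pre != post  # drop autapse events
    pre, post = pre[keep], post[keep]
    syn = rng.zipf(cfg.syn_zipf_a, size=len(pre))
    # the lift multiplies the expected synapse count of labeled-to-labeled
    # contacts as well as their probability: each in-group contact carries
    # M = 1 + Poisson(lift - 1) i.i.d. count draws (lift >= 1; a sub-unit
    # lift scales probability only)
    if lift > 1.0 and len(pre):
        in_group_event = labeled[pre] & labeled[post]
        extra_n = np.where(
            in_group_event, rng.poisson(lift - 1.0, size=len(pre)), 0
        )
        total_extra = int(extra_n.sum())
        if total_extra:
            extra_draws = rng.zipf(cfg.syn_zipf_a, size=total_extra)
            idx = np.repeat(np.arange(len(pre)), extra_n)
            syn = syn.astype(np.int64)
            np.add.at(syn, idx, extra_draws)

    edges = pd.DataFrame(
        {"pre_id": pre.astype(np.int64), "post_id": post.astype(np.int64),
         "syn_count": syn.astype(np.int64)}
    )
    edges = validate_edges(edges)
    neurons = validate_neurons(neurons)
    return neurons, edges


def expected_in_group_fraction(config: GeneratorConfig, n_labeled: int) -> float:
    """Closed-form expected fraction of a labeled cell's output synapses that
    land on other labeled cells, under a uniform kernel (kernel_strength = 0).

    A labeled source samples each target with weight ``lift`` if labeled and
    1 otherwise (self excluded), so the in-group *contact* probability is
    p = lift*(k-1) / (lift*(k-1) + (n-k)).  For lift >= 1 each in-group
    contact additionally carries lift times the expected synapse count, so
    the expected synapse fraction is lift*p / (lift*p + 1 - p); for
    lift < 1 the contact and synapse fractions coincide.
    """
    if config.kernel_strength != 0:
        raise ConfigError("closed form requires kernel_strength = 0")
    n, k, lift = config.n_cells, n_labeled, config.in_group_lift
    p = lift * (k - 1) / (lift * (k - 1) + (n - k))
    if lift <= 1.0:
        return p
    return lift * p / (lift * p + 1 - p)


@dataclass
class FixtureGraph:
    """A small named graph with exact expected analytic results attached."""

    name: str
    neurons: pd.DataFrame
    edges: pd.DataFrame
    seeds: list
    expected_distance: dict = field(default_factory=dict)  # cell -> Fraction|None
    expected_rank: dict = field(default_factory=dict)  # cell -> Fraction|None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seeds": list(self.seeds),
            "edges": self.edges.to_dict("records"),
            "expected_rank": {
                str(c): (None if r is None else [r.numerator, r.denominator])
                for c, r in self.expected_rank.items()
            },
            "params": {k: str(v) for k, v in self.params.items()},
        }


def make_chain_fixture(
    k: int, fraction: Fraction | float, cap: Fraction = Fraction(3, 10)
) -> FixtureGraph:
    """Directed chain seed -> c1 -> ... -> ck where every chain cell receives
    exactly ``fraction`` of its input synapses from its predecessor (the
    remainder from an unreachable distractor cell).

    Once the predecessor is in the pool a chain cell is accepted with
    probability P = min(fraction / cap, 1) at every step, so its traversal
    distance is a sum of i.i.d. geometric(P) waiting times: expected distance
    of c_i is i / P and expected rank 1 + i / P, exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fraction = Fraction(fraction).limit_denominator(10**6)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    p_num, q = fraction.numerator, fraction.denominator
    # scale synapse counts so both the chain and distractor connections
    # survive a 5-synapse threshold
    s = max(
        math.ceil(5 / p_num),
        math.ceil(5 / (q - p_num)) if q > p_num else 1,
    )
    a = p_num * s  # synapses from predecessor
    b = (q - p_num) * s  # synapses from the distractor

    distractor = k + 1
    rows = []
    for i in range(1, k + 1):
        rows.append((i - 1, i, a))
        if b > 0:
            rows.append((distractor, i, b))
    edges = validate_edges(
        pd.DataFrame(rows, columns=["pre_id", "post_id", "syn_count"])
    )
    cells = list(range(k + 2)) if b > 0 else list(range(k + 1))
    neurons = validate_neurons(
        pd.DataFrame(
            {
                "cell_id": cells,
                "hemisphere": "unknown",
                "superclass": "central",
                "gene_label": "none",
                "fru_dsx_type": None,
                "subtype": None,
                "soma_x": np.nan,
                "soma_y": np.nan,
                "soma_z": np.nan,
                "neurotransmitter": "unknown",
                "is_descending": False,
                "is_kenyon": False,
            }
        )
    )

    accept = min(fraction / cap, Fraction(1))
    expected_distance: dict = {0: Fraction(0)}
    expected_rank: dict = {0: Fraction(1)}
    for i in range(1, k + 1):
        d = Fraction(i, 1) / accept
        expected_distance[i] = d
        expected_rank[i] = 1 + d
    if b > 0:
        expected_distance[distractor] = None  # unreachable
        expected_rank[distractor] = None
    return FixtureGraph(
        name=f"chain_k{k}_f{p_num}_{q}",
        neurons=neurons,
        edges=edges,
        seeds=[0],
        expected_distance=expected_distance,
        expected_rank=expected_rank,
        params={"fraction": fraction, "cap": cap, "accept_prob": accept},
    )


#: column naming used by the synthetic label-table stand-in (spreadsheet-like)
LABEL_STANDIN_SCHEMA_MAP = {
    "cell_id": "root_id",
    "hemisphere": "side",
    "superclass": "super_class",
    "gene_label": "gene",
    "fru_dsx_type": "fru_dsx_type",
    "subtype": "subtype",
    "soma_x": "soma_x_um",
    "soma_y": "soma_y_um",
    "soma_z": "soma_z_um",
    "neurotransmitter": "nt_type",
    "is_descending": "is_dn",
    "is_kenyon": "is_kc",
}

_STANDIN_SUPERCLASSES = [
    "central",
    "visual_projection",
    "descending",
    "ascending",
    "optic",
    "sensory",
    "visual_centrifugal",
]


def make_label_table_standin() -> pd.DataFrame:
    """SYNTHETIC stand-in for the study's cell-label spreadsheet.

    This is not the real supplementary table: it is constructed to reproduce
    only the published marginal counts — 1278 Fru + 50 Dsx + 79 Fru-Dsx =
    1407 labeled cells across 91 morphology types and 236 connectivity
    subtypes, spread over 7 superclasses and both hemispheres — so that the
    loading/validation/summary machinery can be exercised end to end.
    All other content (names, positions, transmitters) is fabricated.
    """
    n_types, n_subtypes, n_cells = 91, 236, 1407
    sub_per_type = [1] * n_types
    extra = n_subtypes - n_types
    i = 0
    while extra > 0:
        sub_per_type[i % n_types] += 1
        i += 1
        extra -= 1
    subtypes = []  # (type_idx, subtype_name)
    for t in range(n_types):
        for s in range(sub_per_type[t]):
            subtypes.append((t, f"FD{t:02d}-C{s}"))
    cells_per_sub = [5] * n_subtypes
    for j in range(n_cells - 5 * n_subtypes):
        cells_per_sub[j % n_subtypes] += 1
    assert sum(cells_per_sub) == n_cells

    rows = []
    cid = 720575940600000000  # spreadsheet-scale ids
    gene_seq = ["Fru"] * 1278 + ["Dsx"] * 50 + ["FruDsx"] * 79
    nt_cycle = ["acetylcholine", "GABA", "glutamate", "unknown"]
    c = 0
    for (t, sub), m in zip(subtypes, cells_per_sub):
        sc = _STANDIN_SUPERCLASSES[t % len(_STANDIN_SUPERCLASSES)]
        for j in range(m):
            rows.append(
                {
                    "root_id": cid,
                    "side": "left" if j % 2 == 0 else "right",
                    "super_class": sc,
                    "gene": gene_seq[c],
                    "fru_dsx_type": f"FD{t:02d}",
                    "subtype": sub,
                    "soma_x_um": float(100 + t),
                    "soma_y_um": float(200 + (j % 7)),
                    "soma_z_um": float(300 + (c % 11)),
                    "nt_type": nt_cycle[t % 4],
                    "is_dn": sc == "descending",
                    "is_kc": False,
                }
            )
            cid += 1
            c += 1
    return pd.DataFrame(rows)
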