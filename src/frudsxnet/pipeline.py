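"""End-to-end orchestration: generate/load -> threshold -> null models ->
type networks -> clustering -> traversal ranks -> screens, with a run
manifest capturing configs, per-stage seeds, row counts and output digests so
that a rerun with an identical manifest reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .clustering import build_features, cluster, feature_distances
from .config import AnalysisConfig, GeneratorConfig
from .flow import (
    TraversalParams,
    multisensory_screen,
    normalize_ranks,
    subtype_normalized_ranks,
    traversal_ranks,
)
from .io import (
    apply_synapse_threshold,
    load_annotations,
    load_edges,
    summarize_population,
    write_annotations,
    write_edges,
)
from .network import (
    assign_edge_sign,
    core_network,
    dn_input_screen,
    pair_fractions,
    symmetric_threshold,
    two_step_neighborhood,
    type_neurotransmitters,
    write_type_graph,
)
from .nullmodels import (
    bias_table,
    connected_pair_fraction,
    external_candidate_screen,
    sample_matched_networks,
    type_bias_summary,
    within_network_fractions,
)
from .synth import generate_connectome

__all__ = ["run_pipeline", "report_tables", "flywire_headline_numbers"]

LABELED = ("Fru", "Dsx", "FruDsx")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _maps(neurons: pd.DataFrame) -> dict:
    lab = neurons.loc[neurons["gene_label"].isin(LABELED)]
    maps = {
        "group_ids": set(lab["cell_id"]),
        "type_map": lab.set_index("cell_id")["fru_dsx_type"].dropna().to_dict(),
        "subtype_map": lab.set_index("cell_id")["subtype"].dropna().to_dict(),
    }
    if "cell_type" in neurons.columns:
        maps["cell_type_map"] = (
            neurons.set_index("cell_id")["cell_type"].dropna().to_dict()
        )
    else:
        maps["cell_type_map"] = maps["subtype_map"]
    return maps


def run_pipeline(
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    generator: GeneratorConfig | None = None,
    annotations_path=None,
    edges_path=None,
    schema_map=None,
    seed_sets: Mapping[str, Iterable] | None = None,
    neighborhood_seeds: Iterable | None = None,
    traversal_reps: int | None = None,
    n_matched: int | None = None,
) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON).

    Inputs come either from ``generator`` (synthetic connectome) or from
    ``annotations_path`` (+ optional ``edges_path``).  When the edge table is
    absent only the population summary is produced, with explicit skip
    notices for the connectivity stages.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.rng_seed)
    stage_seed = {
        name: int(master.integers(2**31))
        for name in ("matched", "bias", "traversal")
    }
    manifest: dict = {
        "package_version": __version__,
        "analysis_config": config.__dict__.copy(),
        "stage_seeds": stage_seed,
        "stages": {},
        "outputs": {},
        "skipped": {},
    }
    t0 = time.time()

    def note(stage: str, **info) -> None:
        manifest["stages"][stage] = {
            **info, "elapsed_s": round(time.time() - t0, 2)
        }

    # ---- stage: inputs
    if generator is not None:
        neurons, edges = generate_connectome(generator)
        manifest["generator_config"] = {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in generator.__dict__.items()
        }
    else:
        if annotations_path is None:
            raise ValueError("either generator or annotations_path is required")
        neurons = load_annotations(annotations_path, schema_map, on_invalid="drop")
        edges = load_edges(edges_path) if edges_path is not None else None
        manifest["inputs"] = {
            "annotations": str(annotations_path),
            "annotations_sha256": _sha256(Path(annotations_path)),
        }
        if edges_path is not None:
            manifest["inputs"]["edges"] = str(edges_path)
            manifest["inputs"]["edges_sha256"] = _sha256(Path(edges_path))
    write_annotations(neurons, out / "annotations.csv")
    note("inputs", n_cells=len(neurons),
         n_edges=(0 if edges is None else len(edges)))

    # ---- stage: population summary
    summary = summarize_population(neurons)
    summary.gene_counts.rename("n_cells").to_csv(out / "gene_counts.csv")
    summary.superclass_by_hemisphere.to_csv(out / "superclass_by_hemisphere.csv")
    summary.cells_per_type.rename("n_cells").to_csv(out / "cells_per_type.csv")
    summary.cells_per_subtype.rename("n_cells").to_csv(out / "cells_per_subtype.csv")
    note("population", n_labeled=summary.n_labeled, n_types=summary.n_types,
         n_subtypes=summary.n_subtypes)

    if edges is None or len(edges) == 0:
        for st in ("null_models", "networks", "clustering", "ranks", "screens"):
            manifest["skipped"][st] = "no edge table supplied"
        _finalize(manifest, out)
        return manifest

    write_edges(edges, out / "edges.csv")
    strong = apply_synapse_threshold(edges, config.min_synapses)
    note("threshold", min_synapses=config.min_synapses,
         n_edges_before=len(edges), n_edges_after=len(strong))

    maps = _maps(neurons)
    group_ids = maps["group_ids"]
    if not group_ids:
        for st in ("null_models", "networks", "clustering", "ranks", "screens"):
            manifest["skipped"][st] = "no labeled cells"
        _finalize(manifest, out)
        return manifest

    # ---- stage: matched networks + within-group connectivity
    n_matched = n_matched if n_matched is not None else config.n_matched_networks
    samples = sample_matched_networks(
        neurons, group_ids, n_samples=n_matched,
        tolerance=config.distance_tolerance, rng=stage_seed["matched"],
    )
    pd.DataFrame(
        [
            {
                "sample": i,
                "mean_pairwise_distance": s.mean_pairwise_distance,
                "reference_distance": s.reference_distance,
                "relative_deviation": s.relative_deviation,
                "n_rejections": s.n_rejections_before_acceptance,
            }
            for i, s in enumerate(samples)
        ]
    ).to_csv(out / "matched_samples.csv", index=False)

    rows = []
    for direction in ("input", "output"):
        wf = within_network_fractions(
            strong, group_ids, direction, exclude_within=maps["type_map"]
        )
        wf["network"] = "labeled"
        rows.append(wf)
    for i, s in enumerate(samples):
        for direction in ("input", "output"):
            wf = within_network_fractions(
                strong, s.member_ids, direction,
                exclude_within=maps["cell_type_map"],
            )
            wf["network"] = f"matched_{i}"
            rows.append(wf)
    fractions = pd.concat(rows, ignore_index=True)
    fractions.to_csv(out / "within_fractions.csv", index=False)

    pair_conn = {
        "labeled": connected_pair_fraction(strong, group_ids),
        "matched_mean": float(
            np.mean([connected_pair_fraction(strong, s.member_ids) for s in samples])
        ),
    }
    note("null_models", n_samples=len(samples), **pair_conn)

    # ---- stage: partner bias + external candidates
    bias = bias_table(strong, group_ids, n_draws=config.n_bias_draws,
                      rng=stage_seed["bias"])
    bias.to_csv(out / "bias_cells.csv", index=False)
    tsum = type_bias_summary(bias, maps["type_map"])
    tsum.to_csv(out / "bias_types.csv", index=False)
    candidates = external_candidate_screen(
        strong, group_ids, maps["cell_type_map"],
        min_fraction=config.external_candidate_fraction,
    )
    candidates.to_csv(out / "external_candidates.csv", index=False)
    note("bias", n_cells=bias["cell_id"].nunique(), n_candidates=len(candidates))

    # ---- stage: subtype network, core, clusters
    pairs = pair_fractions(strong, maps["subtype_map"])
    pairs.to_csv(out / "pair_fractions.csv", index=False)
    graph = symmetric_threshold(pairs, config.symmetric_theta)
    nt_map = type_neurotransmitters(neurons, maps["subtype_map"])
    assign_edge_sign(graph, nt_map)
    write_type_graph(graph, out / "network_nodes.csv", out / "network_edges.csv",
                     out / "network.gexf")
    report = core_network(graph)
    with open(out / "core_components.json", "w") as fh:
        json.dump(
            {
                "core": sorted(map(str, report.core)),
                "n_components": report.n_components,
                "component_sizes": [len(c) for c in report.components],
                "isolated": sorted(map(str, report.isolated)),
            },
            fh, indent=2,
        )
    present = sorted(set(graph.nodes), key=str)
    feats = build_features(strong, {c: s for c, s in maps["subtype_map"].items()},
                           maps["cell_type_map"], subtypes=present)
    assign = cluster(feature_distances(feats), cut_height=config.cluster_cut)
    assign.labels.rename("cluster").to_csv(out / "clusters.csv")
    if neighborhood_seeds:
        nb = two_step_neighborhood(
            pairs, neighborhood_seeds,
            config.neighborhood_theta1, config.neighborhood_theta2,
        )
        write_type_graph(nb, out / "neighborhood_nodes.csv",
                         out / "neighborhood_edges.csv")
    note("networks", n_subtypes_in_network=len(present),
         core_size=len(report.core), n_clusters=assign.n_clusters)

    # ---- stage: traversal ranks per seed set
    if seed_sets is None:
        seed_sets = {}
        for sc in ("sensory", "visual_projection"):
            ids = neurons.loc[neurons["superclass"] == sc, "cell_id"]
            ids = ids[ids.isin(strong["pre_id"]) | ids.isin(strong["post_id"])]
            if len(ids):
                seed_sets[sc] = ids.tolist()
    reps = traversal_reps if traversal_reps is not None else config.traversal_reps_sensory
    sub_ranks = {}
    trng = np.random.default_rng(stage_seed["traversal"])
    for name, seeds in sorted(seed_sets.items()):
        params = TraversalParams(cap=config.traversal_cap, n_reps=reps,
                                 rng_seed=int(trng.integers(2**31)))
        rk = normalize_ranks(traversal_ranks(strong, seeds, params))
        rk.to_csv(out / f"ranks_{name}.csv", index=False)
        sub_ranks[name] = subtype_normalized_ranks(rk, maps["subtype_map"])
    if len(sub_ranks) >= 2:
        multi = multisensory_screen(sub_ranks, config.multisensory_rank_cutoff)
        multi.to_csv(out / "multisensory.csv", index=False)
    note("ranks", modalities=sorted(seed_sets), n_reps=reps)

    # ---- stage: descending-neuron screen
    dn_tab, dn_edges = dn_input_screen(
        strong, group_ids, neurons,
        min_input_fraction=config.dn_input_fraction,
        theta=config.neighborhood_theta1,
    )
    dn_tab.to_csv(out / "dn_screen.csv", index=False)
    dn_edges.to_csv(out / "dn_edges.csv", index=False)
    note("screens", n_dn_types=len(dn_tab),
         n_dn_passing=int(dn_tab["passes"].sum()) if len(dn_tab) else 0)

    _finalize(manifest, out)
    return manifest


def _finalize(manifest: dict, out: Path) -> None:
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest["outputs"][f.name] = {
            "sha256": _sha256(f), "bytes": f.stat().st_size
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


#: figure-style report bundles and the stage outputs they repackage
_BUNDLES = {
    "fractions_vs_matched": ["within_fractions.csv", "matched_samples.csv"],
    "partner_bias": ["bias_cells.csv", "bias_types.csv"],
    "external_candidates": ["external_candidates.csv"],
    "connectivity_clusters": ["clusters.csv"],
    "type_network": ["network_nodes.csv", "network_edges.csv",
                     "core_components.json"],
    "seed_neighborhood": ["neighborhood_nodes.csv", "neighborhood_edges.csv"],
    "sensory_ranks": ["multisensory.csv"],
    "dn_map": ["dn_screen.csv", "dn_edges.csv"],
}


def report_tables(out_dir: str | Path) -> dict:
    """Index the per-figure-style CSV bundles produced by a pipeline run.

    Returns a mapping bundle -> {'files': present files, 'missing': absent
    ones}; written alongside the outputs as ``bundle_index.json``.
    """
    out = Path(out_dir)
    rank_files = sorted(p.name for p in out.glob("ranks_*.csv"))
    index = {}
    for bundle, files in _BUNDLES.items():
        files = list(files)
        if bundle == "sensory_ranks":
            files = rank_files + files
        present = [f for f in files if (out / f).exists()]
        missing = [f for f in files if not (out / f).exists()]
        index[bundle] = {"files": present, "missing": missing}
    with open(out / "bundle_index.json", "w") as fh:
        json.dump(index, fh, indent=2)
    return index


def flywire_headline_numbers(
    data_dir: str | Path, config: AnalysisConfig | None = None
) -> dict:
    """Recompute the study's headline connectivity numbers from a local
    whole-brain snapshot export.

    Expects ``data_dir`` to contain ``annotations.(csv|xlsx)`` (+ optional
    ``schema_map.yaml``) and ``edges.csv`` with pre/post/count columns.
    Returns the snapshot-wide quantities: subtypes present in the 3%
    symmetric network, core-component size, mean within-group input/output
    fractions per type, the SAG output fraction, DN types passing the 10%
    input rule, cluster count at the configured cut, and the labeled group's
    mean pairwise soma distance.
    """
    from .nullmodels import mean_pairwise_distance

    config = config or AnalysisConfig()
    data = Path(data_dir)
    ann = next((p for p in (data / "annotations.csv", data / "annotations.xlsx")
                if p.exists()), None)
    if ann is None or not (data / "edges.csv").exists():
        raise FileNotFoundError(
            f"snapshot files not found under {data}: need annotations.csv/xlsx "
            "and edges.csv"
        )
    schema = data / "schema_map.yaml"
    neurons = load_annotations(ann, schema if schema.exists() else None,
                               on_invalid="drop")
    edges = load_edges(data / "edges.csv")
    strong = apply_synapse_threshold(edges, config.min_synapses)
    maps = _maps(neurons)
    group_ids = maps["group_ids"]

    pairs = pair_fractions(strong, maps["subtype_map"])
    graph = symmetric_threshold(pairs, config.symmetric_theta)
    report = core_network(graph)
    present = sorted(set(graph.nodes), key=str)

    per_type = {}
    for direction in ("input", "output"):
        wf = within_network_fractions(strong, group_ids, direction,
                                      exclude_within=maps["type_map"])
        wf["type"] = wf["cell_id"].map(maps["type_map"])
        per_type[direction] = (
            wf.dropna(subset=["fraction"]).groupby("type")["fraction"].mean().mean()
        )

    sag_cells = {
        c for c, t in maps["type_map"].items() if str(t).upper().startswith("SAG")
    }
    sag_out = np.nan
    if sag_cells:
        wf = within_network_fractions(strong, group_ids, "output")
        sag_out = wf.loc[wf["cell_id"].isin(sag_cells), ["group_synapses",
                                                         "total_synapses"]].sum()
        sag_out = float(sag_out["group_synapses"] / sag_out["total_synapses"])

    dn_tab, _ = dn_input_screen(strong, group_ids, neurons,
                                min_input_fraction=config.dn_input_fraction)
    feats = build_features(strong, maps["subtype_map"], maps["cell_type_map"],
                           subtypes=present)
    assign = cluster(feature_distances(feats), cut_height=config.cluster_cut)

    return {
        "n_subtypes_total": len(set(maps["subtype_map"].values())),
        "n_subtypes_in_network": len(present),
        "core_size": len(report.core),
        "mean_input_fraction_pct": 100 * float(per_type["input"]),
        "mean_output_fraction_pct": 100 * float(per_type["output"]),
        "sag_output_fraction_pct": 100 * sag_out,
        "n_dn_types_passing": int(dn_tab["passes"].sum()) if len(dn_tab) else 0,
        "n_clusters": assign.n_clusters,
        "mean_pairwise_distance_um": mean_pairwise_distance(neurons, group_ids),
    }
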