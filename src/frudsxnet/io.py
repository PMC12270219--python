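"""Data model and I/O for neuron annotation and synaptic edge tables.

A *neuron table* holds one row per reconstructed cell: identifier,
hemisphere, superclass, gene label (Fru / Dsx / FruDsx / none), morphology
type and connectivity subtype for labeled cells, soma position in
micrometres, neurotransmitter, and descending / Kenyon-cell flags.  An *edge
table* holds the directed synaptic graph as (pre_id, post_id, syn_count)
rows, pre meaning presynaptic.  Both are plain pandas DataFrames with a
validated schema; cells that appear only in the edge table are legitimate
"background" cells and participate in all synapse-total denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, ParseError, SchemaError

__all__ = [
    "NEURON_COLUMNS",
    "EDGE_COLUMNS",
    "HEMISPHERES",
    "GENE_LABELS",
    "PopulationSummary",
    "load_annotations",
    "load_edges",
    "load_schema_map",
    "validate_neurons",
    "validate_edges",
    "apply_synapse_threshold",
    "summarize_population",
    "write_annotations",
    "write_edges",
    "self_edges",
]

NEURON_COLUMNS = [
    "cell_id",
    "hemisphere",
    "superclass",
    "gene_label",
    "fru_dsx_type",
    "subtype",
    "soma_x",
    "soma_y",
    "soma_z",
    "neurotransmitter",
    "is_descending",
    "is_kenyon",
]
#: optional extra column carrying the connectome ("primary") cell type of
#: every cell, labeled or background; used as the default grouping universe.
OPTIONAL_NEURON_COLUMNS = ["cell_type"]

EDGE_COLUMNS = ["pre_id", "post_id", "syn_count"]

HEMISPHERES = frozenset({"left", "right", "center", "unknown"})
GENE_LABELS = frozenset({"Fru", "Dsx", "FruDsx", "none"})

LABELED = ("Fru", "Dsx", "FruDsx")


def load_schema_map(path: str | Path) -> dict:
    """Read a YAML mapping of canonical column names to file column names."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise SchemaError(f"schema map {path} is not a mapping")
    return dict(mapping)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, sheet_name=0)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def validate_neurons(df: pd.DataFrame, on_invalid: str = "raise") -> pd.DataFrame:
    """Validate and normalize a neuron table.

    Duplicate ``cell_id`` is always a hard :class:`IntegrityError`.  Row-level
    invariant violations (unknown hemisphere / gene label, labeled cell
    without a type, non-finite soma coordinate) either raise or, with
    ``on_invalid='drop'``, are removed; dropped rows and their reasons are
    attached as ``result.attrs['rejected_rows']``.
    """
    if on_invalid not in {"raise", "drop"}:
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    missing = [c for c in NEURON_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"neuron table is missing required columns: {missing}")

    out = df.copy()
    out["cell_id"] = pd.to_numeric(out["cell_id"], errors="raise").astype(np.int64)
    dup = out["cell_id"][out["cell_id"].duplicated()]
    if len(dup):
        raise IntegrityError(
            f"duplicate cell_id values: {sorted(set(dup.tolist()))[:10]}"
        )
    for col in ("soma_x", "soma_y", "soma_z"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in ("is_descending", "is_kenyon"):
        out[col] = out[col].astype(bool)
    for col in ("hemisphere", "superclass", "gene_label", "neurotransmitter"):
        out[col] = out[col].astype(str)
    for col in ("fru_dsx_type", "subtype", "cell_type"):
        if col in out.columns:
            out[col] = out[col].where(out[col].notna(), np.nan)

    reasons = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in out.index[mask]:
            reasons.setdefault(idx, []).append(reason)

    flag(~out["hemisphere"].isin(HEMISPHERES), "unknown hemisphere")
    flag(~out["gene_label"].isin(GENE_LABELS), "unknown gene_label")
    flag(
        out["gene_label"].isin(LABELED) & out["fru_dsx_type"].isna(),
        "labeled cell without fru_dsx_type",
    )
    soma = out[["soma_x", "soma_y", "soma_z"]]
    partial = soma.isna().any(axis=1) & ~soma.isna().all(axis=1)
    flag(partial, "partially specified soma position")
    inf = np.isinf(soma.to_numpy(dtype=float)).any(axis=1)
    flag(pd.Series(inf, index=out.index), "non-finite soma coordinate")

    if reasons:
        report = pd.DataFrame(
            {
                "cell_id": out.loc[list(reasons), "cell_id"].to_numpy(),
                "reasons": ["; ".join(v) for v in reasons.values()],
            }
        )
        if on_invalid == "raise":
            raise IntegrityError(
                f"{len(report)} rows violate neuron-table invariants; "
                f"first offenders: {report.head(5).to_dict('records')}"
            )
        out = out.drop(index=list(reasons)).reset_index(drop=True)
        out.attrs["rejected_rows"] = report
    else:
        out = out.reset_index(drop=True)
        out.attrs["rejected_rows"] = pd.DataFrame(columns=["cell_id", "reasons"])

    # subtype -> type consistency: a subtype may not span two primary types
    sub = out.loc[out["subtype"].notna(), ["subtype", "fru_dsx_type"]]
    n_parents = sub.groupby("subtype")["fru_dsx_type"].nunique()
    bad = n_parents[n_parents > 1]
    if len(bad):
        raise IntegrityError(
            f"subtypes mapping to multiple fru_dsx_type values: {list(bad.index)[:10]}"
        )
    keep = NEURON_COLUMNS + [c for c in OPTIONAL_NEURON_COLUMNS if c in out.columns]
    rejected = out.attrs["rejected_rows"]
    out = out[keep]
    out.attrs["rejected_rows"] = rejected
    return out


def load_annotations(
    path: str | Path,
    schema_map: Mapping[str, str] | str | Path | None = None,
    on_invalid: str = "raise",
) -> pd.DataFrame:
    """Load a neuron annotation table from CSV/TSV/XLSX.

    ``schema_map`` maps canonical column names (see :data:`NEURON_COLUMNS`)
    to the column names present in the file, so both spreadsheet exports and
    pipeline-native files load without code edits.  Missing optional flags
    (``is_descending``, ``is_kenyon``) default to False; missing soma
    columns default to NaN.
    """
    raw = _read_table(path)
    if schema_map is not None and not isinstance(schema_map, Mapping):
        schema_map = load_schema_map(schema_map)
    if schema_map:
        unresolvable = [v for v in schema_map.values() if v not in raw.columns]
        if unresolvable:
            raise SchemaError(
                f"schema map names columns absent from {path}: {unresolvable}"
            )
        raw = raw.rename(columns={v: k for k, v in schema_map.items()})
    for col, default in (
        ("is_descending", False),
        ("is_kenyon", False),
        ("fru_dsx_type", np.nan),
        ("subtype", np.nan),
        ("soma_x", np.nan),
        ("soma_y", np.nan),
        ("soma_z", np.nan),
        ("hemisphere", "unknown"),
        ("neurotransmitter", "unknown"),
        ("gene_label", "none"),
    ):
        if col not in raw.columns:
            raw[col] = default
    return validate_neurons(raw, on_invalid=on_invalid)


def validate_edges(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"edge table is missing required columns: {missing}")
    out = df[EDGE_COLUMNS].copy()
    if len(out) == 0:
        return out.astype({c: np.int64 for c in EDGE_COLUMNS})
    counts = pd.to_numeric(out["syn_count"], errors="coerce")
    if counts.isna().any() or (counts % 1 != 0).any():
        raise ParseError("syn_count contains non-integer values")
    if (counts < 1).any():
        raise ParseError("syn_count contains values < 1")
    out["syn_count"] = counts.astype(np.int64)
    for col in ("pre_id", "post_id"):
        out[col] = pd.to_numeric(out[col], errors="raise").astype(np.int64)
    out = (
        out.groupby(["pre_id", "post_id"], as_index=False, sort=True)["syn_count"]
        .sum()
    )
    return out


def load_edges(path: str | Path, columns: Sequence[str] = ("pre", "post", "count")) -> pd.DataFrame:
    """Load a directed synapse edge table; duplicate (pre, post) rows are summed."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    if path.suffix.lower() == ".parquet":
        raw = pd.read_parquet(path)
    else:
        raw = pd.read_csv(path, sep=sep)
    if len(raw) == 0:
        warnings.warn(f"edge table {path} is empty", stacklevel=2)
        return pd.DataFrame(columns=EDGE_COLUMNS).astype(np.int64)
    rename = dict(zip(columns, EDGE_COLUMNS))
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise SchemaError(f"edge table {path} lacks columns {missing}")
    return validate_edges(raw.rename(columns=rename))


def apply_synapse_threshold(edges: pd.DataFrame, min_synapses: int) -> pd.DataFrame:
    """Keep only connections with at least ``min_synapses`` synapses.

    The published analyses threshold every connection at 5 synapses before
    any downstream computation.
    """
    if min_synapses < 1:
        raise ValueError(f"min_synapses must be >= 1, got {min_synapses!r}")
    return edges.loc[edges["syn_count"] >= min_synapses].reset_index(drop=True)


def self_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Autapses (pre == post); flagged for inspection, never silently dropped."""
    return edges.loc[edges["pre_id"] == edges["post_id"]]


@dataclass
class PopulationSummary:
    n_cells: int
    n_labeled: int
    gene_counts: pd.Series
    superclass_by_hemisphere: pd.DataFrame
    cells_per_type: pd.Series
    cells_per_subtype: pd.Series

    @property
    def n_types(self) -> int:
        return int(self.cells_per_type.size)

    @property
    def n_subtypes(self) -> int:
        return int(self.cells_per_subtype.size)


def summarize_population(
    neurons: pd.DataFrame, restrict: Sequence[str] = LABELED
) -> PopulationSummary:
    """Count labeled cells by gene label, superclass x hemisphere, type, subtype."""
    labeled = neurons.loc[neurons["gene_label"].isin(restrict)]
    gene_counts = (
        labeled["gene_label"].value_counts().reindex(list(restrict), fill_value=0)
    )
    sc = (
        labeled.groupby(["superclass", "hemisphere"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    per_type = labeled.groupby("fru_dsx_type", observed=True).size().sort_index()
    per_subtype = labeled.groupby("subtype", observed=True).size().sort_index()
    return PopulationSummary(
        n_cells=int(len(neurons)),
        n_labeled=int(len(labeled)),
        gene_counts=gene_counts,
        superclass_by_hemisphere=sc,
        cells_per_type=per_type,
        cells_per_subtype=per_subtype,
    )


def write_annotations(neurons: pd.DataFrame, path: str | Path) -> None:
    cols = NEURON_COLUMNS + [c for c in OPTIONAL_NEURON_COLUMNS if c in neurons.columns]
    neurons[cols].to_csv(path, index=False)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges[EDGE_COLUMNS].to_csv(path, index=False)
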