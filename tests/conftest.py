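import numpy as np
import pandas as pd
import pytest

from frudsxnet.config import GeneratorConfig
from frudsxnet.io import apply_synapse_threshold, validate_edges, validate_neurons
from frudsxnet.synth import generate_connectome


def edge_table(rows):
    """Build a validated edge table from (pre, post, count) tuples."""
    return validate_edges(
        pd.DataFrame(rows, columns=["pre_id", "post_id", "syn_count"])
    )


def neuron_table(records):
    """Build a validated neuron table, filling schema defaults."""
    df = pd.DataFrame(records)
    defaults = {
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
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
        elif val is not None and not (isinstance(val, float) and np.isnan(val)):
            df[col] = df[col].where(df[col].notna(), val)
    return validate_neurons(df)


def random_edges(rng, n_cells, density=0.4, max_count=30):
    """Random directed graph on cells 0..n_cells-1 with integer weights."""
    rows = []
    for a in range(n_cells):
        for b in range(n_cells):
            if a != b and rng.random() < density:
                rows.append((a, b, int(rng.integers(1, max_count + 1))))
    if not rows:
        rows = [(0, 1 % n_cells, 1)]
    return edge_table(rows)


@pytest.fixture(scope="session")
def synth_lift1():
    """Uniform-mixing connectome with no planted group effect (null)."""
    cfg = GeneratorConfig(
        n_cells=4000, labeled_fraction=0.05, in_group_lift=1.0,
        kernel_strength=0.0, seed=101,
    )
    neurons, edges = generate_connectome(cfg)
    return cfg, neurons, edges


@pytest.fixture(scope="session")
def synth_lift5():
    """Connectome with a strongly assortative planted labeled group."""
    cfg = GeneratorConfig(
        n_cells=4000, labeled_fraction=0.05, in_group_lift=5.0,
        kernel_strength=0.0, seed=101,
    )
    neurons, edges = generate_connectome(cfg)
    return cfg, neurons, edges


@pytest.fixture(scope="session")
def synth_structured():
    """Connectome with type-level connectivity structure (for clustering
    and network-shape tests)."""
    cfg = GeneratorConfig(
        n_cells=3000, labeled_fraction=0.10, in_group_lift=5.0,
        kernel_strength=4.0, edge_density=150.0, seed=202,
    )
    neurons, edges = generate_connectome(cfg)
    strong = apply_synapse_threshold(edges, 5)
    return cfg, neurons, strong


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
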