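"""Analysis and generator configuration.

``AnalysisConfig`` collects every numeric parameter the downstream analyses
use, with defaults matching the published study: a 5-synapse connection
threshold, a 3% symmetric (bidirectional) threshold for type-level networks,
1%/3% thresholds for the two-step seed neighborhoods, a 0.05% threshold for
weak single-type diagrams, a 10% input rule for the descending-neuron screen,
a 50% rule for the external-candidate screen, 100 matched networks at a
+/-2% mean-distance tolerance, 100 random partner draws for the bias
statistic, a 0.3 traversal probability cap with 10000/1000 repetitions, a
hierarchical-clustering cut at distance 0.3, and a 10% normalized-rank
cutoff for the multisensory screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ConfigError

__all__ = ["AnalysisConfig", "GeneratorConfig"]


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


def _check_count(name: str, value: int) -> None:
    if not (isinstance(value, (int,)) and value >= 1):
        raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")


@dataclass
class AnalysisConfig:
    min_synapses: int = 5
    symmetric_theta: float = 0.03
    neighborhood_theta1: float = 0.01
    neighborhood_theta2: float = 0.03
    weak_theta: float = 0.0005
    dn_input_fraction: float = 0.10
    external_candidate_fraction: float = 0.50
    n_matched_networks: int = 100
    distance_tolerance: float = 0.02
    n_bias_draws: int = 100
    traversal_cap: float = 0.3
    traversal_reps_sensory: int = 10000
    traversal_reps_type: int = 1000
    cluster_cut: float = 0.3
    multisensory_rank_cutoff: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "symmetric_theta",
            "neighborhood_theta1",
            "neighborhood_theta2",
            "weak_theta",
            "dn_input_fraction",
            "external_candidate_fraction",
            "distance_tolerance",
            "multisensory_rank_cutoff",
        ):
            _check_fraction(name, getattr(self, name))
        if not (0.0 < self.traversal_cap <= 1.0):
            raise ConfigError(
                f"traversal_cap must be in (0, 1], got {self.traversal_cap!r}"
            )
        for name in (
            "min_synapses",
            "n_matched_networks",
            "n_bias_draws",
            "traversal_reps_sensory",
            "traversal_reps_type",
        ):
            _check_count(name, getattr(self, name))
        if self.cluster_cut < 0:
            raise ConfigError(f"cluster_cut must be >= 0, got {self.cluster_cut!r}")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-connectome generator.

    The generator emulates the statistical structure of a whole-brain
    connectome around a labeled cell group: superclass partition with
    spatially clustered somas mirrored across a midline, a type/subtype
    hierarchy, a planted labeled block of types with a tunable multiplicative
    lift on labeled-to-labeled connection probability, neurotransmitter
    labels, a minority of descending/Kenyon cells, and heavy-tailed synapse
    counts per connection (so a 5-synapse threshold removes a realistic share
    of edges).
    """

    n_cells: int = 5000
    superclass_proportions: dict = field(
        default_factory=lambda: {
            "central": 0.60,
            "visual_projection": 0.18,
            "optic": 0.08,
            "descending": 0.06,
            "ascending": 0.04,
            "sensory": 0.04,
        }
    )
    n_types: int = 40
    subtypes_per_type: int = 2
    labeled_fraction: float = 0.05
    in_group_lift: float = 1.0
    soma_cluster_spread: float = 30.0  # micrometres, per-superclass Gaussian s.d.
    edge_density: float = 50.0  # expected synaptic contacts sampled per cell
    syn_zipf_a: float = 2.3  # exponent of the per-contact synapse-count law
    kernel_strength: float = 3.0  # type-to-type connectivity preference contrast
    kernel_targets: int = 5  # preferred downstream types per type
    kenyon_fraction: float = 0.04
    center_fraction: float = 0.02  # cells without a clean hemisphere side
    nt_proportions: dict = field(
        default_factory=lambda: {
            "acetylcholine": 0.55,
            "GABA": 0.25,
            "glutamate": 0.15,
            "unknown": 0.05,
        }
    )
    gene_label_proportions: dict = field(
        default_factory=lambda: {"Fru": 0.9083, "Dsx": 0.0355, "FruDsx": 0.0562}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cells < 2:
            raise ConfigError(f"n_cells must be >= 2, got {self.n_cells!r}")
        _check_fraction("labeled_fraction", self.labeled_fraction)
        _check_fraction("kenyon_fraction", self.kenyon_fraction)
        _check_fraction("center_fraction", self.center_fraction)
        if self.in_group_lift < 0:
            raise ConfigError(
                f"in_group_lift must be >= 0, got {self.in_group_lift!r}"
            )
        for name in ("superclass_proportions", "nt_proportions",
                     "gene_label_proportions"):
            props = getattr(self, name)
            total = sum(props.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1, got {total!r}")
            if any(v < 0 for v in props.values()):
                raise ConfigError(f"{name} entries must be >= 0")
        _check_count("n_types", self.n_types)
        _check_count("subtypes_per_type", self.subtypes_per_type)
        if self.syn_zipf_a <= 2.0:
            raise ConfigError(
                "syn_zipf_a must exceed 2 so per-contact synapse counts have "
                f"a finite mean, got {self.syn_zipf_a!r}"
            )
        if self.edge_density <= 0:
            raise ConfigError(f"edge_density must be > 0, got {self.edge_density!r}")
        if self.soma_cluster_spread <= 0:
            raise ConfigError(
                f"soma_cluster_spread must be > 0, got {self.soma_cluster_spread!r}"
            )


def config_fields(cls) -> list[str]:
    return [f.name for f in fields(cls)]
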