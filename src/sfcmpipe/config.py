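"""Pipeline configuration.

Defaults follow the published operating point of the method: |r| > 0.8
correlation pruning, top-10 traits for the cleaning pass and top-8 for
the grouping pass, ~100,000-point pooled subsets, odd forest sizes
(10,001 importance / 1,001 classification / 10,001 biovolume trees), a
>5% abundance floor for functional-group assignment, and density-peak
clustering with tol = 0.25, h0 = 0.05, h = 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigurationError


@dataclass
class ClusterParams:
    """Tuning parameters of the density-peak merging step.

    ``tol`` controls both the peak-coincidence distance and the allowed
    density dip between merged clusters; ``h`` scales each k-means
    component's covariance when smoothing the density estimate; ``h0``
    adds a data-scaled diagonal floor so near-degenerate components keep
    a usable density.  ``k0`` is the number of initial k-means
    components (``None`` = max(8, floor(sqrt(n)/2)), capped at 200).
    """

    tol: float = 0.25
    h0: float = 0.05
    h: float = 2.0
    k0: int | None = None
    max_climb_iters: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tol < 1):
            raise ConfigurationError("tol must lie in (0, 1)")
        if self.h0 < 0:
            raise ConfigurationError("h0 must be >= 0")
        if not self.h > 0:
            raise ConfigurationError("h must be > 0")
        if self.k0 is not None and self.k0 < 1:
            raise ConfigurationError("k0 must be >= 1")

    @staticmethod
    def default_k0(n: int) -> int:
        return min(200, max(8, int(n**0.5 // 2)))


@dataclass
class PipelineConfig:
    """End-to-end configuration of the cleaning/grouping/biovolume pipeline."""

    correlation_threshold: float = 0.8
    n_top_clean: int = 10
    n_top_group: int = 8
    subset_size: int = 100_000
    trees_importance: int = 10_001
    trees_classify: int = 1_001
    trees_biovolume: int = 10_001
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    min_group_fraction: float = 0.05
    live_margin_log10: float = 1.0
    #: Clusters whose median Red1Red2.ratio exceeds this are never called
    #: cyanobacteria, however low their rank.
    cyano_ratio_max: float = 1.5
    detection_limit_substitution_factor: float = 0.5
    #: Explicit live-cluster override (the manual-inspection escape
    #: hatch); ``None`` = use the fluorescence-margin rule.
    live_cluster_override: list | None = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.correlation_threshold < 1):
            raise ConfigurationError("correlation_threshold must lie in (0, 1)")
        if not (0 < self.min_group_fraction < 1):
            raise ConfigurationError("min_group_fraction must lie in (0, 1)")
        for name in ("trees_importance", "trees_classify", "trees_biovolume"):
            n = getattr(self, name)
            if n < 3 or n % 2 == 0:
                raise ConfigurationError(f"{name} must be odd and >= 3")
        if isinstance(self.cluster_params, dict):
            self.cluster_params = ClusterParams(**self.cluster_params)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
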