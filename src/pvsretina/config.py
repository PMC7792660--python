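"""Pipeline configuration.

One configuration object carries every tunable parameter of the pipeline:
Frangi filter settings, connected-component filters, retinal geometry and
caliber constants, and the statistics stage (bootstrap replicates, FDR
level). A single global seed governs every stochastic stage so that a full
run is reproducible from one knob.

The file format is YAML — a single human-readable key-value file that
round-trips through serialization unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "FrangiParams",
    "ComponentFilterParams",
    "QCParams",
    "RetinaParams",
    "StatsParams",
    "PipelineConfig",
]


@dataclass
class FrangiParams:
    """Multi-scale Frangi vesselness settings.

    ``scales`` are Gaussian SDs in mm (anatomical, not voxel, units). PVS are
    by definition thinner than 3 mm in diameter, which bounds the largest
    useful scale near 1.5 mm. ``c`` is the structureness sensitivity in
    intensity units; when None it is set per volume to half the ROI's robust
    intensity range (99th - 1st percentile)/2.
    """

    scales: tuple[float, ...] = (0.5, 1.0, 1.5)
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None
    threshold: float = 0.15
    low_threshold: float | None = 0.06

    def validate(self) -> None:
        scales = tuple(float(s) for s in self.scales)
        if len(scales) == 0:
            raise ValueError("scales must be non-empty")
        if any(s <= 0 for s in scales):
            raise ValueError("scales must be strictly positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.c is not None and self.c <= 0:
            raise ValueError("c must be positive (or None for per-volume adaptive)")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.low_threshold is not None and not (0 < self.low_threshold < self.threshold):
            raise ValueError("low_threshold must lie in (0, threshold)")


@dataclass
class ComponentFilterParams:
    """Connected-component labelling and size filters.

    26-connectivity is the default: thin oblique tubes on an anisotropic
    grid fragment under 6-connectivity. Components of a single voxel are
    dropped as noise. ``max_width_mm`` can enforce the < 3 mm diameter
    definition post hoc but is disabled by default.
    """

    connectivity: int = 26
    min_voxels: int = 2
    max_width_mm: float | None = None

    def validate(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.max_width_mm is not None and self.max_width_mm <= 0:
            raise ValueError("max_width_mm must be positive or None")


@dataclass
class QCParams:
    """Automated quality-control ceilings (surrogate for visual checking)."""

    max_roi_fraction: float = 0.10
    max_components: int = 2000
    stripe_fraction: float = 0.5
    stripe_min_components: int = 40
    stripe_angle_deg: float = 5.0

    def validate(self) -> None:
        if not (0 < self.max_roi_fraction <= 1):
            raise ValueError("max_roi_fraction must lie in (0, 1]")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if not (0 < self.stripe_fraction <= 1):
            raise ValueError("stripe_fraction must lie in (0, 1]")
        if self.stripe_min_components < 2:
            raise ValueError("stripe_min_components must be >= 2")
        if self.stripe_angle_deg <= 0:
            raise ValueError("stripe_angle_deg must be positive")


@dataclass
class RetinaParams:
    """Retinal caliber and fractal-dimension settings.

    Zone B is the annulus 0.5 to 1.0 optic-disc diameters from the disc
    centre. The branching coefficients follow the revised caliber-summary
    convention: 0.88 for arterioles, 0.95 for venules; both configurable.
    """

    zone_b_inner_od: float = 0.5
    zone_b_outer_od: float = 1.0
    k_arteriole: float = 0.88
    k_venule: float = 0.95
    fd_min_box: int = 2
    fd_box_divisor: int = 4

    def validate(self) -> None:
        if not (0 < self.zone_b_inner_od < self.zone_b_outer_od):
            raise ValueError("zone B radii must satisfy 0 < inner < outer")
        if self.k_arteriole <= 0 or self.k_venule <= 0:
            raise ValueError("branching coefficients must be positive")
        if self.fd_min_box < 2:
            raise ValueError("fd_min_box must be >= 2")
        if self.fd_box_divisor < 2:
            raise ValueError("fd_box_divisor must be >= 2")


@dataclass
class StatsParams:
    """Association-stage settings: bootstrap replicates, FDR level."""

    n_boot: int = 2000
    fdr_level: float = 0.05

    def validate(self) -> None:
        if self.n_boot < 200:
            raise ValueError("n_boot must be >= 200")
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must lie in (0, 1)")


@dataclass
class PipelineConfig:
    frangi: FrangiParams = field(default_factory=FrangiParams)
    components: ComponentFilterParams = field(default_factory=ComponentFilterParams)
    qc: QCParams = field(default_factory=QCParams)
    retina: RetinaParams = field(default_factory=RetinaParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0

    def validate(self) -> None:
        self.frangi.validate()
        self.components.validate()
        self.qc.validate()
        self.retina.validate()
        self.stats.validate()
        if int(self.seed) != self.seed or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["frangi"]["scales"] = list(self.frangi.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(
            frangi=FrangiParams(**{**d.get("frangi", {}),
                                   "scales": tuple(d.get("frangi", {}).get("scales", (0.5, 1.0, 1.5)))}),
            components=ComponentFilterParams(**d.get("components", {})),
            qc=QCParams(**d.get("qc", {})),
            retina=RetinaParams(**d.get("retina", {})),
            stats=StatsParams(**d.get("stats", {})),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
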