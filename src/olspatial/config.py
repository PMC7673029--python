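"""Configuration objects for the synthetic tissue / ISS / expression generators.

Regions are axis-aligned vertical strips (half-open in x), which keeps
point-in-region queries trivial for ROI accounting. All coordinates are
0-based pixel indices with x = column and y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

#: fixed base <-> fluorescence channel order (A=Cy5, C=Texas Red, G=Cy3, T=AF488)
BASES = "ACGT"


@dataclass(frozen=True)
class Region:
    """A named vertical strip ``x_min <= x < x_max`` of the imaged field."""

    name: str
    x_min: float
    x_max: float

    def contains(self, x: float) -> bool:
        return self.x_min <= x < self.x_max


def region_of(x: float, regions: list[Region]) -> Optional[str]:
    """Name of the strip containing column coordinate ``x`` (None if outside)."""
    for r in regions:
        if r.contains(x):
            return r.name
    return None


@dataclass
class SimConfig:
    """Parameters of one simulated tissue field.

    ``proportions`` maps region name -> {population -> fraction}; fractions
    must sum to 1 per region. ``expression`` maps population -> {gene ->
    mean ISS spot count per cell}. ``puncta`` maps population -> {marker ->
    mean puncta count per cell} for the RNAscope-style generator.
    ``noise_level`` is the standard deviation of the additive per-channel
    Gaussian noise expressed as a fraction of the signal amplitude;
    ``crosstalk`` is the fraction of the amplitude leaking into each
    off-target channel.
    """

    field_shape: tuple[int, int] = (512, 512)  # (height, width) pixels
    n_nuclei: int = 100
    radius_range: tuple[float, float] = (6.0, 9.0)
    min_separation_margin: float = 22.0  # extra center spacing beyond 2*r_max
    regions: list[Region] = field(
        default_factory=lambda: [Region("WM", 0.0, 256.0), Region("GM", 256.0, 512.0)]
    )
    proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "WM": {"MOL2": 0.30, "MOL5/6": 0.30, "MOL1": 0.40},
            "GM": {"MOL2": 0.05, "MOL5/6": 0.60, "MOL1": 0.35},
        }
    )
    expression: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "MOL2": {"Sox10": 5, "Plp1": 8, "Anxa5": 6, "Klk6": 6, "Hopx": 4},
            "MOL5/6": {"Sox10": 5, "Plp1": 8, "Ptgds": 12, "Car2": 6, "Grm3": 4},
            "MOL1": {"Sox10": 5, "Plp1": 8, "Egr2": 5},
        }
    )
    puncta: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # means 3x above the calling cutoff for the own marker and
            # 3x below it for every other population's marker
            "MOL5/6": {"Ptgds": 36.0, "Klk6": 1.0, "Egr2": 1.0, "Ptprz1": 2.0},
            "MOL2": {"Ptgds": 4.0, "Klk6": 12.0, "Egr2": 1.0, "Ptprz1": 2.0},
            "MOL1": {"Ptgds": 4.0, "Klk6": 1.0, "Egr2": 9.0, "Ptprz1": 2.0},
            "OPC/COP": {"Ptgds": 4.0, "Klk6": 1.0, "Egr2": 1.0, "Ptprz1": 21.0},
        }
    )
    sox10_negative_populations: tuple[str, ...] = ()
    dispersion: Optional[float] = None  # NB size parameter; None -> Poisson
    puncta_dispersion: Optional[float] = 8.0
    amplitude: float = 100.0
    noise_level: float = 0.0
    crosstalk: float = 0.0
    background_rate: float = 0.0  # expected background spots per true spot
    cycles: int = 4
    channels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radii must be positive with min <= max")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not (0.0 <= self.noise_level) or not (0.0 <= self.crosstalk):
            raise ValueError("noise_level and crosstalk must be >= 0")
        region_names = [r.name for r in self.regions]
        if len(set(region_names)) != len(region_names):
            raise ValueError("region names must be unique")
        for name, props in self.proportions.items():
            if name not in region_names:
                raise ValueError(f"proportions given for unknown region {name!r}")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"population proportions for region {name!r} sum to {total}, not 1"
                )
        for name in region_names:
            if name not in self.proportions:
                raise ValueError(f"region {name!r} has no population proportions")

    @property
    def populations(self) -> list[str]:
        pops: list[str] = []
        for props in self.proportions.values():
            for p in props:
                if p not in pops:
                    pops.append(p)
        return pops

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["regions"] = [asdict(r) for r in self.regions]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["regions"] = [Region(**r) for r in data.get("regions", [])]
        for key in ("field_shape", "radius_range", "sox10_negative_populations"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class ExprSimConfig:
    """Parameters of the synthetic cell x gene count matrix.

    Plants cluster structure, condition-specific DE genes (log2 fold change
    ``de_lfc`` between the two conditions, in every cluster), mitochondrial-
    fraction outliers, low/high library-size cells, and spatially
    autocorrelated genes whose rate is a smooth function of position on a 3D
    cluster-blob embedding.
    """

    n_cells: int = 600
    n_genes: int = 200
    n_clusters: int = 3
    conditions: tuple[str, ...] = ("control", "injury")
    n_samples_per_condition: int = 2
    n_de_genes: int = 20
    de_lfc: float = 1.0
    de_base_mean_min: float = 2.0  # DE planted on expressed genes only
    n_spatial_genes: int = 20
    spatial_strength: float = 1.5
    base_mean_log_mu: float = 0.0  # lognormal parameters of per-gene base means
    base_mean_log_sigma: float = 1.0
    marker_genes_per_cluster: int = 5
    marker_lfc: float = 2.5
    dispersion: Optional[float] = None  # NB size; None -> Poisson
    mito_beta: tuple[float, float] = (2.0, 78.0)  # healthy cells, mean 2.5%
    mito_outlier_frac: float = 0.05
    mito_outlier_range: tuple[float, float] = (0.12, 0.40)
    low_count_frac: float = 0.03
    low_count_scale: float = 0.05
    high_count_frac: float = 0.02
    high_count_scale: float = 10.0
    embedding_sep: float = 8.0  # distance between cluster blob centers
    count_noise: bool = True  # False -> spatial genes carry their exact rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need >= 2 clusters")
        if len(self.conditions) < 2:
            raise ValueError("need >= 2 conditions")
        if not 0 <= self.n_de_genes + self.n_spatial_genes <= self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
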