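"""Configuration objects for the synthetic-data generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from holomap.grid import DEFAULT_TIMEFRAMES

#: host groups and sample sizes of the 99-sample microbiome design
#: (five coral/sponge species plus a seawater reference group)
DEFAULT_HOSTS = ("W. bursa", "S. fortis", "L. pertusa", "D. dianthus",
                 "V. pourtalesii")
DEFAULT_SAMPLES_PER_GROUP = {
    "W. bursa": 16,
    "S. fortis": 19,
    "L. pertusa": 8,
    "D. dianthus": 7,
    "V. pourtalesii": 32,
    "seawater": 17,
}

#: per-timeframe bottom-temperature offsets [deg C] relative to the present
#: timeframe: a mild cooling into the past and RCP8.5-style warming for the
#: two future frames.
DEFAULT_WARMING_OFFSETS = {
    "1871-1900": -0.4,
    "1901-1930": -0.3,
    "1931-1960": -0.2,
    "1961-1989": -0.1,
    "1990-2015": 0.0,
    "2046-2065": 1.2,
    "2066-2085": 2.0,
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic-data generator.

    The defaults emulate the study design at a desk-computable grid size:
    seven multi-decadal timeframes, 0.088 deg cells, five host species with
    a seawater reference group, and the 99-sample microbiome design.
    """

    lat_min: float = 42.0
    lat_max: float = 48.0
    lon_min: float = -66.0
    lon_max: float = -58.0
    cell_size: float = 0.088
    timeframes: tuple[str, ...] = DEFAULT_TIMEFRAMES
    seed: int = 0
    n_species: int = 5
    records_per_species: int = 400
    samples_per_group: dict = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES_PER_GROUP))
    warming_offsets: dict = field(
        default_factory=lambda: dict(DEFAULT_WARMING_OFFSETS))
    field_length_scale: float = 5.0    # Gaussian-random-field scale [cells]
    field_amplitude: float = 1.0       # relative GRF amplitude
    max_depth: float = 2600.0          # deepest synthetic bathymetry [m]
    library_size_mean: float = 9.2     # lognormal mu of per-sample read depth
    library_size_sigma: float = 0.25   # lognormal sigma
    rarefaction_depth: int = 6000
    n_asvs: int = 2000
    n_key_asvs: int = 15
    key_asv_coverage: float = 0.67     # summed mean rel. abundance of key ASVs
    overdispersion: float = 0.005      # Dirichlet-multinomial; 0 = multinomial
    n_biomass_species: int = 116
    n_stations: int = 200
    hma_cnidaria_correlation: float = 0.8

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("grid extent must be positive in both axes")
        if len(self.timeframes) < 1:
            raise ValueError("need at least one timeframe")
        self.timeframes = tuple(self.timeframes)
        missing = [t for t in self.timeframes if t not in self.warming_offsets]
        if missing:
            raise ValueError(f"warming offsets missing for timeframes {missing}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (one global seed, per-stage blocks)."""

    out_dir: str = "holomap_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    buffer_km: float = 5.0
    max_depth_m: float = 2000.0
    mld_threshold: float = 0.03
    n_trees: int = 500
    cv_folds: int = 5
    block_size_cells: int = 10
    rarefaction_depth: int = 6000
    jsdm_chains: int = 2
    jsdm_samples: int = 400
    jsdm_warmup: int = 400
    temp_window: tuple[float, float] = (6.2, 8.2)
    sparcc_rounds: int = 20
    sparcc_exclusion_threshold: float = 0.1
    edge_threshold: float = 0.3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw:
            sim_known = set(SimConfig.__dataclass_fields__)
            sim_unknown = set(raw["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            raw["sim"] = SimConfig(**raw["sim"])
        if "temp_window" in raw:
            raw["temp_window"] = tuple(raw["temp_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temp_window"] = list(self.temp_window)
        return d
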