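"""Cumulative microbial richness: overlay, change, areas, uncertainty.

Thresholded host habitat maps are combined with per-host mean microbiome
richness into a per-cell cumulative richness (the sum of the mean richness
of every host predicted present).  On top of that: temporal gain/loss maps
with shifted-area percentages, geodesic cell areas on the WGS-84 ellipsoid,
propagation of host-model SD and microbiome SE into region-wise medians,
and environmental-envelope exceedance counts flagging extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from holomap.grid import ALL_LAYERS, EnvGridStack

log = logging.getLogger(__name__)

__all__ = [
    "ChangeMap",
    "CumulativeRichnessMap",
    "cumulative_richness",
    "envelope_exceedance",
    "geodesic_cell_area",
    "host_uncertainty",
    "region_uncertainty",
    "temporal_change",
    "DEFAULT_REGIONS",
]

# latitude bands of the three subregions (deg N); boundary cells go north
DEFAULT_REGIONS = {"A": (52.1, 71.5), "B": (40.0, 52.1), "C": (25.0, 40.0)}


@dataclass
class CumulativeRichnessMap:
    """Per-cell summed mean richness of predicted-present hosts."""

    richness: np.ndarray                  # NaN where no host present
    contributing: np.ndarray              # int count of present hosts
    hosts: tuple[str, ...] = ()


def cumulative_richness(binary_maps: dict[str, np.ndarray],
                        mean_richness: dict[str, float]
                        ) -> CumulativeRichnessMap:
    """Sum each host's mean richness over the cells where it is predicted
    present; cells with no predicted host carry no value (NaN)."""
    missing = [h for h in binary_maps if h not in mean_richness]
    if missing:
        raise KeyError(f"no mean richness estimate for host(s): {missing}")
    shapes = {m.shape for m in binary_maps.values()}
    if len(shapes) != 1:
        raise ValueError("binary maps are not on a common grid")
    shape = shapes.pop()
    total = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    for host, bmap in binary_maps.items():
        present = bmap == 1
        total[present] += mean_richness[host]
        count[present] += 1
    rich = np.where(count > 0, total, np.nan)
    return CumulativeRichnessMap(richness=rich, contributing=count,
                                 hosts=tuple(binary_maps))


@dataclass
class ChangeMap:
    """Gain/loss/no-change vs the present, with shifted-area summaries."""

    category: np.ndarray          # +1 gain, -1 loss, 0 no change, NaN invalid
    n_gain: int
    n_loss: int
    n_no_change: int
    pct_gains: float              # of shifted cells; NaN if none shifted
    pct_losses: float
    shifted_area_km2: float = float("nan")


def temporal_change(map_t: CumulativeRichnessMap,
                    map_present: CumulativeRichnessMap,
                    lat: np.ndarray | None = None,
                    cell_size: float = 0.088) -> ChangeMap:
    """Per-cell sign of the richness change vs the present.

    Cells without a value are treated as 0 richness, so colonization of an
    empty cell is a gain and complete loss of hosts is a loss.  Percentages
    of gains and losses are taken over the shifted cells only (summing to
    100 whenever at least one cell shifted).  When the grid's latitude axis
    is passed, the total shifted area [km2] is accumulated from per-cell
    geodesic areas.
    """
    a = np.nan_to_num(map_t.richness, nan=0.0)
    b = np.nan_to_num(map_present.richness, nan=0.0)
    if a.shape != b.shape:
        raise ValueError("maps are not on a common grid")
    diff = a - b
    cat = np.sign(diff)
    n_gain = int((cat > 0).sum())
    n_loss = int((cat < 0).sum())
    n_shift = n_gain + n_loss
    if n_shift == 0:
        pct_g = pct_l = float("nan")
        log.info("temporal_change: no shifted cells")
    else:
        pct_g = 100.0 * n_gain / n_shift
        pct_l = 100.0 * n_loss / n_shift
    area = float("nan")
    if lat is not None:
        cell_areas = geodesic_cell_area(np.asarray(lat), cell_size)
        area = float((np.abs(cat) * cell_areas[:, None]).sum())
    return ChangeMap(category=cat, n_gain=n_gain, n_loss=n_loss,
                     n_no_change=int((cat == 0).sum()),
                     pct_gains=pct_g, pct_losses=pct_l,
                     shifted_area_km2=area)


# ---------------------------------------------------------------------------
# geodesic areas (WGS-84 ellipsoid)
# ---------------------------------------------------------------------------
_WGS84_A_KM = 6378.137
_WGS84_E2 = 6.69437999014e-3


def _authalic_q(sin_phi: np.ndarray) -> np.ndarray:
    e = np.sqrt(_WGS84_E2)
    return ((1.0 - _WGS84_E2)
            * (sin_phi / (1.0 - _WGS84_E2 * sin_phi**2)
               + np.arctanh(e * sin_phi) / e))


def geodesic_cell_area(lat_center, cell_size: float = 0.088):
    """Area [km2] of a cell_size x cell_size quadrangle on the WGS-84
    ellipsoid, centered at the given latitude(s)."""
    lat = np.asarray(lat_center, dtype=float)
    half = cell_size / 2.0
    if np.any(np.abs(lat) + half > 90.0):
        raise ValueError("cell crosses a pole")
    phi1 = np.deg2rad(lat - half)
    phi2 = np.deg2rad(lat + half)
    dlam = np.deg2rad(cell_size)
    area = (_WGS84_A_KM**2 * dlam / 2.0
            * (_authalic_q(np.sin(phi2)) - _authalic_q(np.sin(phi1))))
    if area.ndim == 0:
        return float(area)
    return area


# ---------------------------------------------------------------------------
# uncertainty propagation
# ---------------------------------------------------------------------------
def host_uncertainty(sd_surfaces: dict[str, dict[str, np.ndarray]]
                     ) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Two reductions of the per-fold-model SD surfaces.

    ``sd_surfaces[species][timeframe]`` is the per-cell SD of the fold-model
    predictions.  Returns (per-species mean SD across all timeframes and
    cells, per-timeframe summed SD surface across species).
    """
    species = list(sd_surfaces)
    frames = list(sd_surfaces[species[0]])
    for sp in species:
        if list(sd_surfaces[sp]) != frames:
            raise ValueError(f"species {sp!r} is missing timeframes")
    per_species = {
        sp: float(np.nanmean(np.stack(list(sd_surfaces[sp].values()))))
        for sp in species
    }
    per_frame = {
        tf: np.nansum(np.stack([sd_surfaces[sp][tf] for sp in species]), axis=0)
        for tf in frames
    }
    return per_species, per_frame


def region_uncertainty(summed_host_sd: np.ndarray,
                       summed_micro_se: np.ndarray,
                       has_value: np.ndarray,
                       lat: np.ndarray,
                       regions: dict[str, tuple[float, float]] = None,
                       strategy: str = "scale01") -> dict[str, float]:
    """Region-wise medians of the combined, standardized uncertainty.

    Per cell with a predicted microbial data point, the summed host SD and
    the summed microbiome SE are each translated into relative values
    (divided by their study-wide totals), added, and standardized to a
    0-100 scale.  ``strategy``: ``"scale01"`` rescales the combined field
    linearly onto [0, 100]; ``"pct_max"`` expresses each cell as percent of
    the study-wide maximum.  Medians are returned per latitude-band region
    (boundary cells go to the northern region).
    """
    regions = DEFAULT_REGIONS if regions is None else regions
    valid = has_value & np.isfinite(summed_host_sd) & np.isfinite(summed_micro_se)
    if not valid.any():
        raise ValueError("no cells with a predicted microbial data point")
    h = np.where(valid, summed_host_sd, np.nan)
    m = np.where(valid, summed_micro_se, np.nan)
    h_tot = np.nansum(h)
    m_tot = np.nansum(m)
    combined = (h / h_tot if h_tot > 0 else np.zeros_like(h) * np.nan)
    combined = combined + (m / m_tot if m_tot > 0 else 0.0)
    if strategy == "scale01":
        lo, hi = np.nanmin(combined), np.nanmax(combined)
        std = (combined - lo) / (hi - lo) * 100.0 if hi > lo \
            else np.zeros_like(combined)
    elif strategy == "pct_max":
        std = combined / np.nanmax(combined) * 100.0
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    lat2d = np.asarray(lat)[:, None] * np.ones_like(std)
    out = {}
    for name, (lo_lat, hi_lat) in regions.items():
        in_band = (lat2d >= lo_lat) & (lat2d < hi_lat) & valid
        # boundary rule: a cell exactly on the upper bound belongs here only
        # if this is the northernmost region
        if hi_lat >= max(b[1] for b in regions.values()):
            in_band |= (lat2d == hi_lat) & valid
        if not in_band.any():
            log.warning("region %s is empty", name)
            out[name] = float("nan")
        else:
            out[name] = float(np.nanmedian(std[in_band]))
    return out


# ---------------------------------------------------------------------------
# environmental envelope
# ---------------------------------------------------------------------------
_MICRO_PARAMS = ("depth", "bottom_temperature", "bottom_salinity")


def envelope_exceedance(grid: EnvGridStack, timeframe: str,
                        sampled_cells: np.ndarray, mode: str = "host",
                        host_present: np.ndarray | None = None) -> np.ndarray:
    """Count per cell how many parameters fall outside the sampled envelope.

    ``mode="host"`` uses all nine parameters over every valid cell;
    ``mode="microbiome"`` uses depth, bottom temperature and bottom salinity
    only, restricted to cells where hosts are predicted present.  The
    envelope is the min-max range over ``sampled_cells`` (flat indices);
    a parameter counts when strictly above its sampled max or strictly
    below its sampled min.  Counts from both modes are summable per cell.
    """
    sampled_cells = np.asarray(sampled_cells)
    if sampled_cells.size == 0:
        raise ValueError("empty sampled cell set")
    if mode == "host":
        params = ALL_LAYERS
        domain = grid.mask.copy()
    elif mode == "microbiome":
        params = _MICRO_PARAMS
        if host_present is None:
            raise ValueError("microbiome mode needs the host-present mask")
        domain = grid.mask & (host_present == 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    count = np.zeros(grid.shape, dtype=float)
    for name in params:
        layer = grid.layer(name, timeframe if name in grid.dynamic else None)
        samp = layer.ravel()[sampled_cells]
        lo, hi = np.nanmin(samp), np.nanmax(samp)
        count += ((layer < lo) | (layer > hi)).astype(float)
    count[~domain] = np.nan
    return count
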