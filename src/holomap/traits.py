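"""Trait-based (HMA/LMA) occurrence mapping and function correlations.

The microbial-abundance status of sponges (high vs low microbial
abundance) is treated as a binary trait per grid cell: a cell is 1 for a
trait when any member species of that trait is present there.  The two
trait surfaces are then modeled with the same random-forest machinery as
the host SDMs, and the predictions are correlated (Spearman) with
ecosystem-function surfaces such as nutrient cycling or habitat provision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from holomap.grid import EnvGridStack
from holomap.sdm import SDMResult, cross_validate_sdm

__all__ = ["fit_trait_rf", "function_correlation", "trait_presence"]


def trait_presence(gridded: pd.DataFrame,
                   assignment: dict[str, str]) -> pd.DataFrame:
    """Per-cell trait records: OR over member species' gridded presences.

    ``assignment`` maps species -> 'HMA' | 'LMA'; every species in the
    records must be assigned.  Returns one records frame per trait rolled
    into a single frame with ``species`` set to the trait name, suitable
    for :func:`holomap.sdm.cross_validate_sdm`.
    """
    unassigned = set(gridded["species"].unique()) - set(assignment)
    if unassigned:
        raise ValueError(f"species without trait assignment: "
                         f"{sorted(unassigned)}")
    df = gridded.copy()
    df["trait"] = df["species"].map(assignment)
    out = (df.groupby(["trait", "cell"], sort=True)
             .agg(presence=("presence", "max"), lat=("lat", "first"),
                  lon=("lon", "first"))
             .reset_index()
             .rename(columns={"trait": "species"}))
    out["source"] = "derived"
    return out[["species", "lat", "lon", "presence", "source", "cell"]]


def fit_trait_rf(trait_records: pd.DataFrame, grid: EnvGridStack,
                 timeframe: str, **cv_kwargs) -> dict[str, SDMResult]:
    """One cross-validated RF model per trait (reuses the host-SDM
    machinery verbatim: 500 trees, spatial block CV, MSS thresholding)."""
    out = {}
    for trait in trait_records["species"].unique():
        sub = trait_records[trait_records["species"] == trait]
        out[trait] = cross_validate_sdm(sub, grid, timeframe, **cv_kwargs)
    return out


def function_correlation(trait_surface: np.ndarray,
                         function_surface: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties, two-sided p) between a
    trait probability surface and an ecosystem-function surface over their
    shared unmasked cells."""
    a = np.asarray(trait_surface, dtype=float).ravel()
    b = np.asarray(function_surface, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("surfaces are not aligned")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 shared unmasked cells")
    if a[ok].std() == 0 or b[ok].std() == 0:
        raise ValueError("constant surface: correlation undefined")
    rho, p = stats.spearmanr(a[ok], b[ok])
    return float(rho), float(p)
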