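"""Shared helpers: seeding, validation, small numerics."""

from __future__ import annotations

import numpy as np

# Stage names get stable integer offsets so that a single global seed expands
# into independent, reproducible per-stage streams.
_STAGE_OFFSETS = {
    "simulate": 1,
    "env": 2,
    "occurrences": 3,
    "asv": 4,
    "biomass": 5,
    "sdm": 6,
    "rarefy": 7,
    "jsdm": 8,
    "sparcc": 9,
    "traits": 10,
    "cv": 11,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from a global seed."""
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(_STAGE_OFFSETS)}")
    ss = np.random.SeedSequence([int(global_seed), _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))


def check_positive(value: float, name: str) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be positive, got {value!r}")


def as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)
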