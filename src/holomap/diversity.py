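"""Rarefied diversity, per-host richness summaries and key-ASV selection.

Works on a sample x ASV integer count table with per-sample metadata (host
group or seawater, coordinates).  Downstream stages consume the per-group
mean observed richness (after rarefying every sample to a common depth) and
its standard error, plus the key-ASV set of the focal sponge host.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ASVTable",
    "RichnessSummary",
    "mean_richness_by_host",
    "observed_richness",
    "partition_prevalence",
    "rarefy",
    "select_key_asvs",
    "shannon",
]


@dataclass
class ASVTable:
    """Integer counts (samples x ASVs) plus per-sample metadata.

    ``counts`` index = sample ids, columns = ASV ids.  ``metadata`` must
    carry one row per sample with at least a ``host`` column; ``lat``,
    ``lon`` and ``temperature`` are carried when available.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.metadata.index):
            raise ValueError("counts and metadata must share the sample index")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if "host" not in self.metadata.columns:
            raise ValueError("metadata must have a 'host' column")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        lib = self.library_sizes
        if (lib == 0).any():
            raise ValueError("cannot close empty samples to 1")
        return self.counts.div(lib, axis=0)

    def restrict_host(self, host: str) -> "ASVTable":
        keep = self.metadata["host"] == host
        if not keep.any():
            raise KeyError(f"no samples for host {host!r}")
        return ASVTable(self.counts.loc[keep].copy(),
                        self.metadata.loc[keep].copy())

    # -- plain-text IO -----------------------------------------------------
    def to_files(self, counts_tsv, metadata_csv) -> None:
        self.counts.to_csv(counts_tsv, sep="\t", index_label="sample")
        self.metadata.to_csv(metadata_csv, index_label="sample")

    @classmethod
    def from_files(cls, counts_tsv, metadata_csv) -> "ASVTable":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col="sample")
        meta = pd.read_csv(metadata_csv, index_col="sample")
        return cls(counts, meta)


@dataclass
class RichnessSummary:
    """Per host group: mean observed richness, its SE, mean Shannon, n."""

    mean_richness: dict[str, float]
    se_richness: dict[str, float]
    mean_shannon: dict[str, float]
    n_samples: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_richness": pd.Series(self.mean_richness),
            "se_richness": pd.Series(self.se_richness),
            "mean_shannon": pd.Series(self.mean_shannon),
            "n_samples": pd.Series(self.n_samples),
        })


def rarefy(table: ASVTable, depth: int, seed: int) -> ASVTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (logged).  A single
    deterministic draw per sample (multivariate hypergeometric) is taken,
    mirroring single-rarefaction pipelines; the seed is recorded in the
    output metadata.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    lib = table.library_sizes
    keep = lib >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    dropped = list(table.counts.index[~keep])
    if dropped:
        log.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                    len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    sub = np.empty((int(keep.sum()), table.counts.shape[1]), dtype=np.int64)
    for r, (_, row) in enumerate(table.counts.loc[keep].iterrows()):
        sub[r] = rng.multivariate_hypergeometric(row.values.astype(np.int64),
                                                 depth)
    counts = pd.DataFrame(sub, index=table.counts.index[keep],
                          columns=table.counts.columns)
    meta = table.metadata.loc[keep].copy()
    meta["rarefaction_depth"] = depth
    meta["rarefaction_seed"] = seed
    return ASVTable(counts, meta)


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero proportions.

    Natural log by default; pass ``base`` (e.g. 2) for other conventions.
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("need at least one positive count")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def observed_richness(counts) -> int:
    """Number of ASVs with a nonzero count."""
    return int((np.asarray(counts) > 0).sum())


def mean_richness_by_host(table: ASVTable) -> RichnessSummary:
    """Group means of observed richness and Shannon index, with SE = SD/sqrt(n).

    Expects a rarefied table (all library sizes equal); empty groups cannot
    occur by construction of the metadata index.
    """
    rich = table.counts.apply(observed_richness, axis=1, raw=True)
    shan = table.counts.apply(shannon, axis=1, raw=True)
    hosts = table.metadata["host"]
    mean_r, se_r, mean_h, n_s = {}, {}, {}, {}
    for host, idx in hosts.groupby(hosts).groups.items():
        r = rich.loc[idx].to_numpy(dtype=float)
        mean_r[host] = float(r.mean())
        se_r[host] = float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else 0.0
        mean_h[host] = float(shan.loc[idx].mean())
        n_s[host] = int(len(r))
    return RichnessSummary(mean_r, se_r, mean_h, n_s)


def partition_prevalence(table: ASVTable) -> dict[str, list]:
    """Partition one host's ASVs by prevalence across its individuals.

    ``core``: present in all n individuals; ``variable_ge10``: in >= 10 (but
    not all); ``variable_2to9``: in 2-9; ``individual``: in exactly 1.
    ASVs absent from every sample are left out of all classes.
    """
    present = table.counts.values > 0
    prev = present.sum(axis=0)
    n = present.shape[0]
    asvs = np.asarray(table.counts.columns)
    return {
        "core": list(asvs[prev == n]),
        "variable_ge10": list(asvs[(prev >= 10) & (prev < n)]),
        "variable_2to9": list(asvs[(prev >= 2) & (prev <= min(9, n - 1))]),
        "individual": list(asvs[prev == 1]),
    }


def select_key_asvs(table: ASVTable, min_prevalence: int = 10,
                    min_mean_rel_abundance: float = 0.01) -> pd.DataFrame:
    """Key ASVs: prevalence >= 10 individuals and mean relative abundance > 1%.

    The mean relative abundance is taken over all samples of the host
    (zeros included).  Returns a frame (asv, prevalence, mean_rel_abundance)
    sorted by decreasing abundance, with the summed coverage in ``attrs``.
    """
    rel = table.relative_abundance()
    prev = (table.counts.values > 0).sum(axis=0)
    mean_rel = rel.mean(axis=0).values
    sel = (prev >= min_prevalence) & (mean_rel > min_mean_rel_abundance)
    out = pd.DataFrame({
        "asv": np.asarray(table.counts.columns)[sel],
        "prevalence": prev[sel],
        "mean_rel_abundance": mean_rel[sel],
    }).sort_values("mean_rel_abundance", ascending=False).reset_index(drop=True)
    out.attrs["coverage"] = float(mean_rel[sel].sum())
    if out.empty:
        log.warning("select_key_asvs: no ASV passed the key criteria")
    return out
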