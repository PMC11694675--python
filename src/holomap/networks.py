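"""Compositional co-occurrence networks and biomass networks.

SparCC-style basis correlations are inferred from log-ratio variances:
for components i, j the observed variance t_ij = var(log(x_i/x_j))
decomposes as w_i + w_j - 2 rho_ij sqrt(w_i w_j).  Under the sparsity
assumption the basis variances w solve a linear system; strongly
correlated pairs are iteratively excluded from the system and the
procedure is averaged over Dirichlet-resampled fraction estimates.  The
resulting network is thresholded, restricted to ASVs connected to at
least one key ASV, and key ASVs are classified by whether they connect
to any non-key ASV ("highly interconnected") or only to other key ASVs
("interconnected").
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "biomass_network",
    "build_network",
    "classify_connectivity",
    "degree_fit_correlation",
    "filter_biomass_species",
    "sparcc_correlations",
]


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------
def _basis_correlations(log_frac: np.ndarray, exclusion_threshold: float,
                        max_exclusions: int) -> np.ndarray:
    d = log_frac.shape[1]
    # variation matrix t_ij = var(log(x_i / x_j))
    v = np.var(log_frac[:, :, None] - log_frac[:, None, :], axis=0, ddof=1)
    included = ~np.eye(d, dtype=bool)
    rho = np.eye(d)
    for _ in range(max_exclusions + 1):
        # t_i = sum over included partners of (w_i + w_j)
        m = included.astype(float) + np.diag(included.sum(axis=1))
        t_sum = (v * included).sum(axis=1)
        try:
            w = np.linalg.solve(m, t_sum)
        except np.linalg.LinAlgError:
            break
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - v) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # exclude the currently strongest off-diagonal pair, if above threshold
        masked = np.abs(rho) * included
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold or not included[i, j]:
            break
        included[i, j] = included[j, i] = False
    return rho


def sparcc_correlations(counts, n_rounds: int = 20,
                        exclusion_threshold: float = 0.1,
                        max_exclusions: int = 10, seed: int = 0) -> np.ndarray:
    """SparCC basis correlation matrix of an ASV count table.

    ``counts`` is (samples x ASVs); needs >= 4 ASVs (the basis-variance
    system is underdetermined below that) and >= 3 samples.  Fractions are
    resampled ``n_rounds`` times from Dirichlet(counts + 1) and the
    per-round basis correlations averaged.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 4:
        raise ValueError("SparCC needs at least 4 ASVs")
    if y.shape[0] < 3:
        raise ValueError("SparCC needs at least 3 samples")
    rng = np.random.default_rng(seed)
    acc = np.zeros((y.shape[1], y.shape[1]))
    for _ in range(n_rounds):
        frac = np.empty_like(y)
        for r in range(y.shape[0]):
            frac[r] = rng.dirichlet(y[r] + 1.0)
        rho = _basis_correlations(np.log(frac), exclusion_threshold,
                                  max_exclusions)
        acc += rho
    out = acc / n_rounds
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)


# ---------------------------------------------------------------------------
# network construction and classification
# ---------------------------------------------------------------------------
def build_network(corr: np.ndarray, asvs, key_asvs,
                  edge_threshold: float = 0.3) -> nx.Graph:
    """Thresholded signed co-occurrence network.

    Edges where |correlation| >= threshold; nodes restricted to ASVs with
    at least one edge to a key ASV (key ASVs themselves always retained).
    """
    if not abs(edge_threshold) < 1:
        raise ValueError("edge threshold must satisfy |t| < 1")
    asvs = list(asvs)
    key = set(key_asvs)
    g = nx.Graph()
    g.add_nodes_from((a, {"key": a in key}) for a in asvs)
    n = len(asvs)
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if abs(r) >= edge_threshold:
                g.add_edge(asvs[i], asvs[j], correlation=float(r),
                           sign=int(np.sign(r)))
    keep = set(key)
    for a in asvs:
        if a in key:
            continue
        if any(nb in key for nb in g.neighbors(a)):
            keep.add(a)
    g.remove_nodes_from([a for a in asvs if a not in keep])
    if g.number_of_edges() == 0:
        log.warning("build_network: threshold %.2f yields an empty network",
                    edge_threshold)
    return g


def classify_connectivity(g: nx.Graph) -> dict[str, str]:
    """Key ASVs with >= 1 non-key neighbor are 'highly interconnected';
    key ASVs whose every neighbor is a key ASV are 'interconnected'
    (including the degenerate no-edge case, logged)."""
    out = {}
    for node, data in g.nodes(data=True):
        if not data.get("key"):
            continue
        neighbors = list(g.neighbors(node))
        if not neighbors:
            log.info("classify_connectivity: key ASV %s has no edges", node)
            out[node] = "interconnected"
        elif any(not g.nodes[nb].get("key") for nb in neighbors):
            out[node] = "highly interconnected"
        else:
            out[node] = "interconnected"
    return out


def degree_fit_correlation(degrees, fit_metric) -> tuple[float, float]:
    """Pearson r (and two-sided t-test p, n-2 df) between key-ASV network
    degree and a model-fit metric."""
    x = np.asarray(degrees, dtype=float)
    y = np.asarray(fit_metric, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# biomass networks
# ---------------------------------------------------------------------------
_MOTILITY_OK = {"sessile", "sessile-burrow"}
_CONTAGION_OK = {"high abundance", "patchy"}
_FEEDING_OK = {"active filter feeding", "passive filter feeding"}


def filter_biomass_species(table: pd.DataFrame) -> pd.DataFrame:
    """Retain species that are sessile, high-abundance/patchy filter feeders.

    Rows failing (or missing) any of the three trait criteria are dropped
    (logged).  Returns the qualifying subset with a ``group`` column:
    HMA/LMA for status-carrying sponges, else phylum x size class.
    """
    for col in ("motility", "contagion", "feeding_mode", "phylum",
                "size_class"):
        if col not in table.columns:
            raise KeyError(f"biomass table lacks trait column {col!r}")
    ok = (table["motility"].isin(_MOTILITY_OK)
          & table["contagion"].isin(_CONTAGION_OK)
          & table["feeding_mode"].isin(_FEEDING_OK))
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("filter_biomass_species: excluded %d species by traits",
                 n_drop)
    out = table.loc[ok].copy()
    status = out.get("hma_lma", pd.Series("", index=out.index)).fillna("")
    out["group"] = np.where(status != "", status,
                            out["phylum"] + "_" + out["size_class"])
    return out


def group_biomass(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-group station biomass: sum of member species' biomass per
    station (groups x stations)."""
    station_cols = [c for c in filtered.columns if c.startswith("station_")]
    if not station_cols:
        raise ValueError("no station biomass columns found")
    return filtered.groupby("group")[station_cols].sum()


def biomass_network(grouped: pd.DataFrame,
                    corr_threshold: float = 0.5) -> nx.Graph:
    """Signed network of pairwise Pearson correlations between group
    biomass vectors; |r| >= threshold makes an edge, strength = |r|.
    Constant groups are excluded (logged)."""
    if grouped.shape[1] < 3:
        raise ValueError("need >= 3 stations")
    keep = grouped.std(axis=1) > 0
    dropped = list(grouped.index[~keep])
    if dropped:
        log.info("biomass_network: constant group(s) excluded: %s", dropped)
    grouped = grouped.loc[keep]
    corr = np.corrcoef(grouped.values)
    g = nx.Graph()
    g.add_nodes_from(grouped.index)
    names = list(grouped.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr[i, j]
            if abs(r) >= corr_threshold:
                g.add_edge(names[i], names[j], correlation=float(r),
                           sign=int(np.sign(r)), strength=float(abs(r)))
    return g


def export_edge_list(g: nx.Graph, path) -> None:
    """Edge-list CSV (source, target, correlation, sign)."""
    rows = [{"source": u, "target": v,
             "correlation": d.get("correlation", float("nan")),
             "sign": d.get("sign", 0)} for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "correlation",
                                "sign"]).to_csv(path, index=False)
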