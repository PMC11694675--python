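"""Poisson joint model of key-ASV abundances along a temperature gradient.

The response matrix holds "dummy integer" abundances (relative abundances
rescaled by a fixed factor and rounded) of the key ASVs at a small set of
locations; the model is a hierarchical Poisson log-link regression

    log lambda_ij = beta0_j + beta1_j * T_i [+ beta2_j * T_i^2] + Lambda_j eta_i

with one spatially structured latent factor eta ~ N(0, K) under an
exponential covariance over great-circle distance, giving each ASV its own
temperature response plus a shared residual spatial field.  The posterior
is sampled with an in-package MCMC scheme: elliptical slice sampling for
the latent field and vectorized adaptive random-walk Metropolis for the
regression weights and loadings, in two (or more) independent chains whose
convergence is checked with the Gelman-Rubin psrf.

The temperature-matched location augmentation mirrors the study design:
in-situ samples are snapped to grid cells, co-located communities averaged,
and every other predicted-presence cell whose temperature (rounded to two
decimals) matches a sampled temperature category is appended carrying that
category's average composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from holomap.grid import EnvGridStack

log = logging.getLogger(__name__)

__all__ = [
    "JSDMInput",
    "JSDMFit",
    "augment_locations",
    "build_jsdm_input",
    "convergence_psrf",
    "cross_validate",
    "dummy_transform",
    "fit_jsdm",
    "optimal_temperature",
    "spatial_predict",
    "tjur_r2",
]


def dummy_transform(rel_abundance, scale: int = 100) -> np.ndarray:
    """Relative abundances in [0, 1] to dummy integers: round(rel * scale),
    half away from zero."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    rel = np.asarray(rel_abundance, dtype=float)
    if np.any(rel < 0) or np.any(rel > 1):
        raise ValueError("relative abundances must lie in [0, 1]")
    return np.floor(rel * scale + 0.5).astype(int)


@dataclass
class JSDMInput:
    """Locations, temperatures and dummy-integer responses for the model."""

    lat: np.ndarray
    lon: np.ndarray
    temperature: np.ndarray
    counts: np.ndarray              # (n_locations, n_asvs) integers
    asvs: tuple[str, ...]
    provenance: np.ndarray = None   # 'sampled' | 'augmented'

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (locations x ASVs)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.rint(self.counts)):
                raise ValueError("responses must be integers "
                                 "(apply dummy_transform first)")
            self.counts = np.rint(self.counts).astype(int)
        if np.any(self.counts < 0):
            raise ValueError("dummy integers must be >= 0")
        n = len(self.temperature)
        if self.counts.shape[0] != n or len(self.lat) != n or len(self.lon) != n:
            raise ValueError("location array lengths differ")
        if self.provenance is None:
            self.provenance = np.array(["sampled"] * n)

    @property
    def n_locations(self) -> int:
        return len(self.temperature)


def build_jsdm_input(table, key_asvs, grid: EnvGridStack,
                     timeframe: str, host: str = "V. pourtalesii",
                     scale: int = 100) -> JSDMInput:
    """Sampled-location JSDM input from an ASV table.

    Key-ASV relative abundances of the focal host's samples are
    re-standardized to sum to 1, samples are snapped to their nearest grid
    cell (communities in the same cell averaged), the cell's bottom
    temperature is attached and the composition converted to dummy
    integers.
    """
    sub = table.restrict_host(host)
    rel = sub.relative_abundance()[list(key_asvs)]
    rel = rel.div(rel.sum(axis=1), axis=0)
    cells = grid.flat_index(sub.metadata["lat"].values,
                            sub.metadata["lon"].values)
    if np.any(cells < 0):
        raise ValueError("a sample falls outside the grid")
    df = rel.copy()
    df["cell"] = cells
    mean_by_cell = df.groupby("cell").mean()
    temp = grid.layer("bottom_temperature", timeframe).ravel()
    nlon = len(grid.lon)
    cell_ids = mean_by_cell.index.values
    return JSDMInput(
        lat=grid.lat[cell_ids // nlon], lon=grid.lon[cell_ids % nlon],
        temperature=temp[cell_ids],
        counts=dummy_transform(mean_by_cell.values, scale),
        asvs=tuple(key_asvs),
        provenance=np.array(["sampled"] * len(cell_ids)),
    )


def augment_locations(sampled: JSDMInput, grid: EnvGridStack, timeframe: str,
                      present_mask: np.ndarray) -> JSDMInput:
    """Append every predicted-presence cell whose temperature matches a
    sampled temperature category (two-decimal precision).

    Appended rows carry the dummy-count average of their category's sampled
    rows (re-rounded to integers) and ``provenance='augmented'``; sampled
    rows are never modified.
    """
    temp = grid.layer("bottom_temperature", timeframe)
    cats = np.round(sampled.temperature, 2)
    cat_means = {}
    for c in np.unique(cats):
        cat_means[c] = sampled.counts[cats == c].mean(axis=0)
    grid_t = np.round(temp, 2)
    candidate = (present_mask == 1) & np.isfinite(temp)
    sampled_cells = set(zip(*[a.tolist() for a in
                              (grid.cell_index(sampled.lat, sampled.lon))]))
    new_lat, new_lon, new_t, new_y = [], [], [], []
    for (i, j) in zip(*np.nonzero(candidate)):
        if (i, j) in sampled_cells:
            continue
        tc = grid_t[i, j]
        if tc in cat_means:
            new_lat.append(grid.lat[i])
            new_lon.append(grid.lon[j])
            new_t.append(temp[i, j])
            new_y.append(np.rint(cat_means[tc]).astype(int))
    if not new_lat:
        log.warning("augment_locations: no temperature-matched cells found")
        return sampled
    return JSDMInput(
        lat=np.concatenate([sampled.lat, new_lat]),
        lon=np.concatenate([sampled.lon, new_lon]),
        temperature=np.concatenate([sampled.temperature, new_t]),
        counts=np.vstack([sampled.counts, np.asarray(new_y)]),
        asvs=sampled.asvs,
        provenance=np.concatenate([sampled.provenance,
                                   ["augmented"] * len(new_lat)]),
    )


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------
def _great_circle_km(lat, lon):
    la = np.deg2rad(np.asarray(lat))
    lo = np.deg2rad(np.asarray(lon))
    xyz = np.column_stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo),
                           np.sin(la)])
    chord = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    return 2.0 * 6371.0088 * np.arcsin(np.clip(chord / 2.0, 0, 1))


def _design(temperature, t_mean, t_sd, quadratic):
    ts = (np.asarray(temperature, dtype=float) - t_mean) / t_sd
    cols = [np.ones_like(ts), ts]
    if quadratic:
        cols.append(ts**2)
    return np.column_stack(cols)


def _loglik_cols(y, loglam):
    # Poisson log-likelihood per ASV column (constant term dropped)
    return (y * loglam - np.exp(loglam)).sum(axis=0)


@dataclass
class JSDMFit:
    """Posterior draws and diagnostics of the Poisson spatial model."""

    beta: np.ndarray                # (chains, samples, P, J)
    loadings: np.ndarray            # (chains, samples, J)
    eta: np.ndarray                 # (chains, samples, n)
    asvs: tuple[str, ...]
    t_mean: float
    t_sd: float
    quadratic: bool
    input: JSDMInput
    psrf: dict = field(default_factory=dict)
    explanatory_r2: np.ndarray = None
    tjur: dict = field(default_factory=dict)

    def beta_flat(self) -> np.ndarray:
        c, s, p, j = self.beta.shape
        return self.beta.reshape(c, s, p * j)

    def posterior_mean_rate(self, temperature, include_spatial=False):
        """Posterior-mean Poisson rate per ASV at given temperatures
        (marginalizing the spatial field unless requested)."""
        X = _design(temperature, self.t_mean, self.t_sd, self.quadratic)
        b = self.beta.reshape(-1, *self.beta.shape[2:])    # (draws, P, J)
        loglam = np.einsum("np,dpj->dnj", X, b)
        if include_spatial:
            eta = self.eta.reshape(-1, self.eta.shape[-1])
            lam = self.loadings.reshape(-1, self.loadings.shape[-1])
            loglam = loglam + eta[:, :, None] * lam[:, None, :]
        return np.exp(loglam).mean(axis=0)                  # (n, J)


def fit_jsdm(data: JSDMInput, chains: int = 2, samples: int = 500,
             warmup: int = 500, seed: int = 0, quadratic: bool = False,
             gp_range_km: float | None = None,
             compute_diagnostics: bool = True) -> JSDMFit:
    """Sample the posterior of the Poisson spatial joint model.

    ``quadratic`` adds a squared temperature term per ASV (the default is
    the linear effect).  The spatial latent factor uses an exponential
    covariance with range ``gp_range_km`` (default: median pairwise
    distance).  Identical seeds give identical posterior draws.
    """
    if data.n_locations < 2:
        raise ValueError("need at least 2 locations")
    if chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    y = data.counts.astype(float)
    n, J = y.shape
    t_mean = float(data.temperature.mean())
    t_sd = float(data.temperature.std()) or 1.0
    X = _design(data.temperature, t_mean, t_sd, quadratic)
    P = X.shape[1]

    D = _great_circle_km(data.lat, data.lon)
    if gp_range_km is None:
        off = D[np.triu_indices(n, 1)]
        off = off[off > 0]
        gp_range_km = float(np.median(off)) if len(off) else 1.0
    K = np.exp(-D / max(gp_range_km, 1e-6)) + 1e-6 * np.eye(n)
    K_chol = np.linalg.cholesky(K)

    b0_center = np.log(y.mean(axis=0) + 0.1)
    prior_sd = np.full((P, J), 2.0)
    prior_mean = np.zeros((P, J))
    prior_mean[0] = b0_center

    beta_out = np.empty((chains, samples, P, J))
    load_out = np.empty((chains, samples, J))
    eta_out = np.empty((chains, samples, n))
    master = np.random.SeedSequence([int(seed), 777])
    for c, ss in enumerate(master.spawn(chains)):
        rng = np.random.default_rng(ss)
        beta = prior_mean + 0.1 * rng.standard_normal((P, J))
        lam = 0.1 * rng.standard_normal(J)
        eta = K_chol @ rng.standard_normal(n)
        step_b = np.full((P, J), 0.2)
        step_l = np.full(J, 0.2)

        def loglam_of(beta, lam, eta):
            return X @ beta + np.outer(eta, lam)

        ll = _loglik_cols(y, loglam_of(beta, lam, eta))
        for it in range(warmup + samples):
            # vectorized scalar Metropolis for each beta row
            for p in range(P):
                prop = beta.copy()
                prop[p] = beta[p] + step_b[p] * rng.standard_normal(J)
                ll_prop = _loglik_cols(y, loglam_of(prop, lam, eta))
                lp = (ll_prop - ll
                      - 0.5 * ((prop[p] - prior_mean[p]) / prior_sd[p]) ** 2
                      + 0.5 * ((beta[p] - prior_mean[p]) / prior_sd[p]) ** 2)
                acc = np.log(rng.random(J)) < lp
                beta[p, acc] = prop[p, acc]
                ll = np.where(acc, ll_prop, ll)
                if it < warmup:
                    step_b[p] *= np.where(acc, 1.04, 0.985)
            # loadings
            prop_l = lam + step_l * rng.standard_normal(J)
            ll_prop = _loglik_cols(y, loglam_of(beta, prop_l, eta))
            lp = (ll_prop - ll - 0.5 * (prop_l / 0.5) ** 2
                  + 0.5 * (lam / 0.5) ** 2)
            acc = np.log(rng.random(J)) < lp
            lam = np.where(acc, prop_l, lam)
            ll = np.where(acc, ll_prop, ll)
            if it < warmup:
                step_l *= np.where(acc, 1.04, 0.985)
            # latent spatial field: elliptical slice sampling
            nu = K_chol @ rng.standard_normal(n)
            logy = float(ll.sum()) + np.log(rng.random())
            angle = rng.uniform(0, 2 * np.pi)
            amin, amax = angle - 2 * np.pi, angle
            while True:
                eta_prop = eta * np.cos(angle) + nu * np.sin(angle)
                ll_prop = _loglik_cols(y, loglam_of(beta, lam, eta_prop))
                if float(ll_prop.sum()) > logy:
                    eta, ll = eta_prop, ll_prop
                    break
                if angle < 0:
                    amin = angle
                else:
                    amax = angle
                angle = rng.uniform(amin, amax)
            if it >= warmup:
                s = it - warmup
                beta_out[c, s] = beta
                load_out[c, s] = lam
                eta_out[c, s] = eta

    fit = JSDMFit(beta=beta_out, loadings=load_out, eta=eta_out,
                  asvs=data.asvs, t_mean=t_mean, t_sd=t_sd,
                  quadratic=quadratic, input=data)
    if compute_diagnostics:
        fit.psrf = convergence_psrf(fit)
        lam_hat = fit.posterior_mean_rate(data.temperature,
                                          include_spatial=True)
        fit.explanatory_r2 = _log_scale_r2(y, lam_hat)
        fit.tjur = _tjur_by_asv(y, lam_hat, data.asvs)
    return fit


def convergence_psrf(fit: JSDMFit) -> dict:
    """Split-chain Gelman-Rubin psrf for every beta parameter."""
    draws = fit.beta_flat()                         # (chains, samples, K)
    c, s, k = draws.shape
    if c < 2:
        raise ValueError("psrf needs >= 2 chains")
    half = s // 2
    split = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, nn = split.shape[0], split.shape[1]
    means = split.mean(axis=1)                      # (m, K)
    vars_ = split.var(axis=1, ddof=1)               # (m, K)
    W = vars_.mean(axis=0)
    B = nn * means.var(axis=0, ddof=1)
    var_hat = (nn - 1) / nn * W + B / nn
    psrf = np.sqrt(var_hat / np.where(W > 0, W, np.nan))
    psrf = np.where(W > 0, psrf, 1.0)
    lo, hi = np.percentile(psrf, [2.5, 97.5])
    return {"per_parameter": psrf, "mean": float(np.mean(psrf)),
            "ci95": (float(lo), float(hi))}


def tjur_r2(predicted_prob, outcomes) -> float:
    """Tjur's coefficient of discrimination: mean prediction for observed
    successes minus mean prediction for observed failures."""
    p = np.asarray(predicted_prob, dtype=float)
    o = np.asarray(outcomes).astype(bool)
    if o.all() or (~o).all():
        raise ValueError("Tjur R2 undefined with a single outcome class")
    return float(p[o].mean() - p[~o].mean())


def _tjur_by_asv(y, lam_hat, asvs) -> dict:
    out = {}
    vals = []
    for j, asv in enumerate(asvs):
        o = y[:, j] > 0
        if o.all() or (~o).all():
            log.info("Tjur R2: ASV %s has a single outcome class; excluded",
                     asv)
            continue
        p = 1.0 - np.exp(-lam_hat[:, j])    # P(count > 0) under Poisson
        out[asv] = tjur_r2(p, o)
        vals.append(out[asv])
    out["mean"] = float(np.mean(vals)) if vals else float("nan")
    return out


def _log_scale_r2(y, lam_hat) -> np.ndarray:
    """Squared Pearson correlation between log(y + 0.5) and log predicted
    rate, per ASV (variance explained on the log-expected scale)."""
    obs = np.log(y + 0.5)
    pred = np.log(np.maximum(lam_hat, 1e-12))
    r2 = np.empty(y.shape[1])
    for j in range(y.shape[1]):
        if obs[:, j].std() == 0 or pred[:, j].std() == 0:
            r2[j] = np.nan
            continue
        r2[j] = np.corrcoef(obs[:, j], pred[:, j])[0, 1] ** 2
    return r2


def cross_validate(data: JSDMInput, folds: int = 2, seed: int = 0,
                   **fit_kwargs) -> np.ndarray:
    """Predictive R2 per ASV from k-fold cross-validation over locations.

    Held-out rates are predicted from the temperature effect alone (the
    latent field is site-specific and integrates to its prior mean).
    """
    n = data.n_locations
    if n < 2 * folds:
        raise ValueError("need >= 2 locations per fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    assign[perm] = np.arange(n) % folds
    pred = np.full(data.counts.shape, np.nan)
    fit_kwargs.setdefault("compute_diagnostics", False)
    for f in range(folds):
        tr = assign != f
        sub = JSDMInput(lat=data.lat[tr], lon=data.lon[tr],
                        temperature=data.temperature[tr],
                        counts=data.counts[tr], asvs=data.asvs,
                        provenance=data.provenance[tr])
        fit = fit_jsdm(sub, seed=seed + 101 * (f + 1), **fit_kwargs)
        pred[~tr] = fit.posterior_mean_rate(data.temperature[~tr])
    return _log_scale_r2(data.counts.astype(float), pred)


def explanatory_predictive_ratio(explanatory_r2, predictive_r2,
                                 asvs) -> pd.DataFrame:
    """Ratio explanatory/predictive R2, defined only where both positive;
    ranked by smallest positive ratio."""
    e = np.asarray(explanatory_r2, dtype=float)
    p = np.asarray(predictive_r2, dtype=float)
    ok = (e > 0) & (p > 0)
    df = pd.DataFrame({"asv": asvs, "explanatory_r2": e, "predictive_r2": p})
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = np.where(ok, e / p, np.nan)
    return df.sort_values("ratio", na_position="last").reset_index(drop=True)


def spatial_predict(fit: JSDMFit, grid: EnvGridStack, timeframe: str,
                    present_mask: np.ndarray,
                    window: tuple[float, float] = (6.2, 8.2)) -> dict:
    """Per-ASV relative-abundance surfaces (percent, summing to 100 per
    cell) over predicted-presence cells within the temperature window."""
    temp = grid.layer("bottom_temperature", timeframe)
    lo, hi = window
    domain = (present_mask == 1) & (temp >= lo) & (temp <= hi)
    if not domain.any():
        raise ValueError("no cells inside the temperature window")
    t_cells = temp[domain]
    rates = fit.posterior_mean_rate(t_cells)            # (n_cells, J)
    shares = rates / rates.sum(axis=1, keepdims=True) * 100.0
    out = {}
    for j, asv in enumerate(fit.asvs):
        surf = np.full(temp.shape, np.nan)
        surf[domain] = shares[:, j]
        out[asv] = surf
    return out


def optimal_temperature(fit: JSDMFit, asv: str,
                        window: tuple[float, float] = (6.2, 8.2),
                        step: float = 0.01) -> tuple[float, bool]:
    """Temperature [deg C] maximizing the ASV's predicted relative
    abundance over a fine grid; returns (optimum, interior flag)."""
    lo, hi = window
    tgrid = np.arange(lo, hi + step / 2.0, step)
    rates = fit.posterior_mean_rate(tgrid)
    shares = rates / rates.sum(axis=1, keepdims=True)
    j = fit.asvs.index(asv)
    k = int(np.argmax(shares[:, j]))
    interior = 0 < k < len(tgrid) - 1
    if not interior:
        log.warning("optimal_temperature: argmax for %s on the window "
                    "boundary (monotone response)", asv)
    return float(tgrid[k]), interior
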