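# Methods

This note documents the models, numerical choices and known limitations of
`holomap`. It describes what the code computes and why each open design
point was settled the way it was; it states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Analysis grid and environmental layers

The analysis raster is a regular WGS-84 lat/lon grid, cell size 0.088°,
cell-center registration. Nine predictor layers are carried: depth [m,
positive down] and slope [°] (static), and per timeframe the mean bottom
temperature [°C], bottom salinity [psu], bottom current speed [m s⁻¹],
bottom stress [N m⁻²], maximum mixed-layer depth [m], surface temperature
[°C] and surface salinity [psu]. Seven multi-decadal timeframes span
1871–2085. All layers share one validity mask; the study mask removes
cells within a 5 km great-circle buffer of land (land = non-positive or
missing depth) and cells deeper than 2000 m. Timeframe climatologies are
arithmetic means of monthly fields, which commutes with masking.

Bottom stress uses a quadratic drag law, τ_b = 3.5·10⁻³ ρ U_b² for model
output and τ_b = 3.5·10⁻³ ρ U_b √(U_b² + 0.02) for reanalysis-derived
speeds; the 0.02 constant is treated as m² s⁻², making the two laws agree
to within √(1 + 0.02/U_b²) at large speed. Bottom values of T/S depth
cubes are taken from the depth level closest to the local bathymetry (ties
to the shallower level); the 5 m level stands in for the surface.

### Seawater density

Density is computed with the UNESCO EOS-80 international equation of state
(surface polynomial of Millero & Poisson plus the secant bulk modulus),
with potential temperature from the Fofonoff adiabatic-lapse RK4
integration and pressure from depth by hydrostatic fixed-point iteration
over a standard-ocean column (SP = 35, θ = 0 °C) with the 1980
international gravity formula. The implementation reproduces the published
UNESCO check values to their printed precision (ρ(0, 5, 0) = 999.96675,
ρ(35, 5, 0) = 1027.67547, ρ(35, 25, 10000 dbar) = 1062.53817,
θ(40, 40, 10000 dbar) = 36.89073), which the test suite asserts. Absolute
salinity is the reference-composition rescaling SA = SP·35.16504/35; the
regional composition-anomaly climatology is intentionally omitted (the
anomaly is < 0.03 g kg⁻¹ in the study region and density differences of
order 0.01–0.1 kg m⁻³ are irrelevant at the precision bottom stress and
stratification are used here). TEOS-10 and EOS-80 differ by a comparable
margin; EOS-80 was chosen because it is fully self-contained and
check-value verifiable without external coefficient tables.

The mixed-layer depth uses a density-threshold criterion: the shallowest
depth at which surface-referenced potential density exceeds the
shallowest-level value by Δσ = 0.03 kg m⁻³ (config-exposed), linearly
interpolated between levels; unstratified profiles return the deepest
level with a flag. The "maximum" MLD of a timeframe is the maximum of
monthly MLDs.

Point-to-grid interpolation is deterministic inverse-distance weighting
(power 2, 12 nearest neighbors, great-circle metric, exact at coincident
cell centers). It replaces a GIS ordinary-kriging step: a fitted-variogram
interpolator is stochastic and adds a heavy dependency, while the role of
the step — a gap-free surface at the analysis resolution — is preserved.

Slope uses Horn's 3×3 finite differences with metric spacings from the
geographic grid (edge replication at boundaries, equivalent to one-sided
differences). Geodesic cell areas are analytic WGS-84 quadrangle areas via
the authalic-latitude integral, cross-checked against numerical quadrature
of the ellipsoid surface element.

## Host species distribution models

Occurrence records are deduplicated to one record per (species, cell) with
presence dominating and coordinates replaced by cell centroids. Each
species then receives pseudo-absences at every cell that has a record of
any other species but none of its own, after which all species share one
record-cell union. Classification forests use 500 trees, ⌊√9⌋ = 3
candidate features per split, unlimited depth; per-cell probability is the
fraction of tree votes.

Validation is 5-fold spatial block cross-validation: square blocks
(default 10 cells, 5 in the test suite's smaller grids) are assigned
greedily, largest record count first with deterministic tie-breaks, to the
currently smallest fold. AUC (rank-based, midrank ties) is computed per
held-out fold and summarized as mean ± SD. The MSS threshold is taken on
the pooled out-of-fold scores, with candidates the midpoints of sorted
unique scores plus {0, 1} and ties resolved to the smallest maximizing
threshold; fold confusion matrices at that threshold are summed before
sensitivity, specificity and TSS are computed. Binarization is
boundary-inclusive (probability ≥ threshold → suitable). Projections onto
any timeframe report the mean and SD across the five fold models — the SD
definition fixes the fold-model mean (not a refit on all data) as the
projected surface. Response curves are partial-dependence sweeps (100
steps over the observed covariate range) averaged over training cells and
fold models.

## Microbiome diversity and the richness overlay

ASV tables are rarefied by a single multivariate-hypergeometric draw per
sample to exactly 6000 reads (samples below depth dropped and logged; the
seed is recorded in the output metadata). Averaging multiple rarefaction
draws would shrink the variance the SE estimates are meant to carry.
Shannon diversity uses natural log by default (a base flag is provided).
Per-host summaries are means over samples with SE = SD/√n.

Prevalence classes per host partition the observed ASVs into core (all
individuals), variable ≥ 10 individuals, variable 2–9, and individual
(exactly 1); "all individuals" is interpreted per host group. Key ASVs
require prevalence ≥ 10 individuals *and* mean relative abundance > 1 %,
the mean taken over all of the host's samples with zeros included.

Cumulative microbial richness adds, per cell, the mean observed richness
of every host whose binarized habitat map is 1 there; cells with no
predicted host carry no value. For temporal differencing an absent value
counts as 0, so colonization is a gain and loss of all hosts a loss; gain
and loss percentages are taken over shifted cells only. Region-wise
uncertainty first converts the per-cell summed host SD and summed
microbiome SE into relative values (each divided by its study-wide total),
adds them, and rescales the combined field linearly onto [0, 100] before
taking region medians (latitude bands A 52.1–71.5° N, C 25.0–40.0° N, B
between; boundary cells go north). The wording "standardized to 100"
admits more than one reading, so the per-cell percent-of-maximum variant
is implemented behind a strategy flag; neither is asserted as canonical.
Envelope exceedance counts, per cell, the parameters strictly outside the
min–max range spanned by the sampled cells — all nine parameters over all
cells for hosts, and depth/bottom temperature/bottom salinity restricted
to predicted-presence cells for microbiomes; the two counts are summable.

## Joint model of key ASVs vs temperature

Relative abundances of the key ASVs are re-closed to 1, scaled by 100
("dummy" integers, round half away from zero; the scale is recorded in
output metadata) and modeled as

log λ_ij = β0_j + β1_j·T̃_i [+ β2_j·T̃_i²] + Λ_j·η_i,  y_ij ~ Poisson(λ_ij)

with T̃ the standardized temperature and η a latent spatial factor with
exponential covariance exp(−d/ρ) over great-circle distance (range ρ
defaults to the median pairwise distance). Priors: β ~ N(0, 2²) with the
intercept centered at log of the ASV's mean count, Λ_j ~ N(0, 0.5²).
The default is the linear temperature effect; a quadratic flag exists
because interior abundance optima are most directly expressed by
log-quadratic (Gaussian-niche) responses. With the linear model, interior
optima of *relative* abundance can still arise through cross-ASV
renormalization (a softmax over ASVs peaks interiorly for intermediate
slopes).

Sampling is elliptical slice sampling for η and vectorized adaptive
random-walk Metropolis (target acceptance ≈ 0.44 during warmup) for β and
Λ, in ≥ 2 independent chains; identical seeds give bit-identical draws.
Convergence uses the split-chain Gelman–Rubin psrf per β (cross-checked
against a reference implementation on stored draws in the tests).
Tjur R² is binary by definition while the likelihood is Poisson; it is
applied to the presence transform (count > 0) with P(y > 0) = 1 − e^{−λ̂},
single-class ASVs excluded from the mean. "Explanatory R²" for Poisson
responses is not uniquely defined; the package uses squared Pearson
correlation between log-predicted rate and log(y + 0.5) (variance
explained on the log-expected scale), the same metric out-of-fold for
predictive power (2-fold CV over locations, held-out rates from the
temperature effect alone since the latent field is site-specific).
Ratios explanatory/predictive are reported only where both are positive.

The temperature-matched augmentation snaps in-situ samples to grid cells,
averages co-located communities, rounds temperatures to two decimals to
form categories, and appends every other predicted-presence cell whose
rounded temperature matches a category, carrying the category's average
composition; sampled rows are never modified. Spatial predictions are
posterior-mean rates renormalized to 100 % per cell, restricted to
predicted-presence cells inside the modeled temperature window (default
6.2–8.2 °C); optimal temperatures are argmaxes over a 0.01 °C grid, with
boundary argmaxes flagged as non-interior.

## Networks

SparCC basis correlations are estimated from the log-ratio variation
matrix t_ij = var(log x_i/x_j): under sparsity the basis variances solve
the linear system t_i = Σ_j (w_i + w_j), after which
ρ_ij = (w_i + w_j − t_ij)/(2√(w_i w_j)). The most strongly correlated pair
above an exclusion threshold (default 0.1) is iteratively removed from the
system (up to 10 exclusions), and the whole inference is averaged over 20
Dirichlet(counts + 1) resampling rounds with a fixed seed. At least four
ASVs are required (the system is underdetermined below that). Edges keep
sign; the network is restricted to nodes connected to at least one key
ASV. Key ASVs with ≥ 1 non-key neighbor are "highly interconnected";
those whose every neighbor is key (or with no edges, flagged) are
"interconnected". Degree-vs-fit association uses Pearson r with the exact
two-sided t transform (n − 2 df), no multiple-testing correction. The
SparCC edge threshold (0.3) and round count are package defaults exposed
in config — results that depend on them are not asserted in tests.

Biomass networks first filter species to sessile/sessile-burrow,
high-abundance/patchy, active/passive filter feeders (missing traits
exclude the row), group them as HMA, LMA, or phylum × size class, sum
member biomass per station, and correlate group vectors (Pearson, signed
edges above |r| ≥ 0.5, constant groups excluded).

## Synthetic-data generator

The generator's defaults encode the emulated study conditions:

- grid 0.088°, seven timeframes with bottom-temperature offsets −0.4 …
  +2.0 °C relative to 1990–2015 (an RCP8.5-like +2 °C by 2066–2085,
  amplified 1.3× at the surface);
- environmental fields are low-order latitude/longitude trends plus
  Gaussian random fields (Gaussian-smoothed white noise, length scale 5
  cells), so spatial autocorrelation is realistic and spatial block CV
  genuinely differs from random CV; depth/slope are static; stress is
  computed from the generated U_b, T, S and the package's own density;
- five host species with Gaussian-on-logit niches in temperature and
  depth; the two corals are presence-only (their records carry no
  absences, exercising the pseudo-absence machinery); the glass sponge's
  thermal niche (optimum 7.4 °C) overlaps the key-ASV optima;
- the 99-sample microbiome design: 16/19/8/7/32 host individuals plus 17
  seawater samples; Dirichlet-multinomial counts around host mean
  compositions; per-host Zipf exponents and overdispersions chosen so
  observed richness at 6000-read depth lands near the measured magnitudes
  (sponges ≈ 160–470, corals ≈ 140–420, seawater ≈ 580 ASVs);
- the focal host carries exactly 15 ASVs satisfying the key criteria
  (geometric block, ratio 0.88, jointly ≈ 2/3 of the community; all tail
  ASVs stay below 1 %), with Gaussian temperature responses whose first
  two optima sit at 7.5 and 7.7 °C (width 0.6 °C) and the rest respond
  weakly;
- library sizes are lognormal (median ≈ 10⁴, σ = 0.25, floored at the
  rarefaction depth) — the real library-size distribution is not known, so
  it is a config knob;
- the biomass table holds 116 qualifying filter feeders across eight phyla
  (ten sponges with 5 + 5 HMA/LMA status) plus a few non-qualifying mobile
  species, with station biomass from a latent Gaussian group model whose
  HMA–Cnidaria correlation is configurable (default 0.8).

What the generator does *not* emulate: ocean dynamics (fields are
statistical surrogates, not physics), sampling bias in occurrence records,
sequencing error/chimeras (counts are clean draws), and phylogenetic
structure among ASVs. Passing tests therefore demonstrate that the
analysis machinery recovers known structure under its own statistical
assumptions, not that those assumptions hold for any particular real
survey.

## Problem sizes, seeds and determinism

A single global seed expands into per-stage seeds through fixed-offset
`SeedSequence` spawning, so stages rerun in isolation reproduce their
in-pipeline results; every generator and sampler is a deterministic
function of its seed. The test suite and the acceptance script use small
grids (roughly 30 × 40 cells), a few hundred occurrence records per
species, 100 joint-model locations with 2 × (1200–2000) MCMC iterations,
and 20 SparCC rounds — sizes at which every stochastic recovery check has
comfortable signal while the complete suite runs in well under a minute
per heavy test. Fold-model forests keep the 500-tree default where
discrimination itself is asserted and use smaller forests where only
plumbing is under test.

## Known limitations

- EOS-80 instead of TEOS-10 (differences ≲ 0.1 kg m⁻³; see above), and no
  salinity-anomaly climatology.
- The MLD criterion is a stand-in: the upstream profile tooling is not
  specified beyond its function name, so the conventional 0.03 kg m⁻³
  threshold rule was fixed and exposed in config.
- The joint model's "explanatory R²" and Tjur R² involve choices (log-scale
  variance, presence transform) that other implementations may make
  differently; both are documented above and reported, not asserted
  against external values.
- IDW replaces ordinary kriging; smooth fields interpolate comparably but
  kriging variance estimates are not produced.
- GeoTIFF input/output is not supported; raster exchange is NetCDF
  (CF-style, scipy engine) and tabular exchange CSV/TSV.
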