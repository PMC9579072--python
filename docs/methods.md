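# Methods

## Scope and data model

The package analyses long-format benthic survey tables: one row per
station × period × replicate grab × taxon group, with design covariates
(zone, isobath line and measured depth, sediment class, grid vs hotspot)
and wet tissue biomass in g/m². The emulated design is a nearshore
detailed grid — two station lines along the 9 m and 13 m isobaths (52
planned stations each, ~2 km spacing), three zones (North/Middle/South),
three seasonal periods with three replicate van Veen grabs per station —
plus targeted "feeding hotspot" areas sampled once with 12 grabs treated
as replicates. Per-period sampled-station counts default to the staggered
coverage actually achieved in such surveys (e.g. 22/32/14 stations in the
three zones early in the season, 42/41/18 mid-season, 21/21/12 late).

Zone sizes along each line are not fully determined by those counts; the
default splits each 52-station line North/Middle/South as 22/21/9 (9 m)
and 21/21/10 (13 m) so that zone totals (43/42/19) can accommodate the
largest per-period demand. Staggered sampling is modelled as a uniform
without-replacement draw of the per-zone quota; replicate grabs within a
station are exchangeable.

## Synthetic survey generator

Per grab and taxon group *g*:

- with probability π_g the grab records zero biomass (hurdle);
- otherwise ln(Y+1) = m_g(zone, period) + β₁_g z + β₂_g z² + b_station + ε,
  with b_station ~ N(0, σ²_station,g) shared across all visits to the
  station, ε ~ N(0, σ²_resid,g), and Y = max(exp(·) − 1, 0).

z is depth standardized by fixed constants (centre 11 m, scale 2 m), so
the two isobath lines sit near z = ∓1. Station depths are jittered
N(nominal, 0.5 m) truncated to [7, 15] m; sediment is medium sand with
probability 0.8 on the 13 m line and fine sand with probability 0.8 on
the 9 m line. The hurdle-lognormal form is the simplest generative model
consistent with an ln(X+1)-scale Gaussian ANCOVA plus the observation that
fish (sand lance) biomass is frequently zero in individual grabs.

**Calibration.** Default parameters are obtained by exact moment inversion:
for each taxon × zone × period cell with a published dominance-ranking
target (mean, SD) of grab-level biomass, the cell location m and total SD
s = √(σ²_station + σ²_resid) solve the two moment equations of the
hurdle-lognormal, accounting for the equal mixture of the two isobath
depths (Gauss–Hermite quadrature over the depth jitter). Cells outside the
top five ranked groups have no published value and receive nominal low
biomass (mean 1 g/m², SD 2). Because cell SDs vary more than a single
per-taxon residual SD can express, the calibrated defaults carry a
per-cell residual SD; the station SD is set to half the smallest cell
variance of the taxon so every cell's residual variance stays positive.
Zero-inflation defaults: 0.4 for Actinopterygii, 0.02 for the invertebrate
groups, 0.1 for the residual category (the single tunicate entry in the
dominance table is carried under "other"). Depth coefficients place
amphipods and isopods in shallow/fine-sand habitat and bivalves, sand
dollars and sand lance in deeper/medium-sand habitat (|β₁| = 0.2–0.5 on
the ln scale), with curvature for the groups whose quadratic depth term
the univariate analysis flags.

Hotspot cells have no published targets; defaults use each zone's mean of
the two bracketing periods' targets with a 1.5× mean multiplier for prey
groups, reflecting that hotspots are high-biomass patches.

**What the generator does not emulate:** spatial autocorrelation along the
lines beyond the station effect, within-season temporal drift inside a
period, taxonomic composition below the group level, sediment–granulometry
linkage, and any shoreline/oceanographic forcing. The max(·, 0) floor
slightly inflates means of very low-biomass cells (where P(η < 0) is
non-negligible); calibrated dominant cells are unaffected (P(η < 0) < 10⁻³).
Passing calibration tests therefore shows the generator reproduces
grab-level first and second moments and the design's replication
structure, not the full dependence structure of field data.

## Mixed-model ANCOVA

Response: ln(biomass + 1) per replicate grab, grid rows only. Fixed
effects: zone, period, zone:period (sum-to-zero contrasts), standardized
depth z and z² (sample mean/SD of the analysed rows, n−1 convention,
stored with the fit). Random: station intercept; replicate-level residual.
"Replicates nested within station" is implemented as this two-level model;
a station visited in several periods keeps one station effect. Estimation
is REML via statsmodels MixedLM, restarted across optimizers on
non-convergence.

Marginal (Type-III-style) F statistics are computed per effect from the
GLS estimates at the REML variance components — the design is
nonorthogonal, so sequential SS would depend on entry order. Denominator
df use the Satterthwaite approximation: for a contrast L, the matrix
L C(θ) Lᵀ (C = (XᵀV⁻¹X)⁻¹) is eigen-decomposed and each direction's
candidate df ν_i = 2d_i²/(g_iᵀ W g_i) is pooled as in lmerTest, where g_i
is the gradient of the direction's variance in θ = (σ²_station, σ²_resid)
and W the inverse observed REML information. Gradients and the information
matrix are computed by central finite differences of a closed-form
random-intercept REML likelihood (Sherman–Morrison per-station blocks);
the stencil is kept inside the parameter space, and a degenerate
information matrix (variance estimate at the zero boundary) falls back to
the replicate-level residual df. Agreement with R lmerTest is verified in
the test suite to ~10⁻³ relative error; with zero station variance the
F table collapses to the Type-III fixed-effects ANCOVA.

Zero-heavy groups (Actinopterygii) are fit on the full data including
zeros, relying on the F test's robustness at large n. Total prey is the
per-grab sum of Actinopterygii, Amphipoda, Bivalvia, Cumacea, Isopoda and
Polychaeta; Echinoidea and "other" are excluded.

## Minimum-effects tests

The interval null "the true effect is no larger than boundary f" is tested
by comparing the observed F against the upper α quantile of a noncentral
F(df1, df2, λ) with λ = DF_err·PV/(1−PV) = DF_err·f², PV = f²/(1+f²) —
the large-sample approximation of the boundary noncentrality. Boundaries
default to f = 0.2 (small: natural variability), 0.5 (medium: crossing an
ecological boundary; PV = 20% by the analytic conversion), 0.8 (large:
disturbance-scale change, PV ≈ 39%). A tie (F exactly at the critical
value) retains the null. Classification reports the largest rejected
boundary ("exceeds-small/medium/large", else "negligible-to-small") and is
monotone in F. Noncentral-F quantiles and tail probabilities come from
SciPy's ncf routines; the test suite checks them against 10⁷-draw
ratio-of-chi-squares Monte-Carlo oracles, and checks that simulating F
exactly on the boundary yields rejection rate α. A dimensionally odd
variant of the λ formula (DF_err·PV²) that circulates in print is exposed
behind `form="printed"` purely for comparison and is used nowhere.

Post hoc power is P[F′(df1, df2, λ) > F_crit(central)], equal to α at
λ = 0 and increasing in λ.

## Community analysis

Replicate biomasses are ln(X+1)-transformed and averaged per station visit
(transform-then-average; the average-then-transform order is available,
since either reading is defensible — the default is documented and kept
fixed). Groups present at fewer than 5% of station visits are dropped
(configurable; "rare groups excluded" has no published definition).
Bray–Curtis dissimilarities are computed by SciPy; an all-zero row pair is
0/0 and is set to 0 with a warning.

NMDS uses nonmetric SMACOF with isotonic regression (scikit-learn), best
of 20 random starts, reporting Kruskal stress-1; coordinates are centred
and rotated to principal axes so axis 1 carries the dominant gradient
(sign fixed by the largest loading). Group centroids get per-axis t-based
95% CIs; singleton groups are flagged.

NPMANOVA partitions the Gower-centred matrix G = C(−D²/2)C by sequential
(entry-order) sums of squares tr((H_j − H_{j−1})G) over the growing design
(period, zone, sediment, depth as the two-level isobath factor, then
period:zone); pseudo-F = (SS/df)/(SS_res/df_res); p-values from free
permutation of rows, p = (1 + #{F* ≥ F})/(1 + n_perm), default n_perm =
9999, exhaustive enumeration available for tiny inputs. The partition is
verified against R vegan's adonis2 and, for the one-way case, against the
classical within/between-group distance decomposition. Pairwise
period×zone comparisons run two-group permutation tests on sub-matrices of
the full distance matrix with Holm step-down adjustment at α = 0.05.

## Numerical and design choices

- α defaults to 0.05 everywhere; thresholds for amphipod exceedance
  default to 60/100/200 g/m² (60 ≈ minimum biomass for gray-whale
  feeding; configurable) and exceedance is computed over replicate values
  (station-mean mode available).
- Dominance rankings are means/SDs over replicate values per period×zone,
  ties broken alphabetically; summary CIs are t-intervals on untransformed
  biomass (a log-scale option exists, off by default).
- Stage seeds derive from blake2b(master_seed, stage name) mod 2³¹, so
  adding a stage never shifts existing streams; identical configs yield
  byte-identical outputs.
- Model rows are canonically sorted before fitting, so estimates are
  invariant to input row order.
- Validation of survey CSVs reports every violation with its 1-based file
  line number.

## Problem sizes used by the automated checks

Calibration and recovery studies are desk-scale by design: boundary-size
and power oracles use 10⁴–10⁷ Monte-Carlo draws; variance-component and
depth-coefficient recovery averages REML fits over ten simulated surveys
of 200 stations × 3 replicates × 3 periods; null calibration uses 500
no-effect simulations (24-station grids for the ANCOVA, 18 station visits
with 199 permutations for NPMANOVA); moment calibration uses 10⁴–2×10⁴
grabs per cell; ordination-separation checks use 10 simulations of a
36-station single-period design. The recovery scenario widens the depth
jitter to 2 m so the quadratic depth term is identified away from the
two-point isobath design, and raises the ln-scale mean so the hurdle's
floor at zero never truncates the Gaussian model.

## Known limitations

- Satterthwaite df rely on finite-difference curvature of the REML
  surface; very small studies with variance estimates on the boundary fall
  back to conservative residual df.
- The generator's per-cell residual SDs mean the homoscedastic ANCOVA is
  (deliberately) an approximation when fit to the calibrated defaults —
  as it is for real survey data.
- NMDS is stochastic-start; with few starts the best-found stress can sit
  in a local optimum (the k = 3 vs k = 2 comparison in the tests tolerates
  a small margin for this).
- No spatial autocorrelation modelling, no dispersion-homogeneity
  (PERMDISP) test, no constrained ordination, no areal extrapolation of
  feeding habitat.
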