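# Methods

This note documents the models, conventions and design choices behind the
package, and what the synthetic-data tests do and do not demonstrate about
real survey data.

## Echo-integration

The echogram is a depth × along-track grid of volume backscattering
strength `Sv` (dB re 1 m⁻¹) with per-column time, position and bottom
depth. Integration follows the standard areal-backscatter convention:
per column, `NASC = 4π·1852²·Σ 10^(Sv/10)·Δz` (m² nmi⁻²), summing over
depth-bin centres at or below the 10 m surface offset and at or above the
column's bottom depth. Columns are grouped into 0.1 nmi ESDUs by
cumulative great-circle distance; the ESDU's NASC is the **mean** of its
per-column integrals, so the result is an areal density independent of
ping rate. (Whether an integrator should average or sum within an ESDU is
a convention; averaging is chosen because s_A is defined per unit surface
area.) The ESDU's representative position/time is the midpoint column's.
A trailing partial ESDU is kept if it spans at least half the nominal
length. Missing (NaN) cells integrate as zero and are counted; an ESDU
with more than half its water-column cells missing is flagged rather than
dropped, leaving the decision to the analyst.

Trophic classification precedes integration: PG `[−80, −65)` dB,
PFG `[−65, −20)` dB, TG `[−80, −20)` dB, half-open so −65 dB is fish. The
choice of band edges reflects the empirical separation of mesozooplankton
(backscattering below about −70 dB at 38 kHz) from small pelagic fish
(above about −68 dB). Cells outside all bands (below −80 or at/above −20)
are excluded as noise/unclassified targets. Because the two partition
bands are disjoint and TG is their union, `NASC_TG = NASC_PG + NASC_PFG`
is an exact invariant, verified to 1e-9 relative in tests.

Depth re-binning to 1-m output bins assigns each input bin centre to the
1-m interval containing it; grids already at 1 m pass through unchanged.

## Diel labelling and DVM

Solar altitude is computed from the NOAA general solar-position equations
(Julian-century ephemeris, apparent solar longitude, equation of time);
an independently written low-precision almanac algorithm agrees to
≤ 0.05° over 1990–2020, far inside the tolerance that matters here. The
altitude is geometric: refraction is ignored, which at the ±18°
astronomical-twilight thresholds shifts the boundary by well under the
band's width. The threshold is configurable; the ±18° default treats the
full astronomical twilight as "transition", which is then removed before
any day/night contrast so layers caught mid-migration cannot bias the
profiles.

DVM is summarised per 1-m depth bin as `Δ_DVM = mean night NASC − mean
day NASC`. For profile display the per-ESDU values may be
log10(x + 1)-transformed before averaging (the +1 offset admits the many
zero-NASC bins and is configurable); `Δ_DVM` itself is always reported on
untransformed means so its units stay m² nmi⁻².

The day/night contrast is tested with a paired Wilcoxon signed-rank test
on **annual** day vs night mean PA (one pair per survey year): pairing
per depth bin would pseudo-replicate, since all bins of a stratum share
the same ESDUs and their sampling noise moves together. Zero differences
are dropped, tied absolute differences get mid-ranks, the statistic W is
the rank sum of the less-frequent sign, and the p-value is exact for
n ≤ 25 tie-free pairs (normal approximation otherwise). An unpaired
rank-sum mode is provided for unbalanced designs.

## Barycenters

The yearly centre of gravity of a group is the NASC-weighted planar mean
of ESDU positions, computed per area (north/south of Cap Blanc, 20.77°N,
boundary inclusive to north and configurable). Weighted means of raw
degrees are used rather than a spherical centroid: within-area centroids
in this region differ from the spherical result by far less than the
interannual variability of interest, and the weighted-mean definition is
the one used in the spatial-indicator literature. Displacement over years
is tested per coordinate with the Spearman trend test; at least four
yearly positions are required for the rank test to be meaningful.

## Climatology, anomalies and trend tests

The monthly climatology is the long-term mean per calendar month; a month
absent in every year is an error because its anomalies would be
undefined. Anomalies are value minus same-month climatology, which
removes the seasonal cycle exactly for any purely seasonal signal while
preserving linear trends (up to the constant monthly offsets). Missing
values propagate rather than being interpolated — rank tests tolerate
gaps, and interpolation fabricates data.

Spearman's rho is the product-moment correlation of mid-ranks of the
values with ranks of the (strictly increasing) times. For n ≤ 9 the
two-sided p-value is exact, by full enumeration over all n! permutations
of the value ranks; above that the standard t-approximation with n − 2
degrees of freedom is used. A constant series is degenerate and returns
rho = 0, p = 1 with a flag. Environmental trends default to annual means
in the pipeline (monthly and monthly-anomaly granularities are config
switches, since short monthly series with autocorrelation inflate the
effective n); acoustic trends always use annual survey means, whose
anomaly baseline degenerates to the single all-year mean because surveys
are annual and same-season.

The 13-term smoother is the classic centered annual filter for monthly
data — weights 1/24 at the extreme lags and 1/12 in between, i.e. the
mean of two adjacent 12-month means. It annihilates the 12-month cycle
exactly and preserves linear trends; the six points at each end, where
the window is incomplete, are emitted as missing rather than padded.

## Synthetic data: what it emulates, and what it does not

The generator works at the Sv-band level: a layer is a Gaussian profile
in **linear** sv (σ = `thickness`, truncated at ±2σ) around a centre
depth chosen per column from the sun's altitude (up → day depth, down →
night depth), with optional per-cell dB jitter and partial occupancy.
Linear-domain Gaussians were chosen because echo-integration sums linear
backscatter, making closed-form expectations available for tests. Layer
contributions add linearly on top of a −100 dB noise floor. Emitted layer
cells are kept inside their trophic band: profile tails that would fall
below the band floor are cut and jitter is clipped at the band edges, so
ground-truth masks coincide exactly with in-band cells — a simulator
convention, not a physical claim. The same solar-altitude routine drives
the simulator and the analysis, so simulator "day" is pipeline "day" by
construction (the simulator switches at 0°, inside the pipeline's
transition band, so mid-twilight placement never reaches a day/night
stratum).

Default community (the conditions all recovery tests run under): a
plankton layer at −72 dB, σ 8 m, migrating 60 m (day) → 15 m (night),
occupancy 0.9; a non-migrating fish school at −58 dB, σ 5 m, 35 m,
occupancy 0.6. These levels put the integrated PG:PFG abundance ratio
near 1/10, the canonical plankton:fish backscatter ratio for this kind of
shelf ecosystem. Surveys are 13 annual upwelling-season transects
(1995–2004, 2006, 2011, 2015 by default) of 500 columns over ~2 days
crossing Cap Blanc, over a sinusoidal shelf bathymetry that exercises the
10–150 m filter. Environmental skeletons: SST 22 °C ± 3 °C seasonal with
+0.4 °C/decade and σ 0.3 °C noise; wind 5 ± 2 m s⁻¹, +0.2/decade, σ 0.5;
chlorophyll 2 ± 1 mg m⁻³, −0.1/decade, σ 0.3 — 20 years monthly.

Not emulated: the sonar equation (beam pattern, TVG, absorption),
multi-frequency response, species-level target strength, bubble and
surface echoes, spatial autocorrelation of patches along-track, and
cloud/ice gaps in satellite series. Consequently, passing recovery tests
demonstrates that the *analysis chain* is correct and well-calibrated
under its own assumptions — not that the dB thresholds separate real
species assemblages, which is an empirical matter the simulator takes as
given.

One emergent feature deserves note: because the night-time plankton layer
(15 m ± 2σ) partly overlaps the 10 m surface-offset exclusion while the
60 m daytime layer is fully observed over deep bottoms, observed night PA
is systematically below day PA for the migrating layer. The simulated
surveys therefore show a *consistent* annual day/night contrast — which is
exactly what the paired Wilcoxon is designed to detect — though its sign
depends on geometry (offset, bathymetry), not on biology alone.

## Numerical choices and degenerate inputs

- All dB→linear conversions use `10^(Sv/10)`; NaN cells are treated as
  zero backscatter and counted.
- ESDU segmentation uses haversine great-circle distances (R = 6371 km).
- Exact-permutation Spearman caps at n = 9 (9! ≈ 3.6e5 permutations,
  milliseconds); the Wilcoxon exact cap (25) follows the standard
  implementation.
- Barycenters with all-zero weights raise (`no biomass in stratum`)
  rather than returning NaN, so silent empty strata cannot enter trends.
- Reports are written with fixed float formatting (`%.10g`) and sorted
  JSON keys, making runs byte-reproducible for a given config and seed.

## Problem sizes

Defaults were sized for quick iteration: 500-column grids at 1 m × 13
years integrate in ~1 s, and the power studies (500 replicates) and the
type-I calibration (2000 replicates of n = 20) each run in seconds while
leaving binomial noise on the estimated rates of about ±1 percentage
point — small against the margins being tested.

## Known limitations

- The Wilcoxon exact p relies on tie-free differences; heavily tied data
  silently fall back to the normal approximation.
- The t-approximation for Spearman at 10 ≤ n ≤ 13 is mildly liberal;
  the type-I calibration test bounds the effect at n = 20.
- Monthly trend tests ignore serial autocorrelation of anomalies; with
  strongly autocorrelated series the annual-mean granularity is the
  defensible default.
- The CSV echogram fallback stores one row per cell and becomes
  impractical beyond ~10⁶ cells; use the NetCDF path for real grids.
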