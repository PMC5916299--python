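# Methods

This note documents the models, conventions, and design choices behind
`divefmr`, and what the synthetic-data experiments do and do not demonstrate.

## Doubly-labeled-water estimation

The chain is: plateau dilution spaces at equilibration → mass-scaled final
spaces → turnover rates from the log decline of excess enrichment → CO₂
production → watts → water flux → at-sea correction.

**Units.** The internal canonical enrichment unit is excess mole fraction;
ppm values convert by 1e-6. Pools are mol of body water, rates day⁻¹,
mass-specific CO₂ production ml g⁻¹ hr⁻¹ (via 22.4 L/mol at STP), power in
watts (23.6 kJ per liter CO₂, a carnivore-diet value).

**Dilution spaces.** Plateau: N = (mol excess isotope injected) / (excess
mole-fraction enrichment at equilibration), with the dose's excess content
computed against the background mole fraction. Scaling: the final pool is the
initial pool times the body-mass ratio, i.e. a constant body-water fraction
over the interval — the simplest defensible model when only two masses are
known. CO₂ production uses the mean of the initial (plateau) and final
(scaling) ¹⁸O pools; FMR conversion uses the arithmetic mean body mass. Both
conventions were validated against the packaged reference tables, which they
reproduce within 0.5%.

**Equations.** Single-pool rCO₂ = (N/2.078)(k_o − k_d) − 0.0062 k_d N;
two-pool replaces k_d with R·k_d in both terms, with R = 1.0427 by default
(`ratio_mode="fixed"`) or the observed N_d/N_o. Setting R = 1 collapses the
two-pool equation onto the single-pool form exactly, which is tested. All
constants are defined once in `divefmr.constants` with source citations so
the transcription is auditable.

**Water flux.** Efflux uses the linearly-changing-pool form with the log-mean
pool N̄ = (N₂−N₁)/ln(N₂/N₁) (steady-state limit k_d·N); influx is efflux plus
the pool-change rate, so influx − efflux ≡ ΔN/Δt holds identically (property
tested).

**At-sea correction.** at_sea = (FMR_total·interval − r_onshore·(interval −
t_sea))/t_sea. The onshore rate r_onshore is a *required, explicit*
assumption — either a constant W/kg or a multiple of a Kleiber basal
prediction (3.4 m^0.75 W); the default configuration offers 1.5× basal and
is flagged as an assumption. The packaged at-sea FMR column is carried as
data and is *not* recomputed: for at least one reference animal the printed
at-sea value exceeds the ceiling attainable from the whole-interval FMR with
zero onshore expenditure under any constant-rate time-budget partition, so
the exact correction that produced those numbers is not recoverable from the
printed inputs. Downstream statistics therefore treat at-sea FMR as an input
column, and the correction itself is covered by property tests (identity when
t_sea = interval; algebraic partition identity; flagged-invalid on
non-positive results).

**Uncertainty.** Monte-Carlo propagation resamples all six measured
enrichments (two isotopes × three phases) from Gaussians with the per-isotope
analytical SD, recomputes the full chain per draw (vectorized), and reports
the central 95% interval; 10,000 draws by default, deterministic under the
seed. On synthetic noisy cohorts the intervals cover the true CO₂ production
for ≈95–96% of studies. Estimates for animals whose final ¹⁸O excess
approaches the assay noise floor are individually imprecise — the interval
widens accordingly; this is inherent to the method at long intervals and high
turnover, not an implementation artifact.

## Dive processing

**Zero-offset correction** subtracts a rolling baseline (10th percentile of
near-surface readings per 6 hr window, linearly interpolated) — transducer
drift is ubiquitous in archival TDRs and the upstream processing of the
original records is unpublished, so a standard quantile baseline is used.

**Dive detection.** A submergence is a maximal run of samples deeper than a
1 m surface threshold; it is a dive when max depth ≥ 4 m and duration ≥ 16 s.
Each sample represents [t, t+dt), so an n-sample run at spacing dt lasts
n·dt; detection is exact against a brute-force threshold scan and works for
1–10 s sampling intervals. The bottom phase is the span of samples deeper
than 80% of max depth; descent rate = depth at bottom entry / descent time
(ascent symmetric). A configurable 3 m/s physical cap bounds plausible rates.

**Bouts.** Surface intervals within a bout must not exceed the bout-ending
criterion. The default criterion is estimated per deployment from the
log-survivorship curve of inter-dive intervals by a two-line broken-stick
least-squares fit (intersection of the fast within-bout and slow between-bout
processes); it falls back to a fixed 600 s when intervals are few or the fit
degenerates. The source analyses never state their criterion, so it is
configurable throughout.

**Trips.** A haul-out is ≥ 30 min of near-surface (< 1 m) readings; at-sea
periods between haul-outs become foraging trips when longer than 6 hr.
Depth-only records cannot distinguish surface swimming from hauled-out rest,
so the 30 min persistence requirement plus the observation that at-sea sea
lions submerge frequently keeps within-trip surface periods intact.

**Day/night** uses an internal NOAA solar-position routine (Spencer series
for declination and the equation of time); day ⇔ solar elevation > 0°, UTC
timestamps, location from the track median or a supplied fallback.

**Benthic labeling** uses the intra-depth-zone rule: a dive is benthic when
its max depth is within 90% of the running max over the surrounding 5 dives
(repeated dives to a common depth indicate the seafloor), corroborated by a
flat-bottom requirement (≥ 35% of the dive in the bottom phase) that rejects
V-shaped pelagic dives; a single dive is benthic by convention. The original
labeling rule is unpublished; this reconstruction recovers ≥ 90% of planted
labels on simulated mixed-strategy records, with residual errors concentrated
where pelagic dives neighbor benthic bouts in the IDZ window.

**Variable registries.** The exact membership of the two 14-variable sets
used upstream is not published; both registries here are explicit, computed
reconstructions: trip metrics (mean depth/duration/rates, bout duration,
percent time diving, dive rate, counts, percent of long and deep dives) and
fine-scale strategy variables (day/night means and rates, percent benthic /
epipelagic / mesopelagic — a partition that sums to 100% — bottom times,
depth CV, bout duration). Both are configurable.

**Track filter.** Iteratively removes the worst fix implying > 12 km/hr
transit or > 160° course reversal; the score sums the speed evidence of both
adjacent segments, since a genuine outlier produces fast transit on both
sides while its neighbors inherit only one. Hourly positions by linear
interpolation.

## Strategy classification

Variables are standardized and decomposed by correlation-matrix PCA
(components with eigenvalue > 1 retained, minimum 2); Ward-linkage
hierarchical clustering on the retained scores is cut at k = 3 by default
(the species exhibits three diving patterns), with undersized clusters merged
into the nearest occupied cluster so two occupied strategies are permitted;
linear discriminant analysis with equal priors assigns new trips and supplies
posteriors; an animal's label is the modal strategy over its trips (ties:
higher mean posterior, then lexicographic). Linkage, distance, retention rule
and priors are all unstated upstream and therefore configurable; clusters are
named by their mean depth signal (deepest = "deep"). Models serialize to
JSON.

## Population statistics

The five-variable PC regression standardizes the behavioral columns, retains
two components (≈ 90% of variance on the reference tables), tests the PC1 ×
strategy interaction by the OLS t-test on the interaction coefficient, and
fits per-strategy simple regressions on PC1 (the deep stratum, n = 4, is
flagged low-n). Regressions use *unrotated* scores; varimax rotation (of the
unit-norm coefficient matrix, sign convention: largest loading positive) is
applied for interpretation only, with rotated-score regression available as a
sensitivity switch. The Mantel test correlates lower triangles and permutes
rows/columns of one matrix (9999 permutations, one-sided greater by default,
seeded); behavioral distances weight PC scores by explained variance. ANOVA
is fixed-effects, additive in the two-factor case, Type-I sums of squares in
the order (island, strategy). The mass-change rate used to validate water
influx is (final − initial mass)/interval.

On the packaged tables the recomputed influx-by-strategy means are mixed =
128.5 ± 35.4 and deep = 141.3 ± 14.3 ml kg⁻¹ day⁻¹; published prose swaps
these two group labels, so the pipeline reports the computed values. The
recomputed PC1 × strategy interaction p is 0.018 by any sum-of-squares
ordering (reported upstream as .05 under an unstated convention).

## Synthetic-data generator

**Isotope studies.** True CO₂ production, water influx, body mass, TBW
fraction, interval, and time-at-sea are drawn from the observed envelopes of
the study cohort (0.23–0.84 ml g⁻¹ hr⁻¹, 77–174 ml kg⁻¹ day⁻¹, 59–95 kg,
55–67%, 4–17 days, 47–83%). Turnover rates are then *derived* by inverting
the two-pool CO₂ equation (fixed R) and the linearly-changing-pool efflux
equation, so the analysis chain recovers the truth exactly in the noise-free
limit — the round-trip test closes to machine precision. Washout is sampled
at the field protocol's phase structure (background pre-dose, equilibration
3.5 hr post-injection, final at recapture); the dose is sized to land the
equilibration ¹⁸O excess in the 207–327 ppm window; Gaussian analytical noise
(1.5 ppm ¹⁸O, 3 ppm ²H, triplicate-mean scale) is added per sample. Draws
whose final ¹⁸O excess would fall below 10 ppm are redrawn, modeling the
dose/interval design constraint any field protocol enforces.

**Dive records.** Records are built as haul-outs separating 1–4 day trips;
within trips, bouts of 10–22 dives (surface intervals 40–120 s) alternate
with 45–90 min surface periods punctuated by brief sub-2 m dips (so only
genuine haul-outs show sustained dry spells). The mixed strategy mixes
flat-bottomed benthic bouts along a sinusoidal 1-D seafloor (40–160 m) with
pelagic V-dives (lognormal depth, median 90 m); the deep strategy dives long
and deep (lognormal, median 185 m). Transit rates (1.2–1.65 m/s) come from
the observed envelope. Sub-threshold excursions (< 4 m, or < 16 s) are
planted to exercise the detector. These parameters were calibrated once so
the simulated percentages of long (> 4 min) and deep (> 200 m) dives fall in
the published per-strategy regimes (deep ≈ 51%/46%, mixed ≈ 24%/12.5%) and
are the generator's fixed defaults.

All draws come from per-animal `numpy` generators keyed on
(master seed, animal index) via `SeedSequence`, so cohorts are bit-reproducible
and animals are independent streams.

**What the simulator does not emulate:** oceanographic structure (the
seafloor is a 1-D profile; no bathymetry, currents, or prey fields), diel
patterning of dive behavior (day and night dives share distributions, so
day/night contrasts carry no strategy signal in synthetic data), serum
chemistry beyond Gaussian assay noise, and tag failures or gaps. Passing
synthetic tests therefore demonstrates the correctness and calibration of the
estimation machinery under the stated statistical structure, not robustness
to every artifact of real deployments.

## Problem sizes and numerical choices

The test suite and the reproduction script use deliberately modest problem
sizes chosen as representative: 200 noise-free and 500 noisy synthetic
studies (2000 Monte-Carlo draws each) for the DLW checks, 40 animals at 5 s
sampling with 1–2 day trips for strategy recovery, 1000 replicates × 199
permutations for permutation-calibration checks. Varimax iterates to a 1e-10
relative criterion (communalities preserved to the same tolerance); the
broken-stick fit requires ≥ 20 intervals and at least 3 points per segment;
degenerate inputs (equal masses, empty day/night subsets, single dives,
constant variables) follow the documented conventions rather than erroring
where a convention is defensible.

## Known limitations

- The onshore-rate assumption dominates the at-sea correction; published
  at-sea values are treated as data (see above) and cross-study comparisons
  of at-sea FMR inherit whatever correction produced them.
- The deep stratum of the reference cohort has n = 4; its regression results
  are reported but flagged low-n.
- Benthic labeling is a heuristic reconstruction; its errors concentrate at
  bout boundaries.
- The Mantel test on the packaged tables uses the five-variable PCA scores,
  not the unavailable 14-variable fine-scale scores, so its value is not
  comparable to the published fine-scale result.
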