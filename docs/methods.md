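# Methods

## Observable and geometry

Each fish contributes a daily track of geolocations. The analysis reduces
a position to a single scalar, the great-circle distance to a fixed
reference locus in the Great Australian Bight, `d_GAB` (reference 32°S,
130°E; haversine on a sphere of radius 6371 km). The model's observation
is the signed first difference `d_t = d_GAB(t) − d_GAB(t−1)` in km/day:
positive when moving away from the Bight, negative when returning. Signing
the displacement is what lets one 1-D observable separate outward from
inward movement; the reporting layer prints the inward mean as a
magnitude. Steps with |d_t| above a plausibility cap (default 250 km/day,
far beyond sustained swimming speed) are flagged but not altered.

Tracks are regularized to exactly one position per calendar day before
analysis: interior gaps of up to 5 missing days (configurable) are filled
by spherical linear interpolation on the unit sphere — which handles the
dateline by construction, always taking the shorter arc — and longer gaps
split the track into separately analysed segments. This gap policy is a
package convention; the behavioural conclusions are insensitive to it for
gap-free synthetic data.

## The behavioural hidden Markov model

Three latent states: resident (1), outward migration (2), inward
migration (3). Emissions are state-specific normals N(μ_i, σ_i²) on d_t.
The transition matrix carries structural zeros π₂₃ = π₃₂ = 0: direct
switches between the two migratory states are forbidden and must pass
through residence (a single resident day suffices). Rows sum to one, so
four transition parameters are free. Transition probabilities are
time-homogeneous. For tracks that never record a return (tag recovered or
failed mid-excursion) a nested 2-state model — the upper-left 2×2 block,
resident plus one sign-unconstrained migratory state — avoids asking the
data to identify a state they never visit.

Estimation is pooled Baum–Welch EM across all tracks (one population-level
parameter set; decoding is per track): scaled forward–backward recursions
(numerically safe beyond 10⁴ steps), exact preservation of the structural
zeros (a zero transition has zero expected count, so the multiplicative
update keeps it identically zero), and a variance floor σ ≥ 0.1 km/day
with a hard error if a state's variance collapses below (10⁻³)². Equal-
length tracks are batched so the recursions vectorize across fish.
Initialization maps the pooled (10%, 50%, 90%) displacement quantiles to
(inward, resident, outward) means with the pooled SD and 0.9
self-transitions; 5 restarts with perturbed starting emissions guard
against local maxima and the best final likelihood wins. Convergence:
relative log-likelihood change below 10⁻⁸ or 500 iterations (a warning is
raised, and the best parameters returned, if the cap is hit). Label
switching is resolved after fitting by sorting on the fitted means: most
negative → inward, middle → resident, most positive → outward.

Both Viterbi paths and forward–backward posteriors are produced; Viterbi
is the default basis for occupancy and run-length summaries (posterior-
based occupancy is available as an option, and the two agree closely on
well-separated states).

## Synthetic populations

No public archive of the tag tracks exists, so every stage is exercised
against a simulator that inverts the analysis model. Defaults are the
study conditions: 110 fish, tagged in the GAB between DOY 1 and 60,
tracks of 250–1200 days; emissions (0, 14), (+39.02, 21.58),
(−31.08, 22.65) km/day; a transition matrix constructed in closed form to
have stationary occupancy (0.57, 0.25, 0.18) given a pinned resident
self-transition of 0.95 (each migratory state exchanges flux only with
residence, so the two balance equations plus the proportional outflow
split determine the four free parameters); 84% of excursions headed
westward; 60% of tags censored mid-excursion, producing one-way migrants.

Positions are laid down by placing each day at the current `d_GAB` along
a per-excursion great-circle bearing from the reference (westward ≈ 270°,
eastward ≈ 90°, redrawn at each resident→outward excursion start). The
distance itself follows the state's emission draw exactly (reflected at
zero), so the increments recovered from positions by the geometry module
reproduce the generative draws to machine precision — the simulator's
core correctness invariant. Latitudinal spread comes from an AR(1) jitter
on the bearing (φ = 0.95, innovation SD 1.5°/day) rather than a direct
latitude perturbation, deliberately: perturbing latitude would contaminate
`d_GAB` by tens of km/day and the observable would no longer be the
emission draw. Resident movement is likewise a radial N(0, σ_res) wander
with the same bearing jitter rather than a fully isotropic walk, for the
same reason.

A seasonal forcing (on by default) multiplies the resident→outward and
resident→inward probabilities by von Mises windows with annual mean one
(κ = 3), peaked at DOY 147 (departure season) and DOY 300 (return-leg
initiation), giving populations with autumn departures, returns near the
turn of the year and summer GAB residency. The fitted model remains
time-homogeneous, so this is a deliberate model mis-specification that
mimics how the homogeneous HMM meets seasonal reality. Inference-recovery
experiments use the plain constant-P chain instead
(`simulate_observations`). All randomness flows from one root seed via
`numpy.random.default_rng` spawning; identical configurations are
bit-reproducible.

What the simulator does **not** emulate: geolocation error (positions are
exact), environmentally driven movement, discrete distal foraging
centres (simulated residency is distributed along the migration corridor,
so residency maps of simulated data show one dominant corridor region
rather than distinct loci — region extraction with multiple loci is
exercised on constructed point clouds), ontogenetic drift with age, and
irregular sampling. Passing tests therefore validate the estimators under
the model's own assumptions, not robustness to geolocation error.

## Trips, phenology, residency

**Trips.** In-GAB is `d_GAB < 500 km` strictly (the boundary value counts
as outside; the source rule leaves equality undefined). A departure is
the first day of a maximal out-of-GAB run of ≥ 120 positions; the return
is the first subsequent in-GAB day (first crossing, no persistence
requirement — configurable); an excursion open at track end is kept as a
censored trip. Duration statistics use complete trips only; maximum-
distance statistics include censored trips (their maxima are lower
bounds). Trip direction is the sign of the net longitude change over the
first 30 days out.

**Phenology.** Days of year map to angles θ = 2πDOY/365.25 (Feb 29 → 60).
Densities are von Mises KDEs. The default smoothing concentration is the
ML concentration of the sample itself, computed from the mean resultant
length (the circular analogue of a reference-density bandwidth). This
oversmooths fine multimodal structure on purpose: the quantity reported
is the location of the density peak, and the reference rule gives a far
more stable mode than the L2-optimal plug-in (Taylor's rule, available as
`taylor_kappa`), whose kernels are narrow enough that the argmax wobbles
by ~a week at realistic sample sizes. Peaks are read off a 1-day grid;
exact ties return the smallest DOY with a logged warning; peaks within
half a day of the year boundary are printed as DOY 0. Peak recovery is
validated at sample concentration κ = 8 (circular SD ≈ 21 days, a
February–March departure window); much flatter timing distributions
localize less reliably.

**Residency.** All Viterbi-resident positions (the state of a step is
attributed to the day it ends) are pooled and smoothed with a separable
planar Gaussian KDE on a 0.5° grid, per-axis Silverman bandwidths by
default, grid padded by 4 bandwidths so mass is conserved to < 10⁻³.
Densities are reported per km² using cos-latitude cell areas — adequate
planar treatment for a range north of ~50°S. Regions are 8-connected
components of cells above the 75% density quantile (taken over cells with
non-negligible density), ranked by contained mass; the threshold is a
package convention.

## Population summaries

State occupancy is reported two ways, pooled (step-weighted; the headline)
and median-across-fish with IQR, because either could stand behind a
single published proportion. Run lengths are maximal same-state Viterbi
runs, with end-truncated runs counted as observed. "Time in migration" is
the count of steps decoded outward or inward; its relation to maximum
excursion distance is summarized by a least-squares slope and a smoothing
spline whose penalty is chosen by 5-fold cross-validation over a log-
spaced grid. Westward extent by age advances a fish's age at Jan 1 (the
turn of the austral summer; configurable) and averages each track-year's
minimum longitude within age classes. The outward-vs-inward contrast is
100·(μ_out − |μ_in|)/|μ_in| on fitted emission means — the operational
choice that reproduces the published "25% higher" from the published
means (39.02 vs 31.08 → 25.5%); empirical per-state mean step lengths are
an alternative reading and can be computed from the decodings.

## Problem sizes and tolerances

Recovery experiments use 100 tracks × 500 daily steps (50,000 steps,
roughly the scale of 110 tags over multi-year deployments); the worked
analysis simulates the full 110-fish population. Exactness suites compare
the scaled recursions against brute-force path enumeration at T ≤ 8,
S ≤ 3 to 10⁻¹⁰, and the haversine distance against a spherical
law-of-cosines implementation to < 0.1 km. Conservation checks: posterior
rows and occupancy vectors sum to 1 (10⁻⁹–10⁻¹²), KDE mass 1 ± 10⁻³,
run-length mass equals state step counts exactly, EM likelihood is
monotone to numerical tolerance.
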