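# Methods

## Coordinate conventions

Origin at the environment centre, x east, y north, angles in radians
counter-clockwise from east, distances in cm, times in seconds.  Geometry is
strictly two-dimensional: wall height (50 cm) and platform elevation are
metadata only, since no statistic here uses them quantitatively.

## Environments

Each arena is a closed floor polygon plus a list of boundary segments tagged
`wall` or `drop` (platform rim).  Both kinds are boundaries to a BVC, so ray
casting treats them identically; the tag is kept because drop-elicited and
wall-elicited field repetition are analysed as separate manipulations.
Circular floors are polygonised with 180 chords, which bounds the radial
error of `boundary_distance` at about 0.01 cm — far below the 3 cm map
resolution.  The inserted barrier is a 50 × 3 cm rectangle contributing four
wall segments; its two long faces are the candidate "predicted sides", the
3 cm end faces never are.  The three-platform `apart` configuration is one
connected 170 × 50 cm floor (rats cross the 10 cm gaps unaided) whose twelve
platform edges — including the four interior edges facing the gaps — are
drop elements.  The barrier's exact position is configurable; the default is
the floor centre.

## BVC rate model

The firing rate at a position integrates, over 360 allocentric ray
directions (1° steps, below the angular tuning width), a Gaussian in
(boundary distance − d_pref) times a wrapped Gaussian in direction, with the
radial width growing linearly with preferred distance:
σ_rad = σ₀(d_pref/β + 1).  Defaults σ₀ = 12 cm, β = 180 cm, σ_ang = 0.2 rad
follow the standard BVC parametrisation in the modelling literature.  The
response is normalised so its maximum over the environment equals `a_max`
(default 10 Hz), which makes the 40%-of-peak criterion scale-free.  The
normalising maximum is located on a 3 cm grid; spike generation interpolates
the same grid bilinearly (field scale ≈ σ₀ ≫ grid step, so interpolation
error is well under 1%), while single-position queries are evaluated
exactly.  Boundary-off cells are `baseline · (1 − suppression · BVC/a_max)`
floored at zero; head-direction cells are von-Mises-shaped in heading and
location-independent.

## Trajectory simulator

Heading follows a Gaussian-increment random walk (2.2 rad/√s) and speed an
Ornstein–Uhlenbeck process (mean 25 cm/s, relaxation 1.5 s, floored at
zero), sampled at 50 Hz.  At a boundary the heading reflects about the local
boundary normal with added noise.  The path is confined to the floor eroded
by a 5 cm wall clearance — the tracked head position of a foraging rat does
not reach the wall — which is what makes the visited-bin geometry come out
right: an 18.5 cm grid with a bin corner at the centre has exactly 60 bins
reachable inside the 70 cm eroded disk, and 27-minute simulated trials visit
essentially all of them (matching the ~60 visited bins that motivate the
bin-matched correction).  Around an inserted barrier a smaller clearance
(2 cm) applies: the head closely approaches and overhangs the thin barrier,
and without this no bin adjacent to the barrier face would ever be visited.
Head direction is the movement heading plus 0.2 rad of jitter — adequate for
cells tuned to heading at the ~0.35 rad tuning-width scale, but note the
simulator does not model independent head scanning.

Default trial duration is 1620 s (27 min), consistent with analysing trials
in three 9-minute segments; durations are configurable everywhere.

What the simulator does *not* emulate: thigmotaxis (real rats oversample the
perimeter), pauses and grooming bouts, systematic heading–position coupling
beyond what boundary reflection induces, tracking dropouts, and
overdispersed (non-Poisson) spiking.  Tests passing on these trajectories
therefore demonstrate correctness of the analysis chain under its stated
assumptions, not robustness to every artefact of real tracking data.

## Rate maps

3 cm square bins; the grid always places a bin corner at the environment
centre, giving a symmetric, deterministic layout.  Spikes are assigned to
the temporally nearest tracked sample (≤ 10 ms error at 50 Hz).  Smoothing
is a 5 × 5 boxcar applied to counts and dwell *separately* over visited bins
before dividing; at the map border the kernel thus renormalises over visited
bins, avoiding rate dilution exactly where boundary fields live.  Smoothing
the rate directly is available behind a flag (`smooth_mode="rate"`), since
published descriptions are ambiguous between the two; counts/dwell smoothing
is the default because it is stable at low occupancy.  Polar maps use 60
bins of 6° with a circular 5-bin boxcar.  Samples faster than 200 cm/s
(centred differences) are discarded as tracking artefacts before mapping.

## Field-repetition criterion

Eligibility reflects the experimental sampling procedure ("first identify a
cell firing at or near the perimeter"): the baseline field peak must lie in
the outer portion (≥ 0.75 R, boundary inclusive) for circular floors or
within two bin widths of a wall otherwise, **and** the baseline map must be
locationally selective (peak ≥ 3 × mean rate).  The selectivity screen is
this package's own addition: a head-direction cell's locational map is
nearly uniform, so its smoothed peak lands anywhere — including the outer
portion — and a near-uniform map trivially passes a 40%-of-peak coverage
test, which would make uniform cells false positives about half the time.
Measured on 27-minute simulated trials, HD locational selectivity is
1.7–2.2 (inflated above 1 by genuine heading–position covariance near
walls), while simulated BVCs span 4.9–11.2 and real boundary-cell samples
report ≈ 5.5; the threshold 3 sits between the populations and is
configurable.

The preferred direction is estimated from the rate-weighted centroid of bins
at ≥ 50% of peak, pointing toward the nearest perimeter point.  The single
peak bin is deliberately not used: an arc-shaped field hugging a curved wall
has a nearly flat ridge, so the peak bin slides along the arc and can
misstate the direction by ~50°, whereas the centroid recovers it to within a
few degrees.  The predicted barrier side is the face whose outward normal
opposes the preferred direction.

Abutting bins are the visited bins within one bin-width outward of the
predicted 50 cm face (restricted to the barrier's extent, bin-count
convention at the ends).  Strict touching is not required because tracked
positions keep a small clearance from the barrier, so the strictly-touching
bin row can be unvisited.  Coverage is the percentage of abutting bins at
≥ 40% of the locational peak of the (smoothed) barrier-trial map; ≥ 50%
classifies the cell as a BVC.  The boundary-off inverse criterion flags a
cell when ≥ 50% of abutting bins sit at ≤ 40% of the barrier map's median
visited-bin rate — the low-firing threshold is this package's
operationalisation of a qualitative description ("a clear zone of markedly
lower firing") and is configurable.

## Information, selectivity and the bin-matched correction

Skaggs information rate I = Σᵢ pᵢ λᵢ log₂(λᵢ/λ̄) (bits/s) with the
0·log 0 = 0 convention; selectivity is peak/global-mean rate.  Because
information depends strongly on bin number, the locational/directional
comparison uses unsmoothed maps with matched bin counts: 18.5 cm locational
bins in the 150 cm circle and 14 cm in the 100 cm square (~60 visited bins
versus exactly 60 directional bins), or an automatic search for the size
whose visited count is nearest 60 in other floors.  Distributive-hypothesis
style predicted-tuning corrections are out of scope; only bin matching and
unsmoothed maps are applied.

## Monte Carlo field-peak null

Each replicate draws n points uniformly in a disk of radius R by inverse-CDF
radius sampling (r = R√u, exact and rejection-free) and records the mean
distance to the centre; 10⁶ replicates by default.  The percentile of an
observed value uses strict inequality (ties are measure-zero).  The
`converged` flag compares mean/median/95th percentile between the first half
and the full sample at 10⁻ᵗᵒˡ; note that at 10⁶ replicates the Monte Carlo
standard error of the null mean (σ/√N ≈ 0.005 for n = 15, R = 81) sits
exactly at the half-ulp boundary of two-decimal agreement, so the flag is
intrinsically marginal there — the null statistics themselves are stable to
±0.01.

## Theta modulation

Spikes are restricted to runs (speed > 5 cm/s sustained ≥ 0.5 s; the
restriction applies to spikes only).  The 500 ms autocorrelogram uses 4 ms
bins — chosen so the spectrum spans exactly 0–125 Hz — excluding the
zero-lag bin.  The mean-subtracted histogram is zero-padded to ≥ 2 s
(frequency resolution ≤ 0.5 Hz) and transformed; no taper is applied by
default (configurable).  The theta peak is the spectral maximum within
6–12 Hz, per cell; the score is the mean power in the 2 Hz band centred
there divided by the mean power over 0–125 Hz.  On simulated trains the
score rises from ≈ 1 (unmodulated) to ≈ 35–40 at modulation depth 0.8.

## Problem sizes used in the test and acceptance suites

Population-level checks use 20 BVCs and 20 HD cells (plus 5 boundary-off
cells), each with 27-minute baseline and barrier trials, and 10 independent
trajectories for the visited-bin statistic; the Monte Carlo null always runs
its full 10⁶ replicates.  Unit tests use shorter trials (20 s–10 min) chosen
so each property is measured well above its sampling noise.

## Known limitations

Single-cell analyses only (no population decoding or remapping analyses);
no spike sorting, waveforms or LFP; the simulator's foraging statistics are
idealised as noted above; the boundary-off low-firing threshold and the
eligibility selectivity screen are package-defined conventions rather than
published constants, and both are exposed as parameters.
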