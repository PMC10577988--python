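# Methods

`shoalmetrics` quantifies the behavioral and metabolic phenotypes used to
compare surface and cave populations of *Astyanax mexicanus* under dietary
manipulation: social affinity from group trajectories, repetitive turning,
swimming distance, sleep, vibration-attraction foraging, and the
glucose–ketone balance. This note describes the models and procedures, the
parameters that matter, and the choices made where the design was open.

## Coordinate and time conventions

All trajectories are stored in cm with the origin at the arena's lower-left
corner, 0-based frame indices and half-open frame windows `[start, end)`.
Tracker output arrives as long-format (`frame, fish_id, x, y`) or
wide-format (`frame, x1, y1, …`) tables; pixel coordinates are divided by
`px_per_cm`. Tracking dropouts are kept as explicit NaN gaps. The default
gap policy is *no interpolation* (`max_gap_frames = 0`): every downstream
metric treats a missing frame as a run-breaker rather than inventing
positions. `fill_gaps` offers linear interpolation across short interior
gaps when a user explicitly opts in; each gap is reported either way. The
group assay records 6 min at 20 frames/s and analyzes the trailing 5 min
(`assay_window(traj, 60, 300)`).

## Nearby-interaction detection

A *nearby interaction* between two fish is a maximal run of consecutive
frames with pairwise Euclidean distance ≤ 5 cm whose length is at least
4 s. The duration criterion is inclusive (a run of exactly 4.0 s counts);
`InteractionCriteria(inclusive=False)` gives the strict reading, and the
boundary behavior is unit-tested at 79 vs 80 frames at 20 fps. Four fish
yield six unordered pairs; group-level affinity is the sum over pairs of
event durations and counts. A fish may therefore contribute through
several pairs simultaneously — the sum matches the additivity of the
per-pair event raster.

Per-frame speed is the 1-frame displacement times fps, unsmoothed. The
peri-event speed profile partitions each fish's frames exclusively into
*during* (inside any of its events), *before*/*after* (within a 4-s window
of an event edge, a contested frame going to the nearer event) and
*out-of-event* (everything else). Fish with no events report NaN for the
peri-event means.

## Permutation null and criterion calibration

Observed group scores are compared against a chance-encounter null:

* **cross_group** (default): each replicate assembles a virtual group by
  drawing one member trajectory from each of `n_fish` distinct recorded
  groups, so all proximity between members is coincidental. This requires
  at least `n_fish` groups; it is the standard chance null for shoaling
  assays.
* **time_shift**: each fish's series is circularly shifted by an
  independent random offset of at least `min_duration × fps` frames,
  preserving each path's marginal statistics exactly while destroying
  synchrony. Works on a single group.

Each replicate is scored with the same detector and criteria as the
observed data. The empirical p-value uses the add-one estimator
`p = (1 + #{null ≥ observed}) / (n + 1)`, which cannot return zero and is
valid under exchangeability. `calibrate_min_duration` reconstructs the
criterion-calibration step: it tabulates the null distribution of chance
proximity-run durations and returns the smallest grid duration whose
expected per-group chance-event count falls below the tolerance
(default 0.05); if none qualifies the largest grid value is returned
flagged. Both null constructions are labeled in output because the
upstream protocol does not pin the permutation scheme down.

Calibration of the test itself is verified by simulation: for mutually
independent simulated groups, the rejection rate at α = 0.05 over 400–500
groups (12 donor groups, 99 permutations each) lies inside the binomial
95% band. Replicates built from a shared donor pool are mildly dependent,
which is why the check uses a dozen donors rather than the minimum four.

## Turning bias

Headings are computed from the net displacement of consecutive
non-overlapping 5-frame blocks (0.25 s at 20 fps); the signed wrapped
angle between consecutive block headings is one turn, positive = left
(anticlockwise). Blocks moving less than `min_step` (default 0.1 cm, a
jitter floor the upstream protocol does not specify) or containing a gap
are skipped, and turns are only counted between consecutive valid blocks.
The bias ratio is `max(N_L, N_R) / min(N_L, N_R)` in [1, ∞]; with both
counts zero the ratio is 1, and the regularized form
`(N_larger + 1)/(N_smaller + 1)` is reported alongside for Gamma-family
model fits, which need finite values. Whether the original analysis used
tiling or sliding windows is unstated; tiling is the default and
`sliding=True` is available. Mirror reflection swaps the counts exactly
and rotations leave them unchanged; both are property-tested.

## Sleep and vibration attraction

Sleep is scored behaviorally on 24-h single-fish tracks at 15 frames/s: a
bout is a maximal run with speed below 0.5 cm/s lasting at least 60 s.
These two thresholds follow the *A. mexicanus* sleep-assay literature (the
source protocol delegates them to earlier work); both are prominent,
configurable parameters. Day is ZT0–12, night ZT12–24 under the 12:12
cycle, anchored by an explicit lights-on frame index. A run qualifies by
its total length first and is then split at light transitions, so a
night-long rest is one bout per night. Summaries report sleep min/h, bout
count/h and mean bout minutes per phase plus a 10-min binned series.

Vibration attraction (VAB) counts outside→inside transitions of the
tracked point through a circle around the vibrating rod during a 3-min
assay; starting inside does not count until the fish leaves and
re-enters. The printed approach radius of 1.3 is supported in mm and cm;
the default unit is cm because a 1.3-mm capture zone is smaller than a
fish's snout and is likely a typographical slip — the choice is logged in
the result object.

## Glucose–ketone index and diet arithmetic

GKI = glucose (mM) / ketone (mM); values below 9 classify ketosis by the
human criterion. Meter glucose in mg/dL is converted with divisor 18.016
(glucose molar mass / 10); 18.0, the common rounded convention, is
configurable because the original meters' convention is unknown. GKI is
invariant under joint scaling of both analytes.

Diet mixing is exact ratio-weighted averaging of nutrient percentages and
kcal/g; rounding happens only at presentation, half-up to one decimal
(banker's rounding would flip boundary cases such as 47.55 → 47.5). The
bundled components are the brine-shrimp, zebrafish-standard and
3:1-ketogenic-formula labels; the ketogenic feed is the 5:1
formula:zebrafish blend and the control feed the 1:5 blend. Dose
conversion assumes an agar feed density of 1 mg ≈ 1 µL and a meal of 3%
of body weight; molar↔mass conversion always takes the molar mass as
explicit input (the published BHB equivalence of 10 mg ↔ 78.7 µmol per
body gram implies ≈127.1 g/mol, slightly off sodium DL-BHB's 126.09, so
no conversion constant is hard-coded).

## Synthetic trajectory generator

The generator produces group assays with the statistical structure the
pipeline assumes, so every stage is testable without archived video.

Each fish is a correlated random walk: per-frame heading increments are a
deterministic lateral-turn term plus von Mises noise with concentration
κ = 50 per frame at 20 fps (directional persistence on the order of a
second, typical of cruising fish), and speed is drawn around
`mean_speed = 4 cm/s` (σ = 1), realistic for 2.5–5 cm fish. Walls reflect
specularly and re-randomize the heading inward to avoid corner trapping.

Social affinity is a dyadic, exclusive, encounter-triggered state: while
no bout runs, one starts at rate `social_on_rate` (default 0.05 s⁻¹) for
a pair currently within `social_onset_radius_cm` (default 5 cm), and ends
at rate `social_off_rate` (default 0.05 s⁻¹). The single gain parameter
`attraction ∈ [0, 1]` scales the whole behavioral effect of the state:

* the follower (chosen uniformly at onset) closes a fraction of its
  heading error proportional to the gain (up to ~0.2 per frame at 20 fps);
* both members slow by `1 − attraction × (1 − social_speed_factor)`, so
  at full gain speed drops to `social_speed_factor` (default 0.7, the
  moderate slow-down seen during nearby interactions) and at zero gain
  the state is behaviorally inert, making attraction 0 with default
  switching exactly equivalent to independent walkers in distribution of
  any proximity statistic;
* engagement persists longer at higher gain (expected bout length scales
  from 1/off_rate to 3/off_rate), reflecting that affinity lengthens
  interactions — which is precisely the phenotype the assay measures.

This makes detected interaction duration strictly increasing across the
attraction grid {0, 0.3, 0.6, 0.9} under the default assay conditions.

The during/out-of-event speed ratio estimates the slow-down factor with a
small upward bias, because detected events are not exactly the generated
social bouts: chance proximity between non-social pairs and post-bout
lingering contribute full-speed frames to *during*. The recovery check
therefore runs in the regime where events and bouts coincide (full gain,
frequent long bouts, straighter and faster baseline paths, κ = 100,
6 cm/s), where the residual contamination is a few percent of event time
and the estimate lands within 10% of the true factor. Under the default
assay conditions the same estimator overshoots by roughly 10–20%; that
bias is a property of event-based epoching, not of the detector.

Turning bias enters as a per-5-frame-block turn of magnitude 0.35 rad
whose sign is left with probability `left_bias`. Because the measured
turn between blocks k and k+1 mixes both blocks' signs, the recovered
left fraction is still exactly `left_bias` in expectation (p² + pq = p).
Turn-recovery checks use a wall-free arena and tight noise (κ = 300)
because wall contacts re-randomize the heading and would dilute the
binomial signal with boundary artifacts.

The 24-h sleep mode alternates exponential active/quiescent dwells (or
accepts an explicit bout schedule for exact-recovery tests); quiescent
fish jitter around a rest point with σ = 0.002 cm (≈0.02 mm, the wobble
of a resting fish's tracked point), keeping even tail jitter steps an
order of magnitude below the immobility threshold. Detected bout
boundaries match the schedule within one frame — the residual frame comes
from speed being a between-frame quantity.

What the generator does **not** emulate: hydrodynamics, lateral-line or
visual sensing, wall-following (thigmotaxis), burst-and-glide gaits, and
identity-swap tracking errors. Passing tests therefore demonstrate that
the pipeline measures what it claims on data obeying its stated
assumptions, not that those assumptions hold in any particular video.

## Statistics layer

Model fitting is delegated to statsmodels — it is routine inference, not
this package's contribution: Gaussian OLS for continuous scores, Poisson
GLM for counts (responses on a 0.1 grid are multiplied by 10 first, the
published adjustment for meter ketone readings), Gamma GLM (log link) for
positive ratio indices, and a random-intercept mixed model for repeated
weekly recordings of the same groups (weeks treated as categorical). The
factor columns are crossed into cells; all pairwise cell contrasts are
Wald-tested and corrected with a natively implemented Holm step-down
(cross-checked against an independent reference implementation), with
stars at 0.05/0.01/0.001. The exact contrast coding and random-effects
structure of the original R analysis are not published; the defaults here
are recorded in the pipeline manifest.

## Problem sizes and tolerances

Simulation-based checks use sizes chosen to keep sampling error a small
fraction of the tested effect: 1,000 short trajectories for
detector–oracle equivalence (exact agreement required); 400–500
independent groups × 99 permutations for type-I calibration (binomial
95% band); 20 replicates per attraction level for monotonicity; 10
replicates for slow-down recovery (10% tolerance); ~10,000 turn windows
for the binomial turning ratio (10% tolerance, binomial SE ≈ 2%);
exponential-dwell sleep checks compare against the memoryless conditional
mean `min_bout + 1/rate`. All simulations derive from a single seeded
generator and are bit-for-bit reproducible.
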