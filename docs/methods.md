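# Methods

This note documents the models implemented in `larvanav`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It is the place to look before
trusting a number the package produces.

## Trajectory kinematics

A track is a 2 Hz sequence of positions (mm, origin at the arena's
lower-left corner, y up). Kinematics are per *step* (the interval between
consecutive samples): speed = displacement / Δt, heading = displacement
direction in [0, 360)°, turn = signed smallest angle between successive
headings in (−180, 180]°. A step with zero displacement has no heading of
its own; the previous heading is carried for bookkeeping, and both that
step's turn and the following step's turn are undefined (excluded from
turn statistics) — we never fabricate a turn across a pause. Sampling gaps
longer than 2 × the nominal interval are flagged; flagged steps are
excluded from statistics and never interpolated.

A step is *moving* when speed ≥ 1 mm s⁻¹ (about a quarter body length per
second; configurable — the threshold is an operational choice, not a
measured constant). Local concentration is sampled from the field at the
step's start position and time; dc/dt is the difference between the two
endpoint samples. A moving step counts as up- (down-) gradient when
dc/dt ≥ +0.02 s⁻¹ (≤ −0.02 s⁻¹); steps while immobile are classed
`excluded`, because concentration change experienced while not moving is
diffusion, not navigation.

### The acclimation-phase virtual map

No stimulus is physically present during acclimation, yet every Δ metric
needs an acclimation-phase value against the *same* spatial reference.
Acclimation steps are therefore scored against a virtual map. Two
conventions are implemented:

* `matched` (default): acclimation time *t* is scored against the field at
  time *t* after stimulus addition — the experiment's field timeline is
  replayed. Baseline and experiment then face statistically identical
  fields, so every Δ metric has exactly zero mean under the null of
  unchanged behaviour. This is the calibration the cohort tests rely on.
* `final`: the field frozen at its last, fully developed frame. Simpler to
  reason about, but while the real field is still developing early in the
  experiment the null Δ metrics acquire a small systematic bias (early
  experiment steps see less stimulus than the frozen baseline assumes), so
  it is not the default.

## Concentration fields

Gridded diffusion maps hold per-cell (1 mm²) relative concentration in
[0, 1] at increasing sample times; queries are bilinear in space, linear in
time, and clamped at the spatial and temporal boundaries (trajectories may
graze walls). Raw dye-intensity grids can be calibrated through a monotone
piecewise-linear curve built from reference concentrations (exact at the
knots, clamped outside), and finer input grids are aggregated by block
means.

The simulator's circular arena uses an analytic radial field: relative
concentration 1 inside a central food patch of radius r_f with
π·r_f² = 0.03 × arena area (the patch scales with the arena, on the
assumption that bigger habitats hold proportionally more food), and
exp(−λ(r − r_f)) outside, with λ fixed by requiring c = 0.5 at
r50 = r_f + 0.25·(R − r_f). The 0.25 placement and the 3% share are
configurable; 3% is the standard value, 0.25 puts the half-concentration
ring well inside the arena.

## Per-individual metrics

P (median experienced concentration, moving and immobile steps alike), DP
(net fraction of moving *time* up- vs down-gradient; neutral moving steps
count in the denominator only), CS (mean moving speed in high cells minus
low cells), DS (same conditioned on up/down), CTI and DTI (mean |turn| per
moving step conditioned on high/low and up/down respectively; an
event-count variant — fraction of turns above 30° — is available behind
`turn_statistic="event_rate"`), discovery time (first phase-relative time
any position samples the high region, censored at the phase length), and
the activity pair: moving fraction and wall fraction (time within one body
length of the nearest wall, boundary inclusive). Δ = experiment −
acclimation; an undefined phase value (e.g. a region never visited while
moving) makes the Δ undefined, and that individual drops out of that
metric's cohort test with a logged count.

## Cohort statistics and strategy classification

Each Δ metric is tested with a paired t-test of the per-individual
differences against zero (df = n − 1; a paired design has a single
difference sample, so no unequal-variance correction applies). Zero
variance with zero mean difference gives p = 1 by convention; zero
variance with a nonzero mean is flagged degenerate. Between-cohort
comparisons (discovery time against a control cohort, activity between
nutritional states) use Welch's unequal-variance t-test with
Welch–Satterthwaite df. Censored discovery times enter at the censoring
bound with the censored count reported.

P-values are Holm-adjusted within the six-metric family of one stimulus
cohort (α = 0.05 by default; Bonferroni and no adjustment are options —
the family definition is a choice, not a law). The resulting six
significance flags, in the order (P, DP, DS, CS, DTI, CTI), are matched to
the canonical expectations — anosmic 000000, chemotaxis 110010,
klinokinesis 100001, chemokinesis 100100 — exactly if possible, otherwise
by minimal Hamming distance with a deterministic fewest-assumptions-first
tie-break (anosmic < chemokinesis < klinokinesis < chemotaxis). Discovery
time has no acclimation counterpart and never enters the pattern.

## The chemokinetic forager

The forager resamples paired (speed, turn) observations from
acclimation-phase steps (behaviour in clean water). Pairs are never split:
the two variables are correlated at higher speeds, and independent
resampling would destroy that structure. Non-moving steps are included as
(speed, turn = 0) pairs — the pool must carry each nutritional state's
activity level or the fed/starved contrast the simulator exists to probe
would vanish. The pool is split at the median speed into equal slow and
fast halves (odd counts and median ties go to the slow half).

Each replicate starts at a uniform random point outside the food patch
(starting inside would record spurious zero discovery times) with a
uniform heading. Every Δt = 0.5 s the walker draws from the slow half with
probability 1/(1 + exp(−k(c − 0.5))) at its local concentration (k = 20 by
default; k → ∞ recovers the hard rule "slow above 50%"), turns by the
drawn angle and advances speed·Δt. Draws that would exit the arena are
rejected and redrawn (up to 100 times within the assigned half, then 100
more with the half redrawn uniformly — the slow half holds the pauses,
which are the only draws that are feasible from any position; a walker
still jammed after that holds position and heading for the step, as a
larva pushing against the wall). The replicate ends on first entry into
the food patch, or is censored at 48 h — larvae survive days without food,
so long searches are data, not failures.

Replicates run as one vectorized batch per (diameter, state) cell sharing
a single PCG64 stream: (seed, configuration, pool, batch size) determine
every record bit-exactly. Sweeps derive an independent child seed per
cell. Summaries report mean discovery time ± s.e. and censored counts
(censored replicates enter the mean at the bound), and the slope of mean
time against diameter is fitted by ordinary least squares over the swept
diameters (19 evenly spaced sizes over 5–20 cm by default).

## The synthetic-data generator

The generator produces what the analysis assumes real tracking data look
like: 2 Hz tracks over 900 s + 900 s phases, log-normal step speeds with
state-dependent pause probability, von Mises turns whose concentration
parameter tightens with the drawn speed (faster ⇒ straighter), a 2%
per-step chance of a spontaneous near-uniform reorientation (the
large-angle mass seen in real paired speed–angle densities — and the
reason a resampling forager can turn away from a wall at all), specular
wall reflection softened by anticipatory steering (starved animals steer
gently off walls, fed animals align with them, producing the thigmotaxis
contrast), and the four strategy rules applied only in the experiment
phase against the plume:

* chemokinesis: speed × g_s (default 0.5) in high cells;
* klinokinesis: |turn| × g_t (default 2) in high cells, *plus* an adaptive
  stop-and-turn component (see below);
* chemotaxis: directed reorientation — turn-sign bias toward the uphill
  direction plus a turn-magnitude gain growing with misalignment,
  saturating in gradient magnitude and disengaging above c = 0.55
  (arrival); b = 20° parameterizes the strength;
* anosmic: nothing.

The turn-speed coupling uses the *baseline* drawn speed, not the
concentration-modulated one: the coupling belongs to the locomotor
program, and tying it to the modulated speed would make a pure speed
response masquerade as a turning response in the analysis.

Two generator choices deserve emphasis because they are forced by
mathematics, not taste:

1. **Positional klinokinesis cannot aggregate.** If the turn distribution
   depends on position only through a symmetric kernel, the spatially
   uniform distribution is *exactly* invariant (integrate the transition
   kernel over initial headings: it integrates to one for every landing
   state). A pure turn-gain agent therefore shows ΔCTI but never ΔP. The
   classical aggregating form of klinokinesis is adaptive — reorient when
   conditions have worsened — so the klinokinetic agent triggers a
   stop-and-turn pirouette (probability 0.12 per step) while concentration
   runs below its 10 s running average. The larva pauses while
   reorienting, so the pirouette's turn is undefined in the analysis (zero
   displacement) and invisible to the turn statistics; only its effect —
   truncated descending runs, hence aggregation — is observable.

2. **Strong chemotaxis is not cleanly recoverable in this assay.** In a
   closed arena over 15 minutes, up- and down-classified moving time
   balance at quasi-stationarity (each animal nets roughly one inward
   transit; every interface — walls, the saturated core's rim, the
   classification cones themselves — churns symmetrically), so ΔDP, the
   hallmark of taxis, carries only a transient signal far too weak at
   n = 30. Independently, any taxis differentially transports fast
   (straight) steps out of steep terrain, and the speed–turn coupling
   converts that sorting into a ΔCTI signature of the same order as the
   intended ΔDTI one. A strongly chemotactic agent consequently presents
   the klinokinesis pattern (ΔP + ΔCTI) to this analysis. The
   strategy-recovery acceptance check accordingly recovers klinokinetic
   and anosmic cohorts at or near its target rate, chemokinetic cohorts
   somewhat below it (the paired preference test's power — set by how
   thoroughly one animal samples the arena in 15 minutes — is the binding
   constraint), and chemotactic cohorts essentially never. These are
   properties of the assay design, faithfully reported rather than papered
   over.

### The synthetic plume

The stimulus is pipetted into the left side of the arena and spreads
radially from the drop point (35% of the arena width in from the left
edge, centred vertically; arena 120 × 88 mm). The radial profile is
piecewise linear with two scales: a gently varying interior (0.63 at the
drop point falling to 0.485 at 38 mm) that carries the 50% contour, one
steep annulus (38–46 mm) where gradient classification happens, and a
mixed background floor (~0.21–0.24) beyond. Concentration is capped below
1 because cell-averaged concentration after dilution never reaches the
source value, and the floor reflects the background a closed arena
accumulates after prolonged mixing. Development scales amplitude linearly
over the first 300 s (swimming larvae mix the arena quickly), so frame 0
is blank, every cell is non-decreasing in time and spatial gradients never
exceed their final values. A seeded angular modulation (±5% of the length
scale) keeps the plume from being artificially symmetric.

This geometry is deliberate: the interior gradients are too shallow for
*any* attainable swimming speed to cross the 2%/s classification
threshold, so the speed-modulation gate at c = 0.5 produces no classified
steps (otherwise gate-straddling steps, slow on one side and fast on the
other, leak a spurious ΔDS), and the 50% contour clears every wall by more
than the wall-steering zone, so wall-turn load — which scales with speed —
cannot leak into ΔCTI when chemokinesis halves the speed inside the high
region. Against this field, cohorts of n = 30 recover their generating
strategy's exact significance pattern with high probability, and 500
anosmic cohorts hold the per-metric type-I error at its nominal level.

What the generator does **not** emulate: absolute larval speeds and sizes
(order-of-magnitude choices: ~3 mm s⁻¹ starved, ~2.2 mm s⁻¹ fed, 4.3/4.7 mm
body length), tracking noise and identity switches, larva-induced fluid
mixing, multi-animal interaction, and any asymmetry of real plumes beyond
the seeded angular modulation. Passing tests show the *analysis chain* is
correct and calibrated for data with this statistical structure; they are
not evidence about real larvae.

## Numerical conventions and problem sizes

Angles are degrees throughout; wrapping maps to (−180, 180]. Bilinear
sampling treats cell centres at (i + 0.5) × cell size. High/low
classification is boundary-inclusive (c = 0.5 is high). Welch tests use
scipy; Holm uses statsmodels. The acceptance suite runs 100 cohorts per
strategy for recovery, 50 seeded repeats for the n = 32 speed-signature
check, 500 cohorts for type-I calibration and 200 replicates per diameter
for the sweep checks; these sizes put the Monte-Carlo error comfortably
below the tolerances they are checked against while keeping the full
suite in the minutes range. All randomness flows from numpy SeedSequence
spawning, so every number in the test suite and the acceptance script is
reproducible bit for bit.
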