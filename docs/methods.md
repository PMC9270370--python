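# Methods

`eventscope` pairs an event-based microscope-control engine with a virtual
budding-yeast microscope, so that closed-loop acquisition logic — adaptive
framerates, valve-synchronized perturbations, stage feedback, conditional
"zoom" episodes — can be developed and verified against known ground truth
before ever touching hardware. This note documents the models, their
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## The virtual sample

The sample is an agent-based monolayer of budding yeast in a rectangular
microfluidic chamber (coordinates in µm, time in s). Each cell is a disk
with a body radius, an optional bud (a second disk attached at a random
angle, overlapping the mother by 30% of the bud radius), reporter levels,
and a photodose ledger. One seeded `numpy` generator owned by the state
drives every stochastic choice (placement, bud angles, G1 jitter), so a
seed plus a call sequence reproduces a trajectory bit for bit.

**Growth and division.** Cell area grows exponentially with a 90 min
doubling time in glucose (`doubling_time_s = 5400`), standard log-phase
yeast physiology at 30 °C. An unbudded cell initiates a bud once its age in
the current cycle exceeds a jittered G1 duration (30 min ± 20%). While
budded, all growth is routed into the bud; division fires when the bud
reaches `f_div = 0.6`× the mother body area, appending a lineage record and
converting the bud into a daughter placed exactly where the bud was
rendered (positional continuity keeps frame-to-frame displacements smooth,
which matters to the tracking loop). Unbudded growth saturates at a radius
cap of 2.4 µm; without a cap, age-gated budding plus a relative division
threshold lets mother size grow without bound across cycles, and the cap
gives the realistic pattern of mothers converging to a common size while
newborn daughters start at ~60% of it.

**Nuclear separation.** Mitotic nuclear separation is rendered over the
final 10 min of the budded phase: the onset is the instant the bud crosses
the area at which, growing at the glucose rate, it will reach the division
threshold 600 s later (`sep_bud_frac = (1+f_div)·e^{−g·600} − 1 ≈ 0.48`
of the mother area). From the onset, the RFP channel draws a second nucleus
inside the bud. The onset timestamp is part of each lineage record and is
the ground-truth event the mitosis-prediction rule is scored against.
Because both the onset and division are *area* thresholds, their order is
preserved even when photodose slows growth; only the time intervals
stretch.

**Crowding mechanics.** Overlaps are resolved by iterated pairwise
projection: each overlapping pair is displaced apart along its centre line
by half the overlap, positions are clamped to the chamber walls, and the
loop stops when the largest overlap is below ε = 0.05 µm or after
`relax_iters` iterations (default 10; dense dead-end-chamber scenes use
25). A chamber may declare one open side; with three walls closed, growth
pressure produces net directed motion toward the opening — the displacement
field the detect-and-track scenario exercises. The collision footprint of a
budded cell is the circle of its total (body + bud) area. In densely packed
columns the projection scheme can retain residual overlaps of a few tenths
of a µm; this is visible only as slight mask erosion and does not affect
net transport.

**Medium switching and the sucrose lag.** The perfused medium is one of
glucose, sucrose, or sorbitol stress. Switching glucose→sucrose empties a
shared extracellular hexose pool; growth is zero until the pool, refilled
at `k_suc · N` (k_suc = 10⁻³ a.u./cell/s — secreted invertase activity
scales with the population), reaches `h_min`. The lag before growth
resumes is therefore `h_min / (k_suc · N)`: inversely proportional to the
cell count at the switch. `h_min` defaults to 36 a.u., which at desk-scale
counts (20–100 cells) spreads the lags (1800/720/360 s) across several
3-min acquisition frames so the density ordering is resolvable at the
acquisition cadence. Growth in sucrose after recovery runs at 0.9× the
glucose rate; sorbitol stress at 0.5×.

**Hog1 nuclear import.** Under sorbitol stress the nuclear fraction of
Hog1 follows the import/adaptation closed form
`base + A·(1 − e^{−t/τ_in})·e^{−t/τ_adapt}` with τ_in = 40 s,
τ_adapt = 600 s, base 0.25, A 0.45. Its analytic peak,
`t* = τ_in·ln(1 + τ_adapt/τ_in) ≈ 110.9 s`, falls in the physiological 1–2
min window. On stress release the fraction relaxes back to base with a 60 s
time constant. The simulator applies the closed form directly (no ODE
error), so rendered-image localization scores can be compared against it
exactly.

**Optogenetic reporter.** Venus expression follows Hill production with
first-order decay: `dv/dt = V_max·I^n/(K^n + I^n) − δ·v` (K = 10% LED,
n = 2, δ = 1/1800 s⁻¹), integrated exactly per sub-step via the linear
closed form. Steady state is strictly increasing in intensity and zero in
the dark. The blue stimulation channel sets a chamber's persistent light
dose; it contributes no photodose (stimulation intensities sit far below
excitation doses).

**Phototoxicity.** Every fluorescence exposure adds
`exposure_ms × LED %` dose units to each in-view cell. Growth is scaled by
a factor of the trailing 10-min dose *rate*: 1 below `d_safe = 60 /s`
(calibrated so one 150 ms/100% exposure per 5 min is harmless), falling
linearly to 0 at `d_arrest = 600 /s` (the rate of one such exposure every
25 s, which arrests growth within the window). Brightfield is free.

## The virtual devices

The camera renders 16-bit frames at 0.25 µm/px (default 512², most studies
use 128–256² fields). Brightfield shows each cell as a dark boundary ring
(45% darkening, 0.75 µm wide) with a subtly shaded interior (7%) on a
bright background — the two features a wall-based segmenter keys on.
Fluorescence draws the reporters (nuclear RFP for tagged cells, Hog1-split
GFP between a nucleus of 0.35× the cell radius and cytoplasm, uniform
Venus), scaled linearly by exposure × LED intensity, then applies Gaussian
PSF blur (σ = 1 px, inflated by defocus as `σ·(1+|z|/1 µm)`), Poisson shot
noise and Gaussian read noise from a seeded generator. Ground-truth label
masks are rendered from the same geometry; contested pixels of overlapping
footprints go to the cell whose boundary reaches deepest, and buds can be
labelled separately (as a segmenter would see them) or merged into their
mothers (whole-cell counting).

Stage moves are instantaneous with the convention that +x stage motion
shifts image content by −x px. Valves are idempotent (re-asserting a state
is not logged) and act on the sample at the next clock advance. Autofocus
is a deterministic coarse-to-fine z-scan (11 points over ±3 µm, then 13
fine points) maximising the variance of a high-pass-filtered brightfield
render; the metric is computed at half resolution since it only ranks z
planes, and the simulator's unimodal defocus blur guarantees ≤0.2 µm
residual.

## Segmentation

The default backend is classical and keyed to the wall-ring appearance:
smooth, threshold pixels darker than 88% of the median background, make the
thin ring band watertight (dilate–fill–erode), and label the enclosed
interiors. Because every wall is a double ring, the interiors of touching
cells are disconnected and seed a distance-transform watershed. Marker
validation removes the pockets of enclosed background that rings of
neighbouring cells can form: a valid marker is disk-like (area ≤ 1.65·π·
inradius², inradius ≥ 2.8 px) and darkened (mean below 95.5% of
background); markers closer than 8 px are merged (a neighbour's wall
crossing a cell can split its interior). A final size filter (60–5000 px)
yields the label map. On scattered 24-cell scenes this gives exact counts
noise-free and at SNR 5 (ring contrast / read-noise SD).

An *oracle* backend substitutes the simulator's ground-truth masks, with
labels equal to cell ids. Engine-level studies (trigger timing, tracking,
mitosis capture, localization timecourses) use it so that they measure the
engine's decision logic, not pixel-classification error, which is
quantified separately. The learned-segmenter slot in the backend protocol
is intentionally open; the classical backend is the default and only
built-in.

Features per region: area, centroid, per-channel mean intensity, and a
bud-candidate flag (area below 40% of the median region area), with buds
linked to the nearest larger region. The nuclear localization score is the
mean GFP over the nucleus divided by the mean over the cell; when no
nuclear channel exists the nucleus proxy is the brightest quartile of GFP
pixels in the cell (rank-based, so flat backgrounds cannot inflate it).

## Tracking and stage feedback

Global frame-to-frame translation is the argmax of the circular FFT
cross-correlation (integer pixels; a constant frame returns zero with a
degenerate flag); it is tested against exhaustive shift search. Regions are
then matched greedily by nearest centroid after applying the translation,
gated at the median equivalent radius, ties broken by smaller area
difference. The recentering command maps the tracked centroid onto the
image centre with gain 1 under the stage/image sign convention, applied
after every acquisition. At a 30 s follow cadence the per-frame drift of a
crowd-pushed cell stays under ~2 px, so full proportional correction keeps
the rendered centroid within 3 px of centre without damping.

## Triggers

All predicates are pure functions; fire-once semantics live in the engine.

* **Count threshold** — true when the number of non-bud regions reaches N.
* **RFP-positive** — uniform random choice among regions whose RFP mean
  reaches the threshold (default: background + 5 SD).
* **Bud mitosis** — true when a bud's latest area reaches its threshold
  *and* its area rose strictly over each of the last three frames (the
  strictness is what rejects segmentation jitter). The threshold defaults
  to 0.38× the linked mother's current region area. A population-median
  threshold (0.35× median mother area) is also provided but not the
  default: with division pinned at 0.6× the *own* mother's area, a median
  threshold makes the trigger lead depend on mother size (small mothers
  can even divide before crossing it), while the size-relative threshold
  gives a mother-size-independent lead of 2–3 coarse frames at the 3-min
  search cadence.

## The scenario engine

A scenario = named MDA specs (positions × ordered channel settings ×
interval × autofocus flag), a timeline of scheduled actions (valve
switches, MDA changes, optionally repeated each cycle), and conditional
rules mapping triggers to actions. The engine runs on a simulated clock:
acquisition and analysis take zero simulated time and the sample advances
only between scheduled acts, so frame timestamps equal the arithmetic
schedule exactly and runs are deterministic. The horizon is exclusive
(frames lie in `[start, horizon)`). Conditionals are evaluated once per
position visit, after feature extraction; trigger actions are applied
before any further acquisition (atomicity). During a zoom episode the
engine images only that position; bud histories keep accumulating from the
zoom frames but triggers stay suppressed until the episode ends, and the
coarse search resumes one interval after it.

Timestamps in the event log are non-decreasing rather than strictly
increasing: a valve switch synchronized with an acquisition carries the
same timestamp by design, with stable insertion order.

Built-in protocols: `adaptive_stress` (5 min baseline → 25 s burst for
4 min with autofocus off, valve ON at the first burst frame → 60 s recovery
for 20 min → baseline; valve OFF 30 min after ON; hourly cycles),
`detect_and_track`, `count_and_switch`, and `find_and_zoom` (3 min coarse
search; 30 s + RFP for 20 min on trigger). The zoom RFP uses 10% LED so the
episode's own photodose does not stall the division being imaged; the dose
rate stays below `d_safe`.

## Validation studies and what they do (and do not) show

`eventscope.validation` packages the end-to-end studies shared by the test
suite and `scripts/acceptance.py`; problem sizes are desk-scale (colonies
of 8–80 cells, 1–3 simulated hours, 128–256 px fields) so the whole battery
runs in minutes on one CPU. Divisions whose bud predates the first
observation are censored from lead-time statistics (the rule requires a
fully observed history), and "capturing a separation" means the zoom
episode overlaps the separation interval `[onset, division]` — separation
is an extended process, and a bud that crossed its threshold while a
previous episode held the microscope fires late yet still images the
separated nuclei. In the count-trigger study the engine's measured
crossing is checked against an independently advanced copy of the same
colony (valid because brightfield-only acquisition leaves the sample
untouched).

The generator emulates the features these protocols react to — exponential
colony growth, budding with a renderable separation window, shared-pool
sucrose adaptation, saturating stress kinetics, dose-dependent growth
arrest, crowding transport — with circular cells, a uniform environment
per chamber, no cell death, no stage drift or focus drift, and reporter
noise only from the camera. Passing studies therefore demonstrate the
correctness of the *control loop* (scheduling, synchronization, triggers,
feedback) and of the analysis layer on this geometry; they do not certify
segmentation performance on real brightfield texture, nor biological
accuracy of the kinetic constants, all of which are configuration with the
defaults above.

## Numerical choices

Sub-stepping is 5 s; growth, hexose and Venus updates are exact per
sub-step (exponential/linear closed forms), so only the event timing
(budding, division, relaxation cadence) is discretized. Degenerate inputs
are handled explicitly: zero-time advances return the state unchanged,
constant frames flag degenerate registration, empty masks raise, a zero
cell mean makes the localization score NaN. Ties in region matching break
by area difference and then by label order, keeping runs reproducible.
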