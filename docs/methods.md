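# Methods

`colonyscope` models the *cell-losing problem* of long time-lapse microscopy:
a motile cell colony drifts out of a fixed camera field of view (FOV) before
its full division lineage has been recorded, so many pre-programmed stage
positions yield unusable movies.  The package simulates that process,
provides the closed-form random-walk approximations used to reason about it,
and implements a nucleus segmentation / lineage-tracking pipeline evaluated
on synthetic movies with known ground truth.

## Geometry

All simulation happens in continuous micrometre coordinates with the FOV
centred at the origin; camera pixels are metadata (1024 × 1024 px at
216.7 nm/px gives the default 221.9 µm square).  The capture fraction of a
colony is the exact area of its circular footprint inside the FOV rectangle
divided by the footprint area.  The overlap is computed in closed form by
inclusion–exclusion over corner regions of the disk, each reducible to
integrals of `sqrt(r² − x²)`; accuracy is machine precision, so
classification near the 0.5 / 0.9 thresholds is never resolution-limited.
The closed form is validated in the test suite against a 10⁷-point
Monte-Carlo point-sampling oracle across 100 random configurations.

## Colony growth

Two growth models share the area-additivity rule `radius = r1·sqrt(n)` with
single-cell radius `r1 = 7.5 µm`:

- **Synchronized cell cycle** — all cells divide simultaneously every 12 hr,
  so `n(t) = 2^⌊t/12 hr⌋` and the colony radius reaches
  `7.5·16 = 120 µm` after 4 days.
- **Continuous stochastic (Gillespie) growth** — a pure-birth process whose
  waiting time to the next division is drawn as `−(12 hr/n)·ln(u)`,
  `u ~ U(0,1)`.  Note that this rule has per-capita rate `1/12 hr⁻¹` and
  therefore mean colony size `e^(t/12 hr)` (≈ 2981 cells at 96 hr), *not*
  the doubling-per-interval `2^(t/12 hr)` of the synchronized model.  The
  rule is implemented exactly as stated, and the discrepancy matters: under
  it most colonies outgrow the FOV regardless of migration, which caps the
  >50 %-capture rate at ≈ 17 % even for a motionless colony.  Batched runs
  sample the process at frame resolution with the exact Yule transition
  (negative-binomial birth counts), which is tested against the naive
  event-by-event loop.

## Colony migration and its two readings

The colony migrates as a rigid disk performing an unbiased fixed-step random
walk (per-cell walks with enforced compactness would freeze the centre as
`1/n`, contradicting the observed whole-colony drift).  The stated motion,
"1 µm per minute, each step in a random direction", admits two readings that
differ ~15× in diffusivity:

- `per_minute` (default): one 1-µm step per minute → `D = 0.25 µm²/min`;
- `per_frame`: one 15-µm step per 15-min frame → `D = 3.75 µm²/min`,
  matching the separately measured colony displacement of ⟨r⟩ = 15 µm per
  frame (`D_rw = ⟨r⟩²/(π·dt) ≈ 4.8 µm²/min`).

Both are selectable (`MigrationParams.from_convention`), as are both capture
criteria: `throughout` (movie score = minimum capture fraction over frames,
matching the "captured throughout the recording" definition of a full
lineage) and `final_frame`.  `colonyscope.workbench.calibrate_convention`
runs all four combinations of the synchronized model against the reference
no-pattern percentages (24.5 ± 4.6 % at the 0.5 threshold, 2.2 ± 1.6 % at
0.9).  **No combination falls within the reference spread**: at 10,000
movies the four combinations give 80 / 7.0 (per-minute, throughout),
84 / 7.6 (per-minute, final), 0.1 / 0.0 (per-frame, throughout) and
10.7 / 0.5 (per-frame, final) percent.  A speed sweep shows both reference
values are jointly matched only near an effective diffusivity of
≈ 0.8 µm²/min — between the two readings and derivable from neither, so it
is not adopted.  The package ships the literal reading (`per_minute` +
`throughout`) as the default, reports which convention produced every
result in its output metadata, and leaves the discrepancy visible rather
than tuning it away.  The implementation was cross-checked against an
independent naive per-movie simulation with Monte-Carlo point-sampled
capture, which reproduces the same percentages.

## Monte-Carlo throughput experiment

Movies are simulated in batches of 100 (one batch ≈ one experiment's worth
of stage positions).  For each capture threshold the report gives the mean
and SD across batches of the per-batch pass fraction; at pass probability
*p* the between-batch SD is ≈ `sqrt(p(1−p)/100)`, which is what a "±"
printed next to a pass percentage corresponds to.  Batches consume
deterministically spawned random substreams, so adding batches never changes
earlier ones.  The default experiment is 1000 × 100 = 100,000 movies; the
acceptance script and tests use 10,000 movies per model, for which the
standard error on a reported percentage is ≤ 0.5 points.

The effective-throughput improvement ratio divides the experimentally
observed patterned-surface full-lineage rate (72.3 %, treated as a
constant) by the simulated no-pattern >90 %-capture rate.

## Analytic approximations

`estimate_drw(⟨r⟩, dt) = ⟨r⟩²/(π·dt)` and its inverse are exact for
Gaussian (Rayleigh-magnitude) displacements; for the fixed-step per-frame
convention the measured mean displacement is exactly the step length, so the
estimator returns `L²/(π·dt)` exactly.  The mean first-passage time of a
diffusing colony from the centre of a disk-shaped adhesive zone of radius
`R = 125 µm` to its edge is `T = R²/(4D)` ≈ 13.6 hr at `D = 4.8 µm²/min`;
about half of the colonies have escaped the zone by then.  For colony size,
both the end-of-recording radius (120 µm after 4 days) and the literal
time-geometric-mean of the continuous radius trajectory (30 µm over the same
window) are exposed, because "typical colony size over the movie" is
ambiguous between them.

## Synthetic movies

The generator renders simulated colonies into 16-bit image stacks emulating
nuclear-reporter movies: Gaussian spots (σ = 3 µm) of heterogeneous
per-cell intensity, a multiplicative paraboloid illumination bias, a uniform
background (100 counts) and Poisson noise.  Founder brightness is log-normal
(median 4 × 10⁵ integrated counts ⇒ median spot peak a few hundred counts
above background, well separated from shot noise and from 16-bit
saturation; geometric SD 1.8 for strong cell-to-cell heterogeneity).  At
division each daughter receives half the parent's current label (×
log-normal jitter, GSD 1.1), is placed at the parent's position ± one cell
radius, and re-accumulates label over its cycle (doubling per division
interval, capped) — the halve-and-recover dynamics of a histone-fusion
reporter, which keeps brightness stationary across generations while giving
the tracker a clear halving signature at each division.  Within the colony,
cells sit at compact hexagonal-packing-like offsets with small per-frame
jiggle; a few relaxation sweeps keep pairwise distances ≥ 1.9·r1 and the
colony approximately circular.  Every movie carries a ground-truth table of
per-frame cell positions, identities, parent links and division events.

What the generator does **not** emulate: nuclear texture, 3-D structure,
photobleaching, apoptosis, irregular colony shapes, or stage drift beyond
colony motion.  Tracking results on these movies therefore demonstrate the
pipeline's correctness on its stated model, not its accuracy on arbitrary
real data.

## Segmentation and tracking

1. *Flat-field correction*: a 6-coefficient 2-D quadratic is least-squares
   fitted to background pixels (selected by a robust median + 3 MAD
   threshold, refined once after a first correction pass) and the image is
   divided by it; correcting an already-corrected frame changes it by
   < 1 % RMS.
2. *Segmentation*: Otsu threshold (overridable by a fixed value) on the
   corrected frame, connected components, minimum area 20 px;
   intensity-weighted centroids and background-subtracted component sums.
3. *Linking*: per frame pair, the Hungarian algorithm on the standard
   birth/death-augmented matrix minimises
   `Σ w_pos·d² + w_int·|Iᵢ−Iⱼ|/(Iᵢ+Iⱼ)` plus fixed costs for unmatched
   detections (defaults `w_pos = 1 px⁻²`, `w_int = 10`, gate 30 px,
   birth = death = gate²·w_pos).  "Global minimisation" is read as exact
   per-frame-pair assignment, not whole-movie optimisation; optimality is
   tested against exhaustive enumeration for instances up to 6 × 6.
4. *Discontinuity heuristics*: a track that dies next to a neighbour whose
   intensity jumps by a factor in [1.6, 2.6] is treated as a transient merge
   and carried through the merged detections (intensity-weighted split)
   until a nearby birth re-separates the pair; a new track appearing within
   the gate of a track whose intensity drops by a factor in [0.3, 0.7] is
   recorded as a division, with the parent chosen by division geometry (the
   daughters' midpoint falls on the parent's last position) and label
   conservation.  Unresolved events remain plain births/terminations.
   Manual lineage curation is replaced by evaluation against the
   generator's ground truth.

The benchmark used in the acceptance suite runs 20 seeded movies (24–48 hr,
synchronized growth, default rendering) on a 256 × 256 px, 0.65 µm/px field
— a binned-camera geometry chosen so a 48-hr colony remains fully visible —
and requires ≥ 90 % of in-view ground-truth frame links recovered and
≥ 80 % of observable divisions (parent and both daughters in view) called
within one frame.  Measured: 99.97 % links, 87 % divisions.

## Numerical and design notes

- Internal units are µm and minutes; durations and reported times are hours
  at the user-facing surface.
- Capture is evaluated at frame times only (what a recorded movie can
  observe), and zero-radius disks are treated as points.
- The linking matrix uses `∞` for gated pairs and zero-cost dummy–dummy
  entries, so the augmented problem is always feasible and exactly encodes
  matched costs + birth/death penalties.
- Degenerate inputs: a flat image fits a constant paraboloid; fewer
  background pixels than coefficients raises; empty frames segment to no
  detections; a zero unpatterned rate raises with guidance to report a
  lower bound instead.
- Problem sizes: acceptance simulations use 10,000 movies per growth model
  (batches of 100) and the tracking benchmark uses 20 movies at 256² px;
  both choices keep reported standard errors well below the spreads being
  compared against.

## Known limitations

- The migration model is a rigid-disk walk; adhesion-zone confinement (the
  patterned condition) is represented only through the constant experimental
  rate, not simulated.
- The Gillespie rule, taken literally, grows faster than the synchronized
  model (see above); consumers who want doubling-per-interval stochastic
  growth must rescale the interval themselves.
- The tracker does not close gaps across more than one missing frame and
  accepts that close cell pairs may merge transiently.
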