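# Methods

This note documents the models, rules and numerical choices behind
`mazeskill`, and what the synthetic-data generator does and does not
emulate.

## Task and data model

The task is bimanual: a participant tilts a hand-held 170 mm × 150 mm
maze with both hands to roll a 15 mm sphere from a start to a target
region while avoiding thin walls and circular pits. The observables are
(a) the sphere's planar position at 200 Hz in the maze frame, (b) the
board's roll/pitch attitude on the same grid, (c) 3-D positions of eight
joint centres (shoulders, elbows, wrists, hips) at 200 Hz, and (d) 16 × 16
thumb-pressure frames with integer responses 0–4095 per taxel. All
geometry is 2-D in the maze frame (origin at the lower-left playable
corner, +x toward the target, units mm); the board's 3-D attitude enters
only through the tilt series.

### The packaged maze

The physical maze's interior wall map is not published; only the outer
dimensions, the division into 21 tracking sections, the existence of two
alternative paths, and pits on both paths are known. The packaged layout
(`data/default_maze.json`) is therefore a *representative reconstruction*:
a 7 × 3 grid of 21 sections, an upper and a lower corridor around a
central block in the middle row, and one pit per corridor placed close to
the outer wall so that each path remains navigable around its pit. Every
query (`wall_distance`, `detect_wall_contact`, `section_of`,
`corner_set`) validates against this geometry; section boundaries resolve
ties to the lower section id.

## Primitive segmentation

Ten cognitive primitives describe everything the sphere does; the parser
produces an ordered, gapless partition of the trial by a first-match-wins
cascade over per-sample evidence:

1. **AtRest**: speed below `v_rest` = 5 mm/s sustained for `T_rest` =
   0.5 s. Because taking the magnitude of a noisy velocity rectifies
   tracking noise into a positive offset (~25 mm/s at 0.5 mm positional
   noise), the rest speed is computed by differentiating the *low-passed
   position* (4th-order zero-phase Butterworth at `rest_lowpass_hz` =
   6 Hz); sub-threshold gaps shorter than 0.1 s are closed.
2. **InCorner**: within `r_corner_mm` = 15 mm of a wall junction, both
   tilt angles below `level_tilt_deg` = 2°, and speed below
   `v_corner_max` = 40 mm/s. This rule runs *before* the contact rules:
   a sphere parked in a corner necessarily touches both walls (its centre
   sits 7.5·√2 ≈ 10.6 mm from a right-angle junction), so a
   contact-first ordering would make InCorner unreachable. For the same
   reason `r_corner_mm` must exceed 10.6 mm; 15 mm is the default. The
   speed gate keeps fast transits past a corner pocket out of this rule.
   Without a tilt series the rule degrades to "near corner and slower
   than `v_rest`" with a logged warning.
3. **Contact runs**: maximal runs of sphere–wall contact (distance ≤
   sphere radius + `contact_tol_mm` = 1 mm); 1–2-sample dropouts inside a
   run are closed (tracking flicker at the contact boundary) and runs
   under 2 samples are discarded as glints. Runs shorter than
   `T_bounce_max` = 0.15 s are bounce-type; all longer runs are
   **RollAlongWall** (the documented tie rule for durations between
   `T_bounce_max` and `T_roll_min` = 0.25 s). A roll whose final sample
   touches a second wall meeting the first at a corner has its terminal
   portion (within `r_corner_mm` of the junction) relabelled
   **RollToCorner**.
4. **Bounce grouping**: two or more bounce contacts
   (`n_random_bounce_min` = 2) with no section change and no other claim
   between them merge — gaps included — into one **RandomBounce**; an
   isolated bounce is a **ControlledBounce**. (A lone bounce whose exit
   stays in its section is also classed ControlledBounce; the taxonomy
   gives no third option.)
5. **Free-motion head/tail**: after a roll, the contiguous head of free
   motion still within `r_depart_mm` = 20 mm of the departed wall is
   **RollFromWall**; the contiguous tail within `r_approach_mm` = 20 mm
   of a wall about to be rolled along is **RollToWall**.
6. **Remainder**: a free interval ending within `r_return_mm` = 10 mm of
   its start is **Steady**, otherwise **Guide**. Note the whole interval
   is judged at once — Steady is only detectable when flanked by
   non-free segments.

Segments below 3 samples merge into the longer neighbour, preserving the
partition. All thresholds live in one `SegmentationParams` block that the
synthetic generator shares, so generated ground truth and parsed output
are governed by a single config source. The task description defines the
primitives qualitatively only; the thresholds above are this package's
documented operating point, all configurable.

A consequence of rule priority worth noting: samples inside a contact
event may be claimed by AtRest or InCorner (a sphere resting against a
wall, or parked in a corner); only the remaining contact samples are
guaranteed to carry a wall-contact label.

## Scoring and the learning curve

`score_trial` subtracts the per-primitive penalties from the ideal score
of 1 (ControlledBounce 0.03, RandomBounce 0.06, RollAlongWall 0.12,
RollToWall 0.09). RollToCorner, RollFromWall and InCorner default to 0 —
only those four penalty values are published, although the narrative
implies RollToCorner is also penalised — and are overridable through
`PenaltyTable`. Scores are not clipped (a disastrous trial may fall below
0, logged); trial length never enters. `n_contacts` and the
contact-time ratio (fraction of trial time in wall-contact segments) are
reported as precision metrics, and `day_accuracy` is the fraction of
trials that reached the target rather than a pit.

`fit_ols` is closed-form simple regression with the standard inference
block; `t = β/SE` and `F = t₁²` hold exactly by construction, and
`R² = t₁²/(t₁² + n − 2)`. The learning covariate `x1` is the pooled
observation index 0…n−1: with the reference model (intercept 0.57071,
slope 1.016 × 10⁻⁴, residual SD 0.13, n = 1923) that reading reproduces
the slope's standard error analytically,
`SE₁ = σ/(sd(x)·√n) = 0.13/(555.1·43.85) ≈ 5.34 × 10⁻⁶`, which no other
covariate scaling does. Per-day fits use the within-day index. Scores of
pit-terminated trials are included by default. p-values are two-sided
with no multiplicity correction (α = 0.05 throughout).

## Kinematics

Pipeline order is fixed: differentiate (central differences, one-sided at
the ends) → choose the cutoff on the raw speed → filter → align →
summarise. The automatic cutoff uses residual analysis: over candidates
1–20 Hz in 0.5 Hz steps, the RMS residual between raw and filtered speed
is computed; a line fitted to the top quarter of the candidate grid
estimates the noise asymptote, and the smallest candidate whose residual
falls within that line's projection (5% tolerance) is chosen, clamped to
[1, fs/4] Hz. The filter is a 4th-order Butterworth applied
forward–backward — zero net phase so peaks are not shifted before
alignment; the effective order is therefore 8. Filtering a magnitude
series can ring slightly below zero; consumers clip at 0.

Peak windows are ±0.5 s (201 samples at 200 Hz) around the global speed
maximum, ties to the earliest; trials whose peak lies within 0.5 s of a
boundary are excluded with a logged reason. Day summaries are pointwise
mean and SEM. Day-1 vs day-3 comparisons use the two-sample KS test on
the pooled windowed speed samples per joint (the per-sample unit is the
default; per-trial peaks can be compared by passing those instead).
Coordination is the Spearman matrix of filtered speed magnitudes of the
six arm joints, concatenated over a day's included windows, mid-ranked
ties.

## Tactile analysis

Frames are median-filtered (3 × 3, reflected edges) and averaged into a
mean pressure image per trial or day. The high-pressure region is the
largest 4-connected component of taxels at or above half the image
maximum — the half-max rule operationalises "high-pressure region", and
the largest-component rule resolves multi-region images to the dominant
one. Moments are intensity-weighted over that region (grey-scale, not
binary): raw moments give the centroid, second central moments a
covariance whose eigen-decomposition yields the ellipse, axes
`2·k·√λ` with `k = 2`, orientation from the major eigenvector (0 by
convention for isotropic regions), area `π·(major/2)·(minor/2)` in
taxel². Absolute area agreement with any particular published scale is
not claimed; the generator's day-level blob widths are calibrated so mean
areas land near 60 (day 1) and 56 (day 3) taxel², a convenience for
realistic magnitudes. Day areas are compared per trial by one-way ANOVA —
the published degrees of freedom, e.g. F(1, 862), imply per-trial
observations — with Shapiro-Wilk and group-balance pre-checks switching
to Mann–Whitney U (mid-ranks, tie-corrected normal approximation).

## The synthetic generator

Trials are generated **kinematically from scripts**, not by rigid-body
physics: every scripted primitive expands into a trajectory motif
engineered to satisfy that primitive's own detection rule, placed at
feasibility-validated anchors (clear rolling spans, corner pockets,
bounce sites with a free section exit, a visibility-graph router for free
motion). Contact motifs realise with their natural entourage — a roll is
approached (RollToWall) and left (RollFromWall); a corner visit rolls in,
parks level, and rolls out — so ground truth can contain more segments
than the script. Board tilt is synthesised from the commanded
acceleration (gain 0.02°/(mm/s²), clamped at ±10°), overridden by a 5°
pressing tilt during wall contact and a ~0.3° level attitude while
parked in a corner. Tracking noise is Gaussian, SD 0.5 mm per sample,
smoothed with a 25 ms moving average, as a camera tracker would deliver.
Determinism is per seed and byte-exact.

Sessions draw target scores from the linear learning model clipped to
[0, 1]; because all penalties are multiples of 0.03, the greedy motif
composition (corner visit = 0.33, roll = 0.21, random bounce = 0.06,
controlled bounce = 0.03 in realised ground-truth penalties) matches any
clipped target exactly, well within the ±0.015 guarantee. Completion is
Bernoulli at 0.85 per trial (a plausible mid-training accuracy; no value
is published), and incomplete trials end inside a pit.

Joint speeds are monotone transforms of latent Gaussian drives: white
noise low-passed at 6 Hz, mixed by the Cholesky factor of the latent
Pearson matrix `2·sin(π·ρ_s/6)` (the Gaussian-copula inverse of the
Spearman target), exponentiated (`exp(0.6z)`, clipped at ±3.5σ), and
scaled by a weak shared envelope that peaks once inside the trial — the
peak-speed event is simultaneous across joints, as in the task — with
tapered ends so the global peak is strictly interior. Realised Spearman
correlations approximate the target within ±0.1 for series of ≥ 4000
samples. Day-3 amplitudes rise 15% for shoulders/elbows/hips and fall
10% for the wrists (speed refinement), leaving rank correlations
untouched while shifting the KS comparisons. The default 8 × 8 coupling
targets follow the reported day-1/day-3 coordination pattern for the six
arm joints, with unreported pairs and the hips at mid-range values.

Tactile streams are Gaussian bumps plus per-taxel noise (SD 60 counts),
quantised to 0–4095, with optional full-scale salt outliers and
per-trial scatter of the blob geometry (8% relative σ jitter, 0.3 taxel
centroid jitter). Day parameterisation drifts the centroid toward the
pad centre and shrinks σ from day 1 to day 3.

**What the generator does not emulate**: ball–wall restitution and
rolling friction (pieces are eased splines, not dynamics), marker-level
motion-capture artefacts, sensor nonlinearity beyond quantisation, and
participant idiosyncrasies. Passing tests therefore demonstrate that the
analysis chain recovers known structure from data of realistic geometry,
rate and noise — not that it is robust to every artefact of real
recordings.

## Problem sizes used in the checks

The test suite exercises segmentation recovery on 200 random scripted
trials (boundary-tolerant matching at ±0.1 s, ≥ 90% required; observed
≈ 99%), learning-model recovery over 100 seeded replicates of n = 1923,
KS calibration over 2000 null replicates of n = 200, tactile power over
25 replicates of 60 trials per day, and brute-force oracles for the
distance, section, contact, median-filter, rank-correlation and moment
computations. These sizes make the whole suite run in well under a
minute while keeping the Monte-Carlo margins comfortable.

## Known limitations

- The packaged maze is representative, not a replica; conclusions tied to
  a specific interior wall map do not transfer.
- The segmentation thresholds are an operating point chosen for the
  stated sphere/board geometry; other mazes may need retuning (all
  constants are exposed).
- The InCorner-before-contact rule ordering is a deliberate deviation
  from a strict contact-first cascade (see above); with `r_corner_mm`
  below 10.6 mm the rule cannot fire at right-angle corners.
- Spearman targets are approximate under the copula construction and the
  weak envelope; biases are ≤ 0.02 plus sampling noise.
- The tactile ellipse area depends on the half-max region rule; a
  different `region_frac` rescales areas (the σ ↔ area calibration above
  holds only for the default 0.5 and k = 2).
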