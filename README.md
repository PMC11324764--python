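# mazeskill

Analysis of motor-skill acquisition in a bimanual ball-in-maze task.

Participants hold a 170 mm × 150 mm maze board with both hands and tilt it
to roll a 15 mm sphere from a start to a target location, avoiding walls
and pits, while a tracker records the sphere at 200 Hz, motion capture
records eight upper-body joint centres, and each thumb rests on a 16 × 16
tactile array (responses 0–4095 counts). `mazeskill` implements the full
analysis chain for this paradigm, for motor-control researchers who want
to quantify learning in such naturalistic tasks:

1. **Primitive segmentation** — each trial's trajectory (plus board tilt)
   is parsed into an ordered, gapless sequence of ten *cognitive
   primitives* (Guide, Roll To Corner, Roll From Wall, In Corner, Random
   Bounce, Controlled Bounce, Steady, Roll Along Wall, Roll To Wall,
   At Rest) by a deterministic rule cascade over wall distances, section
   membership, corner proximity, filtered speed and tilt.
2. **Performance scoring** — the trial score is
   `1 − Σ penalty(primitive)` with penalties Controlled Bounce 0.03,
   Random Bounce 0.06, Roll Along Wall 0.12, Roll To Wall 0.09 (the rest
   0 by default); an error-free trial scores exactly 1 and trial length is
   never penalised.
3. **Learning curves** — simple OLS of score on the pooled observation
   index, `y ~ 1 + x1`, with the complete inference block (SEs,
   t-statistics, F, R², RMSE, 95% confidence band), pooled or per day.
4. **Kinematics** — joint speeds `|dx/dt|` from 3-D positions, automatic
   Butterworth cutoff by residual analysis, 4th-order zero-phase low-pass,
   1-s windows aligned on each trial's peak speed, per-day mean ± SEM
   profiles, day-1 vs day-3 Kolmogorov–Smirnov tests, and 6 × 6 joint-pair
   Spearman correlation matrices.
5. **Thumb pressure** — median-filtered 16 × 16 frames averaged per trial,
   centroid and 2σ ellipse from intensity-weighted image moments of the
   dominant half-maximum region, and day-wise ellipse-area comparison
   (one-way ANOVA with a Mann–Whitney U fallback).

Because no public recordings exist for this paradigm, the package ships a
first-class **synthetic data generator**: scripted trials whose pieces are
constructed to satisfy the primitives' own detection rules (with
per-sample ground truth), multi-day sessions whose scores follow a linear
learning model (intercept 0.57071, slope 1.016 × 10⁻⁴ per trial, residual
SD 0.13), joint tracks with a target Spearman coupling structure, and
tactile streams with controlled blob geometry, noise and outliers.

## Worked example

```python
import numpy as np
from mazeskill import (default_layout, script_trial, segment_trial,
                       score_trial, generate_session, fit_ols, LearningModel)

layout = default_layout()                      # packaged 21-section maze

# one trial: guide, one deliberate bounce, a roll along a wall
trial = script_trial(layout, ["Guide", "ControlledBounce", "RollAlongWall"],
                     seed=7, finish="target")
seg = segment_trial(trial.trajectory, trial.tilt, layout)
print(seg.symbol_string)                       # -> GAGTWFG
print(score_trial(seg).score)                  # -> 0.76

# a 1923-trial synthetic score series refit by OLS
session = generate_session(layout, model=LearningModel(), n_trials=1923,
                           seed=1, realize="scores")
print(fit_ols(np.arange(1923.0), session.scores()).summary())
```

prints

```
GAGTWFG
0.76
y ~ 1 + x1  (n = 1923)
  intercept  0.55955  (SE = 0.0059219, tStat = 94.49, p = 0)
  x1         0.00011005  (SE = 5.336e-06, tStat = 20.62, p = 1.57e-85)
  F = 425.4 (p = 1.57e-85), R2 = 0.181 (adj 0.181), RMSE = 0.13
```

`GAGTWFG` is the symbolic trial: Guide, Controlled **b**ounce (code `A`),
Guide, Roll **T**o Wall, Roll along **W**all, Roll **F**rom Wall, Guide.
The score 0.76 = 1 − 0.03 − 0.09 − 0.12. The regression recovers the
generating slope (1.016 × 10⁻⁴) within two standard errors; R² ≈ 0.18
says trial-to-trial noise dominates a small, steady improvement.

The `examples/` directory has one short narrative script per capability
(segmentation, learning curve, joint kinematics, thumb pressure), and a
thin CLI (`mazeskill run-all --config cfg.yaml`) orchestrates all stages
from a YAML config with a reproducibility manifest.

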