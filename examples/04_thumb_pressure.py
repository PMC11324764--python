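"""Thumb-pressure ellipses and the day-1 vs day-3 area comparison.

Generates 16x16 tactile frames for both thumbs on days 1 and 3, fits the
moment ellipse to each trial's mean pressure image, and tests whether the
contact area shrank with practice (one-way ANOVA, Mann-Whitney fallback).
"""

import numpy as np

from mazeskill import (compare_areas, generate_tactile_stream, mean_image,
                       pressure_ellipse, tactile_day_blob)

areas = {}
for side in ("L", "R"):
    for day in (1, 3):
        blob = tactile_day_blob(day, side)
        per_trial = []
        for trial in range(60):
            frames = generate_tactile_stream(5, blob=blob, side=side,
                                             seed=day * 10000 + trial)
            ell = pressure_ellipse(mean_image(frames))
            per_trial.append(ell.area)
        areas[(side, day)] = per_trial
        print(f"{side} thumb day {day}: mean area "
              f"{np.mean(per_trial):5.1f} taxel^2 "
              f"(sd {np.std(per_trial):4.1f}, n={len(per_trial)})")

for side in ("L", "R"):
    res = compare_areas(areas[(side, 1)], areas[(side, 3)])
    stat = (f"F(1,{res['df2']}) = {res['F']:.2f}"
            if res["test_used"] == "anova" else f"U = {res['U']:.0f}")
    print(f"{side} thumb day1 vs day3: {res['test_used']}, {stat}, "
          f"p = {res['p']:.2g}")

# A shrinking, centralising pressure ellipse from day 1 to day 3 is the
# tactile signature of growing precision; the test should flag the
# programmed area decrease as significant.
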