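"""Parse one synthetic maze trial into cognitive primitives.

Builds a scripted trial on the packaged 21-section maze (a guided run, a
deliberate wall bounce, a roll along a wall), parses the noisy trajectory
with the rule cascade, and prints the detected segments next to the
generator's ground truth.
"""

from mazeskill import default_layout, script_trial, segment_trial

layout = default_layout()
trial = script_trial(
    layout,
    ["Guide", "ControlledBounce", "RollAlongWall"],
    seed=7,
    finish="target",
)

parsed = segment_trial(trial.trajectory, trial.tilt, layout)

print(f"trial: {trial.trajectory.duration:.2f} s at 200 Hz, "
      f"completed = {trial.completed}")
print(f"{'label':16s} {'start':>7s} {'end':>7s}   truth")
for ps, ts in zip(parsed.segments, trial.truth_segments.segments):
    print(f"{ps.label:16s} {ps.t_start:7.2f} {ps.t_end:7.2f}   {ts.label}")
print("symbol string:", parsed.symbol_string)

# Each line is one behavioural unit of the trial; start/end are seconds.
# The symbol string is the compact per-trial representation used for
# scoring (one character per segment).
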