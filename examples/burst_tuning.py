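"""Classify the 3D motion tuning of a bursting neuron across two light trials.

Plants a clockwise-yaw-tuned neuron (preferred displacement +15 deg) in two
independent five-minute sessions, detects its bursts, computes per-component
burst-triggered displacement averages and wrap-around shuffled nulls, and
prints the joint classification.
"""

import numpy as np

from headmotion import bursts
from headmotion.synth import (
    NeuronModel,
    TrajectoryModel,
    simulate_head_trajectory,
    simulate_spike_train,
)

DT, TRIAL_S = 0.02, 300.0
per_trial = {c: [] for c in ("yaw", "pitch", "roll")}

for li in range(2):
    traj, events = simulate_head_trajectory(TrajectoryModel(duration=TRIAL_S, seed=101 + li))
    neuron = NeuronModel(kind="displacement_tuned", preferred_vector=(15.0, 0.0, 0.0),
                         seed=501 + li)
    spikes = simulate_spike_train(traj, events, neuron)
    found, eligible = bursts.detect_bursts(spikes)
    onsets = np.array([b.onset for b in found])
    print(f"trial {li + 1}: {len(spikes)} spikes, {len(found)} bursts "
          f"(eligible: {eligible})")
    for ci, comp in enumerate(("yaw", "pitch", "roll")):
        angle = traj[comp].to_numpy()
        bta = bursts.burst_triggered_average(onsets, angle, DT, comp)
        null = bursts.shuffled_null(onsets, angle, TRIAL_S, DT, seed=10 * ci + li)
        per_trial[comp].append((bta, null, eligible))

print()
for comp, trials in per_trial.items():
    res = bursts.classify_motion_tuning(
        trials[0][:2], trials[1][:2], trials[0][2], trials[1][2]
    )
    m1, m2 = res.mean_displacements
    label = {1: "positive (CW/up)", -1: "negative (CCW/down)", 0: "-"}[res.direction]
    print(f"{comp:>5}: mean displacement {m1:+6.2f} / {m2:+6.2f} deg -> "
          f"tuned = {res.tuned} ({label})")

print("\nA component is 'tuned' only when the mean displacement escapes the "
      "same side of the 95% shuffled-null band in both trials; the planted "
      "+15 deg yaw preference should be the only robust component.")
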