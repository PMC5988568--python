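"""Test spike trains for allocentric (Earth-referenced) heading modulation.

Simulates an azimuth-modulated neuron and an untuned cell over two trials,
computes dwell-normalized heading tuning curves, Rayleigh vectors against
wrap-around shuffled nulls, and the anticipatory temporal-shift profile.
"""

import numpy as np

from headmotion.allocentric import (
    anticipatory_shift,
    classify_allocentric_modulation,
    shuffled_curves,
    tuning_curve,
)
from headmotion.synth import (
    NeuronModel,
    TrajectoryModel,
    simulate_head_trajectory,
    simulate_spike_train,
)

DT, TRIAL_S = 0.02, 300.0
sessions = [simulate_head_trajectory(TrajectoryModel(duration=TRIAL_S, seed=41 + li))
            for li in range(2)]

for label, kind, kwargs in (
    ("azimuth-modulated", "azimuth_tuned", dict(azimuth_params=(40.0, 4.0, 20.0))),
    ("untuned", "untuned_poisson", dict(baseline_rate=5.0)),
):
    trials = []
    for li, (traj, events) in enumerate(sessions):
        spikes = simulate_spike_train(
            traj, events, NeuronModel(kind=kind, seed=60 + li, **kwargs)
        )
        yaw = traj["yaw"].to_numpy()
        curve = tuning_curve(spikes, yaw, DT, "azimuth")
        null = shuffled_curves(spikes, yaw, TRIAL_S, DT, "azimuth", 200, seed=li)
        trials.append((curve, null))
    cls = classify_allocentric_modulation("azimuth", trials[0], trials[1])
    r1, r2 = cls.statistics
    print(f"{label:>18}: Rayleigh r = {r1:.3f} / {r2:.3f}, preferred "
          f"{cls.preferred_directions[0]:+.0f} / {cls.preferred_directions[1]:+.0f} deg "
          f"-> modulated = {cls.modulated}")

traj, events = sessions[0]
spikes = simulate_spike_train(
    traj, events,
    NeuronModel(kind="azimuth_tuned", azimuth_params=(40.0, 4.0, 20.0), seed=60),
)
rs = anticipatory_shift(spikes, traj["yaw"].to_numpy(), DT)
best = max(rs, key=rs.get)
print(f"\nanticipatory scan: r peaks at spike shift {1000 * best:+.0f} ms "
      f"(r = {rs[best]:.3f}; r at 0 ms = {rs[0.0]:.3f})")
print("Modulation requires a Rayleigh score above 95% of the shuffled null in "
      "both trials with a stable preferred direction; a near-flat shift "
      "profile with its peak close to 0 ms means firing is aligned with, not "
      "anticipating, heading.")
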