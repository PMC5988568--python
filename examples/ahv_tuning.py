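"""Model selection for angular-head-velocity rate tuning.

Simulates one velocity-modulated neuron and one untuned Poisson neuron on the
same session, bins firing rate by yaw angular head velocity, and compares a
constant rate model against a skewed Gaussian by BIC.
"""

from headmotion.ahv import compute_ahv, fit_ahv_models
from headmotion.synth import (
    NeuronModel,
    TrajectoryModel,
    simulate_head_trajectory,
    simulate_spike_train,
)

traj, events = simulate_head_trajectory(TrajectoryModel(duration=300.0, seed=106))
ahv = compute_ahv(traj["yaw"].to_numpy(), 0.02)

for label, model in (
    ("AHV-tuned", NeuronModel(kind="ahv_tuned", baseline_rate=0.0, seed=9)),
    ("untuned", NeuronModel(kind="untuned_poisson", baseline_rate=5.0, seed=10)),
):
    spikes = simulate_spike_train(traj, events, model)
    fit = fit_ahv_models(ahv, spikes, 0.02)
    p = fit.skew_params
    print(f"{label:>9}: delta BIC = {fit.delta_bic:6.1f}  "
          f"center = {p['center']:+7.1f} deg/s  sigma = {p['sigma']:5.1f}  "
          f"gamma = {p['gamma']:+.2f}")

print("\nA BIC advantage of 10 or more for the skewed Gaussian marks a cell as "
      "velocity-modulated; the tuned cell's fitted center should sit near the "
      "planted +150 deg/s preference while the Poisson cell stays below the "
      "evidence threshold.")
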