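"""Detect per-axis head-motion events and characterise their statistics.

Simulates one foraging session, detects motion events in each Eulerian
component, fits Gaussians to the displacement distributions and regresses
conjunctive (yaw x roll) displacements.
"""

from headmotion.kinematics import (
    conjunctive_pairs,
    conjunctive_regression,
    detect_motion_events,
    fit_displacement_distribution,
)
from headmotion.synth import TrajectoryModel, simulate_head_trajectory

traj, events = simulate_head_trajectory(TrajectoryModel(duration=300.0, seed=5))

for comp in ("yaw", "pitch", "roll"):
    detected = detect_motion_events(traj[comp].to_numpy(), component=comp)
    fit = fit_displacement_distribution([e.extent for e in detected])
    print(f"{comp:>5}: {len(detected):3d} events, fitted sigma = {fit.sigma:5.1f} deg, "
          f"center = {fit.center:+5.1f} deg")

pairs = conjunctive_pairs(traj["yaw"].to_numpy(), traj["roll"].to_numpy())
reg = conjunctive_regression(pairs)
print(f"\nyaw x roll conjunction: slope = {reg.slope:+.3f} deg/deg, "
      f"R^2 = {reg.r_squared:.3f} over {reg.n_pairs} pairs")
print("A small negative slope with low R^2 means clockwise yaw weakly "
      "co-occurs with counter-clockwise roll, while most roll variance is free.")
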