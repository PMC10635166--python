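"""FLASH-minus-conventional ROS difference in tumor vs healthy cells.

Evolves Δ[ROS](t) at a well-oxygenated radius during and after the pulse for
the two cell types. Healthy cells produce and clear ROS an order of magnitude
faster, so their ROS level drops further below the conventional baseline —
the source of the differential protection.
"""

import numpy as np

import flashspheroid as fs

model, tumor, _ = fs.preset("table1-tumor")
_, healthy, _ = fs.preset("table1-healthy")
profile = fs.solve_steady_oxygen(model)

r = 0.45  # mm, well inside the oxygenated shell
t = np.array([0.0, 0.05, model.T, 1.0, 10.0])
t_label = ", ".join(f"{v:g}" for v in t)
for cell in (tumor, healthy):
    d = fs.delta_ros_closed_form(profile, cell, model.S_ROD, r, t)
    tail = ", ".join(f"{v:+.2e}" for v in d)
    print(f"{cell.label:>7}: Δ[ROS] at t = [{t_label}] s: [{tail}] μM")

sp = fs.SurvivalParams()
for cell in (tumor, healthy):
    d_end = fs.delta_ros_closed_form(profile, cell, model.S_ROD, r, model.T)
    relief = fs.ros_relief_rate(d_end, sp)
    print(f"{cell.label:>7}: Δ[ROS] at beam-off {d_end:+.3e} μM, "
          f"sigmoid relief rate {relief:.3e} 1/s")

print()
print("Δ[ROS] is zero at t = 0, always non-positive, and larger in magnitude")
print("for healthy cells; the sigmoid converts that deficit into a survival")
print("credit that tumor cells barely receive.")
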