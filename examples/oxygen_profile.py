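"""Steady-state oxygen in a 0.5 mm spheroid and its anoxic core.

Solves the diffusion-consumption balance for the canonical parameterization
(Sm = 4.2 mmHg/s, p_air = 160 mmHg) and cross-checks the closed form against
the finite-difference solver.
"""

import numpy as np

import flashspheroid as fs

model, _, _ = fs.preset("fig1")
profile = fs.solve_steady_oxygen(model)
fd = fs.finite_difference_oxygen(model, n_cells=2000)
exact_on_fd = fs.solve_steady_oxygen(model, r_grid=fd.r_grid)

print(f"anoxic core radius r0 = {profile.r0:.4f} mm (spheroid R = {model.R} mm)")
print(f"oxygen tension at the spheroid surface: {profile.ps_at(model.R):.2f} mmHg")
print(f"oxygen tension at the air interface:    {profile.ps_at(model.H):.2f} mmHg")
err = np.max(np.abs(fd.ps - exact_on_fd.ps)) / model.p_air
print(f"closed form vs finite differences: max deviation {err:.2e} of p_air")
print()
print("Cells inside r0 sit at zero oxygen tension (quiescent necrotic core);")
print("the tension climbs from the core edge to the surface value above, then")
print("through the culture medium up to atmospheric 160 mmHg at r = H.")
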