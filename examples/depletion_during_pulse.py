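"""Radiolytic oxygen depletion during a 10 Gy FLASH pulse at 90 Gy/s.

Shows how the oxygen field drops linearly during the 0.111 s pulse and how
the anoxic region grows, at the historical depletion calibration
S_ROD = 160 mmHg/s and at the measured 15.3 mmHg/s.
"""

import numpy as np

import flashspheroid as fs

model, _, _ = fs.preset("fig1")
profile = fs.solve_steady_oxygen(model)
T = model.T
print(f"pulse length T = dose/rate = {T:.4f} s")

for srod in (160.0, 15.3):
    field = fs.DepletionField(profile=profile, S_ROD=srod)
    r = profile.r_grid[profile.r_grid <= model.R]
    p_end = field.oxygen_at(r, T)
    ps = profile.ps_at(r)
    grown = r[(p_end == 0) & (ps > 0)]
    edge = grown.max() if grown.size else profile.r0
    print(f"S_ROD = {srod:6.1f} mmHg/s: depleted {srod * T:6.2f} mmHg during the "
          f"pulse; anoxic edge moves {profile.r0:.3f} -> {edge:.3f} mm")

print()
print("At 160 mmHg/s most of the proliferating shell is driven anoxic before")
print("the pulse ends; at the measured 15.3 mmHg/s only ~1.7 mmHg is removed")
print("and the core barely grows — oxygen depletion alone is then too weak to")
print("explain the FLASH sparing effect.")
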