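"""The headline result: FLASH spares healthy tissue more than tumor.

Runs the paired tumor (Sm = 4.2 mmHg/s) vs healthy (Sm = 3.2 mmHg/s)
spheroids through the full pipeline at S_ROD = 15.3 mmHg/s and 10 Gy and
compares the FLASH/CONV overall-survival ratios.
"""

import numpy as np

import flashspheroid as fs

mt, tumor, sp = fs.preset("table1-tumor")
mh, healthy, _ = fs.preset("table1-healthy")

for model, cell in ((mt, tumor), (mh, healthy)):
    res = fs.spheroid_survival(model, cell, sp, n_r=200)
    ratio = res.overall_sf_flash / res.overall_sf_conv
    print(f"{cell.label:>7}: log10 SF conv = {np.log10(res.overall_sf_conv):8.3f}, "
          f"flash = {np.log10(res.overall_sf_flash):8.3f}, "
          f"FLASH/CONV ratio = {ratio:.3f}")

print()
print("Both cell types survive FLASH at least as well as conventional delivery")
print("(oxygen depletion lowers the enhancement ratio mid-pulse), but the")
print("healthy-cell ratio is distinctly larger: fast ROS clearance lets healthy")
print("tissue bank the oxidative-stress relief that slow-clearing tumor cells")
print("cannot — preserved tumor kill, extra normal-tissue protection.")
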