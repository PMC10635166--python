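"""Depletion-only dose response via the scenario runner.

Executes the depletion-only preset (S_ROD = 160 mmHg/s, oxidative-stress term
off) over 5/10/15/20 Gy, writing CSV/JSON artifacts to ./scenario_out, and
prints the overall survival gap as a function of dose.
"""

import json
from pathlib import Path

import flashspheroid as fs

spec = fs.scenario_preset("fig3")
out = Path("scenario_out")
manifest = fs.run_scenario(spec, out)
print(f"wrote {len(manifest)} artifacts to {out}/")

summary = json.loads((out / manifest["summary"]).read_text())
doses = summary["cells"]["tumor"]["doses"]
for dose, vals in sorted(doses.items(), key=lambda kv: float(kv[0])):
    gap = vals["log10_overall_sf_flash"] - vals["log10_overall_sf_conv"]
    print(f"  {dose:>2} Gy: log10 SF conv {vals['log10_overall_sf_conv']:8.2f}, "
          f"flash {vals['log10_overall_sf_flash']:8.2f}, gap {gap:+.3f}")

print()
print("The FLASH-vs-conventional survival gap widens with dose: a larger dose")
print("means a longer pulse, deeper oxygen depletion, and more of the delivery")
print("spent in the radioresistant low-OER regime.")
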