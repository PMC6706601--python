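"""Fit internal-standard calibration curves from a simulated dilution series.

Simulates the standard calibration mixture (all analyte groups co-diluted
from 0 to 75 ng/µL, CDNT internal standard constant at 25 ng/µL, triplicate
spots), runs preprocessing, and fits one straight-line model per ion channel.
The printed table mirrors a method-validation summary: slope (normalized
abundance per ng/µL), R², linear range and detection limit per channel.
"""

import nitroquant as nq

model = nq.default_signal_model()
spectra, design = nq.simulate_calibration_series(model=model, n_spots=3, seed=11)
models = nq.fit_simple_models(spectra, design)

print(f"{'channel':<22} {'slope':>9} {'R²':>8} {'range (ng/µL)':>14} {'LOD (ng/µL)':>12}")
for mz in sorted(models):
    m = models[mz]
    print(
        f"{m.label:<22} {m.slope_own:>9.5f} {m.r2:>8.4f} "
        f"{f'{m.range_min:g}-{m.range_max:g}':>14} {m.lod:>12.2f}"
    )
print(
    "\nEach channel is linear over the calibration range; the LOD is"
    "\n3.3 x residual SD / slope. Weakly ionizing analytes (NT, m/z 137)"
    "\nshow the smallest slope and hence the highest detection limit."
)
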