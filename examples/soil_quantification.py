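"""Quantify TNT and ADNT in simulated contaminated-soil extracts.

Soil samples are extracted at 2 g soil / 4 mL acetonitrile, so 1 mg/kg in
soil corresponds to 0.5 ng/µL in the extract.  Each extract is co-deposited
with the CDNT internal standard and measured in triplicate; concentrations
are back-calculated to mg/kg and compared with the known ground truth.

Because old production sites are typically TNT-dominated and TNT signal leaks
into the ADNT channels, calibration uses the TNT × ADNT crossed grid and
quantification the sequential (TNT-first) inversion; the simple single-
analyte inversion is printed alongside to show the bias it would leave.
"""

import nitroquant as nq

model = nq.default_signal_model()

# sequential strategy: bivariate models from the crossed TNT × ADNT grid;
# simple strategy: straight lines from the co-diluted standard mixture series
grid_spectra, grid_design = nq.simulate_interference_series(model=model, n_spots=3, seed=21)
seq_models = nq.fit_interference_models(grid_spectra, grid_design)
series_spectra, series_design = nq.simulate_calibration_series(model=model, n_spots=3, seed=23)
simple_models = nq.fit_simple_models(series_spectra, series_design)

# three soils: heavy TNT, mixed, light contamination (mg/kg)
soils = [
    {"TNT": 60.0, "ADNT": 8.0},
    {"TNT": 12.0, "ADNT": 12.0},
    {"TNT": 3.0, "ADNT": 1.0},
]
spectra, sidecar = nq.simulate_soil_study(soils, model=model, n_spots=3, seed=22)

print(f"{'sample':<8} {'analyte':<8} {'truth mg/kg':>12} {'simple':>8} {'sequential':>11} {'RSD %':>7}")
for sid, reps in spectra.items():
    seq = nq.quantify_sample(
        reps, seq_models, mode="sequential", soil_mass_g=2.0, extract_volume_ml=4.0
    ).set_index("analyte")
    simp = nq.quantify_sample(
        reps, simple_models, mode="simple", soil_mass_g=2.0, extract_volume_ml=4.0
    ).set_index("analyte")
    for g in ("TNT", "ADNT"):
        truth = sidecar[(sidecar.sample_id == sid) & (sidecar.analyte == g)].iloc[0][
            "soil_mg_per_kg"
        ]
        print(
            f"{sid:<8} {g:<8} {truth:>12.1f} {simp.loc[g, 'soil_mg_per_kg']:>8.1f} "
            f"{seq.loc[g, 'soil_mg_per_kg']:>11.1f} {seq.loc[g, 'rsd_pct']:>7.1f}"
        )
print(
    "\nEstimates average the radical-anion and oxygen-loss channels; RSD is"
    "\nthe spot-to-spot precision. The simple inversion is accurate when the"
    "\nsample composition resembles the calibration mixture, but overestimates"
    "\nADNT when TNT dominates (cross-talk at m/z 197/181); the sequential"
    "\ncorrection removes that bias. TNT agrees under both strategies."
)
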