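"""TNT interference on the ADNT channels, and the sequential correction.

TNT signal leaks into the ADNT channels (m/z 197 and 181).  In TNT-dominated
samples a naive single-analyte inversion therefore overestimates ADNT.  The
sequential strategy quantifies TNT first from its own channels, subtracts its
fitted contribution from the ADNT channels, then inverts the ADNT
calibration.  Both strategies are fitted on the same TNT × ADNT crossed
calibration grid and applied to the same TNT-heavy sample.
"""

import nitroquant as nq

model = nq.default_signal_model()
grid_spectra, grid_design = nq.simulate_interference_series(model=model, n_spots=3, seed=31)
interference_models = nq.fit_interference_models(grid_spectra, grid_design)
simple_models = nq.fit_simple_models(grid_spectra, grid_design)

m197 = interference_models[197.0]
print(f"ADNT channel m/z 197:  A = {m197.intercept:.4f} "
      f"+ {m197.slope_own:.4f}·c_ADNT + {m197.slope_tnt:.4f}·c_TNT")

truth = {"TNT": 40.0, "ADNT": 5.0}  # TNT-dominated, as on old production sites
sample = nq.SampleTruth(truth, sample_id="site")
reps = nq.simulate_replicate_set(sample, model, 3, seed=32)

simple = nq.quantify_sample(reps, simple_models, mode="simple").set_index("analyte")
seq = nq.quantify_sample(reps, interference_models, mode="sequential").set_index("analyte")

print(f"\n{'analyte':<8} {'truth':>7} {'simple':>8} {'sequential':>11}  (ng/µL)")
for g in ("TNT", "ADNT"):
    print(f"{g:<8} {truth[g]:>7.1f} {simple.loc[g, 'mean_ng_per_ul']:>8.2f} "
          f"{seq.loc[g, 'mean_ng_per_ul']:>11.2f}")
print(
    "\nTNT is identical under both strategies (its channels carry no"
    "\ncross-term); the sequential correction removes the upward ADNT bias."
)
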