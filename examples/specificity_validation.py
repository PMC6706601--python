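"""Analyte specificity and concentration dependency of the channel signals.

Two checks on simulated calibration data: (1) PCA of the spectra's
IS-normalized channel-abundance profiles — dilution series of different
analytes should cluster apart; (2) balanced two-way ANOVA of abundance on
(channel × concentration level) — both main effects should be highly
significant if the channels are analyte-specific and concentration-dependent.
"""

import nitroquant as nq
from nitroquant.stats import pca_scores, two_way_anova

model = nq.default_signal_model()

# PCA on per-analyte dilution series
spectra = {}
for gi, group in enumerate(("TNT", "ADNT", "DNT")):
    for i, level in enumerate((5.0, 25.0, 75.0)):
        sid = f"{group}_{level:g}"
        truth = nq.SampleTruth({group: level}, sample_id=sid)
        spectra[sid] = nq.simulate_replicate_set(truth, model, 2, seed=100 + 10 * gi + i)
M = nq.abundance_matrix(spectra)
profiles = M.div(M.sum(axis=1), axis=0)
scores, loadings, explained = pca_scores(profiles, n_components=2)
print("PCA of abundance profiles:")
print(f"  explained variance: PC1 {explained[0]:.1%}, PC2 {explained[1]:.1%}")
for group in ("TNT", "ADNT", "DNT"):
    sub = scores[[sid.startswith(group) for sid, _ in scores.index]]
    print(f"  {group:<5} centroid: PC1 {sub['PC1'].mean():+.3f}, PC2 {sub['PC2'].mean():+.3f}")

# two-way ANOVA on the calibration mixture series
cal_spectra, design = nq.simulate_calibration_series(model=model, n_spots=3, seed=200)
Mcal = nq.abundance_matrix(cal_spectra)
level_of = design.drop_duplicates("sample_id").set_index("sample_id")["concentration"]
long = Mcal.stack().rename("value").reset_index()
long["level"] = long["sample_id"].map(level_of)
long = long.rename(columns={"channel_mz": "channel"})
table = two_way_anova(long, value="value", factor_a="channel", factor_b="level")
print("\nTwo-way ANOVA (abundance ~ channel × concentration level):")
for _, row in table.iterrows():
    if row["effect"] in ("channel", "level"):
        print(f"  {row['effect']:<8} F = {row['F']:8.1f}   p = {row['p']:.2e} {row['stars']}")
print(
    "\nDistinct cluster centroids per analyte and *** main effects mirror"
    "\nthe assay's specificity and concentration-dependency validation."
)
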