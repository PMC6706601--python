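"""End-to-end helpers wiring the stages into the standard workflow.

simulate → (recalibrate → TIC-normalize → extract) per spot → average →
calibrate → invert → report.  These functions are what the CLI, the examples
and the acceptance computations call; each is a thin composition of the
module-level operations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import (
    CalibrationModel,
    estimate_lod,
    fit_interference_calibration,
    fit_simple_calibration,
)
from .chem import Channel, Registry, builtin_registry
from .preprocess import (
    average_replicates,
    extract_ion_abundance,
    recalibrate_mass_axis,
    tic_normalize,
)
# Re-exported for pipeline clarity: IS normalization is performed inside
# extract_ion_abundance (ratio to the m/z 216 channel of the same spot).
normalize_to_internal_standard = extract_ion_abundance
from .quantify import GroupEstimate, invert_all_simple, invert_sequential, replicate_summary
from .spectrum import Spectrum

__all__ = [
    "process_spectra",
    "abundance_matrix",
    "fit_simple_models",
    "fit_interference_models",
    "quantify_sample",
    "normalize_to_internal_standard",
    "DEFAULT_RECAL_REFERENCES",
]

#: Axis recalibration anchors: the IS radical anion and the principal DAN
#: matrix ion, both present in every spectrum of this assay.
DEFAULT_RECAL_REFERENCES = (216.0, 156.0)


def process_spectra(
    spectra: list[Spectrum],
    registry: Registry | None = None,
    tolerance: float = 0.5,
    recalibrate: bool = True,
    references: tuple[float, ...] = DEFAULT_RECAL_REFERENCES,
) -> pd.DataFrame:
    """Per-spot channel abundances for a list of spectra (any samples)."""
    registry = registry or builtin_registry()
    channels = registry.quant_channels(include_internal_standard=False)
    frames = []
    for s in spectra:
        if recalibrate:
            s, _ = recalibrate_mass_axis(s, list(references))
        s = tic_normalize(s)
        frames.append(extract_ion_abundance(s, channels, tolerance=tolerance, is_mz=registry.is_mz))
    return pd.concat(frames, ignore_index=True)


def _averaged_by_sample(
    spectra_by_sample: dict[str, list[Spectrum]],
    registry: Registry,
    tolerance: float,
    recalibrate: bool,
) -> pd.DataFrame:
    frames = []
    for sid, spectra in spectra_by_sample.items():
        rows = process_spectra(spectra, registry, tolerance, recalibrate)
        frames.append(average_replicates(rows))
    return pd.concat(frames, ignore_index=True)


def abundance_matrix(
    spectra_by_sample: dict[str, list[Spectrum]],
    registry: Registry | None = None,
    tolerance: float = 0.5,
    recalibrate: bool = True,
) -> pd.DataFrame:
    """Spectra × channels matrix of IS-normalized abundances (one row per spot).

    Rows are indexed by (sample_id, replicate); columns by channel m/z.
    Input to the PCA / ANOVA validation stage.
    """
    registry = registry or builtin_registry()
    all_rows = []
    for spectra in spectra_by_sample.values():
        all_rows.append(process_spectra(spectra, registry, tolerance, recalibrate))
    rows = pd.concat(all_rows, ignore_index=True)
    return rows.pivot_table(
        index=["sample_id", "replicate"],
        columns="channel_mz",
        values="is_normalized",
        aggfunc="first",
    )


def fit_simple_models(
    spectra_by_sample: dict[str, list[Spectrum]],
    design: pd.DataFrame,
    registry: Registry | None = None,
    tolerance: float = 0.5,
    recalibrate: bool = True,
    lod_factor: float = 3.3,
) -> dict[float, CalibrationModel]:
    """Simple straight-line calibration for every quantification channel.

    ``design`` has rows (sample_id, analyte, concentration) with group-total
    concentrations.  Each channel is regressed on its own group's series; the
    LOD is estimated and stored where the slope is positive.
    """
    registry = registry or builtin_registry()
    channels = registry.quant_channels(include_internal_standard=False)
    averaged = _averaged_by_sample(spectra_by_sample, registry, tolerance, recalibrate)
    conc = design.set_index(["sample_id", "analyte"])["concentration"]
    models: dict[float, CalibrationModel] = {}
    for ch in channels:
        sub = averaged[averaged["channel_mz"] == ch.mz]
        x, y = [], []
        for _, row in sub.iterrows():
            key = (row["sample_id"], ch.group)
            if key in conc.index:
                x.append(float(conc.loc[key]))
                y.append(float(row["mean"]))
        if len(x) < 3:
            continue
        m = fit_simple_calibration(x, y, ch.mz, label=ch.label, group=ch.group)
        if not m.degenerate and m.slope_own > 0:
            estimate_lod(m, lod_factor)
        models[ch.mz] = m
    return models


def fit_interference_models(
    spectra_by_sample: dict[str, list[Spectrum]],
    design: pd.DataFrame,
    registry: Registry | None = None,
    channels_with_interference: tuple[float, ...] = (197.0, 181.0),
    tolerance: float = 0.5,
    recalibrate: bool = True,
    lod_factor: float = 3.3,
) -> dict[float, CalibrationModel]:
    """Bivariate (own, TNT) fits for the ADNT channels; simple fits elsewhere.

    ``design`` must contain TNT and ADNT rows per sample from a crossed grid.
    """
    registry = registry or builtin_registry()
    averaged = _averaged_by_sample(spectra_by_sample, registry, tolerance, recalibrate)
    conc = design.set_index(["sample_id", "analyte"])["concentration"]
    channels = registry.quant_channels(include_internal_standard=False)
    models: dict[float, CalibrationModel] = {}
    for ch in channels:
        sub = averaged[averaged["channel_mz"] == ch.mz]
        own, tnt, y = [], [], []
        for _, row in sub.iterrows():
            own_key = (row["sample_id"], ch.group)
            tnt_key = (row["sample_id"], "TNT")
            if own_key not in conc.index:
                continue
            own.append(float(conc.loc[own_key]))
            tnt.append(float(conc.loc[tnt_key]) if tnt_key in conc.index else 0.0)
            y.append(float(row["mean"]))
        if len(y) < 3:
            continue
        if ch.mz in channels_with_interference:
            m = fit_interference_calibration(own, tnt, y, ch.mz, label=ch.label, group=ch.group)
        else:
            if len(set(own)) < 3:
                continue
            m = fit_simple_calibration(own, y, ch.mz, label=ch.label, group=ch.group)
        if not m.degenerate and m.slope_own > 0:
            estimate_lod(m, lod_factor)
        models[ch.mz] = m
    return models


def quantify_sample(
    spectra: list[Spectrum],
    models: dict[float, CalibrationModel],
    registry: Registry | None = None,
    mode: str = "simple",
    tolerance: float = 0.5,
    recalibrate: bool = True,
    soil_mass_g: float | None = None,
    extract_volume_ml: float | None = None,
    dilution_factor: float = 1.0,
    reference: dict[str, float] | None = None,
    reference_units: str = "extract",
) -> pd.DataFrame:
    """Quantify one sample's replicate spectra; returns the summary table.

    ``mode`` is ``"simple"`` or ``"sequential"`` (TNT-first interference
    correction).  Estimates are computed per spot, then summarized
    (mean/SD/RSD) across spots; soil concentrations and reference deviations
    are attached when provenance / references are given.
    """
    if mode not in ("simple", "sequential"):
        raise ValueError(f"unknown quantification mode {mode!r}")
    registry = registry or builtin_registry()
    rows = process_spectra(spectra, registry, tolerance, recalibrate)
    per_spot: dict[int, dict[str, GroupEstimate]] = {}
    for rep, sub in rows.groupby("replicate"):
        abundances = dict(zip(sub["channel_mz"], sub["is_normalized"]))
        if mode == "sequential":
            per_spot[int(rep)] = invert_sequential(models, abundances)
        else:
            per_spot[int(rep)] = invert_all_simple(models, abundances)
    sample_id = spectra[0].sample_id if spectra else ""
    return replicate_summary(
        per_spot,
        sample_id=sample_id,
        soil_mass_g=soil_mass_g,
        extract_volume_ml=extract_volume_ml,
        dilution_factor=dilution_factor,
        reference=reference,
        reference_units=reference_units,
    )
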