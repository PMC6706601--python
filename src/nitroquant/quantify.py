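"""Inverting calibration models to concentrations, and reporting.

Two inversion modes:

* ``simple`` — every channel is inverted through its own straight-line model;
  an analyte group's estimate is the unweighted mean of its channel estimates
  (radical anion and, where present, oxygen-loss fragment).
* ``sequential`` — TNT is quantified first from its own channels, then its
  fitted contribution is subtracted from each ADNT channel before inverting
  the ADNT calibration.  TNT estimates are identical in both modes by
  construction; the correction only changes analytes whose channels carry a
  TNT cross-term.

Negative estimates are reported with a flag, never clamped: clamping would
bias replicate averages upward near the blank.  Estimates below the model's
LOD are flagged and excluded from channel averaging unless every channel is
flagged.  Soil concentrations are back-calculated from extract concentrations
through the extraction provenance (soil mass, solvent volume, dilution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel

__all__ = [
    "QuantifyError",
    "ChannelEstimate",
    "GroupEstimate",
    "invert_simple",
    "average_channel_estimates",
    "invert_sequential",
    "invert_all_simple",
    "extract_to_soil_concentration",
    "replicate_summary",
]

TNT_GROUP = "TNT"


class QuantifyError(ValueError):
    pass


@dataclass
class ChannelEstimate:
    channel_mz: float
    value: float  # ng/µL
    below_lod: bool = False
    negative: bool = False


@dataclass
class GroupEstimate:
    group: str
    value: float  # ng/µL, averaged over channels
    channels: list[ChannelEstimate] = field(default_factory=list)
    below_lod: bool = False
    negative: bool = False


def invert_simple(model: CalibrationModel, abundance: float) -> ChannelEstimate:
    """c = (A − a) / b for one channel."""
    if model.degenerate or model.slope_own <= 0:
        raise QuantifyError(
            f"channel {model.channel_mz:g} has no usable calibration slope"
        )
    c = (abundance - model.intercept) / model.slope_own
    return ChannelEstimate(
        channel_mz=model.channel_mz,
        value=float(c),
        below_lod=(model.lod is not None and c < model.lod),
        negative=c < 0,
    )


def average_channel_estimates(estimates: list[ChannelEstimate], group: str = "") -> GroupEstimate:
    """Unweighted mean over channel estimates for one analyte group.

    Below-LOD channels are excluded unless all channels are flagged, in which
    case the flagged mean is reported (with the flag).
    """
    if not estimates:
        raise QuantifyError("no channel estimates to average")
    usable = [e for e in estimates if not e.below_lod]
    all_flagged = not usable
    pool = estimates if all_flagged else usable
    value = float(np.mean([e.value for e in pool]))
    return GroupEstimate(
        group=group,
        value=value,
        channels=estimates,
        below_lod=all_flagged,
        negative=value < 0,
    )


def _group_channels(models: dict[float, CalibrationModel]) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for mz, m in sorted(models.items()):
        out.setdefault(m.group, []).append(mz)
    return out


def invert_all_simple(
    models: dict[float, CalibrationModel],
    abundances: dict[float, float],
) -> dict[str, GroupEstimate]:
    """Simple inversion of every channel, averaged per analyte group.

    Interference-kind models are inverted ignoring their TNT term (the
    simple-regression strategy applied to the same data uses the per-channel
    straight-line model, so callers should pass simple-kind models here).
    """
    out: dict[str, GroupEstimate] = {}
    for group, mzs in _group_channels(models).items():
        ests = [invert_simple(models[mz], abundances[mz]) for mz in mzs if mz in abundances]
        if ests:
            out[group] = average_channel_estimates(ests, group)
    return out


def invert_sequential(
    models: dict[float, CalibrationModel],
    abundances: dict[float, float],
) -> dict[str, GroupEstimate]:
    """TNT-first sequential inversion with interference correction.

    Step 1: TNT from its channels via simple inversion (averaged).
    Step 2: each interference-kind channel is corrected by its fitted TNT
    term, ĉ = (A − a − b_TNT·ĉ_TNT)/b_own, then averaged per group.
    Step 3: remaining analytes are simple-inverted.  Even a below-LOD TNT
    point estimate is propagated as-is — substituting 0 would bias the
    corrected analytes upward.
    """
    by_group = _group_channels(models)
    has_interference = any(m.kind == "interference" for m in models.values())
    if has_interference and TNT_GROUP not in by_group:
        raise QuantifyError("interference models present but no TNT channels to quantify first")

    out: dict[str, GroupEstimate] = {}
    c_tnt = 0.0
    if TNT_GROUP in by_group:
        tnt_ests = [
            invert_simple(models[mz], abundances[mz])
            for mz in by_group[TNT_GROUP]
            if mz in abundances
        ]
        out[TNT_GROUP] = average_channel_estimates(tnt_ests, TNT_GROUP)
        c_tnt = out[TNT_GROUP].value

    for group, mzs in by_group.items():
        if group == TNT_GROUP:
            continue
        ests = []
        for mz in mzs:
            if mz not in abundances:
                continue
            m = models[mz]
            if m.kind == "interference":
                if m.slope_own <= 0:
                    raise QuantifyError(f"channel {mz:g} has non-positive own slope")
                c = (abundances[mz] - m.intercept - (m.slope_tnt or 0.0) * c_tnt) / m.slope_own
                ests.append(
                    ChannelEstimate(
                        channel_mz=mz,
                        value=float(c),
                        below_lod=(m.lod is not None and c < m.lod),
                        negative=c < 0,
                    )
                )
            else:
                ests.append(invert_simple(m, abundances[mz]))
        if ests:
            out[group] = average_channel_estimates(ests, group)
    return out


def extract_to_soil_concentration(
    c_extract: float,
    soil_mass_g: float,
    extract_volume_ml: float,
    dilution_factor: float = 1.0,
) -> float:
    """mg/kg soil from ng/µL extract.

    ng/µL ≡ µg/mL, so µg extracted = c × V(mL) × dilution; divided by the soil
    mass in g gives µg/g ≡ mg/kg.  Exact inverse of the simulator's
    soil→extract mapping.  The standard 2 g / 4 mL preparation maps
    0.5 ng/µL ↔ 1 mg/kg.
    """
    if soil_mass_g <= 0 or extract_volume_ml <= 0:
        raise QuantifyError("soil mass and extract volume must be positive")
    if dilution_factor < 1:
        raise QuantifyError("dilution factor must be >= 1")
    return c_extract * extract_volume_ml * dilution_factor / soil_mass_g


def replicate_summary(
    per_spot: dict[int, dict[str, GroupEstimate]],
    sample_id: str = "",
    soil_mass_g: float | None = None,
    extract_volume_ml: float | None = None,
    dilution_factor: float = 1.0,
    reference: dict[str, float] | None = None,
    reference_units: str = "extract",
) -> pd.DataFrame:
    """Replicate statistics per analyte group for one sample.

    ``per_spot`` maps replicate index → group estimates.  Reports mean, SD and
    RSD% of the extract concentration over spots; RSD is defined only for a
    positive mean.  With soil provenance the mean is also expressed in mg/kg;
    with a reference (extract ng/µL or soil mg/kg, per ``reference_units``)
    the percent deviation is reported.
    """
    if not per_spot:
        raise QuantifyError("no spot estimates")
    has_soil = soil_mass_g is not None and extract_volume_ml is not None
    groups = sorted({g for ests in per_spot.values() for g in ests})
    rows = []
    for g in groups:
        vals = np.array([ests[g].value for ests in per_spot.values() if g in ests])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        rsd = 100.0 * sd / mean if vals.size > 1 and mean > 0 else np.nan
        soil = (
            extract_to_soil_concentration(mean, soil_mass_g, extract_volume_ml, dilution_factor)
            if has_soil
            else np.nan
        )
        row = {
            "sample_id": sample_id,
            "analyte": g,
            "mean_ng_per_ul": mean,
            "sd_ng_per_ul": sd,
            "rsd_pct": rsd,
            "n_spots": int(vals.size),
            "soil_mg_per_kg": soil,
            "below_lod": all(ests[g].below_lod for ests in per_spot.values() if g in ests),
            "negative": mean < 0,
            "deviation_pct": np.nan,
        }
        if reference and g in reference and reference[g] != 0:
            ref = reference[g]
            if reference_units == "soil":
                if not has_soil:
                    raise QuantifyError("soil reference given but no extraction provenance")
                # compare in soil units
                row["deviation_pct"] = 100.0 * (soil - ref) / ref
            else:
                row["deviation_pct"] = 100.0 * (mean - ref) / ref
        rows.append(row)
    return pd.DataFrame(rows)
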