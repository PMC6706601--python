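"""Seeded synthetic MALDI-TOF spectra with known ground truth.

The generator emulates the signal structure the downstream analysis assumes:

* Gaussian peaks at each analyte group's radical-anion and oxygen-loss
  channels, with areas linear in concentration (plus a TNT cross-term on the
  ADNT channels — the one interference the assay corrects for).
* A constant internal-standard (CDNT) peak at m/z 216 (fragment at 200),
  deposited at 25 ng/µL with every sample.
* DAN matrix ions at the observed m/z 156 and 157.
* A shared per-spot lognormal multiplier (crystallization/laser variability
  affecting every peak of a spot alike — the reason internal-standard
  normalization works), an independent per-peak lognormal factor, a small
  non-negative additive baseline, and a global per-spectrum mass jitter.
* Triplicate spot deposition per sample.

All randomness flows from a single master seed through documented
``numpy.random.SeedSequence`` splitting, so every output is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import Channel, IonKind, Registry, builtin_registry
from .spectrum import Spectrum, default_grid

__all__ = [
    "SignalModel",
    "SampleTruth",
    "default_signal_model",
    "expected_response",
    "render_spectrum",
    "simulate_replicate_set",
    "simulate_calibration_series",
    "simulate_interference_series",
    "simulate_soil_study",
    "soil_to_extract",
    "DEFAULT_CALIBRATION_LEVELS",
    "DEFAULT_INTERFERENCE_LEVELS",
    "IS_REFERENCE_CONCENTRATION",
]

#: The internal standard is co-deposited at this concentration (ng/µL); the
#: signal model's normalized responses are defined relative to the IS peak at
#: this level.
IS_REFERENCE_CONCENTRATION = 25.0

#: Calibration mixture levels in ng/µL. The endpoints 0 (blank) and 75 define
#: the measured series; the interior levels are this package's design choice.
DEFAULT_CALIBRATION_LEVELS = (0.0, 1.0, 5.0, 10.0, 25.0, 50.0, 75.0)

#: Levels for the TNT × ADNT interference calibration grid (full 4×4 cross).
DEFAULT_INTERFERENCE_LEVELS = (0.0, 5.0, 25.0, 75.0)


@dataclass
class SignalModel:
    """Forward model parameters for synthetic spectra.

    ``response_factor`` maps channel m/z to the slope of the IS-normalized
    abundance per ng/µL of the owning analyte group.  ``interference`` maps a
    channel m/z to per-group cross-term slopes; by default only TNT leaks into
    the ADNT channels (m/z 197 and 181).  Noise: ``spot_noise_cv`` is the CV of
    the shared per-spot lognormal multiplier, ``channel_noise_cv`` the CV of
    the independent per-peak lognormal factor, ``baseline_noise_sd`` the
    half-normal additive baseline sd as a fraction of the IS peak height, and
    ``mass_jitter_sd`` the sd (Da) of the global per-spectrum axis shift.
    """

    response_factor: dict[float, float]
    channel_group: dict[float, str]
    abbr_to_group: dict[str, str]
    interference: dict[float, dict[str, float]] = field(default_factory=dict)
    baseline_offset: dict[float, float] = field(default_factory=dict)
    matrix_peak_heights: dict[float, float] = field(
        default_factory=lambda: {156.0: 0.8, 157.0: 0.5}
    )
    is_mz: float = 216.0
    is_fragment_mz: float = 200.0
    is_fragment_ratio: float = 0.5
    is_peak_scale: float = 1000.0  # absolute intensity of the IS peak at 25 ng/µL
    peak_width_sigma: float = 0.05  # Da
    spot_noise_cv: float = 0.08
    channel_noise_cv: float = 0.03
    baseline_noise_sd: float = 1e-4  # fraction of IS peak height
    mass_jitter_sd: float = 0.1  # Da

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.response_factor.values()):
            raise ValueError("response factors must be non-negative")
        for mz, terms in self.interference.items():
            if any(k < 0 for k in terms.values()):
                raise ValueError(f"interference coefficients must be >= 0 (channel {mz})")

    def noise_free(self) -> "SignalModel":
        """A copy with every stochastic term switched off."""
        return replace(
            self,
            spot_noise_cv=0.0,
            channel_noise_cv=0.0,
            baseline_noise_sd=0.0,
            mass_jitter_sd=0.0,
        )


def default_signal_model(registry: Registry | None = None) -> SignalModel:
    """Default responses for the built-in registry.

    Radical anions respond about twice as strongly as their oxygen-loss
    fragments; NT is given the weakest response (it ionizes poorly in this
    assay).  TNB and NT fragments are dark (see the registry notes).  The TNT
    cross-term on the ADNT channels defaults to 25% of the ADNT response.
    """
    registry = registry or builtin_registry()
    channels = registry.quant_channels(include_internal_standard=False)
    base = {
        ("TNT", IonKind.RADICAL_ANION): 0.020,
        ("TNT", IonKind.OXYGEN_LOSS): 0.010,
        ("ADNT", IonKind.RADICAL_ANION): 0.018,
        ("ADNT", IonKind.OXYGEN_LOSS): 0.009,
        ("DNT", IonKind.RADICAL_ANION): 0.015,
        ("DNT", IonKind.OXYGEN_LOSS): 0.0075,
        ("DNB", IonKind.RADICAL_ANION): 0.012,
        ("DNB", IonKind.OXYGEN_LOSS): 0.006,
        ("TNB", IonKind.RADICAL_ANION): 0.016,
        ("NT", IonKind.RADICAL_ANION): 0.002,
    }
    response = {}
    groups = {}
    for ch in channels:
        r = base.get((ch.group, ch.kind))
        if r is None:
            continue
        response[ch.mz] = r
        groups[ch.mz] = ch.group
    interference = {
        197.0: {"TNT": 0.25 * base[("ADNT", IonKind.RADICAL_ANION)]},
        181.0: {"TNT": 0.25 * base[("ADNT", IonKind.OXYGEN_LOSS)]},
    }
    return SignalModel(
        response_factor=response,
        channel_group=groups,
        abbr_to_group=registry.abbr_to_group(),
        interference=interference,
        is_mz=registry.is_mz,
    )


@dataclass
class SampleTruth:
    """Ground-truth concentrations of one deposited solution.

    ``concentrations`` maps analyte abbreviations or group names to ng/µL in
    the deposited solution; members of an isomer group contribute their sum to
    the group's channels.  Optional soil provenance records how the extract
    was made (mass, solvent volume, dilution).
    """

    concentrations: dict[str, float]
    is_concentration: float = IS_REFERENCE_CONCENTRATION
    sample_id: str = "sample"
    soil_mass_g: float | None = None
    extract_volume_ml: float | None = None
    dilution_factor: float | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")
        if self.is_concentration <= 0:
            raise ValueError("internal standard concentration must be positive")

    def group_concentration(self, group: str, abbr_to_group: dict[str, str]) -> float:
        return sum(
            c for key, c in self.concentrations.items() if abbr_to_group.get(key, key) == group
        )


def expected_response(truth: SampleTruth, model: SignalModel, channel_mz: float) -> float:
    """Deterministic IS-normalized abundance at ``channel_mz``.

    Linear model: A = a + r·c(own group) + Σ κ·c(interfering group).
    """
    mz = float(channel_mz)
    if mz not in model.response_factor:
        raise KeyError(f"channel m/z {mz} not in signal model")
    a = model.baseline_offset.get(mz, 0.0)
    own = model.channel_group[mz]
    c_own = truth.group_concentration(own, model.abbr_to_group)
    value = a + model.response_factor[mz] * c_own
    for group, kappa in model.interference.get(mz, {}).items():
        value += kappa * truth.group_concentration(group, model.abbr_to_group)
    return value


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def _add_gaussian(grid: np.ndarray, intensity: np.ndarray, center: float, height: float, sigma: float) -> None:
    if height <= 0:
        return
    lo = np.searchsorted(grid, center - 8 * sigma)
    hi = np.searchsorted(grid, center + 8 * sigma)
    if hi <= lo:
        return
    x = grid[lo:hi]
    intensity[lo:hi] += height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def render_spectrum(
    truth: SampleTruth,
    model: SignalModel,
    seed: int | np.random.SeedSequence | None = None,
    replicate: int = 1,
) -> Spectrum:
    """Render one spot's spectrum from ground truth.

    Peak heights are ``expected_response × IS-peak scale × shared spot
    multiplier × per-peak multiplier``; the IS peak itself scales with the
    deposited IS concentration relative to its 25 ng/µL reference.  Draw order
    is fixed (spot multiplier, mass jitter, per-peak factors in ascending m/z,
    baseline) so a given seed always yields the same spectrum.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    grid = default_grid()
    intensity = np.zeros_like(grid)

    spot = _lognormal_factor(rng, model.spot_noise_cv)
    jitter = float(rng.normal(0.0, model.mass_jitter_sd)) if model.mass_jitter_sd > 0 else 0.0
    base = model.is_peak_scale

    # Assemble (m/z, normalized height) for every active peak.
    peaks: list[tuple[float, float]] = []
    for mz in sorted(model.response_factor):
        a = expected_response(truth, model, mz)
        if a > 0:
            peaks.append((mz, a))
    peaks.append((model.is_mz, truth.is_concentration / IS_REFERENCE_CONCENTRATION))
    peaks.append(
        (model.is_fragment_mz,
         model.is_fragment_ratio * truth.is_concentration / IS_REFERENCE_CONCENTRATION)
    )
    for mz, h in model.matrix_peak_heights.items():
        peaks.append((float(mz), h))
    peaks.sort(key=lambda p: p[0])

    for mz, a_norm in peaks:
        eps = _lognormal_factor(rng, model.channel_noise_cv)
        _add_gaussian(grid, intensity, mz + jitter, a_norm * base * spot * eps, model.peak_width_sigma)

    if model.baseline_noise_sd > 0:
        intensity += np.abs(rng.normal(0.0, model.baseline_noise_sd * base, size=grid.size))

    master = ss.entropy if isinstance(ss.entropy, int) else None
    return Spectrum(
        mz=grid,
        intensity=intensity,
        sample_id=truth.sample_id,
        replicate=replicate,
        seed=master,
        flags=("raw",),
    )


def _child_seeds(seed: int | None, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def simulate_replicate_set(
    truth: SampleTruth,
    model: SignalModel,
    n_spots: int = 3,
    seed: int | None = None,
) -> list[Spectrum]:
    """``n_spots`` spectra of one sample with independent spot multipliers."""
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    return [
        render_spectrum(truth, model, seed=ss, replicate=i + 1)
        for i, ss in enumerate(_child_seeds(seed, n_spots))
    ]


def simulate_calibration_series(
    levels: tuple[float, ...] | list[float] = DEFAULT_CALIBRATION_LEVELS,
    model: SignalModel | None = None,
    n_spots: int = 3,
    seed: int | None = None,
    analyte_groups: list[str] | None = None,
) -> tuple[dict[str, list[Spectrum]], pd.DataFrame]:
    """Calibration mixtures: every analyte group at each level, IS constant.

    Returns ``(spectra_by_sample, design)`` where the design table has one row
    per (sample, analyte group) with the group-total concentration.
    """
    levels = sorted(float(x) for x in levels)
    if not levels:
        raise ValueError("empty calibration level list")
    if any(x < 0 for x in levels):
        raise ValueError("calibration levels must be non-negative")
    model = model or default_signal_model()
    if analyte_groups is None:
        analyte_groups = sorted({g for g in model.channel_group.values()})
    spectra: dict[str, list[Spectrum]] = {}
    rows = []
    seeds = _child_seeds(seed, len(levels))
    for i, (level, ss) in enumerate(zip(levels, seeds)):
        sid = f"cal_L{i}"
        truth = SampleTruth({g: level for g in analyte_groups}, sample_id=sid)
        spectra[sid] = [
            render_spectrum(truth, model, seed=child, replicate=j + 1)
            for j, child in enumerate(ss.spawn(n_spots))
        ]
        for g in analyte_groups:
            rows.append({"sample_id": sid, "level": i, "analyte": g, "concentration": level})
    design = pd.DataFrame(rows)
    return spectra, design


def simulate_interference_series(
    tnt_levels: tuple[float, ...] = DEFAULT_INTERFERENCE_LEVELS,
    adnt_levels: tuple[float, ...] = DEFAULT_INTERFERENCE_LEVELS,
    model: SignalModel | None = None,
    n_spots: int = 3,
    seed: int | None = None,
) -> tuple[dict[str, list[Spectrum]], pd.DataFrame]:
    """Full TNT × ADNT cross for the interference calibration."""
    model = model or default_signal_model()
    spectra: dict[str, list[Spectrum]] = {}
    rows = []
    pairs = [(t, a) for t in sorted(set(tnt_levels)) for a in sorted(set(adnt_levels))]
    seeds = _child_seeds(seed, len(pairs))
    for k, ((c_tnt, c_adnt), ss) in enumerate(zip(pairs, seeds)):
        sid = f"grid_{k}"
        truth = SampleTruth({"TNT": c_tnt, "ADNT": c_adnt}, sample_id=sid)
        spectra[sid] = [
            render_spectrum(truth, model, seed=child, replicate=j + 1)
            for j, child in enumerate(ss.spawn(n_spots))
        ]
        rows.append({"sample_id": sid, "analyte": "TNT", "concentration": c_tnt})
        rows.append({"sample_id": sid, "analyte": "ADNT", "concentration": c_adnt})
    return spectra, pd.DataFrame(rows)


def soil_to_extract(
    mg_per_kg: float,
    soil_mass_g: float = 2.0,
    extract_volume_ml: float = 4.0,
    dilution_factor: float = 1.0,
) -> float:
    """Extract concentration (ng/µL) from a soil load (mg/kg).

    mg/kg soil × g soil gives µg extracted; divided by mL solvent gives µg/mL
    ≡ ng/µL; dilution divides once more.  With the standard 2 g / 4 mL
    preparation, 1 mg/kg soil ↔ 0.5 ng/µL extract.
    """
    if soil_mass_g <= 0 or extract_volume_ml <= 0:
        raise ValueError("soil mass and extract volume must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if mg_per_kg < 0:
        raise ValueError("soil concentration must be non-negative")
    return mg_per_kg * soil_mass_g / extract_volume_ml / dilution_factor


def simulate_soil_study(
    soil_truths: list[dict[str, float]],
    model: SignalModel | None = None,
    soil_mass_g: float = 2.0,
    extract_volume_ml: float = 4.0,
    dilution_factor: float = 1.0,
    n_spots: int = 3,
    seed: int | None = None,
) -> tuple[dict[str, list[Spectrum]], pd.DataFrame]:
    """Spectra for soil extracts with a ground-truth sidecar.

    ``soil_truths`` is one dict per soil sample mapping analyte group to
    mg/kg.  The sidecar records both the soil and the derived extract truth.
    """
    model = model or default_signal_model()
    spectra: dict[str, list[Spectrum]] = {}
    rows = []
    seeds = _child_seeds(seed, len(soil_truths))
    for i, (soil, ss) in enumerate(zip(soil_truths, seeds)):
        sid = f"soil_{i + 1}"
        extract = {
            g: soil_to_extract(c, soil_mass_g, extract_volume_ml, dilution_factor)
            for g, c in soil.items()
        }
        truth = SampleTruth(
            extract,
            sample_id=sid,
            soil_mass_g=soil_mass_g,
            extract_volume_ml=extract_volume_ml,
            dilution_factor=dilution_factor,
        )
        spectra[sid] = [
            render_spectrum(truth, model, seed=child, replicate=j + 1)
            for j, child in enumerate(ss.spawn(n_spots))
        ]
        for g in sorted(soil):
            rows.append(
                {
                    "sample_id": sid,
                    "analyte": g,
                    "soil_mg_per_kg": soil[g],
                    "extract_ng_per_ul": extract[g],
                    "seed": seed,
                }
            )
    return spectra, pd.DataFrame(rows)
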