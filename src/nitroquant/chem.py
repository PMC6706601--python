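"""Compound registry and mass arithmetic for negative-mode nitroaromatic analysis.

The analytes are nitroaromatic explosives (TNT, aminodinitrotoluenes,
dinitrotoluenes, trinitrobenzene, dinitrobenzene, nitrotoluene) measured as
radical anions [M]•− and, through partial in-source reduction of a nitro to a
nitroso group, as oxygen-loss fragments [M − O]•− sitting 16 Da below the
parent.  5-Chloro-2,4-dinitrotoluene (CDNT) serves as the internal standard,
1,5-diaminonaphthalene (DAN) as the MALDI matrix.

Masses are computed from molecular formulas over the element set
{C, H, N, O, Cl}.  The electron mass (≈0.0005 Da) is ignored for anion m/z
values; at the 0.5 Da extraction tolerance used downstream this is
inconsequential, and it keeps nominal channel positions at integers.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ChemFormula",
    "Compound",
    "IonKind",
    "IonSpecies",
    "Channel",
    "Registry",
    "FormulaError",
    "RegistryError",
    "parse_formula",
    "nominal_mass",
    "monoisotopic_mass",
    "ion_mz",
    "builtin_registry",
]

SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "Cl")

#: Integer mass numbers of the lightest isotopes.
NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16, "Cl": 35}

#: Exact masses of the lightest isotopes (12C = 12 by definition).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Cl": 34.96885268,
}

_HILL_ORDER = ("C", "H", "Cl", "N", "O")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


class RegistryError(ValueError):
    """Raised for inconsistent compound registries."""


@dataclass(frozen=True)
class ChemFormula:
    """Element counts over {C, H, N, O, Cl}."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    Cl: int = 0

    def __post_init__(self) -> None:
        for el in SUPPORTED_ELEMENTS:
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"element count {el}={n!r} must be a non-negative integer")

    def counts(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in SUPPORTED_ELEMENTS if getattr(self, el) > 0}

    @property
    def is_empty(self) -> bool:
        return all(getattr(self, el) == 0 for el in SUPPORTED_ELEMENTS)

    def __add__(self, other: "ChemFormula") -> "ChemFormula":
        return ChemFormula(**{el: getattr(self, el) + getattr(other, el) for el in SUPPORTED_ELEMENTS})

    def __str__(self) -> str:
        # Canonical Hill notation: C, H, then remaining elements alphabetically.
        parts = []
        for el in _HILL_ORDER:
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


def parse_formula(text: str) -> ChemFormula:
    """Parse a Hill-notation formula string such as ``"C7H5N3O6"``.

    Element symbols must come from {C, H, N, O, Cl}; an omitted count means 1.
    Raises :class:`FormulaError` naming the offending token otherwise.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {el: 0 for el in SUPPORTED_ELEMENTS}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at {text[pos:]!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {symbol!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"count for {symbol!r} must be a positive integer, got {digits!r}")
        counts[symbol] += n
        pos = m.end()
    return ChemFormula(**counts)


def nominal_mass(f: ChemFormula) -> int:
    """Integer (nominal) mass: sum of count × lightest-isotope mass number."""
    return sum(getattr(f, el) * NOMINAL_MASS[el] for el in SUPPORTED_ELEMENTS)


def monoisotopic_mass(f: ChemFormula) -> float:
    """Exact monoisotopic mass: sum of count × lightest-isotope exact mass."""
    return sum(getattr(f, el) * MONOISOTOPIC_MASS[el] for el in SUPPORTED_ELEMENTS)


class IonKind(str, enum.Enum):
    """Negative-mode ion species produced in this assay.

    ``OXYGEN_LOSS`` is the in-source-decay fragment from partial nitro→nitroso
    reduction, 16 Da below the parent.  ``OBSERVED_FIXED`` carries a literal
    observed m/z (used for the DAN matrix ions at 156/157, which arise from
    reduction chemistry that is not modelled from the formula).
    """

    RADICAL_ANION = "radical_anion"
    DEPROTONATED = "deprotonated"
    OXYGEN_LOSS = "oxygen_loss"
    DEPROTONATED_OXYGEN_LOSS = "deprotonated_oxygen_loss"
    OBSERVED_FIXED = "observed_fixed"


#: (nominal Da offset, exact Da offset) relative to the neutral molecule.
_ION_OFFSETS = {
    IonKind.RADICAL_ANION: (0, 0.0),
    IonKind.DEPROTONATED: (-1, -MONOISOTOPIC_MASS["H"]),
    IonKind.OXYGEN_LOSS: (-16, -MONOISOTOPIC_MASS["O"]),
    IonKind.DEPROTONATED_OXYGEN_LOSS: (-17, -MONOISOTOPIC_MASS["H"] - MONOISOTOPIC_MASS["O"]),
}


class Role(str, enum.Enum):
    ANALYTE = "analyte"
    INTERNAL_STANDARD = "internal_standard"
    MATRIX = "matrix"
    MASS_CALIBRANT = "mass_calibrant"


@dataclass(frozen=True)
class Compound:
    """A registered chemical species.

    ``isomer_group`` names the analyte group reported downstream: positional
    isomers (2-/4-ADNT; 2,4-/2,6-DNT) share one group because the assay cannot
    distinguish them, so environmental results are isomer sums.
    """

    name: str
    abbreviation: str
    formula: ChemFormula
    role: Role
    isomer_group: str | None = None
    fixed_mzs: tuple[float, ...] = ()

    @property
    def group(self) -> str:
        """Reporting group: the isomer group if any, else the abbreviation."""
        return self.isomer_group or self.abbreviation


@dataclass(frozen=True)
class IonSpecies:
    compound: str  # abbreviation
    kind: IonKind
    nominal_mz: float
    monoisotopic_mz: float
    charge: int = -1


@dataclass(frozen=True)
class Channel:
    """A targeted extraction channel: one analyte group at one ion species."""

    group: str
    kind: IonKind
    mz: float
    monoisotopic_mz: float

    @property
    def label(self) -> str:
        tag = {
            IonKind.RADICAL_ANION: "[M]·-",
            IonKind.DEPROTONATED: "[M-H]-",
            IonKind.OXYGEN_LOSS: "[M-O]·-",
            IonKind.DEPROTONATED_OXYGEN_LOSS: "[M-H-O]-",
            IonKind.OBSERVED_FIXED: "(obs)",
        }[self.kind]
        return f"{self.group} {tag} {self.mz:g}"


def ion_mz(compound: Compound, kind: IonKind, resolution: str = "nominal") -> float:
    """m/z of the given ion species of ``compound``.

    ``resolution`` is ``"nominal"`` (integer mass numbers) or
    ``"monoisotopic"``.  The electron mass is ignored by contract.
    """
    if kind is IonKind.OBSERVED_FIXED:
        if not compound.fixed_mzs:
            raise RegistryError(f"{compound.abbreviation} has no observed fixed m/z values")
        # A compound may carry several observed ions; callers wanting all of
        # them should read Compound.fixed_mzs. Return the first (principal).
        return compound.fixed_mzs[0]
    if resolution == "nominal":
        return nominal_mass(compound.formula) + _ION_OFFSETS[kind][0]
    if resolution == "monoisotopic":
        return monoisotopic_mass(compound.formula) + _ION_OFFSETS[kind][1]
    raise ValueError(f"unknown resolution {resolution!r}")


#: Channel kinds used for quantification, per analyte group. Groups whose
#: oxygen-loss fragment is not observed in the assay (TNB, NT) — or whose
#: fragment would collide with another group's parent ion (TNB − O would sit
#: on the ADNT radical anion at m/z 197) — quantify on the parent ion alone.
_QUANT_KINDS: dict[str, tuple[IonKind, ...]] = {
    "TNT": (IonKind.RADICAL_ANION, IonKind.OXYGEN_LOSS),
    "ADNT": (IonKind.RADICAL_ANION, IonKind.OXYGEN_LOSS),
    "DNT": (IonKind.RADICAL_ANION, IonKind.OXYGEN_LOSS),
    "DNB": (IonKind.RADICAL_ANION, IonKind.OXYGEN_LOSS),
    "TNB": (IonKind.RADICAL_ANION,),
    "NT": (IonKind.RADICAL_ANION,),
    "CDNT": (IonKind.RADICAL_ANION, IonKind.OXYGEN_LOSS),
}


class Registry:
    """A set of compounds plus the ion channels the assay extracts."""

    def __init__(self, compounds: Iterable[Compound]):
        self.compounds: dict[str, Compound] = {}
        for c in compounds:
            if c.abbreviation in self.compounds:
                raise RegistryError(f"duplicate abbreviation {c.abbreviation!r}")
            self.compounds[c.abbreviation] = c
        standards = [c for c in self.compounds.values() if c.role is Role.INTERNAL_STANDARD]
        if len(standards) != 1:
            raise RegistryError(
                f"exactly one internal standard required, found {len(standards)}"
            )
        self._internal_standard = standards[0]

    @property
    def internal_standard(self) -> Compound:
        return self._internal_standard

    @property
    def is_mz(self) -> float:
        """Normalization channel: the internal standard's radical anion (m/z 216)."""
        return ion_mz(self._internal_standard, IonKind.RADICAL_ANION)

    def __getitem__(self, abbreviation: str) -> Compound:
        return self.compounds[abbreviation]

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self.compounds

    def __iter__(self):
        return iter(self.compounds.values())

    def analytes(self) -> list[Compound]:
        return [c for c in self.compounds.values() if c.role is Role.ANALYTE]

    def analyte_groups(self) -> list[str]:
        seen: list[str] = []
        for c in self.analytes():
            if c.group not in seen:
                seen.append(c.group)
        return seen

    def group_members(self, group: str) -> list[Compound]:
        return [c for c in self.analytes() if c.group == group] + (
            [self._internal_standard] if self._internal_standard.group == group else []
        )

    def abbr_to_group(self) -> dict[str, str]:
        """Mapping from compound abbreviation (and group name) to group name."""
        out: dict[str, str] = {}
        for c in list(self.analytes()) + [self._internal_standard]:
            out[c.abbreviation] = c.group
            out[c.group] = c.group
        return out

    def _group_formula(self, group: str) -> ChemFormula:
        members = self.group_members(group)
        formulas = {str(m.formula) for m in members}
        if len(formulas) != 1:
            raise RegistryError(f"isomer group {group!r} mixes formulas {formulas}")
        return members[0].formula

    def ion_species(self) -> list[IonSpecies]:
        """All ion species every compound produces (registry exposure)."""
        out: list[IonSpecies] = []
        for c in self.compounds.values():
            if c.fixed_mzs:
                for mz in c.fixed_mzs:
                    out.append(IonSpecies(c.abbreviation, IonKind.OBSERVED_FIXED, mz, mz))
                continue
            if c.role in (Role.ANALYTE, Role.INTERNAL_STANDARD):
                for kind in (IonKind.RADICAL_ANION, IonKind.OXYGEN_LOSS):
                    out.append(
                        IonSpecies(
                            c.abbreviation,
                            kind,
                            ion_mz(c, kind, "nominal"),
                            ion_mz(c, kind, "monoisotopic"),
                        )
                    )
        return out

    def quant_channels(self, include_internal_standard: bool = True) -> list[Channel]:
        """The targeted channels used for quantification, one per group × kind."""
        out: list[Channel] = []
        groups = self.analyte_groups()
        if include_internal_standard:
            groups = groups + [self._internal_standard.group]
        for g in groups:
            f = self._group_formula(g)
            for kind in _QUANT_KINDS.get(g, (IonKind.RADICAL_ANION,)):
                nom, exact = _ION_OFFSETS[kind]
                out.append(Channel(g, kind, nominal_mass(f) + nom, monoisotopic_mass(f) + exact))
        return sorted(out, key=lambda ch: ch.mz)

    def matrix_mzs(self) -> list[float]:
        out: list[float] = []
        for c in self.compounds.values():
            if c.role is Role.MATRIX and c.fixed_mzs:
                out.extend(c.fixed_mzs)
        return sorted(out)

    # -- CSV serialization ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["abbreviation", "name", "formula", "role", "isomer_group", "channels"])
            for c in self.compounds.values():
                if c.fixed_mzs:
                    chans = ";".join(f"observed_fixed:{mz:g}" for mz in c.fixed_mzs)
                elif c.role in (Role.ANALYTE, Role.INTERNAL_STANDARD):
                    chans = ";".join(
                        f"{k.value}:{ion_mz(c, k):g}"
                        for k in (IonKind.RADICAL_ANION, IonKind.OXYGEN_LOSS)
                    )
                else:
                    chans = ""
                w.writerow(
                    [c.abbreviation, c.name, str(c.formula), c.role.value, c.isomer_group or "", chans]
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Registry":
        import csv

        compounds: list[Compound] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                fixed: tuple[float, ...] = ()
                chans = row.get("channels", "")
                if "observed_fixed" in chans:
                    fixed = tuple(
                        float(tok.split(":")[1])
                        for tok in chans.split(";")
                        if tok.startswith("observed_fixed:")
                    )
                compounds.append(
                    Compound(
                        name=row["name"],
                        abbreviation=row["abbreviation"],
                        formula=parse_formula(row["formula"]),
                        role=Role(row["role"]),
                        isomer_group=row["isomer_group"] or None,
                        fixed_mzs=fixed,
                    )
                )
        return cls(compounds)


def builtin_registry() -> Registry:
    """The assay's standard compound set.

    Analytes and the CDNT internal standard carry radical-anion and
    oxygen-loss channels; DAN matrix ions are stored as the observed literals
    m/z 156/157 rather than computed from C10H10N2 (nominal 158), because they
    arise from reduction chemistry at the amino groups.  Mass calibrants are
    the self-made calibration mixture components.
    """
    F = parse_formula
    return Registry(
        [
            Compound("2,4,6-trinitrotoluene", "TNT", F("C7H5N3O6"), Role.ANALYTE),
            Compound("2-amino-4,6-dinitrotoluene", "2-ADNT", F("C7H7N3O4"), Role.ANALYTE, "ADNT"),
            Compound("4-amino-2,6-dinitrotoluene", "4-ADNT", F("C7H7N3O4"), Role.ANALYTE, "ADNT"),
            Compound("2,4-dinitrotoluene", "2,4-DNT", F("C7H6N2O4"), Role.ANALYTE, "DNT"),
            Compound("2,6-dinitrotoluene", "2,6-DNT", F("C7H6N2O4"), Role.ANALYTE, "DNT"),
            Compound("1,3,5-trinitrobenzene", "TNB", F("C6H3N3O6"), Role.ANALYTE),
            Compound("1,3-dinitrobenzene", "DNB", F("C6H4N2O4"), Role.ANALYTE),
            Compound("2-nitrotoluene", "NT", F("C7H7NO2"), Role.ANALYTE),
            Compound(
                "5-chloro-2,4-dinitrotoluene", "CDNT", F("C7H5ClN2O4"), Role.INTERNAL_STANDARD
            ),
            Compound(
                "1,5-diaminonaphthalene", "DAN", F("C10H10N2"), Role.MATRIX,
                fixed_mzs=(156.0, 157.0),
            ),
            Compound("9-aminoacridine", "AA", F("C13H10N2"), Role.MATRIX),
            # Paper-screened alternative matrix; its often-quoted 188 g/mol is
            # at odds with the formula (nominal 189). Stored computed.
            Compound("alpha-cyano-4-hydroxycinnamic acid", "CHCA", F("C10H7NO3"), Role.MATRIX),
            Compound("mefenamic acid", "MEF", F("C15H15NO2"), Role.MASS_CALIBRANT),
            Compound("citric acid", "CIT", F("C6H8O7"), Role.MASS_CALIBRANT),
            Compound("chlorogenic acid", "CGA", F("C16H18O9"), Role.MASS_CALIBRANT),
        ]
    )
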