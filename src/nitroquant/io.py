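"""Spectrum and table file formats, plus run configuration.

Spectra travel as two-column CSV (m/z, intensity; metadata in ``#`` header
comments) or mzML.  The mzML support is a compact reader/writer pair for the
format's profile-spectrum core (64/32-bit float binary arrays, zlib or no
compression); its output is cross-checked against an independent mzML
implementation in the test suite.  Non-uniform m/z axes are resampled onto
the standard acquisition grid by linear interpolation with a logged warning.
"""

from __future__ import annotations

import base64
import hashlib
import json
import logging
import re
import struct
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import yaml

from .simulate import (
    DEFAULT_CALIBRATION_LEVELS,
    DEFAULT_INTERFERENCE_LEVELS,
    IS_REFERENCE_CONCENTRATION,
)
from .spectrum import Spectrum, default_grid

log = logging.getLogger("nitroquant")

__all__ = [
    "SpectrumIOError",
    "read_spectrum",
    "read_spectra_mzml",
    "write_spectrum_csv",
    "write_spectra_mzml",
    "RunConfig",
]


class SpectrumIOError(ValueError):
    pass


_ID_RE = re.compile(r"sample=(?P<sample>[^ ]*) spot=(?P<spot>\d+)")


def _validate_axes(mz: np.ndarray, intensity: np.ndarray, path) -> Spectrum | None:
    if np.any(np.diff(mz) <= 0):
        raise SpectrumIOError(f"{path}: m/z axis is not strictly increasing")
    if np.any(intensity < 0):
        raise SpectrumIOError(f"{path}: negative intensities")
    return None


def _to_spectrum(mz, intensity, path, sample_id="", replicate=1, flags=("raw",)) -> Spectrum:
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size != intensity.size or mz.size < 2:
        raise SpectrumIOError(f"{path}: need two equal-length numeric columns")
    _validate_axes(mz, intensity, path)
    d = np.diff(mz)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        log.warning("%s: non-uniform m/z axis; resampling onto the standard grid", path)
        grid = default_grid()
        intensity = np.interp(grid, mz, intensity, left=0.0, right=0.0)
        mz = grid
    return Spectrum(mz=mz, intensity=intensity, sample_id=sample_id,
                    replicate=replicate, flags=tuple(flags))


def read_spectrum(path: str | Path, fmt: str | None = None) -> Spectrum:
    """Read one spectrum from CSV or mzML (format inferred from the suffix)."""
    path = Path(path)
    fmt = fmt or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "mzml":
        spectra = read_spectra_mzml(path)
        if not spectra:
            raise SpectrumIOError(f"{path}: no spectra found")
        return spectra[0]
    if fmt != "csv":
        raise SpectrumIOError(f"unknown format {fmt!r}")
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line.lstrip("# ").split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumIOError(f"{path}: expected two comma-separated columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if not rows:  # tolerate one header line
                    continue
                raise SpectrumIOError(f"{path}: non-numeric data row {line!r}")
    if not rows:
        raise SpectrumIOError(f"{path}: no data rows")
    mz, intensity = (np.array(col) for col in zip(*rows))
    return _to_spectrum(
        mz, intensity, path,
        sample_id=meta.get("sample_id", path.stem),
        replicate=int(meta.get("replicate", 1)),
        flags=tuple(meta["flags"].split(";")) if meta.get("flags") else ("raw",),
    )


def write_spectrum_csv(s: Spectrum, path: str | Path, extra_meta: dict | None = None) -> None:
    """Two-column CSV with metadata comments; full float precision (%.17g)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id={s.sample_id}\n# replicate={s.replicate}\n")
        if s.seed is not None:
            fh.write(f"# seed={s.seed}\n")
        if s.flags:
            fh.write(f"# flags={';'.join(s.flags)}\n")
        for k, v in (extra_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("mz,intensity\n")
        for m, i in zip(s.mz, s.intensity):
            fh.write(f"{m:.17g},{i:.17g}\n")


# -- minimal mzML writing ----------------------------------------------------

def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{values.size}d", *values)).decode()


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="nitroquant_run">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="sample={sample} spot={spot}" defaultArrayLength="{length}">
        <cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_spectra_mzml(spectra: list[Spectrum], path: str | Path) -> None:
    """Serialize spectra to mzML (one <spectrum> per spot)."""
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(count=len(spectra)))
        for i, s in enumerate(spectra):
            mz_b64 = _encode_array(s.mz)
            int_b64 = _encode_array(s.intensity)
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i,
                    sample=escape(s.sample_id or "sample", {'"': "&quot;"}),
                    spot=s.replicate,
                    length=s.mz.size,
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_MZML_FOOTER)


def _decode_binary_array(bda, ns: str) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    dtype = "<d"
    compressed = False
    kind = None
    for cv in bda.findall(f"{ns}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f"
        elif acc == "MS:1000523":
            dtype = "<d"
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
    node = bda.find(f"{ns}binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_spectra_mzml(path: str | Path) -> list[Spectrum]:
    """Read all spectra from an mzML file.

    Supports the format's profile-spectrum core: 64- or 32-bit float m/z and
    intensity arrays, zlib-compressed or uncompressed.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    out: list[Spectrum] = []
    for spec in root.iter(f"{ns}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            kind, values = _decode_binary_array(bda, ns)
            if kind:
                arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumIOError(f"{path}: spectrum without m/z or intensity array")
        sid = spec.get("id", "")
        m = _ID_RE.search(sid)
        sample = m.group("sample") if m else sid
        spot = int(m.group("spot")) if m else 1
        out.append(
            _to_spectrum(arrays["mz"], arrays["intensity"], path,
                         sample_id=sample, replicate=spot)
        )
    if not out:
        raise SpectrumIOError(f"{path}: no spectra found")
    return out


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of one simulated study / analysis run."""

    seed: int = 0
    calibration_levels: tuple[float, ...] = DEFAULT_CALIBRATION_LEVELS
    interference_levels: tuple[float, ...] = DEFAULT_INTERFERENCE_LEVELS
    n_spots: int = 3
    extraction_tolerance: float = 0.5
    lod_factor: float = 3.3
    is_concentration: float = IS_REFERENCE_CONCENTRATION
    soil_mass_g: float = 2.0
    extract_volume_ml: float = 4.0
    dilution_factor: float = 1.0
    spot_noise_cv: float = 0.08
    channel_noise_cv: float = 0.03
    baseline_noise_sd: float = 1e-4
    mass_jitter_sd: float = 0.1
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.extraction_tolerance <= 0:
            raise ValueError("extraction tolerance must be positive")
        if self.soil_mass_g <= 0 or self.extract_volume_ml <= 0:
            raise ValueError("soil mass and extract volume must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
        for name in ("spot_noise_cv", "channel_noise_cv", "baseline_noise_sd",
                     "mass_jitter_sd", "lod_factor", "is_concentration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("calibration_levels", "interference_levels"):
            if key in raw:
                raw[key] = tuple(float(x) for x in raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("calibration_levels", "interference_levels"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
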