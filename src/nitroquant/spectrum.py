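"""The in-memory spectrum container used throughout the pipeline.

A spectrum is a uniform m/z grid (default 120–300 Da, 0.01 Da step, matching
a negative-mode reflectron acquisition window for these analytes) with
non-negative intensities plus acquisition metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MZ_MIN = 120.0
MZ_MAX = 300.0
MZ_STEP = 0.01

__all__ = ["Spectrum", "default_grid", "MZ_MIN", "MZ_MAX", "MZ_STEP"]


def default_grid() -> np.ndarray:
    """The standard acquisition grid: 120–300 Da at 0.01 Da spacing."""
    n = int(round((MZ_MAX - MZ_MIN) / MZ_STEP)) + 1
    return np.linspace(MZ_MIN, MZ_MAX, n)


@dataclass
class Spectrum:
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int = 1
    seed: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if self.mz.size != self.intensity.size:
            raise ValueError(
                f"length mismatch: {self.mz.size} m/z values vs {self.intensity.size} intensities"
            )
        if self.mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        d = np.diff(self.mz)
        if np.any(d <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("m/z axis must be uniform")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def has_flag(self, flag: str) -> bool:
        return flag in self.flags

    def with_intensity(self, intensity: np.ndarray, add_flag: str | None = None) -> "Spectrum":
        flags = self.flags + (add_flag,) if add_flag and add_flag not in self.flags else self.flags
        return replace(self, intensity=np.asarray(intensity, dtype=float), flags=flags)
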