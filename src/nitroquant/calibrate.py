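"""Per-channel calibration: ordinary least squares on IS-normalized abundance.

Two model kinds mirror the assay's two calibration strategies:

* ``simple`` — abundance vs. the owning analyte's concentration (classical
  linear least squares), one model per channel including the fragment
  channels.
* ``interference`` — abundance vs. (own concentration, TNT concentration) for
  the ADNT channels, fitted on a TNT × ADNT cross design; this captures the
  leakage of TNT signal into the ADNT channels.

The detection limit uses the ICH-style formula LOD = 3.3 × residual SD /
slope.  Fits are unweighted by default (a 1/x weighting switch exists); blank
(0 ng/µL) points are included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "CollinearityError",
    "CalibrationModel",
    "fit_simple_calibration",
    "fit_interference_calibration",
    "estimate_lod",
    "models_to_frame",
    "save_models",
    "load_models",
    "LOD_FACTOR",
]

LOD_FACTOR = 3.3


class CalibrationError(ValueError):
    pass


class CollinearityError(CalibrationError):
    pass


@dataclass
class CalibrationModel:
    channel_mz: float
    label: str
    group: str
    kind: str  # "simple" | "interference"
    intercept: float
    slope_own: float
    slope_tnt: float | None
    resid_sd: float
    r2: float
    range_min: float
    range_max: float
    n_points: int
    lod: float | None = None
    degenerate: bool = False

    def predict(self, c_own: float, c_tnt: float = 0.0) -> float:
        y = self.intercept + self.slope_own * c_own
        if self.kind == "interference":
            y += (self.slope_tnt or 0.0) * c_tnt
        return y


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least squares fit; returns (coefficients, residual SD, R²).

    Residual SD uses n − p degrees of freedom; R² is relative to the mean.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    resid_sd = float(np.sqrt(ssr / (n - p))) if n > p else 0.0
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    return beta, resid_sd, max(0.0, min(1.0, r2))


def _calibration_range(conc: np.ndarray) -> tuple[float, float]:
    nonzero = conc[conc > 0]
    lo = float(nonzero.min()) if nonzero.size else 0.0
    return lo, float(conc.max())


def fit_simple_calibration(
    concentrations,
    abundances,
    channel_mz: float,
    label: str = "",
    group: str = "",
    weights: str | None = None,
) -> CalibrationModel:
    """Unweighted OLS of mean normalized abundance on concentration.

    Requires ≥3 distinct concentration levels.  A constant-abundance design is
    degenerate (no slope information): the model is returned flagged, with
    slope 0, R² 0 and undefined LOD.  ``weights="1/x"`` enables inverse-
    concentration weighting (off by default).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if c.size != y.size:
        raise CalibrationError("concentration and abundance lengths differ")
    if np.unique(c).size < 3:
        raise CalibrationError("need at least 3 distinct concentration levels")
    if np.ptp(c) == 0:
        raise CalibrationError("zero concentration variance")
    rng_min, rng_max = _calibration_range(c)
    if np.ptp(y) == 0:
        return CalibrationModel(
            channel_mz=float(channel_mz), label=label, group=group, kind="simple",
            intercept=float(y[0]), slope_own=0.0, slope_tnt=None,
            resid_sd=0.0, r2=0.0, range_min=rng_min, range_max=rng_max,
            n_points=int(c.size), lod=None, degenerate=True,
        )
    X = np.column_stack([np.ones_like(c), c])
    if weights == "1/x":
        w = np.where(c > 0, 1.0 / np.sqrt(c), 1.0)
        beta, resid_sd, r2 = _ols(X * w[:, None], y * w)
    elif weights is None:
        beta, resid_sd, r2 = _ols(X, y)
    else:
        raise CalibrationError(f"unknown weighting {weights!r}")
    return CalibrationModel(
        channel_mz=float(channel_mz), label=label, group=group, kind="simple",
        intercept=float(beta[0]), slope_own=float(beta[1]), slope_tnt=None,
        resid_sd=resid_sd, r2=r2, range_min=rng_min, range_max=rng_max,
        n_points=int(c.size),
    )


def fit_interference_calibration(
    c_own,
    c_tnt,
    abundances,
    channel_mz: float,
    label: str = "",
    group: str = "",
) -> CalibrationModel:
    """Bivariate classical least squares: A = a + b_own·c_own + b_TNT·c_TNT.

    Requires ≥6 points and a full-rank [1, c_own, c_TNT] design; perfectly
    collinear own/TNT concentrations are rejected by name.
    """
    co = np.asarray(c_own, dtype=float)
    ct = np.asarray(c_tnt, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if not (co.size == ct.size == y.size):
        raise CalibrationError("design column lengths differ")
    if co.size < 6:
        raise CalibrationError("need at least 6 design points for the interference fit")
    X = np.column_stack([np.ones_like(co), co, ct])
    if np.linalg.matrix_rank(X) < 3:
        raise CollinearityError(
            "design is rank-deficient: own-analyte and TNT concentrations are "
            "collinear (vary them independently, e.g. on a full cross)"
        )
    beta, resid_sd, r2 = _ols(X, y)
    rng_min, rng_max = _calibration_range(co)
    return CalibrationModel(
        channel_mz=float(channel_mz), label=label, group=group, kind="interference",
        intercept=float(beta[0]), slope_own=float(beta[1]), slope_tnt=float(beta[2]),
        resid_sd=resid_sd, r2=r2, range_min=rng_min, range_max=rng_max,
        n_points=int(co.size),
    )


def estimate_lod(model: CalibrationModel, factor: float = LOD_FACTOR) -> float:
    """ICH-style detection limit 3.3 × residual SD / slope, stored on the model."""
    if model.degenerate or model.slope_own <= 0:
        raise CalibrationError(
            f"LOD undefined for channel {model.channel_mz:g}: non-positive slope"
        )
    lod = factor * model.resid_sd / model.slope_own
    model.lod = float(lod)
    return model.lod


# -- serialization -----------------------------------------------------------

_COLUMNS = [
    "channel_mz", "label", "group", "kind", "intercept", "slope_own", "slope_tnt",
    "resid_sd", "r2", "range_min", "range_max", "n_points", "lod", "degenerate",
]


def models_to_frame(models: dict[float, CalibrationModel]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in models.values()])[_COLUMNS].sort_values(
        "channel_mz", ignore_index=True
    )


def save_models(models: dict[float, CalibrationModel], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps([asdict(m) for m in models.values()], indent=1))
    else:
        models_to_frame(models).to_csv(path, index=False)


def load_models(path: str | Path) -> dict[float, CalibrationModel]:
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, comment="#")
        records = df.to_dict("records")
    out: dict[float, CalibrationModel] = {}
    for r in records:
        r = {k: r.get(k) for k in _COLUMNS}
        for key in ("slope_tnt", "lod"):
            if r[key] is not None and pd.isna(r[key]):
                r[key] = None
        r["degenerate"] = bool(r["degenerate"])
        m = CalibrationModel(**r)
        out[m.channel_mz] = m
    return out
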