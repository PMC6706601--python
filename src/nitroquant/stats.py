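"""Specificity and concentration-dependency checks.

Two classical procedures validate that channel abundances are analyte-specific
and concentration-dependent:

* PCA of the spectra's IS-normalized channel-abundance profiles — spectra of
  different analytes at increasing concentration should occupy distinct
  regions of the score plot.
* Balanced two-way ANOVA with interaction on the abundance matrix, testing
  the channel and concentration-level main effects.

Both are implemented from their textbook definitions (column-centered
covariance eigendecomposition; classical sums-of-squares partition) so they
can be cross-checked against independent library implementations in tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatsError", "pca_scores", "two_way_anova", "significance_stars"]


class StatsError(ValueError):
    pass


def pca_scores(
    M: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
    scale: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Principal components of an abundance matrix (rows = spectra).

    Columns are centered (and optionally scaled to unit variance; off by
    default since IS-normalized abundances share a scale).  Components come
    from the eigendecomposition of the covariance matrix, ordered by
    decreasing variance, with a deterministic sign convention: the
    largest-magnitude loading of each component is positive.

    Returns (scores, loadings, explained-variance fractions); fractions over
    all components sum to 1.
    """
    df = M if isinstance(M, pd.DataFrame) else pd.DataFrame(np.asarray(M, dtype=float))
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise StatsError("need at least 2 rows and 2 columns")
    if np.isnan(X).any():
        raise StatsError("abundance matrix must be complete")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise StatsError("cannot scale constant columns")
        Xc = Xc / sd
    total_var = float((Xc ** 2).sum() / (n - 1))
    if total_var == 0:
        raise StatsError("constant matrix: zero total variance")
    cov = Xc.T @ Xc / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):  # deterministic sign
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    k = n_components if n_components is not None else min(n - 1, p)
    k = min(k, p)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(Xc @ eigvec[:, :k], index=df.index, columns=comp_names)
    loadings = pd.DataFrame(eigvec[:, :k], index=df.columns, columns=comp_names)
    explained = eigval[:k] / total_var
    return scores, loadings, explained


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "channel",
    factor_b: str = "level",
) -> pd.DataFrame:
    """Balanced two-way ANOVA with interaction (classical sums of squares).

    Requires a complete, balanced design: every (A, B) cell with the same
    number of replicates r ≥ 2 and at least two levels per factor.  Returns a
    table with rows for each main effect, the interaction, residual and total:
    columns ``sum_sq``, ``df``, ``mean_sq``, ``F``, ``p``, ``stars``.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise StatsError(f"missing column {col!r}")
    if data[value].isna().any():
        raise StatsError("response contains missing values")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    a_levels = data[factor_a].unique()
    b_levels = data[factor_b].unique()
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise StatsError("need at least two levels per factor")
    if len(counts) != a * b:
        raise StatsError("incomplete design: some factor cells are empty")
    if counts.nunique() != 1:
        raise StatsError("unbalanced design: unequal replicates per cell")
    r = int(counts.iloc[0])
    if r < 2:
        raise StatsError("need at least 2 replicates per cell for the interaction test")

    y = data[value].to_numpy(dtype=float)
    grand = y.mean()
    mean_a = data.groupby(factor_a, observed=True)[value].mean()
    mean_b = data.groupby(factor_b, observed=True)[value].mean()
    mean_ab = data.groupby([factor_a, factor_b], observed=True)[value].mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_a = r * b * float(((mean_a - grand) ** 2).sum())
    ss_b = r * a * float(((mean_b - grand) ** 2).sum())
    dev_ab = (
        mean_ab
        - mean_a.reindex(mean_ab.index.get_level_values(0)).to_numpy()
        - mean_b.reindex(mean_ab.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ab = r * float((dev_ab ** 2).sum())
    ss_resid = ss_total - ss_a - ss_b - ss_ab

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_resid = a * b * (r - 1)
    ms_resid = ss_resid / df_resid

    def _row(name, ss, dof):
        ms = ss / dof
        if ms_resid > 0:
            F = ms / ms_resid
            p = float(sps.f.sf(F, dof, df_resid))
        else:
            F, p = 0.0, 1.0
        return {"effect": name, "sum_sq": ss, "df": dof, "mean_sq": ms, "F": F, "p": p}

    rows = [
        _row(factor_a, ss_a, df_a),
        _row(factor_b, ss_b, df_b),
        _row(f"{factor_a}:{factor_b}", ss_ab, df_ab),
        {"effect": "residual", "sum_sq": ss_resid, "df": df_resid,
         "mean_sq": ms_resid, "F": np.nan, "p": np.nan},
        {"effect": "total", "sum_sq": ss_total, "df": a * b * r - 1,
         "mean_sq": np.nan, "F": np.nan, "p": np.nan},
    ]
    out = pd.DataFrame(rows)
    out["stars"] = [significance_stars(p) if np.isfinite(p) else "" for p in out["p"]]
    return out


def significance_stars(p: float) -> str:
    """Conventional significance marks (*** for p < 0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
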