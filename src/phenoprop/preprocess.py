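"""Outlier screening and 0-1 standardization of descriptor tables.

Screening uses a k-nearest-neighbour multivariate outlyingness score on
z-scaled descriptors with a Tukey upper-fence flagging rule; flagged units
are reported, never silently dropped. Min-max standardization maps every
descriptor to [0, 1], with out-of-range values (e.g. hybrid observations
beyond the parental range when scaling is fitted on a subset) clipped and
counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ScaledPanel",
    "outlier_scores",
    "flag_outliers",
    "minmax_standardize",
    "screen_and_scale",
]

_META_COLS = ("unit_id", "class_label")


def _feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    return table[[c for c in table.columns if c not in _META_COLS]]


@dataclass
class ScaledPanel:
    """A descriptor table standardized to [0, 1].

    ``scaling`` holds the per-descriptor (min, max) of the fitting subset;
    ``n_clipped`` counts values that fell outside the fitted range and were
    clipped into [0, 1].
    """

    values: pd.DataFrame
    scaling: dict[str, tuple[float, float]]
    n_clipped: int = 0
    fit_on: str = "all"

    @property
    def descriptors(self) -> list[str]:
        return list(self.scaling)


def outlier_scores(table: pd.DataFrame, k: int | None = None) -> pd.Series:
    """Multivariate outlyingness score per unit: mean Euclidean distance to
    the k nearest neighbours, on per-descriptor z-scaled values.

    Constant descriptors carry no information and are dropped with a
    warning before scoring. The default ``k`` is min(10, n - 1). Scores are
    invariant to per-descriptor affine rescaling because of the internal
    z-scaling.
    """
    x = _feature_frame(table).to_numpy(dtype=float)
    n = x.shape[0]
    if n == 0:
        return pd.Series([], dtype=float, index=table.index)
    if k is None:
        k = min(10, n - 1)
    if not 1 <= k <= n - 1:
        raise ValueError(f"need 1 <= k <= n-1, got k={k}, n={n}")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, kp in zip(_feature_frame(table).columns, keep) if not kp]
        warnings.warn(
            f"dropping constant descriptor(s) before outlier scoring: {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("all descriptors are constant; cannot score outliers")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    dist, _ = nn.kneighbors(z)
    # first neighbour is the point itself (distance 0)
    return pd.Series(dist[:, 1:].mean(axis=1), index=table.index, name="outlier_score")


def flag_outliers(scores: pd.Series, rule: str = "tukey", factor: float = 1.5) -> pd.Series:
    """Flag units whose score exceeds the Tukey upper fence Q3 + factor*IQR.

    Returns a boolean Series aligned with ``scores``; with equal scores no
    unit is flagged, and an empty input yields an empty flag vector.
    """
    scores = pd.Series(scores, dtype=float)
    if rule != "tukey":
        raise ValueError(f"unknown outlier rule {rule!r}")
    if (scores < 0).any():
        raise ValueError("outlier scores must be nonnegative")
    if scores.empty:
        return pd.Series([], dtype=bool, index=scores.index)
    q1, q3 = scores.quantile([0.25, 0.75])
    fence = q3 + factor * (q3 - q1)
    return scores > fence


def minmax_standardize(
    table: pd.DataFrame, fit_on: pd.Series | np.ndarray | None = None
) -> ScaledPanel:
    """Standardize every descriptor to [0, 1] by min-max scaling.

    ``fit_on`` is an optional boolean selector of the units used to fit the
    per-descriptor (min, max); values outside the fitted range are clipped
    and counted. By default the scaling is fitted on all rows (parents and
    hybrid jointly).

    Raises
    ------
    ValueError
        Naming the descriptor, if one is constant on the fitting subset.
    """
    feats = _feature_frame(table)
    fit_mask = (
        np.ones(len(table), dtype=bool) if fit_on is None else np.asarray(fit_on, bool)
    )
    if fit_mask.sum() == 0:
        raise ValueError("fit_on selects no units")
    scaling: dict[str, tuple[float, float]] = {}
    out = table.copy()
    n_clipped = 0
    for col in feats.columns:
        vals = feats[col].to_numpy(dtype=float)
        lo, hi = vals[fit_mask].min(), vals[fit_mask].max()
        if hi <= lo:
            raise ValueError(f"descriptor {col!r} is constant on the fitting subset")
        scaled = (vals - lo) / (hi - lo)
        n_clipped += int(((scaled < 0) | (scaled > 1)).sum())
        out[col] = np.clip(scaled, 0.0, 1.0)
        scaling[col] = (float(lo), float(hi))
    return ScaledPanel(
        values=out,
        scaling=scaling,
        n_clipped=n_clipped,
        fit_on="all" if fit_on is None else "subset",
    )


def screen_and_scale(
    table: pd.DataFrame, k: int | None = None, fit_on=None
) -> tuple[ScaledPanel, pd.Series]:
    """Convenience pipeline: drop rows with missing values (logged), score
    and flag outliers, exclude them, then min-max standardize.

    Returns the scaled panel of retained units and the boolean outlier
    flags on the complete-case table.
    """
    complete = table.dropna()
    n_missing = len(table) - len(complete)
    if n_missing:
        warnings.warn(
            f"excluding {n_missing} unit(s) with missing descriptor values",
            RuntimeWarning,
            stacklevel=2,
        )
    flags = flag_outliers(outlier_scores(complete, k=k))
    kept = complete.loc[~flags]
    if fit_on is not None:
        fit_on = np.asarray(fit_on, bool)[~flags.to_numpy()]
    return minmax_standardize(kept, fit_on=fit_on), flags
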