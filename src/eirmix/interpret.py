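"""Model-agnostic interpretation tools for a prediction function.

Partial dependence (PD), accumulated local effects (ALE), the
Friedman–Popescu H-statistic of interaction strength, impurity-importance
tables, and the Spearman rank agreement used to score how well an estimated
interpretation recovers a known ground truth.

All tools operate on ``predict_fn(X) -> probabilities`` over a feature frame
(a DataFrame or 2-D array with named columns), so they apply equally to the
forest inside an EIRM-RF fit, a plain forest, or an explicit tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ParameterError, UndefinedResultError
from .forest import ForestFit


@dataclass
class EffectCurve:
    feature: str
    grid: np.ndarray
    values: np.ndarray
    kind: str  # "pd" or "ale"
    weights: np.ndarray = None  # bin/grid occupancy (ale)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "value": self.values})


@dataclass
class HResult:
    features: tuple
    value: float
    n_sample: int
    raw: float = float("nan")  # pre-clipping variance fraction


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.reset_index(drop=True)
    arr = np.asarray(data)
    return pd.DataFrame(arr, columns=[f"f{j}" for j in range(arr.shape[1])])


def gini_importance_table(fit: ForestFit, normalize: bool = False) -> pd.DataFrame:
    """Per-feature impurity importances, sorted descending.

    With ``normalize`` the scores are rescaled so the top feature is 100.
    Ties keep the original feature order (stable sort).
    """
    imp = np.asarray(fit.gini_importance, dtype=float)
    if normalize:
        top = imp.max()
        imp = imp / top * 100.0 if top > 0 else imp
    table = pd.DataFrame({"feature": fit.feature_names, "importance": imp})
    return table.sort_values("importance", ascending=False,
                             kind="stable").reset_index(drop=True)


def _make_grid(values: pd.Series, grid_size: int):
    uniq = np.unique(values.to_numpy())
    if len(uniq) <= grid_size:
        return uniq
    return np.linspace(uniq.min(), uniq.max(), grid_size)


def partial_dependence(predict_fn, data, feature: str, grid=None,
                       grid_size: int = 50) -> EffectCurve:
    """PD(g) = average prediction with ``feature`` forced to each grid value.

    The grid defaults to the observed unique values (equispaced once there are
    more than ``grid_size`` of them); category labels are used verbatim for
    nominal features.
    """
    df = _as_frame(data)
    if len(df) == 0:
        raise ParameterError("empty data")
    if feature not in df.columns:
        raise ParameterError(f"unknown feature {feature!r}")
    col = df[feature]
    if grid is None:
        if pd.api.types.is_numeric_dtype(col):
            grid = _make_grid(col, grid_size)
        else:
            grid = np.array(sorted(col.unique(), key=str), dtype=object)
    grid = np.asarray(grid)
    stacked = pd.concat([df] * len(grid), ignore_index=True)
    stacked[feature] = np.repeat(grid, len(df))
    preds = np.asarray(predict_fn(stacked))
    values = preds.reshape(len(grid), len(df)).mean(axis=1)
    return EffectCurve(feature=feature, grid=grid, values=values, kind="pd")


def accumulated_local_effects(predict_fn, data, feature: str,
                              n_bins: int = 10) -> EffectCurve:
    """ALE for a continuous feature on quantile bins.

    Within each bin the average prediction difference between the bin's upper
    and lower edges is computed over the rows falling in the bin; the running
    sum of these local effects is centered so its occupancy-weighted mean is
    zero.  The curve is reported at the bin edges.
    """
    df = _as_frame(data)
    if feature not in df.columns:
        raise ParameterError(f"unknown feature {feature!r}")
    x = df[feature].to_numpy(dtype=float)
    if len(np.unique(x)) < n_bins + 1:
        raise ParameterError(
            f"feature {feature!r} has fewer than n_bins+1={n_bins + 1} distinct "
            "values; reduce n_bins")
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    if len(edges) < 3:
        raise ParameterError(
            f"feature {feature!r} has too few distinct values for {n_bins} bins; "
            "reduce n_bins")
    k = len(edges) - 1  # effective bins after collapsing duplicate quantiles
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, k - 1)

    lo = df.copy()
    hi = df.copy()
    lo[feature] = edges[idx]
    hi[feature] = edges[idx + 1]
    both = pd.concat([lo, hi], ignore_index=True)
    preds = np.asarray(predict_fn(both))
    diff = preds[len(df):] - preds[:len(df)]

    local = np.zeros(k)
    counts = np.bincount(idx, minlength=k).astype(float)
    sums = np.bincount(idx, weights=diff, minlength=k)
    nonzero = counts > 0
    local[nonzero] = sums[nonzero] / counts[nonzero]

    cum = np.concatenate([[0.0], np.cumsum(local)])  # value at each edge
    # occupancy weight of edge m: rows in the adjacent bins, split evenly
    w = np.zeros(k + 1)
    w[:-1] += counts / 2
    w[1:] += counts / 2
    centered = cum - np.average(cum, weights=w)
    return EffectCurve(feature=feature, grid=edges, values=centered,
                       kind="ale", weights=w)


def _center(v):
    return v - v.mean()


def h_statistic(predict_fn, data, features, n_sample: int = 200,
                seed: int = 0, report: str = "h2") -> HResult:
    """Friedman–Popescu interaction strength.

    For a single feature ``j``, the overall statistic is the fraction of the
    (centered) prediction variance not captured by the additive decomposition
    PD_j + PD_{-j}; for a pair (j, k) it is the fraction of the variance of
    the two-way PD surface not captured by PD_j + PD_k.  Values are clipped
    into [0, 1] for round-off; ``report='h'`` returns the square root.
    """
    if report not in ("h2", "h"):
        raise ParameterError("report must be 'h2' or 'h'")
    df = _as_frame(data)
    if isinstance(features, str):
        features = (features,)
    features = tuple(features)
    for f in features:
        if f not in df.columns:
            raise ParameterError(f"unknown feature {f!r}")
    if n_sample > len(df):
        raise ParameterError("n_sample exceeds the number of rows")
    if n_sample < len(df):
        rng = np.random.default_rng(seed)
        df = df.iloc[rng.choice(len(df), size=n_sample, replace=False)]
        df = df.reset_index(drop=True)
    n = len(df)

    def pd_partial(fix_cols):
        """n-vector: for each row, average prediction with ``fix_cols`` taken
        from that row and the remaining columns swept over all rows."""
        stacked = pd.concat([df] * n, ignore_index=True)
        for c in fix_cols:
            stacked[c] = np.repeat(df[c].to_numpy(), n)
        preds = np.asarray(predict_fn(stacked))
        return preds.reshape(n, n).mean(axis=1)

    if len(features) == 1:
        j = features[0]
        f_all = np.asarray(predict_fn(df))
        pd_j = pd_partial([j])
        pd_rest = pd_partial([c for c in df.columns if c != j])
        num = np.sum((_center(f_all) - _center(pd_j) - _center(pd_rest)) ** 2)
        den = np.sum(_center(f_all) ** 2)
    elif len(features) == 2:
        j, k = features
        pd_jk = pd_partial([j, k])
        pd_j = pd_partial([j])
        pd_k = pd_partial([k])
        num = np.sum((_center(pd_jk) - _center(pd_j) - _center(pd_k)) ** 2)
        den = np.sum(_center(pd_jk) ** 2)
    else:
        raise ParameterError("features must be one name or a pair")

    if den <= 1e-300:
        raise UndefinedResultError("constant predictions: H is undefined")
    raw = float(num / den)
    value = float(np.clip(raw, 0.0, 1.0))
    if report == "h":
        value = float(np.sqrt(value))
    return HResult(features=features, value=value, n_sample=n, raw=raw)


def spearman_agreement(true_values, estimated_values) -> float:
    """Spearman rank correlation (midranks for ties) between two vectors.

    Returns ``nan`` when either vector is constant, in which case the rank
    correlation is undefined (reported as missing, never coerced to 0).
    """
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimated_values, dtype=float)
    if len(t) != len(e) or len(t) < 2:
        raise ParameterError("need two equal-length vectors with >= 2 entries")
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        return float("nan")
    rho = spearmanr(t, e).statistic
    return float(rho)
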