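"""Per-day exposure rates and weighted descriptive statistics.

Rates are reported per 10-hour day of photographs: each photo contributes
``seconds_per_photo`` (default 7 s, the median interval between images) of
exposure time, and a reporting day is 36,000 s. A child's rate is therefore
``count / (7 x n_photos) x 36000``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DAY_SECONDS",
    "rate_per_day",
    "weighted_quantiles",
    "weighted_median_iqr",
    "margin_shares",
]

DAY_SECONDS = 36_000.0


def rate_per_day(count, exposure_time, day_seconds: float = DAY_SECONDS):
    """Episodes per 10-h day: ``count / exposure_time * day_seconds``.

    ``exposure_time`` is in seconds (7 s per photo). Scalar or array inputs.
    """
    count = np.asarray(count, float)
    exposure_time = np.asarray(exposure_time, float)
    if (exposure_time <= 0).any():
        raise ValueError("exposure_time must be positive (child contributed no photos?)")
    out = count / exposure_time * day_seconds
    return float(out) if out.ndim == 0 else out


def weighted_quantiles(values, weights, probs=(0.25, 0.5, 0.75)) -> np.ndarray:
    """Weighted empirical quantiles via the left-continuous weighted ECDF.

    The quantile at probability p is the smallest observed value whose
    cumulative weight reaches ``p x total weight`` — the direct analogue of
    the type-1 (inverse-ECDF) sample quantile, so with integer weights it
    equals the unweighted type-1 quantile of the weight-expanded sample.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if values.size == 0:
        raise ValueError("empty group: quantiles undefined")
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    total = cum[-1]
    probs = np.atleast_1d(np.asarray(probs, float))
    idx = np.searchsorted(cum, probs * total - 1e-12 * total, side="left")
    return v[np.minimum(idx, len(v) - 1)]


def weighted_median_iqr(
    df: pd.DataFrame,
    value_col: str,
    weight_col: str = "sampling_weight",
    by=None,
) -> pd.DataFrame:
    """Weighted median and interquartile range, optionally by group.

    Returns columns ``q25, median, q75``; groups absent from the data are
    simply absent from the output (missing, never zero).
    """

    def _one(g: pd.DataFrame) -> pd.Series:
        q = weighted_quantiles(g[value_col], g[weight_col])
        return pd.Series({"q25": q[0], "median": q[1], "q75": q[2]})

    if by is None:
        return _one(df).to_frame().T
    parts = {
        key: _one(g) for key, g in df.groupby(by, observed=True) if len(g) > 0
    }
    return pd.DataFrame(parts).T.rename_axis(by)


def margin_shares(rates) -> np.ndarray:
    """Percent share of each margin cell: ``rate_i / sum(rates) * 100``.

    The margin must partition the total (settings, media or product
    categories each partition all exposures), so shares sum to 100.
    """
    rates = np.asarray(rates, float)
    total = rates.sum()
    if total <= 0:
        raise ValueError("zero total rate: shares undefined")
    return rates / total * 100.0
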