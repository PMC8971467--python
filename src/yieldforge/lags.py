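"""Lag selection via the partial autocorrelation function (PACF).

Annual yield series carry short memory: the previous year's yield is
usually the only statistically significant autoregressive input.  The PACF
(Durbin-Levinson on the biased sample autocorrelations) quantifies this;
lags whose partial autocorrelation exceeds the large-sample 95% band
+-1.96/sqrt(n) are flagged significant, and the modelling default is to use
lag 1 when it qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.stattools import pacf as _sm_pacf

__all__ = ["LagSpec", "pacf", "build_lagged_pairs"]


class LagError(ValueError):
    pass


@dataclass
class LagSpec:
    """PACF values for lags 1..max_lag with the significance verdict."""

    pacf_values: np.ndarray  # index 0 <-> lag 1
    confidence_bound: float  # 1.96 / sqrt(n)
    significant_lags: list[int]
    chosen_lags: list[int]
    n: int
    estimator: str = "durbin-levinson (biased ACF)"
    meta: dict = field(default_factory=dict)

    @property
    def max_lag(self) -> int:
        return len(self.pacf_values)


def pacf(series: np.ndarray, max_lag: int) -> LagSpec:
    """Compute the PACF of a series and flag significant lags.

    ``chosen_lags`` defaults to ``[1]`` when lag 1 is significant, otherwise
    to the first significant lag; when nothing clears the band it falls back
    to ``[1]`` (one-step persistence is the field's default predictor).
    """
    x = np.asarray(series, dtype=float)
    if max_lag < 1:
        raise LagError("max_lag must be >= 1")
    if x.ndim != 1 or len(x) <= max_lag + 1:
        raise LagError(f"series length {len(x)} too short for max_lag={max_lag}")
    if np.any(~np.isfinite(x)):
        raise LagError("series contains missing/non-finite values")
    if np.ptp(x) == 0:
        raise LagError("constant series: autocorrelation undefined")

    vals = _sm_pacf(x, nlags=max_lag, method="ldb")[1:]  # drop lag 0
    n = len(x)
    bound = 1.96 / np.sqrt(n)
    significant = [k + 1 for k, v in enumerate(vals) if abs(v) > bound]
    if 1 in significant:
        chosen = [1]
    elif significant:
        chosen = [significant[0]]
    else:
        chosen = [1]
    return LagSpec(
        pacf_values=vals,
        confidence_bound=float(bound),
        significant_lags=significant,
        chosen_lags=chosen,
        n=n,
    )


def build_lagged_pairs(
    series: np.ndarray, lags: list[int] | tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Turn a series into supervised (inputs, target) pairs.

    Row for time t holds inputs (W_{t-l} for l in lags) and target W_t, for
    t = max(lags) .. n-1.  Rows touching a missing value are dropped, so a
    gap costs only the pairs that straddle it.
    """
    x = np.asarray(series, dtype=float)
    lags = sorted(int(l) for l in lags)
    if not lags:
        raise LagError("empty lag list")
    if lags[0] < 1:
        raise LagError("lags must be >= 1")
    m = lags[-1]
    if m >= len(x):
        raise LagError(f"max lag {m} >= series length {len(x)}")
    X = np.column_stack([x[m - l : len(x) - l] for l in lags])
    y = x[m:]
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    return X[keep], y[keep]
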