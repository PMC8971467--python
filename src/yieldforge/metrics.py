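"""Hydrology-style evaluation suite for yield predictions.

Eight measures are computed between observed and predicted yields: Pearson
correlation r, Willmott's index of agreement WI, Nash-Sutcliffe efficiency
NSE, RMSE, MAE, the Legates-McCabe index LM, and the relative errors RRMSE
and RMAE (percent).  The relative errors feed a categorical model rating:

    outstanding  max(RRMSE, RMAE) <= 10%
    good         10% < max <= 20%
    fair         20% < max <= 30%
    poor         max > 30%

Boundary values fall into the better band (the published band definitions
use strict inequalities on both sides, leaving the boundaries open; this
package closes them downward).

The conventional NSE denominator sums squared deviations of the
*observations* from the observed mean.  A variant that deviates from the
predicted mean instead is available via ``nse_denominator="pred_mean"``;
reports record which was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

__all__ = ["EvalReport", "evaluate", "rate", "RATING_LEVELS"]

RATING_LEVELS = ("outstanding", "good", "fair", "poor")


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class EvalReport:
    """The eight agreement/error measures plus the categorical rating."""

    r: float
    wi: float
    nse: float
    rmse: float  # kg ha^-1
    mae: float  # kg ha^-1
    lm: float
    rrmse_pct: float
    rmae_pct: float
    rating: str
    n: int
    nse_denominator: str = "obs_mean"
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_csv_row(self, prefix: str = "") -> str:
        cols = [self.r, self.wi, self.nse, self.rmse, self.mae, self.lm,
                self.rrmse_pct, self.rmae_pct]
        body = ",".join(f"{v:.6g}" for v in cols)
        lead = f"{prefix}," if prefix else ""
        return f"{lead}{body},{self.rating},{self.n}"


def rate(rrmse_pct: float, rmae_pct: float) -> str:
    """Band of the worse (larger) of the two relative errors."""
    if rrmse_pct < 0 or rmae_pct < 0:
        raise MetricError("relative errors must be non-negative")
    worst = max(rrmse_pct, rmae_pct)
    if worst <= 10.0:
        return "outstanding"
    if worst <= 20.0:
        return "good"
    if worst <= 30.0:
        return "fair"
    return "poor"


def evaluate(
    obs: np.ndarray,
    pred: np.ndarray,
    nse_denominator: str = "obs_mean",
) -> EvalReport:
    """Compute the full report for one (observed, predicted) pairing.

    Observations must be strictly positive (RMAE divides by each one) and
    non-constant for r/NSE/LM to be defined; when they are constant those
    three come back NaN with their names in ``report.undefined`` rather than
    silently zero.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise MetricError(f"length mismatch: {obs.shape} vs {pred.shape}")
    n = obs.size
    if n < 2:
        raise MetricError("need at least 2 points")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise MetricError("non-finite values")
    if np.any(obs == 0):
        raise MetricError("observed values of 0 make RMAE undefined")
    if nse_denominator not in ("obs_mean", "pred_mean"):
        raise MetricError(f"unknown nse_denominator {nse_denominator!r}")

    err = pred - obs
    obs_mean = obs.mean()
    pred_mean = pred.mean()
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))

    if obs_mean == 0:
        raise MetricError("observed mean of 0 makes RRMSE undefined")
    rrmse = float(rmse / obs_mean * 100.0)
    rmae = float(np.mean(np.abs(err / obs)) * 100.0)

    od = obs - obs_mean
    pd_ = pred - pred_mean
    undefined: list[str] = []

    sxx = float(np.sum(od**2))
    syy = float(np.sum(pd_**2))
    if sxx == 0:
        r = np.nan
        undefined.append("r")
    elif syy == 0:
        r = np.nan
        undefined.append("r")
    else:
        r = float(np.sum(od * pd_) / np.sqrt(sxx * syy))

    wi_denom = float(np.sum((np.abs(pred - obs_mean) + np.abs(od)) ** 2))
    wi = 1.0 if wi_denom == 0 else float(1.0 - np.sum(err**2) / wi_denom)

    nse_base = obs - pred_mean if nse_denominator == "pred_mean" else od
    nse_denom = float(np.sum(nse_base**2))
    if nse_denom == 0:
        nse = np.nan
        undefined.append("nse")
    else:
        nse = float(1.0 - np.sum(err**2) / nse_denom)

    lm_denom = float(np.sum(np.abs(od)))
    if lm_denom == 0:
        lm = np.nan
        undefined.append("lm")
    else:
        lm = float(1.0 - np.sum(np.abs(err)) / lm_denom)

    return EvalReport(
        r=r, wi=wi, nse=nse, rmse=rmse, mae=mae, lm=lm,
        rrmse_pct=rrmse, rmae_pct=rmae,
        rating=rate(rrmse, rmae), n=n,
        nse_denominator=nse_denominator,
        undefined=tuple(undefined),
    )
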