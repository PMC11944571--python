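"""Model-assessment metrics and per-group summaries.

Conventions:

* R2 = 1 - sum (obs - pred)^2 / sum (obs - mean(obs))^2  (one minus the
  fraction of unexplained variance; can be negative for a bad model);
* RMSE = sqrt(mean (pred - obs)^2)  (RMSEP when the split is the
  validation set), in mg g^-1 for chlorophyll;
* RPIQ = IQR(obs) / RMSE with linear-interpolation (type-7) quartiles;
* bias and MBE both use the single sign convention mean(pred - obs).
  Positive = over-prediction. (Published reports sometimes flip the sign
  of one of the two without defining either; here they are the same
  number under one explicit convention.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EvaluationReport:
    label: str
    n: int
    r2: float | None
    rmse: float
    rpiq: float | None
    bias: float
    mbe: float
    sign_convention: str = "pred-minus-obs"
    per_species: pd.DataFrame | None = field(default=None, repr=False)
    per_month: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "rpiq": self.rpiq,
            "bias": self.bias,
            "mbe": self.mbe,
            "sign_convention": self.sign_convention,
        }


def evaluate(
    obs: np.ndarray, pred: np.ndarray, label: str = ""
) -> EvaluationReport:
    """Compute R2, RMSE, RPIQ, bias and MBE for one dataset split.

    Constant observations leave R2 and RPIQ undefined; they are reported
    as None with a warning rather than raising.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("obs and pred lengths differ")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant observations: R2 undefined", stacklevel=2)
        r2 = None
    else:
        r2 = float(1 - np.sum(resid**2) / ss_tot)
    q75, q25 = np.percentile(obs, [75, 25])  # linear interpolation (type-7)
    iqr = float(q75 - q25)
    if rmse == 0 or iqr == 0:
        if rmse == 0:
            warnings.warn("zero RMSE: RPIQ undefined", stacklevel=2)
        rpiq = None
    else:
        rpiq = iqr / rmse
    return EvaluationReport(
        label=label, n=obs.size, r2=r2, rmse=rmse, rpiq=rpiq, bias=bias, mbe=bias
    )


def group_summaries(
    obs: np.ndarray,
    pred: np.ndarray,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- standard error of predictions (and observations) per
    species and per month; SE = sd / sqrt(n), undefined (NaN) for
    singleton groups."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if not (obs.size == pred.size == len(meta)):
        raise ValueError("obs, pred and metadata lengths differ")
    df = pd.DataFrame(
        {
            "species": meta["species"].to_numpy(),
            "month": meta["month"].to_numpy(),
            "obs": obs,
            "pred": pred,
        }
    )

    def summarize(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        return pd.Series(
            {
                "n": n,
                "obs_mean": g["obs"].mean(),
                "obs_se": g["obs"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "pred_mean": g["pred"].mean(),
                "pred_se": g["pred"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )

    by_species = (
        df.groupby("species", sort=True).apply(summarize, include_groups=False).reset_index()
    )
    by_month = (
        df.groupby("month", sort=True).apply(summarize, include_groups=False).reset_index()
    )
    return by_species, by_month


def evaluate_with_groups(
    obs: np.ndarray, pred: np.ndarray, meta: pd.DataFrame, label: str = ""
) -> EvaluationReport:
    report = evaluate(obs, pred, label)
    report.per_species, report.per_month = group_summaries(obs, pred, meta)
    return report
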