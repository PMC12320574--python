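"""Prediction-versus-experiment comparison statistics.

Three procedures compare predicted surviving fractions with experimental
outgrowth replicates: a one-sample t-test per scenario against the fixed
prediction, ordinary least-squares regression of outgrowth on prediction
across scenarios, and Bland-Altman limits of agreement on the paired
differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["one_sample_t", "linreg", "bland_altman", "compare_table"]


def one_sample_t(replicates, reference: float) -> tuple[float, float]:
    """One-sample t-test of replicate mean against a fixed reference value.

    Returns (t statistic, two-sided p).
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    if np.allclose(x, x[0]):
        raise ValueError("replicates have zero variance")
    res = stats.ttest_1samp(x, popmean=reference)
    return float(res.statistic), float(res.pvalue)


def linreg(x, y) -> dict:
    """Ordinary least squares y ~ x with r^2 and the slope's two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate x (no variation)")
    if np.allclose(y, y[0]):
        # constant response: flat fit explains nothing, by convention r^2 = 0
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0,
                "p_value": 1.0}
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2), "p_value": float(res.pvalue)}


def bland_altman(pred, exp) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean +- 1.96 SD).

    Differences are experiment minus prediction; the SD uses n-1 degrees of
    freedom.
    """
    p = np.asarray(pred, dtype=float)
    e = np.asarray(exp, dtype=float)
    if p.size != e.size:
        raise ValueError("paired vectors must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = e - p
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return md, md - 1.96 * sd, md + 1.96 * sd


def compare_table(predictions: dict, outgrowth: pd.DataFrame,
                  alpha_level: float = 0.01) -> pd.DataFrame:
    """Per-scenario t-tests of outgrowth replicates against predictions.

    ``predictions`` maps scenario name to predicted SF; ``outgrowth`` has
    columns scenario and outgrowth (one row per replicate).  The decision
    column flags scenarios whose outgrowth differs from the prediction at
    the given alpha level.
    """
    rows = []
    for scen, pred in predictions.items():
        reps = outgrowth.loc[outgrowth["scenario"] == scen, "outgrowth"]
        if len(reps) < 2:
            raise ValueError(f"scenario {scen!r} needs >= 2 replicates")
        t, p = one_sample_t(reps.to_numpy(), pred)
        rows.append({"scenario": scen, "predicted_sf": pred,
                     "mean_outgrowth": float(reps.mean()),
                     "n_replicates": int(len(reps)), "t_statistic": t,
                     "p_value": p,
                     "significant": bool(p < alpha_level),
                     "alpha_level": alpha_level})
    return pd.DataFrame(rows)
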