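"""Model comparison (BIC, per-channel RMSE) and physiological indices.

BIC treats the weighted objective as a Gaussian deviance with known
variances: BIC = objective + k_free * ln(n_data).  RMSE is reported per
(protocol, channel) on the variance-normalized residuals, so the
objective decomposes as sum over channels of n_{p,m} * RMSE_{p,m}^2.

AIRg is the acute insulin response to the IV glucose bolus — incremental
insulin AUC above basal over the first 10 minutes — and the disposition
index DI = AIRg * S_I summarizes beta-cell compensation.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fitting import FitResult
from .timeseries import TimeSeries

logger = logging.getLogger(__name__)


def bic(fit: FitResult) -> float:
    """Bayes information criterion of a converged fit."""
    if fit.n_data <= 0:
        raise InvalidInputError("n_data must be positive")
    return fit.objective + fit.k_free * math.log(fit.n_data)


def rmse(fit: FitResult, protocol: str, channel: str) -> float:
    """Root mean square of variance-normalized residuals for one channel."""
    key = (protocol, channel)
    if key not in fit.residuals:
        raise InvalidInputError(f"fit has no residuals for {key}")
    r = fit.residuals[key]
    return float(np.sqrt(np.mean(r**2 / fit.sigma2[key])))


def airg(insulin: TimeSeries) -> float:
    """Acute insulin response to glucose (uU/mL * min).

    Trapezoidal integral over [0, 10] min of the insulin excursion above
    basal, where basal is the mean of the pre-zero (-10, -1 min) samples;
    dips below basal contribute zero.
    """
    pre = insulin.times < 0
    if pre.any():
        basal = float(insulin.values[pre].mean())
    else:
        basal = float(insulin.values[insulin.times == 0][0]) if (
            insulin.times == 0
        ).any() else float(insulin.values[0])
        logger.warning("no pre-zero insulin samples; basal falls back to %.3g", basal)
    mask = (insulin.times >= 0) & (insulin.times <= 10)
    if not mask.any() or insulin.times[mask].max() < 10:
        raise InvalidInputError("insulin samples must span [0, 10] min")
    t = insulin.times[mask]
    inc = np.clip(insulin.values[mask] - basal, 0.0, None)
    return float(np.trapezoid(inc, t))


def disposition_index(airg_value: float, S_I: float) -> float:
    """DI = AIRg * S_I (beta-cell compensation for insulin resistance)."""
    return float(airg_value) * float(S_I)


def comparison_table(fits: list[tuple[str, FitResult]]) -> pd.DataFrame:
    """BIC/RMSE summary, one row per (subject, model, combination) fit."""
    rows = []
    for subject_name, fit in fits:
        row = {
            "model": fit.model_id,
            "combination": fit.combination,
            "subject": subject_name,
            "BIC": bic(fit),
            "n_data": fit.n_data,
            "k_free": fit.k_free,
        }
        for proto, chan, col in (
            ("FSIGT", "glucose", "RMSE_FSIGT_G"),
            ("MT", "glucose", "RMSE_MT_G"),
            ("FSIGT", "ffa", "RMSE_FSIGT_F"),
            ("MT", "ffa", "RMSE_MT_F"),
        ):
            row[col] = (
                rmse(fit, proto, chan) if (proto, chan) in fit.residuals else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
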