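"""Rank-1 singular spectrum analysis (SSA) for residual-variance estimation.

The fitting objective weights each (protocol, channel) by an estimate of
the measurement variance sigma^2 obtained from the raw data alone: the
series is embedded in a Hankel trajectory matrix, only the leading
singular triple is retained, and the reconstruction (by anti-diagonal
averaging) serves as a smooth trend.  The mean squared deviation of the
data from this trend is sigma^2 — a per-subject, per-channel scalar that
is fixed before optimization and never co-estimated with the model
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .timeseries import TimeSeries

logger = logging.getLogger(__name__)

#: Relative floor on sigma: sigma >= SIGMA_FLOOR_FRAC * |channel mean|,
#: so noiseless synthetic data cannot produce infinite weights.
SIGMA_FLOOR_FRAC = 0.01


@dataclass
class VarianceEstimate:
    """sigma2: residual variance (squared channel units); trend: the rank-1
    SSA reconstruction on the sample grid."""

    sigma2: float
    trend: np.ndarray


def _rank1_hankel_reconstruction(x: np.ndarray, window: int) -> np.ndarray:
    n = x.size
    L, K = window, n - window + 1
    # Trajectory (Hankel) matrix, columns are lagged windows.
    traj = np.lib.stride_tricks.sliding_window_view(x, L).T  # L x K
    u, s, vt = np.linalg.svd(traj, full_matrices=False)
    rank1 = s[0] * np.outer(u[:, 0], vt[0])
    # Diagonal (anti-diagonal) averaging back to a series of length n.
    out = np.zeros(n)
    counts = np.zeros(n)
    idx = np.arange(L)[:, None] + np.arange(K)[None, :]
    np.add.at(out, idx, rank1)
    np.add.at(counts, idx, 1.0)
    return out / counts


def ssa_trend(series: TimeSeries | np.ndarray, window: int | None = None) -> np.ndarray:
    """Rank-1 SSA smoothing of a series.

    ``window`` is the embedding length L (default floor(n/2), the standard
    choice); must satisfy 2 <= L <= n-1.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    n = x.size
    if n < 4:
        raise InvalidInputError("SSA needs at least 4 samples")
    L = n // 2 if window is None else int(window)
    if not 2 <= L <= n - 1:
        raise InvalidInputError(f"window must be in [2, {n - 1}], got {L}")
    return _rank1_hankel_reconstruction(x, L)


def estimate_variance(
    series: TimeSeries | np.ndarray,
    window: int | None = None,
    floor_frac: float = SIGMA_FLOOR_FRAC,
) -> VarianceEstimate:
    """Residual variance of a series about its rank-1 SSA trend.

    sigma^2 is the plain mean of squared deviations (per time point, no
    degrees-of-freedom correction), floored at
    (floor_frac * |channel mean|)^2.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    trend = ssa_trend(x, window)
    sigma2 = float(np.mean((x - trend) ** 2))
    floor = (floor_frac * abs(float(np.mean(x)))) ** 2
    if sigma2 < floor:
        logger.warning(
            "SSA residual variance %.3g below floor %.3g; using floor", sigma2, floor
        )
        sigma2 = floor
    return VarianceEstimate(sigma2=sigma2, trend=trend)
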