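"""Back-calculation of meal glucose Ra from data and simulated insulin action.

Rearranging the glucose balance of the minimal model, the appearance rate
is recoverable pointwise from the measured glucose and a simulated
insulin-action trajectory:

    Ra(t) = dG/dt - S_G * G_b + (S_G + S_I * X(t)) * G(t)

Measured meal-test glucose and its derivative are interpolated with a
natural cubic spline on a 1-min grid (matching the simulation grid); the
spline's analytic derivative is used rather than finite differences.  No
positivity constraint is applied: negative stretches (a known artifact of
sparse 30-min sampling) are reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InvalidInputError
from .protocols import Trajectory
from .timeseries import TimeSeries


def spline_series(
    series: TimeSeries, grid_step: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural cubic spline of a series on a dense grid.

    Returns (grid, values, first derivative); the spline interpolates the
    knots exactly.
    """
    if len(series) < 4:
        raise InvalidInputError("spline interpolation needs at least 4 samples")
    cs = CubicSpline(series.times, series.values, bc_type="natural")
    grid = np.arange(series.times[0], series.times[-1] + grid_step / 2, grid_step)
    return grid, cs(grid), cs(grid, 1)


@dataclass
class BackcalcResult:
    """Ra back-calculation output on the dense grid."""

    t: np.ndarray
    ra: np.ndarray
    g_spline: np.ndarray
    dgdt: np.ndarray
    x: np.ndarray


def backcalc_ra(
    glucose_mt: TimeSeries,
    x_mt: Trajectory,
    S_G: float,
    S_I: float,
    G_b: float,
) -> BackcalcResult:
    """Glucose Ra on a 1-min grid from meal-test glucose and simulated X."""
    if x_mt.X is None:
        raise InvalidInputError("trajectory has no insulin-action channel X")
    grid, g, dgdt = spline_series(glucose_mt, 1.0)
    if grid[0] < x_mt.t[0] or grid[-1] > x_mt.t[-1]:
        raise InvalidInputError("trajectory grid does not cover the glucose samples")
    x = x_mt.at_times(grid, "X")
    ra = dgdt - S_G * G_b + (S_G + S_I * x) * g
    return BackcalcResult(t=grid, ra=ra, g_spline=g, dgdt=dgdt, x=x)
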