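"""Experimental protocols and model integration over them.

Two protocols are encoded:

* **FSIGT** — insulin-modified frequently sampled IV glucose tolerance
  test: dextrose bolus at t=0, insulin bolus at t=20 min, dense sampling
  from -10 to 180 min.  Only data in the 10-180 min window are fitted;
  the initial state is the average of the 0-10 min samples, and
  integration starts at t=10.  No meal Ra ever applies.
* **MT** — mixed-meal test sampled every 30 min from 0 to 360 min; the
  initial state is the t=0 measurement and meal Ra terms may apply.

Trajectories are reported on a dense 1-min grid so that Ra
back-calculation and residual extraction never interpolate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .combinations import Combination, get_combination
from .errors import IntegrationError, InvalidInputError
from .models import (
    InsulinInput,
    ModelParams,
    ModelState,
    Mod3Params,
    make_rhs,
)
from .ra import RaType1FFA, RaType1Glucose, RaType2Glucose
from .timeseries import SubjectData, TimeSeries

FSIGT_TIMES = np.array(
    [-10, -1, 0, 1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 20, 22, 23, 24, 25,
     27, 30, 40, 50, 60, 70, 80, 90, 100, 120, 150, 180],
    dtype=float,
)
MT_TIMES = np.arange(0.0, 361.0, 30.0)


@dataclass(frozen=True)
class Protocol:
    """Sampling schedule and fitting window of one test."""

    kind: str
    sample_times: np.ndarray
    fit_window: tuple[float, float]

    def fitted_times(self) -> np.ndarray:
        """Sample times inside the fitting window."""
        lo, hi = self.fit_window
        t = self.sample_times
        return t[(t >= lo) & (t <= hi)]


FSIGT = Protocol("FSIGT", FSIGT_TIMES, (10.0, 180.0))
MT = Protocol("MT", MT_TIMES, (0.0, 360.0))
PROTOCOL_BY_KIND = {"FSIGT": FSIGT, "MT": MT}


@dataclass
class Trajectory:
    """Dense model output on a 1-min grid; G and X are None for MOD 3."""

    t: np.ndarray
    F: np.ndarray
    G: Optional[np.ndarray] = None
    X: Optional[np.ndarray] = None

    def at_times(self, times: np.ndarray, channel: str) -> np.ndarray:
        """Values of one channel at times contained in the grid."""
        arr = {"glucose": self.G, "ffa": self.F, "X": self.X}[channel]
        if arr is None:
            raise InvalidInputError(f"trajectory has no {channel} channel")
        idx = np.searchsorted(self.t, times)
        if not np.allclose(self.t[idx], times):
            raise InvalidInputError("requested times not on trajectory grid")
        return arr[idx]


@dataclass
class RaSet:
    """Meal Ra parameter objects accompanying a model parameter set."""

    glucose: RaType1Glucose | RaType2Glucose | None = None
    ffa: RaType1FFA | None = None


def initial_conditions(
    protocol: Protocol, data: SubjectData, model_id: str = "MOD1"
) -> ModelState:
    """Protocol initial state: X(0)=0; glucose/FFA from the data.

    MT uses the t=0 measurement; FSIGT the mean of the 0-10 min samples
    (times 0..8 of the schedule, excluding the t=10 fitted sample).
    """
    kind = protocol.kind

    def _init(channel: str) -> float:
        ts = data.get(kind, channel)
        if kind == "MT":
            return ts.value_at(0.0)
        mask = (ts.times >= 0.0) & (ts.times < 10.0)
        if not mask.any():
            raise InvalidInputError(f"no {channel} samples in [0, 10) for FSIGT")
        return float(ts.values[mask].mean())

    F0 = _init("ffa")
    if model_id == "MOD3":
        return ModelState(np.nan, np.nan, F0)
    return ModelState(_init("glucose"), 0.0, F0)


def simulate(
    model_id: str,
    params: ModelParams,
    combination: "str | Combination",
    protocol: Protocol,
    insulin: TimeSeries | InsulinInput,
    state0: ModelState,
    ra: RaSet | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate a model over a protocol's fitting window.

    The meal Ra terms in ``ra`` are applied only when the protocol is MT
    and the combination activates them.  Output is on the 1-min grid.
    """
    combo = get_combination(combination)
    if isinstance(insulin, TimeSeries):
        insulin = InsulinInput(insulin)
    ra = ra or RaSet()
    ra_G = ra_F = None
    if protocol.kind == "MT":
        if combo.ra_glucose != "none":
            if ra.glucose is None:
                raise InvalidInputError(
                    f"combination {combo.id} needs a glucose Ra parameter set"
                )
            ra_G = ra.glucose
        if combo.ra_ffa != "none":
            if ra.ffa is None:
                raise InvalidInputError(
                    f"combination {combo.id} needs an FFA Ra parameter set"
                )
            ra_F = ra.ffa

    is_mod3 = isinstance(params, Mod3Params) or model_id == "MOD3"
    if is_mod3:
        y0 = [state0.F]
        rhs = make_rhs(params, insulin, None, ra_F)
    else:
        y0 = [state0.G, state0.X, state0.F]
        rhs = make_rhs(params, insulin, ra_G, ra_F)

    t0, t1 = protocol.fit_window
    grid = np.arange(t0, t1 + 0.5, 1.0)
    sol = solve_ivp(
        rhs, (t0, t1), y0, method="LSODA", t_eval=grid, rtol=rtol, atol=atol
    )
    if not sol.success or sol.y.shape[1] != grid.size:
        raise IntegrationError(
            f"{model_id}/{combo.id}/{protocol.kind} integration failed: "
            f"{sol.message} (params={params})"
        )
    if is_mod3:
        return Trajectory(t=grid, F=sol.y[0])
    return Trajectory(t=grid, G=sol.y[0], X=sol.y[1], F=sol.y[2])
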