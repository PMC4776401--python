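"""Minimal-model variants for insulin-regulated glucose and FFA kinetics.

Three model structures are implemented:

* **MOD 1** — Bergman-type glucose minimal model driven by measured plasma
  insulin through a remote insulin-action compartment X, coupled to an FFA
  equation with Hill-suppressed lipolysis and insulin-*stimulated* clearance
  (clearance factor rises from C_f toward 2*C_f as X grows).
* **MOD 2** — same glucose/X equations, FFA clearance at a constant rate
  C_f0 and a free lipolysis Hill exponent A_l.
* **MOD 3** — FFA-only model in which plasma insulin acts directly, with
  separate time delays for lipolysis suppression and clearance stimulation.

Measured plasma insulin is the model input: it is interpolated linearly
between samples and clamped to the first/last sample outside the record,
so delayed lookups I(t - delay) are always defined.

States: G plasma glucose (mg/dL), X insulin action (uU/mL), F plasma FFA
(mmol/L).  MOD 3 has the single state F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, NamedTuple, Optional

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, NoSteadyStateError
from .timeseries import TimeSeries

MODEL_IDS = ("MOD1", "MOD2", "MOD3")

RaFunc = Optional[Callable[[float], float]]


class ModelState(NamedTuple):
    """Model state (G, X, F); MOD 3 uses only F."""

    G: float
    X: float
    F: float


def _check_nonneg(obj, names) -> None:
    for nm in names:
        v = getattr(obj, nm)
        if not np.isfinite(v) or v < 0:
            raise InvalidParameterError(f"{nm} must be finite and >= 0, got {v}")


@dataclass
class Mod1Params:
    """MOD 1 parameters.

    S_G glucose effectiveness (1/min); G_b target glucose (mg/dL);
    S_I insulin sensitivity (1/min per uU/mL); C_x action rate constant
    (1/min); I_bx action-threshold insulin (uU/mL); l_0 basal lipolysis
    (mmol/L/min); l_2 suppressible lipolysis (mmol/L/min); X_2 lipolysis
    half-inhibition action (uU/mL); A_lipo lipolysis Hill exponent (fixed 2);
    C_f clearance coefficient (1/min); K_Cl clearance half-activation action
    (uU/mL); A_Cl clearance Hill exponent (fixed 2).
    """

    S_G: float
    G_b: float
    S_I: float
    C_x: float
    I_bx: float
    l_0: float
    l_2: float
    X_2: float
    C_f: float
    K_Cl: float
    A_lipo: float = 2.0
    A_Cl: float = 2.0

    def __post_init__(self) -> None:
        _check_nonneg(self, [f.name for f in fields(self)])
        if self.l_2 > 0 and self.X_2 <= 0:
            raise InvalidParameterError("X_2 must be > 0 when l_2 > 0")
        if self.C_f > 0 and self.K_Cl <= 0:
            raise InvalidParameterError("K_Cl must be > 0 when C_f > 0")


@dataclass
class Mod2Params:
    """MOD 2 parameters: shared G/X block, constant FFA clearance C_f0,
    free lipolysis Hill exponent A_l."""

    S_G: float
    G_b: float
    S_I: float
    C_x: float
    I_bx: float
    l_0: float
    l_2: float
    X_2: float
    A_l: float
    C_f0: float

    def __post_init__(self) -> None:
        _check_nonneg(self, [f.name for f in fields(self)])
        if self.A_l <= 0:
            raise InvalidParameterError("A_l must be > 0")
        if self.l_2 > 0 and self.X_2 <= 0:
            raise InvalidParameterError("X_2 must be > 0 when l_2 > 0")


@dataclass
class Mod3Params:
    """MOD 3 parameters: delayed direct insulin action on FFA turnover.

    V_m_Lip maximal lipolysis (mmol/L/min); t_DelayLip / t_DelayRem insulin
    delays (min); K_Lip / K_Rem half-effect insulin levels (uU/mL);
    h_lip / h_Rem Hill exponents; k_Rem insulin-independent clearance
    (1/min); V_m_Rem maximal insulin-stimulated clearance (1/min).
    """

    V_m_Lip: float
    t_DelayLip: float
    K_Lip: float
    h_lip: float
    k_Rem: float
    V_m_Rem: float
    t_DelayRem: float
    K_Rem: float
    h_Rem: float

    def __post_init__(self) -> None:
        _check_nonneg(self, [f.name for f in fields(self)])
        if self.h_lip > 0 and self.K_Lip <= 0:
            raise InvalidParameterError("K_Lip must be > 0 when h_lip > 0")
        if self.V_m_Rem > 0 and self.h_Rem > 0 and self.K_Rem <= 0:
            raise InvalidParameterError("K_Rem must be > 0 when h_Rem > 0")


ModelParams = Mod1Params | Mod2Params | Mod3Params


class InsulinInput:
    """Measured plasma insulin as a continuous model input.

    Linear interpolation between samples; constant (clamped) extrapolation
    before the first and after the last sample, so delayed lookups are
    defined everywhere.
    """

    def __init__(self, insulin: TimeSeries):
        if len(insulin) < 2:
            raise InvalidInputError("insulin input needs at least 2 samples")
        self._t = insulin.times
        self._v = insulin.values

    def __call__(self, t: float, delay: float = 0.0) -> float:
        if delay < 0:
            raise InvalidInputError("delay must be >= 0")
        return float(np.interp(t - delay, self._t, self._v))


def insulin_input(t: float, insulin: TimeSeries, delay: float = 0.0) -> float:
    """Interpolated measured insulin at ``t - delay`` (clamped outside record)."""
    return InsulinInput(insulin)(t, delay)


def _pow_clamped(x: float, a: float) -> float:
    # Hill terms: clamp base at 0 so transient negative solver excursions
    # cannot produce complex powers.
    return 0.0 if x <= 0.0 else x ** a


def rhs_mod1(
    t: float,
    state,
    p: Mod1Params,
    insulin: InsulinInput | TimeSeries,
    ra_G: RaFunc = None,
    ra_F: RaFunc = None,
) -> np.ndarray:
    """Right-hand side of MOD 1: d(G, X, F)/dt."""
    if isinstance(insulin, TimeSeries):
        insulin = InsulinInput(insulin)
    G, X, F = float(state[0]), float(state[1]), float(state[2])
    Xc = max(X, 0.0)
    dG = p.S_G * p.G_b - (p.S_G + p.S_I * X) * G
    dX = p.C_x * (insulin(t) - X - p.I_bx)
    lip = p.l_0
    if p.l_2 > 0:
        lip += p.l_2 / (1.0 + _pow_clamped(Xc / p.X_2, p.A_lipo))
    h = _pow_clamped(Xc / p.K_Cl, p.A_Cl) if p.C_f > 0 else 0.0
    dF = lip - p.C_f * (1.0 + h / (1.0 + h)) * F
    if ra_G is not None:
        dG += ra_G(t)
    if ra_F is not None:
        dF += ra_F(t)
    return np.array([dG, dX, dF])


def rhs_mod2(
    t: float,
    state,
    p: Mod2Params,
    insulin: InsulinInput | TimeSeries,
    ra_G: RaFunc = None,
    ra_F: RaFunc = None,
) -> np.ndarray:
    """Right-hand side of MOD 2: d(G, X, F)/dt."""
    if isinstance(insulin, TimeSeries):
        insulin = InsulinInput(insulin)
    G, X, F = float(state[0]), float(state[1]), float(state[2])
    Xc = max(X, 0.0)
    dG = p.S_G * p.G_b - (p.S_G + p.S_I * X) * G
    dX = p.C_x * (insulin(t) - X - p.I_bx)
    lip = p.l_0
    if p.l_2 > 0:
        lip += p.l_2 / (1.0 + _pow_clamped(Xc / p.X_2, p.A_l))
    dF = lip - p.C_f0 * F
    if ra_G is not None:
        dG += ra_G(t)
    if ra_F is not None:
        dF += ra_F(t)
    return np.array([dG, dX, dF])


def rhs_mod3(
    t: float,
    F: float,
    p: Mod3Params,
    insulin: InsulinInput | TimeSeries,
    ra_F: RaFunc = None,
) -> float:
    """Right-hand side of MOD 3: dF/dt (scalar)."""
    if isinstance(insulin, TimeSeries):
        insulin = InsulinInput(insulin)
    F = float(np.asarray(F).reshape(-1)[0])
    I_lip = max(insulin(t, p.t_DelayLip), 0.0)
    I_rem = max(insulin(t, p.t_DelayRem), 0.0)
    lip = p.V_m_Lip / (1.0 + _pow_clamped(I_lip / p.K_Lip, p.h_lip))
    num = _pow_clamped(I_rem, p.h_Rem)
    stim = p.V_m_Rem * num / (p.K_Rem ** p.h_Rem + num) if p.V_m_Rem > 0 else 0.0
    dF = lip - (p.k_Rem + stim) * F
    if ra_F is not None:
        dF += ra_F(t)
    return dF


def steady_state(p: ModelParams, model_id: str | None = None) -> ModelState:
    """Fixed point with X = 0, Ra = 0 and basal insulin.

    MOD 1/2: G* = G_b, X* = 0, F* = (l_0 + l_2)/clearance-rate.
    MOD 3 (insulin 0): F* = V_m_Lip / k_Rem.
    """
    if isinstance(p, Mod1Params):
        if p.C_f <= 0:
            raise NoSteadyStateError("MOD 1 needs C_f > 0 for a steady state")
        return ModelState(p.G_b, 0.0, (p.l_0 + p.l_2) / p.C_f)
    if isinstance(p, Mod2Params):
        if p.C_f0 <= 0:
            raise NoSteadyStateError("MOD 2 needs C_f0 > 0 for a steady state")
        return ModelState(p.G_b, 0.0, (p.l_0 + p.l_2) / p.C_f0)
    if isinstance(p, Mod3Params):
        if p.k_Rem <= 0:
            raise NoSteadyStateError("MOD 3 needs k_Rem > 0 for a steady state")
        return ModelState(math.nan, math.nan, p.V_m_Lip / p.k_Rem)
    raise InvalidParameterError(f"unknown parameter type {type(p).__name__}")


def make_rhs(
    p: ModelParams,
    insulin: InsulinInput,
    ra_G: RaFunc = None,
    ra_F: RaFunc = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Bind parameters into a fast RHS closure for the ODE solver.

    Equivalent to calling :func:`rhs_mod1` / `rhs_mod2` / `rhs_mod3`, but
    with all parameter lookups hoisted out of the integration loop.
    """
    it, iv = insulin._t, insulin._v

    if isinstance(p, Mod1Params):
        S_G, G_b, S_I, C_x, I_bx = p.S_G, p.G_b, p.S_I, p.C_x, p.I_bx
        l_0, l_2, X_2, A_lipo = p.l_0, p.l_2, p.X_2, p.A_lipo
        C_f, K_Cl, A_Cl = p.C_f, p.K_Cl, p.A_Cl

        def rhs(t: float, y: np.ndarray) -> list[float]:
            G = y[0]
            X = y[1]
            F = y[2]
            Xc = X if X > 0.0 else 0.0
            dG = S_G * G_b - (S_G + S_I * X) * G
            dX = C_x * (np.interp(t, it, iv) - X - I_bx)
            lip = l_0
            if l_2 > 0.0:
                lip += l_2 / (1.0 + (Xc / X_2) ** A_lipo)
            dF = lip
            if C_f > 0.0:
                h = (Xc / K_Cl) ** A_Cl
                dF -= C_f * (1.0 + h / (1.0 + h)) * F
            if ra_G is not None:
                dG += ra_G(t)
            if ra_F is not None:
                dF += ra_F(t)
            return [dG, dX, dF]

        return rhs

    if isinstance(p, Mod2Params):
        S_G, G_b, S_I, C_x, I_bx = p.S_G, p.G_b, p.S_I, p.C_x, p.I_bx
        l_0, l_2, X_2, A_l, C_f0 = p.l_0, p.l_2, p.X_2, p.A_l, p.C_f0

        def rhs(t: float, y: np.ndarray) -> list[float]:
            G = y[0]
            X = y[1]
            F = y[2]
            Xc = X if X > 0.0 else 0.0
            dG = S_G * G_b - (S_G + S_I * X) * G
            dX = C_x * (np.interp(t, it, iv) - X - I_bx)
            lip = l_0
            if l_2 > 0.0:
                lip += l_2 / (1.0 + (Xc / X_2) ** A_l)
            dF = lip - C_f0 * F
            if ra_G is not None:
                dG += ra_G(t)
            if ra_F is not None:
                dF += ra_F(t)
            return [dG, dX, dF]

        return rhs

    if isinstance(p, Mod3Params):
        V_m_Lip, t_dl, K_Lip, h_lip = p.V_m_Lip, p.t_DelayLip, p.K_Lip, p.h_lip
        k_Rem, V_m_Rem, t_dr, K_Rem, h_Rem = (
            p.k_Rem, p.V_m_Rem, p.t_DelayRem, p.K_Rem, p.h_Rem,
        )
        K_Rem_h = K_Rem ** h_Rem if V_m_Rem > 0 else 1.0

        def rhs(t: float, y: np.ndarray) -> list[float]:
            F = y[0]
            I_lip = np.interp(t - t_dl, it, iv)
            if I_lip < 0.0:
                I_lip = 0.0
            lip = V_m_Lip / (1.0 + (I_lip / K_Lip) ** h_lip)
            rate = k_Rem
            if V_m_Rem > 0.0:
                I_rem = np.interp(t - t_dr, it, iv)
                if I_rem < 0.0:
                    I_rem = 0.0
                num = I_rem ** h_Rem
                rate += V_m_Rem * num / (K_Rem_h + num)
            dF = lip - rate * F
            if ra_F is not None:
                dF += ra_F(t)
            return [dF]

        return rhs

    raise InvalidParameterError(f"unknown parameter type {type(p).__name__}")
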