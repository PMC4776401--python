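"""Weighted least-squares estimation of per-subject model parameters.

The objective is a chi-square-like sum over active protocols p, channels
m (glucose, FFA) and sample times t:

    sum_p sum_m sum_t (y_data - y_model)^2 / sigma2_{p,m}

with one variance scalar per (protocol, channel) pair, estimated from the
raw data by rank-1 SSA (see :mod:`glufa.ssa`) and held fixed during
optimization.  Insulin is the model input and never a residual channel;
MOD 3 contributes only FFA residuals.

Optimization is bounded trust-region least squares (``scipy``'s ``trf``)
from a configurable multi-start set — by default the reference parameter
means and their 0.5x / 1.5x perturbations.  Upper bounds default to five
times the reference means; lower bounds are zero (a tiny positive value
for parameters that must stay strictly positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .combinations import Combination, get_combination
from .errors import (
    IntegrationError,
    InvalidInputError,
    InvalidParameterError,
    NonConvergenceError,
)
from .models import Mod1Params, Mod2Params, Mod3Params, ModelParams, InsulinInput
from .protocols import PROTOCOL_BY_KIND, RaSet, initial_conditions, simulate
from .ra import RaType1FFA, RaType1Glucose, RaType2Glucose
from .timeseries import SubjectData
from .ssa import estimate_variance

logger = logging.getLogger(__name__)

#: Finite penalty returned by the objective when the ODE solver fails.
PENALTY = 1e12

MOD1_NAMES = ("S_G", "G_b", "S_I", "C_x", "I_bx", "l_0", "l_2", "X_2", "C_f", "K_Cl")
MOD2_NAMES = ("S_G", "G_b", "S_I", "C_x", "I_bx", "l_0", "l_2", "X_2", "A_l", "C_f0")
MOD3_NAMES = (
    "V_m_Lip", "t_DelayLip", "K_Lip", "h_lip",
    "k_Rem", "V_m_Rem", "t_DelayRem", "K_Rem", "h_Rem",
)
RA_G_TYPE1_NAMES = ("Delta_G", "m_G", "sigma_G")
RA_G_TYPE2_NAMES = ("phi_G", "tau_G")
RA_F_TYPE1_NAMES = ("Delta_F", "sigma_F")

#: Parameters held fixed by convention rather than fitted (togglable via
#: FitConfig.fixed): Hill exponents of MOD 1 and the FFA-Ra lag/time scale.
FIXED_DEFAULTS = {"A_lipo": 2.0, "A_Cl": 2.0, "t_0F": 60.0, "m_F": 300.0}

#: Parameters that must remain strictly positive (they appear in
#: denominators or logs); their lower bound is a tiny epsilon instead of 0.
_STRICTLY_POSITIVE = {
    "X_2", "K_Cl", "A_l", "m_G", "sigma_G", "tau_G", "sigma_F",
    "K_Lip", "K_Rem", "m_F", "G_b", "C_f0", "C_f",
}
_EPS_LB = 1e-8

_DELAY_NAMES = {"t_DelayLip", "t_DelayRem"}


def model_channels(model_id: str) -> tuple[str, ...]:
    return ("ffa",) if model_id == "MOD3" else ("glucose", "ffa")


def free_param_names(model_id: str, combo: "str | Combination") -> tuple[str, ...]:
    """Ordered names of the free parameters of a (model, combination) fit."""
    combo = get_combination(combo)
    if model_id == "MOD1":
        names = list(MOD1_NAMES)
    elif model_id == "MOD2":
        names = list(MOD2_NAMES)
    elif model_id == "MOD3":
        names = list(MOD3_NAMES)
    else:
        raise InvalidInputError(f"unknown model {model_id!r}")
    if model_id != "MOD3":
        if combo.ra_glucose == "type1":
            names += RA_G_TYPE1_NAMES
        elif combo.ra_glucose == "type2":
            names += RA_G_TYPE2_NAMES
    if combo.ra_ffa == "type1":
        names += RA_F_TYPE1_NAMES
    return tuple(names)


def build_params(
    model_id: str,
    combo: "str | Combination",
    values: Mapping[str, float],
    fixed: Mapping[str, float] | None = None,
) -> tuple[ModelParams, RaSet]:
    """Assemble model and Ra parameter objects from a name->value mapping."""
    combo = get_combination(combo)
    fx = dict(FIXED_DEFAULTS)
    if fixed:
        fx.update(fixed)

    def v(name: str) -> float:
        return float(values[name]) if name in values else float(fx[name])

    if model_id == "MOD1":
        model = Mod1Params(
            *(v(n) for n in MOD1_NAMES), A_lipo=v("A_lipo"), A_Cl=v("A_Cl")
        )
    elif model_id == "MOD2":
        model = Mod2Params(*(v(n) for n in MOD2_NAMES))
    elif model_id == "MOD3":
        model = Mod3Params(*(v(n) for n in MOD3_NAMES))
    else:
        raise InvalidInputError(f"unknown model {model_id!r}")

    ra = RaSet()
    if model_id != "MOD3":
        if combo.ra_glucose == "type1":
            ra.glucose = RaType1Glucose(v("Delta_G"), v("m_G"), v("sigma_G"))
        elif combo.ra_glucose == "type2":
            ra.glucose = RaType2Glucose(v("phi_G"), v("tau_G"))
    if combo.ra_ffa == "type1":
        ra.ffa = RaType1FFA(v("Delta_F"), v("sigma_F"), m_F=v("m_F"), t_0F=v("t_0F"))
    return model, ra


def resolve_sigma2(
    subject: SubjectData,
    model_id: str,
    combo: Combination,
    mode: str = "subject",
) -> dict[tuple[str, str], float]:
    """Variance weights for every active (protocol, channel).

    mode "subject": use the subject's stored sigma2, filling gaps with SSA
    estimates; "ssa": always re-estimate; "unit": all ones (for noiseless
    synthetic fits).
    """
    out: dict[tuple[str, str], float] = {}
    for kind in combo.protocols:
        for chan in model_channels(model_id):
            key = (kind, chan)
            if mode == "unit":
                out[key] = 1.0
            elif mode == "subject" and key in subject.sigma2:
                out[key] = float(subject.sigma2[key])
            elif mode in ("subject", "ssa"):
                lo, hi = PROTOCOL_BY_KIND[kind].fit_window
                out[key] = estimate_variance(subject.get(kind, chan).window(lo, hi)).sigma2
            else:
                raise InvalidInputError(f"unknown variance mode {mode!r}")
    return out


def _residual_context(subject: SubjectData, model_id: str, combo: Combination):
    """Precompute per-protocol inputs that do not depend on parameters."""
    ctx = []
    for kind in combo.protocols:
        protocol = PROTOCOL_BY_KIND[kind]
        if not subject.has_protocol(kind):
            raise InvalidInputError(
                f"combination {combo.id} requires protocol {kind}, "
                f"missing from subject {subject.name!r}"
            )
        insulin = InsulinInput(subject.insulin(kind))
        state0 = initial_conditions(protocol, subject, model_id)
        times = protocol.fitted_times()
        data = {
            chan: np.array(
                [subject.get(kind, chan).value_at(t) for t in times]
            )
            for chan in model_channels(model_id)
        }
        ctx.append((protocol, insulin, state0, times, data))
    return ctx


def _weighted_residuals(values, subject, model_id, combo, sigma2, ctx, fixed, rtol):
    res = []
    try:
        model_p, ra = build_params(model_id, combo, values, fixed)
        for protocol, insulin, state0, times, data in ctx:
            traj = simulate(
                model_id, model_p, combo, protocol, insulin, state0, ra, rtol=rtol
            )
            for chan in model_channels(model_id):
                sd = np.sqrt(sigma2[(protocol.kind, chan)])
                res.append((data[chan] - traj.at_times(times, chan)) / sd)
    except (IntegrationError, InvalidParameterError) as exc:
        logger.warning("objective penalty for %s/%s: %s", model_id, combo.id, exc)
        n = sum(len(d) for *_, data in ctx for d in data.values())
        return np.full(n, np.sqrt(PENALTY / n))
    return np.concatenate(res)


def objective(
    params: Mapping[str, float],
    subject: SubjectData,
    model_id: str,
    combo: "str | Combination",
    sigma2: Mapping[tuple[str, str], float] | None = None,
    fixed: Mapping[str, float] | None = None,
    rtol: float = 1e-8,
) -> float:
    """Weighted sum of squared residuals for one parameter assignment."""
    combo = get_combination(combo)
    if sigma2 is None:
        sigma2 = resolve_sigma2(subject, model_id, combo)
    ctx = _residual_context(subject, model_id, combo)
    r = _weighted_residuals(params, subject, model_id, combo, sigma2, ctx, fixed, rtol)
    return float(r @ r)


def default_bounds(
    model_id: str,
    combo: "str | Combination",
    reference: Mapping[str, float],
    multiplier: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper bounds per free parameter.

    Lower bounds are 0 (a tiny epsilon for strictly-positive parameters);
    upper bounds are ``multiplier`` times the reference group means, with
    insulin delays additionally capped by the protocol window.
    """
    combo = get_combination(combo)
    names = free_param_names(model_id, combo)
    missing = [n for n in names if n not in reference]
    if missing:
        raise InvalidInputError(f"reference means missing for {missing}")
    lb, ub = [], []
    window = max(PROTOCOL_BY_KIND[k].fit_window[1] for k in combo.protocols)
    for n in names:
        ref = float(reference[n])
        lb.append(_EPS_LB if n in _STRICTLY_POSITIVE else 0.0)
        hi = multiplier * ref if ref > 0 else 1.0
        if n in _DELAY_NAMES:
            hi = min(hi, window)
        ub.append(hi)
    return np.array(lb), np.array(ub)


@dataclass
class FitConfig:
    """Controls for :func:`fit_subject`.

    reference: name->value means used for bounds and default starts.
    start_multipliers: deterministic multi-start scalings of the reference.
    n_random_starts: extra seeded log-normal jitters of the reference.
    variances: "subject" | "ssa" | "unit".
    tol: optimizer ftol/xtol/gtol (objective convergence tolerance).
    """

    reference: Mapping[str, float]
    start_multipliers: Sequence[float] = (1.0, 0.5, 1.5)
    n_random_starts: int = 0
    seed: int = 0
    bounds_multiplier: float = 5.0
    variances: str = "subject"
    tol: float = 1e-10
    rtol_sim: float = 1e-8
    diff_step: float = 1e-4
    max_nfev: int | None = None
    fixed: Mapping[str, float] = field(default_factory=dict)
    check_identifiability: bool = True


@dataclass
class FitResult:
    """Outcome of one subject x model x combination fit."""

    model_id: str
    combination: str
    params: dict[str, float]
    fixed: dict[str, float]
    model_params: ModelParams
    ra: RaSet
    objective: float
    n_data: int
    k_free: int
    residuals: dict[tuple[str, str], np.ndarray]
    sigma2: dict[tuple[str, str], float]
    converged: bool
    n_starts: int
    best_start: int
    message: str
    flat_params: list[str] = field(default_factory=list)


def _starts(names, reference, lb, ub, config) -> list[np.ndarray]:
    ref = np.array([float(reference[n]) for n in names])
    starts = [np.clip(m * ref, lb, ub) for m in config.start_multipliers]
    if config.n_random_starts:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_random_starts):
            jitter = np.exp(rng.normal(0.0, 0.3, ref.size))
            starts.append(np.clip(ref * jitter, lb, ub))
    return starts


def fit_subject(
    subject: SubjectData,
    model_id: str,
    combo: "str | Combination",
    config: FitConfig,
) -> FitResult:
    """Estimate one subject's parameters by bounded multi-start least squares.

    Each start is refined with a trust-region reflective solver; the best
    converged local optimum is returned.  Fits are deterministic given the
    seed and start set.
    """
    combo = get_combination(combo)
    names = free_param_names(model_id, combo)
    fixed = dict(FIXED_DEFAULTS)
    fixed.update(config.fixed)
    sigma2 = resolve_sigma2(subject, model_id, combo, config.variances)
    ctx = _residual_context(subject, model_id, combo)
    lb, ub = default_bounds(model_id, combo, config.reference, config.bounds_multiplier)
    starts = _starts(names, config.reference, lb, ub, config)
    x_scale = np.maximum(np.abs(np.array([config.reference[n] for n in names])), _EPS_LB)

    def fun(x: np.ndarray) -> np.ndarray:
        values = dict(zip(names, x))
        return _weighted_residuals(
            values, subject, model_id, combo, sigma2, ctx, fixed, config.rtol_sim
        )

    best = None
    best_idx = -1
    n_ok = 0
    for i, x0 in enumerate(starts):
        try:
            sol = least_squares(
                fun,
                x0,
                bounds=(lb, ub),
                method="trf",
                x_scale=x_scale,
                diff_step=config.diff_step,
                ftol=config.tol,
                xtol=config.tol,
                gtol=config.tol,
                max_nfev=config.max_nfev,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("start %d failed: %s", i, exc)
            continue
        if sol.status > 0:
            n_ok += 1
        if best is None or sol.cost < best.cost:
            best, best_idx = sol, i
    if best is None or n_ok == 0:
        raise NonConvergenceError(
            f"no start converged for {subject.name}/{model_id}/{combo.id}"
        )

    values = dict(zip(names, best.x))
    model_p, ra = build_params(model_id, combo, values, fixed)
    obj = float(2.0 * best.cost)

    residuals: dict[tuple[str, str], np.ndarray] = {}
    for protocol, insulin, state0, times, data in ctx:
        traj = simulate(
            model_id, model_p, combo, protocol, insulin, state0, ra,
            rtol=config.rtol_sim,
        )
        for chan in model_channels(model_id):
            residuals[(protocol.kind, chan)] = data[chan] - traj.at_times(times, chan)
    n_data = sum(r.size for r in residuals.values())

    flat: list[str] = []
    if config.check_identifiability:
        for j, nm in enumerate(names):
            deltas = []
            for f in (0.9, 1.1):
                x = best.x.copy()
                x[j] = np.clip(x[j] * f, lb[j], ub[j])
                r = fun(x)
                deltas.append(abs(float(r @ r) - obj))
            if max(deltas) < 1e-6:
                flat.append(nm)
        if flat:
            logger.info("flat (possibly unidentifiable) parameters: %s", flat)

    return FitResult(
        model_id=model_id,
        combination=combo.id,
        params=values,
        fixed=fixed,
        model_params=model_p,
        ra=ra,
        objective=obj,
        n_data=n_data,
        k_free=len(names),
        residuals=residuals,
        sigma2=sigma2,
        converged=n_ok > 0,
        n_starts=len(starts),
        best_start=best_idx,
        message=str(best.message),
        flat_params=flat,
    )
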