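"""Protocol-faithful synthetic subjects and named parameter fixtures.

No subject-level data accompany the study design this package implements,
so every pipeline stage is exercised on synthetic subjects: a smooth
parametric insulin input is built for each protocol, the chosen model is
integrated with a fixture parameter set, glucose and FFA are sampled at
the protocol times, and seeded multiplicative Gaussian noise emulates
assay variability.

Fixtures are group-mean parameter sets (African-American "AA" and white
"WH" groups, per model and simulation combination) and double as the
reference means for fitting bounds and starts.

The generator is self-consistent with the fitting conventions: meal-test
series start at the simulated initial state, and the IV-test samples
before the 10-min fitting window are held at the initial state so that
their average reproduces it exactly.  Noise is applied only at sample
times, never inside the integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .combinations import get_combination
from .errors import InvalidInputError
from .fitting import build_params
from .models import ModelState, steady_state
from .protocols import PROTOCOL_BY_KIND, Protocol, simulate
from .timeseries import SubjectData, TimeSeries


@dataclass(frozen=True)
class InsulinShape:
    """Parametric insulin excursions (uU/mL, minutes).

    FSIGT: basal level, an endogenous first-phase peak after the t=0
    glucose bolus, and a second exogenous peak after the 20-min insulin
    bolus.  MT: a monophasic peak relaxing back toward basal by 360 min.
    Peak heights are measured above basal; each pulse is a gamma-like
    bump h * (s/tp) * exp(1 - s/tp) peaking at s = tp.
    """

    basal: float = 10.0
    fsigt_peak: float = 90.0
    fsigt_peak_time: float = 3.0
    fsigt_spike: float = 60.0
    fsigt_spike_time: float = 5.0
    mt_peak: float = 35.0
    mt_peak_time: float = 40.0

    def __post_init__(self) -> None:
        for f in (
            "basal", "fsigt_peak", "fsigt_spike", "mt_peak",
            "fsigt_peak_time", "fsigt_spike_time", "mt_peak_time",
        ):
            if getattr(self, f) < 0:
                raise InvalidInputError(f"{f} must be >= 0")


DEFAULT_SHAPE = InsulinShape()


def _pulse(s: float, height: float, tp: float) -> float:
    if s <= 0.0 or height == 0.0:
        return 0.0
    return height * (s / tp) * math.exp(1.0 - s / tp)


@dataclass(frozen=True)
class Fixture:
    """Named group-mean parameter set for one model and combination."""

    name: str
    model_id: str
    combination: str
    values: Mapping[str, float]


_FIXTURES: dict[str, Fixture] = {}


def _register(name, model_id, combination, **values) -> None:
    _FIXTURES[name] = Fixture(name, model_id, combination, values)


# MOD 1 group means. AA-C3: AA group, combination 3 (Type I glucose Ra only);
# WH-C4: white group, combination 4 (Type II glucose Ra); AA-C2: AA group,
# combination 2 (Type I Ra for glucose and FFA).
_register(
    "AA-C3", "MOD1", "C3",
    S_G=5.6e-3, G_b=136.4, S_I=3.2e-4, C_x=0.12, I_bx=4.6,
    l_0=0.006, l_2=0.12, X_2=12.7, C_f=0.047, K_Cl=21.7,
    m_G=124.9, sigma_G=0.66, Delta_G=67.9,
)
_register(
    "WH-C4", "MOD1", "C4",
    S_G=0.0087, G_b=142.8, S_I=5.5e-4, C_x=0.091, I_bx=5.5,
    l_0=7.4e-4, l_2=0.049, X_2=12.6, C_f=0.029, K_Cl=6.1,
    phi_G=58.1, tau_G=33.1,
)
_register(
    "AA-C2", "MOD1", "C2",
    S_G=0.0046, G_b=186.5, S_I=3.1e-4, C_x=0.076, I_bx=3.02,
    l_0=0.0026, l_2=0.12, X_2=12.7, C_f=0.035, K_Cl=23.32,
    m_G=118.4, sigma_G=0.67, Delta_G=65.9, sigma_F=0.61, Delta_F=0.32,
)
# MOD 2 AA group means, combination 3.
_register(
    "AA-MOD2-C3", "MOD2", "C3",
    S_G=6.5e-3, G_b=179.3, S_I=3.9e-4, C_x=0.11, I_bx=7.4,
    l_0=0.033, l_2=0.23, X_2=13.4, A_l=2.1, C_f0=0.23,
    m_G=124.6, sigma_G=0.71, Delta_G=61.2,
)
# MOD 3 AA group means, combination 1 (FFA kinetics only, no Ra).
_register(
    "AA-MOD3-C1", "MOD3", "C1",
    V_m_Lip=0.54, t_DelayLip=26.9, K_Lip=25.2, h_lip=4.1,
    k_Rem=0.33, V_m_Rem=0.11, t_DelayRem=12.0, K_Rem=47.4, h_Rem=5.3,
)


def fixture(name: str) -> Fixture:
    """Look up a registered fixture by name."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def synth_insulin(protocol: Protocol | str, shape: InsulinShape = DEFAULT_SHAPE) -> TimeSeries:
    """Deterministic smooth insulin series at the protocol sample times."""
    if isinstance(protocol, str):
        protocol = PROTOCOL_BY_KIND[protocol]
    times = protocol.sample_times
    vals = np.empty_like(times)
    for i, t in enumerate(times):
        if protocol.kind == "FSIGT":
            v = shape.basal
            if t > 0:
                v += _pulse(t, shape.fsigt_peak, shape.fsigt_peak_time)
            if t > 20:
                v += _pulse(t - 20.0, shape.fsigt_spike, shape.fsigt_spike_time)
        else:
            v = shape.basal + _pulse(t, shape.mt_peak, shape.mt_peak_time)
        vals[i] = v
    return TimeSeries(times.copy(), vals)


def synth_subject(
    fixture_name: str,
    insulin_shape: InsulinShape = DEFAULT_SHAPE,
    noise_cv: float = 0.0,
    seed: int | None = None,
    g0_fsigt: float = 250.0,
    g0_mt: float = 90.0,
    g_prezero: float = 90.0,
    noise_kind: str = "multiplicative",
) -> SubjectData:
    """Generate one synthetic subject from a named fixture.

    The fixture's model is simulated over its combination's protocols with
    the parametric insulin input; glucose and FFA are sampled at the
    protocol times and perturbed with independent Gaussian noise of
    coefficient of variation ``noise_cv`` (or additive noise with standard
    deviation ``noise_cv`` times the channel mean when
    ``noise_kind="additive"``).  The stored per-channel sigma2 are the true
    noise variances when noise_cv > 0, and 1 otherwise.

    Initial states: meal test starts at (g0_mt, X=0, basal FFA); the IV
    test starts at t=10 min from (g0_fsigt, X=0, basal FFA), with the
    pre-window samples pinned to that state so the 0-10 min average used
    for fitting reproduces it.  Basal FFA is the model's X=0 fixed point.
    """
    if noise_cv < 0:
        raise InvalidInputError("noise_cv must be >= 0")
    if noise_kind not in ("multiplicative", "additive"):
        raise InvalidInputError(f"unknown noise_kind {noise_kind!r}")
    fix = fixture(fixture_name)
    combo = get_combination(fix.combination)
    model_p, ra = build_params(fix.model_id, combo, fix.values)
    f_basal = steady_state(model_p).F
    rng = np.random.default_rng(seed)

    subject = SubjectData(name=f"{fixture_name}-synth")
    for kind in combo.protocols:
        protocol = PROTOCOL_BY_KIND[kind]
        insulin = synth_insulin(protocol, insulin_shape)
        subject.series[(kind, "insulin")] = insulin
        g0 = g0_fsigt if kind == "FSIGT" else g0_mt
        state0 = ModelState(g0, 0.0, f_basal)
        traj = simulate(fix.model_id, model_p, combo, protocol, insulin, state0, ra)
        times = protocol.sample_times
        in_window = (times >= protocol.fit_window[0]) & (times <= protocol.fit_window[1])
        channels = ("ffa",) if fix.model_id == "MOD3" else ("glucose", "ffa")
        for chan in channels:
            vals = np.empty_like(times)
            vals[in_window] = traj.at_times(times[in_window], chan)
            if kind == "FSIGT":
                # pre-window: pinned to the initial state; pre-zero glucose
                # at a fasting basal (never fitted, basal summaries only)
                pre = ~in_window
                if chan == "glucose":
                    vals[pre & (times >= 0)] = g0
                    vals[pre & (times < 0)] = g_prezero
                else:
                    vals[pre] = f_basal
            true_vals = vals.copy()
            if noise_cv > 0:
                if noise_kind == "multiplicative":
                    vals = vals * (1.0 + noise_cv * rng.standard_normal(vals.size))
                else:
                    sd = noise_cv * abs(float(true_vals.mean()))
                    vals = vals + sd * rng.standard_normal(vals.size)
            subject.series[(kind, chan)] = TimeSeries(times.copy(), vals)
            if noise_cv > 0:
                if noise_kind == "multiplicative":
                    sigma2 = float(np.mean((noise_cv * true_vals[in_window]) ** 2))
                else:
                    sigma2 = (noise_cv * abs(float(true_vals.mean()))) ** 2
            else:
                sigma2 = 1.0
            subject.sigma2[(kind, chan)] = sigma2
    return subject


def perturbed_reference(fixture_name: str, factor: float) -> dict[str, float]:
    """Fixture values uniformly scaled by ``factor`` (optimizer starts)."""
    fix = fixture(fixture_name)
    return {k: factor * v for k, v in fix.values.items()}
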