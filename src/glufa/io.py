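"""CSV/JSON/YAML serialization for subjects, trajectories, fits and Ra.

Subject files are single CSVs with columns
``protocol,time_min,insulin,glucose,ffa`` (one subject per file; empty
cells mark unmeasured channels).  Units: glucose mg/dL, insulin uU/mL,
FFA mmol/L, time minutes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .backcalc import BackcalcResult
from .errors import InvalidInputError
from .fitting import FitConfig, FitResult
from .protocols import Trajectory
from .timeseries import CHANNELS, PROTOCOLS, SubjectData, TimeSeries

_SUBJECT_COLUMNS = ["protocol", "time_min", "insulin", "glucose", "ffa"]


def read_subject(path: str | Path, name: str | None = None) -> SubjectData:
    """Read a subject CSV; validates columns, numeric cells, increasing times."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    for col in _SUBJECT_COLUMNS[1:]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise InvalidInputError(f"{path}: non-numeric value in {col!r}: {exc}")
    subject = SubjectData(name=name or path.stem)
    for proto, grp in df.groupby("protocol"):
        if proto not in PROTOCOLS:
            raise InvalidInputError(f"{path}: unknown protocol {proto!r}")
        times = grp["time_min"].to_numpy(float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise InvalidInputError(
                f"{path}: {proto} times not strictly increasing at row {bad}"
            )
        for chan in CHANNELS:
            vals = grp[chan].to_numpy(float)
            keep = ~np.isnan(vals)
            if keep.any():
                subject.series[(proto, chan)] = TimeSeries(times[keep], vals[keep])
    if not subject.series:
        raise InvalidInputError(f"{path}: no measured channels")
    return subject


def write_subject(subject: SubjectData, path: str | Path) -> None:
    """Write a subject CSV (inverse of :func:`read_subject`)."""
    rows: dict[tuple[str, float], dict[str, Any]] = {}
    for (proto, chan), ts in subject.series.items():
        for t, v in zip(ts.times, ts.values):
            rows.setdefault((proto, float(t)), {})[chan] = v
    recs = [
        {"protocol": proto, "time_min": t, **vals}
        for (proto, t), vals in sorted(rows.items())
    ]
    pd.DataFrame(recs, columns=_SUBJECT_COLUMNS).to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    cols = {"time_min": traj.t}
    if traj.G is not None:
        cols["glucose"] = traj.G
    if traj.X is not None:
        cols["X"] = traj.X
    cols["ffa"] = traj.F
    pd.DataFrame(cols).to_csv(path, index=False)


def write_backcalc(result: BackcalcResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_min": result.t,
            "Ra": result.ra,
            "G_spline": result.g_spline,
            "dGdt": result.dgdt,
            "X": result.x,
        }
    ).to_csv(path, index=False)


def fit_to_dict(fit: FitResult) -> dict[str, Any]:
    """JSON-serializable view of a fit, with parameter provenance."""
    return {
        "model": fit.model_id,
        "combination": fit.combination,
        "params": dict(fit.params),
        "fixed": dict(fit.fixed),
        "objective": fit.objective,
        "n_data": fit.n_data,
        "k_free": fit.k_free,
        "converged": fit.converged,
        "n_starts": fit.n_starts,
        "best_start": fit.best_start,
        "message": fit.message,
        "flat_params": list(fit.flat_params),
        "sigma2": {f"{p}/{m}": v for (p, m), v in fit.sigma2.items()},
        "residuals": {
            f"{p}/{m}": [float(x) for x in r] for (p, m), r in fit.residuals.items()
        },
    }


def write_fit(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2))


def load_config(path: str | Path, reference: dict[str, float] | None = None) -> FitConfig:
    """Build a :class:`FitConfig` from a YAML key-value file.

    Recognized keys mirror the FitConfig fields; ``reference`` may be
    supplied in the file or by the caller (caller wins).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if reference is not None:
        raw["reference"] = reference
    if "reference" not in raw:
        raise InvalidInputError(f"{path}: config needs reference parameter means")
    known = {f.name for f in dataclasses.fields(FitConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"{path}: unknown config keys {sorted(unknown)}")
    return FitConfig(**raw)
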