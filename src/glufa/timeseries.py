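"""Core data containers: sampled time series and per-subject data bundles.

A :class:`TimeSeries` is one analyte sampled for one subject under one
protocol.  A :class:`SubjectData` collects the insulin / glucose / FFA
series of a subject for the IV glucose tolerance test (FSIGT) and/or the
meal test (MT), together with the per-(protocol, channel) residual
variances used to weight the fitting objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

PROTOCOLS = ("FSIGT", "MT")
CHANNELS = ("insulin", "glucose", "ffa")


@dataclass
class TimeSeries:
    """Paired (time [min], value) samples, strictly increasing in time."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InvalidInputError("times and values must be 1-D and equal length")
        if self.times.size == 0:
            raise InvalidInputError("empty time series")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise InvalidInputError("times and values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    def value_at(self, t: float) -> float:
        """Exact sample value at time ``t`` (must be a sample time)."""
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise InvalidInputError(f"no sample at t={t}")
        return float(self.values[idx[0]])

    def window(self, t_min: float, t_max: float) -> "TimeSeries":
        """Sub-series with t_min <= t <= t_max."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        if not mask.any():
            raise InvalidInputError("no samples in requested window")
        return TimeSeries(self.times[mask], self.values[mask])


@dataclass
class SubjectData:
    """All measured series of one subject, keyed by (protocol, channel).

    ``sigma2`` holds one residual-variance scalar per (protocol, channel),
    the weights of the chi-square-like fitting objective.
    """

    series: dict[tuple[str, str], TimeSeries] = field(default_factory=dict)
    sigma2: dict[tuple[str, str], float] = field(default_factory=dict)
    name: str = "subject"

    def __post_init__(self) -> None:
        for proto, chan in self.series:
            if proto not in PROTOCOLS or chan not in CHANNELS:
                raise InvalidInputError(f"unknown series key {(proto, chan)!r}")

    def has_protocol(self, protocol: str) -> bool:
        return any(p == protocol for p, _ in self.series)

    def get(self, protocol: str, channel: str) -> TimeSeries:
        try:
            return self.series[(protocol, channel)]
        except KeyError:
            raise InvalidInputError(
                f"subject {self.name!r} has no {channel} series for {protocol}"
            ) from None

    def insulin(self, protocol: str) -> TimeSeries:
        return self.get(protocol, "insulin")

    def glucose(self, protocol: str) -> TimeSeries:
        return self.get(protocol, "glucose")

    def ffa(self, protocol: str) -> TimeSeries:
        return self.get(protocol, "ffa")
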