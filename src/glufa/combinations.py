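"""Simulation combinations: which protocols are fitted and which meal Ra
terms are switched on.

Ra terms apply to the meal test only; the IV glucose tolerance test never
includes an appearance rate (all input is the bolus, represented through
the measured insulin and the initial state).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError


@dataclass(frozen=True)
class Combination:
    """One fitting configuration: active protocols and meal-Ra choices.

    ``ra_glucose`` in {"none", "type1", "type2"}; ``ra_ffa`` in
    {"none", "type1"}.
    """

    id: str
    protocols: tuple[str, ...]
    ra_glucose: str
    ra_ffa: str

    def __post_init__(self) -> None:
        if self.ra_glucose not in ("none", "type1", "type2"):
            raise InvalidInputError(f"bad ra_glucose {self.ra_glucose!r}")
        if self.ra_ffa not in ("none", "type1"):
            raise InvalidInputError(f"bad ra_ffa {self.ra_ffa!r}")


COMBINATIONS: dict[str, Combination] = {
    "C1": Combination("C1", ("FSIGT", "MT"), "none", "none"),
    "C2": Combination("C2", ("FSIGT", "MT"), "type1", "type1"),
    "C3": Combination("C3", ("FSIGT", "MT"), "type1", "none"),
    "C4": Combination("C4", ("FSIGT", "MT"), "type2", "none"),
    "S1": Combination("S1", ("FSIGT",), "none", "none"),
    "S2": Combination("S2", ("MT",), "type1", "none"),
    "S3": Combination("S3", ("MT",), "type2", "none"),
}


def get_combination(combo: "str | Combination") -> Combination:
    if isinstance(combo, Combination):
        return combo
    try:
        return COMBINATIONS[combo]
    except KeyError:
        raise InvalidInputError(f"unknown combination {combo!r}") from None
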