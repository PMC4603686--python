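"""Vital-rate parameter sets for a single plant group.

A "group" is one combination of endophytic status (symbiotic S /
non-symbiotic NS) and edaphic resource level (natural / fertilized F+).
Six vital rates are estimated from census data; adult survival ``S_A`` is
a model constant (no adult deaths were observed in the field, so it is
fixed rather than estimated, with a robustness sweep available in
:mod:`festuca_demography.matrix`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace


class VitalRateError(ValueError):
    """A vital-rate parameter is outside its admissible range."""


_PROBABILITY_FIELDS = ("s1", "s2", "e1", "P", "e0", "S_A")


@dataclass(frozen=True)
class VitalRates:
    """The demographic parameters of one plant group.

    Parameters
    ----------
    s1 : float
        Probability of a seedling surviving its first year.
    s2 : float
        Probability of a juvenile surviving one year.
    e1 : float
        Probability of a year-one juvenile reaching the reproductive
        threshold of 30 tillers.
    f1 : float
        Mean number of seeds produced per flowering plant (>= 0).
    P : float
        Probability of an adult plant flowering.
    e0 : float
        Probability of seedling emergence from a sown seed.
    S_A : float
        Adult survival probability; a model constant, default 0.95.
    """

    s1: float
    s2: float
    e1: float
    f1: float
    P: float
    e0: float
    S_A: float = 0.95

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise VitalRateError(
                    f"{name}={value!r} is not a probability in [0, 1]"
                )
        if self.f1 < 0:
            raise VitalRateError(f"f1={self.f1!r} must be >= 0")

    def with_adult_survival(self, S_A: float) -> "VitalRates":
        """Return a copy with a different fixed adult survival rate."""
        return replace(self, S_A=S_A)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "VitalRates":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise VitalRateError(f"unknown vital-rate keys: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class VitalRateUncertainty:
    """Standard errors attached to a :class:`VitalRates` set.

    A zero entry means the parameter is treated as known exactly (the
    convention used for the fixed adult survival rate).
    """

    s1: float = 0.0
    s2: float = 0.0
    e1: float = 0.0
    f1: float = 0.0
    P: float = 0.0
    e0: float = 0.0
    S_A: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise VitalRateError(f"SEM for {f.name} must be >= 0")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "VitalRateUncertainty":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise VitalRateError(f"unknown SEM keys: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items()})
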