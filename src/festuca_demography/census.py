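"""Synthetic census generation emulating the field and sowing design.

The design is a 2×2 factorial (endophytic status × resource level) of
mother-plant cohorts: per group, 20 mother plants with 50 harvested
seeds each sown in boxes, 10 emerged seedlings per mother followed to
the juvenile stage, and (for S mothers) endophyte assays on seeds,
seedlings and juveniles.  Counts are binomial at each stage transition;
per-plant seed production is negative-binomial, since the reported
between-mother spread in seed counts is far beyond Poisson.

The generator is the ground-truth counterpart of
:mod:`festuca_demography.estimation`: estimates from a generated census
recover the configured truths up to sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupled import TransmissionRates
from .estimation import CENSUS_COLUMNS, validate_census
from .vitalrates import VitalRates


@dataclass(frozen=True)
class DesignSizes:
    """Sampling effort per group, defaulting to the field design."""

    n_mothers: int = 20
    seeds_sown: int = 50
    seedlings_followed: int = 10
    seeds_tested: int = 24
    seedlings_tested: int = 5
    juveniles_tested: int = 5

    def __post_init__(self) -> None:
        for name in (
            "n_mothers", "seeds_sown", "seedlings_followed",
            "seeds_tested", "seedlings_tested", "juveniles_tested",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"design size {name} must be >= 1")


@dataclass(frozen=True)
class GroupTruth:
    """Ground truth for one group: vital rates, transmission (S groups
    only), seed-count overdispersion and design sizes.

    ``seed_dispersion`` is the negative-binomial shape k (variance
    mu + mu**2/k); the default k = 1 reproduces the reported
    between-mother SEM magnitudes for seed counts at 20 mothers.
    """

    rates: VitalRates
    transmission: "TransmissionRates | None" = None
    seed_dispersion: float = 1.0
    design: DesignSizes = field(default_factory=DesignSizes)

    def __post_init__(self) -> None:
        if self.seed_dispersion <= 0:
            raise ValueError("seed_dispersion must be > 0")


def _negative_binomial(
    rng: np.random.Generator, mu: float, k: float, size: int
) -> np.ndarray:
    if mu == 0.0:
        return np.zeros(size, dtype=int)
    return rng.negative_binomial(k, k / (k + mu), size=size)


def generate_census(
    truths: dict[tuple[str, str], GroupTruth], seed: int
) -> pd.DataFrame:
    """Generate one census table; deterministic given ``seed``.

    ``truths`` maps (endophyte_status, resource) to a :class:`GroupTruth`.
    NS mothers carry missing (NaN) transmission-assay fields, matching
    how the assays are only defined for symbiotic mothers.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for (status, resource), truth in truths.items():
        if status == "S" and truth.transmission is None:
            raise ValueError(
                f"group {(status, resource)!r} is symbiotic but has no "
                "transmission truth"
            )
        v, d = truth.rates, truth.design
        for m in range(d.n_mothers):
            emerged = int(rng.binomial(d.seeds_sown, v.e0))
            alive = int(rng.binomial(emerged, v.s1))
            followed = min(d.seedlings_followed, emerged)
            juv_alive = int(rng.binomial(followed, v.s2))
            ge30 = int(rng.binomial(juv_alive, v.e1))
            flowered = int(rng.random() < v.P)
            seeds = (
                int(_negative_binomial(rng, v.f1, truth.seed_dispersion, 1)[0])
                if flowered
                else 0
            )
            row = {
                "mother_id": f"{status}-{resource}-{m + 1:02d}",
                "endophyte_status": status,
                "resource": resource,
                "seeds_sown": d.seeds_sown,
                "seedlings_emerged": emerged,
                "seedlings_alive": alive,
                "juveniles_followed": followed,
                "juveniles_alive": juv_alive,
                "juveniles_ge30_tillers": ge30,
                "flowered": flowered,
                "seeds_produced": seeds,
            }
            if status == "S":
                T = truth.transmission
                row.update(
                    seeds_tested=d.seeds_tested,
                    seeds_positive=int(rng.binomial(d.seeds_tested, T.T_A)),
                    seedlings_tested=d.seedlings_tested,
                    seedlings_positive=int(
                        rng.binomial(d.seedlings_tested, T.T_seed)
                    ),
                    juveniles_tested=d.juveniles_tested,
                    juveniles_positive=int(
                        rng.binomial(d.juveniles_tested, T.T_S)
                    ),
                )
            else:
                row.update(
                    seeds_tested=np.nan, seeds_positive=np.nan,
                    seedlings_tested=np.nan, seedlings_positive=np.nan,
                    juveniles_tested=np.nan, juveniles_positive=np.nan,
                )
            rows.append(row)
    df = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
    return validate_census(df)
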