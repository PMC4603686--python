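"""Coupled projection model for a mixed symbiotic / non-symbiotic
population with imperfect vertical transmission.

The 8-stage matrix stacks the four symbiotic (S) stages on top of the
four non-symbiotic (NS) stages.  The endophyte passes only from mother
to offspring, so there are no NS→S arcs: the matrix is block
lower-triangular,

    B = [[ A_S~ , 0    ],
         [ L    , A_NS ]]

where ``A_S~`` is the symbiotic block with its fecundity arc discounted
by adult→seed transmission (``F_S · T_A · T_seed``) and its
seedling→juvenile-1 arc discounted by seedling→juvenile retention
(``G_J1,S · T_S``), ``A_NS`` is the plain single-status matrix for NS
plants, and the leakage block ``L`` routes the transmission failures
into the NS stages.  Losing the endophyte makes a plant demographically
NS, so leaked offspring simply join the NS cohort.

Because of the triangular structure the symbiont persists exactly when
the discounted S-block growth rate exceeds the NS growth rate; the
long-run endophyte prevalence follows from the dominant eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .matrix import (
    STAGES,
    StageMatrix,
    build_projection_matrix,
    dominant_eigen,
)
from .vitalrates import VitalRateError, VitalRates

COUPLED_STAGES = tuple(f"{s}_S" for s in STAGES) + tuple(
    f"{s}_NS" for s in STAGES
)

S_SLICE = slice(0, 4)
NS_SLICE = slice(4, 8)


@dataclass(frozen=True)
class TransmissionRates:
    """Vertical transmission probabilities of the endophyte.

    T_A: adult → seed retention; T_S: seedling → juvenile-1 retention;
    T_seed: optional seed → seedling retention (measured ≈ 0.97 but not
    part of the named life-cycle arcs, so it defaults to 1).
    """

    T_A: float
    T_S: float
    T_seed: float = 1.0

    def __post_init__(self) -> None:
        for name in ("T_A", "T_S", "T_seed"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise VitalRateError(
                    f"{name}={value!r} is not a probability in [0, 1]"
                )


@dataclass(frozen=True)
class CoupledMatrix:
    """8x8 coupled projection matrix (S stages 0–3, NS stages 4–7)."""

    B: np.ndarray
    s_block: StageMatrix
    ns_block: StageMatrix

    @property
    def A(self) -> np.ndarray:  # array protocol shared with StageMatrix
        return self.B

    @property
    def leakage(self) -> np.ndarray:
        return self.B[NS_SLICE, S_SLICE]


def _as_stage_matrix(v: "VitalRates | StageMatrix") -> StageMatrix:
    return v if isinstance(v, StageMatrix) else build_projection_matrix(v)


def build_coupled(
    vS: "VitalRates | StageMatrix",
    vNS: "VitalRates | StageMatrix",
    T: TransmissionRates,
) -> CoupledMatrix:
    """Assemble the coupled matrix from the two groups' vital rates and
    the transmission rates.

    Either group may be given as a :class:`VitalRates` set (the matrix
    is assembled from it) or directly as a :class:`StageMatrix` (e.g. a
    transcribed published matrix).  With all rates interior there are
    14 structurally non-zero arcs: six per status block plus the two
    leakage arcs.  Perfect transmission (T = 1) gives an exactly
    block-diagonal matrix.
    """
    A_S = _as_stage_matrix(vS)
    A_NS = _as_stage_matrix(vNS)
    F_S = A_S["F"]
    G_J1_S = A_S["G_J1"]
    retained_seed = T.T_A * T.T_seed

    S_block = StageMatrix.from_elements(
        F=F_S * retained_seed,
        G_J1=G_J1_S * T.T_S,
        G_J2=A_S["G_J2"],
        G_A1=A_S["G_A1"],
        G_A2=A_S["G_A2"],
        S_A=A_S["S_A"],
    )
    B = np.zeros((8, 8))
    B[S_SLICE, S_SLICE] = S_block.A
    B[NS_SLICE, NS_SLICE] = A_NS.A
    # transmission failures join the NS cohort at the same stage
    B[4, 3] = F_S * (1.0 - retained_seed)
    B[5, 0] = G_J1_S * (1.0 - T.T_S)
    return CoupledMatrix(B=B, s_block=S_block, ns_block=A_NS)


def s_block_lambda(
    vS: "VitalRates | StageMatrix", T: TransmissionRates
) -> float:
    """Growth rate of the symbiotic lineage after transmission losses.

    This is the dominant eigenvalue of the discounted S block; it equals
    the single-status λ when transmission is perfect and governs
    persistence: the symbiont invades iff it exceeds the NS λ.
    """
    return dominant_eigen(build_coupled(vS, vS, T).s_block).lam


def _stage_mask(stage_set: "Iterable[str] | None") -> np.ndarray:
    if stage_set is None:
        stage_set = STAGES
    stage_set = set(stage_set)
    unknown = stage_set - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if not stage_set:
        raise ValueError("stage_set must be non-empty")
    return np.array([s in stage_set for s in STAGES])


def asymptotic_prevalence(
    B: CoupledMatrix, stage_set: "Iterable[str] | None" = None
) -> float:
    """Long-run endophyte prevalence (share of S plants) in the coupled
    population, restricted to ``stage_set`` (default: all stages).

    If the discounted S block cannot out-grow the NS block the symbiont
    frequency tends to 0.  Otherwise the dominant eigenvalue of the
    coupled matrix is the S-block λ and the NS components of its
    eigenvector solve the forced balance ``(λI − A_NS) x = L w_S``; this
    linear solve avoids the slow power-iteration convergence that occurs
    when the block eigenvalues are close.
    """
    mask = _stage_mask(stage_set)
    lam_S = dominant_eigen(B.s_block).lam
    lam_NS = dominant_eigen(B.ns_block).lam
    if lam_S <= lam_NS:
        return 0.0
    K = lam_S * np.eye(4) - B.ns_block.A
    if abs(np.linalg.det(K)) < 1e-12 * lam_S**4:
        raise np.linalg.LinAlgError(
            "coupled eigenproblem singular: S-block lambda coincides with "
            "an NS-block eigenvalue"
        )
    w_S = dominant_eigen(B.s_block).w
    x = np.linalg.solve(K, B.leakage @ w_S)
    s_part = float(w_S[mask].sum())
    ns_part = float(x[mask].sum())
    return s_part / (s_part + ns_part)


def finite_horizon_prevalence(
    B: CoupledMatrix,
    n0: np.ndarray,
    t: int,
    stage_set: "Iterable[str] | None" = None,
) -> float:
    """S-share of the projected population at time ``t``.

    The projection is renormalized to total 1 at every step: prevalence
    is invariant to population scale, and renormalizing keeps long
    horizons (growth compounding over thousands of years) within
    floating-point range.
    """
    mask = _stage_mask(stage_set)
    n_t = np.asarray(n0, dtype=float)
    if n_t.shape != (8,):
        raise ValueError("n0 must have shape (8,)")
    if np.any(n_t < 0):
        raise ValueError("initial stage vector must be nonnegative")
    if t < 0:
        raise ValueError("t must be >= 0")
    for _ in range(t):
        n_t = B.B @ n_t
        total = n_t.sum()
        if total > 0:
            n_t = n_t / total
    s_part = float(n_t[S_SLICE][mask].sum())
    ns_part = float(n_t[NS_SLICE][mask].sum())
    total = s_part + ns_part
    if total <= 0:
        raise ValueError(f"no individuals in stage_set at t={t}")
    return s_part / total


DEFAULT_N0 = np.array([0, 0, 0, 100.0, 0, 0, 0, 100.0])
Criterion = Literal["asymptotic", "finite_horizon"]


@dataclass(frozen=True)
class SweepResult:
    """Prevalence and growth rates along a transmission-rate grid."""

    table: pd.DataFrame
    varied: str
    fixed: dict[str, float]
    criterion: str
    horizon: "int | None"


def _transmission_for(varied: str, value: float, fixed: dict) -> TransmissionRates:
    rates = dict(fixed)
    rates[varied] = value
    return TransmissionRates(**rates)


def transmission_sweep(
    vS: "VitalRates | StageMatrix",
    vNS: "VitalRates | StageMatrix",
    varied: Literal["T_A", "T_S"],
    fixed: "dict[str, float] | None" = None,
    grid: "Sequence[float] | None" = None,
    criterion: Criterion = "asymptotic",
    horizon: int = 50,
    n0: "np.ndarray | None" = None,
    stage_set: "Iterable[str] | None" = None,
) -> SweepResult:
    """Endophyte prevalence and growth rates as one transmission rate
    varies over [0, 1] with the other held fixed.

    ``fixed`` holds the non-varied rates; by default the non-varied rate
    is 1 (the convention used for published prevalence-vs-transmission
    curves), and observed values can be supplied instead.
    """
    if varied not in ("T_A", "T_S"):
        raise ValueError("varied must be 'T_A' or 'T_S'")
    defaults = {"T_A": 1.0, "T_S": 1.0, "T_seed": 1.0}
    if fixed:
        defaults.update(fixed)
    defaults.pop(varied, None)
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    grid = np.sort(np.asarray(grid, dtype=float))
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("grid values must lie in [0, 1]")
    if n0 is None:
        n0 = DEFAULT_N0

    rows = []
    for value in grid:
        T = _transmission_for(varied, float(value), defaults)
        B = build_coupled(vS, vNS, T)
        lam_S = dominant_eigen(B.s_block).lam
        lam_coupled = dominant_eigen(B.B).lam
        if criterion == "asymptotic":
            prev = asymptotic_prevalence(B, stage_set)
        elif criterion == "finite_horizon":
            prev = finite_horizon_prevalence(B, n0, horizon, stage_set)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        rows.append(
            {
                "varied_rate": float(value),
                "prevalence": prev,
                "lambda_coupled": lam_coupled,
                "lambda_S_block": lam_S,
            }
        )
    return SweepResult(
        table=pd.DataFrame(rows),
        varied=varied,
        fixed=defaults,
        criterion=criterion,
        horizon=horizon if criterion == "finite_horizon" else None,
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Persistence threshold for one transmission rate.

    ``rate`` is the smallest value of the varied rate at which the
    symbiont persists; ``at_boundary`` flags that no sign change existed
    on [0, 1] so the returned value is an endpoint, not a root.
    """

    rate: float
    varied: str
    criterion: str
    at_boundary: bool


def persistence_threshold(
    vS: "VitalRates | StageMatrix",
    vNS: "VitalRates | StageMatrix",
    varied: Literal["T_A", "T_S"],
    fixed: "dict[str, float] | None" = None,
    criterion: Criterion = "asymptotic",
    cutoff: float = 0.01,
    grid: "Sequence[float] | None" = None,
    horizon: int = 50,
    n0: "np.ndarray | None" = None,
    tol: float = 1e-6,
) -> ThresholdResult:
    """Transmission rate below which the symbiont frequency tends to 0.

    Under the asymptotic criterion this is the root of
    ``λ_S-block(rate) = λ_NS`` (bisection to ``tol``); under the
    finite-horizon criterion it is the smallest grid value whose
    horizon prevalence reaches ``cutoff``.
    """
    from scipy.optimize import brentq

    defaults = {"T_A": 1.0, "T_S": 1.0, "T_seed": 1.0}
    if fixed:
        defaults.update(fixed)
    defaults.pop(varied, None)

    if criterion == "asymptotic":
        lam_NS = dominant_eigen(_as_stage_matrix(vNS)).lam

        def gap(value: float) -> float:
            T = _transmission_for(varied, value, defaults)
            return s_block_lambda(vS, T) - lam_NS

        g0, g1 = gap(0.0), gap(1.0)
        if g0 >= 0:  # persists even with total loss at this arc
            return ThresholdResult(0.0, varied, criterion, at_boundary=True)
        if g1 <= 0:  # cannot persist even with perfect transmission
            return ThresholdResult(1.0, varied, criterion, at_boundary=True)
        root = float(brentq(gap, 0.0, 1.0, xtol=tol))
        return ThresholdResult(root, varied, criterion, at_boundary=False)

    if criterion == "finite_horizon":
        sweep = transmission_sweep(
            vS, vNS, varied, fixed=fixed, grid=grid,
            criterion="finite_horizon", horizon=horizon, n0=n0,
        )
        tab = sweep.table
        hit = tab[tab["prevalence"] >= cutoff]
        if hit.empty:
            return ThresholdResult(1.0, varied, criterion, at_boundary=True)
        rate = float(hit["varied_rate"].iloc[0])
        return ThresholdResult(
            rate, varied, criterion, at_boundary=rate == tab["varied_rate"].iloc[0]
        )

    raise ValueError(f"unknown criterion {criterion!r}")
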