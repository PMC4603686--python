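"""The four-stage projection matrix (single endophyte status) and its
asymptotic analysis.

The life cycle has four stages — seedling, first-year juvenile,
second-year juvenile, adult — projected on a one-year time step.  Six
arcs are structurally non-zero:

========  =============================  ==================
element   transition                     formula
========  =============================  ==================
G_J1      seedling -> juvenile 1         s1
G_J2      juvenile 1 -> juvenile 2       (1 - e1) * s2
G_A1      juvenile 1 -> adult            e1 * s2
G_A2      juvenile 2 -> adult            s2
S_A       adult -> adult                 fixed constant
F         adult -> seedling (fecundity)  f1 * P * e0
========  =============================  ==================

Columns are source stages, rows destination stages, so projection is
``n(t+1) = A @ n(t)``.  The model is linear, deterministic and not
density dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vitalrates import VitalRates

STAGES = ("seedling", "juvenile1", "juvenile2", "adult")

#: (row, column) index of each named non-zero element.
ELEMENT_INDEX = {
    "F": (0, 3),
    "G_J1": (1, 0),
    "G_J2": (2, 1),
    "G_A1": (3, 1),
    "G_A2": (3, 2),
    "S_A": (3, 3),
}


class MatrixStructureError(ValueError):
    """A matrix violates the fixed life-cycle sparsity pattern."""


@dataclass(frozen=True)
class StageMatrix:
    """A 4x4 projection matrix with the fixed six-arc life-cycle pattern."""

    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.shape != (4, 4):
            raise MatrixStructureError(f"expected 4x4 matrix, got {A.shape}")
        allowed = np.zeros((4, 4), dtype=bool)
        for idx in ELEMENT_INDEX.values():
            allowed[idx] = True
        if np.any(A[~allowed] != 0.0):
            raise MatrixStructureError(
                "non-zero entries outside the six life-cycle arcs"
            )
        if np.any(A < 0):
            raise MatrixStructureError("projection matrix entries must be >= 0")
        for name in ("G_J1", "G_J2", "G_A1", "G_A2", "S_A"):
            if A[ELEMENT_INDEX[name]] > 1.0:
                raise MatrixStructureError(
                    f"survival/growth element {name} exceeds 1"
                )
        # juvenile-1 column splits survivors between two fates
        if A[ELEMENT_INDEX["G_J2"]] + A[ELEMENT_INDEX["G_A1"]] > 1.0 + 1e-12:
            raise MatrixStructureError(
                "G_J2 + G_A1 exceeds 1: juvenile-1 survivors over-allocated"
            )
        object.__setattr__(self, "A", A)

    def __getitem__(self, name: str) -> float:
        return float(self.A[ELEMENT_INDEX[name]])

    @classmethod
    def from_elements(
        cls,
        F: float,
        G_J1: float,
        G_J2: float,
        G_A1: float,
        G_A2: float,
        S_A: float,
    ) -> "StageMatrix":
        A = np.zeros((4, 4))
        for name, value in (
            ("F", F), ("G_J1", G_J1), ("G_J2", G_J2),
            ("G_A1", G_A1), ("G_A2", G_A2), ("S_A", S_A),
        ):
            A[ELEMENT_INDEX[name]] = value
        return cls(A)

    def elements(self) -> dict[str, float]:
        return {name: self[name] for name in ELEMENT_INDEX}


def build_projection_matrix(v: VitalRates) -> StageMatrix:
    """Assemble the projection matrix from a group's vital rates.

    The fecundity element ``F = f1 * P * e0`` is the mean number of
    seeds per adult that germinate to generate seedlings.
    """
    return StageMatrix.from_elements(
        F=v.f1 * v.P * v.e0,
        G_J1=v.s1,
        G_J2=(1.0 - v.e1) * v.s2,
        G_A1=v.e1 * v.s2,
        G_A2=v.s2,
        S_A=v.S_A,
    )


@dataclass(frozen=True)
class EigenAnalysis:
    """Dominant eigen-structure of a projection matrix.

    ``lam`` is the asymptotic growth rate; ``w`` the stable stage
    distribution (sums to 1); ``v`` the reproductive values (normalized
    to sum to 100); ``w_raw``/``v_raw`` keep an un-normalized copy for
    sensitivity work.
    """

    lam: float
    w: np.ndarray
    v: np.ndarray
    w_raw: np.ndarray
    v_raw: np.ndarray
    converged: bool
    iterations: int


class EigenConvergenceError(RuntimeError):
    pass


def _power_iteration(
    A: np.ndarray, tol: float = 1e-13, max_iter: int = 100_000
) -> tuple[float, np.ndarray, int]:
    n = A.shape[0]
    x = np.full(n, 1.0 / n)
    lam = 0.0
    for it in range(1, max_iter + 1):
        y = A @ x
        lam_new = float(np.linalg.norm(y, 1))
        if lam_new == 0.0:
            raise EigenConvergenceError("matrix annihilates the iterate")
        y /= lam_new
        if np.linalg.norm(y - x, 1) < tol and abs(lam_new - lam) < tol:
            return lam_new, y, it
        x, lam = y, lam_new
    residual = float(np.linalg.norm(A @ x - lam * x, 1))
    raise EigenConvergenceError(
        f"power iteration failed to converge in {max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def dominant_eigen(M: "StageMatrix | np.ndarray") -> EigenAnalysis:
    """Dominant eigenvalue with right (stable stage) and left
    (reproductive value) eigenvectors.

    Uses a dense eigen-decomposition; for reducible matrices (the
    coupled model) the eigenvalue of largest real part is taken and its
    eigenvectors rectified to the nonnegative orthant.  Falls back to
    power iteration if the dense eigenvectors are numerically unusable.
    """
    A = M.A if isinstance(M, StageMatrix) else np.asarray(M, dtype=float)
    if np.any(A < 0):
        raise ValueError("projection matrix must be nonnegative")

    eigval, V = np.linalg.eig(A)
    i = int(np.argmax(eigval.real))
    lam = float(eigval[i].real)
    w = V[:, i].real
    eigval_l, U = np.linalg.eig(A.T)
    j = int(np.argmax(eigval_l.real))
    v = U[:, j].real
    iterations = 0
    converged = True

    # rectify sign: a Perron vector of a nonnegative matrix can be taken >= 0
    for vec in (w, v):
        if vec.sum() < 0:
            vec *= -1.0
    if np.any(w < -1e-9) or np.any(v < -1e-9) or lam <= 0:
        # reducible corner cases: fall back to power iteration
        lam, w, iterations = _power_iteration(A)
        _, v, _ = _power_iteration(A.T)
        converged = True
    w = np.clip(w, 0.0, None)
    v = np.clip(v, 0.0, None)

    resid_r = np.linalg.norm(A @ w - lam * w, 1) / max(np.linalg.norm(w, 1), 1e-300)
    resid_l = np.linalg.norm(A.T @ v - lam * v, 1) / max(np.linalg.norm(v, 1), 1e-300)
    if resid_r > 1e-8 or resid_l > 1e-8:
        raise EigenConvergenceError(
            f"eigenpair residuals too large (right {resid_r:.2e}, left {resid_l:.2e})"
        )
    return EigenAnalysis(
        lam=lam,
        w=w / w.sum(),
        v=100.0 * v / v.sum(),
        w_raw=w,
        v_raw=v,
        converged=converged,
        iterations=iterations,
    )


def loop_equation_lambda(M: StageMatrix, tol: float = 1e-12) -> float:
    """Asymptotic growth rate from the characteristic loop equation.

    The life cycle has exactly three loops — the adult self-loop and the
    two reproductive paths (via G_A1, length 3; via G_J2 then G_A2,
    length 4) — giving the characteristic equation

        1 = S_A/lam + G_J1*G_A1*F / lam**3 + G_J1*G_J2*G_A2*F / lam**4.

    The right-hand side is strictly decreasing in lam, so the positive
    root is unique; it is bracketed and found by scalar root finding.
    This is an independent cross-check on :func:`dominant_eigen`.
    """
    from scipy.optimize import brentq

    e = M.elements()
    loop1 = e["S_A"]
    loop3 = e["G_J1"] * e["G_A1"] * e["F"]
    loop4 = e["G_J1"] * e["G_J2"] * e["G_A2"] * e["F"]
    if loop1 == 0.0 and loop3 == 0.0 and loop4 == 0.0:
        raise ValueError("no growth loop: all loop products are zero")

    def f(lam: float) -> float:
        return loop1 / lam + loop3 / lam**3 + loop4 / lam**4 - 1.0

    hi = max(1.0, loop1) + loop3 ** (1.0 / 3.0) + loop4 ** 0.25 + 1.0
    lo = hi * 1e-12
    while f(lo) < 0:  # pragma: no cover - lo is far below any root
        lo *= 0.5
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def project(
    M: "StageMatrix | np.ndarray", n0: np.ndarray, steps: int
) -> np.ndarray:
    """Iterate ``n(t+1) = A @ n(t)``; returns an array of shape
    ``(steps + 1, n_stages)`` with ``trajectory[0] = n0``."""
    A = M.A if isinstance(M, StageMatrix) else np.asarray(M, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != (A.shape[0],):
        raise ValueError(f"n0 must have shape ({A.shape[0]},)")
    if np.any(n0 < 0):
        raise ValueError("initial stage vector must be nonnegative")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    out = np.empty((steps + 1, A.shape[0]))
    out[0] = n0
    for t in range(steps):
        out[t + 1] = A @ out[t]
    return out


def survival_ranking_sweep(
    groups: dict[str, VitalRates], sa_grid
) -> "pandas.DataFrame":
    """Growth rate and rank of each group across fixed adult survival values.

    Adult survival is a model constant, not an estimate; this sweep
    checks that the group ranking of λ does not depend on its value.
    Ranks are 1 = largest λ within each ``S_A`` value.
    """
    import pandas as pd

    rows = []
    for sa in sa_grid:
        if not 0.0 <= sa < 1.0:
            raise ValueError(f"S_A grid value {sa!r} outside [0, 1)")
        lams = {
            name: dominant_eigen(
                build_projection_matrix(v.with_adult_survival(sa))
            ).lam
            for name, v in groups.items()
        }
        order = sorted(lams, key=lams.get, reverse=True)
        for name in groups:
            rows.append(
                {
                    "group": name,
                    "S_A": float(sa),
                    "lam": lams[name],
                    "rank": order.index(name) + 1,
                }
            )
    return pd.DataFrame(rows)
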