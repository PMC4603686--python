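"""Vital-rate and transmission-rate estimation from census tables, plus
the statistical comparisons used on them.

A census table has one row per mother plant, labelled by endophytic
status (S/NS) and resource level (natural/F+), carrying the sowing and
survival counts of her offspring cohort and, for S mothers, the
endophyte-assay counts.

Estimators follow the ratio conventions of the field design exactly:
``s1``, ``s2``, ``e1``, ``e0``, ``T_A`` are unweighted means of
per-mother ratios (mothers with a zero denominator are excluded from
that parameter, with a warning), while ``P`` and ``f1`` are plot-level
ratios pooled over plants.  SEMs are the SD of the per-mother ratios
over the square root of the number of contributing mothers.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .coupled import TransmissionRates
from .vitalrates import VitalRates, VitalRateUncertainty

logger = logging.getLogger(__name__)

CENSUS_COLUMNS = [
    "mother_id",
    "endophyte_status",
    "resource",
    "seeds_sown",
    "seedlings_emerged",
    "seedlings_alive",
    "juveniles_followed",
    "juveniles_alive",
    "juveniles_ge30_tillers",
    "flowered",
    "seeds_produced",
    "seeds_tested",
    "seeds_positive",
    "seedlings_tested",
    "seedlings_positive",
    "juveniles_tested",
    "juveniles_positive",
]

#: (numerator, denominator) pairs that must satisfy num <= den row-wise.
_PAIRED_COUNTS = [
    ("seedlings_emerged", "seeds_sown"),
    ("seedlings_alive", "seedlings_emerged"),
    ("juveniles_alive", "juveniles_followed"),
    ("juveniles_ge30_tillers", "juveniles_alive"),
    ("seeds_positive", "seeds_tested"),
    ("seedlings_positive", "seedlings_tested"),
    ("juveniles_positive", "juveniles_tested"),
]

_COUNT_COLUMNS = [c for c in CENSUS_COLUMNS if c not in
                  ("mother_id", "endophyte_status", "resource")]


class CensusValidationError(ValueError):
    pass


def validate_census(df: pd.DataFrame) -> pd.DataFrame:
    """Check the census schema and count invariants; returns the frame.

    Transmission-assay columns may be missing (NaN) for NS mothers.
    """
    missing = set(CENSUS_COLUMNS) - set(df.columns)
    if missing:
        raise CensusValidationError(f"missing census columns: {sorted(missing)}")
    bad_status = set(df["endophyte_status"]) - {"S", "NS"}
    if bad_status:
        raise CensusValidationError(f"unknown endophyte status: {bad_status}")
    bad_res = set(df["resource"]) - {"natural", "F+"}
    if bad_res:
        raise CensusValidationError(f"unknown resource level: {bad_res}")
    for col in _COUNT_COLUMNS:
        if (df[col].dropna() < 0).any():
            rows = df.index[df[col] < 0].tolist()
            raise CensusValidationError(f"negative {col} in rows {rows}")
    for num, den in _PAIRED_COUNTS:
        both = df[[num, den]].dropna()
        bad = both.index[both[num] > both[den]].tolist()
        if bad:
            raise CensusValidationError(
                f"{num} exceeds {den} in rows {bad}"
            )
    return df


def read_census(path: "str | Path | StringIO") -> pd.DataFrame:
    """Read a tab-delimited census table (header row, one mother per row)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_census(df)


def write_census(df: pd.DataFrame, path: "str | Path") -> None:
    validate_census(df).to_csv(path, sep="\t", index=False)


def _select_group(df: pd.DataFrame, group: tuple[str, str]) -> pd.DataFrame:
    status, resource = group
    sub = df[(df["endophyte_status"] == status) & (df["resource"] == resource)]
    if sub.empty:
        raise CensusValidationError(f"no mothers in group {group!r}")
    return sub


def _mean_of_ratios(
    num: pd.Series, den: pd.Series, name: str
) -> tuple[float, float]:
    ok = den > 0
    dropped = int((~ok).sum())
    if dropped:
        logger.warning(
            "%s: excluding %d mother(s) with zero denominator", name, dropped
        )
    if not ok.any():
        raise CensusValidationError(f"no mother with data for {name}")
    ratios = (num[ok] / den[ok]).to_numpy(dtype=float)
    est = float(ratios.mean())
    sem = (
        float(ratios.std(ddof=1) / np.sqrt(len(ratios)))
        if len(ratios) > 1
        else float("nan")
    )
    return est, sem


def estimate_vital_rates(
    census: pd.DataFrame, group: tuple[str, str], S_A: float = 0.95
) -> tuple[VitalRates, VitalRateUncertainty]:
    """Estimate the six vital rates (and their SEMs) for one group.

    ``P`` is the flowering fraction over all plants and ``f1`` the mean
    seed count over flowering plants (both plot-level); the rest are
    means of per-mother ratios.  ``S_A`` is a constant, not estimated,
    and carries SEM 0.
    """
    sub = _select_group(validate_census(census), group)
    est: dict[str, float] = {}
    sem: dict[str, float] = {}
    est["e0"], sem["e0"] = _mean_of_ratios(
        sub["seedlings_emerged"], sub["seeds_sown"], "e0")
    est["s1"], sem["s1"] = _mean_of_ratios(
        sub["seedlings_alive"], sub["seedlings_emerged"], "s1")
    est["s2"], sem["s2"] = _mean_of_ratios(
        sub["juveniles_alive"], sub["juveniles_followed"], "s2")
    est["e1"], sem["e1"] = _mean_of_ratios(
        sub["juveniles_ge30_tillers"], sub["juveniles_alive"], "e1")

    flowered = sub["flowered"].astype(float)
    est["P"] = float(flowered.sum() / len(sub))
    sem["P"] = (
        float(flowered.std(ddof=1) / np.sqrt(len(sub)))
        if len(sub) > 1
        else float("nan")
    )
    fl = sub[sub["flowered"] > 0]
    if fl.empty:
        raise CensusValidationError("no flowering plants: f1 inestimable")
    seeds = fl["seeds_produced"].to_numpy(dtype=float)
    est["f1"] = float(seeds.sum() / len(fl))
    sem["f1"] = (
        float(seeds.std(ddof=1) / np.sqrt(len(fl)))
        if len(fl) > 1
        else float("nan")
    )

    rates = VitalRates(S_A=S_A, **est)
    sems = VitalRateUncertainty(
        S_A=0.0, **{k: (0.0 if np.isnan(v) else v) for k, v in sem.items()}
    )
    return rates, sems


def estimate_transmission(
    census: pd.DataFrame, group: tuple[str, str] = ("S", "natural")
) -> tuple[TransmissionRates, dict[str, float]]:
    """Estimate vertical transmission rates from S mothers' assays.

    ``T_A`` (adult→seed) is the unweighted mean of per-mother positive
    seed fractions; seed→seedling (``T_seed``) and seedling→juvenile
    (``T_S``) retention are cohort-level pooled fractions, matching how
    the stage-to-stage assays were scored.  Returns the rates and a dict
    of standard errors.
    """
    sub = _select_group(validate_census(census), group)
    assayed = sub[sub["seeds_tested"].fillna(0) > 0]
    if assayed.empty:
        raise CensusValidationError("no mothers with tested offspring")
    fractions = (
        assayed["seeds_positive"] / assayed["seeds_tested"]
    ).to_numpy(dtype=float)
    T_A = float(fractions.mean())
    se: dict[str, float] = {
        "T_A": float(fractions.std(ddof=1) / np.sqrt(len(fractions)))
        if len(fractions) > 1
        else float("nan")
    }

    def pooled(num_col: str, den_col: str, name: str) -> float:
        n = float(sub[den_col].fillna(0).sum())
        if n == 0:
            logger.warning("%s: no tested offspring; defaulting to 1", name)
            se[name] = float("nan")
            return 1.0
        p = float(sub[num_col].fillna(0).sum() / n)
        se[name] = float(np.sqrt(p * (1 - p) / n))
        return p

    T_seed = pooled("seedlings_positive", "seedlings_tested", "T_seed")
    T_S = pooled("juveniles_positive", "juveniles_tested", "T_S")
    return TransmissionRates(T_A=T_A, T_S=T_S, T_seed=T_seed), se


#: response name -> (successes column, trials column); trials None means
#: the response is the 0/1 flowering indicator.
RESPONSE_COLUMNS: dict[str, tuple[str, "str | None"]] = {
    "s1": ("seedlings_alive", "seedlings_emerged"),
    "s2": ("juveniles_alive", "juveniles_followed"),
    "e1": ("juveniles_ge30_tillers", "juveniles_alive"),
    "e0": ("seedlings_emerged", "seeds_sown"),
    "P": ("flowered", None),
    "T_A": ("seeds_positive", "seeds_tested"),
}


def factorial_deviance_test(
    census: pd.DataFrame, response: str
) -> pd.DataFrame:
    """Grouped-binomial logistic regression of one parameter on
    endophytic status, resource level and their interaction, assessed by
    sequential χ² analysis of deviance.

    Terms are added in the order status, resource, interaction; each
    p-value compares the deviance drop against χ² with the term's
    degrees of freedom.  When only one status carries the response
    (transmission assays), the status and interaction terms are not
    estimable and are reported as NaN.  Complete separation is flagged
    and the affected p-values suppressed.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats

    if response not in RESPONSE_COLUMNS:
        raise ValueError(f"unknown response {response!r}; "
                         f"choose from {sorted(RESPONSE_COLUMNS)}")
    num_col, den_col = RESPONSE_COLUMNS[response]
    df = validate_census(census).copy()
    if den_col is None:
        df["_succ"] = df[num_col].astype(float)
        df["_fail"] = 1.0 - df["_succ"]
    else:
        df = df[df[den_col].fillna(0) > 0].copy()
        df["_succ"] = df[num_col].astype(float)
        df["_fail"] = (df[den_col] - df[num_col]).astype(float)

    statuses = sorted(df["endophyte_status"].unique())
    resources = sorted(df["resource"].unique())
    terms = []
    if len(statuses) > 1:
        terms.append(("status", "C(endophyte_status)"))
    if len(resources) > 1:
        terms.append(("resource", "C(resource)"))
    if len(statuses) > 1 and len(resources) > 1:
        terms.append(("interaction", "C(endophyte_status):C(resource)"))
    if not terms:
        raise ValueError("need at least two factor levels to test")

    def fit(rhs: str):
        return smf.glm(
            f"_succ + _fail ~ {rhs}", data=df, family=sm.families.Binomial()
        ).fit()

    rows = []
    rhs = "1"
    current = fit(rhs)
    separated = bool(
        np.any(np.isclose(current.fittedvalues, 0.0))
        or np.any(np.isclose(current.fittedvalues, 1.0))
    )
    for name, term in terms:
        rhs = f"{rhs} + {term}"
        nxt = fit(rhs)
        ddev = current.deviance - nxt.deviance
        ddf = current.df_resid - nxt.df_resid
        fitted = np.asarray(nxt.fittedvalues)
        sep_here = bool(
            np.any(np.isclose(fitted, 0.0, atol=1e-8))
            or np.any(np.isclose(fitted, 1.0, atol=1e-8))
        )
        separated = separated or sep_here
        if ddf <= 0 or separated:
            p = float("nan")
        else:
            p = float(stats.chi2.sf(max(ddev, 0.0), ddf))
        rows.append(
            {
                "term": name,
                "deviance_drop": float(ddev),
                "df": int(ddf),
                "p_value": p,
                "separation": separated,
            }
        )
        current = nxt

    out = pd.DataFrame(rows).set_index("term")
    for name in ("status", "resource", "interaction"):
        if name not in out.index:
            out.loc[name] = {
                "deviance_drop": float("nan"),
                "df": 0,
                "p_value": float("nan"),
                "separation": False,
            }
    return out.loc[["status", "resource", "interaction"]]


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test with Satterthwaite degrees of freedom.

    Returns ``(t, df, p)``.  Two identical zero-variance samples give
    ``t = 0, p = 1`` by convention.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples must have size >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float("inf") * np.sign(x.mean() - y.mean()), float(
            len(x) + len(y) - 2
        ), 0.0
    se2x, se2y = vx / len(x), vy / len(y)
    t = float((x.mean() - y.mean()) / np.sqrt(se2x + se2y))
    df = float(
        (se2x + se2y) ** 2
        / (se2x**2 / (len(x) - 1) + se2y**2 / (len(y) - 1))
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p
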