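"""Reference parameter sets for the Guzet *Festuca eskia* population.

Two parallel parameterizations are provided for the four groups
(endophytic status S/NS × resource level natural/F+):

* ``FIELD_MEANS`` / ``FIELD_SEMS`` — the six estimated vital rates per
  group, as mean ± SEM over mother plants, from the three-year field
  and sowing census.  Matrices assembled from these via the vital-rate
  formulas differ in the last digit from the printed matrices (e.g.
  ``G_A1`` = 0.05·0.63 = 0.0315 for NS/natural, printed as 0.032).
* ``PRINTED_MATRICES`` — the projection-matrix entries exactly as
  printed (fecundity kept as the ``f1·P`` and ``e0`` factors), used
  when reproducing the published eigen-analysis to printed precision.

``TRANSMISSION`` holds the observed vertical transmission rates per
resource level: adult→seed retention (T_A) per condition; the
seedling→juvenile retention (T_S) observed overall (0.85), reported to
drop by 5 percentage points under fertilization; and the seed→seedling
retention 0.97 exposed as the optional T_seed.
"""

from __future__ import annotations

from .coupled import TransmissionRates
from .matrix import StageMatrix
from .vitalrates import VitalRates, VitalRateUncertainty

GROUPS = (
    ("NS", "natural"),
    ("S", "natural"),
    ("NS", "F+"),
    ("S", "F+"),
)

FIELD_MEANS: dict[tuple[str, str], VitalRates] = {
    ("NS", "natural"): VitalRates(s1=0.79, s2=0.63, e1=0.05, f1=123, P=0.59, e0=0.31),
    ("S", "natural"): VitalRates(s1=0.85, s2=0.69, e1=0.08, f1=125, P=0.66, e0=0.48),
    ("NS", "F+"): VitalRates(s1=0.95, s2=0.91, e1=0.11, f1=77, P=0.72, e0=0.45),
    ("S", "F+"): VitalRates(s1=0.97, s2=0.99, e1=0.09, f1=184, P=0.80, e0=0.42),
}

FIELD_SEMS: dict[tuple[str, str], VitalRateUncertainty] = {
    ("NS", "natural"): VitalRateUncertainty(
        s1=0.036, s2=0.095, e1=0.019, f1=38, P=0.058, e0=0.047),
    ("S", "natural"): VitalRateUncertainty(
        s1=0.028, s2=0.078, e1=0.009, f1=40, P=0.054, e0=0.020),
    ("NS", "F+"): VitalRateUncertainty(
        s1=0.012, s2=0.042, e1=0.011, f1=52, P=0.091, e0=0.040),
    ("S", "F+"): VitalRateUncertainty(
        s1=0.009, s2=0.007, e1=0.018, f1=70, P=0.082, e0=0.023),
}

#: printed matrix entries: (f1*P, e0, G_J1, G_J2, G_A1, G_A2, S_A)
_PRINTED = {
    ("NS", "natural"): (73, 0.31, 0.79, 0.60, 0.032, 0.63, 0.95),
    ("S", "natural"): (83, 0.48, 0.85, 0.58, 0.055, 0.69, 0.95),
    ("NS", "F+"): (55, 0.45, 0.95, 0.81, 0.09, 0.90, 0.95),
    ("S", "F+"): (149, 0.42, 0.97, 0.90, 0.087, 0.99, 0.95),
}

PRINTED_MATRICES: dict[tuple[str, str], StageMatrix] = {
    group: StageMatrix.from_elements(
        F=seeds * e0, G_J1=g_j1, G_J2=g_j2, G_A1=g_a1, G_A2=g_a2, S_A=s_a
    )
    for group, (seeds, e0, g_j1, g_j2, g_a1, g_a2, s_a) in _PRINTED.items()
}

TRANSMISSION: dict[str, TransmissionRates] = {
    "natural": TransmissionRates(T_A=0.63, T_S=0.85, T_seed=0.97),
    "F+": TransmissionRates(T_A=0.52, T_S=0.80, T_seed=0.97),
}

#: reported asymptotic growth rates (mean across Monte-Carlo draws)
REPORTED_LAMBDA = {
    ("NS", "natural"): 1.97,
    ("S", "natural"): 2.34,
    ("NS", "F+"): 2.45,
    ("S", "F+"): 3.17,
}


def group_label(group: tuple[str, str]) -> str:
    status, resource = group
    return f"{status}/{resource}"
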