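"""Derived clinical covariates for the gabapentin popPK analysis.

Body-size metrics (BMI, Devine ideal body weight, adjusted body weight,
Janmahasatian lean body weight), renal-function indices (4-variable MDRD
eGFR, Cockcroft-Gault creatinine clearance with ideal-weight capping),
an acute-kidney-injury flag from a serum-creatinine series, and the
combined obesity/diabetes metabolic category.

Units follow clinical convention throughout: weight kg, height cm, serum
creatinine mg/dL, eGFR mL/min/1.73 m^2, CrCl mL/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Tuple

__all__ = [
    "BodySizeMetrics",
    "RenalMetrics",
    "derive_body_size",
    "derive_renal",
    "flag_aki",
    "classify_metabolic",
    "METABOLIC_CATEGORIES",
    "OBESITY_BMI_THRESHOLD",
]

CM_PER_INCH = 2.54
OBESITY_BMI_THRESHOLD = 30.0  # kg/m^2, inclusive
AKI_SCR_DELTA = 0.3  # mg/dL rise over the preceding 48 h
AKI_WINDOW_H = 48.0

#: Four-level combined obesity/diabetes category labels.
METABOLIC_CATEGORIES = (
    "non-diabetic and non-obese",
    "diabetic but not obese",
    "obese but metabolically healthy",
    "both diabetic and obese",
)


@dataclass(frozen=True)
class BodySizeMetrics:
    """Body-size descriptors derived from weight, height and sex."""

    bmi: float  # kg/m^2
    ibw: float  # ideal body weight, kg (Devine)
    abw: float  # adjusted body weight, kg (IBW + 0.4*(WT-IBW))
    lbw: float  # lean body weight, kg (Janmahasatian)


@dataclass(frozen=True)
class RenalMetrics:
    """Renal-function indices derived from serum creatinine."""

    egfr: float  # mL/min/1.73 m^2 (MDRD, IDMS-traceable coefficient 175)
    crcl: float  # mL/min (Cockcroft-Gault)
    aki: bool = False


def _check_sex(sex: str) -> str:
    s = str(sex).lower()
    if s not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return s


def derive_body_size(weight: float, height: float, sex: str) -> BodySizeMetrics:
    """Compute BMI, Devine IBW, adjusted body weight and Janmahasatian LBW.

    Parameters
    ----------
    weight : float
        Actual body weight, kg.
    height : float
        Height, cm.
    sex : {'male', 'female'}

    Notes
    -----
    Devine IBW uses height in inches above 60; for heights below 60 inches
    the excess-height term is clamped at zero (with a warning) so the
    formula stays physiological.  ABW = IBW + 0.4 * (WT - IBW), the common
    clinical adjustment factor.
    """
    sex = _check_sex(sex)
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be strictly positive")
    bmi = weight / (height / 100.0) ** 2
    height_in = height / CM_PER_INCH
    excess = height_in - 60.0
    if excess < 0:
        warnings.warn(
            "height below 60 inches: Devine IBW excess-height term clamped at 0",
            stacklevel=2,
        )
        excess = 0.0
    ibw = (50.0 if sex == "male" else 45.5) + 2.3 * excess
    abw = ibw + 0.4 * (weight - ibw)
    if sex == "male":
        lbw = 9270.0 * weight / (6680.0 + 216.0 * bmi)
    else:
        lbw = 9270.0 * weight / (8780.0 + 244.0 * bmi)
    return BodySizeMetrics(bmi=bmi, ibw=ibw, abw=abw, lbw=lbw)


def derive_renal(
    scr: float,
    age: float,
    sex: str,
    race: str,
    weight: float,
    ibw: float,
) -> RenalMetrics:
    """MDRD eGFR and Cockcroft-Gault CrCl from a single serum creatinine.

    eGFR = 175 * SCr^-1.154 * age^-0.203 * 0.742(female) * 1.212(black).
    CrCl = (140 - age) * W / (72 * SCr) * 0.85(female), with W the actual
    body weight unless WT >= 1.3 * IBW, in which case the ideal body weight
    is substituted (standard obesity capping rule).
    """
    sex = _check_sex(sex)
    if scr <= 0:
        raise ValueError("serum creatinine must be strictly positive")
    if age <= 0:
        raise ValueError("age must be strictly positive")
    egfr = 175.0 * scr ** -1.154 * age ** -0.203
    if sex == "female":
        egfr *= 0.742
    if str(race).lower() == "black":
        egfr *= 1.212
    w = ibw if weight >= 1.3 * ibw else weight
    crcl = (140.0 - age) * w / (72.0 * scr)
    if sex == "female":
        crcl *= 0.85
    return RenalMetrics(egfr=egfr, crcl=crcl)


def flag_aki(
    scr_series: Iterable[Tuple[float, float]],
    reference_time: float = 0.0,
) -> bool:
    """Acute kidney injury flag from a time-stamped SCr series.

    True iff the SCr at ``reference_time`` exceeds the minimum SCr observed
    within the preceding 48 h by more than 0.3 mg/dL.  With no prior value
    inside the window the change cannot be demonstrated and the flag is
    False.

    Parameters
    ----------
    scr_series : iterable of (time_h, scr_mg_dl)
        Times in hours on any consistent clock.
    reference_time : float
        The time (typically of sample collection) at which AKI is assessed.
    """
    series = sorted(scr_series)
    if not series:
        raise ValueError("scr_series must be nonempty")
    at_ref = [s for t, s in series if abs(t - reference_time) < 1e-9]
    if not at_ref:
        # nearest measurement at or before the reference time stands in
        before = [(t, s) for t, s in series if t <= reference_time]
        if not before:
            return False
        at_ref = [before[-1][1]]
    current = at_ref[-1]
    window = [
        s
        for t, s in series
        if reference_time - AKI_WINDOW_H <= t < reference_time
    ]
    if not window:
        return False
    return current - min(window) > AKI_SCR_DELTA


def classify_metabolic(bmi: float, diabetes: bool) -> Tuple[str, bool]:
    """Combined obesity/diabetes category and the obesity flag.

    Obesity is BMI >= 30 kg/m^2 (inclusive).  Returns ``(category, obese)``
    with category one of :data:`METABOLIC_CATEGORIES`.
    """
    if bmi <= 0:
        raise ValueError("BMI must be strictly positive")
    obese = bmi >= OBESITY_BMI_THRESHOLD
    diabetes = bool(diabetes)
    if obese and diabetes:
        cat = "both diabetic and obese"
    elif obese:
        cat = "obese but metabolically healthy"
    elif diabetes:
        cat = "diabetic but not obese"
    else:
        cat = "non-diabetic and non-obese"
    return cat, obese
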