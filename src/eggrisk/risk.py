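"""Deterministic exposure and health-risk metrics for dietary metal intake.

Core quantities, following the US-EPA deterministic framework:

* ``EDI = F_IR x C_M / W_AB`` — estimated daily intake, with F_IR the egg
  consumption rate (g/day), C_M the mean metal concentration (µg/kg wet
  weight) and W_AB the adult body weight (kg).  EWI/EMI are the weekly
  (x7) and monthly (x30) analogues, compared against the JECFA PTWI/PTMI
  guideline values.
* ``THQ = (EF x ED x F_IR x C_M) / (RfD x W_AB x TA) x 1e-3`` — target
  hazard quotient, with C_M in mg/kg and the 1e-3 factor converting F_IR
  from g/day to kg/day; THQ >= 1 flags potential non-carcinogenic risk.
* ``ILCR = EDI x CSF`` — incremental lifetime cancer risk, with EDI in
  mg/kg bw/day and CSF the oral cancer slope factor.

Unit conventions
----------------
Published risk tables in this literature often multiply the EDI numerals
as printed — g/day times µg/kg divided by kg — without converting grams to
kilograms, so the tabulated EDI/EWI/EMI are 1000x the strictly dimensional
value in µg/kg bw/day.  ``convention="paper"`` (default) reproduces that
arithmetic so outputs can be compared digit-for-digit against published
tables; ``convention="strict"`` applies the g->kg factor.  THQ and ILCR
carry their own explicit unit conversions and are identical under both
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError
from .survey import SurveySummary

__all__ = [
    "ExposureParams",
    "ToxProfile",
    "RiskEstimate",
    "GuidelineComparison",
    "CONVENTIONS",
    "compute_edi",
    "derive_ewi_emi",
    "compute_thq",
    "compute_ilcr",
    "classify_thq",
    "classify_ilcr",
    "classify_risk",
    "compare_guidelines",
    "assess",
]

CONVENTIONS = ("paper", "strict")

#: ILCR band edges (US-EPA): negligible < 1e-6 <= acceptable <= 1e-4
#: < threshold_exceeded <= 1e-3 < moderate_risk
ILCR_NEGLIGIBLE = 1e-6
ILCR_THRESHOLD = 1e-4
ILCR_MODERATE = 1e-3


@dataclass(frozen=True)
class ExposureParams:
    """Exposure factors for an adult consumer.

    Defaults describe an Iranian adult: 25.4 g of eggs per day, 70 kg body
    weight, exposure every day (EF = 365 d/yr) over a 70-year lifetime
    (ED), averaged over TA = EF x ED = 25550 days for non-carcinogens.
    """

    fir: float = 25.4  # egg consumption, g/day
    wab: float = 70.0  # body weight, kg
    ef: float = 365.0  # exposure frequency, days/year
    ed: float = 70.0  # exposure duration, years
    ta: float = 25550.0  # averaging time, days

    def __post_init__(self) -> None:
        for name in ("fir", "wab", "ef", "ed", "ta"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ToxProfile:
    """Toxicological reference values for one metal.

    ``csf`` may be None — no oral cancer slope factor has been established
    for mercury, so ILCR is simply not computed for it.  ``ptmi`` defaults
    to ``ptwi * 30/7`` when a monthly guideline is requested but none is set.
    """

    metal: str
    rfd: float  # oral reference dose, mg/kg bw/day
    csf: Optional[float] = None  # cancer slope factor, (mg/kg bw/day)^-1
    ptwi: Optional[float] = None  # µg/kg bw/week
    ptmi: Optional[float] = None  # µg/kg bw/month

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise ValidationError(f"{self.metal}: rfd must be > 0")
        if self.csf is not None and self.csf <= 0:
            raise ValidationError(f"{self.metal}: csf must be > 0 when present")

    @property
    def ptmi_effective(self) -> Optional[float]:
        if self.ptmi is not None:
            return self.ptmi
        if self.ptwi is not None:
            return self.ptwi * 30.0 / 7.0
        return None


@dataclass(frozen=True)
class RiskEstimate:
    """Deterministic risk metrics for one metal x season cell."""

    metal: str
    season: str
    convention: str
    edi: float  # per-day intake in the active convention
    ewi: float  # 7 x edi
    emi: float  # 30 x edi
    thq: float
    ilcr: Optional[float]
    thq_class: str  # below_1 / at_or_above_1
    ilcr_class: Optional[str]


@dataclass(frozen=True)
class GuidelineComparison:
    metal: str
    ewi_fraction_of_ptwi: float
    emi_fraction_of_ptmi: Optional[float]
    within_limits: bool


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValidationError(
            f"unknown unit convention {convention!r}; expected one of {CONVENTIONS}"
        )


def _mean_of(summary: "SurveySummary | float") -> float:
    mean = summary.mean if isinstance(summary, SurveySummary) else float(summary)
    if mean < 0:
        raise ValidationError(f"mean concentration must be >= 0, got {mean}")
    return mean


def compute_edi(
    summary: "SurveySummary | float",
    exposure: ExposureParams = ExposureParams(),
    convention: str = "paper",
) -> float:
    """Estimated daily intake F_IR x C_M / W_AB.

    ``summary`` is a :class:`~eggrisk.survey.SurveySummary` (its mean is
    used) or a bare mean concentration in µg/kg.  In the ``paper``
    convention the numerals are multiplied as printed; ``strict`` divides
    by 1000 to land on µg/kg bw/day.
    """
    _check_convention(convention)
    edi = exposure.fir * _mean_of(summary) / exposure.wab
    return edi / 1000.0 if convention == "strict" else edi


def derive_ewi_emi(edi: float) -> tuple[float, float]:
    """Weekly (7 x EDI) and monthly (30 x EDI) intake, same convention as EDI."""
    if edi < 0:
        raise ValidationError(f"edi must be >= 0, got {edi}")
    return 7.0 * edi, 30.0 * edi


def compute_thq(
    summary: "SurveySummary | float",
    exposure: ExposureParams = ExposureParams(),
    tox: ToxProfile | None = None,
) -> float:
    """Target hazard quotient (dimensionless).

    The concentration (µg/kg) is converted to mg/kg before entering the
    formula; the 1e-3 factor converts F_IR from g/day to kg/day.  When
    EF x ED = TA this reduces to (F_IR x 1e-3 x C_M[mg/kg]) / (RfD x W_AB).
    """
    if tox is None:
        raise ValidationError("a ToxProfile with rfd is required for THQ")
    cm_mgkg = _mean_of(summary) / 1000.0
    return (
        (exposure.ef * exposure.ed * exposure.fir * cm_mgkg)
        / (tox.rfd * exposure.wab * exposure.ta)
        * 1e-3
    )


def compute_ilcr(edi_paper: float, tox: ToxProfile) -> Optional[float]:
    """Incremental lifetime cancer risk, or None when no CSF is established.

    ``edi_paper`` is the EDI in the paper numeral convention; dividing by
    1000 expresses it in mg/kg bw/day before multiplying by the slope
    factor.
    """
    if tox.csf is None:
        return None
    if edi_paper < 0:
        raise ValidationError(f"edi must be >= 0, got {edi_paper}")
    return (edi_paper / 1000.0) * tox.csf


def classify_thq(thq: float) -> str:
    if thq < 0:
        raise ValidationError(f"thq must be >= 0, got {thq}")
    return "below_1" if thq < 1.0 else "at_or_above_1"


def classify_ilcr(ilcr: float) -> str:
    """US-EPA cancer-risk band.

    negligible: ilcr < 1e-6; acceptable: 1e-6 <= ilcr <= 1e-4;
    threshold_exceeded: 1e-4 < ilcr <= 1e-3; moderate_risk: ilcr > 1e-3.
    """
    if ilcr < 0:
        raise ValidationError(f"ilcr must be >= 0, got {ilcr}")
    if ilcr < ILCR_NEGLIGIBLE:
        return "negligible"
    if ilcr <= ILCR_THRESHOLD:
        return "acceptable"
    if ilcr <= ILCR_MODERATE:
        return "threshold_exceeded"
    return "moderate_risk"


def classify_risk(thq: float, ilcr: Optional[float]) -> tuple[str, Optional[str]]:
    """Joint classification; the ILCR class is None when ILCR is absent."""
    return classify_thq(thq), None if ilcr is None else classify_ilcr(ilcr)


def compare_guidelines(
    ewi: float,
    emi: float,
    exposure: ExposureParams,
    tox: ToxProfile,
) -> GuidelineComparison:
    """Weekly/monthly intake as a fraction of the JECFA PTWI/PTMI.

    ``ewi``/``emi`` are paper-convention intakes (µg/kg bw/week and /month
    numerals); fractions below 1 mean the guideline is respected.
    """
    if tox.ptwi is None:
        raise ValidationError(f"{tox.metal}: ptwi is required for guideline comparison")
    if ewi < 0 or emi < 0:
        raise ValidationError("intakes must be >= 0")
    ewi_frac = ewi / tox.ptwi
    ptmi = tox.ptmi_effective
    emi_frac = None if ptmi is None else emi / ptmi
    fracs = [ewi_frac] + ([] if emi_frac is None else [emi_frac])
    return GuidelineComparison(
        metal=tox.metal,
        ewi_fraction_of_ptwi=float(ewi_frac),
        emi_fraction_of_ptmi=None if emi_frac is None else float(emi_frac),
        within_limits=bool(all(f < 1.0 for f in fracs)),
    )


def assess(
    summary: "SurveySummary | float",
    tox: ToxProfile,
    exposure: ExposureParams = ExposureParams(),
    convention: str = "paper",
    season: str = "pooled",
) -> RiskEstimate:
    """All deterministic metrics for one concentration summary.

    ILCR is always derived from the paper-convention EDI (its own 1e-3
    factor lands it in mg/kg bw/day), regardless of the reporting
    convention used for EDI/EWI/EMI.
    """
    _check_convention(convention)
    metal = summary.metal if isinstance(summary, SurveySummary) else tox.metal
    edi = compute_edi(summary, exposure, convention)
    ewi, emi = derive_ewi_emi(edi)
    thq = compute_thq(summary, exposure, tox)
    edi_paper = compute_edi(summary, exposure, "paper")
    ilcr = compute_ilcr(edi_paper, tox)
    thq_class, ilcr_class = classify_risk(thq, ilcr)
    return RiskEstimate(
        metal=metal,
        season=season,
        convention=convention,
        edi=edi,
        ewi=ewi,
        emi=emi,
        thq=thq,
        ilcr=ilcr,
        thq_class=thq_class,
        ilcr_class=ilcr_class,
    )
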