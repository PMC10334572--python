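"""Deterministic intake and risk metrics from seasonal mean concentrations.

Uses the package's reference seasonal means (winter/summer As and Hg) and
the default adult exposure factors: 25.4 g eggs/day, 70 kg body weight,
lifetime exposure.  Intakes are reported in the conventional numeral form
(no g->kg conversion); THQ and ILCR are dimensionless.
"""

from eggrisk import assess, round_half_up, round_sig
from eggrisk.defaults import SURVEY_MOMENTS, TOX_PROFILES

for metal in ("As", "Hg"):
    tox = TOX_PROFILES[metal]
    means = {
        season: SURVEY_MOMENTS[(metal, season)][0] for season in ("winter", "summer")
    }
    means["mean"] = (means["winter"] + means["summer"]) / 2
    print(f"{metal} (RfD {tox.rfd} mg/kg/day, CSF {tox.csf}):")
    for season, cm in means.items():
        est = assess(cm, tox, season=season)
        ilcr = "-" if est.ilcr is None else f"{round_sig(est.ilcr, 3):.2E}"
        print(
            f"  {season:>6}: C={cm:.3f} µg/kg  EDI={round_half_up(est.edi, 2):.2f}"
            f"  EWI={round_half_up(est.ewi, 2):.2f}  EMI={round_half_up(est.emi, 2):.2f}"
            f"  THQ={round_half_up(est.thq, 5):.5f} ({est.thq_class})"
            f"  ILCR={ilcr} ({est.ilcr_class})"
        )
    print()

print(
    "THQ < 1 means no appreciable non-carcinogenic risk; an ILCR above"
    " 1e-4 crosses the regulatory threshold for cancer risk (no CSF is"
    " established for Hg, so its ILCR is not computed)."
)
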