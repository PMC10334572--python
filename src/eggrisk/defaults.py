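"""Default study conditions: exposure factors, toxicological profiles, and
the seasonal concentration moments of the underlying Iranian hen-egg
market survey (21 brands x 2 replicates x 2 seasons, ICP-MS, µg/kg wet
weight).

These constants parameterize the synthetic survey generator and the
worked examples; every one of them can be overridden per call.
"""

from __future__ import annotations

from .risk import ExposureParams, ToxProfile
from .survey import CensoringRule

#: Adult consumer: 25.4 g eggs/day, 70 kg, lifetime exposure.
DEFAULT_EXPOSURE = ExposureParams(fir=25.4, wab=70.0, ef=365.0, ed=70.0, ta=25550.0)

#: US-EPA RfD / CSF and JECFA PTWI values. Mercury has no oral CSF.
TOX_PROFILES: dict[str, ToxProfile] = {
    "As": ToxProfile(metal="As", rfd=0.0003, csf=1.5, ptwi=15.0),
    "Hg": ToxProfile(metal="Hg", rfd=0.0001, csf=None, ptwi=4.0),
}

#: Analytical limits of the ICP-MS method (µg/kg); sub-LOD values are
#: substituted with 0 by default, matching reported minima of 0.00.
DEFAULT_CENSORING = CensoringRule(lod=0.0003, loq=0.001, policy="zero")

#: Survey design: eggs per brand-season cell and brands per season.
N_BRANDS = 21
REPLICATES_PER_BRAND = 2
N_PER_SEASON = N_BRANDS * REPLICATES_PER_BRAND  # 42

#: Seasonal (mean, standard error of the mean) in µg/kg per metal, n = 42
#: per cell.  Summer Hg was uniform at the reported value (se = 0).
SURVEY_MOMENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("As", "winter"): (0.52, 0.050),
    ("As", "summer"): (1.07, 0.557),
    ("Hg", "winter"): (0.26, 0.021),
    ("Hg", "summer"): (0.10, 0.0),
}

METALS = ("As", "Hg")
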