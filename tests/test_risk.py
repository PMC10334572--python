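"""Deterministic exposure and risk metrics: EDI/EWI/EMI, THQ, ILCR,
classification bands and guideline fractions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eggrisk import (
    ExposureParams,
    ToxProfile,
    ValidationError,
    assess,
    classify_ilcr,
    classify_risk,
    classify_thq,
    compare_guidelines,
    compute_edi,
    compute_ilcr,
    compute_thq,
    derive_ewi_emi,
    round_half_up,
    round_sig,
)
from eggrisk.defaults import DEFAULT_EXPOSURE, TOX_PROFILES

AS, HG = TOX_PROFILES["As"], TOX_PROFILES["Hg"]


class TestEDI:
    @pytest.mark.parametrize(
        "mean,rounded",
        [
            (0.79, 0.29),  # two-season mean arsenic
            (0.52, 0.19),  # winter arsenic
            (1.07, 0.39),  # summer arsenic
            (0.26, 0.09),  # winter mercury
            (0.0, 0.0),
        ],
    )
    def test_paper_convention_numerals(self, mean, rounded):
        edi = compute_edi(mean, DEFAULT_EXPOSURE, "paper")
        assert round_half_up(edi, 2) == pytest.approx(rounded)

    def test_mean_arsenic_raw_value(self):
        assert compute_edi(0.79) == pytest.approx(25.4 * 0.79 / 70, rel=1e-12)

    def test_strict_is_paper_over_1000(self):
        assert compute_edi(0.79, convention="strict") == pytest.approx(
            compute_edi(0.79, convention="paper") / 1000.0, rel=1e-12
        )

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValidationError):
            compute_edi(0.5, convention="si")


class TestWeeklyMonthly:
    @pytest.mark.parametrize(
        "edi,ewi,emi",
        [
            (25.4 * 0.52 / 70, 1.32, 5.66),  # winter As row
            (25.4 * 1.07 / 70, 2.72, 11.65),  # summer As row
            (25.4 * 0.26 / 70, 0.66, 2.83),  # winter Hg row
            (25.4 * 0.10 / 70, 0.25, 1.09),  # summer Hg row
            (0.0, 0.0, 0.0),
        ],
    )
    def test_weekly_monthly_rows(self, edi, ewi, emi):
        w, m = derive_ewi_emi(edi)
        assert round_half_up(w, 2) == pytest.approx(ewi)
        assert round_half_up(m, 2) == pytest.approx(emi)

    def test_factors_are_7_and_30(self):
        w, m = derive_ewi_emi(0.1)
        assert (w, m) == (pytest.approx(0.7), pytest.approx(3.0))


class TestTHQ:
    @pytest.mark.parametrize(
        "mean,tox,expect5",
        [
            (0.26, HG, 0.00094),  # winter mercury
            (0.10, HG, 0.00036),  # summer mercury
            (0.18, HG, 0.00065),  # two-season mercury
            (0.0, HG, 0.0),
        ],
    )
    def test_mercury_values(self, mean, tox, expect5):
        assert round_half_up(compute_thq(mean, DEFAULT_EXPOSURE, tox), 5) == pytest.approx(
            expect5
        )

    @pytest.mark.parametrize(
        "mean,expect3sf",
        [(0.79, 0.000956), (0.52, 0.000629), (1.07, 0.00129)],
    )
    def test_arsenic_values_follow_the_dose_equation(self, mean, expect3sf):
        """Arsenic THQ computed directly from the hazard-quotient equation
        at RfD 0.0003 mg/kg/day.  Published arsenic THQ figures in this
        problem's source literature run about 4x higher than the equation
        yields; this package reports the equation's value."""
        thq = compute_thq(mean, DEFAULT_EXPOSURE, AS)
        assert round_sig(thq, 3) == pytest.approx(expect3sf)

    def test_unit_boundary_gives_exactly_one(self):
        # concentration (µg/kg) at which THQ crosses 1 at mercury defaults
        cm = HG.rfd * DEFAULT_EXPOSURE.wab / (DEFAULT_EXPOSURE.fir * 1e-3) * 1000.0
        assert cm == pytest.approx(275.59, abs=0.01)
        assert compute_thq(cm, DEFAULT_EXPOSURE, HG) == pytest.approx(1.0, rel=1e-12)

    def test_thq_requires_tox(self):
        with pytest.raises(ValidationError):
            compute_thq(0.5, DEFAULT_EXPOSURE, None)


class TestILCR:
    def test_winter_arsenic(self):
        ilcr = compute_ilcr(compute_edi(0.52), AS)
        assert round_sig(ilcr, 3) == pytest.approx(2.83e-4)

    def test_mean_arsenic_from_seasonal_average(self):
        seasonal = [compute_ilcr(compute_edi(c), AS) for c in (0.52, 1.07)]
        assert round_sig(sum(seasonal) / 2, 3) == pytest.approx(4.33e-4)

    def test_zero_intake(self):
        assert compute_ilcr(0.0, AS) == 0.0

    def test_mercury_has_no_slope_factor(self):
        assert compute_ilcr(compute_edi(0.26), HG) is None
        est = assess(0.26, HG, season="winter")
        assert est.ilcr is None and est.ilcr_class is None


class TestClassification:
    @pytest.mark.parametrize(
        "ilcr,band",
        [
            (5e-7, "negligible"),
            (math.nextafter(1e-6, 0), "negligible"),
            (1e-6, "acceptable"),
            (5e-5, "acceptable"),
            (1e-4, "acceptable"),
            (math.nextafter(1e-4, 1), "threshold_exceeded"),
            (4.33e-4, "threshold_exceeded"),
            (1e-3, "threshold_exceeded"),
            (math.nextafter(1e-3, 1), "moderate_risk"),
            (2e-3, "moderate_risk"),
        ],
    )
    def test_ilcr_band_edges_are_half_open(self, ilcr, band):
        assert classify_ilcr(ilcr) == band

    @pytest.mark.parametrize(
        "thq,cls",
        [(0.0, "below_1"), (0.00094, "below_1"), (math.nextafter(1, 0), "below_1"),
         (1.0, "at_or_above_1"), (3.2, "at_or_above_1")],
    )
    def test_thq_threshold(self, thq, cls):
        assert classify_thq(thq) == cls

    def test_joint_classification(self):
        assert classify_risk(0.00094, 4.33e-4) == ("below_1", "threshold_exceeded")
        assert classify_risk(0.5, None) == ("below_1", None)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            classify_thq(-0.1)
        with pytest.raises(ValidationError):
            classify_ilcr(-1e-6)


class TestGuidelines:
    def test_arsenic_weekly_fraction(self):
        g = compare_guidelines(2.03, 8.71, DEFAULT_EXPOSURE, AS)
        assert g.ewi_fraction_of_ptwi == pytest.approx(2.03 / 15, rel=1e-9)
        assert g.within_limits

    def test_zero_intake(self):
        g = compare_guidelines(0.0, 0.0, DEFAULT_EXPOSURE, HG)
        assert g.ewi_fraction_of_ptwi == 0.0

    def test_boundary_not_within_limits(self):
        g = compare_guidelines(15.0, 0.0, DEFAULT_EXPOSURE, AS)
        assert g.ewi_fraction_of_ptwi == pytest.approx(1.0)
        assert not g.within_limits

    def test_ptmi_defaults_to_ptwi_scaled(self):
        assert AS.ptmi_effective == pytest.approx(15 * 30 / 7)

    def test_missing_ptwi_is_config_error(self):
        bare = ToxProfile(metal="X", rfd=0.001)
        with pytest.raises(ValidationError):
            compare_guidelines(1.0, 4.0, DEFAULT_EXPOSURE, bare)


@given(cm=st.floats(min_value=0, max_value=1e3), k=st.floats(min_value=0.1, max_value=10))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_metrics_are_linear_in_concentration(cm, k):
    """EDI, THQ and ILCR all scale proportionally with the mean
    concentration, so seasonal metric ratios track concentration ratios."""
    e1, e2 = compute_edi(cm), compute_edi(k * cm)
    t1, t2 = compute_thq(cm, DEFAULT_EXPOSURE, AS), compute_thq(k * cm, DEFAULT_EXPOSURE, AS)
    i1, i2 = compute_ilcr(e1, AS), compute_ilcr(e2, AS)
    assert e2 == pytest.approx(k * e1, rel=1e-9, abs=1e-300)
    assert t2 == pytest.approx(k * t1, rel=1e-9, abs=1e-300)
    assert i2 == pytest.approx(k * i1, rel=1e-9, abs=1e-300)


def test_thq_is_convention_independent():
    a = assess(0.26, HG, convention="paper")
    b = assess(0.26, HG, convention="strict")
    assert a.thq == b.thq
    assert b.edi == pytest.approx(a.edi / 1000.0)
    assert b.emi == pytest.approx(a.emi / 1000.0)


def test_exposure_param_validation():
    with pytest.raises(ValidationError):
        ExposureParams(fir=-1)
    with pytest.raises(ValidationError):
        ToxProfile(metal="As", rfd=0.0)
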