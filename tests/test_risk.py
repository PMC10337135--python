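"""Relative-risk curves and potential impact fractions."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from bmiburden.datatypes import (
    BMIDistribution,
    ModelConfig,
    RRBand,
    RRSpec,
    SpecificationGapError,
    default_rr_specs,
)
from bmiburden.risk import (
    bmi_grid,
    incidence_multiplier,
    normal_weights,
    pif,
    pif_from_weights,
    rr_at_bmi,
)

SPECS = default_rr_specs()
GRID = bmi_grid(ModelConfig())


def test_loglinear_rr_is_one_at_tmrel_and_floored_below():
    chd = SPECS["coronary_heart_disease"]
    assert rr_at_bmi(chd, "male", 45, 22.0) == 1.0
    assert rr_at_bmi(chd, "male", 45, 18.0) == 1.0  # no risk reversal below TMREL
    # one 5-unit step above the TMREL returns the printed band value
    assert rr_at_bmi(chd, "male", 45, 27.0) == pytest.approx(1.50)
    # ages below the youngest band borrow it; above the oldest, the oldest
    assert rr_at_bmi(chd, "female", 25, 27.0) == pytest.approx(1.50)
    assert rr_at_bmi(chd, "male", 95, 27.0) == pytest.approx(1.30)


def test_categorical_rr_returns_band_values_as_printed():
    hhd = SPECS["hypertensive_heart_disease"]
    assert rr_at_bmi(hhd, "female", 50, 30.0) == pytest.approx(2.03)
    assert rr_at_bmi(hhd, "female", 50, 20.0) == pytest.approx(1.17)
    cirrhosis = SPECS["cirrhosis"]
    assert rr_at_bmi(cirrhosis, "male", 50, 20.0) == pytest.approx(0.73)  # as printed
    # outside the printed BMI span the nearest band extends
    assert rr_at_bmi(hhd, "male", 50, 55.0) == pytest.approx(2.03)
    assert rr_at_bmi(hhd, "male", 50, 12.0) == pytest.approx(1.17)


def test_applicability_windows_return_neutral_risk():
    liver = SPECS["liver_cancer"]
    assert rr_at_bmi(liver, "male", 30, 30.0) == 1.0
    assert rr_at_bmi(liver, "male", 50, 27.0) == pytest.approx(1.47)
    breast = SPECS["breast_cancer"]
    assert rr_at_bmi(breast, "male", 70, 30.0) == 1.0
    assert rr_at_bmi(breast, "female", 50, 30.0) == 1.0
    assert rr_at_bmi(breast, "female", 70, 27.0) == pytest.approx(1.12)


def test_missing_band_without_window_is_a_specification_gap():
    spec = RRSpec(
        "coronary_heart_disease",
        "per5_loglinear",
        (RRBand(1.5, 1.4, 1.6, sex="male"),),
    )
    with pytest.raises(SpecificationGapError, match="female"):
        rr_at_bmi(spec, "female", 50, 27.0)


def test_pif_two_point_distribution_by_hand():
    # reference: 25% of mass at RR 1, 75% at RR 2; counterfactual all at RR 1
    rr = np.array([1.0, 2.0])
    w_ref = np.array([0.25, 0.75])
    w_cf = np.array([1.0, 0.0])
    assert pif_from_weights(w_ref, w_cf, rr) == pytest.approx(0.42857142857, abs=1e-6)


def test_pif_point_masses_log_linear():
    spec = RRSpec(
        "pancreatic_cancer", "per5_loglinear", (RRBand(1.5, 1.4, 1.6),), tmrel=22.0
    )
    ref = BMIDistribution(27.0)  # RR 1.5 exactly
    cf = BMIDistribution(22.0)  # RR 1 at the TMREL
    assert pif(ref, cf, spec, "male", 50) == pytest.approx(1.0 / 3.0, abs=1e-6)
    assert pif(ref, ref, spec, "male", 50) == 0.0
    assert incidence_multiplier(ref, ref, spec, "male", 50) == 1.0


@given(
    ref_mean=st.floats(24.0, 34.0),
    cf_shift=st.floats(-4.0, 4.0),
    sd=st.floats(1.0, 6.0),
)
def test_pif_and_multiplier_are_exact_complements(ref_mean, cf_shift, sd):
    spec = SPECS["coronary_heart_disease"]
    ref = BMIDistribution(ref_mean, sd)
    cf = BMIDistribution(ref_mean + cf_shift, sd)
    p = pif(ref, cf, spec, "male", 50, GRID)
    m = incidence_multiplier(ref, cf, spec, "male", 50, GRID)
    assert p + m == 1.0  # complement by construction, to machine precision
    assert p <= 1.0


@given(shift=st.floats(0.1, 3.0), sd=st.floats(1.0, 6.0))
def test_lower_counterfactual_mean_increases_pif(shift, sd):
    spec = SPECS["coronary_heart_disease"]
    ref = BMIDistribution(29.0, sd)
    down = pif(ref, BMIDistribution(29.0 - shift, sd), spec, "male", 50, GRID)
    down_more = pif(ref, BMIDistribution(29.0 - shift - 0.5, sd), spec, "male", 50, GRID)
    assert down > 0
    assert down_more > down


def test_swapping_reference_and_counterfactual_flips_the_numerator():
    spec = SPECS["coronary_heart_disease"]
    a = BMIDistribution(29.0, 4.0)
    b = BMIDistribution(27.5, 4.0)
    fwd = pif(a, b, spec, "male", 50, GRID)
    rev = pif(b, a, spec, "male", 50, GRID)
    assert rev == pytest.approx(-fwd / (1.0 - fwd), rel=1e-9)


def test_higher_counterfactual_raises_the_multiplier():
    spec = SPECS["pancreatic_cancer"]
    ref = BMIDistribution(28.0, 4.0)
    up = BMIDistribution(29.5, 4.0)
    assert incidence_multiplier(ref, up, spec, "female", 50, GRID) > 1.0


@pytest.mark.parametrize("disease", ["coronary_heart_disease", "type2_diabetes"])
def test_grid_convergence_against_finer_oracle(disease):
    spec = SPECS[disease]
    coarse = ModelConfig()
    fine = ModelConfig(bmi_grid_step=0.01)  # 10x finer oracle grid
    half = ModelConfig(bmi_grid_step=0.05)
    ref = BMIDistribution(28.5, 4.2)
    cf = BMIDistribution(27.3, 4.2)
    values = {
        cfg.bmi_grid_step: pif(ref, cf, spec, "male", 55, bmi_grid(cfg))
        for cfg in (coarse, half, fine)
    }
    assert values[0.1] == pytest.approx(values[0.01], abs=1e-4)
    assert values[0.05] == pytest.approx(values[0.01], abs=1e-4)


def test_weights_are_renormalised_probability_vectors():
    w = normal_weights(np.array([28.0, 45.0]), np.array([4.0, 9.0]), GRID)
    np.testing.assert_allclose(w.sum(axis=1), 1.0, rtol=1e-12)
    assert (w >= 0).all()
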