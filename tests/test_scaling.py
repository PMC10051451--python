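"""Fitting, applying, and comparing the shielding-to-shift scaling line."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shiftbench import (
    LEGACY_C13_FACTORS,
    LEGACY_H1_FACTORS,
    RECOMMENDED_FACTORS,
    DegenerateFitError,
    Nucleus,
    ScalingFactors,
    compare_scalings,
    fit_scaling,
    predict_shift,
    predict_shifts,
)
from conftest import ols_normal_equations


def test_perfect_line_recovered_exactly():
    factors = fit_scaling([(0, 31.0), (1, 30.0), (2, 29.0)], Nucleus.H1)
    assert factors.slope_m == pytest.approx(-1.0, abs=1e-12)
    assert factors.intercept_b == pytest.approx(31.0, abs=1e-12)
    assert factors.r_squared == pytest.approx(1.0, abs=1e-12)
    assert factors.fit_rmsd == pytest.approx(0.0, abs=1e-9)


def test_fit_matches_hand_computed_normal_equations():
    delta = [1.0, 2.0, 3.0, 4.0]
    sigma = [30.0, 29.1, 27.9, 27.0]
    factors = fit_scaling(list(zip(delta, sigma)), Nucleus.H1)
    assert factors.slope_m == pytest.approx(-1.02, abs=1e-12)
    assert factors.intercept_b == pytest.approx(31.05, abs=1e-12)


def test_fit_recovers_published_line_from_noiseless_data(delta50):
    """Shieldings generated exactly on the high-accuracy 1H line refit to it."""
    truth = RECOMMENDED_FACTORS["method2"][Nucleus.H1]
    deltas = [
        s.delta_exp
        for c in delta50
        for s in c.sites_for(Nucleus.H1)
    ]
    pairs = [(d, truth.slope_m * d + truth.intercept_b) for d in deltas]
    fitted = fit_scaling(pairs, Nucleus.H1)
    assert fitted.slope_m == pytest.approx(-1.0311, abs=1e-9)
    assert fitted.intercept_b == pytest.approx(32.2654, abs=1e-7)
    assert fitted.n_points == 114


def test_degenerate_fits_rejected():
    with pytest.raises(DegenerateFitError):
        fit_scaling([(1.0, 30.0)], Nucleus.H1)
    with pytest.raises(DegenerateFitError):
        fit_scaling([(1.0, 30.0), (1.0, 29.0)], Nucleus.H1)


@settings(deadline=None, max_examples=60)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=-5, max_value=250, allow_nan=False),
            st.floats(min_value=-60, max_value=250, allow_nan=False),
        ),
        min_size=2,
        max_size=50,
    )
)
def test_fit_agrees_with_normal_equations_oracle(pairs):
    delta = np.array([p[0] for p in pairs])
    sigma = np.array([p[1] for p in pairs])
    if np.ptp(delta) < 1e-6:
        return
    m, b = ols_normal_equations(delta, sigma)
    if m == 0:
        return
    try:
        factors = fit_scaling(pairs, Nucleus.C13)
    except DegenerateFitError:
        # oracle slope is nonzero only through rounding noise
        assert abs(m) < 1e-12
        return
    assert factors.slope_m == pytest.approx(m, abs=1e-10, rel=1e-9)
    assert factors.intercept_b == pytest.approx(b, abs=1e-8, rel=1e-9)


def test_fit_invariant_to_ordering_and_uniform_duplication():
    pairs = [(1.0, 30.0), (2.5, 28.4), (4.0, 27.1), (7.25, 23.9)]
    f1 = fit_scaling(pairs, Nucleus.H1)
    f2 = fit_scaling(pairs[::-1], Nucleus.H1)
    f3 = fit_scaling(pairs * 3, Nucleus.H1)
    assert f1.slope_m == pytest.approx(f2.slope_m, abs=1e-14)
    assert f1.intercept_b == pytest.approx(f2.intercept_b, abs=1e-12)
    assert f3.slope_m == pytest.approx(f1.slope_m, abs=1e-12)
    assert f3.intercept_b == pytest.approx(f1.intercept_b, abs=1e-10)
    assert f3.n_points == 12


def test_predict_hand_evaluations():
    m1_c = RECOMMENDED_FACTORS["method1"][Nucleus.C13]
    assert predict_shift(94.9073, m1_c) == pytest.approx(
        (195.6683 - 94.9073) / 1.0081, abs=1e-12
    )
    assert predict_shift(94.9073, m1_c) == pytest.approx(99.951, abs=5e-4)
    m2_h = RECOMMENDED_FACTORS["method2"][Nucleus.H1]
    assert predict_shift(25.0, m2_h) == pytest.approx(7.046, abs=5e-4)
    # sigma at the intercept maps to zero shift
    assert predict_shift(m2_h.intercept_b, m2_h) == 0.0


def test_predict_attaches_residuals():
    factors = ScalingFactors(Nucleus.H1, -1.0, 31.0)
    preds = predict_shifts(
        {("x", "H1"): 30.0},
        factors,
        delta_exp={("x", "H1"): 0.9},
    )
    assert preds[0].delta_pred == pytest.approx(1.0)
    assert preds[0].residual == pytest.approx(0.1)


def test_roundtrip_predict_after_fit_on_noiseless_line():
    rng = np.random.default_rng(11)
    delta = rng.uniform(-2.9, 219.4, size=40)
    sigma = -1.0065 * delta + 196.0386
    factors = fit_scaling(list(zip(delta, sigma)), Nucleus.C13)
    back = [(factors.intercept_b - s) / (-factors.slope_m) for s in sigma]
    assert np.max(np.abs(np.array(back) - delta)) <= 1e-9


def test_compare_scalings_closed_form_equals_dense_grid():
    f1, f2 = LEGACY_C13_FACTORS
    lo, hi = -2.9, 219.4
    max_diff, argmax = compare_scalings(f1, f2, (lo, hi))
    grid = np.linspace(lo, hi, 10_000)
    sigma = f1.slope_m * grid + f1.intercept_b
    back = (f2.intercept_b - sigma) / (-f2.slope_m)
    dense = np.max(np.abs(back - grid))
    assert max_diff == pytest.approx(dense, abs=1e-12)
    assert argmax in (lo, hi)


def test_compare_scalings_identical_lines_and_errors():
    f = LEGACY_H1_FACTORS[0]
    assert compare_scalings(f, f, (0.25, 9.80))[0] == 0.0
    with pytest.raises(ValueError):
        compare_scalings(LEGACY_H1_FACTORS[0], LEGACY_C13_FACTORS[0], (0, 1))
    with pytest.raises(ValueError):
        compare_scalings(f, f, (2.0, 1.0))


def test_published_cross_dataset_differences():
    h_diff, _ = compare_scalings(*LEGACY_H1_FACTORS, (0.25, 9.80))
    c_diff, _ = compare_scalings(*LEGACY_C13_FACTORS, (-2.9, 219.4))
    assert round(h_diff, 2) == 0.04
    assert round(c_diff, 2) == 0.15
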