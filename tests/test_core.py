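"""Unit and property tests for the compositional density model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesidens import (
    ComponentMixture,
    DegenerateSystemError,
    InfeasibleMeasurementError,
    InvariantError,
    SizeObservation,
    TreatmentMeasurements,
    attribution_fraction,
    diameter_ratio,
    forward_density,
    observed_size_change,
    post_density,
    relative_volume,
    solve_composition,
    solve_post_composition,
    solve_pre_composition,
)

# ---------------------------------------------------------------------------
# forward density
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "components, expected",
    [
        ([("chol", 1.067, 1.0)], 1.067),  # identity case
        # the solved bench composition reproduces the measured pre density
        ([("residual", 1.134, 0.433), ("chol", 1.067, 0.567)], 1.096),
        ([("a", 1.0, 0.5), ("b", 1.2, 0.5)], 1.1),  # equal-volume mean
    ],
)
def test_forward_density_examples(components, expected):
    assert forward_density(ComponentMixture(components)) == pytest.approx(expected, abs=5e-4)


def test_forward_density_rejects_unnormalized_fractions():
    with pytest.raises(InvariantError, match="sum to 1"):
        ComponentMixture([("a", 1.0, 0.4), ("b", 1.2, 0.4)])


@given(
    rho=st.lists(st.floats(0.9, 1.5), min_size=1, max_size=5),
    raw=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
)
def test_forward_density_bounded_by_component_densities(rho, raw):
    n = min(len(rho), len(raw))
    rho, raw = rho[:n], raw[:n]
    fracs = np.array(raw) / np.sum(raw)
    # renormalize exactly so the invariant check passes
    fracs[-1] = 1.0 - fracs[:-1].sum()
    mix = ComponentMixture([(f"c{i}", rho[i], fracs[i]) for i in range(n)])
    d = forward_density(mix)
    assert min(rho) - 1e-12 <= d <= max(rho) + 1e-12


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def _meas(rho_pre=1.096, rho_post=1.122, M=0.166, rho_s=1.067):
    return TreatmentMeasurements(
        rho_pre=rho_pre, rho_pre_sem=0.0, rho_post=rho_post, rho_post_sem=0.0,
        mass_remaining_M=M, mass_remaining_M_sem=0.0, rho_sensitive=rho_s,
    )


def test_inversion_reproduces_bench_composition():
    """The printed density measurements invert to 0.567/0.433 and rho_r 1.134."""
    v_s, v_r, rho_r = solve_pre_composition(_meas())
    assert round(v_s, 3) == 0.567
    assert round(v_r, 3) == 0.433
    assert round(rho_r, 3) == 1.134


def test_inversion_satisfies_all_three_equations():
    meas = _meas()
    v_s, v_r, rho_r = solve_pre_composition(meas)
    assert v_r * rho_r + v_s * meas.rho_sensitive == pytest.approx(meas.rho_pre, abs=1e-9)
    assert v_s + v_r == pytest.approx(1.0, abs=1e-9)
    assert post_density(v_s, v_r, rho_r, meas.rho_sensitive, meas.mass_remaining_M) == (
        pytest.approx(meas.rho_post, abs=1e-9)
    )


def test_no_density_shift_means_no_sensitive_component():
    v_s, v_r, rho_r = solve_pre_composition(_meas(rho_pre=1.122, rho_post=1.122))
    assert v_s == 0.0
    assert rho_r == pytest.approx(1.122, abs=1e-12)


@pytest.mark.parametrize(
    "kwargs, exc",
    [
        ({"M": 1.0}, DegenerateSystemError),
        ({"rho_s": 1.122}, DegenerateSystemError),
        ({"rho_pre": 1.2}, InfeasibleMeasurementError),  # V_s < 0
        ({"rho_pre": 1.05}, InfeasibleMeasurementError),  # V_s > 1
    ],
)
def test_inversion_error_modes(kwargs, exc):
    with pytest.raises(exc):
        solve_pre_composition(_meas(**kwargs))


def test_infeasible_error_names_feasible_range():
    with pytest.raises(InfeasibleMeasurementError, match=r"rho_pre would need to lie"):
        solve_pre_composition(_meas(rho_pre=1.2))


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(
    v_s=st.floats(0.05, 0.95),
    rho_r=st.floats(1.08, 1.40),
    M=st.floats(0.01, 0.99),
)
def test_forward_inverse_round_trip(v_s, rho_r, M):
    """Forward-simulating densities and inverting recovers the composition to 1e-10."""
    rho_s = 1.067
    mix = ComponentMixture([("s", rho_s, v_s), ("r", rho_r, 1.0 - v_s)])
    rho_pre = forward_density(mix)
    rho_post = post_density(v_s, 1.0 - v_s, rho_r, rho_s, M)
    v_s_hat, v_r_hat, rho_r_hat = solve_pre_composition(
        _meas(rho_pre=rho_pre, rho_post=rho_post, M=M, rho_s=rho_s)
    )
    assert v_s_hat == pytest.approx(v_s, abs=1e-10)
    assert rho_r_hat == pytest.approx(rho_r, abs=1e-10)


# ---------------------------------------------------------------------------
# post-treatment quantities
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "args, expected",
    [
        ((0.567, 0.433, 1.134, 1.067, 0.166), 1.122),
        ((0.567, 0.433, 1.134, 1.067, 1.0), 1.096),  # no extraction
        # re-inflating the post composition by 1/M recovers the pre density
        ((0.179, 0.821, 1.134, 1.067, 6.02), 1.096),
    ],
)
def test_post_density_examples(args, expected):
    assert post_density(*args) == pytest.approx(expected, abs=5e-4)


def test_post_density_vanishing_vesicle_raises():
    with pytest.raises(DegenerateSystemError):
        post_density(1.0, 0.0, 1.134, 1.067, 0.0)


@pytest.mark.parametrize(
    "v_s, v_r, M, expected",
    [
        (0.567, 0.433, 0.166, (0.179, 0.821)),
        (0.567, 0.433, 1.0, (0.567, 0.433)),
        (0.567, 0.433, 0.0, (0.0, 1.0)),
    ],
)
def test_solve_post_composition_examples(v_s, v_r, M, expected):
    v_s_post, v_r_post = solve_post_composition(v_s, v_r, M)
    assert v_s_post == pytest.approx(expected[0], abs=5e-4)
    assert v_r_post == pytest.approx(expected[1], abs=5e-4)
    assert v_s_post + v_r_post == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "v_s, v_r, M, expected",
    [
        (0.567, 0.433, 0.166, 0.527),
        (0.567, 0.433, 1.0, 1.0),
        (0.567, 0.433, 0.0, 0.433),
    ],
)
def test_relative_volume_examples(v_s, v_r, M, expected):
    assert relative_volume(v_s, v_r, M) == pytest.approx(expected, abs=5e-4)


@given(v_s=st.floats(0.05, 0.95), m1=st.floats(0.0, 1.0), m2=st.floats(0.0, 1.0))
def test_relative_volume_strictly_increasing_in_M(v_s, m1, m2):
    lo, hi = sorted((m1, m2))
    # strictness is only meaningful above float resolution of v_r + v_s*M
    if hi - lo < 1e-12:
        return
    assert relative_volume(v_s, 1 - v_s, lo) < relative_volume(v_s, 1 - v_s, hi)


@pytest.mark.parametrize(
    "rel_vol, expected",
    [(0.527, 0.808), (1.0, 1.0), (0.125, 0.5)],
)
def test_diameter_ratio_examples(rel_vol, expected):
    assert diameter_ratio(rel_vol) == pytest.approx(expected, abs=5e-4)


def test_diameter_ratio_rejects_nonpositive_volume():
    with pytest.raises(InvariantError):
        diameter_ratio(0.0)


@given(v1=st.floats(0.01, 1.0), v2=st.floats(0.01, 1.0))
def test_diameter_ratio_strictly_increasing(v1, v2):
    if v1 == v2:
        return
    lo, hi = sorted((v1, v2))
    assert diameter_ratio(lo) < diameter_ratio(hi)


def test_solved_radius_shrinkage_is_19_pct():
    sol = solve_composition(_meas())
    assert round(sol.diameter_ratio, 2) == 0.81
    assert round(sol.radius_shrinkage_pct) == 19


@settings(deadline=None, derandomize=True)
@given(v_s=st.floats(0.05, 0.95), rho_r=st.floats(1.08, 1.4), M=st.floats(0.01, 0.99))
def test_removed_mass_accounting(v_s, rho_r, M):
    """Mass removed by treatment equals (1-M) * v_s * rho_s / rho_pre of the pre mass."""
    rho_s = 1.067
    v_r = 1.0 - v_s
    rho_pre = v_r * rho_r + v_s * rho_s
    rho_post = post_density(v_s, v_r, rho_r, rho_s, M)
    rel_vol = relative_volume(v_s, v_r, M)
    # pre mass = rho_pre * 1; post mass = rho_post * rel_vol
    removed_fraction = (rho_pre - rho_post * rel_vol) / rho_pre
    assert removed_fraction == pytest.approx((1 - M) * v_s * rho_s / rho_pre, abs=1e-12)


# ---------------------------------------------------------------------------
# observed size change and attribution
# ---------------------------------------------------------------------------


def _obs(mean, sd=10.0, condition="control", fraction_class="dense"):
    return SizeObservation(
        condition=condition, fraction_class=fraction_class,
        diameter_mean=mean, diameter_sd=sd,
    )


def test_observed_size_change_dense_band():
    """453 -> 270.2 nm is a 40.4% diameter and 78.8% volume decline."""
    d_decline, v_decline = observed_size_change(
        _obs(453.0), _obs(270.2, condition="treated")
    )
    assert round(d_decline, 1) == 40.4
    assert round(v_decline, 1) == 78.8


def test_observed_size_change_identical_diameters():
    assert observed_size_change(_obs(300.0), _obs(300.0, condition="treated")) == (0.0, 0.0)


def test_observed_size_change_warns_on_band_mismatch():
    with pytest.warns(UserWarning, match="different gradient bands"):
        observed_size_change(
            _obs(453.0), _obs(42.2, condition="treated", fraction_class="buoyant")
        )


@pytest.mark.parametrize(
    "predicted, observed, expected",
    [
        (47.3, 88.8, 0.53),  # vs the reported observed volume fall
        (47.3, 78.8, 0.60),  # vs the diameter-consistent observed volume fall
        (40.0, 40.0, 1.0),
    ],
)
def test_attribution_fraction_examples(predicted, observed, expected):
    assert attribution_fraction(predicted, observed) == pytest.approx(expected, abs=5e-3)


def test_attribution_fraction_rejects_zero_observed():
    with pytest.raises(InvariantError):
        attribution_fraction(47.3, 0.0)
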