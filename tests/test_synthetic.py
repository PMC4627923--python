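"""Tests for the synthetic-experiment generator and recovery study."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesidens import (
    InvariantError,
    PropagationConfig,
    TruthParameters,
    generate_experiment,
    generate_gradient_profiles,
    recovery_study,
    solve_pre_composition,
)

ZERO_NOISE = (0.0, 0.0, 0.0)


def _profiles(exp, quantity):
    out = {p.condition: p for p in exp.gradient if p.quantity == quantity}
    assert set(out) == {"control", "treated"}
    return out["control"], out["treated"]


def test_zero_noise_reproduces_measured_inputs():
    """At the reference operating point the noiseless forward model regenerates
    the measured densities and the predicted diameter ratio."""
    truth = TruthParameters(noise_sems=ZERO_NOISE)
    exp = generate_experiment(truth)
    m = exp.measurements
    assert round(m.rho_pre, 3) == 1.096
    assert round(m.rho_post, 3) == 1.122
    assert m.mass_remaining_M == 0.166
    control, treated = exp.dls
    assert treated.diameter_mean / control.diameter_mean == pytest.approx(
        0.527 ** (1 / 3), abs=1e-3
    )


def test_same_seed_gives_identical_experiment():
    e1 = generate_experiment(TruthParameters(seed=11))
    e2 = generate_experiment(TruthParameters(seed=11))
    assert e1 == e2
    e3 = generate_experiment(TruthParameters(seed=12))
    assert e3.measurements != e1.measurements


def test_null_treatment_leaves_gradients_unchanged():
    truth = TruthParameters(M_true=1.0, noise_sems=ZERO_NOISE)
    exp = generate_experiment(truth)
    for quantity in ("cholesterol", "protein", "ganglioside"):
        ctrl, trt = _profiles(exp, quantity)
        assert np.allclose(ctrl.values, trt.values)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    v_s=st.floats(0.05, 0.95),
    rho_r=st.floats(1.08, 1.40),
    M=st.floats(0.01, 0.99),
)
def test_generator_solver_adjointness(v_s, rho_r, M):
    """With zero noise, inverting a generated experiment recovers the truth to 1e-10."""
    truth = TruthParameters(
        v_s_true=v_s, rho_r_true=rho_r, M_true=M, noise_sems=ZERO_NOISE
    )
    exp = generate_experiment(truth, n_particles=2)
    v_s_hat, _, rho_r_hat = solve_pre_composition(exp.measurements)
    assert v_s_hat == pytest.approx(v_s, abs=1e-10)
    assert rho_r_hat == pytest.approx(rho_r, abs=1e-10)


def test_cholesterol_conservation_law():
    """Treated/control total cholesterol signal equals M_true exactly at zero noise,
    and the loss is confined to the buoyant band."""
    truth = TruthParameters(noise_sems=ZERO_NOISE)
    ctrl, trt = _profiles(generate_experiment(truth), "cholesterol")
    assert trt.total / ctrl.total == pytest.approx(truth.M_true, abs=1e-12)
    dense = [i for i in range(9, 13)]
    for f in dense:
        assert trt.value_at(f) == ctrl.value_at(f)  # zero in both: nothing accumulates


def test_protein_total_is_conserved_but_redistributed():
    truth = TruthParameters(noise_sems=ZERO_NOISE)
    ctrl, trt = _profiles(generate_experiment(truth), "protein")
    assert trt.total == pytest.approx(ctrl.total, rel=1e-12)
    dense_ctrl = sum(ctrl.value_at(f) for f in range(9, 13))
    dense_trt = sum(trt.value_at(f) for f in range(9, 13))
    assert dense_trt > dense_ctrl  # shifted toward the dense band


def test_ganglioside_buoyant_band_halved_at_reference_strength():
    truth = TruthParameters(noise_sems=ZERO_NOISE)
    ctrl, trt = _profiles(generate_experiment(truth), "ganglioside")
    buoyant_ctrl = sum(ctrl.value_at(f) for f in range(5, 9))
    buoyant_trt = sum(trt.value_at(f) for f in range(5, 9))
    assert buoyant_trt / buoyant_ctrl == pytest.approx(0.5, abs=1e-12)
    for f in range(9, 13):
        assert trt.value_at(f) == ctrl.value_at(f)


def test_two_fraction_gradient_is_degenerate_but_conserved():
    truth = TruthParameters(noise_sems=ZERO_NOISE)
    profiles = generate_gradient_profiles(truth, n_fractions=2)
    by_key = {(p.quantity, p.condition): p for p in profiles}
    chol_ratio = (
        by_key[("cholesterol", "treated")].total / by_key[("cholesterol", "control")].total
    )
    assert chol_ratio == pytest.approx(truth.M_true, abs=1e-12)
    assert by_key[("protein", "treated")].total == pytest.approx(
        by_key[("protein", "control")].total, rel=1e-12
    )


def test_truth_parameter_validation():
    with pytest.raises(InvariantError):
        TruthParameters(v_s_true=1.2)
    with pytest.raises(InvariantError):
        TruthParameters(M_true=0.0)
    with pytest.raises(InvariantError):
        TruthParameters(noise_sems=(-0.1, 0.0, 0.0))


def test_noisy_generator_warns_when_inversion_will_be_infeasible():
    # residual lighter than the sensitive component: treated density falls
    # below rho_s and noisy draws frequently leave the feasible region
    truth = TruthParameters(v_s_true=0.5, rho_r_true=1.05, seed=1)
    with pytest.warns(UserWarning, match="infeasible"):
        generate_experiment(truth)


def test_recovery_zero_noise_has_zero_error():
    truth = TruthParameters(noise_sems=ZERO_NOISE, seed=2)
    report = recovery_study(truth, n_replicates=5, cfg=PropagationConfig(n_draws=200, seed=3))
    assert report.n_failed == 0
    assert abs(report.bias["v_s_pre"]) < 1e-12
    assert report.rmse["v_s_pre"] < 1e-12


def test_recovery_rmse_grows_with_noise():
    base = TruthParameters(seed=4)
    doubled = TruthParameters(seed=4, noise_sems=(0.006, 0.001, 0.055))
    cfg = PropagationConfig(n_draws=200, seed=5)
    r1 = recovery_study(base, n_replicates=60, cfg=cfg)
    r2 = recovery_study(doubled, n_replicates=60, cfg=cfg)
    assert r2.rmse["v_s_pre"] > r1.rmse["v_s_pre"]
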