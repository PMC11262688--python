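"""Kinetic model: closed form vs numerical integration, equilibria,
positivity and scaling properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cllkin.dynamics import (COMPARTMENTS, PARAM_NAMES, KineticParameters,
                             Trajectory, closed_form, closed_form_states,
                             percent_change_curve, simulate, steady_state)
from cllkin.exceptions import ValidationError

from conftest import random_valid_params


def _equilibrium_params():
    # f_in = F_out, kappa*F_out = mu_B, lam_i + sig_i*F_out = mu_i
    d = {"f_in": 0.05, "F_out": 0.05, "mu_B": 0.1, "kappa": 2.0}
    for s in ("4", "8", "NK", "reg"):
        d[f"sig_{s}"] = 0.4
        d[f"mu_{s}"] = 0.1
        d[f"lam_{s}"] = 0.1 - 0.4 * 0.05
    return KineticParameters(**d)


def test_equilibrium_parameterisation_gives_constant_unit_trajectory():
    times = np.linspace(0, 730, 25)
    for solver in (simulate, closed_form):
        traj = solver(_equilibrium_params(), times)
        assert np.allclose(traj.states, 1.0, atol=1e-8)


def test_pure_exponential_decay_without_production():
    p = KineticParameters(f_in=0.0, F_out=0.1, mu_B=0.05, kappa=1.0,
                          mu_4=0.1, mu_8=0.1, mu_NK=0.1, mu_reg=0.1)
    traj = simulate(p, np.array([0.0, 10.0]))
    assert traj.compartment("B_LN")[1] == pytest.approx(np.exp(-1.0), rel=1e-8)


def test_closed_form_steady_start_and_identity_at_t0(rng):
    p = KineticParameters(f_in=0.05, F_out=0.05, mu_B=0.1, kappa=1.0,
                          mu_4=0.1, mu_8=0.1, mu_NK=0.1, mu_reg=0.1)
    traj = closed_form(p, np.linspace(0, 500, 11))
    assert np.allclose(traj.compartment("B_LN"), 1.0, atol=1e-12)

    x0 = rng.uniform(0.2, 3.0, 6)
    p2 = KineticParameters.from_dict(random_valid_params(rng))
    traj0 = closed_form(p2, np.array([0.0]), initial_state=x0)
    assert np.allclose(traj0.states[0], x0, atol=1e-12)


def test_degenerate_equal_rates_match_limit_of_distinct_rates():
    base = dict(f_in=1e-3, F_out=0.04, kappa=3.0,
                mu_4=0.1, mu_8=0.1, mu_NK=0.1, mu_reg=0.1)
    times = np.linspace(0, 400, 9)
    exact = closed_form(KineticParameters(mu_B=0.04, **base), times)
    near = closed_form(KineticParameters(mu_B=0.04 + 1e-9, **base), times)
    assert np.allclose(exact.states, near.states, rtol=1e-5)
    # and the degenerate branch agrees with the integrator
    num = simulate(KineticParameters(mu_B=0.04, **base), times)
    assert np.allclose(exact.states, num.states, rtol=1e-6)


@pytest.mark.parametrize("n_draws", [50])
def test_integrator_matches_closed_form_on_random_draws(rng, n_draws):
    times = np.linspace(0, 730, 15)
    for _ in range(n_draws):
        p = KineticParameters.from_dict(random_valid_params(rng))
        a = simulate(p, times)
        b = closed_form(p, times)
        scale = np.maximum(np.abs(b.states), 1e-6)
        assert np.max(np.abs(a.states - b.states) / scale) < 1e-6


def test_steady_state_limits_and_long_horizon(rng):
    d = random_valid_params(rng)
    d["f_in"] = 0.0
    p = KineticParameters.from_dict(d)
    ss = steady_state(p)
    assert ss[0] == 0.0 and ss[1] == 0.0

    d2 = random_valid_params(rng)
    d2["f_in"] = d2["F_out"]
    assert steady_state(KineticParameters.from_dict(d2))[0] == pytest.approx(1.0)

    p3 = KineticParameters.from_dict(random_valid_params(rng))
    rates = [p3.F_out, p3.mu_B, p3.mu_4, p3.mu_8, p3.mu_NK, p3.mu_reg]
    t_end = 20.0 / min(rates)
    traj = closed_form(p3, np.array([0.0, t_end]))
    ss3 = steady_state(p3)
    assert np.allclose(traj.states[-1], ss3, rtol=1e-4, atol=1e-12)


def test_percent_change_trivial_and_interior_maximum(ref_theta):
    tr = Trajectory(times=np.array([0.0, 1.0, 2.0]),
                    states=np.ones((3, 6)))
    assert np.allclose(percent_change_curve(tr).states, 0.0)

    tr2 = Trajectory(times=np.array([0.0, 1.0]),
                     states=np.vstack([np.ones(6), 2 * np.ones(6)]))
    assert np.allclose(percent_change_curve(tr2).states[1], 100.0)

    # pHL-like kinetics: blood compartment rises before decaying
    phl = dict(ref_theta)
    phl["F_out"] *= 44
    phl["f_in"] /= 5
    times = np.linspace(0, 730, 200)
    pc = percent_change_curve(closed_form(KineticParameters(**phl), times))
    b = pc.compartment("B_bl")
    i_max = int(np.argmax(b))
    assert 0 < i_max < len(b) - 1 and b[i_max] > 0

    bad = Trajectory(times=np.array([0.0, 1.0]),
                     states=np.vstack([np.array([0, 1, 1, 1, 1, 1.0]),
                                       np.ones(6)]))
    with pytest.raises(ValidationError, match="B_LN"):
        percent_change_curve(bad)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_positivity_and_monotone_ln_kinetics(seed):
    rng = np.random.default_rng(seed)
    p = KineticParameters.from_dict(random_valid_params(rng))
    times = np.linspace(0, 730, 40)
    traj = closed_form(p, times)
    assert np.all(traj.states >= -1e-12)
    b_ln = traj.compartment("B_LN")
    diffs = np.diff(b_ln)
    if b_ln[0] > p.f_in / p.F_out:
        assert np.all(diffs <= 1e-12)
    else:
        assert np.all(diffs >= -1e-12)


def test_superposition_of_initial_condition(rng):
    """x(t; a*x0) - x_forced(t) scales linearly with a for the homogeneous
    part (linear system)."""
    p = KineticParameters.from_dict(random_valid_params(rng))
    times = np.linspace(0, 300, 7)
    x0 = rng.uniform(0.5, 2.0, 6)
    forced = closed_form(p, times, initial_state=np.zeros(6)).states
    full = closed_form(p, times, initial_state=x0).states
    scaled = closed_form(p, times, initial_state=3.0 * x0).states
    assert np.allclose(scaled - forced, 3.0 * (full - forced),
                       rtol=1e-9, atol=1e-10)


def test_parameter_validation_errors():
    with pytest.raises(ValidationError):
        KineticParameters(f_in=np.nan, F_out=0.1, mu_B=0.1, kappa=1,
                          mu_4=0.1, mu_8=0.1, mu_NK=0.1, mu_reg=0.1)
    with pytest.raises(ValidationError):
        KineticParameters(f_in=0.0, F_out=-0.1, mu_B=0.1, kappa=1,
                          mu_4=0.1, mu_8=0.1, mu_NK=0.1, mu_reg=0.1)
    p = KineticParameters(f_in=0.0, F_out=0.1, mu_B=0.1, kappa=1,
                          mu_4=0.1, mu_8=0.1, mu_NK=0.1, mu_reg=0.1)
    with pytest.raises(ValidationError):
        simulate(p, np.array([1.0, 0.5]))


def test_vectorised_closed_form_matches_scalar(rng):
    times = np.linspace(0, 500, 9)
    thetas = np.stack([KineticParameters.from_dict(
        random_valid_params(rng)).to_array() for _ in range(5)])
    batch = closed_form_states(thetas, times)
    for i in range(5):
        single = closed_form(KineticParameters.from_array(thetas[i]), times)
        assert np.allclose(batch[i], single.states, rtol=1e-12)
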