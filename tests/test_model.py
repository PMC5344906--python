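"""Model equations: defaults, gating, currents, derivatives, Jacobian."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hbih import (
    ModelParameters,
    derivatives,
    ionic_currents,
    numeric_jacobian,
    steady_state_activation,
    temperature_factors,
)
from hbih import _kernels

from conftest import reference_rhs

# the published reference parameter set, frozen independently of the
# dataclass defaults
REFERENCE_PARAMETERS = {
    "C_m": 1.0,
    "g_d": 2.5, "g_r": 2.8, "g_sd": 0.21, "g_sr": 0.28, "g_l": 0.06, "g_h": 0.4,
    "V0_d": -25.0, "V0_r": -25.0, "V0_sd": -40.0, "V0_h": -85.0,
    "s_d": 0.25, "s_r": 0.25, "s_sd": 0.11, "s_h": -0.14,
    "tau_r": 2.0, "tau_sd": 10.0, "tau_sr": 35.0, "tau_h": 125.0,
    "E_d": 50.0, "E_sd": 50.0, "E_r": -90.0, "E_sr": -90.0,
    "E_l": -80.0, "E_h": -30.0,
    "kappa": 0.18, "eta": 0.014, "K_sr": 0.16,
}


def test_defaults_match_reference_table():
    p = ModelParameters()
    for key, value in REFERENCE_PARAMETERS.items():
        assert getattr(p, key) == value, key


def test_json_round_trip_preserves_defaults(tmp_path):
    p = ModelParameters()
    path = tmp_path / "params.json"
    p.to_json(path)
    assert ModelParameters.from_json(path) == p


def test_unknown_json_keys_rejected():
    data = json.loads(ModelParameters().to_json())
    data["g_bogus"] = 1.0
    with pytest.raises(KeyError, match="g_bogus"):
        ModelParameters.from_dict(data)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        ModelParameters(C_m=0.0)
    with pytest.raises(ValueError):
        ModelParameters(tau_h=-1.0)
    with pytest.raises(ValueError):
        ModelParameters(g_sd=-0.1)


@pytest.mark.parametrize(
    "T, rho, phi",
    [
        (25.0, 1.0, 1.0),
        (35.0, 1.3, 3.0),
        (36.0, 1.3**1.1, 3.0**1.1),
    ],
)
def test_temperature_factors(T, rho, phi):
    r, f = temperature_factors(T)
    assert r == pytest.approx(rho, rel=1e-12)
    assert f == pytest.approx(phi, rel=1e-12)


@pytest.mark.parametrize(
    "V, s, V0, expected",
    [
        (-25.0, 0.25, -25.0, 0.5),
        (-85.0, -0.14, -85.0, 0.5),
        (-13.0, 0.25, -25.0, 1.0 / (1.0 + np.exp(-3.0))),
    ],
)
def test_steady_state_activation_values(V, s, V0, expected):
    assert steady_state_activation(V, s, V0) == pytest.approx(expected, rel=1e-12)


def test_steady_state_activation_monotone():
    V = np.linspace(-100, 40, 500)
    assert np.all(np.diff(steady_state_activation(V, 0.25, -25.0)) > 0)
    assert np.all(np.diff(steady_state_activation(V, -0.14, -85.0)) < 0)


def test_all_conductances_zero_gives_zero_currents():
    p = ModelParameters(g_d=0, g_r=0, g_sd=0, g_sr=0, g_l=0, g_h=0)
    cur = ionic_currents([-50.0, 0.3, 0.3, 0.3, 0.3], p)
    assert cur.total == 0.0


def test_ih_vanishes_at_its_reversal():
    p = ModelParameters()
    cur = ionic_currents([p.E_h, 0.1, 0.2, 0.3, 0.9], p)
    assert cur.I_h == 0.0


def test_sr_current_saturable_gate_value():
    # direct evaluation of the saturable calcium gate a^2/(a^2 + K)
    p = ModelParameters(T=25.0, K_sr=0.42)
    cur = ionic_currents([-60.0, 0.0, 0.0, 0.42, 0.0], p)
    gate = 0.42**2 / (0.42**2 + 0.42)
    assert cur.I_sr == pytest.approx(0.28 * gate * 30.0, rel=1e-12)


def test_total_is_sum_of_currents():
    p = ModelParameters(T=31.0)
    cur = ionic_currents([-48.0, 0.2, 0.4, 0.3, 0.1], p)
    assert cur.total == pytest.approx(
        cur.I_d + cur.I_r + cur.I_sd + cur.I_sr + cur.I_h + cur.I_l, rel=1e-14
    )


@pytest.mark.parametrize("slow_only", [False, True])
def test_derivatives_match_reference_equations(slow_only):
    rng = np.random.default_rng(42)
    p = ModelParameters(T=33.5)
    for _ in range(50):
        y = np.array([rng.uniform(-90, 20), rng.uniform(0, 1), rng.uniform(0, 1),
                      rng.uniform(0, 1.5), rng.uniform(0, 1)])
        expected = reference_rhs(y, p, slow_only=slow_only)
        np.testing.assert_allclose(
            derivatives(y, p, slow_only=slow_only), expected, rtol=1e-12, atol=1e-14
        )


def test_compiled_rhs_matches_reference_equations():
    rng = np.random.default_rng(3)
    for slow_only in (False, True):
        p = ModelParameters(T=36.0)
        pv = _kernels.pack_params(p, slow_only=slow_only)
        for _ in range(20):
            y = np.concatenate([[rng.uniform(-90, 20)], rng.uniform(0, 1, 4)])
            if slow_only:
                y[1] = 0.0
            np.testing.assert_allclose(
                _kernels.rhs_vector(y, pv),
                reference_rhs(y, p, slow_only=slow_only),
                rtol=1e-12,
                atol=1e-14,
            )


def test_slow_subsystem_consistent_with_zeroed_fast_conductances():
    rng = np.random.default_rng(7)
    p = ModelParameters(T=36.0)
    p_zeroed = p.replace(g_d=0.0, g_r=0.0)
    for _ in range(20):
        y = np.concatenate([[rng.uniform(-90, 20)], rng.uniform(0, 1, 4)])
        y[1] = 0.0
        full = derivatives(y, p_zeroed)
        slow = derivatives(y, p, slow_only=True)
        # the four slow components agree exactly; a_r's own relaxation is
        # decoupled (g_r = 0) and clamped in the slow subsystem
        np.testing.assert_allclose(full[[0, 2, 3, 4]], slow[[0, 2, 3, 4]],
                                   rtol=0, atol=1e-15)
        assert slow[1] == 0.0


def test_nonfinite_state_rejected():
    with pytest.raises(FloatingPointError):
        derivatives([np.nan, 0.1, 0.1, 0.1, 0.1], ModelParameters())


@given(
    V=st.floats(-90, 20),
    a_sr=st.floats(0, 1.5),
    others=st.tuples(*[st.floats(0, 1)] * 2),
    T=st.floats(5, 40),
)
def test_gate_derivatives_point_inward_at_faces(V, a_sr, others, T):
    """The gating ODEs relax toward values in (0, 1): at a face a_i = 0
    the derivative is positive, at a_i = 1 negative, so [0,1] is
    forward-invariant for a_r, a_sd, a_h."""
    p = ModelParameters(T=T)
    for i in (1, 2, 4):  # a_r, a_sd, a_h
        y = np.array([V, others[0], others[1], a_sr, others[0]])
        y[i] = 0.0
        assert derivatives(y, p)[i] > 0
        y[i] = 1.0
        assert derivatives(y, p)[i] < 0


def test_calcium_proxy_nonnegative_while_isd_inward():
    # at a_sr = 0 with V below E_sd, -eta * I_sd >= 0 so da_sr/dt >= 0
    p = ModelParameters(T=36.0)
    for V in (-90.0, -60.0, -20.0, 40.0):
        y = np.array([V, 0.2, 0.5, 0.0, 0.1])
        d = derivatives(y, p)
        if V <= p.E_sd:
            assert d[3] >= 0


def test_jacobian_linear_relaxation_entries_exact():
    p = ModelParameters(T=30.0)
    y = np.array([-55.0, 0.3, 0.4, 0.2, 0.1])
    J = numeric_jacobian(y, p)
    _, phi = temperature_factors(p.T)
    assert J[2, 2] == pytest.approx(-phi / p.tau_sd, rel=1e-9)
    assert J[4, 4] == pytest.approx(-phi / p.tau_h, rel=1e-9)
    assert J[1, 1] == pytest.approx(-phi / p.tau_r, rel=1e-9)
    # gates do not feed back on each other directly
    assert J[1, 2] == pytest.approx(0.0, abs=1e-12)
    assert J[4, 2] == pytest.approx(0.0, abs=1e-12)


def test_jacobian_leak_only_voltage_row():
    p = ModelParameters(g_d=0, g_r=0, g_sd=0, g_sr=0, g_h=0, T=25.0)
    y = np.array([-55.0, 0.3, 0.4, 0.2, 0.1])
    J = numeric_jacobian(y, p)
    assert J[0, 0] == pytest.approx(-p.g_l / p.C_m, rel=1e-9)
    np.testing.assert_allclose(J[0, 1:], 0.0, atol=1e-9)
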