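import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    from hbih import ModelParameters

    return ModelParameters()


def reference_rhs(state, p, slow_only=False):
    """Independent reference implementation of the model equations,
    written directly from the published formulas (used as the oracle for
    the packaged vector field)."""
    V, a_r, a_sd, a_sr, a_h = [float(v) for v in state]
    if slow_only:
        a_r = 0.0
        g_d, g_r = 0.0, 0.0
    else:
        g_d, g_r = p.g_d, p.g_r
    rho = 1.3 ** ((p.T - 25.0) / 10.0)
    phi = 3.0 ** ((p.T - 25.0) / 10.0)

    def inf(V, s, V0):
        return 1.0 / (1.0 + np.exp(-s * (V - V0)))

    I_d = rho * g_d * inf(V, p.s_d, p.V0_d) * (V - p.E_d)
    I_r = rho * g_r * a_r * (V - p.E_r)
    I_sd = rho * p.g_sd * a_sd * (V - p.E_sd)
    I_sr = rho * p.g_sr * (a_sr**2 / (a_sr**2 + p.K_sr)) * (V - p.E_sr)
    I_h = rho * p.g_h * a_h * (V - p.E_h)
    I_l = rho * p.g_l * (V - p.E_l)
    dV = -(I_d + I_r + I_sd + I_sr + I_h + I_l) / p.C_m
    da_r = 0.0 if slow_only else phi * (inf(V, p.s_r, p.V0_r) - a_r) / p.tau_r
    da_sd = phi * (inf(V, p.s_sd, p.V0_sd) - a_sd) / p.tau_sd
    da_sr = phi * (-p.eta * I_sd - p.kappa * a_sr) / p.tau_sr
    da_h = phi * (inf(V, p.s_h, p.V0_h) - a_h) / p.tau_h
    return np.array([dV, da_r, da_sd, da_sr, da_h])
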