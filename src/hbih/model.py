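"""Equations of the HB+Ih conductance-based neuron model.

The model describes a bursting neuron inspired by mammalian cold
thermoreceptors.  Two fast currents (a depolarizing Na_V-like current I_d
and a repolarizing K_dr-like current I_r) generate action potentials, while
three slow currents drive a subthreshold oscillation: a persistent
sodium/calcium current I_sd, a calcium-activated potassium current I_sr
(whose gating variable a_sr tracks intracellular calcium), and a
hyperpolarization-activated cation current I_h (HCN-like, activating as the
membrane hyperpolarizes).  A temperature-scaled leak I_l closes the circuit.

State vector (in this fixed order throughout the package)::

    y = (V, a_r, a_sd, a_sr, a_h)

with V the membrane voltage in mV and the remaining entries dimensionless
activation variables.  The fast activation a_d is instantaneous and is
evaluated algebraically from its steady-state curve inside the right-hand
side; it is never integrated.

Temperature enters through two Q10-style factors: ``rho`` scales all
conductances (Q10 = 1.3) and ``phi`` scales all gating kinetics (Q10 = 3),
both referenced to 25 degrees C.

The "slow subsystem" is the same vector field with g_d = g_r = 0 and a_r
pinned at 0; it is effectively four-dimensional and still oscillates (and,
for some parameters, is chaotic).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParameters",
    "CurrentBreakdown",
    "STATE_LABELS",
    "temperature_factors",
    "steady_state_activation",
    "ionic_currents",
    "derivatives",
    "numeric_jacobian",
    "SLOW_STATE_INDICES",
]

#: names of the state-vector entries, in order
STATE_LABELS = ("V", "a_r", "a_sd", "a_sr", "a_h")

#: indices of the state entries that remain dynamical in the slow subsystem
SLOW_STATE_INDICES = (0, 2, 3, 4)


@dataclass
class ModelParameters:
    """One simulation condition: all model constants plus temperature.

    Defaults are the published reference parameter set of the HB+Ih model.
    Units: capacitance uF/cm^2, conductances mS/cm^2, voltages mV, time
    constants ms, slopes 1/mV, ``eta`` cm^2/uA; ``kappa`` and ``K_sr`` are
    dimensionless; ``T`` is in degrees C.

    ``K_sr`` is the half-saturation constant of the calcium-dependent
    activation term a_sr^2 / (a_sr^2 + K_sr) of I_sr (the published form
    uses 0.4^2 = 0.16); it is exposed as a parameter rather than
    hard-wired so that the saturation behaviour can be explored.
    """

    C_m: float = 1.0
    g_d: float = 2.5
    g_r: float = 2.8
    g_sd: float = 0.21
    g_sr: float = 0.28
    g_l: float = 0.06
    g_h: float = 0.4
    V0_d: float = -25.0
    V0_r: float = -25.0
    V0_sd: float = -40.0
    V0_h: float = -85.0
    s_d: float = 0.25
    s_r: float = 0.25
    s_sd: float = 0.11
    s_h: float = -0.14
    tau_r: float = 2.0
    tau_sd: float = 10.0
    tau_sr: float = 35.0
    tau_h: float = 125.0
    E_d: float = 50.0
    E_sd: float = 50.0
    E_r: float = -90.0
    E_sr: float = -90.0
    E_l: float = -80.0
    E_h: float = -30.0
    kappa: float = 0.18
    eta: float = 0.014
    K_sr: float = 0.16
    T: float = 36.0
    spike_threshold: float = -15.0

    def __post_init__(self) -> None:
        if not self.C_m > 0:
            raise ValueError("C_m must be positive")
        for name in ("tau_r", "tau_sd", "tau_sr", "tau_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_d", "g_r", "g_sd", "g_sr", "g_l", "g_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.K_sr > 0:
            raise ValueError("K_sr must be positive")
        if not math.isfinite(self.T):
            raise ValueError("T must be finite")

    # -- construction helpers -------------------------------------------------

    def replace(self, **overrides: float) -> "ModelParameters":
        """Copy with some fields overridden (unknown names rejected)."""
        return dataclasses.replace(self, **overrides)

    def slow(self) -> "ModelParameters":
        """The slow-subsystem condition: fast conductances removed."""
        return self.replace(g_d=0.0, g_r=0.0)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParameters":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class CurrentBreakdown:
    """Instantaneous membrane current densities in uA/cm^2 (outward > 0
    for the repolarizing currents by the sign of their driving force)."""

    I_d: float
    I_r: float
    I_sd: float
    I_sr: float
    I_h: float
    I_l: float

    @property
    def total(self) -> float:
        return self.I_d + self.I_r + self.I_sd + self.I_sr + self.I_h + self.I_l


def temperature_factors(T: float) -> tuple[float, float]:
    """Q10 scale factors ``(rho, phi)`` at temperature ``T`` (degrees C).

    ``rho = 1.3**((T - 25) / 10)`` scales conductances, and
    ``phi = 3**((T - 25) / 10)`` scales gating kinetics.  Both equal 1 at
    the 25 degrees C reference temperature.
    """
    if not math.isfinite(T):
        raise ValueError("T must be finite")
    x = (T - 25.0) / 10.0
    return 1.3**x, 3.0**x


def steady_state_activation(V, s: float, V0: float):
    """Boltzmann steady-state activation ``1 / (1 + exp(-s (V - V0)))``.

    Monotone increasing in ``V`` for s > 0 (activation gates) and
    decreasing for s < 0 (the h-gate); equals 0.5 at ``V = V0``.
    Accepts scalar or array ``V``.
    """
    return 1.0 / (1.0 + np.exp(-s * (np.asarray(V, dtype=float) - V0)))


def _sr_gate(a_sr, K_sr: float):
    a2 = np.square(a_sr)
    return a2 / (a2 + K_sr)


def ionic_currents(state, params: ModelParameters) -> CurrentBreakdown:
    """Evaluate every membrane current density at a state.

    Each current is ``rho(T) * g * gate * (V - E)``; the leak gate is
    identically 1 (but the leak is still temperature-scaled by ``rho``),
    the fast depolarizing gate is the instantaneous ``a_d_inf(V)``, and the
    I_sr gate is the saturable calcium term ``a_sr^2 / (a_sr^2 + K_sr)``.
    """
    V, a_r, a_sd, a_sr, a_h = (float(x) for x in state)
    p = params
    rho, _ = temperature_factors(p.T)
    a_d = float(steady_state_activation(V, p.s_d, p.V0_d))
    return CurrentBreakdown(
        I_d=rho * p.g_d * a_d * (V - p.E_d),
        I_r=rho * p.g_r * a_r * (V - p.E_r),
        I_sd=rho * p.g_sd * a_sd * (V - p.E_sd),
        I_sr=rho * p.g_sr * float(_sr_gate(a_sr, p.K_sr)) * (V - p.E_sr),
        I_h=rho * p.g_h * a_h * (V - p.E_h),
        I_l=rho * p.g_l * (V - p.E_l),
    )


def derivatives(state, params: ModelParameters, slow_only: bool = False) -> np.ndarray:
    """Time derivative of the state vector (length 5, units per ms).

    With ``slow_only`` the fast conductances are zeroed, a_r is treated as
    pinned at 0 and its derivative reported as 0 — the four remaining
    entries are exactly the slow-subsystem vector field.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (5,):
        raise ValueError("state must have 5 entries (V, a_r, a_sd, a_sr, a_h)")
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state: {y}")
    p = params.slow() if slow_only else params
    V, a_r, a_sd, a_sr, a_h = y
    if slow_only:
        a_r = 0.0
    rho, phi = temperature_factors(p.T)
    cur = ionic_currents((V, a_r, a_sd, a_sr, a_h), p)
    dy = np.empty(5)
    dy[0] = -cur.total / p.C_m
    dy[1] = 0.0 if slow_only else phi * (
        float(steady_state_activation(V, p.s_r, p.V0_r)) - a_r) / p.tau_r
    dy[2] = phi * (float(steady_state_activation(V, p.s_sd, p.V0_sd)) - a_sd) / p.tau_sd
    dy[3] = phi * (-p.eta * cur.I_sd - p.kappa * a_sr) / p.tau_sr
    dy[4] = phi * (float(steady_state_activation(V, p.s_h, p.V0_h)) - a_h) / p.tau_h
    return dy


def numeric_jacobian(
    state, params: ModelParameters, slow_only: bool = False, rel_step: float = 1e-6
) -> np.ndarray:
    """Jacobian of the vector field by central finite differences.

    Returns a 5x5 matrix for the full system or a 4x4 matrix over
    (V, a_sd, a_sr, a_h) for the slow subsystem.  The step for each
    coordinate is ``rel_step * max(1, |y_i|)``, which keeps the linear
    relaxation entries exact to rounding.
    """
    y0 = np.asarray(state, dtype=float).copy()
    idx = list(SLOW_STATE_INDICES) if slow_only else list(range(5))
    n = len(idx)
    J = np.empty((n, n))
    for col, j in enumerate(idx):
        h = rel_step * max(1.0, abs(y0[j]))
        yp = y0.copy()
        ym = y0.copy()
        yp[j] += h
        ym[j] -= h
        dp = derivatives(yp, params, slow_only=slow_only)
        dm = derivatives(ym, params, slow_only=slow_only)
        J[:, col] = (dp[idx] - dm[idx]) / (2.0 * h)
    return J
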