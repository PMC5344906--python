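"""Surrogate series and reference ODE systems with known behaviour.

These are first-class fixtures for exercising the chaos estimators:
interval series whose Lyapunov exponent is known (constant and periodic
series: none; logistic-map-driven series: ln 2 per step at r = 4), and
small ODE systems with known maximal Lyapunov exponents (a linear system:
exactly its rate; the Lorenz system at the classic parameters: ~0.9056
per unit time).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "constant_isi",
    "periodic_isi",
    "logistic_map_series",
    "logistic_isi",
    "linear_rhs",
    "lorenz_rhs",
    "LORENZ_MLE",
    "LOGISTIC_LE",
]

#: maximal Lyapunov exponent of the Lorenz system at (sigma, rho, beta) =
#: (10, 28, 8/3), per unit time (literature value)
LORENZ_MLE = 0.9056

#: Lyapunov exponent of the fully chaotic logistic map x -> 4x(1-x): ln 2
LOGISTIC_LE = float(np.log(2.0))


def constant_isi(n: int, value: float = 100.0) -> np.ndarray:
    """A perfectly regular interval series."""
    return np.full(n, float(value))


def periodic_isi(n: int, pattern=(50.0, 150.0)) -> np.ndarray:
    """A period-k interval series repeating ``pattern``."""
    reps = int(np.ceil(n / len(pattern)))
    return np.tile(np.asarray(pattern, dtype=float), reps)[:n]


def logistic_map_series(n: int, r: float = 4.0, seed: int = 0,
                        transient: int = 100) -> np.ndarray:
    """Iterates of the logistic map ``x -> r x (1 - x)`` after a transient."""
    rng = np.random.default_rng(seed)
    x = float(rng.uniform(0.1, 0.9))
    for _ in range(transient):
        x = r * x * (1.0 - x)
    out = np.empty(n)
    for i in range(n):
        x = r * x * (1.0 - x)
        out[i] = x
    return out


def logistic_isi(n: int, lo: float = 50.0, hi: float = 150.0, seed: int = 0) -> np.ndarray:
    """Logistic-map iterates mapped affinely onto a positive ISI range.

    The affine map leaves the Lyapunov exponent unchanged: ln 2 per step.
    """
    return lo + (hi - lo) * logistic_map_series(n, r=4.0, seed=seed)


def linear_rhs(lam: float):
    """Right-hand side of ``dx/dt = lam * x`` (MLE exactly ``lam``)."""

    def rhs(y):
        return lam * np.asarray(y, dtype=float)

    return rhs


def lorenz_rhs(sigma: float = 10.0, rho: float = 28.0, beta: float = 8.0 / 3.0):
    """Right-hand side of the Lorenz system at the classic parameters."""

    def rhs(y):
        x, yy, z = y
        return np.array(
            [sigma * (yy - x), x * (rho - z) - yy, x * yy - beta * z]
        )

    return rhs
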