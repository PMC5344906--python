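"""Chaos estimators against systems with known exponents."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hbih import (
    EmbeddingConfig,
    benettin_mle,
    binarize,
    embed,
    isi_lyapunov,
    lempel_ziv,
)
from hbih.surrogates import (
    LOGISTIC_LE,
    constant_isi,
    linear_rhs,
    logistic_isi,
    lorenz_rhs,
    periodic_isi,
)


def tangent_linear_mle(rhs, jac, y0, dt, total_time, renorm_interval,
                       equilibration=0.0, discard_fraction=0.1):
    """Independent MLE oracle: propagate a tangent vector with the
    Jacobian along the trajectory and accumulate its growth rate."""

    n = len(y0)

    def aug_rhs(z):
        y, v = z[:n], z[n:]
        return np.concatenate([rhs(y), jac(y) @ v])

    def rk4(f, z):
        k1 = f(z)
        k2 = f(z + 0.5 * dt * k1)
        k3 = f(z + 0.5 * dt * k2)
        k4 = f(z + dt * k3)
        return z + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    y = np.asarray(y0, dtype=float).copy()
    for _ in range(int(round(equilibration / dt))):
        y = rk4(rhs, y)
    v = np.ones(n) / np.sqrt(n)
    steps = int(round(renorm_interval / dt))
    n_intervals = int(round(total_time / (steps * dt)))
    logs = []
    for _ in range(n_intervals):
        z = np.concatenate([y, v])
        for _ in range(steps):
            z = rk4(aug_rhs, z)
        y, v = z[:n], z[n:]
        norm = np.linalg.norm(v)
        logs.append(np.log(norm))
        v /= norm
    logs = np.array(logs)
    kept = logs[int(discard_fraction * len(logs)):]
    return kept.sum() / (len(kept) * steps * dt)


def lorenz_jacobian(sigma=10.0, rho=28.0, beta=8.0 / 3.0):
    def jac(y):
        x, yy, z = y
        return np.array(
            [[-sigma, sigma, 0.0], [rho - z, -1.0, -x], [yy, x, -beta]]
        )

    return jac


@pytest.mark.parametrize("lam, total", [(-1.0, 200.0), (-0.1, 200.0), (0.1, 100.0)])
def test_mle_matches_analytic_rate_on_linear_systems(lam, total):
    res = benettin_mle(linear_rhs(lam), [1.0], dt=0.01, total_time=total,
                       renorm_interval=1.0, seed=1)
    assert res.value == pytest.approx(lam, abs=1e-3)


def test_mle_matches_tangent_linear_oracle_on_lorenz():
    """Two independent estimators (two-trajectory renormalization vs
    Jacobian propagation) must agree on the Lorenz exponent, and both
    must sit near the literature value ~0.906."""
    kwargs = dict(dt=0.005, total_time=600.0, renorm_interval=0.5,
                  equilibration=20.0)
    two_traj = benettin_mle(lorenz_rhs(), [1.0, 1.0, 1.0], seed=1, **kwargs).value
    oracle = tangent_linear_mle(lorenz_rhs(), lorenz_jacobian(),
                                [1.0, 1.0, 1.0], **kwargs)
    assert two_traj == pytest.approx(oracle, abs=0.02)
    assert two_traj == pytest.approx(0.906, abs=0.05)


def test_embed_examples():
    pts = embed([1.0, 2.0, 3.0, 4.0], 2)
    np.testing.assert_array_equal(pts, [[1, 2], [2, 3], [3, 4]])
    series = np.arange(50.0)
    for m in (2, 5, 11):
        assert len(embed(series, m)) == len(series) - m + 1
    with pytest.raises(ValueError):
        embed([1.0, 2.0], 5)


def test_constant_embedding_is_degenerate():
    pts = embed(constant_isi(20), 3)
    assert np.ptp(pts) == 0.0


def test_isi_lyapunov_recovers_logistic_map_exponent():
    """The fully chaotic logistic map has exponent ln 2 per step; a 1-D
    map is reconstructed faithfully at low embedding dimension."""
    series = logistic_isi(20_000, seed=1)
    res = isi_lyapunov(series, EmbeddingConfig(dims=(3, 4, 5)))
    assert res.significant
    assert res.value == pytest.approx(LOGISTIC_LE, rel=0.10)


@pytest.mark.parametrize(
    "series",
    [
        constant_isi(1000),
        periodic_isi(1000, (50.0, 150.0)),
        periodic_isi(1000, (50.0, 80.0, 120.0)),
        periodic_isi(1000, (50.0, 80.0, 120.0, 200.0)),
    ],
    ids=["constant", "period2", "period3", "period4"],
)
def test_periodic_series_not_significant(series):
    res = isi_lyapunov(series)
    assert not res.significant
    assert res.value == 0.0


def test_binarize_examples():
    word, bw = binarize([5.0, 15.0], duration=20.0, bin_width=4.0)
    np.testing.assert_array_equal(word, [0, 1, 0, 1, 0])
    assert bw == 4.0
    # ones count equals spike count; auto width = half the minimum ISI
    rng = np.random.default_rng(1)
    spikes = np.cumsum(rng.uniform(10, 50, 100))
    word, bw = binarize(spikes, duration=float(spikes[-1] + 1))
    assert word.sum() == len(spikes)
    assert bw == pytest.approx(0.5 * np.diff(spikes).min())
    # explicit bin on an empty train
    word, _ = binarize([], duration=10.0, bin_width=2.0)
    np.testing.assert_array_equal(word, np.zeros(5))


def test_binarize_rejects_bin_width_at_or_above_min_isi():
    with pytest.raises(ValueError, match="minimum ISI"):
        binarize([5.0, 15.0], duration=20.0, bin_width=10.0)


def test_lempel_ziv_hand_traced_words():
    assert lempel_ziv(np.zeros(100)).c_n == 2
    assert lempel_ziv(np.tile([0, 1], 50)).c_n == 3


def test_lempel_ziv_random_word_normalizes_to_one():
    rng = np.random.default_rng(7)
    word = rng.integers(0, 2, 100_000)
    assert 0.9 <= lempel_ziv(word).normalized <= 1.1


@given(st.integers(0, 2**32 - 1), st.integers(50, 400))
def test_lempel_ziv_relabel_invariance(seed, n):
    rng = np.random.default_rng(seed)
    word = rng.integers(0, 2, n)
    assert abs(lempel_ziv(word).c_n - lempel_ziv(1 - word).c_n) <= 1


def test_trajectory_mle_agrees_with_isi_le_on_transect():
    """The two chaos measures classify the same points as chaotic on a
    20-point g_sd transect at g_h = 0.2 (>= 90 % agreement; the odd
    disagreement sits at regime boundaries where both are marginal)."""
    from hbih import ModelParameters, mle_ode, simulate

    agree = 0
    points = np.linspace(0.19, 0.2375, 20)
    for i, g_sd in enumerate(points):
        p = ModelParameters(T=36.0, g_h=0.2, g_sd=float(g_sd))
        traj = simulate(p, duration=200_000.0, record_stride=400)
        le = isi_lyapunov(np.diff(traj.crossing_times))
        mle = mle_ode(p, total_time=100_000.0, seed=i)
        chaotic_mle = mle.value > 1e-4
        chaotic_le = le.significant and le.value > 0
        agree += chaotic_mle == chaotic_le
    assert agree / len(points) >= 0.9


def test_lempel_ziv_monotone_in_prefix_length():
    rng = np.random.default_rng(11)
    word = rng.integers(0, 2, 2000)
    counts = [lempel_ziv(word[:n]).c_n for n in (100, 500, 1000, 2000)]
    assert all(a <= b for a, b in zip(counts, counts[1:]))
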