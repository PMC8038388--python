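"""T2* fitting: exact recovery, degeneracy handling, and oracle equivalence.

The independent oracle is a dense 1D grid search over T2* with the
amplitude profiled out in closed form (for fixed T2* the optimal S0 of the
least-squares objective is linear), minimizing the same sum-of-squares the
Levenberg-Marquardt fit minimizes.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxypd.phantom import default_phantom, make_echo_series, rician
from oxypd.relaxometry import (EchoSeries, fit_volume, fit_voxel,
                               loglinear_init)

TE8 = np.linspace(5.0, 75.0, 8)


def grid_search_t2star(signals: np.ndarray, te: np.ndarray,
                       grid: np.ndarray) -> np.ndarray:
    """Profiled exhaustive search: argmin_T2 min_S0 sum (y - S0 e^{-TE/T2})^2."""
    signals = np.atleast_2d(signals)
    basis = np.exp(-te[None, :] / grid[:, None])          # (G, E)
    ey = basis @ signals.T                                 # (G, V)
    ee = (basis ** 2).sum(axis=1)[:, None]                 # (G, 1)
    ssr = (signals ** 2).sum(axis=1)[None, :] - ey ** 2 / ee
    return grid[np.argmin(ssr, axis=0)]


def grid_search_objective(signal: np.ndarray, te: np.ndarray,
                          grid: np.ndarray) -> float:
    basis = np.exp(-te[None, :] / grid[:, None])
    ey = basis @ signal
    ee = (basis ** 2).sum(axis=1)
    return float(((signal ** 2).sum() - ey ** 2 / ee).min())


def test_noiseless_eight_echo_recovery():
    signal = 1000.0 * np.exp(-TE8 / 35.0)
    s0, t2, rmse, valid = fit_voxel(signal, TE8)
    assert valid
    assert s0 == pytest.approx(1000.0, rel=1e-6)
    assert t2 == pytest.approx(35.0, rel=1e-6)
    assert rmse < 1e-6


@settings(max_examples=40, deadline=None, derandomize=True)
@given(s0=st.floats(1.0, 1e5), t2=st.floats(2.0, 400.0))
def test_noiseless_identifiability_property(s0, t2):
    signal = s0 * np.exp(-TE8 / t2)
    s0_hat, t2_hat, _, valid = fit_voxel(signal, TE8)
    assert valid
    assert s0_hat == pytest.approx(s0, rel=1e-5)
    assert t2_hat == pytest.approx(t2, rel=1e-5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(1e-3, 1e3))
def test_scale_equivariance(scale):
    """Scaling all signals by c scales S0 by c and leaves T2* unchanged."""
    rng = np.random.default_rng(3)
    signal = 800.0 * np.exp(-TE8 / 42.0) + rng.normal(0, 5, TE8.size)
    signal = np.clip(signal, 1e-6, None)
    s0_a, t2_a, _, _ = fit_voxel(signal, TE8)
    s0_b, t2_b, _, _ = fit_voxel(signal * scale, TE8)
    assert t2_b == pytest.approx(t2_a, rel=1e-6)
    assert s0_b == pytest.approx(s0_a * scale, rel=1e-6)


def test_all_zero_signal_is_invalid_not_exception():
    s0, t2, rmse, valid = fit_voxel(np.zeros(8), TE8)
    assert not valid and np.isnan(t2)


def test_fit_rejects_malformed_echo_axes():
    with pytest.raises(ValueError):
        fit_voxel(np.ones(8), TE8[::-1])
    with pytest.raises(ValueError):
        fit_voxel(np.ones(7), TE8)


def test_loglinear_two_point_exact():
    te = np.array([5.0, 75.0])
    s = 1000.0 * np.exp(-te / 35.0)
    s0_i, t2_i = loglinear_init(s, te)
    assert t2_i == pytest.approx(35.0, rel=1e-12)
    assert s0_i == pytest.approx(1000.0, rel=1e-12)


def test_loglinear_excludes_nonpositive_samples():
    te = np.array([5.0, 15.0, 25.0, 35.0])
    s = 1000.0 * np.exp(-te / 35.0)
    s_bad = s.copy()
    s_bad[2] = -4.0  # excluded from log fit; remaining 3 points still exact
    s0_i, t2_i = loglinear_init(s_bad, te)
    assert t2_i == pytest.approx(35.0, rel=1e-9)
    assert loglinear_init(np.array([5.0, 0.0, -1.0, 0.0]), te) is None


def test_loglinear_init_equals_lm_solution_on_noiseless_decay():
    signal = 1000.0 * np.exp(-TE8 / 35.0)
    s0_i, t2_i = loglinear_init(signal, TE8)
    s0_f, t2_f, _, _ = fit_voxel(signal, TE8)
    assert t2_i == pytest.approx(t2_f, abs=1e-6)
    assert s0_i == pytest.approx(s0_f, abs=1e-4)


def test_lm_residual_never_exceeds_init_residual():
    rng = np.random.default_rng(4)
    for _ in range(50):
        t2 = rng.uniform(10, 100)
        signal = rician(1000.0 * np.exp(-TE8 / t2), 25.0, rng)
        init = loglinear_init(signal, TE8)
        if init is None:
            continue
        s0_i, t2_i = init
        rmse_init = np.sqrt(np.mean((s0_i * np.exp(-TE8 / t2_i) - signal) ** 2))
        _, _, rmse_lm, valid = fit_voxel(signal, TE8)
        if valid:
            assert rmse_lm <= rmse_init + 1e-9


def test_lm_objective_not_worse_than_grid_oracle():
    """On 100 noisy voxels the LM objective is <= the dense-grid optimum."""
    rng = np.random.default_rng(5)
    grid = np.arange(1.0, 200.0, 0.05)
    for _ in range(100):
        signal = rician(1000.0 * np.exp(-TE8 / rng.uniform(15, 80)), 30.0, rng)
        s0, t2, rmse, valid = fit_voxel(signal, TE8)
        assert valid
        lm_obj = rmse ** 2 * TE8.size
        assert lm_obj <= grid_search_objective(signal, TE8, grid) + 1e-6


def test_noisy_median_matches_grid_oracle():
    """Median fitted T2* over 2000 noisy voxels agrees with the oracle's."""
    rng = np.random.default_rng(6)
    truth = 35.0
    signals = rician(np.tile(1000.0 * np.exp(-TE8 / truth), (2000, 1)), 40.0, rng)
    lm = np.array([fit_voxel(s, TE8)[1] for s in signals])
    grid = np.arange(5.0, 120.0, 0.25)
    oracle = grid_search_t2star(signals, TE8, grid)
    assert abs(np.median(lm[np.isfinite(lm)]) - np.median(oracle)) < 0.5


def test_fit_volume_recovers_two_class_phantom(small_phantom):
    series = make_echo_series(small_phantom, "pre")
    t2map = fit_volume(series, mask=small_phantom.object_mask)
    truth = small_phantom.t2star_field
    sel = t2map.valid
    assert sel.sum() == small_phantom.object_mask.sum()
    assert np.abs(t2map.t2star[sel] - truth[sel]).max() < 1e-4


def test_fit_volume_masking_and_shape_checks(small_phantom):
    series = make_echo_series(small_phantom, "pre")
    empty = fit_volume(series, mask=np.zeros(small_phantom.grid_shape, bool))
    assert empty.valid.sum() == 0
    with pytest.raises(ValueError):
        fit_volume(series, mask=np.zeros((2, 2, 2), bool))
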