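"""Reweighting, FES construction, block errors, state integration."""
import math

import numpy as np
import pytest

from petfes.constants import kbt
from petfes.errors import NoDataError, PetfesError
from petfes.fes_analysis import (CVTrajectory, FESGrid, FreeEnergyResult,
                                 StatePartition, block_error,
                                 convergence_series, delta_delta_f,
                                 discard_transient, frame_weights, make_fes,
                                 state_delta_f)

T = 300.0
KT = kbt(T)


class _FixedBias:
    """Stand-in bias with a closed-form potential (test oracle side)."""

    def __init__(self, fn, cv_names=("x",)):
        self.fn = fn
        self.cv_names = cv_names

    def evaluate_many(self, pts):
        return self.fn(np.atleast_2d(pts)[:, 0])


def _traj(x, **meta):
    return CVTrajectory.from_columns(metadata=meta, x=np.asarray(x, float))


# ---------------------------------------------------------------------------
# frame_weights
# ---------------------------------------------------------------------------

def test_uniform_weights_without_bias():
    traj = _traj(np.linspace(0, 1, 10))
    w = frame_weights(traj, None, T)
    assert np.allclose(w, 0.1)


def test_constant_bias_gives_uniform_weights():
    traj = _traj(np.linspace(0, 1, 50))
    w = frame_weights(traj, _FixedBias(lambda x: np.full_like(x, 37.0)), T)
    assert np.allclose(w, 1 / 50)
    assert w.sum() == pytest.approx(1.0)


def test_harmonic_bias_reweighting_recovers_gaussian_variance(rng):
    """Samples of the biased density exp(-x^2/2s^2 - V/kT) with
    V = k x^2 / 2 reweight back to the unbiased variance s^2."""
    k_spring, s2 = 2.0, 1.0
    s2_biased = 1.0 / (1.0 / s2 + k_spring / KT)
    x = rng.normal(0.0, math.sqrt(s2_biased), 300_000)
    traj = _traj(x)
    w = frame_weights(traj, _FixedBias(lambda v: 0.5 * k_spring * v ** 2), T)
    var = float(np.sum(w * x ** 2) - np.sum(w * x) ** 2)
    assert var == pytest.approx(s2, rel=0.02)


def test_missing_bias_column_raises():
    traj = _traj([1.0, 2.0])
    with pytest.raises(NoDataError):
        frame_weights(traj, _FixedBias(lambda v: v, cv_names=("y",)), T)


def test_discard_transient():
    traj = _traj(np.arange(10.0))
    w = np.full(10, 0.1)
    sub, w2 = discard_transient(traj, w, 0.2)
    assert sub.n_frames == 8
    assert w2.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# make_fes
# ---------------------------------------------------------------------------

def test_two_bin_fes_closed_form():
    traj = _traj([0.25, 0.75])
    w = np.array([0.9, 0.1])
    fes = make_fes(traj, w, ("x",), np.array([0.0, 0.5, 1.0]), T)
    assert fes.values.min() == 0.0
    assert fes.values[1] == pytest.approx(KT * math.log(9.0))
    assert fes.values[1] == pytest.approx(5.48, abs=0.06)


def test_uniform_samples_give_flat_fes(rng):
    traj = _traj(rng.random(200_000))
    w = np.full(traj.n_frames, 1.0 / traj.n_frames)
    fes = make_fes(traj, w, ("x",), np.linspace(0, 1, 21), T)
    assert np.nanmax(fes.values) < 0.15


def test_gaussian_fes_curvature(rng):
    """F(x) for N(0, s) samples is quadratic with curvature kBT/s^2."""
    s = 0.5
    traj = _traj(rng.normal(0, s, 400_000))
    w = np.full(traj.n_frames, 1.0 / traj.n_frames)
    fes = make_fes(traj, w, ("x",), np.linspace(-1.2, 1.2, 49), T)
    c = fes.centers(0)
    keep = fes.occupied & (np.abs(c) < 1.0)
    coeffs = np.polyfit(c[keep], fes.values[keep], 2)
    assert coeffs[0] == pytest.approx(0.5 * KT / s ** 2, rel=0.05)


def test_fes_zero_weight_is_error():
    traj = _traj([0.1, 0.2])
    with pytest.raises(NoDataError):
        make_fes(traj, np.zeros(2), ("x",), 5, T)


def test_fes_2d_and_minimum_shift(rng):
    traj = CVTrajectory.from_columns(x=rng.random(5000), y=rng.random(5000))
    w = np.full(5000, 1 / 5000)
    fes = make_fes(traj, w, ("x", "y"), 8, T)
    assert fes.values.shape == (8, 8)
    assert np.nanmin(fes.values) == 0.0


# ---------------------------------------------------------------------------
# block_error
# ---------------------------------------------------------------------------

def test_identical_blocks_zero_error():
    block = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)])
    x = np.tile(block, 4)
    traj = _traj(x)
    w = np.full(len(x), 1.0 / len(x))
    err = block_error(traj, w, "x", np.array([0.0, 0.5, 1.0]), T, n_blocks=4)
    assert np.allclose(err, 0.0)


def test_block_error_preconditions():
    traj = _traj(np.arange(10.0))
    w = np.full(10, 0.1)
    with pytest.raises(PetfesError):
        block_error(traj, w, "x", 5, T, n_blocks=1)


def test_block_error_matches_bootstrap(rng):
    """For i.i.d. frames, block errors agree with a bootstrap oracle."""
    n = 40_000
    x = rng.normal(0.5, 0.15, n)
    traj = _traj(x)
    w = np.full(n, 1.0 / n)
    edges = np.linspace(0.1, 0.9, 9)
    err = block_error(traj, w, "x", edges, T, n_blocks=10)

    boot = []
    for _ in range(120):
        idx = rng.integers(0, n, n)
        hist, _ = np.histogram(x[idx], bins=edges)
        with np.errstate(divide="ignore"):
            f = -KT * np.log(hist / hist.sum())
        boot.append(f - f.mean())
    boot_err = np.std(np.array(boot), axis=0, ddof=1)
    keep = np.isfinite(err) & (boot_err > 0)
    ratio = err[keep] / boot_err[keep]
    assert np.median(ratio) == pytest.approx(1.0, abs=0.2)


# ---------------------------------------------------------------------------
# state_delta_f and friends
# ---------------------------------------------------------------------------

def test_state_delta_f_closed_form():
    x = np.array([2.0] * 9 + [4.0])
    traj = _traj(x, system="toy")
    w = np.array([0.1] * 9 + [0.1])
    part = StatePartition("x", 3.0, "below")
    res = state_delta_f(traj, w, part, T)
    assert res.delta_f == pytest.approx(-KT * math.log(9.0))
    assert res.delta_f == pytest.approx(-5.48, abs=0.06)


def test_state_delta_f_antisymmetric(rng):
    x = rng.uniform(1, 5, 1000)
    traj = _traj(x)
    w = rng.random(1000)
    w /= w.sum()
    below = state_delta_f(traj, w, StatePartition("x", 3.0, "below"), T)
    above = state_delta_f(traj, w, StatePartition("x", 2.9999, "above"), T)
    assert below.delta_f == pytest.approx(-above.delta_f)


def test_state_delta_f_empty_region_errors():
    traj = _traj([1.0, 2.0])
    w = np.array([0.5, 0.5])
    with pytest.raises(NoDataError):
        state_delta_f(traj, w, StatePartition("x", 3.0, "below"), T)


def test_symmetric_double_well_partition_is_zero(rng):
    x = np.concatenate([rng.normal(-1, 0.1, 5000), rng.normal(1, 0.1, 5000)])
    rng.shuffle(x)
    traj = _traj(x)
    w = np.full(len(x), 1.0 / len(x))
    res = state_delta_f(traj, w, StatePartition("x", 0.0, "below"), T)
    assert abs(res.delta_f) < max(0.2, 3 * res.error)


def test_delta_f_additive_over_three_way_partition():
    """dF(A,C) = dF(A,B) + dF(B,C) on closed-form weights."""
    wa, wb, wc = 0.6, 0.3, 0.1

    def pair_df(w1, w2):
        return -KT * math.log(w1 / w2)

    assert pair_df(wa, wc) == pytest.approx(pair_df(wa, wb) + pair_df(wb, wc))
    # same identity via state_delta_f on restricted trajectories
    x = np.array([1.0] * 6 + [2.0] * 3 + [3.0] * 1)
    w = np.full(10, 0.1)
    tr_ab = _traj(x[:9])
    tr_bc = _traj(x[6:])
    tr_ac = _traj(np.concatenate([x[:6], x[9:]]))
    p_ab = StatePartition("x", 1.5, "below")
    p_bc = StatePartition("x", 2.5, "below")
    df_ab = state_delta_f(tr_ab, w[:9], p_ab, T).delta_f
    df_bc = state_delta_f(tr_bc, w[6:], p_bc, T).delta_f
    df_ac = state_delta_f(tr_ac, w[:7], p_ab, T).delta_f
    assert df_ac == pytest.approx(df_ab + df_bc)


# ---------------------------------------------------------------------------
# convergence_series and delta_delta_f
# ---------------------------------------------------------------------------

def test_convergence_final_entry_equals_full_estimate(rng):
    x = rng.uniform(1, 5, 2000)
    traj = _traj(x)
    w = np.full(2000, 1 / 2000)
    part = StatePartition("x", 3.0, "below")
    series = convergence_series(traj, w, part, window=400, stride=400, T=T)
    full = state_delta_f(traj, w, part, T)
    assert series[-1].delta_f == full.delta_f


def test_stationary_series_is_flat(rng):
    x = np.where(rng.random(20_000) < 0.7, 2.0, 4.0)
    traj = _traj(x)
    w = np.full(len(x), 1 / len(x))
    part = StatePartition("x", 3.0, "below")
    series = convergence_series(traj, w, part, window=2000, stride=2000, T=T)
    values = [r.delta_f for r in series]
    assert np.ptp(values) < 0.3


def test_two_regime_series_drifts_then_settles():
    from petfes.fixtures import FixtureSpec, generate_fixture
    spec = FixtureSpec("bound_unbound_mixture", n_frames=40_000, seed=8,
                       params={"p_bound": 0.3, "T": T, "switch_frame": 4_000,
                               "p_bound_late": 0.9})
    traj = generate_fixture(spec)
    w = np.full(traj.n_frames, 1.0 / traj.n_frames)
    part = StatePartition("d_COM", 3.0, "below")
    series = convergence_series(traj, w, part, window=2000, stride=2000, T=T)
    values = [r.delta_f for r in series]
    # early estimate reflects regime 1, the tail the 10:90 mixture
    p_mix = (0.3 * 4_000 + 0.9 * 36_000) / 40_000
    expected_final = -KT * math.log(p_mix / (1 - p_mix))
    assert values[0] > values[-1] + 1.0      # detectable drift down
    assert abs(values[-1] - expected_final) < 0.2
    assert abs(values[-1] - values[-2]) < 0.1  # plateau


def test_delta_delta_f():
    a = FreeEnergyResult(-25.0, 0.3, system="aPET", temperature=T,
                         partition="d_COM:below:3")
    c = FreeEnergyResult(-60.0, 0.4, system="cPET", temperature=T,
                         partition="d_COM:below:3")
    dd = delta_delta_f(a, c)
    assert dd.delta_f == pytest.approx(35.0)
    assert dd.error == pytest.approx(math.hypot(0.3, 0.4))
    assert delta_delta_f(c, a).delta_f == -dd.delta_f
    assert delta_delta_f(a, a).delta_f == 0.0
    with pytest.raises(PetfesError):
        delta_delta_f(a, FreeEnergyResult(-60.0, 0.4, temperature=500.0,
                                          partition="d_COM:below:3"))


def test_fesgrid_validates_minimum():
    with pytest.raises(PetfesError):
        FESGrid(edges=[np.array([0, 1, 2])], values=np.array([1.0, 2.0]))
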