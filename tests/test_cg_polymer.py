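"""Coarse-grained chain: classification, geometry, walls, sampling."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petfes.cg_polymer import (ChainGeometry, ChainState, TorsionPotential,
                               TorsionTrajectory, WallRestraint,
                               calibrate_gt_gap, classify_torsion,
                               classify_torsions, gt_ratio,
                               min_terminal_distance, sample_chain, scan_d1,
                               two_state_gap, two_state_populations,
                               wall_energy, wrap_angle)
from petfes.constants import KB, T_CALIBRATION
from petfes.errors import (InvalidAngleError, InvalidGeometryError,
                           InvalidRestraintError, NoDataError, SamplerError,
                           UnreachableRatioError)

TORSION_STATES = (180.0, 70.0, -70.0)


# ---------------------------------------------------------------------------
# Conformer classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("psi,label", [
    (70.0, "gauche"),
    (-70.0, "gauche"),
    (0.0, "gauche"),
    (119.999, "gauche"),
    (120.0, "trans"),
    (-120.0, "trans"),
    (180.0, "trans"),
    (-179.5, "trans"),
])
def test_classify_torsion_partition(psi, label):
    assert classify_torsion(psi) == label


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
def test_classify_torsion_rejects_nonfinite(bad):
    with pytest.raises(InvalidAngleError):
        classify_torsion(bad)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=-180.0, max_value=180.0, exclude_min=True))
def test_classify_symmetric_and_total(psi):
    label = classify_torsion(psi)
    assert label in ("gauche", "trans")
    assert classify_torsion(-psi) == label
    # periodic invariance
    assert classify_torsion(wrap_angle(psi + 360.0)) == label


def test_gt_ratio_limits():
    all_trans = TorsionTrajectory(psis=np.full((50, 4), 180.0),
                                  d1=np.full(50, 4.1), temperature=300,
                                  seed=0)
    assert gt_ratio(all_trans) == (0.0, 1.0)
    psis = np.tile([70.0, 180.0], (50, 2))
    half = TorsionTrajectory(psis=psis, d1=np.full(50, 3.0),
                             temperature=300, seed=0)
    g, t = gt_ratio(half)
    assert g == pytest.approx(0.5) and g + t == pytest.approx(1.0)


def test_gt_ratio_empty_trajectory():
    traj = TorsionTrajectory(psis=np.empty((0, 4)), d1=np.empty(0),
                             temperature=300, seed=0)
    with pytest.raises(NoDataError):
        gt_ratio(traj)


def test_two_state_boltzmann_sample_matches_closed_form(rng):
    """An exact two-state sample reproduces p_g/p_t = 2 exp(-dE/kBT)."""
    dE, T = -4.09, T_CALIBRATION
    w = 2.0 * math.exp(-dE / (KB * T))        # independent closed form
    p_expected = w / (1.0 + w)
    n = 80_000
    labels = rng.random(n) < p_expected
    psis = np.where(labels, 70.0, 180.0).reshape(-1, 4)
    traj = TorsionTrajectory(psis=psis, d1=np.full(len(psis), 3.0),
                             temperature=T, seed=0)
    g, t = gt_ratio(traj)
    sigma = math.sqrt(p_expected * (1 - p_expected) / n)
    assert abs(g - p_expected) < 3 * sigma
    assert (g, t) == pytest.approx((0.91, 0.09), abs=0.01)


# ---------------------------------------------------------------------------
# Wall restraints
# ---------------------------------------------------------------------------

def test_wall_energy_values():
    lower = WallRestraint(cv_name="d1", limit=2.4, k=1500.0, side="lower")
    assert wall_energy(2.5, lower) == 0.0
    assert wall_energy(2.4, lower) == 0.0
    assert wall_energy(2.3, lower) == pytest.approx(15.0)   # k * 0.1^2
    free = WallRestraint(limit=2.4, k=0.0)
    assert wall_energy(0.5, free) == 0.0
    upper = WallRestraint(cv_name="h0", limit=0.6, k=5000.0, side="upper")
    assert wall_energy(0.5, upper) == 0.0
    assert wall_energy(0.7, upper) == pytest.approx(50.0)


def test_wall_restraint_invariants():
    with pytest.raises(InvalidRestraintError):
        WallRestraint(k=-1.0)
    with pytest.raises(InvalidRestraintError):
        WallRestraint(exponent=3)
    with pytest.raises(InvalidRestraintError):
        WallRestraint(side="sideways")
    with pytest.raises(InvalidRestraintError):
        wall_energy(float("nan"), WallRestraint())


# ---------------------------------------------------------------------------
# Geometry and kinematics
# ---------------------------------------------------------------------------

def test_extended_chain_spans_beyond_4nm(geometry):
    state = ChainState.from_torsions(geometry, [180.0] * 4)
    assert min_terminal_distance(state) > 4.0
    assert geometry.all_trans_repeat_length * geometry.n_units > 4.0


def test_geometric_exclusion_by_enumeration(geometry):
    """Every torsion combination containing a gauche falls below 4.0 nm."""
    for combo in itertools.product(TORSION_STATES, repeat=4):
        state = ChainState.from_torsions(geometry, combo)
        d1 = min_terminal_distance(state)
        if any(abs(c) < 120 for c in combo):
            assert d1 < 4.0, f"gauche combo {combo} spans {d1:.3f} nm"
        else:
            assert d1 > 4.0


def test_coincident_terminal_beads_give_zero():
    geo = ChainGeometry()
    state = ChainState.from_torsions(geo, [180.0] * 4)
    state.positions[-1] = state.positions[0]
    assert min_terminal_distance(state) == 0.0


def test_single_repeat_chain_rejected():
    with pytest.raises(InvalidGeometryError):
        ChainGeometry(n_units=1)
    with pytest.raises(InvalidGeometryError):
        ChainGeometry(ring_bond=-0.1)


def test_torsion_potential_shape(amorphous_potential):
    pot = amorphous_potential
    assert pot.energy(70) - pot.energy(180) == pytest.approx(-4.09)
    assert pot.energy(-70) == pytest.approx(pot.energy(70))   # periodic even
    grid = np.arange(-180, 180, 0.25)
    u = pot.energy(grid)
    assert np.all(np.isfinite(u))
    minima = grid[(u < np.roll(u, 1)) & (u < np.roll(u, -1))]
    assert len(minima) == 3


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def test_sampler_deterministic(geometry, amorphous_potential):
    a = sample_chain(geometry, amorphous_potential, None, n_sweeps=2000,
                     seed=7)
    b = sample_chain(geometry, amorphous_potential, None, n_sweeps=2000,
                     seed=7)
    np.testing.assert_array_equal(a.psis, b.psis)
    np.testing.assert_array_equal(a.d1, b.d1)


def test_huge_gauche_barrier_keeps_trans(geometry):
    pot = TorsionPotential(gt_gap=0.0, barrier=200.0)
    # small local moves only: jump proposals (or wide Gaussian tails)
    # would teleport over even an arbitrarily high barrier
    traj = sample_chain(geometry, pot, None, n_sweeps=2000, seed=3,
                        initial_psis=[180.0] * 4, jump_prob=0.0,
                        step_deg=10.0)
    assert gt_ratio(traj)[1] == 1.0


def test_sampler_rejects_empty_run(geometry, amorphous_potential):
    with pytest.raises(SamplerError):
        sample_chain(geometry, amorphous_potential, None, n_sweeps=0, seed=0)


def test_single_torsion_boltzmann_histogram(geometry, amorphous_potential):
    """Sampled Psi marginal matches the closed-form 1D Boltzmann density."""
    from scipy import stats

    T = 300.0
    traj = sample_chain(geometry, amorphous_potential, None, T=T,
                        n_sweeps=60_000, seed=11)
    samples = traj.psis[::15].ravel()          # thin to decorrelate
    edges = np.linspace(-180, 180, 25)
    observed, _ = np.histogram(samples, bins=edges)
    grid = np.linspace(-180, 180, 14401)
    dens = np.exp(-amorphous_potential.energy(grid) / (KB * T))
    cdf = np.concatenate([[0], np.cumsum(dens)])
    cdf /= cdf[-1]
    idx = np.searchsorted(grid, edges[1:-1])
    probs = np.diff(np.concatenate([[0], cdf[idx], [1]]))
    expected = probs * len(samples)
    keep = expected > 5
    chi2, p = stats.chisquare(observed[keep], expected[keep]
                              * observed[keep].sum() / expected[keep].sum())
    assert p > 0.01


def test_wall_at_4nm_forces_trans(geometry, amorphous_potential):
    traj = sample_chain(geometry, amorphous_potential,
                        WallRestraint(limit=4.0, k=1500.0), T=300.0,
                        n_sweeps=30_000, seed=5)
    assert gt_ratio(traj)[1] >= 0.99


def test_trans_fraction_monotone_in_wall(geometry, amorphous_potential):
    res = scan_d1(geometry, amorphous_potential, [2.4, 3.0, 3.4, 3.8, 4.0],
                  T=300.0, n_sweeps=15_000, seed=4)
    trans = [t for _, t in res]
    for a, b in zip(trans, trans[1:]):
        assert b >= a - 0.03      # 3 sigma of sampling noise


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def test_two_state_gap_closed_form():
    assert two_state_gap(0.91, 0.09, T_CALIBRATION) == pytest.approx(-4.09,
                                                                     abs=0.01)
    # degeneracy-only ratio: 2:1 gauche needs no gap
    assert two_state_gap(2 / 3, 1 / 3, 300.0) == pytest.approx(0.0, abs=1e-12)
    p_g, p_t = two_state_populations(-4.09, T_CALIBRATION)
    assert (p_g, p_t) == pytest.approx((0.91, 0.09), abs=0.01)


def test_unreachable_target_rejected():
    with pytest.raises(UnreachableRatioError):
        two_state_gap(1.0, 0.0, 300.0)
    with pytest.raises(UnreachableRatioError):
        calibrate_gt_gap((1.0, 0.0), T=300.0)


def test_calibration_recovers_planted_gap(geometry):
    """Plant a gap, measure the ratio, re-calibrate: recover within 0.2."""
    planted = -4.5
    pot = TorsionPotential(gt_gap=planted)
    traj = sample_chain(geometry, pot, None, T=T_CALIBRATION,
                        n_sweeps=120_000, seed=21)
    g, t = gt_ratio(traj)
    recovered = calibrate_gt_gap((g, t), T=T_CALIBRATION, seed=22)
    assert abs(recovered - planted) < 0.2
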