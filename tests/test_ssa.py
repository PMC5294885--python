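"""Exact stochastic simulation and its statistical oracles."""

import numpy as np
import pytest

import grnmsm as g
from grnmsm.ssa import _HAVE_NUMBA, autocorrelation
from conftest import make_birth_death


@pytest.fixture(scope="module")
def small_net():
    return g.build_motif(
        "self_regulating",
        g.self_regulating_preset(h_a=0.05, f_a=0.7, g0=0.5, g1=4.0),
        sequester=False,
    )


def test_seeded_determinism(small_net):
    a = g.simulate(small_net, (0, 0), 100.0, seed=5)
    b = g.simulate(small_net, (0, 0), 100.0, seed=5)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.states, b.states)
    c = g.simulate(small_net, (0, 0), 100.0, seed=6)
    assert not np.array_equal(a.times, c.times)


def test_python_fallback_reproduces_compiled_stream(small_net):
    a = g.simulate(small_net, (0, 0), 50.0, seed=3, use_numba=True)
    b = g.simulate(small_net, (0, 0), 50.0, seed=3, use_numba=False)
    assert np.allclose(a.times, b.times)
    assert np.array_equal(a.states, b.states)


def test_trajectory_invariants(small_net):
    traj = g.simulate(small_net, (0, 0), 200.0, seed=9)
    assert np.all(np.diff(traj.times) > 0)
    # every consecutive state pair differs by exactly one reaction's change:
    # production (+1), degradation (-1), or a promoter flip (no sequestration)
    diffs = {tuple(map(int, d)) for d in np.diff(traj.states, axis=0)}
    assert diffs <= {(1, 0), (-1, 0), (0, 1), (0, -1)}
    assert np.all(traj.states[:, 0] >= 0)


def test_pure_death_extinction_time():
    """Mean extinction time from n0 = 5 with k = 1 is sum_{i=1..5} 1/i."""
    net = make_birth_death(0.0, 1.0)
    times = []
    for s in range(4000):
        traj = g.simulate(net, (5,), 50.0, seed=s)
        assert traj.exhausted  # propensity hits zero at extinction
        times.append(traj.times[-1])
    times = np.asarray(times)
    expected = sum(1.0 / i for i in range(1, 6))
    sem = times.std() / np.sqrt(times.size)
    assert abs(times.mean() - expected) < 3 * sem


def test_production_off_constant_trajectory():
    net = make_birth_death(0.0, 1.0)
    traj = g.simulate(net, (0,), 10.0, seed=1)
    assert traj.n_events == 0
    assert traj.exhausted
    assert np.array_equal(traj.states, [[0]])


def test_flip_occupancy_matches_stationary(flip):
    h, f = flip["h"], flip["f"]
    traj = g.simulate(flip["net"], (0,), 20000.0, seed=12)
    hist, outside = g.empirical_stationary(traj, flip["space"])
    assert outside == 0.0
    p_unbound = f / (h + f)
    # binomial-style 3 sigma band with the effective number of flips
    n_flips = traj.n_events
    sigma = np.sqrt(p_unbound * (1 - p_unbound) / n_flips) * 2
    assert abs(hist[0] - p_unbound) < 3 * sigma + 0.01


def test_empirical_stationary_tv_decreases_with_time():
    """Ergodic averaging: TV to the exact stationary shrinks (checked over
    doublings of the simulated horizon, three seeds, on median)."""
    net = g.build_motif(
        "self_regulating",
        g.self_regulating_preset(h_a=0.05, f_a=0.7, g0=0.5, g1=4.0),
        sequester=False,
    )
    space = g.enumerate_states(net, 15)
    pi = g.stationary(g.build_generator(space)).pi
    horizons = [500.0 * 2**i for i in range(5)]
    tv = np.zeros((3, len(horizons)))
    for si, seed in enumerate((1, 2, 3)):
        for hi, t_end in enumerate(horizons):
            traj = g.simulate(net, (0, 0), t_end, seed=seed)
            hist, _ = g.empirical_stationary(traj, space)
            tv[si, hi] = 0.5 * np.abs(hist - pi).sum()
    med = np.median(tv, axis=0)
    assert med[-1] < med[0]
    assert np.sum(np.diff(med) < 0) >= 3  # mostly decreasing


def test_mean_waiting_time_matches_exit_rate(small_net):
    """Average dwell time in a microstate converges to 1/|Q_ii|."""
    space = g.enumerate_states(small_net, 15)
    Q = g.build_generator(space).Q
    traj = g.simulate(small_net, (0, 0), 30000.0, seed=21)
    idx = space.indices_of(traj.states[:-1, :1], traj.states[:-1, 1:])
    dwell = np.diff(np.concatenate([[0.0], traj.times]))
    # pick the most visited microstate
    target = np.bincount(idx).argmax()
    visits = dwell[idx == target]
    expected = 1.0 / abs(Q[target, target])
    sem = visits.std() / np.sqrt(visits.size)
    assert abs(visits.mean() - expected) < 3 * sem


def test_macrostate_trace_and_relaxation(flip):
    labels = np.array([0, 1])
    traj = g.simulate(flip["net"], (0,), 100.0, seed=2)
    trace = g.macrostate_trace(traj, labels, flip["space"])
    assert trace[0] == 0
    assert set(trace.tolist()) <= {0, 1}

    grid = np.linspace(0.0, 30.0, 16)
    occ = g.relaxation_curves(flip["net"], (0,), 600, labels, flip["space"],
                              grid, seed=100)
    # t = 0: everyone in the initial macrostate
    assert occ[0, 0] == 1.0
    h, f = flip["h"], flip["f"]
    p0 = f / (h + f)
    expected = p0 + (1 - p0) * np.exp(-(h + f) * grid)
    sigma = np.sqrt(expected * (1 - expected) / 600)
    assert np.all(np.abs(occ[:, 0] - expected) < 3 * sigma + 0.01)


def test_white_noise_acf_vanishes():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20000)
    acf = autocorrelation(x, 50)
    assert acf[0] == pytest.approx(1.0)
    assert np.abs(acf[1:]).max() < 0.05


def test_flip_relaxation_constant_both_routes(flip):
    """tau_r = 1/(h+f) from the MSM-analytic acf and from a long SSA run."""
    h, f = flip["h"], flip["f"]
    expected = 1.0 / (h + f)
    pi = g.stationary(flip["gen"])
    T = g.transition_matrix(flip["gen"], 0.25)
    chi = np.eye(2)
    model = g.coarse_grain(T, pi, chi)
    grid = np.arange(0.0, 8.0, 0.25)
    _, _, tau_msm = g.autocorrelation_relaxation(model, grid,
                                                 initial_macrostate=0)
    assert tau_msm == pytest.approx(expected, rel=1e-6)

    traj = g.simulate(flip["net"], (0,), 60000.0, seed=8)
    part = g.crispify(chi)
    _, _, tau_ssa = g.autocorrelation_relaxation(
        traj, grid, partition=part, space=flip["space"], initial_macrostate=0)
    assert tau_ssa == pytest.approx(expected, rel=0.15)


def test_ssa_mass_outside_box_estimates_leak():
    """SSA runs unconstrained by the truncation, so out-of-box occupancy is
    an independent leak estimate (zero for a generous box)."""
    net = make_birth_death(2.0, 1.0)
    space = g.enumerate_states(net, 3)  # deliberately tight box
    traj = g.simulate(net, (0,), 20000.0, seed=4)
    _, outside = g.empirical_stationary(traj, space)
    from scipy.stats import poisson
    assert outside == pytest.approx(poisson.sf(3, 2.0), rel=0.25)
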