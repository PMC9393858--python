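import math

import numpy as np
import pytest
from scipy import stats as sps

from avbmc.cluster_mc import (ClusterState, MoveParams, ReservoirSpec,
                              SizeWindow, adaptive_flattening,
                              initial_liquid_cluster, initial_solid_cluster,
                              intrasite_jump, original_avbmc_swap,
                              run_gc_cluster, translate)
from avbmc.cluster_criteria import SolidClusterParams, solid_cluster_ok
from avbmc.model_core import ParticleConfig
from avbmc.validation_oracle import liquid_dimer_ratio, liquid_trimer_ratio_ideal


def _size_ratio_with_error(hist, hi, lo):
    """Ratio P(hi)/P(lo) with a 5-block standard error."""
    i_hi, i_lo = hi - hist.n_min, lo - hist.n_min
    per_block = hist.block_counts[:, i_hi] / hist.block_counts[:, i_lo]
    return (float(hist.counts[i_hi] / hist.counts[i_lo]),
            float(per_block.std(ddof=1) / math.sqrt(len(per_block))))


def test_liquid_size_distribution_matches_quadrature_oracle(liquid_params):
    res = ReservoirSpec(0.6, 1.0)
    win = SizeWindow(1, 3)
    state = ClusterState("liquid", np.zeros((1, 3)), epsilon=1.0)
    hist, _, _ = run_gc_cluster(state, res, liquid_params, win, None,
                                400_000, seed=21)
    r21, e21 = _size_ratio_with_error(hist, 2, 1)
    exact21 = liquid_dimer_ratio(res, liquid_params.R, epsilon=1.0)
    assert abs(r21 - exact21) < 3.0 * max(e21, 0.02 * exact21)


def test_ideal_dimer_ratio_is_half_activity_volume(liquid_params):
    # n_v V_in / 2: the 1/2! of indistinguishable-cluster statistics
    res = ReservoirSpec(0.6, 1.0)
    win = SizeWindow(1, 2)
    state = ClusterState("liquid", np.zeros((1, 3)), epsilon=0.0)
    hist, _, _ = run_gc_cluster(state, res, liquid_params, win, None,
                                400_000, seed=22)
    r, e = _size_ratio_with_error(hist, 2, 1)
    v_in = (4.0 / 3.0) * math.pi * liquid_params.R ** 3
    assert abs(r - v_in / 2.0) < 3.0 * max(e, 0.02 * v_in / 2.0)


def test_ideal_trimer_ratio_matches_brute_force_integral(liquid_params):
    res = ReservoirSpec(0.6, 1.0)
    win = SizeWindow(1, 3)
    state = ClusterState("liquid", np.zeros((1, 3)), epsilon=0.0)
    hist, _, _ = run_gc_cluster(state, res, liquid_params, win, None,
                                600_000, seed=23)
    r32, e32 = _size_ratio_with_error(hist, 3, 2)
    exact, err = liquid_trimer_ratio_ideal(res, liquid_params.R,
                                           n_samples=2_000_000, seed=5)
    assert abs(r32 - exact) < 3.0 * math.hypot(max(e32, 0.02 * exact), err)


def test_translation_proposal_bounded_and_free_particle_always_accepted(
        reservoir, liquid_params, rng):
    state = ClusterState("liquid", np.zeros((1, 3)), epsilon=0.0)
    for _ in range(200):
        before = state.pos[0].copy()
        prop = translate(state, reservoir, liquid_params, rng)
        assert prop.accepted
        assert np.all(np.abs(state.pos[0] - before) <= 0.2 + 1e-15)


def test_two_particle_distance_distribution_matches_quadrature(
        reservoir, liquid_params):
    # translations only (window pinned at n=2): p(r) ~ e^{-beta u(r)} r^2
    state = ClusterState(
        "liquid", np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.1]]), epsilon=1.0)
    win = SizeWindow(2, 2)
    samples = []
    run_gc_cluster(state, reservoir, liquid_params, win, None, 150_000,
                   seed=31, observer_stride=25,
                   observer=lambda s: samples.append(
                       float(np.linalg.norm(s.pos[1] - s.pos[0]))))
    samples = np.asarray(samples)
    edges = np.linspace(0.8, liquid_params.R, 12)
    r = np.linspace(0.8, liquid_params.R, 2000)
    u = 4.0 * (r ** -12 - r ** -6)
    w = np.exp(-reservoir.beta * u) * r ** 2
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    probs = np.diff(np.interp(edges, r, np.concatenate([[0], cdf[1:]])))
    probs /= probs.sum()
    obs = np.histogram(samples[samples >= 0.8], bins=edges)[0]
    chi2, p = sps.chisquare(obs, probs * obs.sum())
    assert p > 0.001


def test_intrasite_radial_marginal_is_uniform_in_sphere(
        lattice, reservoir, solid_params, rng):
    state = initial_solid_cluster(lattice, 1, epsilon=0.0)
    ds = []
    for _ in range(30_000):
        intrasite_jump(state, reservoir, solid_params, rng)
        ds.append(float(np.linalg.norm(state.pos[0] - state.site_pos[0])))
    ds = np.asarray(ds[100:])
    # uniform in sphere: P(d < x) = (x/r)^3
    ks = sps.kstest(ds[::10] / solid_params.r, lambda x: x ** 3)
    assert ks.pvalue > 0.001
    assert ds.max() <= solid_params.r + 1e-12


def test_ideal_intrasite_always_accepted(lattice, reservoir, solid_params, rng):
    state = initial_solid_cluster(lattice, 8, epsilon=0.0)
    props = [intrasite_jump(state, reservoir, solid_params, rng)
             for _ in range(500)]
    assert all(p.accepted for p in props)


def test_run_determinism_and_zero_moves(lattice, reservoir, solid_params):
    win = SizeWindow(3, 10)
    mk = lambda: initial_solid_cluster(lattice, 6)
    h1, s1, _ = run_gc_cluster(mk(), reservoir, solid_params, win, None,
                               30_000, seed=77)
    h2, s2, _ = run_gc_cluster(mk(), reservoir, solid_params, win, None,
                               30_000, seed=77)
    np.testing.assert_array_equal(h1.block_counts, h2.block_counts)
    assert s1.as_dict() == s2.as_dict()
    h0, _, _ = run_gc_cluster(mk(), reservoir, solid_params, win, None,
                              0, seed=1)
    assert h0.total == 0


def test_window_bounds_are_hard(lattice, reservoir, solid_params):
    win = SizeWindow(4, 8)
    state = initial_solid_cluster(lattice, 6)
    hist, _, _ = run_gc_cluster(state, reservoir, solid_params, win, None,
                                60_000, seed=3)
    assert hist.sizes.min() == 4 and hist.sizes.max() == 8
    assert hist.counts.sum() == 60_000
    assert win.contains(state.n)


def test_rejected_moves_leave_state_intact(lattice, reservoir, rng):
    # tiny r and a cold cluster: most swaps reject; audit state each time
    params = MoveParams(r=0.2)
    from avbmc.cluster_mc import lattice_avbmc_swap
    state = initial_solid_cluster(lattice, 6)
    win = SizeWindow(6, 6)  # every swap is window-rejected
    for _ in range(400):
        pos_before = state.snapshot_positions()
        e_before = state.energy
        prop = lattice_avbmc_swap(state, reservoir, params, win, rng)
        assert not prop.accepted
        np.testing.assert_array_equal(state.snapshot_positions(), pos_before)
        assert state.energy == e_before
        state.occ.audit()


def test_solid_state_invariants_after_run(lattice, reservoir, solid_params):
    win = SizeWindow(3, 12)
    state = initial_solid_cluster(lattice, 6)
    run_gc_cluster(state, reservoir, solid_params, win, None, 80_000, seed=9)
    state.occ.audit()
    assert solid_cluster_ok(ParticleConfig(state.snapshot_positions()),
                            state.occ, lattice, SolidClusterParams(r=0.5))
    # cached energy consistent with a full recompute
    assert state.energy == pytest.approx(state.full_energy(), abs=1e-7)


def test_liquid_state_energy_cache_consistency(reservoir, liquid_params):
    win = SizeWindow(2, 12)
    state = initial_liquid_cluster(4, reservoir, liquid_params, seed=5,
                                   relax_sweeps=50)
    run_gc_cluster(state, reservoir, liquid_params, win, None, 60_000, seed=11)
    assert state.energy == pytest.approx(state.full_energy(), abs=1e-7)


def test_adaptive_flattening_two_state_toy(lattice, reservoir):
    # free-energy gap of several kT across a small window flattens quickly
    params = MoveParams(r=0.5)
    win = SizeWindow(6, 10)
    state = initial_solid_cluster(lattice, 8)
    bias, hist, n_it = adaptive_flattening(state, reservoir, params, win,
                                           seed=13, moves_per_iter=40_000)
    assert n_it <= 20
    assert hist.flatness_ratio() < 10.0


def test_swap_acceptance_decreases_with_cluster_size(lattice, reservoir):
    params = MoveParams(r=0.5)
    rates = []
    for n0, seed in ((15, 41), (80, 42)):
        win = SizeWindow(n0 - 3, n0 + 3)
        state = initial_solid_cluster(lattice, n0)
        bias, _, _ = adaptive_flattening(state, reservoir, params, win,
                                         seed=seed, moves_per_iter=60_000)
        _, st, _ = run_gc_cluster(state, reservoir, params, win, bias,
                                  150_000, seed=seed + 1)
        rates.append(st.rate("lattice_insert", "lattice_delete"))
    assert rates[1] < rates[0]


def test_invalid_initial_state_rejected(lattice, reservoir, solid_params):
    state = initial_solid_cluster(lattice, 3)
    with pytest.raises(ValueError, match="window"):
        run_gc_cluster(state, reservoir, solid_params, SizeWindow(5, 9),
                       None, 100, seed=1)
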