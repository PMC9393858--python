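import math

import numpy as np
import pytest
from scipy.integrate import quad

from avbmc.model_core import (Deletion, Displacement, Insertion,
                              PairPotentialSpec, ParticleConfig, delta_energy,
                              pair_energy, read_xyz, tail_correction,
                              total_energy, write_xyz)

SPEC = PairPotentialSpec()


@pytest.mark.parametrize("r, expected", [
    (2.0 ** (1.0 / 6.0), -1.0),            # potential minimum
    (1.0, 0.0),                            # zero crossing
    (2.0, 4.0 * (2.0 ** -12 - 2.0 ** -6)),  # direct substitution
])
def test_pair_energy_reference_points(r, expected):
    assert pair_energy(r, SPEC) == pytest.approx(expected, abs=1e-15)


def test_pair_energy_zero_distance_rejected():
    with pytest.raises(ValueError):
        pair_energy(0.0, SPEC)


def test_pair_energy_beyond_cutoff_is_zero():
    spec = PairPotentialSpec(cutoff=2.5)
    assert pair_energy(3.0, spec) == 0.0
    assert pair_energy(2.0, spec) == pair_energy(2.0, SPEC)


def test_total_energy_trivial_cases():
    assert total_energy(ParticleConfig(np.empty((0, 3))), SPEC) == 0.0
    assert total_energy(ParticleConfig(np.zeros((1, 3))), SPEC) == 0.0
    dimer = ParticleConfig(np.array([[0, 0, 0], [0, 0, 2 ** (1 / 6)]]))
    assert total_energy(dimer, SPEC) == pytest.approx(-1.0)


def test_total_energy_matches_bruteforce_double_loop(lattice):
    # central particle plus its 12 FCC neighbors at 1.128
    from avbmc.cluster_mc import initial_solid_cluster
    pos = initial_solid_cluster(lattice, 13).snapshot_positions()
    cfg = ParticleConfig(pos)
    expected = 0.0
    for i in range(13):
        for j in range(i + 1, 13):
            expected += pair_energy(float(np.linalg.norm(pos[i] - pos[j])), SPEC)
    assert total_energy(cfg, SPEC) == pytest.approx(expected, rel=1e-12)


def test_total_energy_overlap_rejected():
    cfg = ParticleConfig(np.zeros((2, 3)))
    with pytest.raises(ValueError, match="overlap"):
        total_energy(cfg, SPEC)


def test_cluster_energy_rototranslation_invariant(rng):
    pos = rng.normal(scale=2.0, size=(20, 3))
    cfg = ParticleConfig(pos)
    e0 = total_energy(cfg, SPEC)
    # random proper rotation (QR with positive determinant) plus translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = ParticleConfig(pos @ q.T + rng.normal(size=3))
    assert total_energy(moved, SPEC) == pytest.approx(e0, rel=1e-10)


def test_delta_energy_trivial_cases():
    dimer = ParticleConfig(np.array([[0, 0, 0], [0, 0, 2 ** (1 / 6)]]))
    far = delta_energy(dimer, Insertion(np.array([0.0, 0.0, 1e8])), SPEC)
    assert far == pytest.approx(0.0, abs=1e-20)
    assert delta_energy(dimer, Deletion(1), SPEC) == pytest.approx(1.0)
    with pytest.raises(IndexError):
        delta_energy(dimer, Deletion(5), SPEC)


def test_delta_energy_matches_full_recompute(rng):
    pos = rng.normal(scale=1.6, size=(20, 3))
    cfg = ParticleConfig(pos.copy())
    e0 = total_energy(cfg, SPEC)
    for _ in range(30):
        i = int(rng.integers(20))
        new = cfg.positions[i] + rng.normal(scale=0.15, size=3)
        de = delta_energy(cfg, Displacement(i, new), SPEC)
        after = cfg.positions.copy()
        after[i] = new
        e1 = total_energy(ParticleConfig(after), SPEC)
        assert de == pytest.approx(e1 - e0, rel=1e-9, abs=1e-12)
        cfg = ParticleConfig(after)
        e0 = e1


def test_tail_correction_limits_and_quadrature():
    assert tail_correction(0.0, 4.75, SPEC) == (0.0, 0.0)
    u_inf, p_inf = tail_correction(0.8, 1e6, SPEC)
    assert abs(u_inf) < 1e-15 and abs(p_inf) < 1e-15
    # quadrature oracle: u_tail = (rho/2) int_rc^inf u(r) 4 pi r^2 dr
    rho, rc = 0.8, 4.75
    val, _ = quad(lambda r: 4.0 * ((1 / r) ** 12 - (1 / r) ** 6)
                  * rho * 4.0 * math.pi * r ** 2 / 2.0, rc, np.inf)
    u_tail, _ = tail_correction(rho, rc, SPEC)
    assert u_tail == pytest.approx(val, rel=1e-10)


def test_bulk_energy_cutoff_convergence_on_liquidlike_config(rng):
    # dense disordered configuration: tail-corrected energy per particle
    # should be nearly cutoff-independent once rc is a few sigma
    from avbmc import _kernels as K
    n, rho = 200, 0.8
    box = (n / rho) ** (1 / 3)
    pos, placed = K.rsa_fill(n, box, 0.88, 99, 500 * n)
    assert placed == n
    cfg = ParticleConfig(pos, box_length=box, mode="bulk")
    vals = []
    for rc in (2.5, 3.1):
        spec = PairPotentialSpec(cutoff=rc, tail_corrections=True)
        vals.append(total_energy(cfg, spec) / n)
    assert vals[0] == pytest.approx(vals[1], abs=0.05)


def test_bulk_requires_minimum_image_compatible_box():
    cfg = ParticleConfig(np.random.default_rng(0).random((8, 3)) * 5.0,
                         box_length=5.0, mode="bulk")
    with pytest.raises(ValueError, match="minimum-image"):
        total_energy(cfg, PairPotentialSpec(cutoff=3.0))


def test_xyz_round_trip(tmp_path, rng):
    cfg = ParticleConfig(rng.normal(size=(7, 3)))
    path = tmp_path / "c.xyz"
    write_xyz(path, cfg)
    back = read_xyz(path)
    assert back.mode == "cluster" and back.box_length is None
    np.testing.assert_allclose(back.positions, cfg.positions, rtol=1e-10)

    bulk = ParticleConfig(rng.random((5, 3)) * 8.0, box_length=8.0, mode="bulk")
    write_xyz(path, bulk)
    back = read_xyz(path)
    assert back.mode == "bulk"
    assert back.box_length == pytest.approx(8.0)


def test_mode_spec_consistency_enforced():
    with pytest.raises(ValueError):
        ParticleConfig(np.zeros((1, 3)), box_length=5.0)  # cluster + box
    cfg = ParticleConfig(np.zeros((1, 3)))
    with pytest.raises(ValueError):
        total_energy(cfg, PairPotentialSpec(cutoff=3.0))  # cluster + cutoff
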