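import math

import numpy as np
import pytest

from avbmc.cnt_analysis import FitResult
from avbmc.umbrella import (BiasPotential, DeltaGSeries, FreeEnergyProfile,
                            InsufficientSamplingError, SizeHistogram,
                            adapt_bias, cnt_extend_bias, delta_g_series,
                            shape_x, stitch_profiles, unbias)
from conftest import synthetic_histogram


def _flat_hist(n_min, k, count=1000.0):
    return SizeHistogram(n_min, np.full((5, k), count))


def test_flat_histogram_zero_bias_gives_constant_profile():
    hist = _flat_hist(10, 6)
    prof = unbias(hist, BiasPotential.zero(10, 15), T=0.7, anchor=(10, 0.0))
    np.testing.assert_allclose(prof.delta_G, 0.0, atol=1e-12)
    np.testing.assert_allclose(prof.se, 0.0, atol=1e-12)


def test_count_ratio_translates_to_free_energy_difference():
    # H(n)/H(n-1) = e^{-1} at T=1 and zero bias -> dG increment of +1
    counts = 1000.0 * np.exp(-np.arange(4.0))
    hist = SizeHistogram(5, np.tile(counts, (5, 1)))
    prof = unbias(hist, BiasPotential.zero(5, 8), T=1.0)
    series = delta_g_series(prof)
    np.testing.assert_allclose(series.delta, 1.0, rtol=1e-12)


def test_unvisited_size_raises_naming_the_size():
    bc = np.full((5, 4), 50.0)
    bc[3, 2] = 0.0
    with pytest.raises(InsufficientSamplingError, match="size 9"):
        unbias(SizeHistogram(7, bc), BiasPotential.zero(7, 10), T=0.6)


def test_synthetic_sampler_profile_recovery(rng):
    # draw sizes from a known beta*dG under a known bias; recover profile
    n_min, T = 20, 0.6
    beta_dg = np.array([0.0, -1.2, -2.1, -2.6, -3.4, -3.3])
    eta = -T * beta_dg + 0.3 * rng.standard_normal(6)
    hist = synthetic_histogram(n_min, beta_dg, eta / T, 250_000, rng)
    prof = unbias(hist, BiasPotential(n_min, eta), T, anchor=(20, 0.0))
    recovered = (prof.delta_G - prof.delta_G[0]) / T
    err = np.maximum(prof.se / T, 1e-4)
    assert np.all(np.abs(recovered - beta_dg) < 3.5 * err)


def test_adapt_bias_flat_profile_gives_constant_zero():
    prof = FreeEnergyProfile(np.arange(5, 9), np.full(4, 2.5),
                             np.zeros(4), np.full((5, 4), 2.5), (5, 2.5))
    bias = adapt_bias(prof)
    np.testing.assert_allclose(bias.eta, 0.0, atol=1e-12)


def test_adapt_bias_flattens_two_state_toy(rng):
    # 5 kT gap: one iteration brings the count ratio below 2
    T, n_min = 1.0, 1
    beta_dg = np.array([0.0, 5.0])
    hist = synthetic_histogram(n_min, beta_dg, np.zeros(2), 200_000, rng)
    prof = unbias(hist, BiasPotential.zero(1, 2), T)
    bias = adapt_bias(prof)
    hist2 = synthetic_histogram(n_min, beta_dg, bias.eta / T, 200_000, rng)
    assert hist2.flatness_ratio() < 2.0


def test_adapt_bias_idempotent_at_exact_profile(rng):
    T = 0.6
    beta_dg = np.array([0.0, -2.0, -3.5, -4.0])
    prof = FreeEnergyProfile(np.arange(8, 12), T * beta_dg, np.zeros(4),
                             np.tile(T * beta_dg, (5, 1)), (8, 0.0))
    bias = adapt_bias(prof)
    hist = synthetic_histogram(8, beta_dg, bias.eta / T, 400_000, rng)
    assert hist.flatness_ratio() < 1.1


def test_cnt_extension_constant_and_sign_conventions():
    flat = FitResult(0.0, 0.0, 0.0, 0.0, 10, 50)
    ext = cnt_extend_bias(flat, (50, -7.0), np.arange(51, 61))
    np.testing.assert_allclose(ext.eta, 7.0, atol=1e-12)
    down = FitResult(0.0, -1.0, 0.0, 0.0, 10, 50)
    ext = cnt_extend_bias(down, (50, 0.0), np.arange(51, 56))
    # dG drops by 1 per particle, so the bias (-dG) rises by 1 per particle
    np.testing.assert_allclose(np.diff(ext.eta), 1.0, atol=1e-12)
    with pytest.raises(ValueError, match="anchor"):
        cnt_extend_bias(flat, (50, 0.0), np.arange(40, 45))


def test_cnt_extension_reproduces_exact_cnt_profile():
    b, s = -4.0, 6.0
    ns = np.arange(2, 101)
    dg = np.cumsum(b + s * shape_x(ns))  # dG relative to dG(1)=0
    fit = FitResult(s, b, 0.0, 0.0, 2, 50)
    ext = cnt_extend_bias(fit, (50, float(dg[48])), np.array([100]))
    assert -ext.eta[0] == pytest.approx(float(dg[98]), abs=1e-10)


def test_delta_g_series_properties():
    ns = np.arange(30, 40)
    g = 0.3 * ns + 1.7
    prof = FreeEnergyProfile(ns, g, np.zeros(10), np.tile(g, (5, 1)), (30, g[0]))
    series = delta_g_series(prof)
    np.testing.assert_allclose(series.delta, 0.3, rtol=1e-12)
    assert np.all(np.diff(series.x) < 0)  # x decreases with n
    # anchor shift leaves the series untouched (up to float rounding)
    shifted = delta_g_series(prof.shifted(7.0))
    np.testing.assert_allclose(shifted.delta, series.delta, atol=1e-12)
    np.testing.assert_allclose(shifted.se, series.se, atol=1e-12)


def test_delta_g_series_exact_cnt_points_lie_on_line():
    b, s = -4.385, 6.344
    ns = np.arange(2, 60)
    dg = np.cumsum(b + s * shape_x(ns))
    prof = FreeEnergyProfile(np.concatenate([[1], ns]),
                             np.concatenate([[0.0], dg]),
                             np.zeros(len(ns) + 1),
                             np.tile(np.concatenate([[0.0], dg]), (5, 1)),
                             (1, 0.0))
    series = delta_g_series(prof)
    np.testing.assert_allclose(series.delta, b + s * series.x, rtol=1e-12)


def test_block_errors_shrink_with_sample_size(rng):
    T, n_min = 0.6, 5
    beta_dg = np.linspace(0.0, -2.0, 6)
    se = []
    for n_tot in (40_000, 160_000):
        hist = synthetic_histogram(n_min, beta_dg, np.zeros(6), n_tot, rng)
        prof = unbias(hist, BiasPotential.zero(5, 10), T)
        se.append(delta_g_series(prof).se.mean())
    ratio = se[0] / se[1]
    assert 1.4 < ratio < 2.6  # ~2 when quadrupling samples


def test_stitching_aligns_overlapping_windows():
    ns1 = np.arange(10, 16)
    ns2 = np.arange(14, 20)
    g = lambda n: -0.8 * n + 0.1 * n ** (2 / 3)
    p1 = FreeEnergyProfile(ns1, g(ns1), np.zeros(6),
                           np.tile(g(ns1), (5, 1)), (10, float(g(ns1)[0])))
    p2 = FreeEnergyProfile(ns2, g(ns2) + 3.0, np.zeros(6),
                           np.tile(g(ns2) + 3.0, (5, 1)), (14, 0.0))
    table = stitch_profiles([p1, p2])
    np.testing.assert_allclose(table["delta_G"].to_numpy(),
                               g(table["n"].to_numpy()), atol=1e-10)
    p3 = FreeEnergyProfile(np.arange(30, 33), np.zeros(3), np.zeros(3),
                           np.zeros((5, 3)), (30, 0.0))
    with pytest.raises(ValueError, match="overlap"):
        stitch_profiles([p1, p3])


def test_bias_tsv_round_trip(tmp_path):
    bias = BiasPotential(12, np.array([0.0, -1.5, 2.25]))
    bias.to_tsv(tmp_path / "b.tsv")
    back = BiasPotential.from_tsv(tmp_path / "b.tsv")
    assert back.n_min == 12
    np.testing.assert_allclose(back.eta, bias.eta)
    assert bias.value(11) == np.inf  # outside the domain: excluded
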