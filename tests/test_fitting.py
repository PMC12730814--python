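"""Pixel-wise fitting: recovery, degeneracy handling, masks and maps."""

import numpy as np
import pytest

from relaxmap import (
    T1ModelParams,
    T2ModelParams,
    fit_map,
    fit_t1_pixel,
    fit_t2_pixel,
    foreground_mask,
    make_three_tissue_phantom,
    simulate_series,
    t1_signal,
    t2_signal,
)
from relaxmap.phantom import rician_corrupt


@pytest.mark.parametrize("t1_true", [1351.7, 727.7, 368.9])
def test_noiseless_t1_recovery(t1_true, t1_grid):
    signals = t1_signal(t1_grid.variable_ms, T1ModelParams(1000.0, 1.0, t1_true))
    res = fit_t1_pixel(signals, t1_grid)
    assert res.converged
    assert res.params.t1_ms == pytest.approx(t1_true, rel=1e-4)
    assert res.r_squared > 1 - 1e-9


@pytest.mark.parametrize("t2_true", [93.5, 78.5, 55.7])
def test_noiseless_t2_recovery(t2_true, t2_grid):
    signals = t2_signal(t2_grid.variable_ms, T2ModelParams(1000.0, t2_true, 0.0))
    res = fit_t2_pixel(signals, t2_grid)
    assert res.converged
    assert res.params.t2_ms == pytest.approx(t2_true, rel=1e-4)
    assert res.r_squared > 1 - 1e-9


def test_noiseless_recovery_with_baseline_and_partial_recovery(t1_grid, t2_grid):
    s1 = t1_signal(t1_grid.variable_ms, T1ModelParams(800.0, 0.9, 950.0))
    r1 = fit_t1_pixel(s1, t1_grid)
    assert r1.converged
    assert r1.params.t1_ms == pytest.approx(950.0, rel=1e-4)
    assert r1.params.recovery_fraction == pytest.approx(0.9, rel=1e-3)
    s2 = t2_signal(t2_grid.variable_ms, T2ModelParams(800.0, 120.0, 40.0))
    r2 = fit_t2_pixel(s2, t2_grid)
    assert r2.converged
    assert r2.params.t2_ms == pytest.approx(120.0, rel=1e-4)
    assert r2.params.baseline == pytest.approx(40.0, rel=1e-3)


def test_degenerate_signals_flagged_not_raised(t1_grid, t2_grid):
    zero = np.zeros(len(t1_grid))
    res = fit_t1_pixel(zero, t1_grid)
    assert not res.converged and res.status == "all-zero signal"
    const = np.full(len(t2_grid), 55.0)
    res2 = fit_t2_pixel(const, t2_grid)
    assert not res2.converged


def test_signal_length_and_sign_validated(t1_grid):
    with pytest.raises(ValueError):
        fit_t1_pixel(np.ones(5), t1_grid)
    with pytest.raises(ValueError):
        fit_t1_pixel(-np.ones(len(t1_grid)), t1_grid)


def test_foreground_mask_noiseless_equals_tissue(noiseless_phantom, t1_grid):
    series = simulate_series(noiseless_phantom, t1_grid)
    mask = foreground_mask(series, 0.05)
    tissue = sum(r.mask for r in noiseless_phantom.regions).astype(bool)
    np.testing.assert_array_equal(mask, tissue)


def test_foreground_mask_threshold_selectivity(noiseless_phantom, t2_grid):
    """Raising the threshold fraction keeps only the brightest tissue: in
    the shortest-TE image the healthy region (longest T2) is brightest."""
    series = simulate_series(noiseless_phantom, t2_grid)
    strict = foreground_mask(series, 0.985)
    loose = foreground_mask(series, 0.05)
    healthy = noiseless_phantom.region("healthy").mask
    np.testing.assert_array_equal(strict, healthy)
    assert strict.sum() < loose.sum()
    with pytest.raises(ValueError):
        foreground_mask(series, 1.5)


def test_foreground_mask_excludes_noisy_background(t1_grid):
    """Rayleigh background at sigma, tissue at SNR >= 20, fraction 0.2:
    at least 99% of background pixels are excluded."""
    spec = make_three_tissue_phantom(
        shape=(64, 64), seed=9, proton_density=400.0, noise_sigma=20.0
    )
    series = simulate_series(spec, t1_grid)
    mask = foreground_mask(series, 0.2)
    background = ~sum(r.mask for r in spec.regions).astype(bool)
    excluded = 1.0 - mask[background].mean()
    assert excluded >= 0.99


def test_fit_map_noiseless_region_means(noiseless_phantom, t1_grid, t2_grid):
    for grid, attr in ((t1_grid, "t1_ms"), (t2_grid, "t2_ms")):
        series = simulate_series(noiseless_phantom, grid)
        rmap = fit_map(series, foreground_mask(series, 0.05))
        assert np.all(rmap.r2_map[rmap.mask] > 1 - 1e-9)
        assert rmap.qc["n_failed"] == 0
        for region in noiseless_phantom.regions:
            sel = region.mask & rmap.mask
            truth = getattr(region, attr)
            assert np.nanmean(rmap.value_map[sel]) == pytest.approx(truth, rel=1e-4)


def test_fit_map_empty_mask_rejected(noiseless_phantom, t1_grid):
    series = simulate_series(noiseless_phantom, t1_grid)
    with pytest.raises(ValueError, match="no pixels"):
        fit_map(series, np.zeros(series.shape, dtype=bool))


def test_fit_map_matches_individual_pixel_fits(t2_grid):
    """The map is a pure per-pixel reduction: order/iteration independent."""
    spec = make_three_tissue_phantom(shape=(32, 32), seed=2, noise_sigma=20.0)
    series = simulate_series(spec, t2_grid)
    mask = foreground_mask(series, 0.1)
    rmap = fit_map(series, mask)
    rows, cols = np.nonzero(mask)
    rng = np.random.default_rng(0)
    for i in rng.choice(len(rows), size=10, replace=False):
        r, c = rows[i], cols[i]
        res = fit_t2_pixel(series.images[:, r, c], t2_grid)
        if res.converged:
            assert rmap.value_map[r, c] == res.params.t2_ms
        else:
            assert not rmap.mask[r, c]


def test_noise_consistency_attains_information_bound(t1_grid, rng):
    """At SNR 50 the T1 estimator is efficient: its median relative error
    over 500 replicate pixels matches the Cramér–Rao prediction for the
    three-parameter model on this TR grid (and stays below 5%)."""
    t1_true, a, b = 727.7, 1000.0, 1.0
    tr = t1_grid.variable_ms
    clean = t1_signal(tr, T1ModelParams(a, b, t1_true))
    sigma = a / 50.0
    # CRLB for (a, b, T1); half-normal median = 0.6745 * sd
    e = np.exp(-tr / t1_true)
    jac = np.column_stack([1 - b * e, -a * e, -a * b * e * tr / t1_true**2])
    crlb_sd = sigma * np.sqrt(np.linalg.inv(jac.T @ jac)[2, 2])
    predicted_median = 0.6745 * crlb_sd / t1_true
    errors = []
    for _ in range(500):
        noisy = rician_corrupt(clean, sigma, rng)
        res = fit_t1_pixel(noisy, t1_grid)
        if res.converged:
            errors.append(abs(res.params.t1_ms - t1_true) / t1_true)
    assert len(errors) > 450
    median = np.median(errors)
    assert 0.7 * predicted_median < median < 1.3 * predicted_median
    assert median < 0.05


def test_r2_decreases_with_noise(t2_grid, rng):
    """Mean fit R² drops monotonically over three increasing noise levels."""
    clean = t2_signal(t2_grid.variable_ms, T2ModelParams(1000.0, 78.5, 0.0))
    mean_r2 = []
    for sigma in (5.0, 40.0, 150.0):
        r2s = []
        for _ in range(60):
            res = fit_t2_pixel(rician_corrupt(clean, sigma, rng), t2_grid)
            r2s.append(res.r_squared)
        mean_r2.append(np.mean(r2s))
    assert mean_r2[0] > mean_r2[1] > mean_r2[2]
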