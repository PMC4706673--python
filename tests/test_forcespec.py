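"""Force-curve processing: baseline, contact, Hertz fit, QC, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from collagenkit.forcespec import (
    Cantilever,
    ForceCurve,
    baseline_correct,
    build_modulus_map,
    compare_groups,
    find_contact_point,
    fit_hertz,
    process_curve,
    qc_filter,
)
from collagenkit.synthetic import gen_force_grid


def _synthetic_curve(e_kpa=500.0, z_c=200.0, cant=None, n=300, noise=0.0,
                     slope=0.0, seed=0):
    cant = cant or Cantilever(3.0, 1.0)
    curves, _ = gen_force_grid(
        np.array([[e_kpa]]), cant, contact_offset_sd=0.0,
        baseline_slope_sd=0.0, noise_sd=0.0, n_samples=n, seed=seed,
    )
    z, d = curves[0].z, curves[0].deflection
    z = z + (z_c - 150.0)  # generator plants contact at 150 nm
    rng = np.random.default_rng(seed)
    d = d + slope * z / 1000.0 + (rng.normal(0, noise, d.shape) if noise else 0.0)
    return ForceCurve(z=z, deflection=d)


# ---------------------------------------------------------------------------
# baseline


def test_baseline_removes_planted_tilt():
    curve = _synthetic_curve(slope=2.0)
    corrected = baseline_correct(curve)
    pre = corrected.deflection[: len(curve) // 4]
    assert np.abs(pre.mean()) < 1e-9
    # tilt estimate: difference of raw and corrected is the fitted line
    fitted = curve.deflection - corrected.deflection
    est_slope = np.polyfit(curve.z, fitted, 1)[0] * 1000.0
    assert est_slope == pytest.approx(2.0, rel=0.05)


def test_baseline_idempotent_on_flat_curve():
    curve = _synthetic_curve()
    once = baseline_correct(curve)
    twice = baseline_correct(once)
    np.testing.assert_allclose(twice.deflection, once.deflection, atol=1e-9)


def test_baseline_needs_enough_points():
    curve = _synthetic_curve(n=60)
    with pytest.raises(ValueError):
        baseline_correct(curve, fraction=0.05)


# ---------------------------------------------------------------------------
# contact point


def test_contact_point_exact_on_noiseless_curve():
    curve = _synthetic_curve(z_c=200.0)
    idx, z_c = find_contact_point(curve)
    step = curve.z[1] - curve.z[0]
    assert z_c == pytest.approx(200.0, abs=step)


def test_contact_point_monte_carlo_accuracy(cantilever):
    """Median contact-position error below 5 nm over 100 noisy curves
    (0.5 nm deflection noise)."""
    errors = []
    for seed in range(100):
        curves, truth = gen_force_grid(
            np.array([[500.0]]), cantilever, noise_sd=0.5, seed=seed
        )
        corrected = baseline_correct(curves[0])
        _, z_c = find_contact_point(corrected, coarse_step=3)
        errors.append(abs(z_c - truth.params["contact_z_nm"][0, 0]))
    assert np.median(errors) < 5.0


def test_pure_noise_curve_flags_no_contact():
    rng = np.random.default_rng(1)
    curve = ForceCurve(z=np.linspace(0, 300, 200),
                       deflection=rng.normal(0, 0.5, 200))
    with pytest.raises(ValueError, match="no contact"):
        find_contact_point(curve)


# ---------------------------------------------------------------------------
# Hertz fit


def test_noiseless_inversion_is_exact(cantilever):
    curve = _synthetic_curve(500.0, cant=cantilever)
    fit = process_curve(curve, cantilever)
    assert fit.converged
    assert fit.reduced_modulus == pytest.approx(500.0, rel=1e-3)


def test_noisy_inversion_median_error_under_5_percent(cantilever):
    errors = []
    for seed in range(100):
        curves, _ = gen_force_grid(np.array([[500.0]]), cantilever,
                                   noise_sd=0.5, seed=seed)
        fit = process_curve(curves[0], cantilever, coarse_step=3)
        errors.append(abs(fit.reduced_modulus - 500.0) / 500.0)
    assert np.median(errors) < 0.05


def test_fit_agrees_with_brute_force_grid_search(cantilever):
    """Closed-form linearised slope vs an independent 1-D grid search over
    the modulus on a noiseless curve: < 0.5 % apart."""
    curve = _synthetic_curve(400.0, cant=cantilever)
    idx, z_c = find_contact_point(curve)
    fit = fit_hertz(curve, cantilever, (idx, z_c))

    z, d = curve.z[idx:], curve.deflection[idx:]
    force = cantilever.spring_constant * d
    delta = np.clip((z - z_c) - d, 0.0, None)
    cap = 0.7 * force.max()
    use = (delta > 0) & (force <= cap)
    grid = np.linspace(100.0, 1000.0, 30001)  # kPa
    coef = (4.0 / 3.0) * grid[:, None] * 1e-6 * np.sqrt(1000.0)
    sse = ((force[use][None, :] - coef * delta[use][None, :] ** 1.5) ** 2).sum(axis=1)
    brute = grid[np.argmin(sse)]
    assert fit.reduced_modulus == pytest.approx(brute, rel=0.005)


def test_fit_scale_consistency(cantilever):
    """Doubling the spring constant with halved deflections leaves the
    modulus unchanged (force is the physical quantity)."""
    curve = _synthetic_curve(500.0, cant=cantilever)
    idx, z_c = find_contact_point(curve)
    fit = fit_hertz(curve, cantilever, (idx, z_c))

    stiff = Cantilever(2 * cantilever.spring_constant, cantilever.tip_radius)
    # halving deflection changes indentation; rebuild a physically
    # consistent curve for the stiffer lever instead of naive scaling
    curves, _ = gen_force_grid(
        np.array([[500.0]]), stiff, contact_offset_sd=0.0,
        baseline_slope_sd=0.0, noise_sd=0.0, seed=0,
    )
    fit2 = process_curve(curves[0], stiff)
    assert fit2.reduced_modulus == pytest.approx(fit.reduced_modulus, rel=1e-3)


def test_fit_fraction_targets_shallow_regime(cantilever):
    """On a curve that stiffens at depth, the 70 % force cap recovers the
    shallow modulus better than fitting the full curve."""
    shallow, deep = 300.0, 900.0
    n = 400
    z = np.linspace(0.0, 400.0, n)
    z_c, crossover = 100.0, 60.0  # nm indentation where stiffening starts
    coef_s = (4 / 3) * shallow * 1e-6 * np.sqrt(1000.0)
    coef_d = (4 / 3) * deep * 1e-6 * np.sqrt(1000.0)
    d = np.zeros(n)
    for i, zi in enumerate(z):
        if zi <= z_c:
            continue
        lo, hi = 0.0, zi - z_c
        for _ in range(60):
            mid = (lo + hi) / 2
            delta = zi - z_c - mid
            coef = coef_s if delta <= crossover else coef_d
            f = coef * max(delta, 0) ** 1.5 - 3.0 * mid
            lo, hi = (mid, hi) if f > 0 else (lo, mid)
        d[i] = (lo + hi) / 2
    curve = ForceCurve(z=z, deflection=d)
    idx = int(np.searchsorted(z, z_c))
    fit70 = fit_hertz(curve, Cantilever(3.0, 1.0), (idx, z_c), 0.7)
    fit100 = fit_hertz(curve, Cantilever(3.0, 1.0), (idx, z_c), 1.0)
    assert abs(fit70.reduced_modulus - shallow) < abs(fit100.reduced_modulus - shallow)


# ---------------------------------------------------------------------------
# QC


def test_qc_single_outlier_removed():
    kept, n_excl, frac = qc_filter([10.0, 10.0, 10.0, 10.0, 1000.0])
    assert n_excl == 1
    assert list(kept) == [10.0, 10.0, 10.0, 10.0]
    assert frac == pytest.approx(0.2)


def test_qc_zero_sd_excludes_nothing():
    kept, n_excl, frac = qc_filter([100.0] * 10)
    assert n_excl == 0 and frac == 0.0


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
             min_size=3, max_size=100)
)
def test_qc_order_invariant_and_bounded(values):
    kept, n_excl, _ = qc_filter(values)
    kept_rev, n_excl_rev, _ = qc_filter(values[::-1])
    assert n_excl == n_excl_rev
    assert sorted(kept) == sorted(kept_rev)
    assert n_excl <= int(np.ceil(len(values) / 2))


def test_qc_gaussian_exclusion_under_10_percent():
    fracs = []
    for seed in range(100):
        draws = np.random.default_rng(seed).normal(500.0, 100.0, 400)
        _, _, frac = qc_filter(draws)
        fracs.append(frac)
    assert np.mean(fracs) < 0.10


# ---------------------------------------------------------------------------
# modulus map


def test_map_geometry_matches_scan_protocol():
    fits = [
        type("F", (), {"reduced_modulus": 500.0, "converged": True})()
        for _ in range(400)
    ]
    mmap = build_modulus_map(fits, region_size=25.0)
    assert mmap.grid.shape == (20, 20)
    assert mmap.spacing == pytest.approx(1.25)


def test_map_small_grid_spacing():
    fits = [type("F", (), {"reduced_modulus": 100.0, "converged": True})()
            for _ in range(4)]
    mmap = build_modulus_map(fits, region_size=2.0)
    assert mmap.grid.shape == (2, 2)
    assert mmap.spacing == pytest.approx(1.0)


def test_map_rejects_nonsquare_count():
    fits = [type("F", (), {"reduced_modulus": 100.0, "converged": True})()
            for _ in range(5)]
    with pytest.raises(ValueError):
        build_modulus_map(fits, 25.0)


def test_map_median_ignores_excluded_cells():
    values = [500.0] * 15 + [5000.0]
    fits = [type("F", (), {"reduced_modulus": v, "converged": True})()
            for v in values]
    mmap = build_modulus_map(fits, 5.0)
    assert mmap.excluded.sum() == 1
    assert mmap.median() == pytest.approx(500.0)


# ---------------------------------------------------------------------------
# group statistics


def test_mann_whitney_exact_small_sample():
    """U = 0 with fully separated triples; the exact two-sided p is 0.1
    (2 of the 20 equally likely rank assignments are as extreme)."""
    stat, p = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert stat == 0.0
    assert p == pytest.approx(0.1)


def test_mann_whitney_identical_groups_p_one():
    _, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)


def test_anova_matches_hand_computed_f():
    """The one-way F statistic equals the classical between/within
    mean-square ratio computed directly."""
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 10), rng.normal(2, 1, 10)
    stat, p = compare_groups(a, b, "anova")

    grand = np.concatenate([a, b]).mean()
    ss_between = 10 * (a.mean() - grand) ** 2 + 10 * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    f_manual = (ss_between / 1) / (ss_within / 18)
    assert stat == pytest.approx(f_manual)
    assert p < 0.01


def test_groups_need_two_values():
    with pytest.raises(ValueError):
        compare_groups([1.0], [2.0, 3.0])
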