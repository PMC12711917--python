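"""Binding-model fits: Hill, ligand-depletion isotherm, EC50 logistic."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from calmlobe import synth
from calmlobe.fits import (
    AffinityProfile,
    IsothermSeries,
    TitrationCurve,
    anisotropy_from_intensities,
    build_affinity_profile,
    compare_to_wt,
    ec50_model,
    fit_ec50,
    fit_hill,
    fit_stoichiometric,
    hill_model,
    stoich_model,
    stoichiometric_bound_fraction,
)

CA_GRID = np.logspace(np.log10(40e-9), np.log10(8e-3), 16)


# ---------------------------------------------------------------------------
# Hill


def test_hill_noiseless_recovery():
    fi = hill_model(CA_GRID, 2.0e-6, 2.0, 100.0, 10.0)
    fit = fit_hill(TitrationCurve(CA_GRID, fi))
    assert fit.kd_app == pytest.approx(2.0e-6, rel=1e-3)
    assert fit.h == pytest.approx(2.0, rel=1e-3)
    assert fit.fi_span == pytest.approx(100.0, rel=1e-3)
    assert fit.fi_initial == pytest.approx(10.0, rel=1e-3)
    assert fit.converged


def test_hill_midpoint_identity():
    kd = 5e-7
    assert hill_model(kd, kd, 1.7, 80.0, 5.0) == pytest.approx(5.0 + 40.0)


def test_hill_ratio_recovery_at_one_percent_noise():
    """A 1.9-fold affinity change between two variants is recovered within
    +/-0.1 from 16-point curves at 1% multiplicative noise (10 replicates)."""
    ratios = []
    for seed in range(10):
        wt, _ = synth.gen_titration(seed, kd_app=2.0e-6, noise=0.01, n_replicates=1)
        var, _ = synth.gen_titration(1000 + seed, kd_app=3.8e-6, noise=0.01,
                                     n_replicates=1)
        ratios.append(fit_hill(var[0]).kd_app / fit_hill(wt[0]).kd_app)
    assert np.median(ratios) == pytest.approx(1.9, abs=0.1)


def test_hill_h1_equals_langmuir():
    """On noiseless hyperbolic (h=1) data the free Hill fit returns the
    Langmuir isotherm parameters."""
    fi = hill_model(CA_GRID, 1e-6, 1.0, 50.0, 2.0)
    fit = fit_hill(TitrationCurve(CA_GRID, fi))
    assert fit.h == pytest.approx(1.0, abs=1e-4)
    assert fit.kd_app == pytest.approx(1e-6, rel=1e-4)


def test_hill_rejects_thin_curves():
    with pytest.raises(ValueError):
        fit_hill(TitrationCurve(np.array([1e-6, 2e-6, 3e-6, 4e-6, 5e-6]),
                                np.ones(5)))


def test_hill_flags_kd_outside_range():
    ca = np.logspace(-6, -3, 10)
    fi = hill_model(ca, 1e-9, 1.0, 10.0, 0.0)  # saturated everywhere
    fit = fit_hill(TitrationCurve(ca, fi))
    assert not fit.converged or "kd-outside-data-range" in fit.flags


# ---------------------------------------------------------------------------
# stoichiometric isotherm


def test_stoich_zero_cam_gives_initial():
    assert stoich_model(0.0, 50e-9, 0.2, 0.05, 20e-9) == pytest.approx(0.05)


def test_stoich_tight_binding_limit():
    # K_D -> 0 with CaM >= IQ: everything bound
    assert stoich_model(40e-9, 1e-15, 0.2, 0.05, 20e-9) == pytest.approx(0.25, rel=1e-4)


def test_stoich_bound_fraction_physical_root():
    rng = np.random.default_rng(0)
    for _ in range(200):
        kd = 10.0 ** rng.uniform(-11, -5)
        iq = 10.0 ** rng.uniform(-9, -7)
        cam = 10.0 ** rng.uniform(-11, -4)
        frac = stoichiometric_bound_fraction(cam, kd, iq)
        assert 0.0 <= frac <= min(cam, iq) / iq + 1e-12


def test_stoich_noiseless_recovery_on_plate_geometry():
    cam = synth.plate_dilution_series(22.7e-6 * 3 / 68)
    fa = stoich_model(cam, 50e-9, 0.15, 0.05, 20e-9)
    fit = fit_stoichiometric(IsothermSeries(cam, fa, 20e-9, 200e-9))
    assert fit.kd == pytest.approx(50e-9, rel=0.01)
    assert fit.converged


def test_stoich_flags_unresolvably_tight_kd():
    cam = synth.plate_dilution_series(22.7e-6 * 3 / 68)
    fa = stoich_model(cam, 1e-14, 0.15, 0.05, 20e-9)
    fit = fit_stoichiometric(IsothermSeries(cam, fa, 20e-9, 400e-6))
    assert "tighter-than-resolvable-at-this-iq" in fit.flags
    assert not fit.converged


# ---------------------------------------------------------------------------
# affinity profile + EC50


def _plate_fits(seed=0, noise=0.0, **kw):
    series, truth = synth.gen_iq_plate(seed, noise=noise, **kw)
    return [fit_stoichiometric(s) for s in series], truth


def test_profile_from_eight_levels():
    fits, _ = _plate_fits()
    prof = build_affinity_profile(fits, "WT")
    assert prof.log_free_ca.size == 8
    assert np.all(np.diff(prof.log_free_ca) > 0)


def test_profile_excludes_flagged_fits():
    fits, _ = _plate_fits()
    from dataclasses import replace

    broken = [replace(fits[0], converged=False, flags=("no-convergence",))] + fits[1:]
    prof = build_affinity_profile(broken)
    assert prof.log_free_ca.size == 7
    assert len(prof.excluded) == 1


def test_profile_needs_four_points():
    fits, _ = _plate_fits()
    with pytest.raises(ValueError):
        build_affinity_profile(fits[:3])


def test_flat_profile_fits_zero_span():
    x = np.linspace(-8, -4, 8)
    prof = AffinityProfile(x, np.full(8, -7.0), np.full(8, np.nan))
    fit = fit_ec50(prof)
    assert abs(fit.log_kd_span) < 1e-6


def test_ec50_midpoint_identity():
    y = ec50_model(math.log10(3e-7), math.log10(3e-7), 2.0, -4.0, -5.0)
    assert y == pytest.approx(-5.0 - 2.0)


def test_ec50_noiseless_recovery():
    fits, truth = _plate_fits()
    fit = fit_ec50(build_affinity_profile(fits))
    assert fit.ec50 == pytest.approx(10 ** truth["log10_ec50"], rel=0.005)
    assert fit.slope == pytest.approx(truth["slope"], rel=0.005)
    assert fit.log_kd_span == pytest.approx(truth["log_kd_span"], rel=0.005)


def test_ec50_shift_direction_always_recovered():
    """Two profiles with EC50 1.5-fold apart: the fitted shift has the
    correct sign in 100/100 replicates at 5% noise on log K_D."""
    rng = np.random.default_rng(11)
    x = np.linspace(math.log10(3e-9), math.log10(400e-6), 8)
    base = ec50_model(x, math.log10(300e-9), 2.0, -4.2, math.log10(5e-6))
    shifted = ec50_model(x, math.log10(450e-9), 2.0, -4.2, math.log10(5e-6))
    sd = 0.05 / math.log(10)   # 5% multiplicative noise on K_D, in log10
    correct = 0
    for _ in range(100):
        p1 = AffinityProfile(x, base + sd * rng.standard_normal(8),
                             np.full(8, np.nan))
        p2 = AffinityProfile(x, shifted + sd * rng.standard_normal(8),
                             np.full(8, np.nan))
        if fit_ec50(p2).ec50 > fit_ec50(p1).ec50:
            correct += 1
    assert correct == 100


def test_ec50_profile_span_exceeds_four_logs():
    fits, _ = _plate_fits()
    prof = build_affinity_profile(fits)
    assert prof.log_kd.max() - prof.log_kd.min() > 4.0


# ---------------------------------------------------------------------------
# anisotropy


@pytest.mark.parametrize(
    "ipar,iperp,g,expected",
    [(1.0, 1.0, 1.0, 0.0), (1.0, 0.0, 0.99, 1.0),
     (2.0, 1.0, 0.99, (2.0 - 0.99) / (2.0 + 1.98))],
)
def test_anisotropy_values(ipar, iperp, g, expected):
    assert anisotropy_from_intensities(ipar, iperp, g) == pytest.approx(expected)


def test_anisotropy_rejects_nonpositive_denominator():
    with pytest.raises(ValueError):
        anisotropy_from_intensities(-3.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# variant comparisons


def test_compare_to_wt_identical_groups():
    groups = {"WT": [1.0, 1.1, 0.9, 1.0], "V1": [1.0, 1.1, 0.9, 1.0]}
    res = compare_to_wt(groups)
    assert all(p > 0.9 for p in res.p_adjusted)


def test_compare_to_wt_two_groups_equals_t_test():
    rng = np.random.default_rng(2)
    wt = np.exp(rng.normal(0, 0.1, 6))
    v = np.exp(rng.normal(0.5, 0.1, 6))
    res = compare_to_wt({"WT": wt, "V": v})
    t_p = sps.ttest_ind(np.log10(v), np.log10(wt), equal_var=True).pvalue
    assert res.p_adjusted[0] == pytest.approx(t_p, rel=1e-4)


def test_compare_to_wt_power_for_1p9_fold_shift():
    """n=6/group, 10% lognormal noise, 1.9x K_D shift: > 80% rejections."""
    rng = np.random.default_rng(3)
    rejected = 0
    n_sims = 500
    for _ in range(n_sims):
        wt = 2e-6 * np.exp(0.1 * rng.standard_normal(6))
        var = 3.8e-6 * np.exp(0.1 * rng.standard_normal(6))
        null = 2e-6 * np.exp(0.1 * rng.standard_normal(6))
        res = compare_to_wt({"WT": wt, "shifted": var, "null": null})
        p = dict(zip(res.labels, res.p_adjusted))
        if p["shifted"] < 0.05:
            rejected += 1
    assert rejected / n_sims > 0.8


def test_compare_to_wt_validation():
    with pytest.raises(ValueError, match="WT"):
        compare_to_wt({"A": [1, 2, 3]})
    with pytest.raises(ValueError, match="nonpositive"):
        compare_to_wt({"WT": [1.0, 2.0], "V": [0.0, 1.0]})
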