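"""Baseline/phase processing, Voigt-derivative fitting, descriptors."""

import numpy as np
import pytest

from cwesr.direct_propagation import Spectrum
from cwesr.lineshape_fit import (
    VoigtLineParams,
    baseline_correct,
    collective_voigt_fit,
    default_baseline_intervals,
    descriptors,
    fit_voigt_line,
    integrate_to_absorption,
    lorentzian_width_to_t2,
    phase_correct,
    synth_derivative_spectrum,
    t2_to_lorentzian_width,
    voigt,
    voigt_derivative,
)

X = np.linspace(-6.0, 6.0, 8192)


# ----------------------------------------------------------------------
# Voigt evaluation
# ----------------------------------------------------------------------
def test_voigt_limits_and_area():
    # Lorentzian limit
    pl = VoigtLineParams(0.0, 200.0, 0.0, 1.0)
    yl = voigt(X, pl)
    ref = (0.1 / np.pi) / (X**2 + 0.1**2)  # HWHM 0.1 mT
    assert np.abs(yl - ref).max() < 1e-10 * ref.max()
    # Gaussian limit
    pg = VoigtLineParams(0.0, 0.0, 200.0, 1.0)
    sigma = 0.2 / (2 * np.sqrt(2 * np.log(2)))
    refg = np.exp(-0.5 * (X / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    assert np.abs(voigt(X, pg) - refg).max() < 1e-9 * refg.max()
    # unit area (Lorentzian tails leak ~(2/pi)(gamma/6) outside the window)
    assert np.trapezoid(voigt(X, pg), X) == pytest.approx(1.0, abs=2e-4)
    for p in (pl, VoigtLineParams(0.0, 100.0, 100.0, 1.0)):
        gamma = p.lorentz_fwhm_ut * 1e-3 / 2.0
        leak = 2.0 / np.pi * gamma / 6.0
        assert np.trapezoid(voigt(X, p), X) == pytest.approx(1.0 - leak,
                                                             abs=1e-3)


def test_voigt_derivative_consistent_with_finite_difference():
    p = VoigtLineParams(0.3, 80.0, 150.0, 2.5)
    num = np.gradient(voigt(X, p), X)
    ana = voigt_derivative(X, p)
    assert np.abs(num - ana).max() < 1e-3 * np.abs(ana).max()


# ----------------------------------------------------------------------
# processing
# ----------------------------------------------------------------------
def _narrow_three_lines(center_scale=1.0):
    lines = [VoigtLineParams(-1.63 * center_scale, 40, 126, 1.0),
             VoigtLineParams(0.0, 40, 126, 1.0),
             VoigtLineParams(1.63 * center_scale, 80, 126, 1.0)]
    return synth_derivative_spectrum(X, lines)


def test_baseline_removes_linear_ramp():
    """Gaussian lines vanish in the wings, so a ramp is removed exactly."""
    s = _narrow_three_lines()
    ramped = s.copy_with(s.intensity + 0.25 * X - 0.4)
    out = baseline_correct(ramped)
    # wings carry only the (tiny) Lorentzian tails; compare on clean input
    clean = baseline_correct(s)
    resid = out.intensity - clean.intensity
    assert np.abs(resid).max() < 1e-10 * np.abs(s.intensity).max()


def test_baseline_flat_wings_unchanged():
    gauss_only = synth_derivative_spectrum(
        X, [VoigtLineParams(0.0, 0.0, 200.0, 1.0)]
    )
    out = baseline_correct(gauss_only)
    assert np.abs(out.intensity - gauss_only.intensity).max() < 1e-12 * np.abs(
        gauss_only.intensity
    ).max()


def test_baseline_interval_defaults():
    assert default_baseline_intervals("14N") == [(-6.0, -3.5), (3.5, 6.0)]
    assert default_baseline_intervals("15N") == [(-5.0, -3.5), (3.5, 5.0)]
    with pytest.raises(ValueError, match="fewer"):
        baseline_correct(_narrow_three_lines(), intervals=[(100.0, 101.0)])


def test_phase_correct_rotation_composition():
    s = _narrow_three_lines()
    out = phase_correct(phase_correct(s, 90.0), -90.0)
    core = np.abs(X) < 4.0  # away from Hilbert edge effects
    assert np.abs(out.intensity[core] - s.intensity[core]).max() < 1e-6 * np.abs(
        s.intensity
    ).max()
    assert np.array_equal(phase_correct(s, 0.0).intensity, s.intensity)


def test_phase_correct_recovers_absorption():
    """A dispersion-mixed Lorentzian is rephased to pure absorption."""
    gamma = 0.05
    absorption = (gamma / np.pi) / (X**2 + gamma**2)
    dispersion = (X / np.pi) / (X**2 + gamma**2)
    phi = np.deg2rad(-25.0)
    mixed = np.cos(phi) * absorption - np.sin(phi) * dispersion
    s = Spectrum(X, mixed, "absorption")
    out = phase_correct(s, -25.0)
    core = np.abs(X) < 2.0  # away from the truncated dispersion tails
    assert np.abs(out.intensity[core] - absorption[core]).max() < 5e-3 * absorption.max()


def test_integrate_derivative_of_gaussian():
    sigma = 0.5
    g = np.exp(-0.5 * (X / sigma) ** 2)
    s = Spectrum(X, np.gradient(g, X), "first_derivative")
    out = integrate_to_absorption(s)
    rms = np.sqrt(np.mean((out.intensity - g) ** 2)) / g.max()
    assert rms < 0.005
    zero = integrate_to_absorption(Spectrum(X, np.zeros_like(X),
                                            "first_derivative"))
    assert np.abs(zero.intensity).max() == 0.0


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
@pytest.mark.parametrize("lor,gau", [(50.0, 100.0), (100.0, 0.0),
                                     (0.0, 100.0), (13.5, 126.0)])
def test_fit_voigt_line_recovery(lor, gau):
    s = synth_derivative_spectrum(X, [VoigtLineParams(0.1, lor, gau, 1.0)])
    fit, rms = fit_voigt_line(s, (-1.0, 1.2))
    assert fit.center_mT == pytest.approx(0.1, abs=1e-4)
    assert fit.lorentz_fwhm_ut == pytest.approx(lor, abs=max(0.01 * lor, 0.5))
    assert fit.gauss_fwhm_ut == pytest.approx(gau, abs=max(0.01 * gau, 0.5))
    assert fit.amplitude == pytest.approx(1.0, rel=0.01)


def test_fit_invariance_under_scaling_and_translation():
    s = synth_derivative_spectrum(X, [VoigtLineParams(0.0, 60.0, 90.0, 1.0)])
    fit0, _ = fit_voigt_line(s, (-1.0, 1.0))
    scaled = s.copy_with(s.intensity * 37.0)
    fit1, _ = fit_voigt_line(scaled, (-1.0, 1.0))
    assert fit1.lorentz_fwhm_ut == pytest.approx(fit0.lorentz_fwhm_ut, rel=1e-6)
    assert fit1.amplitude == pytest.approx(37.0 * fit0.amplitude, rel=1e-6)
    shifted = Spectrum(X + 2.0, s.intensity, "first_derivative")
    fit2, _ = fit_voigt_line(shifted, (1.0, 3.0))
    assert fit2.center_mT == pytest.approx(2.0, abs=1e-4)
    assert fit2.lorentz_fwhm_ut == pytest.approx(fit0.lorentz_fwhm_ut, rel=1e-4)


def test_fit_with_noise_snr50():
    rng = np.random.default_rng(99)
    clean = synth_derivative_spectrum(X, [VoigtLineParams(0.0, 60.0, 120.0, 1.0)])
    noise = rng.normal(0.0, clean.intensity.max() / 50.0, X.size)
    noisy = clean.copy_with(clean.intensity + noise)
    fit, _ = fit_voigt_line(noisy, (-1.0, 1.0))
    assert fit.lorentz_fwhm_ut + fit.gauss_fwhm_ut == pytest.approx(
        180.0, rel=0.10
    )


def test_fit_rejects_region_without_extremum_pair():
    s = synth_derivative_spectrum(X, [VoigtLineParams(0.0, 60.0, 90.0, 1.0)])
    with pytest.raises(ValueError, match="extremum"):
        fit_voigt_line(s, (0.5, 2.0))  # only the falling flank


def test_lorentzian_peak_to_peak_relation():
    """Pure derivative Lorentzian: Delta_pp = FWHM / sqrt(3)."""
    s = synth_derivative_spectrum(X, [VoigtLineParams(0.0, 120.0, 0.0, 1.0)])
    desc, _ = descriptors(s, centers_mT=[0.0], a_iso_mT=1.5)
    assert desc.delta_pp_ut[0] == pytest.approx(120.0 / np.sqrt(3), rel=0.005)


# ----------------------------------------------------------------------
# descriptors
# ----------------------------------------------------------------------
def test_descriptors_identical_lines_ratio_one():
    lines = [VoigtLineParams(c, 50, 120, 1.0) for c in (-1.63, 0.0, 1.63)]
    s = synth_derivative_spectrum(X, lines)
    desc, fits = descriptors(s, n_lines=3, a_iso_mT=1.63)
    assert desc.labels == ["+1", "0", "-1"]
    assert desc.ratio == pytest.approx(1.0, abs=0.01)
    assert np.ptp(desc.delta_pp_ut) < 0.01 * desc.delta_pp_ut.mean()


def test_descriptors_width_doubled_amplitude_quartered():
    """Equal-area derivative Lorentzians: amplitude ~ area / width^2."""
    lines = [VoigtLineParams(-2.0, 60.0, 0.0, 1.0),
             VoigtLineParams(2.0, 120.0, 0.0, 1.0)]
    s = synth_derivative_spectrum(X, lines)
    desc, _ = descriptors(s, centers_mT=[-2.0, 2.0], a_iso_mT=4.0)
    assert desc.h_pp[0] / desc.h_pp[1] == pytest.approx(4.0, rel=0.02)


def test_descriptors_overlap_error():
    lines = [VoigtLineParams(-0.05, 300, 300, 1.0),
             VoigtLineParams(0.05, 300, 300, 1.0)]
    s = synth_derivative_spectrum(X, lines)
    with pytest.raises(ValueError, match="overlap|extremum"):
        descriptors(s, centers_mT=[-0.05, 0.05], a_iso_mT=0.1)


# ----------------------------------------------------------------------
# collective fit and width conversion
# ----------------------------------------------------------------------
def test_collective_fit_recovers_g_and_lo2():
    centers = [-1.63, 0.0, 1.63]
    l_i = [30.0, 32.0, 35.0]
    air = synth_derivative_spectrum(
        X, [VoigtLineParams(c, l + 13.5, 126.0, 1.0) for c, l in zip(centers, l_i)]
    )
    deg = synth_derivative_spectrum(
        X, [VoigtLineParams(c, l, 126.0, 1.0) for c, l in zip(centers, l_i)]
    )
    res = collective_voigt_fit(air, deg, centers)
    assert res["gauss_fwhm_ut"] == pytest.approx(126.0, rel=0.02)
    assert res["l_o2_fwhm_ut"] == pytest.approx(13.5, rel=0.02)
    for fit, l in zip(res["lines"], l_i):
        assert fit["lorentz_fwhm_ut"] == pytest.approx(l, rel=0.02)


def test_collective_fit_identical_pair_gives_zero_lo2():
    centers = [-1.63, 0.0, 1.63]
    s = synth_derivative_spectrum(
        X, [VoigtLineParams(c, 40.0, 126.0, 1.0) for c in centers]
    )
    res = collective_voigt_fit(s, s, centers)
    assert abs(res["l_o2_fwhm_ut"]) < 1.0


def test_width_t2_conversion_and_roundtrip():
    t2 = lorentzian_width_to_t2(13.5, 2.006)
    assert t2 == pytest.approx(0.835, abs=0.01)  # the calibrated O2 value
    assert t2_to_lorentzian_width(t2, 2.006) == pytest.approx(13.5, rel=1e-12)
    # limits and errors
    assert lorentzian_width_to_t2(1e9) < 1e-7
    with pytest.raises(ValueError):
        lorentzian_width_to_t2(0.0)


def test_double_integral_conserved_by_processing():
    """The absorption integral (spin count) survives baseline correction
    and zero-phase correction."""
    s = _narrow_three_lines()
    ramped = s.copy_with(s.intensity + 0.1 * X + 0.05)
    cleaned = baseline_correct(ramped)
    a0 = integrate_to_absorption(s)
    a1 = integrate_to_absorption(cleaned)
    i0 = np.trapezoid(a0.intensity, a0.field_mT)
    i1 = np.trapezoid(a1.intensity, a1.field_mT)
    assert i1 == pytest.approx(i0, rel=0.01)
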