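"""Spectral post-processing and Voigt-derivative fitting.

A CW ESR line is modelled as a Voigt profile: the convolution of a
Lorentzian contour (homogeneous relaxation, including the contribution
of dissolved paramagnetic oxygen) with a Gaussian contour (static-field
inhomogeneity and unresolved hyperfine couplings).  First-derivative
spectra are fitted with the analytic derivative of the Voigt function,
evaluated through the Faddeeva function w(z); fit windows follow the
80% rule: each line is fitted between the leftmost point at 80% of its
maximum and the rightmost point at 80% of its minimum.

Descriptors follow the field's conventions: the peak-to-peak width
Delta_(i) is the separation between the maximum and the minimum of the
best-fit function, and the amplitude h_(i) is their intensity
difference; the asymmetry quotient h_(0)/h_(-1) compares the central and
high-field lines.  Collective fitting of an air-equilibrated / degassed
spectrum pair shares one Gaussian width G and per-line Lorentzians L_(i),
with the oxygen Lorentzian L_O2 added only to the air spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import hilbert
from scipy.special import wofz

from .constants import H_PLANCK, MU_B
from .direct_propagation import Spectrum

__all__ = [
    "VoigtLineParams",
    "DescriptorSet",
    "voigt",
    "voigt_derivative",
    "baseline_correct",
    "phase_correct",
    "integrate_to_absorption",
    "fit_voigt_line",
    "descriptors",
    "collective_voigt_fit",
    "lorentzian_width_to_t2",
    "t2_to_lorentzian_width",
    "synth_derivative_spectrum",
    "default_baseline_intervals",
]

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VoigtLineParams:
    """One spectral line: center (mT), widths (uT, FWHM), amplitude.

    ``amplitude`` multiplies the unit-area Voigt profile, so for the
    first-derivative model it is the area of the absorption line.
    """

    center_mT: float
    lorentz_fwhm_ut: float
    gauss_fwhm_ut: float
    amplitude: float

    def __post_init__(self):
        if self.lorentz_fwhm_ut < 0 or self.gauss_fwhm_ut < 0:
            raise ValueError("widths must be non-negative")


@dataclass
class DescriptorSet:
    """Peak-to-peak widths and amplitudes per line, low field first.

    For 14N the line order is (m_I = +1, 0, -1): low-field, central,
    high-field.  ``ratio`` is h_(0)/h_(-1).
    """

    labels: list
    delta_pp_ut: np.ndarray
    h_pp: np.ndarray

    @property
    def ratio(self) -> float:
        if len(self.labels) < 2:
            raise ValueError("need at least two lines for h(0)/h(-1)")
        center = len(self.labels) // 2 if len(self.labels) % 2 else 0
        return float(self.h_pp[center] / self.h_pp[-1])


# ----------------------------------------------------------------------
# Voigt evaluation (Faddeeva based, analytic derivative)
# ----------------------------------------------------------------------
def _voigt_sig_gam(x, sigma, gamma):
    """Unit-area Voigt and its x-derivative for sigma, gamma in x units.

    The pure-Lorentzian limit is evaluated analytically: wofz loses all
    relative precision once sigma is tiny compared to gamma.
    """
    sigma = float(sigma)
    gamma = float(gamma)
    if sigma <= max(1e-4 * gamma, 1e-9):
        g = max(gamma, 1e-9)
        denom = x * x + g * g
        v = (g / np.pi) / denom
        dv = -(2.0 * g / np.pi) * x / denom**2
        return v, dv
    z = (x + 1j * gamma) / (sigma * _SQRT2)
    w = wofz(z)
    v = w.real / (sigma * _SQRT2PI)
    # w'(z) = -2 z w(z) + 2i/sqrt(pi)
    wprime = -2.0 * z * w + 2.0j / np.sqrt(np.pi)
    dv = wprime.real / (sigma * _SQRT2PI) / (sigma * _SQRT2)
    return v, dv


def voigt(x_mT, params: VoigtLineParams) -> np.ndarray:
    """Absorption-mode Voigt line on a field axis in mT."""
    sigma = params.gauss_fwhm_ut * 1e-3 * _FWHM_TO_SIGMA
    gamma = params.lorentz_fwhm_ut * 1e-3 / 2.0
    v, _ = _voigt_sig_gam(np.asarray(x_mT, float) - params.center_mT, sigma, gamma)
    return params.amplitude * v


def voigt_derivative(x_mT, params: VoigtLineParams) -> np.ndarray:
    """First derivative of the Voigt line (the CW detection mode)."""
    sigma = params.gauss_fwhm_ut * 1e-3 * _FWHM_TO_SIGMA
    gamma = params.lorentz_fwhm_ut * 1e-3 / 2.0
    _, dv = _voigt_sig_gam(np.asarray(x_mT, float) - params.center_mT, sigma, gamma)
    return params.amplitude * dv


def synth_derivative_spectrum(field_mT, lines) -> Spectrum:
    """Sum of first-derivative Voigt lines (synthesis helper)."""
    field_mT = np.asarray(field_mT, float)
    total = np.zeros_like(field_mT)
    for ln in lines:
        total += voigt_derivative(field_mT, ln)
    return Spectrum(field_mT=field_mT, intensity=total, mode="first_derivative")


# ----------------------------------------------------------------------
# processing
# ----------------------------------------------------------------------
def default_baseline_intervals(isotope: str = "14N"):
    """Wing intervals used for the linear baseline: [-6.0, -3.5] and
    [3.5, 6.0] mT for 14N samples, [-5.0, -3.5] and [3.5, 5.0] mT for
    15N samples (narrower sweep)."""
    if isotope == "15N":
        return [(-5.0, -3.5), (3.5, 5.0)]
    return [(-6.0, -3.5), (3.5, 6.0)]


def baseline_correct(spectrum: Spectrum, intervals=None) -> Spectrum:
    """Subtract a straight line fitted over the wing intervals."""
    if intervals is None:
        intervals = default_baseline_intervals()
    x, y = spectrum.field_mT, spectrum.intensity
    mask = np.zeros(x.size, dtype=bool)
    for lo, hi in intervals:
        mask |= (x >= lo) & (x <= hi)
    if mask.sum() < 2:
        raise ValueError("baseline intervals cover fewer than 2 points")
    coeff = np.polyfit(x[mask], y[mask], 1)
    return spectrum.copy_with(y - np.polyval(coeff, x))


def phase_correct(spectrum: Spectrum, angle_deg: float) -> Spectrum:
    """Mix in the Hilbert-transform quadrature component.

    output = cos(phi) * signal + sin(phi) * quadrature, the standard
    phasing of a detected spectrum recorded slightly off quadrature.
    """
    phi = np.deg2rad(angle_deg)
    if phi == 0.0:
        return spectrum.copy_with(spectrum.intensity.copy())
    quad = np.imag(hilbert(spectrum.intensity))
    return spectrum.copy_with(
        np.cos(phi) * spectrum.intensity + np.sin(phi) * quad
    )


def integrate_to_absorption(spectrum: Spectrum, intervals=None) -> Spectrum:
    """Cumulative trapezoid of a first-derivative spectrum, wing-zeroed."""
    if spectrum.mode != "first_derivative":
        raise ValueError("input must be a first-derivative spectrum")
    from scipy.integrate import cumulative_trapezoid

    x = spectrum.field_mT
    absorb = cumulative_trapezoid(spectrum.intensity, x, initial=0.0)
    if intervals is None:
        intervals = default_baseline_intervals()
    mask = np.zeros(x.size, dtype=bool)
    for lo, hi in intervals:
        mask |= (x >= lo) & (x <= hi)
    if mask.any():
        absorb = absorb - absorb[mask].mean()
    return Spectrum(field_mT=x.copy(), intensity=absorb, mode="absorption")


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
def _fit_window_80(x, y):
    """The 80% rule: from the leftmost point at 80% of the maximum to the
    rightmost point at 80% of the minimum (applied to the raw data)."""
    imax, imin = int(np.argmax(y)), int(np.argmin(y))
    if imax >= imin:
        raise ValueError(
            "line region does not contain a (max, min) extremum pair in "
            "field order; not a first-derivative line"
        )
    up, dn = 0.8 * y[imax], 0.8 * y[imin]
    left_candidates = np.flatnonzero(y[: imax + 1] >= up)
    right_candidates = np.flatnonzero(y[imin:] <= dn) + imin
    left = int(left_candidates.min()) if left_candidates.size else imax
    right = int(right_candidates.max()) if right_candidates.size else imin
    return left, right


def _pack(p: VoigtLineParams):
    return [p.center_mT, p.lorentz_fwhm_ut, p.gauss_fwhm_ut, p.amplitude]


def fit_voigt_line(
    spectrum: Spectrum,
    region_mT: tuple[float, float],
    initial: VoigtLineParams | None = None,
):
    """Least-squares Voigt-derivative fit of one line.

    The fit runs over the 80% window only.  Returns
    ``(VoigtLineParams, rms_residual)``.
    """
    x, y = spectrum.field_mT, spectrum.intensity
    sel = (x >= region_mT[0]) & (x <= region_mT[1])
    if sel.sum() < 8:
        raise ValueError("line region contains too few points")
    xr, yr = x[sel], y[sel]
    left, right = _fit_window_80(xr, yr)
    xw, yw = xr[left : right + 1], yr[left : right + 1]

    imax, imin = int(np.argmax(yr)), int(np.argmin(yr))
    pp_mT = max(abs(xr[imin] - xr[imax]), 2.0 * (xr[1] - xr[0]))
    center = 0.5 * (xr[imax] + xr[imin])
    h = yr[imax] - yr[imin]

    def amp_for(lor_ut):
        # derivative-Lorentzian peak-to-peak height for unit area
        return h / (np.sqrt(3.0) * 9.0 / (4.0 * np.pi * (lor_ut * 1e-3) ** 2))

    if initial is not None:
        starts = [_pack(initial)]
    else:
        # peak-to-peak separation of the pure limits: Lorentzian
        # FWHM = sqrt(3) pp, Gaussian FWHM = (2 sqrt(2 ln 2) / 2) pp
        lor = np.sqrt(3.0) * pp_mT * 1e3
        gau = np.sqrt(2.0 * np.log(2.0)) * pp_mT * 1e3
        # G and L trade off inside the narrow 80% window: multi-start
        # from the two pure limits and a mixed seed, keep the best fit
        starts = [
            [center, lor, 1e-3 * lor, amp_for(lor)],
            [center, 1e-3 * lor, gau, amp_for(lor)],
            [center, 0.6 * lor, 0.6 * gau, amp_for(lor)],
        ]

    def resid(p):
        params = VoigtLineParams(p[0], abs(p[1]), abs(p[2]), p[3])
        return voigt_derivative(xw, params) - yw

    best = None
    for p0 in starts:
        scale = [max(abs(p0[0]), 0.1), max(abs(p0[1]), 10.0),
                 max(abs(p0[2]), 10.0), max(abs(p0[3]), 1e-30)]
        sol = least_squares(resid, p0, x_scale=scale, method="trf",
                            max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    p = best.x
    params = VoigtLineParams(float(p[0]), float(abs(p[1])), float(abs(p[2])),
                             float(p[3]))
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return params, rms


def _line_extrema(params: VoigtLineParams):
    """Positions/values of the max and min of the fitted derivative."""
    width_mT = max(params.lorentz_fwhm_ut + params.gauss_fwhm_ut, 1.0) * 1e-3
    x = params.center_mT + np.linspace(-3.0 * width_mT, 3.0 * width_mT, 4001)
    y = voigt_derivative(x, params)

    def refine(i):
        if 0 < i < x.size - 1:
            # parabolic interpolation through the three nearest samples
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            if denom != 0.0:
                shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
                h = x[1] - x[0]
                return (x[i] + shift * h,
                        y[i] - 0.25 * (y[i - 1] - y[i + 1]) * shift)
        return x[i], y[i]

    return refine(int(np.argmax(y))), refine(int(np.argmin(y)))


def descriptors(
    spectrum: Spectrum,
    n_lines: int = 3,
    a_iso_mT: float | None = None,
    centers_mT=None,
) -> tuple[DescriptorSet, list]:
    """Delta_(i) and h_(i) per line from per-line Voigt-derivative fits.

    Line centers are seeded at the first-order resonance offsets (0 and
    +/- the isotropic hyperfine splitting in field units) unless given
    explicitly.  Widths and amplitudes are measured on the best-fit
    functions, not on raw samples.
    """
    x = spectrum.field_mT
    if centers_mT is None:
        if a_iso_mT is None:
            raise ValueError("supply either centers_mT or a_iso_mT")
        if n_lines == 3:
            centers_mT = [-a_iso_mT, 0.0, a_iso_mT]
            labels = ["+1", "0", "-1"]
        else:
            centers_mT = [-a_iso_mT / 2.0, a_iso_mT / 2.0]
            labels = ["+1/2", "-1/2"]
    else:
        labels = [str(i) for i in range(len(centers_mT))]
        if a_iso_mT is None:
            a_iso_mT = (
                np.diff(sorted(centers_mT)).mean() if len(centers_mT) > 1 else 1.0
            )

    half = 0.5 * a_iso_mT
    fits, widths, heights = [], [], []
    for c in centers_mT:
        params, _ = fit_voigt_line(spectrum, (c - half, c + half))
        (xmax, ymax), (xmin, ymin) = _line_extrema(params)
        width_ut = abs(xmin - xmax) * 1e3
        height = ymax - ymin
        fits.append(params)
        widths.append(width_ut)
        heights.append(height)

    # unresolved overlap guard: fitted centers must stay ordered and
    # separated by more than their mean width
    centers_fit = [p.center_mT for p in fits]
    for a, b, wa, wb in zip(centers_fit, centers_fit[1:], widths, widths[1:]):
        if (b - a) * 1e3 < 0.5 * (wa + wb):
            raise ValueError(
                f"lines at {a:.3f} and {b:.3f} mT overlap beyond resolution"
            )
    if n_lines == 3:
        labels = ["+1", "0", "-1"]
    return (
        DescriptorSet(labels=labels, delta_pp_ut=np.asarray(widths),
                      h_pp=np.asarray(heights)),
        fits,
    )


def collective_voigt_fit(
    spectrum_air: Spectrum,
    spectrum_degassed: Spectrum,
    centers_mT,
    window_mT: float | None = None,
):
    """Joint fit of an air/degassed pair with shared G and per-line L_(i).

    Air-spectrum lines carry Lorentzian widths L_(i) + L_O2; degassed
    lines carry L_(i).  Both spectra share the Gaussian width G, the line
    centers, and per-line amplitudes are fitted per spectrum.  Returns a
    dict with G, L_O2, per-line Lorentzians and the fitted lines.
    """
    centers_mT = list(centers_mT)
    n = len(centers_mT)
    if n < 1:
        raise ValueError("need at least one line")
    if window_mT is None:
        window_mT = (
            0.5 * float(np.diff(sorted(centers_mT)).mean()) if n > 1 else 1.0
        )

    def window_data(spectrum):
        xs, ys = [], []
        for c in centers_mT:
            sel = (spectrum.field_mT >= c - window_mT) & (
                spectrum.field_mT <= c + window_mT
            )
            xr, yr = spectrum.field_mT[sel], spectrum.intensity[sel]
            left, right = _fit_window_80(xr, yr)
            xs.append(xr[left : right + 1])
            ys.append(yr[left : right + 1])
        return xs, ys

    xa, ya = window_data(spectrum_air)
    xd, yd = window_data(spectrum_degassed)

    # initial values from independent line fits of the degassed spectrum
    init_lines = []
    for c in centers_mT:
        p, _ = fit_voigt_line(spectrum_degassed, (c - window_mT, c + window_mT))
        init_lines.append(p)
    g0 = float(np.mean([p.gauss_fwhm_ut for p in init_lines]))

    # parameter vector: [G, L_O2, (center_i, L_i, amp_air_i, amp_deg_i) x n]
    p0 = [max(g0, 5.0), 10.0]
    for p in init_lines:
        p0 += [p.center_mT, max(p.lorentz_fwhm_ut, 5.0), p.amplitude, p.amplitude]

    def unpack(p):
        g, lo2 = abs(p[0]), abs(p[1])
        lines = []
        for i in range(n):
            c, li, aa, ad = p[2 + 4 * i : 6 + 4 * i]
            lines.append((c, abs(li), aa, ad))
        return g, lo2, lines

    def resid(p):
        g, lo2, lines = unpack(p)
        out = []
        for i, (c, li, aa, ad) in enumerate(lines):
            out.append(
                voigt_derivative(xa[i], VoigtLineParams(c, li + lo2, g, aa))
                - ya[i]
            )
            out.append(
                voigt_derivative(xd[i], VoigtLineParams(c, li, g, ad)) - yd[i]
            )
        return np.concatenate(out)

    sol = least_squares(resid, p0, method="trf", max_nfev=5000)
    g, lo2, lines = unpack(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    # identifiability guard: L_O2 is determined by the air/degassed width
    # difference; flag when the fit collapses
    jac_rank = np.linalg.matrix_rank(sol.jac)
    flagged = jac_rank < sol.x.size
    return {
        "gauss_fwhm_ut": g,
        "l_o2_fwhm_ut": lo2,
        "lines": [
            {
                "center_mT": c,
                "lorentz_fwhm_ut": li,
                "amp_air": aa,
                "amp_degassed": ad,
            }
            for (c, li, aa, ad) in lines
        ],
        "rms_residual": rms,
        "l_o2_unidentifiable": bool(flagged),
    }


# ----------------------------------------------------------------------
# width <-> T2 conversion
# ----------------------------------------------------------------------
def lorentzian_width_to_t2(fwhm_field_ut: float, g_iso: float = 2.006) -> float:
    """T2 (us) from a Lorentzian FWHM on the field axis (uT).

    A Lorentzian of transverse relaxation time T2 has angular-frequency
    FWHM 2/T2; converting through delta_omega = g mu_B delta_B / hbar
    gives T2 = h / (pi g mu_B delta_B_FWHM).  The calibrated oxygen
    width of 13.5 uT corresponds to T2_O2 ~ 0.83 us.
    """
    if fwhm_field_ut <= 0:
        raise ValueError("width must be positive")
    return H_PLANCK / (np.pi * g_iso * MU_B * fwhm_field_ut * 1e-6) * 1e6


def t2_to_lorentzian_width(t2_us: float, g_iso: float = 2.006) -> float:
    """Inverse of :func:`lorentzian_width_to_t2` (uT from us)."""
    if t2_us <= 0:
        raise ValueError("T2 must be positive")
    return H_PLANCK / (np.pi * g_iso * MU_B * t2_us * 1e-6) * 1e6
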