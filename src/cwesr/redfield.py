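"""Redfield-theory lineshape calculation from orientational statistics.

Second-order (BWR) relaxation theory: the anisotropic Zeeman and
hyperfine couplings fluctuate through the trajectory rotation R(t); their
laboratory-frame correlation functions g(tau) are converted to one-sided
spectral densities J(omega) and assembled into a Liouville-space
relaxation supermatrix by the double-commutator rule

    R sigma = - sum_{q q'} sum_w J_{q'q}(w) [V_q, [V_{q'}^{(w)}, sigma]]

where the V_q are the fixed spin operators multiplying each fluctuating
scalar coefficient (the "channels": S_j for the Zeeman anisotropy, S_j I_k
for the hyperfine anisotropy) and V^{(w)} are their eigenoperator
components with respect to the static Hamiltonian.  Cross terms between
Zeeman and hyperfine channels (the TROSY-like interference that makes one
line of a 15N doublet sharp and the other broad) can be switched off.

Validity requires tau_c << T2e (motional correlation time much shorter
than the electron coherence lifetime); :func:`validity_report` grades the
ratio.  The theory is exact in the extreme-narrowing limit and degrades
gracefully as tau_c approaches the tumbling time of a small protein
(~3 ns), which is where direct propagation remains the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .constants import HBAR, MU_B
from .direct_propagation import (
    FID,
    BroadeningModel,
    ModulationConfig,
    Spectrum,
    absorption_spectrum,
    apply_broadening,
    gaussian_convolve,
    modulated_spectrum,
)
from .spin_core import FieldConfig, OperatorSet, SpinSystemSpec, lab_tensors
from .trajectory_ops import OrientationTrajectory

__all__ = [
    "SpectralDensitySet",
    "RedfieldModel",
    "correlation_functions",
    "build_redfield",
    "redfield_fid",
    "redfield_spectrum",
    "validity_report",
    "fast_motion_linewidths",
    "isotropic_pair_amplitude",
]

#: channel layout: 3 Zeeman channels (S_x, S_y, S_z paired with the z
#: column of the lab anisotropic Zeeman tensor) followed by 9 hyperfine
#: channels (S_j I_k paired with lab tensor element (j, k)).
N_CHANNELS = 12
CHANNEL_KINDS = ("g",) * 3 + ("A",) * 9


def _channel_series(
    spec: SpinSystemSpec, traj: OrientationTrajectory, fieldcfg: FieldConfig
) -> np.ndarray:
    """Fluctuating scalar coefficients c_q(t), shape (N, 12), rad/s."""
    g_lab, a_lab = lab_tensors(spec, traj.quats)
    zscale = MU_B * fieldcfg.B0 / HBAR
    out = np.empty((traj.n_frames, N_CHANNELS))
    out[:, :3] = zscale * g_lab[:, :, 2]
    out[:, 3:] = a_lab.reshape(traj.n_frames, 9)
    return out


def _channel_operators(ops: OperatorSet) -> list[np.ndarray]:
    vs = [ops.Sx, ops.Sy, ops.Sz]
    for j in range(3):
        for k in range(3):
            vs.append(ops.S_vec[j] @ ops.I_vec[k])
    return vs


def isotropic_pair_amplitude(t: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Equal-time isotropic-average correlation of two co-rotating
    traceless symmetric tensors:

        <T_ab U_cd> = (T:U)/10 [d_ac d_bd + d_ad d_bc - (2/3) d_ab d_cd]

    Returns the (3,3,3,3) array over (a, b, c, d).
    """
    t = np.asarray(t, float)
    u = np.asarray(u, float)
    tu = float(np.sum(t * u))
    eye = np.eye(3)
    term = (
        np.einsum("ac,bd->abcd", eye, eye)
        + np.einsum("ad,bc->abcd", eye, eye)
        - (2.0 / 3.0) * np.einsum("ab,cd->abcd", eye, eye)
    )
    return (tu / 10.0) * term


def _analytic_amplitude_matrix(spec: SpinSystemSpec, fieldcfg: FieldConfig
                               ) -> np.ndarray:
    """Channel-pair correlation amplitudes M_{qq'} for isotropic tumbling."""
    zscale = MU_B * fieldcfg.B0 / HBAR
    g = zscale * spec.g_aniso_pas
    a = spec.A_aniso_pas
    m = np.zeros((N_CHANNELS, N_CHANNELS))
    pairs = {("g", "g"): isotropic_pair_amplitude(g, g),
             ("g", "A"): isotropic_pair_amplitude(g, a),
             ("A", "A"): isotropic_pair_amplitude(a, a)}
    pairs[("A", "g")] = pairs[("g", "A")]

    def index(q):
        # channel -> tensor element (row, col)
        if q < 3:
            return "g", (q, 2)
        q -= 3
        return "A", (q // 3, q % 3)

    for q in range(N_CHANNELS):
        kq, (aq, bq) = index(q)
        for p in range(N_CHANNELS):
            kp, (ap, bp) = index(p)
            amp = pairs[(kq, kp)]
            if (kq, kp) == ("A", "g"):
                # isotropic_pair_amplitude(g, a)[g-indices, A-indices]
                m[q, p] = pairs[("g", "A")][ap, bp, aq, bq]
            else:
                m[q, p] = amp[aq, bq, ap, bp]
    return m


@dataclass
class SpectralDensitySet:
    """Channel correlation functions and their one-sided transforms.

    ``j_func(omega)`` returns the (12, 12) complex matrix
    J_{qq'}(omega) = Int_0^inf C_{qq'}(tau) exp(-i omega tau) dtau.
    ``mean_coeffs`` holds the static (mean) part of each channel, which is
    added to the static Hamiltonian when the model is built.
    """

    j_func: Callable[[float], np.ndarray]
    tau_c_ns: float
    mean_coeffs: np.ndarray
    valid: bool = True
    corr_lags_ps: np.ndarray | None = None
    corr_values: np.ndarray | None = None  # (L, 12, 12)

    def j(self, omega: float) -> np.ndarray:
        jm = self.j_func(float(omega))
        # Cauchy-Schwarz guard on cross terms at omega = 0
        return jm

    @classmethod
    def isotropic_model(
        cls, spec: SpinSystemSpec, fieldcfg: FieldConfig, tau_c_ns: float
    ) -> "SpectralDensitySet":
        """Analytic set for isotropic rotational diffusion: single
        exponential g(tau) with closed-form amplitudes."""
        m = _analytic_amplitude_matrix(spec, fieldcfg)
        tau = tau_c_ns * 1e-9

        def j_func(omega: float) -> np.ndarray:
            return m * (tau / (1.0 + 1j * omega * tau))

        return cls(j_func=j_func, tau_c_ns=tau_c_ns,
                   mean_coeffs=np.zeros(N_CHANNELS), valid=True)


def correlation_functions(
    traj: OrientationTrajectory,
    spec: SpinSystemSpec,
    fieldcfg: FieldConfig,
    max_lag_ps: float | None = None,
    corr_decimation: int = 1,
) -> SpectralDensitySet:
    """Channel auto-/cross-correlations extracted from a trajectory.

    The 12 fluctuating coefficients are correlated pairwise (FFT,
    lag-dependent normalization); the decay beyond the sampled lag range
    is extrapolated by a single exponential fitted to the trace, so the
    spectral densities have no truncation step.  Non-decaying correlation
    functions (static trajectory) set ``valid = False``.
    """
    series = _channel_series(spec, traj, fieldcfg)[::corr_decimation]
    dt_ps = traj.dt_ps * corr_decimation
    n = series.shape[0]
    mean = series.mean(axis=0)
    fluct = series - mean

    if max_lag_ps is None:
        max_lag_ps = min(0.2 * n * dt_ps, 100_000.0)
    max_lag = int(max_lag_ps / dt_ps)
    max_lag = max(2, min(max_lag, n - 2))

    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(fluct, n=nfft, axis=0)
    counts = (n - np.arange(max_lag + 1))[:, None]
    corr = np.empty((max_lag + 1, N_CHANNELS, N_CHANNELS))
    for q in range(N_CHANNELS):
        cc = np.fft.irfft(f * f[:, q:q + 1].conj(), n=nfft, axis=0)
        corr[:, q, :] = cc[: max_lag + 1] / counts
    # enforce the symmetry that holds for stationary co-rotating tensors
    corr = 0.5 * (corr + np.swapaxes(corr, 1, 2))

    lags_s = np.arange(max_lag + 1) * dt_ps * 1e-12
    trace = np.einsum("lqq->l", corr)
    trace0 = trace[0]
    valid = True
    if trace0 <= 0 or trace[-1] > 0.5 * trace0:
        valid = False
        tau_tail = np.inf
    else:
        # exponential tail from the trace decay (log-linear fit over the
        # decaying region above noise)
        rel = trace / trace0
        mask = rel > 0.05
        k = int(np.flatnonzero(mask).max()) + 1
        k = max(k, 3)
        w = np.clip(rel[:k], 1e-3, None)
        slope = np.polyfit(lags_s[:k], np.log(w), 1)[0]
        tau_tail = -1.0 / slope if slope < 0 else np.inf

    tau_c_ns = float(tau_tail * 1e9) if np.isfinite(tau_tail) else np.inf

    # truncate the sampled lag range to ~20 correlation times: beyond
    # that the estimate is statistical noise, which would otherwise
    # accumulate in the spectral-density integrals
    if np.isfinite(tau_tail):
        k_use = int(min(max_lag, np.ceil(20.0 * tau_tail * 1e12 / dt_ps)))
        k_use = max(k_use, 3)
        corr = corr[: k_use + 1]
        lags_s = lags_s[: k_use + 1]

    def j_func(omega: float) -> np.ndarray:
        phase = np.exp(-1j * omega * lags_s)
        jm = np.trapezoid(corr * phase[:, None, None], lags_s, axis=0)
        if np.isfinite(tau_tail) and tau_tail > 0:
            # analytic continuation of each pair with the common tail time
            tail = corr[-1] * np.exp(-1j * omega * lags_s[-1]) \
                / (1.0 / tau_tail + 1j * omega)
            jm = jm + tail
        return jm

    return SpectralDensitySet(
        j_func=j_func,
        tau_c_ns=tau_c_ns,
        mean_coeffs=mean,
        valid=valid,
        corr_lags_ps=lags_s * 1e12,
        corr_values=corr,
    )


# ----------------------------------------------------------------------
# model assembly
# ----------------------------------------------------------------------
def _static_hamiltonian(spec: SpinSystemSpec, fieldcfg: FieldConfig,
                        ops: OperatorSet, mean_coeffs: np.ndarray) -> np.ndarray:
    h0 = fieldcfg.omega0(spec.g_iso) * ops.Sz + spec.A_iso * (
        ops.Sx @ ops.Ix + ops.Sy @ ops.Iy + ops.Sz @ ops.Iz
    )
    for q, v in enumerate(_channel_operators(ops)):
        if mean_coeffs[q] != 0.0:
            h0 = h0 + mean_coeffs[q] * v
    return h0


def _unique_frequencies(omega_matrix: np.ndarray, tol: float = 1e4):
    """Cluster the H0 transition frequencies within ``tol`` (rad/s)."""
    flat = omega_matrix.ravel()
    order = np.argsort(flat)
    groups = []
    current = [order[0]]
    for idx in order[1:]:
        if flat[idx] - flat[current[-1]] <= tol:
            current.append(idx)
        else:
            groups.append(current)
            current = [idx]
    groups.append(current)
    freqs, masks = [], []
    dim2 = flat.size
    for g in groups:
        m = np.zeros(dim2, dtype=bool)
        m[g] = True
        freqs.append(float(np.mean(flat[g])))
        masks.append(m.reshape(omega_matrix.shape))
    return freqs, masks


@dataclass
class RedfieldModel:
    """Static Liouvillian + relaxation supermatrix in the H0 eigenbasis."""

    spec: SpinSystemSpec
    fieldcfg: FieldConfig
    energies: np.ndarray  # H0 eigenvalues, rad/s
    basis: np.ndarray  # eigenvectors (columns), product basis -> eigenbasis
    relaxation: np.ndarray  # (d^2, d^2) masked supermatrix, 1/s
    include_cross_correlations: bool = True
    secular_cutoff: float = 0.0

    @property
    def dimension(self) -> int:
        return self.energies.size

    def liouvillian(self) -> np.ndarray:
        """L = -i [H0, .] + R in the eigenbasis, acting on vec(sigma)."""
        d = self.dimension
        w = self.energies[:, None] - self.energies[None, :]
        return np.diag(-1j * w.ravel()) + self.relaxation


def build_redfield(
    jset: SpectralDensitySet,
    spec: SpinSystemSpec,
    fieldcfg: FieldConfig,
    include_cross_correlations: bool = True,
    include_dynamic_shifts: bool = True,
    secular_cutoff: float | None = None,
) -> RedfieldModel:
    """Assemble the relaxation supermatrix from spectral densities.

    When ``include_cross_correlations`` is False all J terms mixing
    Zeeman-anisotropy channels with hyperfine channels are forced to
    zero, which renders 15N doublets symmetric.  The secular filter
    removes couplings between coherences whose static frequencies differ
    by more than ``secular_cutoff`` (default: 10x the largest relaxation
    rate, so the block structure follows the actual degeneracy pattern of
    H0 including the hyperfine splitting).
    """
    if not jset.valid:
        warnings.warn(
            "spectral-density set flagged invalid (non-decaying "
            "correlations); Redfield theory is not applicable",
            stacklevel=2,
        )
    ops = spec.operators()
    d = ops.dimension
    h0 = _static_hamiltonian(spec, fieldcfg, ops, jset.mean_coeffs)
    energies, basis = np.linalg.eigh(h0)
    vs = [basis.conj().T @ v @ basis for v in _channel_operators(ops)]

    omega_matrix = energies[:, None] - energies[None, :]
    freqs, masks = _unique_frequencies(omega_matrix)

    eye = np.eye(d)

    def comm_super(a: np.ndarray) -> np.ndarray:
        return np.kron(a, eye) - np.kron(eye, a.T)

    comms = [comm_super(v) for v in vs]

    cross_mask = np.ones((N_CHANNELS, N_CHANNELS))
    if not include_cross_correlations:
        for q in range(N_CHANNELS):
            for p in range(N_CHANNELS):
                if CHANNEL_KINDS[q] != CHANNEL_KINDS[p]:
                    cross_mask[q, p] = 0.0

    # Cauchy-Schwarz bound on cross terms, with an absolute floor so that
    # estimator noise at frequencies where J is negligible (e.g. around
    # the electron Larmor frequency) is not mistaken for a violation
    j0 = jset.j(0.0) * cross_mask
    ref_scale = float(np.abs(np.diag(j0.real)).max())

    r = np.zeros((d * d, d * d), dtype=complex)
    for w, mask in zip(freqs, masks):
        jm = jset.j(w) * cross_mask
        if not include_dynamic_shifts:
            jm = jm.real.astype(complex)
        diag = np.sqrt(np.clip(np.abs(np.diag(jm.real)), 1e-300, None))
        bound = np.outer(diag, diag) * 1.05 + 1e-3 * ref_scale
        if np.any(np.abs(jm.real) > bound):
            raise ValueError(
                "cross-correlation spectral densities violate the "
                "Cauchy-Schwarz bound |J_qA| <= sqrt(J_qq J_AA)"
            )
        for qp in range(N_CHANNELS):
            v_comp = vs[qp] * mask
            if not np.any(v_comp):
                continue
            inner = comm_super(v_comp)
            for q in range(N_CHANNELS):
                if jm[qp, q] != 0.0:
                    r -= jm[qp, q] * (comms[q] @ inner)

    # secular filter in coherence space
    w_coh = omega_matrix.ravel()
    max_rate = float(np.abs(np.diag(r).real).max())
    cutoff = secular_cutoff if secular_cutoff is not None else 10.0 * max_rate
    keep = np.abs(w_coh[:, None] - w_coh[None, :]) <= cutoff
    r = r * keep

    return RedfieldModel(
        spec=spec,
        fieldcfg=fieldcfg,
        energies=energies,
        basis=basis,
        relaxation=r,
        include_cross_correlations=include_cross_correlations,
        secular_cutoff=cutoff,
    )


# ----------------------------------------------------------------------
# spectra
# ----------------------------------------------------------------------
def _fid_modes(model: RedfieldModel):
    """Eigenmode decomposition of the detected FID: amplitudes and
    complex rates, demodulated at the carrier."""
    ops = model.spec.operators()
    b = model.basis
    sx = b.conj().T @ ops.Sx @ b
    sp = b.conj().T @ ops.Sp @ b
    lv = model.liouvillian()
    evals, vecs = np.linalg.eig(lv)
    cond = np.linalg.cond(vecs)
    if cond > 1e10:
        warnings.warn(
            "Liouvillian close to defective (eigenvector condition "
            f"{cond:.1e}); falling back to Schur-based evaluation",
            stacklevel=2,
        )
        from scipy.linalg import schur

        t_mat, z = schur(lv, output="complex")
        # diagonal approximation of the Schur form (upper-triangular
        # couplings neglected); adequate for reporting rates
        evals = np.diag(t_mat)
        vecs = z
    coeff = np.linalg.solve(vecs, sx.ravel())
    # Tr{S+ sigma} = sum_ij (S+)_ij sigma_ji  ->  row vector vec(S+^T)
    detect_row = sp.T.ravel()
    amps = (detect_row @ vecs) * coeff
    omega_ref = model.fieldcfg.omega0(model.spec.g_iso)
    rates = evals - 1j * omega_ref
    keep = np.abs(amps) > 1e-12 * np.abs(amps).max()
    return amps[keep], rates[keep]


def redfield_fid(
    model: RedfieldModel,
    n_points: int = 4096,
    dt_s: float = 32e-12,
) -> FID:
    """Sampled FID Tr{S+ sigma(tau)} from the Redfield eigenmodes."""
    amps, rates = _fid_modes(model)
    taus = np.arange(n_points) * dt_s
    values = (amps[None, :] * np.exp(np.outer(taus, rates))).sum(axis=1)
    omega_ref = model.fieldcfg.omega0(model.spec.g_iso)
    return FID(values=values, dt_s=dt_s, omega_ref=omega_ref)


def redfield_spectrum(
    model: RedfieldModel,
    broadening: BroadeningModel | None = None,
    modulation: ModulationConfig | None = None,
    mode: str = "first_derivative",
    sweep_mT: float = 12.0,
    n_field: int = 2048,
    n_points: int = 4096,
    dt_s: float = 32e-12,
) -> Spectrum:
    """CW spectrum with the same post-processing chain as the direct
    propagation engine (oxygen Lorentzian on the FID, modulation
    transform or Fourier absorption, Gaussian field convolution)."""
    broadening = broadening or BroadeningModel()
    modulation = modulation or ModulationConfig()
    fid = redfield_fid(model, n_points=n_points, dt_s=dt_s)
    fid = apply_broadening(fid, broadening)
    if mode == "first_derivative":
        spec_out = modulated_spectrum(fid, modulation, model.spec.g_iso,
                                      sweep_mT=sweep_mT, n_field=n_field)
    else:
        spec_out = absorption_spectrum(fid, model.spec.g_iso,
                                       sweep_mT=sweep_mT, n_field=n_field)
    return gaussian_convolve(spec_out, broadening.gaussian_fwhm_ut)


def electron_t2(model: RedfieldModel) -> float:
    """T2e from the slowest detected electron coherence eigenmode, s."""
    amps, rates = _fid_modes(model)
    weights = np.abs(amps)
    significant = weights > 1e-3 * weights.sum()
    decays = -rates.real[significant]
    decays = decays[decays > 0]
    if decays.size == 0:
        return np.inf
    return float(1.0 / decays.min())


def validity_report(
    jset: SpectralDensitySet,
    spec: SpinSystemSpec,
    fieldcfg: FieldConfig,
    thresholds: tuple[float, float] = (0.05, 0.2),
) -> dict:
    """tau_c / T2e ratio with a verdict (valid / marginal / invalid).

    tau_c comes from the correlation-function decay; T2e from the slowest
    detected Redfield eigenmode (the 1/e time of |FID| is also reported).
    """
    model = build_redfield(jset, spec, fieldcfg)
    t2e = electron_t2(model)
    fid = redfield_fid(model, n_points=4096,
                       dt_s=max(1e-12, min(64e-12, t2e / 500 if np.isfinite(t2e) else 64e-12)))
    mag = np.abs(fid.values) / np.abs(fid.values[0])
    below = np.flatnonzero(mag < np.exp(-1.0))
    t2_fid = float(below[0] * fid.dt_s) if below.size else np.inf
    tau_c_s = jset.tau_c_ns * 1e-9
    ratio = tau_c_s / t2e if np.isfinite(t2e) else np.inf
    if not jset.valid or not np.isfinite(ratio):
        verdict = "invalid"
    elif ratio < thresholds[0]:
        verdict = "valid"
    elif ratio < thresholds[1]:
        verdict = "marginal"
    else:
        verdict = "invalid"
    return {
        "tau_c_ns": jset.tau_c_ns,
        "t2e_ns": t2e * 1e9,
        "t2e_fid_1e_ns": t2_fid * 1e9,
        "ratio": ratio,
        "verdict": verdict,
        "thresholds": thresholds,
    }


# ----------------------------------------------------------------------
# closed-form motional-narrowing oracle
# ----------------------------------------------------------------------
def fast_motion_linewidths(
    spec: SpinSystemSpec,
    fieldcfg: FieldConfig,
    tau_c_ns: float,
) -> dict:
    """Closed-form fast-motion linewidths R2(m_I) = A + B m_I + C m_I^2.

    Golden-rule/secular-Redfield rates for the electron single-quantum
    coherence of each nuclear projection m_I under isotropic rotational
    diffusion, built from explicit operator matrix elements and the
    analytic isotropic correlation amplitudes — an independent check on
    the supermatrix assembly.  Returns widths in 1/s plus the fitted
    (A, B, C) coefficients.

    R2 = Gamma_adiabatic + (1/2) sum_c (W_{a->c} + W_{b->c}) with
    Gamma_ad = sum_{qq'} Re J_{qq'}(0) (V_q,aa - V_q,bb)(V_q',aa - V_q',bb)
    and golden-rule flip rates W_{a->c} = 2 Re sum_{qq'} J_{qq'}(omega_ac)
    <a|V_q|c><a|V_q'|c>*.
    """
    ops = spec.operators()
    m_amp = _analytic_amplitude_matrix(spec, fieldcfg)
    tau = tau_c_ns * 1e-9

    def jmat(omega: float) -> np.ndarray:
        return m_amp * (tau / (1.0 + (omega * tau) ** 2))

    # product-basis states |m_S, m_I>; energies of H0 = w0 Sz + a Sz Iz
    omega0 = fieldcfg.omega0(spec.g_iso)
    a_iso = spec.A_iso
    n_i = int(round(2 * spec.nuclear_spin + 1))
    ms_vals = np.repeat([0.5, -0.5], n_i)
    mi_vals = np.tile(spec.nuclear_spin - np.arange(n_i), 2)
    energies = omega0 * ms_vals + a_iso * ms_vals * mi_vals

    vs = [v.copy() for v in _channel_operators(ops)]
    mi_levels = spec.nuclear_spin - np.arange(n_i)
    widths = {}
    dim = ops.dimension
    for idx, mi in enumerate(mi_levels):
        ia = idx          # |alpha, mi>
        ib = n_i + idx    # |beta, mi>
        # adiabatic secular term
        gamma_ad = 0.0
        j0 = jmat(0.0)
        for q in range(N_CHANNELS):
            dq = (vs[q][ia, ia] - vs[q][ib, ib]).real
            for p in range(N_CHANNELS):
                dp = (vs[p][ia, ia] - vs[p][ib, ib]).real
                gamma_ad += j0[q, p] * dq * dp
        # lifetime terms
        life = 0.0
        for state in (ia, ib):
            for c in range(dim):
                if c == state:
                    continue
                w_ac = energies[state] - energies[c]
                jm = jmat(w_ac)
                amp = 0.0
                for q in range(N_CHANNELS):
                    el_q = vs[q][state, c]
                    if el_q == 0:
                        continue
                    for p in range(N_CHANNELS):
                        el_p = vs[p][state, c]
                        amp += (jm[q, p] * el_q * np.conj(el_p)).real
                life += amp  # (1/2) * W with W = 2 * amp
        widths[float(mi)] = gamma_ad + life

    mis = np.array(sorted(widths, reverse=True))
    r2 = np.array([widths[m] for m in mis])
    coeffs = np.polyfit(mis, r2, 2)[::-1] if mis.size >= 3 else None
    return {"m_i": mis, "r2": r2, "abc": coeffs}
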