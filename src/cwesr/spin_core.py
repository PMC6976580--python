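"""Spin operators, tensor handling, and the electron-nuclear Hamiltonian.

The model system is a nitroxide radical: electron spin S = 1/2 coupled to
the nitrogen nucleus (I = 1 for 14N, I = 1/2 for 15N) through the
hyperfine interaction.  Both the Zeeman coupling tensor g and the
hyperfine tensor A are split into an isotropic part and a traceless
anisotropic part expressed in the principal axes system (PAS) of the
nitroxide ring (x along the N-O bond, z normal to the ring plane).  The
orientation of the PAS with respect to the laboratory frame, R(t), is
what an orientational trajectory supplies; the time-dependent Hamiltonian
in angular-frequency units is

    H(t) = (mu_B/hbar) S . g_iso . B0
         + (mu_B/hbar) S . (R g_aniso^PAS R^-1) . B0
         + A_iso S.I + S . (R A_aniso^PAS R^-1) . I

with B0 along the laboratory z axis.  Nuclear Zeeman and 14N quadrupole
terms are intentionally absent from this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict

import numpy as np

from . import quat
from .constants import GAMMA_RATIO_15N_14N, HBAR, H_PLANCK, MHZ_TO_RADS, MU_B

__all__ = [
    "SpinSystemSpec",
    "OperatorSet",
    "FieldConfig",
    "build_operators",
    "hamiltonian",
    "hamiltonian_sequence",
]


def _single_spin_matrices(s: float) -> Dict[str, np.ndarray]:
    """Angular-momentum matrices for one spin quantum number ``s``."""
    dim = int(round(2 * s + 1))
    m = s - np.arange(dim)  # m = s, s-1, ..., -s
    sz = np.diag(m).astype(complex)
    # <m+1| J+ |m> = sqrt(s(s+1) - m(m+1))
    raise_elems = np.sqrt(s * (s + 1) - m[1:] * (m[1:] + 1))
    jp = np.zeros((dim, dim), dtype=complex)
    jp[np.arange(dim - 1), np.arange(1, dim)] = raise_elems
    jm = jp.conj().T
    jx = 0.5 * (jp + jm)
    jy = -0.5j * (jp - jm)
    return {"x": jx, "y": jy, "z": sz, "p": jp, "m": jm}


@dataclass(frozen=True)
class OperatorSet:
    """Electron and nuclear spin operators on the composite Hilbert space.

    The composite space has dimension 2(2I+1): 6 for 14N (I=1) and 4 for
    15N (I=1/2).  Electron operators act as S x 1, nuclear ones as 1 x I.
    """

    nuclear_spin: float
    dimension: int
    Sx: np.ndarray
    Sy: np.ndarray
    Sz: np.ndarray
    Sp: np.ndarray
    Sm: np.ndarray
    Ix: np.ndarray
    Iy: np.ndarray
    Iz: np.ndarray
    Ip: np.ndarray
    Im: np.ndarray
    identity: np.ndarray

    @property
    def S_vec(self) -> np.ndarray:
        return np.stack([self.Sx, self.Sy, self.Sz])

    @property
    def I_vec(self) -> np.ndarray:
        return np.stack([self.Ix, self.Iy, self.Iz])


def build_operators(nuclear_spin: float) -> OperatorSet:
    """Construct the operator set for S=1/2 coupled to a spin-I nucleus."""
    if nuclear_spin not in (0.5, 1.0):
        raise ValueError(
            f"unsupported nuclear spin {nuclear_spin!r}: expected 1/2 (15N) or 1 (14N)"
        )
    s_ops = _single_spin_matrices(0.5)
    i_ops = _single_spin_matrices(nuclear_spin)
    dim_i = i_ops["z"].shape[0]
    eye_s = np.eye(2, dtype=complex)
    eye_i = np.eye(dim_i, dtype=complex)

    def lift_s(op):
        return np.kron(op, eye_i)

    def lift_i(op):
        return np.kron(eye_s, op)

    return OperatorSet(
        nuclear_spin=nuclear_spin,
        dimension=2 * dim_i,
        Sx=lift_s(s_ops["x"]),
        Sy=lift_s(s_ops["y"]),
        Sz=lift_s(s_ops["z"]),
        Sp=lift_s(s_ops["p"]),
        Sm=lift_s(s_ops["m"]),
        Ix=lift_i(i_ops["x"]),
        Iy=lift_i(i_ops["y"]),
        Iz=lift_i(i_ops["z"]),
        Ip=lift_i(i_ops["p"]),
        Im=lift_i(i_ops["m"]),
        identity=np.eye(2 * dim_i, dtype=complex),
    )


@dataclass(frozen=True)
class SpinSystemSpec:
    """g- and hyperfine-tensor principal values plus the nuclear spin.

    ``A_principal`` is stored internally in rad/s.  Use the classmethods
    to construct from MHz or from field units (mT/G), which are the units
    hyperfine tensors are quoted in in the literature.
    """

    nuclear_spin: float
    g_principal: np.ndarray  # (3,) dimensionless, PAS order (x, y, z)
    A_principal: np.ndarray  # (3,) rad/s

    def __post_init__(self):
        object.__setattr__(self, "g_principal", np.asarray(self.g_principal, float))
        object.__setattr__(self, "A_principal", np.asarray(self.A_principal, float))
        if self.g_principal.shape != (3,) or self.A_principal.shape != (3,):
            raise ValueError("g_principal and A_principal must have 3 components")
        if self.nuclear_spin not in (0.5, 1.0):
            raise ValueError("nuclear_spin must be 1/2 (15N) or 1 (14N)")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_mhz(cls, nuclear_spin, g_principal, A_principal_mhz) -> "SpinSystemSpec":
        return cls(nuclear_spin, np.asarray(g_principal, float),
                   np.asarray(A_principal_mhz, float) * MHZ_TO_RADS)

    @classmethod
    def from_mT(cls, nuclear_spin, g_principal, A_principal_mT) -> "SpinSystemSpec":
        g_iso = float(np.mean(np.asarray(g_principal, float)))
        conv = g_iso * MU_B / HBAR * 1e-3  # mT -> rad/s
        return cls(nuclear_spin, np.asarray(g_principal, float),
                   np.asarray(A_principal_mT, float) * conv)

    @classmethod
    def nitroxide_14n(cls) -> "SpinSystemSpec":
        """Typical literature tensor values for a proxyl nitroxide in water.

        These are representative defaults (g ~ (2.0085, 2.0061, 2.0022),
        A ~ (18.5, 18.5, 100.5) MHz, A_iso ~ 45.8 MHz); actual samples
        should supply their own calibrated tensors.
        """
        return cls.from_mhz(1.0, (2.0085, 2.0061, 2.0022), (18.5, 18.5, 100.5))

    @classmethod
    def nitroxide_15n(cls) -> "SpinSystemSpec":
        """15N analogue of :meth:`nitroxide_14n` (gamma-ratio scaled)."""
        return cls.nitroxide_14n().to_15n()

    def to_15n(self) -> "SpinSystemSpec":
        """Opt-in helper: scale a 14N tensor by |gamma_15N / gamma_14N|."""
        if self.nuclear_spin != 1.0:
            raise ValueError("to_15n expects a 14N (I=1) spin system")
        return SpinSystemSpec(0.5, self.g_principal.copy(),
                              self.A_principal * GAMMA_RATIO_15N_14N)

    # -- derived quantities -------------------------------------------
    @property
    def isotope_label(self) -> str:
        return "14N" if self.nuclear_spin == 1.0 else "15N"

    @property
    def g_iso(self) -> float:
        return float(np.mean(self.g_principal))

    @property
    def A_iso(self) -> float:
        """Isotropic hyperfine coupling, rad/s."""
        return float(np.mean(self.A_principal))

    @property
    def A_iso_mhz(self) -> float:
        return self.A_iso / MHZ_TO_RADS

    @property
    def g_aniso_pas(self) -> np.ndarray:
        """Traceless anisotropic g tensor in its PAS, (3, 3)."""
        return np.diag(self.g_principal - self.g_iso)

    @property
    def A_aniso_pas(self) -> np.ndarray:
        """Traceless anisotropic hyperfine tensor in its PAS, rad/s, (3, 3)."""
        return np.diag(self.A_principal - self.A_iso)

    def operators(self) -> OperatorSet:
        return build_operators(self.nuclear_spin)


@dataclass(frozen=True)
class FieldConfig:
    """Static-field / microwave settings of the CW experiment.

    ``B0`` is the static field magnitude in Tesla, along the laboratory z
    axis by convention.  At X band (9.45 GHz) and g ~ 2.006 the resonance
    field is ~0.3367 T.
    """

    B0: float
    mw_frequency_ghz: float = dc_field(default=9.45)

    def __post_init__(self):
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")
        if self.mw_frequency_ghz <= 0:
            raise ValueError("mw_frequency must be positive")

    @classmethod
    def x_band(cls, g_iso: float, mw_frequency_ghz: float = 9.45) -> "FieldConfig":
        """Field placed exactly on resonance for the given g_iso."""
        b0 = H_PLANCK * mw_frequency_ghz * 1e9 / (g_iso * MU_B)
        return cls(B0=b0, mw_frequency_ghz=mw_frequency_ghz)

    def omega0(self, g_iso: float) -> float:
        """Isotropic electron Larmor angular frequency, rad/s."""
        return g_iso * MU_B * self.B0 / HBAR


def _check_unit_quaternion(q: np.ndarray, tol: float = 1e-6) -> None:
    norms = np.linalg.norm(np.atleast_2d(q), axis=-1)
    bad = np.abs(norms - 1.0) > tol
    if np.any(bad):
        raise ValueError(
            f"non-unit quaternion(s): |q|-1 up to {np.abs(norms - 1.0).max():.3e}"
        )


def lab_tensors(spec: SpinSystemSpec, rotation: np.ndarray):
    """Anisotropic g and A tensors rotated into the laboratory frame.

    ``rotation`` is one quaternion (4,) or a stack (N, 4) mapping
    PAS -> lab.  Returns ``(g_lab, A_lab)`` with shapes (..., 3, 3); both
    stay traceless because the similarity transform preserves the trace.
    """
    _check_unit_quaternion(rotation)
    R = quat.to_matrix(rotation)
    g_lab = R @ spec.g_aniso_pas @ np.swapaxes(R, -1, -2)
    a_lab = R @ spec.A_aniso_pas @ np.swapaxes(R, -1, -2)
    return g_lab, a_lab


def hamiltonian(
    spec: SpinSystemSpec,
    rotation: np.ndarray,
    fieldcfg: FieldConfig,
    ops: OperatorSet | None = None,
) -> np.ndarray:
    """Laboratory-frame Hamiltonian (rad/s) for one orientation."""
    return hamiltonian_sequence(spec, np.asarray(rotation, float)[None, :],
                                fieldcfg, ops)[0]


def hamiltonian_sequence(
    spec: SpinSystemSpec,
    rotations: np.ndarray,
    fieldcfg: FieldConfig,
    ops: OperatorSet | None = None,
) -> np.ndarray:
    """Batched laboratory-frame Hamiltonians H(t_k), shape (N, d, d), rad/s.

    The electron Zeeman term is evaluated with the field along lab z;
    anisotropic tensors are rotated per frame.  All terms are Hermitian by
    construction.
    """
    if ops is None:
        ops = spec.operators()
    g_lab, a_lab = lab_tensors(spec, rotations)
    zeeman_scale = MU_B * fieldcfg.B0 / HBAR

    omega0 = spec.g_iso * zeeman_scale
    h0 = omega0 * ops.Sz + spec.A_iso * (
        ops.Sx @ ops.Ix + ops.Sy @ ops.Iy + ops.Sz @ ops.Iz
    )

    # Zeeman anisotropy: (mu_B B0 / hbar) sum_j S_j (g_lab)_{jz}
    gz = zeeman_scale * g_lab[..., :, 2]  # (N, 3)
    h_g = np.einsum("nj,jab->nab", gz, ops.S_vec)

    # Hyperfine anisotropy: sum_{jk} (A_lab)_{jk} S_j I_k
    si = np.einsum("jab,kbc->jkac", ops.S_vec, ops.I_vec)  # (3,3,d,d)
    h_a = np.einsum("njk,jkab->nab", a_lab, si)

    return h0[None, :, :] + h_g + h_a
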