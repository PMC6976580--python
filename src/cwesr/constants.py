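"""Physical constants and unit conversions used across the package.

Internal conventions:

* interaction strengths — angular frequency, rad/s
* magnetic field — Tesla
* time — seconds (file formats use ps / ns / us where stated)
"""

from scipy.constants import physical_constants, h, hbar

MU_B = physical_constants["Bohr magneton"][0]  # J/T
H_PLANCK = h  # J s
HBAR = hbar  # J s

#: |gamma(15N)/gamma(14N)| — opt-in rescaling of a 14N hyperfine tensor
#: to its 15N analogue (gyromagnetic ratios from CODATA shielded values
#: are not needed at this precision; bare-nucleus ratio used).
GAMMA_RATIO_15N_14N = 1.4027

MHZ_TO_RADS = 2.0e6 * 3.141592653589793  # 2*pi*1e6


def field_to_angular(delta_b: float, g_iso: float) -> float:
    """Convert a field offset/width (T) to angular frequency (rad/s)."""
    return g_iso * MU_B * delta_b / HBAR


def angular_to_field(omega: float, g_iso: float) -> float:
    """Convert an angular frequency (rad/s) to a field offset/width (T)."""
    return HBAR * omega / (g_iso * MU_B)
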