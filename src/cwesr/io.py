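"""File formats: trajectories, spectra, FIDs, spin configs, manifests.

All formats are whitespace-delimited text with ``#`` header lines so
runs diff cleanly and round-trip losslessly:

* trajectory: columns ``time_ps qw qx qy qz``; header records the step
  and frame count (and the generator seed when applicable)
* spectrum: columns ``field_mT intensity``; header records mode and the
  experiment settings; the field axis is stored as offsets from the
  sweep center
* FID: columns ``time_ps re im``
* spin-system config: YAML key-value block (nuclear_spin, g_principal,
  A_principal + unit, field or mw frequency)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .direct_propagation import FID, Spectrum
from .spin_core import FieldConfig, SpinSystemSpec
from .trajectory_ops import OrientationTrajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_spectrum",
    "read_spectrum",
    "write_fid",
    "read_fid",
    "read_spin_config",
    "write_spin_config",
    "write_manifest",
]


def _write_with_header(path, header: dict, columns: list[str],
                       data: np.ndarray, fmt: str = "%.10g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# columns: " + " ".join(columns) + "\n")
        np.savetxt(fh, data, fmt=fmt)


def _read_header(path) -> dict:
    header = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
    return header


def write_trajectory(path, traj: OrientationTrajectory, extra: dict | None = None
                     ) -> None:
    header = {"format": "cwesr-trajectory-v1", "dt_ps": traj.dt_ps,
              "n_frames": traj.n_frames}
    if extra:
        header.update(extra)
    data = np.column_stack([traj.times_ps, traj.quats])
    _write_with_header(path, header, ["time_ps", "qw", "qx", "qy", "qz"], data,
                       fmt="%.12g")


def read_trajectory(path) -> OrientationTrajectory:
    header = _read_header(path)
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 5:
        raise ValueError(f"{path}: expected 5 columns (time_ps qw qx qy qz)")
    dt = float(header.get("dt_ps", data[1, 0] - data[0, 0]))
    return OrientationTrajectory(quats=data[:, 1:], dt_ps=dt)


def write_spectrum(path, spectrum: Spectrum, extra: dict | None = None) -> None:
    header = {"format": "cwesr-spectrum-v1", "mode": spectrum.mode}
    if extra:
        header.update(extra)
    data = np.column_stack([spectrum.field_mT, spectrum.intensity])
    _write_with_header(path, header, ["field_mT", "intensity"], data)


def read_spectrum(path) -> Spectrum:
    header = _read_header(path)
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (field_mT intensity)")
    return Spectrum(field_mT=data[:, 0], intensity=data[:, 1],
                    mode=header.get("mode", "first_derivative"))


def write_fid(path, fid: FID, extra: dict | None = None) -> None:
    header = {"format": "cwesr-fid-v1", "dt_ps": fid.dt_s * 1e12,
              "omega_ref_rads": fid.omega_ref, "n_windows": fid.n_windows}
    if extra:
        header.update(extra)
    data = np.column_stack([fid.times_s * 1e12, fid.values.real,
                            fid.values.imag])
    _write_with_header(path, header, ["time_ps", "re", "im"], data)


def read_fid(path) -> FID:
    header = _read_header(path)
    data = np.loadtxt(path)
    return FID(values=data[:, 1] + 1j * data[:, 2],
               dt_s=float(header.get("dt_ps", data[1, 0] - data[0, 0])) * 1e-12,
               omega_ref=float(header.get("omega_ref_rads", 0.0)),
               n_windows=int(header.get("n_windows", 1)))


_A_UNIT_SCALE = {"MHz": "mhz", "mT": "mT", "G": "G"}


def read_spin_config(path) -> tuple[SpinSystemSpec, FieldConfig]:
    """Spin-system + field configuration from a YAML key-value file.

    Keys: ``nuclear_spin`` (0.5 or 1), ``g_principal`` (3 floats),
    ``A_principal`` (3 floats), ``A_unit`` (MHz | mT | G), and either
    ``mw_frequency_ghz`` or ``field_T``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        nuclear_spin = float(cfg["nuclear_spin"])
        gp = [float(v) for v in cfg["g_principal"]]
        ap = [float(v) for v in cfg["A_principal"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed spin config ({exc})") from exc
    unit = str(cfg.get("A_unit", "MHz"))
    if unit == "MHz":
        spec = SpinSystemSpec.from_mhz(nuclear_spin, gp, ap)
    elif unit == "mT":
        spec = SpinSystemSpec.from_mT(nuclear_spin, gp, ap)
    elif unit == "G":
        spec = SpinSystemSpec.from_mT(nuclear_spin, gp, [a * 0.1 for a in ap])
    else:
        raise ValueError(f"{path}: unknown A_unit {unit!r} (MHz, mT or G)")
    if "field_T" in cfg:
        fieldcfg = FieldConfig(B0=float(cfg["field_T"]),
                               mw_frequency_ghz=float(
                                   cfg.get("mw_frequency_ghz", 9.45)))
    else:
        fieldcfg = FieldConfig.x_band(spec.g_iso,
                                      float(cfg.get("mw_frequency_ghz", 9.45)))
    return spec, fieldcfg


def write_spin_config(path, spec: SpinSystemSpec,
                      fieldcfg: FieldConfig | None = None) -> None:
    cfg = {
        "nuclear_spin": spec.nuclear_spin,
        "g_principal": [float(g) for g in spec.g_principal],
        "A_principal": [float(a) for a in spec.A_principal / (2e6 * np.pi)],
        "A_unit": "MHz",
    }
    if fieldcfg is not None:
        cfg["field_T"] = fieldcfg.B0
        cfg["mw_frequency_ghz"] = fieldcfg.mw_frequency_ghz
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_manifest(path, config: dict) -> None:
    """Reproducibility manifest: config + seeds + package version."""
    from . import __version__

    payload = {"package": "cwesr", "version": __version__,
               "schema_version": 1, "config": config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
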