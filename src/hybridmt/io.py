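"""File formats: pulse-train CSV, config YAML, fingerprint HDF5, NIfTI maps.

Conventions
-----------
* Pulse trains: a CSV with columns ``index, alpha_rad, trf_s`` plus a YAML
  sidecar holding TR, cycle time and the inversion-pulse duration (SI units).
* Tissue/system parameters: flat YAML keys ``m0s, R1f, R2f, Rx, R1s, T2s,
  omega_z, b1, m0_abs, m0_phase`` (SI units).
* Fingerprint volumes: HDF5 with paired ``real``/``imag`` float datasets and
  attributes recording TR, the number of pulses and the generation seed.
* Parameter maps: one float32 NIfTI per parameter with the unit recorded in
  the header description.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .generalized_bloch import LinearizationTable
from .mt_model import SystemParameters, TissueParameters
from .sequence import PulseTrain, RFPulse

__all__ = [
    "save_train",
    "load_train",
    "save_params",
    "load_params",
    "save_fingerprints",
    "load_fingerprints",
    "save_table",
    "load_table",
    "save_maps",
    "load_maps",
]


def save_train(train: PulseTrain, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "index": np.arange(train.n_pulses),
            "alpha_rad": train.alphas,
            "trf_s": train.trfs,
        }
    ).to_csv(csv_path, index=False)
    sidecar = {
        "tr": float(train.tr),
        "cycle_time": float(train.cycle_time),
        "inversion_trf": float(train.inversion.trf),
        "sample_delay": None
        if train.sample_delay is None
        else float(train.sample_delay),
    }
    csv_path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def load_train(csv_path: str | Path) -> PulseTrain:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = yaml.safe_load(csv_path.with_suffix(".yaml").read_text())
    pulses = tuple(
        RFPulse(float(a), float(t), (k % 2) * np.pi)
        for k, (a, t) in enumerate(zip(df["alpha_rad"], df["trf_s"]))
    )
    return PulseTrain(
        pulses=pulses,
        tr=meta["tr"],
        cycle_time=meta["cycle_time"],
        inversion=RFPulse(np.pi, meta["inversion_trf"], 0.0),
        sample_delay=meta.get("sample_delay"),
    )


def save_params(
    tissue: TissueParameters, system: SystemParameters, path: str | Path
) -> None:
    data = {
        "m0s": tissue.m0s,
        "R1f": tissue.R1f,
        "R2f": tissue.R2f,
        "Rx": tissue.Rx,
        "R1s": tissue.R1s,
        "T2s": tissue.T2s,
        "omega_z": system.omega_z,
        "b1": system.b1,
        "m0_abs": float(abs(system.m0_complex)),
        "m0_phase": float(np.angle(system.m0_complex)),
    }
    Path(path).write_text(yaml.safe_dump({k: float(v) for k, v in data.items()}))


def load_params(path: str | Path) -> tuple[TissueParameters, SystemParameters]:
    data = yaml.safe_load(Path(path).read_text())
    tissue = TissueParameters(
        m0s=data["m0s"],
        R1f=data["R1f"],
        R2f=data["R2f"],
        Rx=data["Rx"],
        R1s=data["R1s"],
        T2s=data["T2s"],
    )
    system = SystemParameters(
        omega_z=data.get("omega_z", 0.0),
        b1=data.get("b1", 1.0),
        m0_complex=data.get("m0_abs", 1.0)
        * np.exp(1j * data.get("m0_phase", 0.0)),
    )
    return tissue, system


def save_fingerprints(
    signal: np.ndarray,
    path: str | Path,
    tr: float,
    seed: int | None = None,
) -> None:
    """Write a complex fingerprint array (last axis = TR index) to HDF5."""
    signal = np.asarray(signal, dtype=complex)
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=signal.real)
        f.create_dataset("imag", data=signal.imag)
        f.attrs["tr"] = float(tr)
        f.attrs["n_pulses"] = int(signal.shape[-1])
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_fingerprints(path: str | Path) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        signal = f["real"][()] + 1j * f["imag"][()]
        attrs = dict(f.attrs)
    return signal, attrs


def save_table(table: LinearizationTable, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("alpha_grid", data=table.alphas)
        f.create_dataset("trf_r2s_grid", data=table.trf_r2s)
        f.create_dataset("r2sl_t2s_values", data=table.values)
        f.attrs["lineshape"] = table.kind
        f.attrs["tolerance"] = 1e-9


def load_table(path: str | Path) -> LinearizationTable:
    with h5py.File(path, "r") as f:
        return LinearizationTable(
            f["alpha_grid"][()],
            f["trf_r2s_grid"][()],
            f["r2sl_t2s_values"][()],
            str(f.attrs["lineshape"]),
        )


_UNITS = {
    "m0s": "fraction",
    "R1f": "1/s",
    "R2f": "1/s",
    "Rx": "1/s",
    "R1s": "1/s",
    "T2s": "s",
    "omega_z": "rad/s",
    "b1": "relative",
    "m0_abs": "a.u.",
    "m0_phase": "rad",
    "residual": "a.u.",
}


def save_maps(
    maps: dict[str, np.ndarray],
    directory: str | Path,
    voxel_size_mm: float = 1.0,
    prefix: str = "",
) -> list[Path]:
    """Write parameter maps as per-parameter NIfTI volumes (float32).

    The integer ``flags`` map, if present, is written as int16.  Returns the
    written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    written = []
    for name, arr in maps.items():
        dtype = np.int16 if name == "flags" else np.float32
        img = nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine)
        img.header["descrip"] = _UNITS.get(name, "").encode()[:79]
        out = directory / f"{prefix}{name}.nii"
        nib.save(img, out)
        written.append(out)
    return written


def load_maps(directory: str | Path, prefix: str = "") -> dict[str, np.ndarray]:
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob(f"{prefix}*.nii")):
        name = path.stem[len(prefix):]
        out[name] = np.asarray(nib.load(path).dataobj)
    return out
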