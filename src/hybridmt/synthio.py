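"""Synthetic data: BSA phantom tubes and a procedural digital brain.

Two generators emulate the study objects used to validate the method:

* a seven-tube phantom of thermally cross-linked bovine serum albumin (BSA)
  solutions whose tissue parameters follow empirical linear surfaces in the
  BSA mass fraction ``c`` and field strength ``B0``
  (``a0 + a_bsa*c + a_b0*B0 + a2*c*B0``), and
* a digital brain with nested procedural ROIs carrying literature white/gray
  matter parameter means, optional demyelinating (MS-like) lesions with a
  reduced semi-solid pool, and smooth polynomial B0/B1 fields.

Both produce ground-truth parameters alongside noisy complex fingerprints,
so estimator accuracy can be audited voxel by voxel.  The noise model is
i.i.d. complex Gaussian (independent per real channel), the thermal-noise
model of a well-calibrated receive chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .generalized_bloch import LinearizationTable
from .mt_model import SystemParameters, TissueParameters
from .sequence import PulseTrain, simulate_fingerprint

__all__ = [
    "PhantomSpec",
    "BrainSpec",
    "BSA_GLM_COEFFICIENTS",
    "ROI_PARAMETERS",
    "make_bsa_phantom",
    "make_brain_phantom",
    "add_noise",
]

#: empirical GLM surfaces (a0, a_bsa, a_b0 [1/T], a2 [1/T]) per parameter;
#: T2s is tabulated in microseconds
BSA_GLM_COEFFICIENTS: dict[str, tuple[float, float, float, float]] = {
    "m0s": (-0.007, 0.53, -0.0011, 0.024),
    "R1f": (0.28, 3.6, -0.012, -0.37),
    "R2f": (-2.9, 119.0, -0.16, -0.81),
    "Rx": (26.0, 34.0, 2.0, -5.9),
    "R1s": (4.8, 1.8, -0.92, -0.8),
    "T2s_us": (15.0, -1.6, -2.6, 5.7),
}

# physical floors applied to the GLM surfaces (the R2f surface has a
# negative intercept, which is an artifact of the linear fit)
_PHANTOM_FLOORS = {"m0s": 0.0, "R1f": 0.05, "R2f": 0.2, "Rx": 1.0, "R1s": 0.2}

#: per-ROI mean tissue parameters in healthy adults (white/gray matter
#: structures); CSF values are nominal free-water parameters
ROI_PARAMETERS: dict[str, TissueParameters] = {
    "wm": TissueParameters(0.212, 1 / 1.84, 1 / 0.0769, 13.6, 1 / 0.34, 12.5e-6),
    "cc_anterior": TissueParameters(
        0.237, 1 / 1.77, 1 / 0.0699, 13.4, 1 / 0.349, 14.5e-6
    ),
    "cc_posterior": TissueParameters(
        0.235, 1 / 1.80, 1 / 0.0763, 13.5, 1 / 0.350, 12.6e-6
    ),
    "cortical_gm": TissueParameters(
        0.098, 1 / 2.46, 1 / 0.083, 14.0, 1 / 0.42, 14.4e-6
    ),
    "caudate": TissueParameters(
        0.113, 1 / 1.95, 1 / 0.0733, 13.8, 1 / 0.432, 15.1e-6
    ),
    "putamen": TissueParameters(
        0.118, 1 / 1.84, 1 / 0.0674, 14.9, 1 / 0.385, 15.4e-6
    ),
    "pallidum": TissueParameters(
        0.164, 1 / 1.664, 1 / 0.0593, 15.8, 1 / 0.351, 14.9e-6
    ),
    "thalamus": TissueParameters(
        0.158, 1 / 2.02, 1 / 0.0708, 14.2, 1 / 0.396, 13.0e-6
    ),
    "hippocampus": TissueParameters(
        0.097, 1 / 2.65, 1 / 0.091, 15.3, 1 / 0.376, 13.0e-6
    ),
    "csf": TissueParameters(0.0, 0.25, 1.0, 1.0, 0.25, 10e-6),
}

_LABEL_IDS = {name: i + 1 for i, name in enumerate(ROI_PARAMETERS)}
_LABEL_IDS["lesion"] = len(_LABEL_IDS) + 1


@dataclass(frozen=True)
class PhantomSpec:
    """BSA phantom: tube concentrations, field strength, noise, seed."""

    concentrations: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
    field_strength: float = 2.89
    coefficients: tuple[tuple[str, tuple[float, float, float, float]], ...] = tuple(
        BSA_GLM_COEFFICIENTS.items()
    )
    voxels_per_tube: int = 8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= c <= 0.4 for c in self.concentrations):
            raise ValueError("concentrations must lie in [0, 0.4]")
        for _, co in self.coefficients:
            if not np.all(np.isfinite(co)):
                raise ValueError("GLM coefficients must be finite")


@dataclass(frozen=True)
class BrainSpec:
    """Digital brain: geometry, ROI parameters, fields, lesions, noise."""

    shape: tuple[int, int, int] = (24, 24, 12)
    roi_parameters: tuple[tuple[str, TissueParameters], ...] = tuple(
        ROI_PARAMETERS.items()
    )
    n_lesions: int = 3
    lesion_m0s_multiplier: float = 0.6
    lesion_t1f_multiplier: float = 1.1
    b0_amplitude: float = 2 * np.pi * 20.0  # rad/s
    b1_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.0
    voxel_size_mm: float = 1.0
    seed: int = 0


def _tube_parameters(spec: PhantomSpec) -> pd.DataFrame:
    coeffs = dict(spec.coefficients)
    rows = []
    for c in spec.concentrations:
        row = {"c_bsa": c, "b0": spec.field_strength}
        for name, (a0, a_bsa, a_b0, a2) in coeffs.items():
            val = a0 + a_bsa * c + a_b0 * spec.field_strength + a2 * c * spec.field_strength
            if name == "T2s_us":
                row["T2s"] = max(val, 1.0) * 1e-6
            else:
                row[name] = max(val, _PHANTOM_FLOORS[name])
        if row["m0s"] >= 1.0:
            raise ValueError("GLM surface yields non-physical m0s >= 1")
        rows.append(row)
    return pd.DataFrame(rows)


def make_bsa_phantom(
    spec: PhantomSpec,
    train: PulseTrain,
    table: LinearizationTable,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-tube ground truth and noisy fingerprints for a BSA phantom.

    Returns a truth DataFrame (one row per tube: concentration, field
    strength and the six tissue parameters) and a complex array of shape
    ``(n_tubes, voxels_per_tube, n_TR)`` with seeded complex Gaussian noise
    of SD ``noise_sd`` per real channel.
    """
    truth = _tube_parameters(spec)
    signals = np.empty(
        (len(truth), spec.voxels_per_tube, train.n_pulses), dtype=complex
    )
    system = SystemParameters()
    for i, row in truth.iterrows():
        tissue = TissueParameters(
            m0s=row["m0s"],
            R1f=row["R1f"],
            R2f=row["R2f"],
            Rx=row["Rx"],
            R1s=row["R1s"],
            T2s=row["T2s"],
        )
        clean = simulate_fingerprint(tissue, system, train, table).signal
        signals[i] = clean[None, :]
    signals = add_noise(signals, spec.noise_sd, spec.seed)
    return truth, signals


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _brain_labels(spec: BrainSpec) -> np.ndarray:
    """Procedural nested-ellipsoid label volume (0 = background)."""
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.int16)
    center = (nx / 2 - 0.5, ny / 2 - 0.5, nz / 2 - 0.5)
    outer = (0.46 * nx, 0.46 * ny, 0.46 * nz)
    inner = tuple(0.8 * r for r in outer)
    brain = _ellipsoid_mask(spec.shape, center, outer)
    wm_core = _ellipsoid_mask(spec.shape, center, inner)
    labels[brain] = _LABEL_IDS["cortical_gm"]
    labels[wm_core] = _LABEL_IDS["wm"]
    # ventricles: small central CSF ellipsoid
    csf = _ellipsoid_mask(spec.shape, center, tuple(0.22 * r for r in outer))
    labels[csf] = _LABEL_IDS["csf"]
    # corpus callosum: two blobs anterior/posterior of the ventricles
    offsets = {"cc_anterior": 0.34, "cc_posterior": -0.34}
    for name, off in offsets.items():
        c = (center[0], center[1] + off * ny, center[2])
        blob = _ellipsoid_mask(spec.shape, c, (0.1 * nx, 0.1 * ny, 0.12 * nz))
        labels[blob & wm_core] = _LABEL_IDS[name]
    # subcortical nuclei: seeded small ellipsoids inside the WM core
    deep = ("caudate", "putamen", "pallidum", "thalamus", "hippocampus")
    for name in deep:
        c = tuple(
            ci + rng.uniform(-0.16, 0.16) * s for ci, s in zip(center, spec.shape)
        )
        blob = _ellipsoid_mask(
            spec.shape, c, (0.08 * nx, 0.08 * ny, 0.1 * nz)
        )
        labels[blob & wm_core & (labels == _LABEL_IDS["wm"])] = _LABEL_IDS[name]
    # lesions: small spheres restricted to remaining WM; at least one voxel
    # across even at coarse grids
    for _ in range(spec.n_lesions):
        c = tuple(
            ci + rng.uniform(-0.2, 0.2) * s for ci, s in zip(center, spec.shape)
        )
        radii = (
            max(0.05 * nx, 1.1),
            max(0.05 * ny, 1.1),
            max(0.07 * nz, 1.1),
        )
        blob = _ellipsoid_mask(spec.shape, c, radii)
        labels[blob & (labels == _LABEL_IDS["wm"])] = _LABEL_IDS["lesion"]
    return labels


def _smooth_field(shape, rng, lo: float, hi: float) -> np.ndarray:
    """Random low-order polynomial field scaled into [lo, hi]."""
    coords = [np.linspace(-1, 1, s) for s in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    c = rng.normal(size=7)
    f = (
        c[0] * X
        + c[1] * Y
        + c[2] * Z
        + c[3] * X * Y
        + c[4] * X * Z
        + c[5] * Y * Z
        + c[6] * (X**2 - Z**2)
    )
    f = (f - f.min()) / (f.max() - f.min() + 1e-30)
    return lo + (hi - lo) * f


def make_brain_phantom(
    spec: BrainSpec,
    train: PulseTrain,
    table: LinearizationTable,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Ground-truth volumes, brain mask and noisy fingerprints.

    Lesion voxels carry white-matter parameters with ``m0s`` multiplied by
    the lesion multiplier (demyelination reduces the macromolecular pool)
    and ``T1f`` increased by the T1 multiplier.  Smooth polynomial
    off-resonance (B0, rad/s) and transmit-scale (B1) fields are applied
    voxel-wise.  Returns ``(truth_maps, mask, fingerprints)`` where
    ``truth_maps`` holds per-parameter volumes plus the ``labels`` volume
    and ``fingerprints`` has shape ``(*shape, n_TR)``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _brain_labels(spec)
    mask = labels > 0
    roi_params = dict(spec.roi_parameters)
    wm = roi_params["wm"]
    lesion = replace(
        wm,
        m0s=wm.m0s * spec.lesion_m0s_multiplier,
        R1f=wm.R1f / spec.lesion_t1f_multiplier,
    )
    by_id = {_LABEL_IDS[name]: par for name, par in roi_params.items()}
    by_id[_LABEL_IDS["lesion"]] = lesion

    b0 = _smooth_field(spec.shape, rng, -spec.b0_amplitude, spec.b0_amplitude)
    b1 = _smooth_field(spec.shape, rng, *spec.b1_range)

    names = ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s")
    truth = {n: np.full(spec.shape, np.nan) for n in names}
    truth["omega_z"] = np.full(spec.shape, np.nan)
    truth["b1"] = np.full(spec.shape, np.nan)
    truth["labels"] = labels
    fingerprints = np.zeros((*spec.shape, train.n_pulses), dtype=complex)

    # fingerprints depend on (label, b0, b1); the smooth fields are quantized
    # (0.1 rad/s, 1e-3 in b1, both far below estimator precision) so repeated
    # voxels share one simulation; the truth maps record the quantized values
    cache: dict[tuple, np.ndarray] = {}
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        par = by_id[int(labels[idx])]
        for n in names:
            truth[n][idx] = getattr(par, n)
        key = (int(labels[idx]), round(float(b0[idx]), 1), round(float(b1[idx]), 3))
        truth["omega_z"][idx] = key[1]
        truth["b1"][idx] = key[2]
        if key not in cache:
            system = SystemParameters(omega_z=key[1], b1=key[2])
            cache[key] = simulate_fingerprint(par, system, train, table).signal
        fingerprints[idx] = cache[key]
    fingerprints = add_noise(fingerprints, spec.noise_sd, spec.seed + 1)
    fingerprints[~mask] = 0.0
    return truth, mask, fingerprints


def add_noise(signal: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. complex Gaussian noise (SD ``sigma`` per real channel)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=complex)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=signal.shape) + 1j * rng.normal(size=signal.shape)
    return signal + sigma * noise
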