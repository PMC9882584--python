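"""Dictionary generation, subspace compression and voxel-wise fitting.

Fingerprints live near a low-dimensional subspace: the singular vectors of a
coarse dictionary of simulated signals span it, and projecting measured
signals onto that basis compresses them with negligible loss.  Parameter
estimation is bounded nonlinear least squares on the (full-length or
projected) signal, with the complex scale M0 eliminated analytically at
every iterate (variable projection), multi-start initialization from the
best-matching dictionary atom, and optional constraints on the semi-solid
longitudinal rate (fixed value or tied to the free pool, the classical
constrained MT model).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .generalized_bloch import LinearizationTable
from .mt_model import SystemParameters, TissueParameters
from .sequence import PulseTrain, simulate_fingerprint

__all__ = [
    "Dictionary",
    "SubspaceBasis",
    "FitResult",
    "FitOptions",
    "build_dictionary",
    "compress_basis",
    "project",
    "fit_voxel",
    "fit_volume",
    "DEFAULT_BOUNDS",
]

#: default physical fitting bounds (natural units)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "m0s": (0.0, 0.5),
    "R1f": (0.1, 5.0),
    "R2f": (1.0, 50.0),
    "Rx": (1.0, 100.0),
    "R1s": (0.2, 20.0),
    "T2s": (1e-6, 50e-6),
    "omega_z": (-np.pi / 3.5e-3, np.pi / 3.5e-3),
    "b1": (0.5, 1.5),
}

_FREE_LABELS = ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s", "omega_z", "b1")
# rates and times are fitted in log space for positivity and scale balance
_LOG_LABELS = frozenset({"R1f", "R2f", "Rx", "R1s", "T2s"})


@dataclass
class Dictionary:
    """Cartesian-grid dictionary of unit-M0 fingerprints."""

    grid: dict[str, np.ndarray]
    params: np.ndarray  # (n_atoms, n_grid_params)
    atoms: np.ndarray  # (n_atoms, n_TR) complex
    seed: int | None = None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.grid.keys())


@dataclass
class SubspaceBasis:
    """Orthonormal complex basis of the fingerprint subspace."""

    basis: np.ndarray  # (n_TR, rank)
    singular_values: np.ndarray
    captured_energy: float

    @property
    def rank(self) -> int:
        return self.basis.shape[1]


@dataclass
class FitResult:
    """Voxel fit: parameter estimates plus convergence diagnostics."""

    tissue: TissueParameters
    system: SystemParameters
    residual_norm: float
    iterations: int
    converged: bool
    bound_hit: dict[str, bool]

    def as_vector(self, labels: tuple[str, ...] = _FREE_LABELS) -> np.ndarray:
        out = []
        for lab in labels:
            if lab == "omega_z":
                out.append(self.system.omega_z)
            elif lab == "b1":
                out.append(self.system.b1)
            else:
                out.append(getattr(self.tissue, lab))
        return np.array(out)


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_voxel` / :func:`fit_volume`.

    ``n_restarts`` jittered restarts are run after the dictionary-match (or
    user-supplied) initialization; the best residual wins, ties broken by
    the smaller m0s.  ``constraint`` is ``None``, ``("r1s_fixed", value)``
    or ``"r1s_equals_r1f"``.
    """

    bounds: tuple[tuple[str, tuple[float, float]], ...] = tuple(
        DEFAULT_BOUNDS.items()
    )
    constraint: object = None
    n_restarts: int = 2
    jitter: float = 0.1
    seed: int = 0
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int | None = None

    def bounds_dict(self) -> dict[str, tuple[float, float]]:
        return dict(self.bounds)


def build_dictionary(
    grid: dict[str, np.ndarray],
    train: PulseTrain,
    table: LinearizationTable,
    base_tissue: TissueParameters | None = None,
    base_system: SystemParameters | None = None,
) -> Dictionary:
    """One unit-M0 fingerprint per point of a Cartesian parameter grid.

    ``grid`` maps parameter labels (tissue fields, ``omega_z`` or ``b1``) to
    value lists; parameters not in the grid stay at ``base_tissue`` /
    ``base_system``.  Deterministic: identical grids give bit-identical
    dictionaries.
    """
    base_tissue = base_tissue or TissueParameters(
        m0s=0.2, R1f=0.5, R2f=15.0, Rx=15.0, R1s=3.0, T2s=10e-6
    )
    base_system = base_system or SystemParameters()
    labels = tuple(grid.keys())
    axes = [np.asarray(grid[lab], dtype=float) for lab in labels]
    combos = np.array(list(itertools.product(*axes)))
    atoms = []
    for row in combos:
        tis, sysp = base_tissue, base_system
        for lab, val in zip(labels, row):
            if lab == "omega_z":
                sysp = replace(sysp, omega_z=float(val))
            elif lab == "b1":
                sysp = replace(sysp, b1=float(val))
            else:
                tis = replace(tis, **{lab: float(val)})
        atoms.append(simulate_fingerprint(tis, sysp, train, table).signal)
    return Dictionary(
        grid={lab: ax for lab, ax in zip(labels, axes)},
        params=combos,
        atoms=np.asarray(atoms),
    )


def compress_basis(dictionary: Dictionary, rank: int) -> SubspaceBasis:
    """Rank-r SVD subspace of the dictionary's fingerprint matrix."""
    n_atoms, n_tr = dictionary.atoms.shape
    if not 1 <= rank <= min(n_atoms, n_tr):
        raise ValueError("rank out of range")
    _, s, vh = np.linalg.svd(dictionary.atoms, full_matrices=False)
    energy = float(np.sum(s[:rank] ** 2) / np.sum(s**2))
    return SubspaceBasis(vh[:rank].conj().T, s, energy)


def project(fingerprint: np.ndarray, basis: SubspaceBasis) -> np.ndarray:
    """Subspace coefficients ``B^H s`` of a fingerprint."""
    s = np.asarray(fingerprint)
    if s.shape[-1] != basis.basis.shape[0]:
        raise ValueError("fingerprint length does not match basis")
    return s @ np.conj(basis.basis)


def _match_dictionary(
    signal: np.ndarray, dictionary: Dictionary
) -> dict[str, float]:
    """Grid point of the atom with maximal normalized correlation."""
    norms = np.linalg.norm(dictionary.atoms, axis=1)
    scores = np.abs(dictionary.atoms.conj() @ signal) / norms
    best = int(np.argmax(scores))
    return dict(zip(dictionary.labels, dictionary.params[best]))


def _pack(values: dict[str, float], labels: tuple[str, ...]) -> np.ndarray:
    return np.array(
        [
            np.log(values[lab]) if lab in _LOG_LABELS else values[lab]
            for lab in labels
        ]
    )


def _unpack(x: np.ndarray, labels: tuple[str, ...]) -> dict[str, float]:
    return {
        lab: float(np.exp(v)) if lab in _LOG_LABELS else float(v)
        for lab, v in zip(labels, x)
    }


def _model_tuple(
    values: dict[str, float], constraint: object
) -> tuple[TissueParameters, SystemParameters]:
    vals = dict(values)
    if constraint == "r1s_equals_r1f":
        vals["R1s"] = vals["R1f"]
    elif isinstance(constraint, tuple) and constraint[0] == "r1s_fixed":
        vals["R1s"] = float(constraint[1])
    tissue = TissueParameters(
        m0s=vals["m0s"],
        R1f=vals["R1f"],
        R2f=vals["R2f"],
        Rx=vals["Rx"],
        R1s=vals["R1s"],
        T2s=vals["T2s"],
    )
    system = SystemParameters(
        omega_z=vals.get("omega_z", 0.0), b1=vals.get("b1", 1.0)
    )
    return tissue, system


def _varpro_residual(
    model: np.ndarray, signal: np.ndarray
) -> tuple[np.ndarray, complex]:
    """Residual after analytically eliminating the complex scale M0."""
    denom = np.vdot(model, model).real
    if denom == 0:
        return np.concatenate([signal.real, signal.imag]), 0.0 + 0.0j
    m0 = np.vdot(model, signal) / denom
    r = signal - m0 * model
    return np.concatenate([r.real, r.imag]), m0


def fit_voxel(
    signal: np.ndarray,
    train: PulseTrain,
    table: LinearizationTable,
    options: FitOptions | None = None,
    init: dict[str, float] | None = None,
    dictionary: Dictionary | None = None,
    basis: SubspaceBasis | None = None,
) -> FitResult:
    """Bounded nonlinear least-squares fit of one voxel's signal.

    Minimizes ``||s - M0 f(theta)||^2`` over the real unknowns ``theta``
    (m0s, R1f, R2f, Rx, R1s, T2s, omega_z, b1, minus any constrained ones),
    with the complex M0 eliminated in closed form at every iterate
    (variable projection), a trust-region-reflective bounded solver, and
    log-parameterized rates.  Initialization comes from ``init`` if given,
    else from the best-matching atom of ``dictionary``; ``n_restarts``
    jittered restarts guard against local minima.  If ``basis`` is given,
    ``signal`` is interpreted as subspace coefficients and the model is
    projected through the same basis.
    """
    options = options or FitOptions()
    signal = np.asarray(signal, dtype=complex)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    bounds = options.bounds_dict()
    labels = [lab for lab in _FREE_LABELS if lab in bounds]
    if options.constraint == "r1s_equals_r1f":
        labels.remove("R1s")
    elif (
        isinstance(options.constraint, tuple)
        and options.constraint[0] == "r1s_fixed"
    ):
        labels.remove("R1s")
    labels = tuple(labels)

    if init is not None:
        start = {lab: init[lab] for lab in labels}
    elif dictionary is not None:
        matched = _match_dictionary(
            signal if basis is None else signal, dictionary
        )
        start = {}
        for lab in labels:
            if lab in matched:
                start[lab] = matched[lab]
            else:
                lo, hi = bounds[lab]
                start[lab] = 0.5 * (lo + hi)
    else:
        raise ValueError("provide either init or a dictionary for initialization")
    for lab in labels:
        lo, hi = bounds[lab]
        start[lab] = float(np.clip(start[lab], lo, hi))

    lo_vec = _pack({lab: bounds[lab][0] for lab in labels}, labels)
    hi_vec = _pack({lab: bounds[lab][1] for lab in labels}, labels)
    # guard the log transform: replace log(0) bounds with a wide floor
    lo_vec = np.where(np.isfinite(lo_vec), lo_vec, -50.0)

    def residual(x: np.ndarray) -> np.ndarray:
        vals = _unpack(x, labels)
        tissue, system = _model_tuple(vals, options.constraint)
        # clamp table-hull excursions of transient iterates (extreme T2s or
        # b1 trial points); near the solution all queries are in-hull
        model = simulate_fingerprint(
            tissue, system, train, table, hull="clamp"
        ).signal
        if basis is not None:
            model = project(model, basis)
        return _varpro_residual(model, signal)[0]

    rng = np.random.default_rng(options.seed)
    starts = [_pack(start, labels)]
    for _ in range(options.n_restarts):
        x = starts[0].copy()
        jit = options.jitter * (hi_vec - lo_vec)
        x = np.clip(x + rng.uniform(-1, 1, x.size) * jit, lo_vec, hi_vec)
        starts.append(x)

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residual,
                np.clip(x0, lo_vec, hi_vec),
                bounds=(lo_vec, hi_vec),
                method="trf",
                x_scale="jac",
                xtol=options.xtol,
                gtol=options.gtol,
                ftol=options.xtol,
                max_nfev=options.max_nfev,
                diff_step=1e-6,
            )
        except Exception:
            continue
        key = (sol.cost, _unpack(sol.x, labels).get("m0s", 0.0))
        if best is None or key < (best[0].cost, best[1].get("m0s", 0.0)):
            best = (sol, _unpack(sol.x, labels))
    if best is None:
        # every start diverged: flag, return the initial guess unfitted
        vals = _unpack(starts[0], labels)
        tissue, system = _model_tuple(vals, options.constraint)
        model = simulate_fingerprint(
            tissue, system, train, table, hull="clamp"
        ).signal
        if basis is not None:
            model = project(model, basis)
        r, m0 = _varpro_residual(model, signal)
        return FitResult(
            tissue,
            replace(system, m0_complex=m0),
            float(np.linalg.norm(r)),
            0,
            False,
            {lab: False for lab in labels},
        )
    sol, vals = best
    tissue, system = _model_tuple(vals, options.constraint)
    model = simulate_fingerprint(
        tissue, system, train, table, hull="clamp"
    ).signal
    if basis is not None:
        model = project(model, basis)
    _, m0 = _varpro_residual(model, signal)
    tol = 1e-8
    bound_hit = {
        lab: bool(
            sol.x[i] <= lo_vec[i] + tol or sol.x[i] >= hi_vec[i] - tol
        )
        for i, lab in enumerate(labels)
    }
    return FitResult(
        tissue,
        replace(system, m0_complex=complex(m0)),
        float(np.sqrt(2 * sol.cost)),
        int(sol.nfev),
        bool(sol.status > 0),
        bound_hit,
    )


def fit_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    train: PulseTrain,
    table: LinearizationTable,
    options: FitOptions | None = None,
    dictionary: Dictionary | None = None,
    basis: SubspaceBasis | None = None,
    progress: bool = False,
) -> dict[str, np.ndarray]:
    """Independent :func:`fit_voxel` per masked voxel of a fingerprint volume.

    ``volume`` has shape ``(*spatial, n_TR)`` and ``mask`` shape
    ``(*spatial,)``.  Returns float maps for every tissue/system parameter
    plus ``m0_abs``, ``m0_phase``, ``residual`` and an integer ``flags`` map
    (0 ok, 1 bound-pinned, 2 not converged); failures are flagged, never
    raised.  Voxel order is irrelevant to the results.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape[:-1] != mask.shape:
        raise ValueError("mask shape must match the spatial shape")
    spatial = mask.shape
    out_labels = list(_FREE_LABELS) + ["m0_abs", "m0_phase", "residual"]
    maps = {lab: np.full(spatial, np.nan, dtype=float) for lab in out_labels}
    flags = np.zeros(spatial, dtype=np.int16)
    idxs = np.argwhere(mask)
    for count, idx in enumerate(map(tuple, idxs)):
        try:
            fit = fit_voxel(
                volume[idx],
                train,
                table,
                options=options,
                dictionary=dictionary,
                basis=basis,
            )
        except Exception:
            flags[idx] = 3
            continue
        vec = fit.as_vector()
        for lab, val in zip(_FREE_LABELS, vec):
            maps[lab][idx] = val
        maps["m0_abs"][idx] = abs(fit.system.m0_complex)
        maps["m0_phase"][idx] = np.angle(fit.system.m0_complex)
        maps["residual"][idx] = fit.residual_norm
        if any(fit.bound_hit.values()):
            flags[idx] = 1
        elif not fit.converged:
            flags[idx] = 2
        if progress and (count + 1) % 50 == 0:
            print(f"fitted {count + 1}/{len(idxs)} voxels")
    maps["flags"] = flags
    return maps
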