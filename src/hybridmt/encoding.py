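"""Cramér-Rao bounds over fingerprints and CRB-driven train optimization.

The Cramér-Rao bound (CRB) lower-bounds the variance of any unbiased
estimator of the tissue/system parameters from a noisy fingerprint.  With
i.i.d. complex Gaussian noise of standard deviation ``sigma`` per real
channel, the Fisher information of the real parameter vector is
``F = Re(J^H J) / sigma^2`` where ``J`` is the complex signal Jacobian, and
``CRB(theta) = [F^-1]_(theta,theta)``.  Because the signal is linear in the
complex scale M0, its two real components always count as unknowns; fixing
nuisance parameters can only shrink the bound (information nesting).

The pulse train (flip angles, pulse durations) is the experiment design:
optimizing a weighted sum of normalized CRBs over the train is how the
sequence is tuned to disentangle the MT parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .generalized_bloch import LinearizationTable
from .mt_model import SystemParameters, TissueParameters
from .sequence import PulseTrain, simulate_fingerprint

__all__ = [
    "ParameterSet",
    "CRBResult",
    "signal_jacobian",
    "crb",
    "optimize_train",
    "constrained_vs_unconstrained_crb",
    "DEFAULT_UNKNOWNS",
]

#: the nine real unknowns of the full voxel model
DEFAULT_UNKNOWNS = (
    "m0_re",
    "m0_im",
    "m0s",
    "R1f",
    "R2f",
    "Rx",
    "R1s",
    "T2s",
    "omega_z",
    "b1",
)

_TISSUE_FIELDS = ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s")


@dataclass(frozen=True)
class ParameterSet:
    """Ordered unknowns and their reference values for CRB normalization."""

    labels: tuple[str, ...]
    reference: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        for lab in self.labels:
            if lab not in DEFAULT_UNKNOWNS:
                raise ValueError(f"unknown parameter label {lab!r}")
        if len(self.reference) != len(self.labels):
            raise ValueError("reference length must match labels")

    @classmethod
    def from_model(
        cls,
        tissue: TissueParameters,
        system: SystemParameters,
        labels: tuple[str, ...] = DEFAULT_UNKNOWNS,
    ) -> "ParameterSet":
        """Parameter set with reference values taken from a model point."""
        ref = []
        for lab in labels:
            if lab == "m0_re":
                ref.append(float(np.real(system.m0_complex)))
            elif lab == "m0_im":
                ref.append(float(np.imag(system.m0_complex)))
            elif lab == "omega_z":
                ref.append(system.omega_z)
            elif lab == "b1":
                ref.append(system.b1)
            else:
                ref.append(float(getattr(tissue, lab)))
        return cls(tuple(labels), tuple(ref))


@dataclass
class CRBResult:
    """Fisher matrix, per-parameter CRB and normalized CRB."""

    labels: tuple[str, ...]
    fisher: np.ndarray
    crb: np.ndarray
    normalized_crb: np.ndarray
    condition_number: float

    def __getitem__(self, label: str) -> float:
        return float(self.crb[self.labels.index(label)])

    def normalized(self, label: str) -> float:
        return float(self.normalized_crb[self.labels.index(label)])


def _perturbed(
    tissue: TissueParameters,
    system: SystemParameters,
    label: str,
    value: float,
) -> tuple[TissueParameters, SystemParameters]:
    if label in _TISSUE_FIELDS:
        return replace(tissue, **{label: value}), system
    if label == "omega_z":
        return tissue, replace(system, omega_z=value)
    if label == "b1":
        return tissue, replace(system, b1=value)
    raise ValueError(f"cannot perturb {label!r}")


def _get_value(
    tissue: TissueParameters, system: SystemParameters, label: str
) -> float:
    if label in _TISSUE_FIELDS:
        return float(getattr(tissue, label))
    if label == "omega_z":
        return system.omega_z
    return system.b1


def signal_jacobian(
    tissue: TissueParameters,
    system: SystemParameters,
    train: PulseTrain,
    table: LinearizationTable,
    params: ParameterSet,
    rel_step: float = 1e-5,
) -> np.ndarray:
    """Complex Jacobian of the fingerprint wrt the unknown parameters.

    Derivatives wrt the real and imaginary parts of M0 are analytic (the
    signal is linear in M0); all others are central finite differences with
    per-parameter relative step ``rel_step`` and an absolute floor of 1e-8
    for parameters near zero (such as ``omega_z``).  Returns an
    ``(n_TR, n_params)`` complex matrix.
    """
    if not 1e-7 <= rel_step <= 1e-2:
        raise ValueError("rel_step must be in [1e-7, 1e-2]")
    base = simulate_fingerprint(tissue, system, train, table).signal
    unit = base / system.m0_complex
    J = np.empty((len(base), len(params.labels)), dtype=complex)
    for k, lab in enumerate(params.labels):
        if lab == "m0_re":
            J[:, k] = unit
        elif lab == "m0_im":
            J[:, k] = 1j * unit
        else:
            val = _get_value(tissue, system, lab)
            h = max(abs(val) * rel_step, 1e-8)
            tp, sp = _perturbed(tissue, system, lab, val + h)
            tm, sm = _perturbed(tissue, system, lab, val - h)
            sp_sig = simulate_fingerprint(tp, sp, train, table).signal
            sm_sig = simulate_fingerprint(tm, sm, train, table).signal
            J[:, k] = (sp_sig - sm_sig) / (2 * h)
    return J


def crb(
    jacobian: np.ndarray,
    sigma: float,
    params: ParameterSet,
    t_total: float = 1.0,
    m0_scale: float = 1.0,
) -> CRBResult:
    """Cramér-Rao bounds from a complex signal Jacobian.

    ``fisher = Re(J^H J) / sigma^2``; the CRB is the diagonal of its
    inverse.  The normalized CRB follows the convention
    ``rCRB(theta) = CRB(theta) * T_total * (|M0| / sigma)^2 / theta_ref^2``,
    which has units of time and removes the trivial dependence on scan
    time, signal scale and noise level; ``t_total`` is the total
    acquisition time and ``m0_scale`` the magnitude of M0.  Parameters with
    zero reference value get a NaN normalized bound.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    F = np.real(jacobian.conj().T @ jacobian) / sigma**2
    n = F.shape[0]
    # invert on the correlation scale: the raw Fisher matrix mixes parameter
    # units (seconds vs rates) and its condition number reflects that scale
    # disparity, not information loss
    d = np.sqrt(np.diag(F))
    if np.any(d == 0):
        cond = np.inf
        bounds = np.full(n, np.inf)
    else:
        C = F / np.outer(d, d)
        cond = float(np.linalg.cond(C))
        if cond > 1e12:
            bounds = np.full(n, np.inf)
        else:
            bounds = np.diag(np.linalg.inv(C)) / d**2
    ref = np.asarray(params.reference, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = bounds * t_total * (m0_scale / sigma) ** 2 / ref**2
        norm[ref == 0] = np.nan
    return CRBResult(params.labels, F, bounds, norm, cond)


def compute_crb(
    tissue: TissueParameters,
    system: SystemParameters,
    train: PulseTrain,
    table: LinearizationTable,
    params: ParameterSet | None = None,
    sigma: float = 1.0,
    rel_step: float = 1e-5,
) -> CRBResult:
    """Convenience wrapper: Jacobian + CRB at a model point."""
    if params is None:
        params = ParameterSet.from_model(tissue, system)
    J = signal_jacobian(tissue, system, train, table, params, rel_step)
    t_total = train.n_pulses * train.tr
    return crb(J, sigma, params, t_total, abs(system.m0_complex))


def _smoothness_penalty(alphas: np.ndarray, limit: float = 0.1) -> float:
    excess = np.abs(np.diff(alphas)) - limit
    return float(np.sum(np.clip(excess, 0.0, None) ** 2))


def optimize_train(
    initial: PulseTrain,
    tissue: TissueParameters,
    system: SystemParameters,
    table: LinearizationTable,
    params: ParameterSet | None = None,
    weights: dict[str, float] | None = None,
    alpha_bounds: tuple[float, float] = (0.01, np.pi),
    trf_bounds: tuple[float, float] = (100e-6, 1e-3),
    max_iter: int = 20,
    sigma: float = 1.0,
    progress: list | None = None,
) -> PulseTrain:
    """Locally minimize a weighted sum of normalized CRBs over the train.

    Optimizes the flip angles and pulse durations under box bounds (enforced
    by a logistic reparameterization, so the quasi-Newton iteration is
    unconstrained) and the hybrid-state smoothness bound
    ``|d alpha| <= 0.1 rad`` between neighbors (quadratic penalty).  Returns
    the optimized train if its objective improves on the initial one, else
    the initial train (monotone acceptance).  Deterministic.  If ``progress``
    is a list, it receives one record per iteration (objective, max |d
    alpha|).
    """
    if params is None:
        params = ParameterSet.from_model(tissue, system)
    if weights is None:
        weights = {lab: 1.0 for lab in params.labels if lab.startswith(("m0s",))}
        weights = weights or {params.labels[0]: 1.0}
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be >= 0")
    a_lo, a_hi = alpha_bounds
    t_lo, t_hi = trf_bounds
    if not (0 < a_lo < a_hi <= np.pi and 0 < t_lo < t_hi <= initial.tr):
        raise ValueError("infeasible bounds")
    w_vec = np.array([weights.get(lab, 0.0) for lab in params.labels])

    def to_unconstrained(x, lo, hi):
        p = np.clip((x - lo) / (hi - lo), 1e-6, 1 - 1e-6)
        return np.log(p / (1 - p))

    def from_unconstrained(y, lo, hi):
        return lo + (hi - lo) / (1.0 + np.exp(-y))

    # the trf axis is log-scaled in effect through the logistic map itself
    def objective(y: np.ndarray) -> float:
        n = initial.n_pulses
        alphas = from_unconstrained(y[:n], a_lo, a_hi)
        trfs = from_unconstrained(y[n:], t_lo, t_hi)
        train = initial.with_angles(alphas, trfs)
        res = compute_crb(tissue, system, train, table, params, sigma)
        vals = np.where(np.isnan(res.normalized_crb), 0.0, res.normalized_crb)
        return float(vals @ w_vec) * (
            1.0 + 100.0 * _smoothness_penalty(alphas)
        )

    y0 = np.concatenate(
        [
            to_unconstrained(initial.alphas, a_lo, a_hi),
            to_unconstrained(initial.trfs, t_lo, t_hi),
        ]
    )
    f0 = objective(y0)
    if max_iter == 0:
        return initial

    def record(y: np.ndarray) -> None:
        if progress is not None:
            n = initial.n_pulses
            alphas = from_unconstrained(y[:n], a_lo, a_hi)
            progress.append(
                {
                    "objective": objective(y),
                    "max_dalpha": float(np.max(np.abs(np.diff(alphas)))),
                }
            )

    res = minimize(
        objective,
        y0,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_iter, "eps": 1e-3},
    )
    if res.fun >= f0:
        return initial
    n = initial.n_pulses
    alphas = from_unconstrained(res.x[:n], a_lo, a_hi)
    trfs = from_unconstrained(res.x[n:], t_lo, t_hi)
    # project residual smoothness violations onto the feasible set
    for i in range(1, n):
        d = alphas[i] - alphas[i - 1]
        if abs(d) > 0.1:
            alphas[i] = alphas[i - 1] + np.sign(d) * 0.1
    return initial.with_angles(np.clip(alphas, a_lo, a_hi), trfs)


def constrained_vs_unconstrained_crb(
    tissue: TissueParameters,
    system: SystemParameters,
    train: PulseTrain,
    table: LinearizationTable,
    fixed: dict[str, float],
    sigma: float = 1.0,
) -> dict[str, dict[str, float]]:
    """CRB ratios between the full model and one with parameters fixed.

    ``fixed`` maps parameter labels to their (assumed known) values; those
    parameters are removed from the unknown set.  Returns, per remaining
    parameter, the unconstrained and constrained CRBs and their ratio
    (always >= 1 by information nesting).
    """
    full = ParameterSet.from_model(tissue, system)
    if not set(fixed) <= set(full.labels):
        raise ValueError("fixed labels must be model parameters")
    for lab, val in fixed.items():
        tissue, system = _perturbed(tissue, system, lab, val)
    kept = tuple(lab for lab in full.labels if lab not in fixed)
    sub = ParameterSet.from_model(tissue, system, kept)
    full = ParameterSet.from_model(tissue, system)
    res_full = compute_crb(tissue, system, train, table, full, sigma)
    res_sub = compute_crb(tissue, system, train, table, sub, sigma)
    out = {}
    for lab in kept:
        u, c = res_full[lab], res_sub[lab]
        out[lab] = {
            "unconstrained": u,
            "constrained": c,
            "ratio": u / c if c > 0 else np.inf,
        }
    return out
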