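"""Core two-pool magnetization-transfer (MT) model.

The model splits the proton magnetization of a voxel into a *free* pool
(water, exponential relaxation, observable) and a *semi-solid* pool
(macromolecule-bound protons, T2s ~ 10 us, invisible to direct acquisition).
The two pools exchange longitudinal magnetization at rate ``Rx``, which makes
the observed longitudinal relaxation bi-exponential.  The state is written as
a homogeneous 6-vector ``(xf, yf, zf, xs, zs, 1)`` so that relaxation toward a
non-zero thermal equilibrium becomes a linear (matrix) operation.

This module provides the state/parameter containers, the Bloch-McConnell
generator matrix and its exact propagator, the eigen-analysis of the
longitudinal sub-system, the Taylor-expanded *apparent* parameters that an
``R1s = R1f``-constrained model would report, pool-fraction normalization
conversions, and Bloembergen-Purcell-Pound (BPP) reference rates for pure
water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "TissueParameters",
    "SystemParameters",
    "MagnetizationState",
    "thermal_equilibrium",
    "build_generator",
    "propagate",
    "eigen_relaxation",
    "taylor_apparent",
    "pool_fraction_convert",
    "bpp_rates",
    "bpp_relative_change",
    "GAMMA_H",
]

#: proton gyromagnetic ratio, rad/s/T
GAMMA_H = 2 * np.pi * 42.577478518e6

# vacuum permeability and reduced Planck constant (SI)
_MU0 = 4e-7 * np.pi
_HBAR = 1.054571817e-34
#: default intra-molecular proton-proton distance in water, m
DEFAULT_R_HH = 1.58e-10


@dataclass(frozen=True)
class TissueParameters:
    """The six biophysical unknowns of the unconstrained MT model.

    Parameters
    ----------
    m0s : float
        Semi-solid pool fraction, normalized so that ``m0f + m0s = 1``;
        dimensionless, in ``[0, 1)``.
    R1f, R2f : float
        Longitudinal / transverse relaxation rates of the free pool, 1/s.
    Rx : float
        Exchange rate between the pools, 1/s.
    R1s : float
        Longitudinal relaxation rate of the semi-solid pool, 1/s.
    T2s : float
        Transverse relaxation time of the semi-solid pool, s
        (``R2s = 1/T2s``).
    """

    m0s: float
    R1f: float
    R2f: float
    Rx: float
    R1s: float
    T2s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m0s < 1.0:
            raise ValueError(f"m0s must be in [0, 1), got {self.m0s}")
        for name in ("R1f", "R2f", "Rx", "R1s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.T2s <= 0:
            raise ValueError("T2s must be > 0")

    @property
    def m0f(self) -> float:
        """Free-pool fraction, always derived as ``1 - m0s``."""
        return 1.0 - self.m0s

    @property
    def R2s(self) -> float:
        """Semi-solid transverse rate ``1/T2s``, 1/s."""
        return 1.0 / self.T2s


@dataclass(frozen=True)
class SystemParameters:
    """Scanner/system parameters of a voxel.

    ``omega_z`` is the off-resonance angular frequency (rad/s), ``b1`` the
    relative transmit-field scale (actual over nominal Rabi frequency), and
    ``m0_complex`` the complex overall scale combining spin density and
    receive-coil sensitivity.
    """

    omega_z: float = 0.0
    b1: float = 1.0
    m0_complex: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if self.b1 <= 0:
            raise ValueError("b1 must be > 0")


@dataclass
class MagnetizationState:
    """Homogeneous state vector ``(xf, yf, zf, xs, zs, 1)``."""

    vec: np.ndarray = field(
        default_factory=lambda: np.array([0, 0, 1, 0, 0, 1], dtype=float)
    )

    def __post_init__(self) -> None:
        self.vec = np.asarray(self.vec, dtype=float)
        if self.vec.shape != (6,):
            raise ValueError("state must be a 6-vector")

    @property
    def xf(self) -> float:
        return float(self.vec[0])

    @property
    def yf(self) -> float:
        return float(self.vec[1])

    @property
    def zf(self) -> float:
        return float(self.vec[2])

    @property
    def xs(self) -> float:
        return float(self.vec[3])

    @property
    def zs(self) -> float:
        return float(self.vec[4])


def thermal_equilibrium(tissue: TissueParameters) -> MagnetizationState:
    """Thermal-equilibrium state ``(0, 0, m0f, 0, m0s, 1)``."""
    return MagnetizationState(
        np.array([0.0, 0.0, tissue.m0f, 0.0, tissue.m0s, 1.0])
    )


def build_generator(
    tissue: TissueParameters,
    omega_y: float,
    omega_z: float,
    r2sl: float,
) -> np.ndarray:
    """Bloch-McConnell generator matrix of the two-pool system.

    The returned 6x6 matrix ``G`` defines ``d/dt M = G M`` for the homogeneous
    state ``(xf, yf, zf, xs, zs, 1)``.  ``omega_y`` is the (signed) Rabi
    frequency of the RF pulse in effect, ``omega_z`` the off-resonance
    frequency and ``r2sl`` the linearized semi-solid transverse rate for that
    pulse (see :mod:`hybridmt.generalized_bloch`); the ``ys`` component is
    neglected (``omega_x = 0`` and ``r2sl >> omega_z``).

    Exchange couples only the longitudinal components, with rates
    ``Rx*m0s`` out of and ``Rx*m0f`` into the free pool; the last column
    carries the recovery terms ``m0f*R1f`` and ``m0s*R1s`` and the last row
    is zero so the homogeneous component stays 1.
    """
    if r2sl < 0:
        raise ValueError("r2sl must be >= 0")
    t = tissue
    G = np.zeros((6, 6))
    # free pool: rotation about y couples xf and zf
    G[0, 0] = -t.R2f
    G[0, 1] = -omega_z
    G[0, 2] = omega_y
    G[1, 0] = omega_z
    G[1, 1] = -t.R2f
    # free pool longitudinal with exchange and recovery
    G[2, 0] = -omega_y
    G[2, 2] = -t.R1f - t.Rx * t.m0s
    G[2, 4] = t.Rx * t.m0f
    G[2, 5] = t.m0f * t.R1f
    # semi-solid pool
    G[3, 3] = -r2sl
    G[3, 4] = omega_y
    G[4, 2] = t.Rx * t.m0s
    G[4, 3] = -omega_y
    G[4, 4] = -t.R1s - t.Rx * t.m0f
    G[4, 5] = t.m0s * t.R1s
    return G


def propagate(
    state: MagnetizationState, generator: np.ndarray, duration: float
) -> MagnetizationState:
    """Evolve a state by ``exp(generator * duration)`` (exact LTI solution)."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if not np.all(np.isfinite(generator)):
        raise ValueError("generator has non-finite entries")
    if duration == 0:
        return MagnetizationState(state.vec.copy())
    out = expm(generator * duration) @ state.vec
    return MagnetizationState(out)


def longitudinal_subblock(tissue: TissueParameters) -> np.ndarray:
    """Homogeneous 2x2 block of the (zf, zs) sub-system without RF."""
    t = tissue
    return np.array(
        [
            [-t.R1f - t.Rx * t.m0s, t.Rx * t.m0f],
            [t.Rx * t.m0s, -t.R1s - t.Rx * t.m0f],
        ]
    )


def eigen_relaxation(tissue: TissueParameters) -> tuple[float, float]:
    """Exact apparent relaxation rates from the longitudinal eigen-system.

    Without RF the (zf, zs, 1) sub-system has three eigenvalues: zero
    (thermal equilibrium) and two negative ones.  The smaller-magnitude one is
    the apparent free-pool relaxation rate ``R1f_a`` and the larger-magnitude
    one the apparent exchange (cross-relaxation) rate ``Rx_a``.  Both are
    returned as positive rates.
    """
    t = tissue
    if t.R1f <= 0 or t.R1s <= 0 or t.Rx <= 0 or not 0 < t.m0s < 1:
        raise ValueError("eigen_relaxation requires R1f, R1s, Rx > 0 and 0 < m0s < 1")
    ev = np.linalg.eigvals(longitudinal_subblock(t))
    ev = np.sort(np.real(ev))[::-1]  # both real and negative
    if np.isclose(ev[0], ev[1], rtol=1e-12, atol=1e-12):
        raise ValueError(f"degenerate longitudinal eigenvalues {ev}")
    return float(-ev[0]), float(-ev[1])


def taylor_apparent(
    tissue: TissueParameters, order: int = 2
) -> tuple[float, float, float]:
    """Apparent parameters of an ``R1s = R1f``-constrained model.

    Returns ``(r1f_apparent, rx_apparent, m0s_apparent)`` from a Taylor
    expansion of the longitudinal eigen-system around ``R1s = R1f``:

    .. math::

        R_1^{f,a} \\approx R_1^f + m_0^s \\delta - m_0^f m_0^s \\delta^2/R_x,
        \\qquad
        R_x^{a} \\approx (R_x + R_1^f) + m_0^f \\delta
                 + m_0^f m_0^s \\delta^2/R_x,

    with :math:`\\delta = R_1^s - R_1^f`, and

    .. math:: m_0^{s,a} \\approx m_0^s (1 - 2 m_0^f \\delta / R_x).

    ``order=1`` keeps only terms linear in ``delta`` in the two rates;
    ``order=2`` adds the quadratic terms.  Since ``R1s > R1f`` in brain
    tissue, the constrained model underestimates both ``R1f`` and ``m0s``.
    With ``Rx = 0`` the exchange-mediated corrections are undefined; the
    function then falls back to the order-1 rates and leaves ``m0s``
    unchanged, with a warning.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    t = tissue
    delta = t.R1s - t.R1f
    r1f_a = t.R1f + t.m0s * delta
    rx_a = t.Rx + t.R1f + t.m0f * delta
    if t.Rx == 0:
        warnings.warn(
            "Rx = 0: returning order-1 rates and uncorrected m0s",
            RuntimeWarning,
            stacklevel=2,
        )
        return r1f_a, rx_a, t.m0s
    m0s_a = t.m0s * (1.0 - 2.0 * t.m0f * delta / t.Rx)
    if order == 2:
        quad = t.m0f * t.m0s * delta**2 / t.Rx
        r1f_a -= quad
        rx_a += quad
    return r1f_a, rx_a, m0s_a


def pool_fraction_convert(value: float, direction: str) -> float:
    """Convert between the two semi-solid pool-size normalizations.

    ``tilde_to_plain`` maps the free-pool-normalized fraction
    ``m~0s = m0s/m0f`` to the total-pool fraction ``m0s = m~0s/(1 + m~0s)``;
    ``plain_to_tilde`` is the inverse ``m~0s = m0s/(1 - m0s)``.
    """
    if direction == "tilde_to_plain":
        if value < 0:
            raise ValueError("tilde fraction must be >= 0")
        return value / (1.0 + value)
    if direction == "plain_to_tilde":
        if not 0.0 <= value < 1.0:
            raise ValueError("total-pool fraction must be in [0, 1)")
        return value / (1.0 - value)
    raise ValueError("direction must be 'tilde_to_plain' or 'plain_to_tilde'")


def _bpp_spectral_density(omega: float | np.ndarray, tau_c: float):
    """BPP spectral density ``J(w) = tau_c / (1 + w^2 tau_c^2)``."""
    return tau_c / (1.0 + (omega * tau_c) ** 2)


def bpp_rates(
    tau_c: float, omega_0: float, r_hh: float = DEFAULT_R_HH
) -> tuple[float, float]:
    """Bloembergen-Purcell-Pound relaxation rates of pure water.

    Intramolecular homonuclear dipolar relaxation of a two-spin system with
    rotational correlation time ``tau_c`` (s) at Larmor frequency ``omega_0``
    (rad/s) and inter-proton distance ``r_hh`` (m):

    ``R1 = (3/10) b^2 [J(w0) + 4 J(2 w0)]`` and
    ``R2 = (3/20) b^2 [3 J(0) + 5 J(w0) + 2 J(2 w0)]`` with dipolar coupling
    ``b = mu0 gamma^2 hbar / (4 pi r_hh^3)``.  The absolute rates scale as
    ``r_hh^-6``; the default 1.58 Angstrom is the conventional water H-H
    distance.
    """
    if tau_c <= 0 or omega_0 <= 0 or r_hh <= 0:
        raise ValueError("tau_c, omega_0 and r_hh must be > 0")
    b = _MU0 * GAMMA_H**2 * _HBAR / (4 * np.pi * r_hh**3)
    J = _bpp_spectral_density
    r1 = 0.3 * b**2 * (J(omega_0, tau_c) + 4 * J(2 * omega_0, tau_c))
    r2 = 0.15 * b**2 * (
        3 * J(0.0, tau_c) + 5 * J(omega_0, tau_c) + 2 * J(2 * omega_0, tau_c)
    )
    return float(r1), float(r2)


def bpp_relative_change(
    tau_c: float, omega_a: float, omega_b: float, which: str = "R1"
) -> float:
    """Relative BPP rate change between two Larmor frequencies, in percent.

    Returns ``100 * (R(omega_a) - R(omega_b)) / R(omega_a)``.  The dipolar
    prefactor cancels, so the result is independent of the inter-proton
    distance.  For pure water at clinical field strengths the dispersion is
    tiny (hundredths of a permille), which is why free-water relaxation is
    treated as field-independent.
    """
    if tau_c <= 0 or omega_a <= 0 or omega_b <= 0:
        raise ValueError("inputs must be > 0")
    if which not in ("R1", "R2"):
        raise ValueError("which must be 'R1' or 'R2'")
    idx = 0 if which == "R1" else 1
    ra = bpp_rates(tau_c, omega_a)[idx]
    rb = bpp_rates(tau_c, omega_b)[idx]
    return 100.0 * (ra - rb) / ra
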