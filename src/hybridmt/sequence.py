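"""Hybrid-state pulse trains and periodic fingerprint simulation.

The pulse sequence is an anti-periodic balanced SSFP variant: a rectangular
pi inversion pulse (flanked by crusher gradients) followed by a train of
rectangular RF pulses with slowly varying flip angles and durations,
separated by a fixed TR and phase-cycled by pi between consecutive pulses.
After one *cycle* (1142 pulses in 4 s at TR = 3.5 ms by default) the train
repeats, so the magnetization settles into a periodic steady cycle.  Slow
flip-angle variation keeps the spins in the *hybrid state*: adiabatic in
direction, transient in magnitude, which is what encodes the relaxation and
magnetization-transfer parameters into the signal time course (the
*fingerprint*).

Since the dynamics within a cycle are affine in the homogeneous 6-vector,
the steady cycle is found exactly as a linear fixed point rather than by
long transient simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .generalized_bloch import LinearizationTable
from .mt_model import (
    MagnetizationState,
    SystemParameters,
    TissueParameters,
    build_generator,
    thermal_equilibrium,
)

__all__ = [
    "RFPulse",
    "PulseTrain",
    "Fingerprint",
    "n_pulses_per_cycle",
    "default_train",
    "inversion_operator",
    "simulate_fingerprint",
    "simulate_transient",
    "effective_resolution",
]


@dataclass(frozen=True)
class RFPulse:
    """A rectangular RF pulse: flip angle (rad), duration (s), phase (rad)."""

    alpha: float
    trf: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= np.pi:
            raise ValueError("alpha must be in [0, pi]")
        if self.trf <= 0:
            raise ValueError("trf must be > 0")


@dataclass(frozen=True)
class PulseTrain:
    """An ordered cycle of RF pulses plus timing and inversion-pulse spec.

    ``pulses`` are played TR-aligned (each pulse centered within its TR),
    with phases alternating by pi between consecutive pulses.  ``cycle_time``
    is the duration of one repetition of the train including the inversion
    pulse.  ``sample_delay`` is the signal sampling time measured from the
    end of each pulse; ``None`` samples midway between pulses (the balanced
    SSFP echo).
    """

    pulses: tuple[RFPulse, ...]
    tr: float = 3.5e-3
    cycle_time: float = 4.0
    inversion: RFPulse = field(
        default_factory=lambda: RFPulse(np.pi, 500e-6, 0.0)
    )
    sample_delay: float | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if len(self.pulses) * self.tr > self.cycle_time + self.tr:
            raise ValueError("pulses do not fit into the cycle time")
        for p in self.pulses:
            if p.trf > self.tr:
                raise ValueError("pulse duration exceeds TR")
        phases = np.array([p.phase for p in self.pulses])
        if len(phases) > 1 and not np.allclose(
            np.abs(np.diff(phases)) % (2 * np.pi), np.pi
        ):
            raise ValueError("RF phase must alternate by pi between pulses")

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([p.alpha for p in self.pulses])

    @property
    def trfs(self) -> np.ndarray:
        return np.array([p.trf for p in self.pulses])

    def with_angles(
        self, alphas: np.ndarray, trfs: np.ndarray | None = None
    ) -> "PulseTrain":
        """Copy of the train with new flip angles (and optionally durations)."""
        trfs = self.trfs if trfs is None else np.asarray(trfs, dtype=float)
        pulses = tuple(
            RFPulse(float(a), float(t), p.phase)
            for a, t, p in zip(alphas, trfs, self.pulses)
        )
        return replace(self, pulses=pulses)


@dataclass
class Fingerprint:
    """Complex signal per TR over one steady cycle, scaled by complex M0."""

    signal: np.ndarray
    tr: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=complex)
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("fingerprint must be finite")


def n_pulses_per_cycle(cycle_time: float, tr: float) -> int:
    """Number of TR-aligned pulses fitting into one cycle: floor(Tc/TR)."""
    if cycle_time <= 0 or tr <= 0:
        raise ValueError("cycle_time and tr must be > 0")
    return int(np.floor(cycle_time / tr + 1e-12))


def default_train(
    n_pulses: int, tr: float = 3.5e-3, seed: int = 0
) -> PulseTrain:
    """Smooth pseudo-random hybrid-state train.

    Flip angles are a seeded sum of five low-frequency sinusoids mapped into
    [alpha_min, 0.9 pi], rescaled if needed so that neighboring pulses differ
    by at most 0.1 rad (the hybrid-state adiabaticity bound); pulse durations
    alternate between blocks in [100 us, 1 ms] to modulate semi-solid
    saturation independently of the flip angle.
    """
    if n_pulses < 2:
        raise ValueError("n_pulses must be >= 2")
    rng = np.random.default_rng(seed)
    i = np.arange(n_pulses)
    x = np.zeros(n_pulses)
    for _ in range(5):
        freq = rng.uniform(0.5, 3.0)  # cycles per cycle_time
        phase = rng.uniform(0, 2 * np.pi)
        x += rng.uniform(0.3, 1.0) * np.sin(
            2 * np.pi * freq * i / n_pulses + phase
        )
    x = (x - x.min()) / (x.max() - x.min())  # into [0, 1]
    alpha_min, alpha_max = 0.05, 0.9 * np.pi
    alphas = alpha_min + (alpha_max - alpha_min) * x
    # enforce the smoothness bound by shrinking toward the mean if violated
    dmax = np.max(np.abs(np.diff(alphas)))
    if dmax > 0.1:
        scale = 0.1 / dmax
        alphas = alphas.mean() + scale * (alphas - alphas.mean())
    # pulse durations: slow alternation between short and long blocks
    trf_short, trf_long = 100e-6, 1e-3
    block = (i // max(1, n_pulses // 8)) % 2
    trfs = np.where(block == 0, trf_short, trf_long)
    pulses = tuple(
        RFPulse(float(a), float(t), (k % 2) * np.pi)
        for k, (a, t) in enumerate(zip(alphas, trfs))
    )
    cycle_time = n_pulses * tr + 0.01
    return PulseTrain(pulses=pulses, tr=tr, cycle_time=cycle_time)


def _signed_omega_y(pulse: RFPulse, b1: float) -> float:
    """Rabi frequency with the pi phase cycling folded into its sign."""
    c = np.cos(pulse.phase)
    if abs(abs(c) - 1.0) > 1e-9:
        raise ValueError("only phases that are multiples of pi are supported")
    return float(np.sign(c) * b1 * pulse.alpha / pulse.trf)


def inversion_operator(
    tissue: TissueParameters,
    system: SystemParameters,
    inv_pulse: RFPulse,
    table: LinearizationTable,
) -> np.ndarray:
    """Propagator of the T2s-selective inversion pulse with ideal crushers.

    The free pool is rotated by ``b1 * pi`` about the transverse axis with
    relaxation active during the pulse; the semi-solid pool, whose T2s is
    much shorter than the pulse, is merely saturated: ``zs`` is attenuated
    according to the linearized generalized-Bloch rate for
    ``(b1 * alpha, trf)``.  Exchange during the sub-millisecond pulse is
    negligible and omitted.  The crusher gradients zero all transverse
    components afterwards.
    """
    t = tissue
    flip = system.b1 * inv_pulse.alpha
    omega_y = flip / inv_pulse.trf
    # free pool: (xf, yf, zf, 1) Bloch with rotation about y
    Af = np.array(
        [
            [-t.R2f, -system.omega_z, omega_y, 0.0],
            [system.omega_z, -t.R2f, 0.0, 0.0],
            [-omega_y, 0.0, -t.R1f, t.m0f * t.R1f],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    Ef = expm(Af * inv_pulse.trf)
    # semi-solid pool: (xs, zs, 1) with the linearized saturation rate;
    # the inversion pulse may fall outside the tabulated hull (b1 > 1 pushes
    # the flip beyond pi; its duration is longer than the excitation pulses)
    # where the dimensionless rate varies slowly -- clamp to the hull edge
    r2sl = table.query(flip, inv_pulse.trf / t.T2s, clamp="all").item() / t.T2s
    As = np.array(
        [
            [-r2sl, omega_y, 0.0],
            [-omega_y, -t.R1s, t.m0s * t.R1s],
            [0.0, 0.0, 0.0],
        ]
    )
    Es = expm(As * inv_pulse.trf)
    op = np.zeros((6, 6))
    op[:3, :3] = Ef[:3, :3]
    op[:3, 5] = Ef[:3, 3]
    op[3:5, 3:5] = Es[:2, :2]
    op[3:5, 5] = Es[:2, 2]
    op[5, 5] = 1.0
    # ideal crushers: zero the transverse components
    crush = np.diag([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
    return crush @ op


def _cycle_propagators(
    tissue: TissueParameters,
    system: SystemParameters,
    train: PulseTrain,
    table: LinearizationTable,
    hull: str = "strict",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-TR building blocks: pulse propagators, half-gap and sample-delay
    free-precession propagators, all as stacked 6x6 arrays."""
    t = tissue
    n = train.n_pulses
    alphas = train.alphas * system.b1
    trfs = train.trfs
    clamp = "all" if hull == "clamp" else "alpha"
    r2sl = table.r2sl(alphas, trfs, t.T2s, clamp=clamp)
    signs = np.array([np.cos(p.phase) for p in train.pulses])
    if np.any(np.abs(np.abs(signs) - 1.0) > 1e-9):
        raise ValueError("only phases that are multiples of pi are supported")
    omega_y = np.sign(signs) * alphas / trfs
    # vectorized batch of Eq.-(1) generators, one per pulse
    gens = np.zeros((n, 6, 6))
    gens[:, 0, 0] = -t.R2f
    gens[:, 0, 1] = -system.omega_z
    gens[:, 0, 2] = omega_y
    gens[:, 1, 0] = system.omega_z
    gens[:, 1, 1] = -t.R2f
    gens[:, 2, 0] = -omega_y
    gens[:, 2, 2] = -t.R1f - t.Rx * t.m0s
    gens[:, 2, 4] = t.Rx * t.m0f
    gens[:, 2, 5] = t.m0f * t.R1f
    gens[:, 3, 3] = -r2sl
    gens[:, 3, 4] = omega_y
    gens[:, 4, 2] = t.Rx * t.m0s
    gens[:, 4, 3] = -omega_y
    gens[:, 4, 4] = -t.R1s - t.Rx * t.m0f
    gens[:, 4, 5] = t.m0s * t.R1s
    P = expm(gens * trfs[:, None, None])
    # free precession: same generator, different durations; dedupe durations
    G_free = build_generator(t, 0.0, system.omega_z, 0.0)
    half_gaps = (train.tr - trfs) / 2.0
    delays = (
        half_gaps
        if train.sample_delay is None
        else np.full(n, train.sample_delay)
    )
    uniq, inv = np.unique(np.concatenate([half_gaps, delays]), return_inverse=True)
    E_uniq = expm(G_free[None] * uniq[:, None, None])
    F = E_uniq[inv[:n]]
    D = E_uniq[inv[n:]]
    return P, F, D


def simulate_fingerprint(
    tissue: TissueParameters,
    system: SystemParameters,
    train: PulseTrain,
    table: LinearizationTable,
    hull: str = "strict",
) -> Fingerprint:
    """Complex per-TR signal over one periodic steady cycle.

    Each TR propagates the state through free precession for
    ``(TR - TRF)/2``, the pulse (with the linearized semi-solid rate for its
    effective flip angle and duration), and the remaining gap.  The cycle
    propagator (inversion followed by all TRs) is affine in the homogeneous
    6-vector; its fixed point is solved as a 5x5 linear system and defines
    the steady cycle.  The signal is ``xf + i yf`` at the sampling point of
    every TR, demodulated for the pi phase cycling (multiplied by (-1)^i)
    and scaled by the complex M0.
    """
    P, F, D = _cycle_propagators(tissue, system, train, table, hull)
    inv_op = inversion_operator(tissue, system, train.inversion, table)
    PF = P @ F  # batched: start-of-TR to end-of-pulse
    T = F @ PF  # batched: full-TR propagators
    A = inv_op.copy()
    for i in range(train.n_pulses):
        A = T[i] @ A
    # fixed point M = A M with M[5] = 1
    B = np.eye(5) - A[:5, :5]
    if np.linalg.cond(B) > 1e9:
        raise RuntimeError("degenerate periodic fixed point (eigenvalue ~ 1)")
    m = np.linalg.solve(B, A[:5, 5])
    state = inv_op @ np.concatenate([m, [1.0]])
    signal = np.empty(train.n_pulses, dtype=complex)
    sign = 1.0
    for i in range(train.n_pulses):
        after_pulse = PF[i] @ state
        sampled = D[i] @ after_pulse
        signal[i] = sign * (sampled[0] + 1j * sampled[1])
        state = F[i] @ after_pulse
        sign = -sign
    return Fingerprint(signal * system.m0_complex, train.tr)


def cycle_fixed_point(
    tissue: TissueParameters,
    system: SystemParameters,
    train: PulseTrain,
    table: LinearizationTable,
) -> MagnetizationState:
    """Steady-cycle state at the cycle boundary (just before the inversion)."""
    P, F, _ = _cycle_propagators(tissue, system, train, table)
    inv_op = inversion_operator(tissue, system, train.inversion, table)
    T = F @ (P @ F)
    A = inv_op.copy()
    for i in range(train.n_pulses):
        A = T[i] @ A
    m = np.linalg.solve(np.eye(5) - A[:5, :5], A[:5, 5])
    return MagnetizationState(np.concatenate([m, [1.0]]))


def simulate_transient(
    tissue: TissueParameters,
    system: SystemParameters,
    train: PulseTrain,
    n_cycles: int,
    table: LinearizationTable,
) -> list[MagnetizationState]:
    """Cycle-boundary states of repeated cycles from thermal equilibrium.

    Returns the state before each cycle's inversion pulse, for ``n_cycles``
    applications of the cycle propagator.  Useful to diagnose how fast the
    periodic steady cycle is approached (a linear contraction).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    P, F, _ = _cycle_propagators(tissue, system, train, table)
    inv_op = inversion_operator(tissue, system, train.inversion, table)
    T = F @ (P @ F)
    A = inv_op.copy()
    for i in range(train.n_pulses):
        A = T[i] @ A
    out = []
    state = thermal_equilibrium(tissue).vec
    for _ in range(n_cycles):
        state = A @ state
        out.append(MagnetizationState(state.copy()))
    return out


def effective_resolution(nominal: float) -> float:
    """Effective resolution of insphere-covering radial k-space sampling.

    A 3D radial (koosh-ball) trajectory with nominal resolution ``d``
    (``kmax = pi/d``) samples the insphere of the Cartesian k-space cube of
    side ``2 kmax``.  Equating covered k-space volumes gives an effective
    resolution of ``d * (6/pi)^(1/3)`` (1.24 mm for a nominal 1.0 mm).
    """
    if nominal <= 0:
        raise ValueError("nominal resolution must be > 0")
    return float(nominal * (6.0 / np.pi) ** (1.0 / 3.0))
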