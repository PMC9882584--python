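"""Pulse trains, inversion, periodic fingerprints, acquisition geometry."""

import numpy as np
import pytest
from scipy.linalg import expm

from hybridmt.generalized_bloch import Lineshape, solve_generalized_bloch
from hybridmt.mt_model import SystemParameters, TissueParameters
from hybridmt.sequence import (
    PulseTrain,
    RFPulse,
    default_train,
    effective_resolution,
    inversion_operator,
    n_pulses_per_cycle,
    simulate_fingerprint,
    simulate_transient,
)
from hybridmt.sequence import cycle_fixed_point


def constant_train(n, alpha, trf, tr=3.5e-3, sample_delay=None):
    pulses = tuple(RFPulse(alpha, trf, (k % 2) * np.pi) for k in range(n))
    return PulseTrain(
        pulses=pulses, tr=tr, cycle_time=n * tr + 0.1, sample_delay=sample_delay
    )


def single_pool_oracle(tissue, system, train, m0=1.0):
    """Independent 4x4 (xf, yf, zf, 1) Bloch simulator for m0s = 0."""
    t, s = tissue, system

    def gen(omega_y):
        return np.array(
            [
                [-t.R2f, -s.omega_z, omega_y, 0.0],
                [s.omega_z, -t.R2f, 0.0, 0.0],
                [-omega_y, 0.0, -t.R1f, t.R1f],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )

    # inversion with crushers
    inv = expm(gen(s.b1 * train.inversion.alpha / train.inversion.trf) * train.inversion.trf)
    crush = np.diag([0.0, 0.0, 1.0, 1.0])
    inv = crush @ inv
    props = []
    samplers = []
    for i, p in enumerate(train.pulses):
        sign = 1.0 if np.cos(p.phase) > 0 else -1.0
        h = (train.tr - p.trf) / 2
        delay = h if train.sample_delay is None else train.sample_delay
        F = expm(gen(0.0) * h)
        P = expm(gen(sign * s.b1 * p.alpha / p.trf) * p.trf)
        D = expm(gen(0.0) * delay)
        props.append(F @ P @ F)
        samplers.append((D @ P @ F, F, P))
    A = inv.copy()
    for T in props:
        A = T @ A
    m = np.linalg.solve(np.eye(3) - A[:3, :3], A[:3, 3])
    state = inv @ np.concatenate([m, [1.0]])
    sig = np.empty(len(props), dtype=complex)
    for i, p in enumerate(train.pulses):
        S, F, P = samplers[i]
        sampled = S @ state
        sig[i] = (-1.0) ** i * (sampled[0] + 1j * sampled[1])
        state = F @ (P @ (F @ state))
    return sig * m0


class TestGeometryAndCounting:
    def test_pulses_per_four_second_cycle(self):
        assert n_pulses_per_cycle(4.0, 3.5e-3) == 1142

    @pytest.mark.parametrize(
        "tc,tr,n", [(1.0, 1e-3, 1000), (3.5e-3, 3.5e-3, 1)]
    )
    def test_counting_edges(self, tc, tr, n):
        assert n_pulses_per_cycle(tc, tr) == n

    def test_effective_resolution_printed_value(self):
        assert round(effective_resolution(1.0), 2) == 1.24

    def test_effective_resolution_scale_invariance(self):
        r1 = effective_resolution(1.0)
        assert effective_resolution(2.0) == pytest.approx(2 * r1, rel=1e-12)
        assert effective_resolution(2.0) == pytest.approx(2.4814, abs=1e-4)


class TestDefaultTrain:
    def test_deterministic_in_seed(self):
        a = default_train(200, seed=5)
        b = default_train(200, seed=5)
        assert np.array_equal(a.alphas, b.alphas)
        assert np.array_equal(a.trfs, b.trfs)
        c = default_train(200, seed=6)
        assert not np.array_equal(a.alphas, c.alphas)

    def test_occupancy_and_bounds(self):
        tr = default_train(1142, tr=3.5e-3, seed=0)
        assert 1142 * 3.5e-3 <= 4.0
        assert np.all(tr.alphas >= 0.0) and np.all(tr.alphas <= 0.9 * np.pi)
        assert np.all((tr.trfs >= 100e-6) & (tr.trfs <= 1e-3))

    def test_hybrid_state_smoothness(self):
        tr = default_train(500, seed=1)
        assert np.max(np.abs(np.diff(tr.alphas))) <= 0.1 + 1e-12


class TestInversionOperator:
    def test_perfect_inversion_relaxation_free(self, table):
        t = TissueParameters(0.0, 1e-9, 1e-9, 0.0, 1e-9, 10e-6)
        op = inversion_operator(t, SystemParameters(), RFPulse(np.pi, 500e-6), table)
        out = op @ np.array([0, 0, 1.0, 0, 0, 1.0])
        assert out[2] == pytest.approx(-1.0, abs=1e-9)

    def test_transverse_crushed(self, table, wm_tissue):
        op = inversion_operator(
            wm_tissue, SystemParameters(), RFPulse(np.pi, 500e-6), table
        )
        out = op @ np.array([0.3, -0.2, 0.5, 0.1, 0.15, 1.0])
        assert out[0] == out[1] == out[3] == 0.0

    def test_semisolid_attenuation_matches_generalized_bloch(self, table):
        # trf >> T2s: the zs attenuation equals the generalized-Bloch value
        # through the linearized rate (r1s excluded from the matching)
        t = TissueParameters(0.2, 1e-9, 1e-9, 0.0, 1e-9, 10e-6)
        trf = 500e-6
        op = inversion_operator(t, SystemParameters(), RFPulse(np.pi, trf), table)
        factor = op[4, 4]
        ls = Lineshape("super_lorentzian", t.T2s)
        oracle = solve_generalized_bloch(1.0, np.pi / trf, trf, ls, r1s=0.0)
        assert factor == pytest.approx(oracle, rel=2e-3)


class TestFingerprint:
    def test_no_excitation_no_signal(self, table):
        t = TissueParameters(0.0, 1.0, 10.0, 0.0, 1.0, 10e-6)
        tr = constant_train(50, 0.0011, 100e-6)  # near-zero flips
        sig = simulate_fingerprint(t, SystemParameters(), tr, table).signal
        assert np.abs(sig).max() < 1e-3
        # and exactly linear in M0
        sig2 = simulate_fingerprint(
            t, SystemParameters(m0_complex=2.0), tr, table
        ).signal
        np.testing.assert_allclose(sig2, 2 * sig, rtol=0, atol=1e-15)

    def test_m0_linearity_complex(self, table, wm_tissue, train100):
        s1 = simulate_fingerprint(
            wm_tissue, SystemParameters(), train100, table
        ).signal
        m0 = 1.3 * np.exp(0.7j)
        s2 = simulate_fingerprint(
            wm_tissue, SystemParameters(m0_complex=m0), train100, table
        ).signal
        np.testing.assert_allclose(s2, m0 * s1, rtol=1e-12)

    def test_bssfp_steady_state_closed_form(self, table):
        # single pool, constant flip angle, on resonance: the late-cycle
        # signal sampled right after the pulse matches the alternating-phase
        # bSSFP steady state M0 sin(a) (1-E1) / (1-(E1-E2)cos(a)-E1 E2)
        t = TissueParameters(0.0, 1.0, 2.0, 0.0, 1.0, 0.4e-6)
        alpha, tr = 0.6, 3.5e-3
        train = constant_train(4000, alpha, 4e-6, tr=tr, sample_delay=0.0)
        sig = simulate_fingerprint(t, SystemParameters(), train, table).signal
        e1, e2 = np.exp(-t.R1f * tr), np.exp(-t.R2f * tr)
        ss = np.sin(alpha) * (1 - e1) / (1 - (e1 - e2) * np.cos(alpha) - e1 * e2)
        assert abs(sig[-1]) == pytest.approx(ss, rel=1e-4)

    def test_single_pool_matches_independent_oracle(self, table, train100):
        t = TissueParameters(0.0, 0.8, 12.0, 0.0, 1.0, 10e-6)
        s = SystemParameters(omega_z=150.0, b1=1.05, m0_complex=1.2 - 0.4j)
        sig = simulate_fingerprint(t, s, train100, table).signal
        oracle = single_pool_oracle(t, s, train100, m0=s.m0_complex)
        np.testing.assert_allclose(sig, oracle, atol=1e-10)

    def test_fixed_point_self_consistency(self, table, wm_tissue, train100):
        from hybridmt.sequence import _cycle_propagators

        fp = cycle_fixed_point(wm_tissue, SystemParameters(), train100, table)
        P, F, _ = _cycle_propagators(wm_tissue, SystemParameters(), train100, table)
        inv_op = inversion_operator(
            wm_tissue, SystemParameters(), train100.inversion, table
        )
        A = inv_op.copy()
        for i in range(train100.n_pulses):
            A = F[i] @ (P[i] @ (F[i] @ A))
        np.testing.assert_allclose(A @ fp.vec, fp.vec, atol=1e-12)

    def test_transient_approaches_fixed_point(self, table, wm_tissue, train100):
        states = simulate_transient(
            wm_tissue, SystemParameters(), train100, 20, table
        )
        fp = cycle_fixed_point(wm_tissue, SystemParameters(), train100, table)
        diffs = [np.abs(s.vec - fp.vec).max() for s in states]
        assert diffs[-1] < 1e-8
        # contraction: differences non-increasing after the first cycles
        assert all(d2 <= d1 + 1e-15 for d1, d2 in zip(diffs[2:], diffs[3:]))

    def test_transient_single_cycle(self, table, wm_tissue, train100):
        states = simulate_transient(
            wm_tissue, SystemParameters(), train100, 1, table
        )
        assert len(states) == 1

    def test_signal_bounded_by_free_pool(self, table, train150):
        rng = np.random.default_rng(11)
        for _ in range(5):
            t = TissueParameters(
                m0s=rng.uniform(0.0, 0.4),
                R1f=rng.uniform(0.2, 2.0),
                R2f=rng.uniform(5.0, 20.0),
                Rx=rng.uniform(5.0, 40.0),
                R1s=rng.uniform(0.5, 6.0),
                T2s=rng.uniform(5e-6, 20e-6),
            )
            s = SystemParameters(omega_z=rng.uniform(-300, 300))
            sig = simulate_fingerprint(t, s, train150, table).signal
            assert np.abs(sig).max() <= t.m0f + 1e-9

    def test_b1_equivalence(self, table, wm_tissue):
        # b1 scaling the train equals scaling all flips (including the
        # inversion, whose nominal pi is likewise transmit-scaled) at b1 = 1
        from dataclasses import replace

        base = default_train(80, seed=9)
        scaled = base.with_angles(0.8 * base.alphas)
        scaled = replace(
            scaled,
            inversion=RFPulse(0.8 * np.pi, base.inversion.trf, 0.0),
        )
        s1 = simulate_fingerprint(
            wm_tissue, SystemParameters(b1=0.8), base, table
        ).signal
        s2 = simulate_fingerprint(
            wm_tissue, SystemParameters(b1=1.0), scaled, table
        ).signal
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_off_resonance_conjugation_symmetry(self, table, wm_tissue, train100):
        s_pos = simulate_fingerprint(
            wm_tissue, SystemParameters(omega_z=220.0), train100, table
        ).signal
        s_neg = simulate_fingerprint(
            wm_tissue, SystemParameters(omega_z=-220.0), train100, table
        ).signal
        np.testing.assert_allclose(s_pos, np.conj(s_neg), atol=1e-12)


class TestValidation:
    def test_phase_alternation_enforced(self):
        pulses = tuple(RFPulse(0.5, 1e-4, 0.0) for _ in range(4))
        with pytest.raises(ValueError):
            PulseTrain(pulses=pulses, tr=3.5e-3, cycle_time=1.0)

    def test_pulse_longer_than_tr_rejected(self):
        pulses = (RFPulse(0.5, 5e-3, 0.0), RFPulse(0.5, 5e-3, np.pi))
        with pytest.raises(ValueError):
            PulseTrain(pulses=pulses, tr=3.5e-3, cycle_time=1.0)
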