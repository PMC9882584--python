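"""Dictionary, subspace compression and voxel-wise NLLS fitting."""

import numpy as np
import pytest

from hybridmt.estimation import (
    FitOptions,
    build_dictionary,
    compress_basis,
    fit_volume,
    fit_voxel,
    project,
)
from hybridmt.mt_model import SystemParameters, TissueParameters
from hybridmt.sequence import simulate_fingerprint
from hybridmt.synthio import add_noise


@pytest.fixture(scope="module")
def dictionary(table, train100):
    grid = {
        "m0s": np.array([0.05, 0.15, 0.25, 0.35]),
        "R1f": np.array([0.3, 0.55, 1.0]),
        "R2f": np.array([9.0, 14.0, 21.0]),
        "Rx": np.array([8.0, 20.0, 40.0]),
        "R1s": np.array([1.0, 3.0, 6.0]),
        "T2s": np.array([8e-6, 13e-6, 18e-6]),
    }
    return build_dictionary(grid, train100, table)


def wm_truth():
    return np.array([0.212, 1 / 1.84, 1 / 0.0769, 13.6, 1 / 0.34, 12.5e-6])


class TestDictionary:
    def test_atom_count_on_tiny_grid(self, table, train100):
        d = build_dictionary(
            {"m0s": np.array([0.1, 0.2]), "R1f": np.array([0.5, 1.0])},
            train100,
            table,
        )
        assert d.atoms.shape == (4, train100.n_pulses)
        assert d.params.shape == (4, 2)

    def test_deterministic(self, table, train100):
        grid = {"m0s": np.array([0.1, 0.3])}
        a = build_dictionary(grid, train100, table)
        b = build_dictionary(grid, train100, table)
        assert np.array_equal(a.atoms, b.atoms)

    def test_zero_m0s_rows_match_single_pool_oracle(self, table, train100):
        from test_sequence import single_pool_oracle

        base = TissueParameters(0.2, 0.5, 15.0, 15.0, 3.0, 10e-6)
        d = build_dictionary(
            {"m0s": np.array([0.0]), "R1f": np.array([0.7])},
            train100,
            table,
            base_tissue=base,
        )
        t0 = TissueParameters(0.0, 0.7, 15.0, 15.0, 3.0, 10e-6)
        oracle = single_pool_oracle(t0, SystemParameters(), train100)
        np.testing.assert_allclose(d.atoms[0], oracle, atol=1e-10)


class TestSubspace:
    def test_full_rank_projection_is_identity_on_atoms(self, dictionary):
        rank = min(dictionary.atoms.shape)
        basis = compress_basis(dictionary, rank)
        coeffs = project(dictionary.atoms, basis)
        recon = coeffs @ basis.basis.conj().T
        np.testing.assert_allclose(recon, dictionary.atoms, atol=1e-10)

    def test_captured_energy_monotone_in_rank(self, dictionary):
        energies = [
            compress_basis(dictionary, r).captured_energy for r in (1, 3, 8, 15)
        ]
        assert all(b >= a for a, b in zip(energies, energies[1:]))
        assert energies[-1] <= 1.0 + 1e-12

    def test_basis_orthonormal(self, dictionary):
        basis = compress_basis(dictionary, 10)
        gram = basis.basis.conj().T @ basis.basis
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-10)

    def test_rank15_captures_held_out_fingerprints(
        self, dictionary, table, train100
    ):
        # fingerprints at off-grid (held-out) tissues project with small error
        basis = compress_basis(dictionary, 15)
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(10):
            t = TissueParameters(
                m0s=rng.uniform(0.06, 0.34),
                R1f=rng.uniform(0.35, 0.95),
                R2f=rng.uniform(10.0, 20.0),
                Rx=rng.uniform(9.0, 38.0),
                R1s=rng.uniform(1.2, 5.5),
                T2s=rng.uniform(9e-6, 17e-6),
            )
            s = simulate_fingerprint(t, SystemParameters(), train100, table).signal
            recon = project(s, basis) @ basis.basis.conj().T
            worst = max(worst, np.linalg.norm(s - recon) / np.linalg.norm(s))
        assert worst < 1e-2

    def test_projection_norm_contraction(self, dictionary, train100):
        basis = compress_basis(dictionary, 5)
        rng = np.random.default_rng(0)
        s = rng.normal(size=train100.n_pulses) + 1j * rng.normal(
            size=train100.n_pulses
        )
        assert np.linalg.norm(project(s, basis)) < np.linalg.norm(s)
        # basis vector projects to a unit coordinate vector
        e = project(basis.basis[:, 2], basis)
        np.testing.assert_allclose(e, np.eye(5)[2], atol=1e-10)

    def test_parseval_on_in_span_signal(self, dictionary):
        basis = compress_basis(dictionary, 12)
        s = basis.basis @ (np.arange(12) + 1j)
        assert np.linalg.norm(project(s, basis)) == pytest.approx(
            np.linalg.norm(s), rel=1e-10
        )

    def test_rank_validation(self, dictionary):
        with pytest.raises(ValueError):
            compress_basis(dictionary, 0)


class TestFitVoxel:
    def test_truth_init_is_fixed_point(self, table, train100, wm_tissue):
        sig = simulate_fingerprint(
            wm_tissue, SystemParameters(), train100, table
        ).signal
        init = {
            "m0s": wm_tissue.m0s,
            "R1f": wm_tissue.R1f,
            "R2f": wm_tissue.R2f,
            "Rx": wm_tissue.Rx,
            "R1s": wm_tissue.R1s,
            "T2s": wm_tissue.T2s,
            "omega_z": 0.0,
            "b1": 1.0,
        }
        fit = fit_voxel(
            sig,
            train100,
            table,
            options=FitOptions(n_restarts=0),
            init=init,
        )
        assert fit.residual_norm < 1e-9
        np.testing.assert_allclose(
            fit.as_vector()[:6], wm_truth(), rtol=1e-10
        )

    def test_wm_recovery_from_dictionary_init(
        self, table, train100, wm_tissue, dictionary
    ):
        # noiseless white-matter fingerprint: recover m0s, R1f, R2f to 1e-3
        # and Rx, R1s, T2s to 1e-2 relative
        sig = simulate_fingerprint(
            wm_tissue, SystemParameters(), train100, table
        ).signal
        fit = fit_voxel(
            sig,
            train100,
            table,
            options=FitOptions(n_restarts=0, xtol=1e-12, gtol=1e-12),
            dictionary=dictionary,
        )
        rel = np.abs(fit.as_vector()[:6] - wm_truth()) / wm_truth()
        assert np.all(rel[:3] < 1e-3)
        assert np.all(rel[3:] < 1e-2)

    def test_constrained_fit_underestimates_m0s(self, table, train100):
        # data generated with R1s >> R1f; the R1s = R1f constrained model
        # absorbs the mismatch by shrinking the apparent pool
        truth = TissueParameters(0.2, 0.5, 15.0, 15.0, 3.0, 10e-6)
        sig = simulate_fingerprint(
            truth, SystemParameters(), train100, table
        ).signal
        init = dict(
            m0s=0.2, R1f=0.5, R2f=15.0, Rx=15.0, T2s=10e-6, omega_z=0.0, b1=1.0
        )
        fit = fit_voxel(
            sig,
            train100,
            table,
            options=FitOptions(constraint="r1s_equals_r1f", n_restarts=0),
            init=init,
        )
        assert fit.tissue.m0s < truth.m0s

    def test_constrained_residual_not_smaller(self, table, train100, dictionary):
        truth = TissueParameters(0.25, 0.5, 15.0, 20.0, 4.0, 12e-6)
        sig = simulate_fingerprint(
            truth, SystemParameters(), train100, table
        ).signal
        free = fit_voxel(
            sig, train100, table, options=FitOptions(n_restarts=0),
            dictionary=dictionary,
        )
        constrained = fit_voxel(
            sig,
            train100,
            table,
            options=FitOptions(constraint=("r1s_fixed", 0.5), n_restarts=0),
            dictionary=dictionary,
        )
        assert constrained.residual_norm >= free.residual_norm - 1e-12

    def test_subspace_coefficient_fitting(
        self, table, train100, wm_tissue, dictionary
    ):
        basis = compress_basis(dictionary, 15)
        sig = simulate_fingerprint(
            wm_tissue, SystemParameters(), train100, table
        ).signal
        coeffs = project(sig, basis)
        init = {
            "m0s": 0.25,
            "R1f": 0.5,
            "R2f": 14.0,
            "Rx": 15.0,
            "R1s": 3.5,
            "T2s": 11e-6,
            "omega_z": 0.0,
            "b1": 1.0,
        }
        fit = fit_voxel(
            coeffs,
            train100,
            table,
            options=FitOptions(n_restarts=0),
            init=init,
            basis=basis,
        )
        rel = np.abs(fit.as_vector()[:6] - wm_truth()) / wm_truth()
        assert np.all(rel[:3] < 5e-3)

    def test_varpro_scale_matches_closed_form(self, table, train100, wm_tissue):
        # the eliminated M0 equals the closed-form least-squares scale
        from hybridmt.estimation import _varpro_residual

        m0 = 1.4 * np.exp(0.9j)
        sig = m0 * simulate_fingerprint(
            wm_tissue, SystemParameters(), train100, table
        ).signal
        model = simulate_fingerprint(
            wm_tissue, SystemParameters(), train100, table
        ).signal
        _, m0_hat = _varpro_residual(model, sig)
        assert m0_hat == pytest.approx(m0, rel=1e-12)

    def test_noiseless_recovery_sweep(self, table, train100, dictionary):
        # random in-bounds tissues, noiseless fits with dictionary-match
        # init: the large majority recover m0s, R1f, R2f to 1e-3 relative,
        # failures are flagged as bound-pinned or unconverged
        rng = np.random.default_rng(21)
        n_ok, n_flagged = 0, 0
        n_cases = 24
        for _ in range(n_cases):
            t = TissueParameters(
                m0s=rng.uniform(0.05, 0.35),
                R1f=rng.uniform(0.25, 1.2),
                R2f=rng.uniform(8.0, 25.0),
                Rx=rng.uniform(6.0, 45.0),
                R1s=rng.uniform(0.8, 6.0),
                T2s=rng.uniform(7e-6, 19e-6),
            )
            sig = simulate_fingerprint(
                t, SystemParameters(), train100, table
            ).signal
            fit = fit_voxel(
                sig,
                train100,
                table,
                options=FitOptions(n_restarts=0, xtol=1e-12, gtol=1e-12),
                dictionary=dictionary,
            )
            truth = np.array([t.m0s, t.R1f, t.R2f])
            rel = np.abs(fit.as_vector()[:3] - truth) / truth
            if np.all(rel < 1e-3):
                n_ok += 1
            elif any(fit.bound_hit.values()) or not fit.converged:
                n_flagged += 1
        assert n_ok / n_cases >= 0.95 or (n_ok + n_flagged) == n_cases

    def test_nonfinite_signal_rejected(self, table, train100, dictionary):
        bad = np.full(train100.n_pulses, np.nan, dtype=complex)
        with pytest.raises(ValueError):
            fit_voxel(bad, train100, table, dictionary=dictionary)


class TestFitVolume:
    def test_empty_mask(self, table, train100, dictionary):
        vol = np.zeros((2, 2, train100.n_pulses), dtype=complex)
        maps = fit_volume(
            vol, np.zeros((2, 2), bool), train100, table, dictionary=dictionary
        )
        assert np.all(np.isnan(maps["m0s"]))
        assert maps["flags"].sum() == 0

    def test_voxels_fit_independently(self, table, train100, dictionary):
        # per-voxel results equal standalone fit_voxel calls regardless of
        # the volume layout
        tissues = [
            TissueParameters(0.15, 0.5, 14.0, 15.0, 2.0, 10e-6),
            TissueParameters(0.25, 0.7, 12.0, 20.0, 4.0, 14e-6),
        ]
        sigs = [
            simulate_fingerprint(t, SystemParameters(), train100, table).signal
            for t in tissues
        ]
        vol = np.stack(sigs).reshape(2, 1, -1)
        opts = FitOptions(n_restarts=0, xtol=1e-9, gtol=1e-9)
        maps = fit_volume(
            vol, np.ones((2, 1), bool), train100, table,
            options=opts, dictionary=dictionary,
        )
        rev = fit_volume(
            vol[::-1], np.ones((2, 1), bool), train100, table,
            options=opts, dictionary=dictionary,
        )
        np.testing.assert_array_equal(maps["m0s"][::-1], rev["m0s"])
        for i, t in enumerate(tissues):
            single = fit_voxel(
                sigs[i], train100, table, options=opts, dictionary=dictionary
            )
            assert maps["m0s"][i, 0] == single.tissue.m0s

    def test_mask_shape_mismatch(self, table, train100, dictionary):
        with pytest.raises(ValueError):
            fit_volume(
                np.zeros((2, 2, 10), complex),
                np.zeros((3, 3), bool),
                train100,
                table,
                dictionary=dictionary,
            )


class TestEstimatorConsistency:
    def test_sd_scales_inverse_with_snr(self, table, train100, wm_tissue):
        # voxel-fit SD over noise realizations ~ 1/SNR (slope -1 on log-log)
        sig = simulate_fingerprint(
            wm_tissue, SystemParameters(), train100, table
        ).signal
        init = {
            "m0s": wm_tissue.m0s,
            "R1f": wm_tissue.R1f,
            "R2f": wm_tissue.R2f,
            "Rx": wm_tissue.Rx,
            "R1s": wm_tissue.R1s,
            "T2s": wm_tissue.T2s,
            "omega_z": 0.0,
            "b1": 1.0,
        }
        snrs = [3000.0, 1000.0, 300.0]
        sds = []
        for snr in snrs:
            sigma = np.abs(sig).max() / snr
            ests = []
            for rep in range(8):
                noisy = add_noise(sig, sigma, 1000 + rep)
                fit = fit_voxel(
                    noisy,
                    train100,
                    table,
                    options=FitOptions(n_restarts=0, xtol=1e-9, gtol=1e-9),
                    init=init,
                )
                ests.append(fit.tissue.R2f)
            sds.append(np.std(ests, ddof=1))
        slope = np.polyfit(np.log(snrs), np.log(sds), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)
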