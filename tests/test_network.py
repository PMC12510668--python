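"""Decoder sampling, thresholds, and the steady-state rate solver."""

import numpy as np
import pytest
from oracles import brute_force_qp, objective

from placeremap import network as net


class TestSampleDecoder:
    def test_mixed_code_unit_columns(self, rng):
        D = net.sample_decoder(6, 40, "M", rng)
        np.testing.assert_allclose(np.linalg.norm(D, axis=0), 1.0, atol=1e-12)

    def test_conjunctive_pair_norms(self, rng):
        D = net.sample_decoder(4, 24, "C", rng)
        for j in range(2):
            pair = D[2 * j : 2 * j + 2]
            np.testing.assert_allclose(
                np.linalg.norm(pair, axis=0), 1 / np.sqrt(2), atol=1e-12
            )
        np.testing.assert_allclose(np.linalg.norm(D, axis=0), 1.0, atol=1e-12)

    def test_cm_code_block_norms(self, rng):
        D = net.sample_decoder(8, 32, "CM", rng, zp_dim=4)
        np.testing.assert_allclose(
            np.linalg.norm(D[:4], axis=0), 1 / np.sqrt(2), atol=1e-12
        )
        np.testing.assert_allclose(
            np.linalg.norm(D[4:], axis=0), 1 / np.sqrt(2), atol=1e-12
        )
        # positional pairs have equal norm within the block (conjunctive)
        np.testing.assert_allclose(
            np.linalg.norm(D[0:2], axis=0), np.linalg.norm(D[2:4], axis=0), atol=1e-12
        )

    def test_pure_mixed_zero_blocks(self, rng):
        D = net.sample_decoder(4, 16, "pM", rng, zp_dim=2, pure_P=4, pure_C=4)
        np.testing.assert_array_equal(D[2:, :4], 0.0)  # pure position
        np.testing.assert_array_equal(D[:2, 4:8], 0.0)  # pure cognitive
        assert np.all(np.abs(D[:2, 8:]).max(axis=0) > 0)  # mixed keep both
        np.testing.assert_allclose(np.linalg.norm(D, axis=0), 1.0, atol=1e-12)

    def test_pure_counts_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            net.sample_decoder(4, 6, "pM", rng, zp_dim=2, pure_P=4, pure_C=4)

    def test_identity_code(self, rng):
        D = net.sample_decoder(8, 8, "identity", rng)
        np.testing.assert_array_equal(D, np.eye(8))

    def test_unknown_code_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown code"):
            net.sample_decoder(4, 8, "X", rng)


class TestThresholds:
    def test_half_squared_column_norm(self, rng):
        D = net.sample_decoder(4, 12, "M", rng)
        np.testing.assert_allclose(net.default_thresholds(D), 0.5, atol=1e-12)
        np.testing.assert_allclose(
            net.default_thresholds(2.0 * D), 2.0, atol=1e-12
        )
        np.testing.assert_allclose(
            net.default_thresholds(np.eye(5)), 0.5, atol=1e-12
        )

    @pytest.mark.parametrize(
        "spar, n_suppressed", [(1.0, 0), (0.0, 48), (0.5, 24), (0.25, 36)]
    )
    def test_modulation_counts(self, rng, spar, n_suppressed):
        T = np.full(48, 0.5)
        T_mod, mod = net.modulate_thresholds(T, spar, rng)
        assert len(mod.suppressed) == n_suppressed
        assert np.sum(T_mod == 10.0) == n_suppressed
        untouched = np.setdiff1d(np.arange(48), mod.suppressed)
        np.testing.assert_array_equal(T_mod[untouched], 0.5)

    def test_invalid_spar_rejected(self, rng):
        with pytest.raises(ValueError, match="spar"):
            net.modulate_thresholds(np.full(8, 0.5), 1.2, rng)


class TestSolveRates:
    def test_orthonormal_soft_threshold(self):
        D = np.eye(2)
        r = net.solve_rates(np.array([0.7, 0.2]), D, np.array([0.5, 0.5]))
        np.testing.assert_allclose(r, [0.2, 0.0], atol=1e-10)

    def test_zero_input_zero_rates(self, small_network):
        r = net.solve_rates(np.zeros(4), small_network.D, small_network.T)
        np.testing.assert_array_equal(r, 0.0)

    def test_diagonal_closed_form(self, rng):
        Y = 6
        scales = rng.uniform(0.5, 2.0, Y)
        D = np.diag(scales)
        T = net.default_thresholds(D)
        y = rng.standard_normal(Y) * 2
        r = net.solve_rates(y, D, T)
        expected = np.maximum((scales * y - T) / scales**2, 0.0)
        np.testing.assert_allclose(r, expected, atol=1e-9)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            N = int(rng.integers(4, 13))
            Y = int(rng.integers(2, 5))
            D = rng.standard_normal((Y, N))
            D /= np.linalg.norm(D, axis=0)
            T = net.default_thresholds(D) * rng.uniform(0.5, 2.0, N)
            y = rng.standard_normal(Y) * rng.uniform(0.5, 4.0)
            r = net.solve_rates(y, D, T)
            best_obj, _ = brute_force_qp(y, D, T, Y + 1)
            assert objective(r, y, D, T) <= best_obj + 1e-8

    def test_kkt_certificate_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            D = rng.standard_normal((4, 32))
            D /= np.linalg.norm(D, axis=0)
            T = net.default_thresholds(D)
            y = rng.standard_normal(4) * 4
            r = net.solve_rates(y, D, T)
            g = 2 * (D.T @ (D @ r - y)) + 2 * T
            assert np.min(g) >= -1e-6
            assert np.max(r * g) <= 1e-6
            assert np.all(r >= 0)

    def test_permutation_equivariance(self, rng):
        D = rng.standard_normal((4, 20))
        D /= np.linalg.norm(D, axis=0)
        T = net.default_thresholds(D) * rng.uniform(0.8, 1.2, 20)
        y = rng.standard_normal(4) * 3
        r = net.solve_rates(y, D, T)
        perm = rng.permutation(20)
        r_perm = net.solve_rates(y, D[:, perm], T[perm])
        np.testing.assert_allclose(r_perm, r[perm], atol=1e-7)

    def test_raising_threshold_never_raises_rate(self, rng):
        for _ in range(10):
            D = rng.standard_normal((3, 16))
            D /= np.linalg.norm(D, axis=0)
            T = net.default_thresholds(D)
            y = rng.standard_normal(3) * 3
            r0 = net.solve_rates(y, D, T)
            active = np.flatnonzero(r0 > 1e-9)
            if active.size == 0:
                continue
            i = int(active[0])
            T2 = T.copy()
            T2[i] *= 3.0
            r1 = net.solve_rates(y, D, T2)
            assert r1[i] <= r0[i] + 1e-9

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            net.solve_rates(np.ones(2), np.eye(2), np.array([0.5, 0.0]))


class TestBatchSolveAndDecoding:
    def test_constant_input_constant_rates(self, small_network):
        y = np.tile(np.array([1.0, 0.3, -0.2, 0.5])[:, None], (1, 6))
        rm = net.batch_solve(y, small_network.D, small_network.T)
        assert np.allclose(rm.rates, rm.rates[:, :1])

    def test_ratemapset_invariants(self, small_network, rng):
        y = rng.standard_normal((4, 10))
        rm = net.batch_solve(y, small_network.D, small_network.T, E=small_network.E)
        np.testing.assert_allclose(rm.decoded, small_network.D @ rm.rates, atol=1e-12)
        np.testing.assert_allclose(
            small_network.D @ rm.null_component, 0.0, atol=1e-8
        )
        assert np.all(rm.rates >= 0)

    def test_pseudo_inverse_identities(self, rng):
        D = rng.standard_normal((5, 20))
        E = net.pseudo_inverse_encoder(D)
        np.testing.assert_allclose(D @ E, np.eye(5), atol=1e-10)
        P = E @ D
        np.testing.assert_allclose(P @ P, P, atol=1e-8)

    def test_orthonormal_rows_give_transpose(self):
        Q = np.linalg.qr(np.random.default_rng(0).standard_normal((8, 3)))[0].T
        np.testing.assert_allclose(net.pseudo_inverse_encoder(Q), Q.T, atol=1e-12)

    def test_rank_deficient_rejected(self):
        D = np.ones((3, 5))
        with pytest.raises(np.linalg.LinAlgError):
            net.pseudo_inverse_encoder(D)

    def test_decode_latents_exact_for_null_free_rates(self, small_network, rng):
        z = rng.standard_normal(4)
        r = small_network.E @ z
        np.testing.assert_allclose(
            net.decode_latents(r, small_network.D), z, atol=1e-10
        )
        R = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        np.testing.assert_allclose(
            net.decode_latents(r, small_network.D, R), R.T @ z, atol=1e-10
        )
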