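"""The weighted reweighting loop: back-solve, block weights, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wssgwas_kit.mixed_model import ModelSpec
from wssgwas_kit.relationships import (
    SnpWeights,
    blend_G,
    compute_A,
    compute_G,
    centered_dosages,
    invert_spd,
)
from wssgwas_kit.synthetic_data import (
    SimulationConfig,
    one_qtl_recovery_study,
    simulate_genotypes,
    simulate_pedigree,
)
from wssgwas_kit.wssgwas import (
    MarkerEffects,
    backsolve_snp_effects,
    block_weights,
    make_windows,
    normalize_weights,
    run_wssgwas,
    select_windows,
    window_variance_explained,
)


def toy_map(chroms):
    return pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(len(chroms))],
            "chrom": [str(c) for c in chroms],
            "pos_bp": np.arange(1, len(chroms) + 1) * 1000,
        }
    )


class TestMakeWindows:
    def test_blocks_restart_at_chromosome_boundary(self):
        snp_map = toy_map([1] * 25 + [2] * 7)
        windows = make_windows(snp_map, block_size=20)
        sizes = [len(w.snp_indices) for w in windows]
        assert sizes == [20, 5, 7]
        assert [w.chrom for w in windows] == ["1", "1", "2"]

    def test_windows_partition_the_map(self):
        snp_map = toy_map([1] * 33 + [2] * 21)
        windows = make_windows(snp_map, block_size=20)
        covered = np.concatenate([w.snp_indices for w in windows])
        np.testing.assert_array_equal(covered, np.arange(54))


class TestBacksolve:
    def _full_rank_setup(self, seed=47):
        # reference frequencies from 40 founders, G over the first 6
        # animals: full rank (own-frequency centering would make the
        # ones-vector a kernel vector of G)
        cfg = SimulationConfig(
            n_founders=40, n_generations=0, n_snps=40,
            maf_range=(0.2, 0.5), seed=seed,
        )
        panel = simulate_genotypes(simulate_pedigree(cfg), cfg)
        p = panel.allele_frequencies()
        c = float(2.0 * np.sum(p * (1.0 - p)))
        M = (panel.imputed_dosages() - 2.0 * p)[:6]
        return M @ M.T / c, M, c

    def test_zero_breeding_values_zero_effects(self):
        G, M, c = self._full_rank_setup()
        u = backsolve_snp_effects(
            M, SnpWeights.identity(40), np.linalg.inv(G), np.zeros(6), c
        )
        np.testing.assert_array_equal(u.u_hat, np.zeros(40))

    def test_reconstruction_identity_full_rank(self):
        # M D M' = c G  =>  M u_hat = a_hat exactly
        G, M, c = self._full_rank_setup()
        rng = np.random.default_rng(0)
        a_hat = rng.normal(size=6)
        u = backsolve_snp_effects(
            M, SnpWeights.identity(40), np.linalg.inv(G), a_hat, c
        )
        np.testing.assert_allclose(M @ u.u_hat, a_hat, atol=1e-8)

    def test_matches_dense_expression_on_blended_toy(self, two_by_two_panel):
        from wssgwas_kit.pedigree import Pedigree

        G, stats = compute_G(two_by_two_panel)
        A22 = compute_A(Pedigree([("a1", None, None), ("a2", None, None)]))
        Gb = blend_G(G, A22)
        Gb_inv = invert_spd(Gb)
        M, _ = centered_dosages(two_by_two_panel)
        a_hat = np.array([0.7, -0.4])
        d = SnpWeights(np.array([1.5, 0.5]))
        u = backsolve_snp_effects(M, d, Gb_inv, a_hat, stats.scale_c)
        expected = (np.diag(d.d) @ M.T @ Gb_inv @ a_hat) / stats.scale_c
        np.testing.assert_allclose(u.u_hat, expected, atol=1e-12)

    def test_unscaled_variant_differs_by_global_scalar(self):
        G, M, c = self._full_rank_setup()
        a_hat = np.ones(6)
        Ginv = np.linalg.inv(G)
        w = SnpWeights.identity(40)
        scaled = backsolve_snp_effects(M, w, Ginv, a_hat, c)
        literal = backsolve_snp_effects(
            M, w, Ginv, a_hat, c, backsolve_scaling=False
        )
        np.testing.assert_allclose(
            literal.u_hat, scaled.u_hat * c, atol=1e-10
        )


class TestBlockWeights:
    def test_split_signal(self):
        snp_map = toy_map([1] * 40)
        windows = make_windows(snp_map, block_size=20)
        u = MarkerEffects(np.r_[np.ones(20), np.zeros(20)], 1)
        d = block_weights(u, windows)
        np.testing.assert_array_equal(d.d[:20], 20.0)
        np.testing.assert_array_equal(d.d[20:], 0.0)

    def test_single_snp_tail_block(self):
        snp_map = toy_map([1] * 21)
        windows = make_windows(snp_map, block_size=20)
        u = MarkerEffects(np.r_[np.zeros(20), 3.0], 1)
        d = block_weights(u, windows)
        assert d.d[20] == pytest.approx(9.0)

    def test_all_zero_fallback_uniform(self):
        snp_map = toy_map([1] * 10)
        windows = make_windows(snp_map, block_size=5)
        d = block_weights(MarkerEffects(np.zeros(10), 1), windows)
        np.testing.assert_array_equal(d.d, np.ones(10))

    def test_permutation_within_block_invariant(self):
        snp_map = toy_map([1] * 40)
        windows = make_windows(snp_map, block_size=20)
        rng = np.random.default_rng(1)
        u = rng.normal(size=40)
        d1 = block_weights(MarkerEffects(u, 1), windows)
        shuffled = u.copy()
        shuffled[:20] = rng.permutation(shuffled[:20])
        d2 = block_weights(MarkerEffects(shuffled, 1), windows)
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-12)


class TestNormalizeWeights:
    @given(
        scale=st.floats(0.01, 100),
        values=st.lists(st.floats(0.01, 50), min_size=2, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_trace_preserved(self, scale, values):
        d_old = SnpWeights.identity(len(values))
        d_new = SnpWeights(np.array(values) * scale)
        out = normalize_weights(d_new, d_old)
        assert out.trace == pytest.approx(len(values), rel=1e-12)

    def test_doubling_cancels(self):
        d_old = SnpWeights(np.array([1.0, 2.0, 3.0]))
        d_new = SnpWeights(2.0 * d_old.d)
        np.testing.assert_allclose(
            normalize_weights(d_new, d_old).d, d_old.d, atol=1e-12
        )


class TestWindowVariance:
    def test_zero_effects_zero_everywhere(self):
        snp_map = toy_map([1] * 10)
        windows = make_windows(snp_map, block_size=5)
        M = np.random.default_rng(0).normal(size=(6, 10))
        res = window_variance_explained(
            M, MarkerEffects(np.zeros(10), 1), 1.0, windows
        )
        assert all(r.gv_percent == 0 for r in res)

    def test_single_window_equals_total(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(8, 6))
        u = rng.normal(size=6)
        snp_map = toy_map([1] * 6)
        windows = make_windows(snp_map, block_size=6)
        res = window_variance_explained(M, MarkerEffects(u, 1), 2.0, windows)
        assert res[0].gv_percent == pytest.approx(
            np.var(M @ u, ddof=1) / 2.0 * 100
        )

    def test_three_window_toy_matches_direct_sums(self):
        # spreadsheet-style oracle: per-window scores tabulated explicitly
        M = np.array(
            [
                [1.0, 0.0, -1.0, 2.0, 0.5, -0.5],
                [0.0, 1.0, 1.0, -1.0, 0.5, 0.5],
                [-1.0, -1.0, 0.0, 0.0, -1.0, 0.0],
                [0.5, 0.0, 0.0, -1.0, 0.0, 0.0],
            ]
        )
        u = np.array([0.2, -0.1, 0.3, 0.0, 0.5, -0.2])
        snp_map = toy_map([1, 1, 2, 2, 3, 3])
        windows = make_windows(snp_map, block_size=2)
        res = window_variance_explained(M, MarkerEffects(u, 1), 0.5, windows)
        for r, cols in zip(res, [(0, 1), (2, 3), (4, 5)]):
            score = M[:, cols[0]] * u[cols[0]] + M[:, cols[1]] * u[cols[1]]
            assert r.gv_percent == pytest.approx(
                np.var(score, ddof=1) / 0.5 * 100
            )

    def test_nonpositive_variance_rejected(self):
        snp_map = toy_map([1])
        windows = make_windows(snp_map, block_size=1)
        with pytest.raises(ValueError):
            window_variance_explained(
                np.ones((2, 1)), MarkerEffects(np.ones(1), 1), 0.0, windows
            )


class TestSelectWindows:
    def test_inclusive_threshold_and_ordering(self):
        snp_map = toy_map([1, 1, 1])
        windows = make_windows(snp_map, block_size=1)
        results = [
            type("R", (), {})()
            for _ in range(3)
        ]
        from wssgwas_kit.wssgwas import WindowResult

        results = [
            WindowResult(windows[0], 0.5),
            WindowResult(windows[1], 1.0),
            WindowResult(windows[2], 2.3),
        ]
        out = select_windows(results, threshold=1.0)
        assert [r.gv_percent for r in out] == [2.3, 1.0]

    def test_empty_input(self):
        assert select_windows([]) == []

    def test_printed_fixture_all_selected(self):
        from wssgwas_kit.synthetic_data import load_table2_fixture

        table = load_table2_fixture()
        assert all(r.gv_percent >= 1.0 for r in table.rows)


class TestRunWssgwas:
    def test_single_iteration_is_plain_ssgwas(self):
        # loop with n_iterations=1 must equal the manual D = I pipeline
        ped, panel, pheno, qtl, sa2, se2 = one_qtl_recovery_study(
            seed=0, n_snps=400, qtl_index=200
        )
        spec = ModelSpec("y", [], [], sa2, se2)
        res = run_wssgwas(panel, ped, pheno, spec, n_iterations=1)
        from wssgwas_kit.mixed_model import build_incidence, compute_dgv, solve_mme
        from wssgwas_kit.relationships import (
            compute_A_inverse, compute_H_inverse,
        )

        A22 = compute_A(ped, subset=panel.animal_ids)
        G, stats = compute_G(panel)
        Gb = blend_G(G, A22)
        Gb_inv = invert_spd(Gb)
        h_inv = compute_H_inverse(
            compute_A_inverse(ped), A22, Gb, panel.animal_ids, ped.ids
        )
        design = build_incidence(pheno, spec, ped.ids)
        sol = solve_mme(design, h_inv, spec)
        dgv = compute_dgv(Gb_inv, sol.gebv.loc[panel.animal_ids].to_numpy())
        M, _ = centered_dosages(panel)
        u = backsolve_snp_effects(
            M, SnpWeights.identity(400), Gb_inv, dgv, stats.scale_c
        )
        np.testing.assert_allclose(res.effects.u_hat, u.u_hat, atol=1e-8)

    def test_trace_conserved_and_entropy_monotone(self):
        ped, panel, pheno, qtl, sa2, se2 = one_qtl_recovery_study(
            seed=1, n_snps=400, qtl_index=200
        )
        spec = ModelSpec("y", [], [], sa2, se2)
        res = run_wssgwas(panel, ped, pheno, spec, n_iterations=2)
        for diag in res.per_iteration:
            assert diag["trace_d"] == pytest.approx(400.0, abs=1e-9)
        assert res.weights.trace == pytest.approx(400.0, abs=1e-9)
        assert (
            res.per_iteration[1]["weight_entropy"]
            <= res.per_iteration[0]["weight_entropy"]
        )

    def test_qtl_window_gv_grows_with_reweighting(self):
        ped, panel, pheno, qtl, sa2, se2 = one_qtl_recovery_study(seed=2)
        spec = ModelSpec("y", [], [], sa2, se2)
        res = run_wssgwas(panel, ped, pheno, spec, n_iterations=2)
        qtl_window = next(
            w.window_id for w in res.windows if qtl in w.snp_indices
        )
        gv1 = res.per_iteration[0]["gv_percent_by_window"][qtl_window]
        gv2 = res.per_iteration[1]["gv_percent_by_window"][qtl_window]
        assert gv2 > gv1
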