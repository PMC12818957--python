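"""GRM estimators against hand/loop oracles; LD pruning against brute force."""

import numpy as np
import pytest

from invgwas.data_model import filter_variants
from invgwas.relatedness import build_grm, grm_gcta, grm_loco, grm_vanraden, ld_prune

from conftest import make_panel


class TestVanRaden:
    def test_hand_example(self):
        # 3 lines x 2 variants; K evaluated by hand from the definition
        panel = make_panel([[0, 2], [2, 0], [2, 2]])
        K = grm_vanraden(panel).K
        assert K[0, 0] == pytest.approx(2.5)
        assert K[0, 1] == pytest.approx(-2.0)

    def test_identical_lines_share_relatedness(self):
        panel = make_panel([[0, 2, 2], [0, 2, 2], [2, 0, 0]])
        K = grm_vanraden(panel).K
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 0] == pytest.approx(K[1, 1])

    def test_unrelated_hwe_panel_normalization(self):
        # binomial(2, p) dosages: E[diag] -> 1, E[offdiag] -> 0 at large M
        rng = np.random.default_rng(0)
        n, m = 60, 8000
        p = rng.uniform(0.1, 0.9, m)
        panel = make_panel(rng.binomial(2, p, size=(n, m)).astype(float))
        K = grm_vanraden(panel).K
        off = K[~np.eye(n, dtype=bool)]
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.03)
        assert abs(off.mean()) < 0.02

    def test_mean_imputation_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0.0, 2.0], size=(6, 10))
        d[2, 3] = np.nan
        panel = make_panel(d)
        K = grm_vanraden(panel).K
        # loop oracle: impute to 2p computed from non-missing, then definition
        D = d.copy()
        p = np.array([np.nanmean(D[:, j]) / 2 for j in range(10)])
        for j in range(10):
            D[np.isnan(D[:, j]), j] = 2 * p[j]
        Z = D - 2 * p
        K2 = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K, K2, atol=1e-12)

    def test_all_missing_variant_errors(self):
        d = np.array([[0.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="all-missing"):
            grm_vanraden(make_panel(d))


class TestGcta:
    def test_single_variant_formula(self):
        panel = make_panel([[0.0], [2.0]])
        K = grm_gcta(panel).K
        np.testing.assert_allclose(K, [[2, -2], [-2, 2]], atol=1e-12)

    def test_equals_standardized_vanraden_without_missingness(self):
        rng = np.random.default_rng(2)
        d = rng.choice([0.0, 2.0], size=(12, 30))
        d[:, 0] = [0, 2] * 6  # ensure polymorphic everywhere
        panel = make_panel(d)
        panel = filter_variants(panel, 0.01, 1.0)
        K = grm_gcta(panel).K
        p = panel.alt_freq()
        X = (panel.dosage - 2 * p) / np.sqrt(2 * p * (1 - p))
        np.testing.assert_allclose(K, X @ X.T / panel.n_variants, atol=1e-10)

    def test_pairwise_counts_match_loop_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.choice([0.0, 2.0], size=(5, 12))
        d[:, 0] = [0, 2, 0, 2, 0]
        d[1, 4] = np.nan  # single masked entry
        panel = make_panel(d)
        panel = panel.subset_variants(panel.maf() > 0)
        K = grm_gcta(panel).K
        p = panel.alt_freq()
        X = (panel.dosage - 2 * p) / np.sqrt(2 * p * (1 - p))
        n = panel.n_lines
        K2 = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                terms = [
                    X[i, v] * X[j, v]
                    for v in range(panel.n_variants)
                    if not (np.isnan(X[i, v]) or np.isnan(X[j, v]))
                ]
                K2[i, j] = np.mean(terms)
        np.testing.assert_allclose(K, K2, atol=1e-12)

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            grm_gcta(make_panel([[0.0], [0.0]]))


class TestLdPrune:
    def test_identical_within_window_second_removed(self):
        d = np.array([[0, 0], [2, 2], [0, 0], [2, 2]], dtype=float)
        panel = make_panel(d, positions=[1000, 4000])
        assert ld_prune(panel) == [panel.variants["id"].iloc[0]]

    def test_identical_outside_window_both_kept(self):
        d = np.array([[0, 0], [2, 2], [0, 0], [2, 2]], dtype=float)
        panel = make_panel(d, positions=[1000, 7000])
        assert ld_prune(panel) == panel.variants["id"].tolist()

    def test_window_boundary_inclusive(self):
        d = np.array([[0, 0], [2, 2], [0, 0], [2, 2]], dtype=float)
        panel = make_panel(d, positions=[1000, 6000])  # distance exactly 5000
        assert ld_prune(panel) == [panel.variants["id"].iloc[0]]

    def test_brute_force_oracle_50_variants(self):
        rng = np.random.default_rng(7)
        n, m = 40, 50
        pos = np.sort(rng.choice(np.arange(1, 60_001), size=m, replace=False))
        base = rng.choice([0.0, 2.0], size=(n, 8))
        d = base[:, rng.integers(0, 8, m)]  # blocks of correlated variants
        flip = rng.random((n, m)) < 0.1
        d = np.where(flip, 2 - d, d)
        panel = make_panel(d, positions=pos)
        kept = ld_prune(panel, r2_max=0.2, window_bp=5000)

        # independent greedy-first oracle
        expected = []
        for i in range(m):
            gi = d[:, i]
            ok = True
            for jid in expected:
                j = panel.variants.index[panel.variants["id"] == jid][0]
                if abs(pos[i] - pos[j]) > 5000:
                    continue
                if gi.std() == 0 or d[:, j].std() == 0:
                    continue
                if np.corrcoef(gi, d[:, j])[0, 1] ** 2 > 0.2:
                    ok = False
                    break
            if ok:
                expected.append(panel.variants["id"].iloc[i])
        assert kept == expected
        # retained pairs within window all satisfy the r^2 bound
        kept_idx = [panel.variants.index[panel.variants["id"] == v][0] for v in kept]
        for a_i, a in enumerate(kept_idx):
            for b in kept_idx[a_i + 1:]:
                if abs(pos[a] - pos[b]) <= 5000 and d[:, a].std() > 0 and d[:, b].std() > 0:
                    assert np.corrcoef(d[:, a], d[:, b])[0, 1] ** 2 <= 0.2 + 1e-12


class TestLoco:
    def test_excluding_empty_arm_equals_full(self):
        rng = np.random.default_rng(4)
        d = rng.choice([0.0, 2.0], size=(10, 20))
        d[:, 0] = [0, 2] * 5
        panel = make_panel(d)
        panel = panel.subset_variants((panel.maf() > 0))
        np.testing.assert_allclose(grm_loco(panel, "X").K, grm_gcta(panel).K)

    def test_arm_exclusions_partition_variants(self, sim_small):
        panel = filter_variants(sim_small["panel"], 0.05, 0.15)
        pruned = panel.subset_variants(ld_prune(panel))
        arms = pruned.variants["arm"].unique()
        counts = {a: (pruned.variants["arm"] != a).sum() for a in arms}
        total = len(pruned.variants)
        # each variant omitted exactly once across the arm exclusions
        assert sum(total - counts[a] for a in arms) == total

    def test_grms_are_psd(self, sim_small):
        panel = sim_small["panel"]
        for method, arm in [("full", None), ("ld", None), ("loco", "2L")]:
            grm = build_grm(panel, method, excluded_arm=arm)
            w = np.linalg.eigvalsh(grm.K)
            # pairwise-complete estimation permits slightly negative values
            assert w[0] >= -0.05 * np.trace(grm.K) / len(grm.line_ids)

    def test_loco_removes_karyotype_relatedness(self, sim_small):
        panel, kary = sim_small["panel"], sim_small["karyotypes"]
        full = build_grm(panel, "full")
        loco = build_grm(panel, "loco", excluded_arm="2L")
        calls = kary.calls["In(2L)t"].to_numpy()
        inv_idx = np.flatnonzero(calls == "INV")
        r, c = np.triu_indices(len(inv_idx), k=1)

        def invinv_mean(K):
            return K[np.ix_(inv_idx, inv_idx)][r, c].mean()

        assert invinv_mean(full.K) > 0.2
        assert abs(invinv_mean(loco.K)) < 0.1
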