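"""Pedigree kinship, marker QC pipeline and relationship-matrix blending."""

import numpy as np
import pandas as pd
import pytest

from gxepred.relatedness import (combine_h, compute_genomic_kinship,
                                 compute_pedigree_kinship, filter_markers,
                                 impute_markers, prune_markers, scale_g_to_a)
from gxepred.simulate import simulate_marker_matrix, simulate_pedigree


def ped_frame(rows, gens=6):
    df = pd.DataFrame(rows, columns=["id", "parent1", "parent2"])
    df["inbreeding_gens"] = gens
    return df


class TestPedigreeKinship:
    def test_unrelated_founders_zero_offdiagonal(self):
        A = compute_pedigree_kinship(
            ped_frame([("A", pd.NA, pd.NA), ("B", pd.NA, pd.NA)]))
        assert A.loc["A", "B"] == 0.0

    def test_self_kinship_after_six_selfing_generations(self):
        A = compute_pedigree_kinship(
            ped_frame([("A", pd.NA, pd.NA), ("B", pd.NA, pd.NA),
                       ("X", "A", "B")]))
        # F = 1 - 2^-6 for a line from unrelated parents
        assert A.loc["X", "X"] == pytest.approx((1 + (1 - 2**-6)) / 2)
        assert A.loc["X", "X"] == pytest.approx(0.9921875)

    def test_full_sibs_of_inbred_unrelated_parents_near_half(self):
        A = compute_pedigree_kinship(
            ped_frame([("A", pd.NA, pd.NA), ("B", pd.NA, pd.NA),
                       ("S1", "A", "B"), ("S2", "A", "B")]))
        assert A.loc["S1", "S2"] == pytest.approx(0.5, abs=0.005)

    def test_diagonal_in_valid_range(self):
        cfg_rows = [("A", pd.NA, pd.NA), ("B", pd.NA, pd.NA),
                    ("C", "A", "B"), ("D", "C", "A"), ("E", "C", "D")]
        A = compute_pedigree_kinship(ped_frame(cfg_rows))
        d = np.diag(A)
        assert ((d >= 0.5) & (d <= 1.0)).all()
        assert (A.to_numpy() >= 0).all() and (A.to_numpy() <= 1).all()

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            compute_pedigree_kinship(
                ped_frame([("A", "B", "B"), ("B", "A", "A")]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kinship_matrix_is_psd(self, seed):
        from gxepred import SimulationConfig
        cfg = SimulationConfig(seed=seed, n_founders=8, n_generations=4,
                               n_genotypes=40, n_years=3,
                               trials_per_year_range=(2, 3), n_locations=4)
        A = compute_pedigree_kinship(simulate_pedigree(cfg))
        assert np.allclose(A, A.T, atol=1e-10)
        assert np.linalg.eigvalsh(A.to_numpy()).min() >= -1e-8


@pytest.fixture
def toy_markers():
    rng = np.random.default_rng(7)
    X = rng.choice([0.0, 1.0, 2.0], size=(20, 10),
                   p=[0.25, 0.5, 0.25])
    return pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                        columns=[f"m{j}" for j in range(10)])


class TestFilter:
    def test_missingness_and_maf_boundaries(self):
        n = 100
        cols = {
            "miss11": [np.nan] * 11 + [2.0] * 89,           # 11% -> removed
            "miss10": [np.nan] * 10 + [2.0] * 45 + [0.0] * 45,  # kept
            "maf04": [2.0] * 96 + [0.0] * 4,                 # MAF .04 removed
            "maf05": [2.0] * 90 + [0.0] * 10,                # MAF .05 kept
        }
        mk = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        out = filter_markers(mk)
        assert list(out.columns) == ["miss10", "maf05"]

    def test_clean_matrix_unchanged(self, toy_markers):
        pd.testing.assert_frame_equal(filter_markers(toy_markers),
                                      toy_markers)

    def test_all_removed_raises(self):
        mk = pd.DataFrame({"m": [2.0] * 99 + [0.0]})  # MAF .005
        with pytest.raises(ValueError, match="all markers"):
            filter_markers(mk)


class TestImpute:
    def test_no_missing_identity(self, toy_markers):
        pd.testing.assert_frame_equal(impute_markers(toy_markers),
                                      toy_markers)

    def test_unanimous_column(self):
        mk = pd.DataFrame({"a": [2.0, 2.0, np.nan, 2.0],
                           "b": [0.0, 2.0, 0.0, 2.0]})
        out = impute_markers(mk, seed=1)
        assert out.loc[2, "a"] == 2.0
        assert not out.isna().any().any()

    def test_mask_and_recover_on_related_lines(self):
        from gxepred import SimulationConfig
        cfg = SimulationConfig(seed=5, n_founders=8, n_generations=4,
                               n_genotypes=60, n_years=3,
                               trials_per_year_range=(2, 3), n_locations=4)
        mk = simulate_marker_matrix(simulate_pedigree(cfg), 40, seed=5)
        rng = np.random.default_rng(9)
        mask = rng.random(mk.shape) < 0.05
        masked = mk.mask(mask)
        out = impute_markers(masked, seed=2)
        recovered = (out.to_numpy()[mask] == mk.to_numpy()[mask]).mean()
        assert recovered >= 0.80

    def test_fully_missing_column_raises(self):
        mk = pd.DataFrame({"a": [np.nan] * 4, "b": [0.0, 2.0, 0.0, 2.0]})
        with pytest.raises(ValueError, match="fully missing"):
            impute_markers(mk)


class TestPrune:
    def test_duplicate_column_removed(self, toy_markers):
        mk = toy_markers.copy()
        mk["dup"] = mk["m0"]
        out = prune_markers(mk)
        assert "m0" in out.columns and "dup" not in out.columns

    def test_boundary_and_greedy_triple(self):
        # exact correlations via Cholesky on orthonormal columns:
        # r(1,2)=0.9 > threshold, r(2,3)=0.9, r(1,3)=0.65 < threshold,
        # so the greedy scan keeps {m1, m3} and drops m2
        rng = np.random.default_rng(3)
        n = 200
        Z = rng.standard_normal((n, 3))
        Q, _ = np.linalg.qr(Z - Z.mean(axis=0))   # centered orthonormal
        R = np.array([[1.0, 0.9, 0.65],
                      [0.9, 1.0, 0.9],
                      [0.65, 0.9, 1.0]])
        X = Q @ np.linalg.cholesky(R).T
        mk = pd.DataFrame(X, columns=["m1", "m2", "m3"])
        corr = np.corrcoef(X.T)
        assert abs(corr[0, 1]) > 0.8 and abs(corr[0, 2]) < 0.8
        out = prune_markers(mk)
        assert list(out.columns) == ["m1", "m3"]

    def test_pair_below_threshold_kept(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(500)
        w = 0.5 * z + np.sqrt(1 - 0.25) * rng.standard_normal(500)
        mk = pd.DataFrame({"a": z, "b": w})
        assert abs(np.corrcoef(z, w)[0, 1]) < 0.8
        assert list(prune_markers(mk).columns) == ["a", "b"]

    def test_zero_variance_dropped_with_warning(self, toy_markers):
        mk = toy_markers.copy()
        mk["const"] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = prune_markers(mk)
        assert "const" not in out.columns

    def test_pipeline_idempotent(self):
        from gxepred import SimulationConfig
        cfg = SimulationConfig(seed=6, n_founders=8, n_generations=3,
                               n_genotypes=30, n_years=3,
                               trials_per_year_range=(2, 3), n_locations=4)
        mk = simulate_marker_matrix(simulate_pedigree(cfg), 100, seed=6,
                                    missing_rate=0.03)
        once = prune_markers(impute_markers(filter_markers(mk), seed=1))
        twice = prune_markers(impute_markers(filter_markers(once), seed=1))
        pd.testing.assert_frame_equal(once, twice)


class TestGenomicKinship:
    def test_identical_rows_equal_entries(self, toy_markers):
        mk = toy_markers.copy()
        mk.loc["g1"] = mk.loc["g0"]
        G = compute_genomic_kinship(mk)
        assert G.loc["g0", "g0"] == pytest.approx(G.loc["g0", "g1"])
        assert np.allclose(G.loc["g0"], G.loc["g1"])

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(8)
        X = rng.choice([0.0, 1.0, 2.0], size=(20, 50))
        mk = pd.DataFrame(X)
        G = compute_genomic_kinship(mk).to_numpy()
        M = (X - X.mean(axis=0)) / X.std(axis=0)
        brute = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                brute[i, j] = float(M[i] @ M[j]) / 50
        assert np.max(np.abs(G - brute)) < 1e-10

    def test_toy_matrix_entrywise(self):
        X = np.array([[0.0, 2.0, 1.0, 2.0],
                      [2.0, 0.0, 1.0, 0.0],
                      [0.0, 2.0, 2.0, 2.0]])
        G = compute_genomic_kinship(pd.DataFrame(X)).to_numpy()
        M = (X - X.mean(axis=0)) / X.std(axis=0)
        assert np.max(np.abs(G - M @ M.T / 4)) < 1e-12

    def test_mean_diagonal_one(self):
        rng = np.random.default_rng(9)
        mk = pd.DataFrame(rng.choice([0.0, 1.0, 2.0], size=(80, 500)))
        G = compute_genomic_kinship(mk)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=1e-12)


class TestScaleAndBlend:
    def _pair(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((10, 30))
        G = pd.DataFrame(X @ X.T / 30, index=list("abcdefghij"),
                         columns=list("abcdefghij"))
        A = pd.DataFrame(np.eye(10) * 0.95 + 0.05,
                         index=G.index, columns=G.columns)
        return G, A

    def test_matching_moments_identity(self):
        G, A = self._pair()
        Gs = scale_g_to_a(G, A)
        Gs2 = scale_g_to_a(Gs, A)
        pd.testing.assert_frame_equal(Gs, Gs2, atol=1e-10, rtol=0,
                                      check_exact=False)

    def test_affine_invariance(self):
        G, A = self._pair()
        Gs1 = scale_g_to_a(G, A)
        Gs2 = scale_g_to_a(2.0 * G + 3.0, A)
        assert np.max(np.abs(Gs1.to_numpy() - Gs2.to_numpy())) < 1e-10

    def test_single_shared_genotype_rejected(self):
        G, A = self._pair()
        with pytest.raises(ValueError):
            scale_g_to_a(G.iloc[:1, :1], A)

    def test_blend_endpoints_and_weighting(self):
        G, A = self._pair()
        Gs = scale_g_to_a(G, A)
        assert np.allclose(combine_h(A, Gs, omega=1.0), A)
        assert np.allclose(combine_h(A, Gs, omega=0.0), Gs)
        A2 = A.copy(); A2.iloc[0, 1] = A2.iloc[1, 0] = 0.5
        Gs2 = Gs.copy(); Gs2.iloc[0, 1] = Gs2.iloc[1, 0] = 0.4
        H = combine_h(A2, Gs2, omega=0.2)
        assert H.iloc[0, 1] == pytest.approx(0.42)

    def test_ungenotyped_lines_keep_pedigree_values(self):
        G, A = self._pair()
        Gs = scale_g_to_a(G, A).iloc[:4, :4]     # only 4 lines genotyped
        H = combine_h(A, Gs, omega=0.2)
        assert np.allclose(H.iloc[4:, :], A.iloc[4:, :])
        assert list(H.index) == list(A.index)

    def test_no_markers_reduces_to_a(self):
        G, A = self._pair()
        empty = G.iloc[:0, :0]
        H = combine_h(A, empty, omega=0.2)
        pd.testing.assert_frame_equal(H, A.astype(float), check_exact=False)

    def test_omega_out_of_range(self):
        G, A = self._pair()
        with pytest.raises(ValueError):
            combine_h(A, G, omega=1.5)
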