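"""Module activation scoring: z-scores, signed/joint/single-cell variants,
offset calibration and evaluation statistics."""

import numpy as np
import pandas as pd
import pytest

import epifem as ef
from epifem.scoring import ModuleSignature


def _sig(signs):
    return ModuleSignature("M1", pd.Series(signs))


class TestZscore:
    def test_normals_have_mean_zero_sd_one(self, rng):
        mat = pd.DataFrame(rng.normal(0.5, 0.1, (30, 20)),
                           columns=[f"s{i}" for i in range(20)])
        normals = [f"s{i}" for i in range(8)]
        z = ef.zscore_vs_normals(mat, normals)
        np.testing.assert_allclose(z[normals].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z[normals].std(axis=1, ddof=0), 1.0,
                                   atol=1e-12)

    def test_two_sigma_value_scores_two(self):
        mat = pd.DataFrame(
            {"n1": [0.4], "n2": [0.6], "c": [0.5 + 2 * 0.1]}, index=["g"]
        )
        z = ef.zscore_vs_normals(mat, ["n1", "n2"])
        assert z.loc["g", "c"] == pytest.approx(2.0)

    def test_zero_sd_gene_dropped_with_warning(self):
        mat = pd.DataFrame({"n1": [0.5, 0.2], "n2": [0.5, 0.4], "c": [0.9, 0.6]},
                           index=["flat", "ok"])
        with pytest.warns(UserWarning, match="zero normal SD"):
            z = ef.zscore_vs_normals(mat, ["n1", "n2"])
        assert list(z.index) == ["ok"]

    def test_fewer_than_two_normals_error(self):
        mat = pd.DataFrame({"n1": [0.5], "c": [0.9]}, index=["g"])
        with pytest.raises(ValueError, match=">=2 normal"):
            ef.zscore_vs_normals(mat, ["n1"])


class TestSignedScore:
    def test_hand_case(self):
        z = pd.DataFrame({"s1": [2.0, -1.0]}, index=["a", "b"])
        out = ef.fem_score_signed(z, _sig({"a": 1, "b": -1}))
        assert out["score"].iloc[0] == pytest.approx(1.5)
        assert out["n_genes_used"].iloc[0] == 2

    def test_all_zero_z_scores_zero(self):
        z = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        out = ef.fem_score_signed(z, _sig({"a": 1, "b": -1}))
        assert out["score"].iloc[0] == 0.0

    def test_linear_in_z(self, rng):
        z = pd.DataFrame(rng.normal(size=(5, 4)),
                         index=list("abcde"), columns=[f"s{i}" for i in range(4)])
        sig = _sig({g: 1 if i % 2 else -1 for i, g in enumerate("abcde")})
        a = ef.fem_score_signed(z, sig)["score"]
        b = ef.fem_score_signed(2 * z, sig)["score"]
        np.testing.assert_allclose(b, 2 * a)

    def test_invariant_to_per_gene_affine_transform(self, rng):
        mat = pd.DataFrame(rng.normal(5, 1, (6, 30)),
                           index=list("abcdef"),
                           columns=[f"s{i}" for i in range(30)])
        normals = [f"s{i}" for i in range(10)]
        sig = _sig({g: 1 for g in "abcdef"})
        base = ef.fem_score_signed(ef.zscore_vs_normals(mat, normals), sig)
        scale = pd.Series(rng.uniform(0.5, 3, 6), index=mat.index)
        shift = pd.Series(rng.normal(size=6), index=mat.index)
        mat2 = mat.mul(scale, axis=0).add(shift, axis=0)
        trans = ef.fem_score_signed(ef.zscore_vs_normals(mat2, normals), sig)
        np.testing.assert_allclose(trans["score"], base["score"], atol=1e-9)

    def test_no_signature_gene_present_error(self):
        z = pd.DataFrame({"s1": [1.0]}, index=["x"])
        with pytest.raises(ValueError, match="no signature gene"):
            ef.fem_score_signed(z, _sig({"a": 1}))

    def test_planted_shift_separates_groups(self, rng):
        n_genes, n = 30, 40
        genes = [f"g{i}" for i in range(n_genes)]
        normals = [f"n{i}" for i in range(n)]
        cases = [f"c{i}" for i in range(n)]
        signs = {g: (1 if i % 2 else -1) for i, g in enumerate(genes)}
        base = rng.normal(0, 1, (n_genes, 2 * n))
        shift = np.array([signs[g] for g in genes], dtype=float)
        base[:, n:] += shift[:, None]  # |delta z| = 1 along the signature
        mat = pd.DataFrame(base, index=genes, columns=normals + cases)
        z = ef.zscore_vs_normals(mat, normals)
        scores = ef.fem_score_signed(z, _sig(signs))
        groups = pd.Series(["normal"] * n + ["case"] * n, index=normals + cases)
        res = ef.evaluate_scores(scores, groups, "case")
        assert res["wilcoxon_p"] < 1e-6
        assert res["auc"] > 0.95


class TestJointScore:
    def test_hand_case(self):
        zm = pd.DataFrame({"s1": [1.0, -2.0]}, index=["a", "b"])
        zr = pd.DataFrame({"s1": [-1.0, 1.0]}, index=["a", "b"])
        out = ef.fem_score_joint(zm, zr, _sig({"a": 1, "b": -1}))
        assert out["score"].iloc[0] == pytest.approx(2.5)

    def test_identical_modalities_score_zero(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"),
                         columns=[f"s{i}" for i in range(4)])
        out = ef.fem_score_joint(z, z, _sig({g: 1 for g in "abc"}))
        assert (out["score"] == 0).all()

    def test_nonnegative(self, rng):
        zm = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"),
                          columns=[f"s{i}" for i in range(6)])
        zr = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"),
                          columns=zm.columns)
        out = ef.fem_score_joint(zm, zr, _sig({g: 1 for g in "abcd"}))
        assert (out["score"] >= 0).all()

    def test_no_common_samples_error(self, rng):
        zm = pd.DataFrame({"s1": [1.0]}, index=["a"])
        zr = pd.DataFrame({"s2": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="common samples"):
            ef.fem_score_joint(zm, zr, _sig({"a": 1}))

    def test_divergent_cases_score_higher(self, rng):
        genes = [f"g{i}" for i in range(20)]
        normals = [f"n{i}" for i in range(20)]
        cases = [f"c{i}" for i in range(20)]
        m = rng.normal(0, 1, (20, 40))
        r = rng.normal(0, 1, (20, 40))
        m[:, 20:] += 1.5
        r[:, 20:] -= 1.5  # anti-correlated deviation in cases
        zm = ef.zscore_vs_normals(
            pd.DataFrame(m, index=genes, columns=normals + cases), normals
        )
        zr = ef.zscore_vs_normals(
            pd.DataFrame(r, index=genes, columns=normals + cases), normals
        )
        scores = ef.fem_score_joint(zm, zr, _sig({g: 1 for g in genes}))
        groups = pd.Series(["normal"] * 20 + ["case"] * 20,
                           index=normals + cases)
        res = ef.evaluate_scores(scores, groups, "case")
        assert res["wilcoxon_p"] < 0.01


class TestOffsetCalibration:
    def test_target_equal_to_sd_at_zero_gives_zero(self, rng):
        mat = pd.DataFrame(rng.uniform(0.3, 0.7, (50, 20)),
                           columns=[f"s{i}" for i in range(20)])
        normals = [f"s{i}" for i in range(6)]
        sd0 = float(np.std(ef.zscore_vs_normals(mat, normals).to_numpy()))
        cal = ef.calibrate_offset(mat, normals, target_sd=sd0)
        assert cal.gamma_offset == 0.0

    def test_bisection_hits_target_to_tolerance(self, rng):
        mat = pd.DataFrame(rng.uniform(0.3, 0.7, (80, 24)),
                           columns=[f"s{i}" for i in range(24)])
        normals = [f"s{i}" for i in range(6)]
        sd0 = float(np.std(ef.zscore_vs_normals(mat, normals).to_numpy()))
        cal = ef.calibrate_offset(mat, normals, target_sd=sd0 / 2)
        assert cal.gamma_offset > 0
        assert abs(cal.achieved_sd - sd0 / 2) < 1e-6

    def test_unreachable_target_clamps_to_zero(self, rng):
        mat = pd.DataFrame(rng.uniform(0.3, 0.7, (50, 20)),
                           columns=[f"s{i}" for i in range(20)])
        normals = [f"s{i}" for i in range(6)]
        sd0 = float(np.std(ef.zscore_vs_normals(mat, normals).to_numpy()))
        with pytest.warns(UserWarning, match="clamped"):
            cal = ef.calibrate_offset(mat, normals, target_sd=2 * sd0)
        assert cal.gamma_offset == 0.0
        assert cal.clamped


class TestSingleCellScore:
    def test_too_few_variable_genes_unscoreable(self, rng):
        genes = list("abcdefg")
        cells = [f"c{i}" for i in range(20)]
        x = pd.DataFrame(rng.normal(2, 1, (7, 20)).clip(0),
                         index=genes, columns=cells)
        x.loc[list("abcd")] = 1.0  # constant -> not variable
        sig = _sig({g: -1 for g in genes})
        with pytest.warns(UserWarning, match="unscoreable"):
            out = ef.fem_score_scrna(x, sig, cells[:10], min_var_genes=5)
        assert out is None

    def test_identical_cells_unscoreable(self):
        genes = list("abcdef")
        cells = [f"c{i}" for i in range(10)]
        x = pd.DataFrame(1.0, index=genes, columns=cells)
        with pytest.warns(UserWarning, match="unscoreable"):
            assert ef.fem_score_scrna(x, _sig({g: 1 for g in genes}),
                                      cells[:5]) is None

    def test_planted_shift_separates_cells_per_patient(self, network_truth,
                                                       sim_cfg):
        net, truth = network_truth
        genes = sorted(set(sorted(net.nodes())[:100]) | set(truth.modules[0]))
        scr = ef.simulate_scrna(genes, truth.modules[0], sim_cfg)
        sig = _sig({g: -1 for g in truth.modules[0]})
        cells = scr["cells"]
        normal_cells = cells.index[cells["tissue"] == "normal"]
        out = ef.fem_score_scrna(scr["logexpr"], sig, normal_cells)
        assert out is not None
        merged = out.merge(cells, left_on="sample_id", right_index=True)
        for _, sub in merged.groupby("patient"):
            res = ef.evaluate_scores(
                sub, sub.set_index("sample_id")["tissue"], "BE"
            )
            assert res["wilcoxon_p"] < 0.05


class TestEvaluateScores:
    def test_perfect_separation_auc_one(self):
        sc = pd.DataFrame({"sample_id": list("abcd"), "module_id": "M1",
                           "score": [5.0, 6.0, 1.0, 2.0], "n_genes_used": 3})
        groups = pd.Series(["case", "case", "normal", "normal"],
                           index=list("abcd"))
        assert ef.evaluate_scores(sc, groups, "case")["auc"] == 1.0

    def test_identical_distributions_auc_half(self, rng):
        n = 200
        ids = [f"s{i}" for i in range(2 * n)]
        sc = pd.DataFrame({"sample_id": ids, "module_id": "M1",
                           "score": rng.normal(size=2 * n), "n_genes_used": 3})
        groups = pd.Series(["case"] * n + ["normal"] * n, index=ids)
        res = ef.evaluate_scores(sc, groups, "case")
        assert 0.4 < res["auc"] < 0.6
        assert res["wilcoxon_p"] > 0.05

    def test_tied_scores_counted_half_oracle(self):
        # cases {3,4,5} vs controls {1,2,3}: 8 wins + 1 tie of 9 pairs
        sc = pd.DataFrame({"sample_id": list("abcdef"), "module_id": "M1",
                           "score": [3, 4, 5, 1, 2, 3], "n_genes_used": 2})
        groups = pd.Series(["case"] * 3 + ["normal"] * 3, index=list("abcdef"))
        assert ef.evaluate_scores(sc, groups, "case")["auc"] == pytest.approx(
            8.5 / 9
        )

    def test_empty_group_error(self):
        sc = pd.DataFrame({"sample_id": ["a"], "module_id": "M1",
                           "score": [1.0], "n_genes_used": 1})
        groups = pd.Series(["case"], index=["a"])
        with pytest.raises(ValueError, match="non-empty"):
            ef.evaluate_scores(sc, groups, "case")


class TestCovariateAdjustment:
    def test_orthogonal_covariate_keeps_group_effect(self, rng):
        n = 60
        ids = [f"s{i}" for i in range(2 * n)]
        g = np.array([0.0] * n + [1.0] * n)
        cov = pd.Series(rng.normal(size=2 * n), index=ids)
        score = g * 1.0 + rng.normal(0, 0.5, 2 * n)
        sc = pd.DataFrame({"sample_id": ids, "module_id": "M1",
                           "score": score, "n_genes_used": 3})
        groups = pd.Series(np.where(g == 1, "case", "normal"), index=ids)
        adj = ef.score_with_covariate_adjustment(sc, groups, cov, "case")
        unadj = ef.evaluate_scores(sc, groups, "case")
        assert adj["p"] < 1e-6
        assert unadj["wilcoxon_p"] < 1e-6

    def test_fully_confounded_covariate_removes_group_effect(self, rng):
        n = 60
        ids = [f"s{i}" for i in range(2 * n)]
        g = np.array([0.0] * n + [1.0] * n)
        cov = pd.Series(g + rng.normal(0, 0.01, 2 * n), index=ids)
        score = cov.to_numpy() * 2.0 + rng.normal(0, 0.05, 2 * n)
        sc = pd.DataFrame({"sample_id": ids, "module_id": "M1",
                           "score": score, "n_genes_used": 3})
        groups = pd.Series(np.where(g == 1, "case", "normal"), index=ids)
        adj = ef.score_with_covariate_adjustment(sc, groups, cov, "case")
        with pytest.warns(UserWarning, match="constant covariate"):
            unadj = ef.score_with_covariate_adjustment(
                sc, groups, pd.Series(1.0, index=ids), "case"
            )
        # group effect collapses once the confounder is in the model
        assert abs(adj["t"]) < 0.05 * abs(unadj["t"])

    def test_constant_covariate_warns_and_reduces_to_unadjusted(self, rng):
        ids = [f"s{i}" for i in range(20)]
        sc = pd.DataFrame({"sample_id": ids, "module_id": "M1",
                           "score": rng.normal(size=20), "n_genes_used": 3})
        groups = pd.Series(["case"] * 10 + ["normal"] * 10, index=ids)
        cov = pd.Series(1.0, index=ids)
        with pytest.warns(UserWarning, match="constant covariate"):
            out = ef.score_with_covariate_adjustment(sc, groups, cov, "case")
        assert np.isfinite(out["t"])
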