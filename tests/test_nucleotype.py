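"""Nucleotype quantification: clustering, shifts, modes, PCA, rarefaction."""

import numpy as np
import pandas as pd
import pytest

from karyoshift.filtering import c3_site_filter, depth_iqr_filter
from karyoshift.nucleotype import (
    LineProfile,
    NucleotypeModel,
    af_mode_report,
    binary_distance_matrix,
    binary_distance_tree,
    per_site_shift_tests,
    presence_absence_matrix,
    qualitative_pca,
    quantitative_pca,
    rarefaction_regression,
)
from karyoshift.simulate import SimConfig, simulate_control


def make_profile(line_id, counts, role="offspring"):
    counts = np.asarray(counts, dtype=int)
    keys = [("s1", i, "A", "G") for i in range(len(counts))]
    f = counts[:, 0] / counts.sum(axis=1)
    return LineProfile(line_id, role, "dikaryon", keys, f, counts)


class TestPresenceAbsence:
    def test_snp_count_threshold(self):
        loci = {"a": set(range(4000)), "b": set(range(3999))}
        matrix, kept = presence_absence_matrix(loci)
        assert kept == ["a"]

    def test_missing_is_absent(self):
        loci = {"a": {1, 2, 3}, "b": {2, 3, 4}}
        matrix, _ = presence_absence_matrix(loci, min_snps=1)
        assert matrix.loc["a", "4"] == 0
        assert matrix.loc["b", "1"] == 0

    def test_identical_samples_identical_rows(self):
        loci = {"a": {1, 2}, "b": {1, 2}}
        matrix, _ = presence_absence_matrix(loci, min_snps=1)
        assert (matrix.loc["a"] == matrix.loc["b"]).all()

    def test_all_filtered_raises(self):
        with pytest.raises(ValueError):
            presence_absence_matrix({"a": {1}}, min_snps=10)


class TestBinaryDistance:
    def test_hand_values(self):
        matrix = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
        dist = binary_distance_matrix(matrix)
        assert dist.loc["a", "b"] == pytest.approx(2 / 3)

    def test_identical_and_complementary(self):
        matrix = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]], index=list("abc"))
        dist = binary_distance_matrix(matrix)
        assert dist.loc["a", "b"] == 0
        assert dist.loc["a", "c"] == 1

    def test_empty_union_warns(self):
        matrix = pd.DataFrame([[0, 0], [0, 0]], index=["a", "b"])
        with pytest.warns(UserWarning, match="no present locus"):
            dist = binary_distance_matrix(matrix)
        assert dist.loc["a", "b"] == 0

    def test_newick_contains_all_tips(self):
        matrix = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 1], [0, 0, 1, 1]], index=["x", "y", "z"]
        )
        _, newick = binary_distance_tree(matrix)
        for tip in ("x", "y", "z"):
            assert tip in newick


class TestQualitativePca:
    def test_single_variable_column(self):
        matrix = pd.DataFrame([[1, 1], [0, 1], [1, 1], [0, 1]], index=list("abcd"))
        _, _, explained = qualitative_pca(matrix)
        assert explained[0] == pytest.approx(1.0)

    def test_duplicated_sample_coincident_scores(self):
        matrix = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]], index=list("abc"))
        scores, _, _ = qualitative_pca(matrix)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["b"], atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(4, 3)).astype(float)
        matrix = pd.DataFrame(x, index=list("abcd"))
        scores, _, explained = qualitative_pca(matrix)
        cov = np.cov(x, rowvar=False, bias=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = eigvals[: len(explained)]
        np.testing.assert_allclose(
            explained[: len(eigvals)], eigvals / eigvals.sum(), atol=1e-10
        )
        assert explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            qualitative_pca(pd.DataFrame([[1, 0]], index=["a"]))


class TestShiftTests:
    def test_identical_lines_no_shift(self):
        parent = make_profile("P", [(50, 50)] * 10, role="parent")
        offspring = make_profile("O", [(50, 50)] * 10)
        per_site, shift = per_site_shift_tests(parent, offspring)
        assert shift.n_sites_significant == 0
        assert shift.direction == "none"

    def test_constant_difference_closed_form(self):
        # parent 50/50 vs offspring 60/40 at each site: chi2 = 2.0202...
        parent = make_profile("P", [(50, 50)] * 100, role="parent")
        offspring = make_profile("O", [(60, 40)] * 100)
        per_site, shift = per_site_shift_tests(parent, offspring)
        expected = 200 * (50 * 40 - 50 * 60) ** 2 / (100 * 100 * 110 * 90)
        assert per_site["chi2"].iloc[0] == pytest.approx(expected, abs=1e-10)
        assert shift.n_sites_significant == 0  # p ~ 0.155 per site
        # constant deltas across significant sites exercise the zero-variance path
        strong = make_profile("O2", [(80, 20)] * 100)
        _, shift2 = per_site_shift_tests(parent, strong)
        assert shift2.n_sites_significant == 100
        assert shift2.t_test is None  # zero-variance deltas: t undefined
        assert shift2.mean_delta_f_ref == pytest.approx(0.30)

    def test_antisymmetry_under_line_swap(self):
        rng = np.random.default_rng(1)
        counts_p = rng.integers(20, 90, size=(40, 2))
        counts_o = rng.integers(20, 90, size=(40, 2))
        p = make_profile("P", counts_p, role="parent")
        o = make_profile("O", counts_o)
        _, fwd = per_site_shift_tests(p, o)
        _, rev = per_site_shift_tests(o, p)
        assert fwd.mean_delta_f_ref == pytest.approx(-rev.mean_delta_f_ref, abs=1e-12)
        assert fwd.n_sites_significant == rev.n_sites_significant
        assert fwd.mw_test.p_value == pytest.approx(rev.mw_test.p_value, abs=1e-12)

    def test_simulated_upward_shift_detected(self):
        rng = np.random.default_rng(2)
        n = 500
        parent_counts = np.stack([rng.binomial(100, 0.5, n), np.zeros(n, int)], axis=1)
        parent_counts[:, 1] = 100 - parent_counts[:, 0]
        off_counts = np.stack([rng.binomial(100, 0.6, n), np.zeros(n, int)], axis=1)
        off_counts[:, 1] = 100 - off_counts[:, 0]
        p = make_profile("P", parent_counts, role="parent")
        o = make_profile("O", off_counts)
        _, shift = per_site_shift_tests(p, o)
        assert shift.t_test.p_value < 1e-6
        assert shift.direction == "increase"

    def test_too_few_common_sites_raises(self):
        p = make_profile("P", [(50, 50)])
        o = make_profile("O", [(50, 50)])
        with pytest.raises(ValueError, match="common sites"):
            per_site_shift_tests(p, o)


class TestModeReport:
    def test_tight_unimodal_at_half(self):
        rng = np.random.default_rng(3)
        f = 0.5 + rng.normal(0, 0.004, size=300)
        report = af_mode_report(f)
        assert report.classification == "unimodal"
        assert report.mode_locations[0] == pytest.approx(0.5, abs=0.01)

    def test_balanced_mixture_bimodal(self):
        rng = np.random.default_rng(4)
        depth = 100
        truth = np.repeat([0.4, 0.6], 500)
        f = rng.binomial(depth, truth) / depth
        report = af_mode_report(f)
        assert report.classification == "bimodal"
        assert report.mode_locations[0] == pytest.approx(0.4, abs=0.03)
        assert report.mode_locations[1] == pytest.approx(0.6, abs=0.03)

    def test_tetraploid_control_three_modes(self):
        ctrl = simulate_control(4, SimConfig(seed=5), n_sites=3000)
        report = af_mode_report(ctrl["f_ref"].to_numpy())
        assert report.n_modes == 3

    def test_small_sample_raises(self):
        with pytest.raises(ValueError, match=">= 50"):
            af_mode_report(np.full(49, 0.5))


class TestQuantitativePca:
    def test_extreme_lines_oppose_on_pc1(self):
        rng = np.random.default_rng(6)
        n = 200
        ref_is_nuc1 = rng.random(n) < 0.5
        profiles = []
        for i, p in enumerate([0.5, 0.5, 0.5, 0.4, 0.6]):
            f_nuc1 = rng.binomial(100, p, n) / 100
            f_ref = np.where(ref_is_nuc1, f_nuc1, 1 - f_nuc1)
            counts = np.stack([(f_ref * 100).astype(int), (100 - f_ref * 100).astype(int)], 1)
            profiles.append(
                LineProfile(
                    f"L{i}", "offspring", "dikaryon",
                    [("s1", j, "A", "G") for j in range(n)], f_ref, counts,
                )
            )
        scores, _, explained = quantitative_pca(profiles)
        pc1 = scores["PC1"]
        extremes = {pc1.idxmax(), pc1.idxmin()}
        assert extremes == {"L3", "L4"}
        assert abs(pc1.loc["L3"]) > 2 * pc1.drop(["L3", "L4"]).abs().max()
        assert explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_identical_lines_coincide(self):
        keys = [("s1", j, "A", "G") for j in range(10)]
        f = np.linspace(0.3, 0.7, 10)
        counts = np.stack([(f * 100).astype(int), (100 - f * 100).astype(int)], 1)
        profiles = [
            LineProfile(f"L{i}", "offspring", "dikaryon", keys, f, counts) for i in range(3)
        ]
        scores, _, explained = quantitative_pca(profiles)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-10)

    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(7)
        mat = rng.random((5, 10))
        keys = [("s1", j, "A", "G") for j in range(10)]
        profiles = [
            LineProfile(
                f"L{i}", "offspring", "dikaryon", keys, mat[i],
                np.stack([(mat[i] * 100).astype(int), (100 - mat[i] * 100).astype(int)], 1),
            )
            for i in range(5)
        ]
        _, _, explained = quantitative_pca(profiles)
        cov = np.cov(mat, rowvar=True, bias=False)  # sample covariance over sites
        centered = mat - mat.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(centered @ centered.T))[::-1]
        np.testing.assert_allclose(explained[: len(eig)], eig / eig.sum(), atol=1e-10)

    def test_too_few_common_sites_raises(self):
        keys = [("s1", 0, "A", "G"), ("s1", 1, "A", "G")]
        profiles = [
            LineProfile("a", "offspring", "dikaryon", keys, np.array([0.5, 0.5]),
                        np.array([[50, 50], [50, 50]])),
            LineProfile("b", "offspring", "dikaryon", keys, np.array([0.5, 0.5]),
                        np.array([[50, 50], [50, 50]])),
        ]
        with pytest.raises(ValueError, match=">= 3"):
            quantitative_pca(profiles)


class TestRarefactionRegression:
    def test_constant_table_zero_slope(self):
        table = pd.DataFrame({"k": [1, 2, 3, 4], "mean_common_sites": [40.0] * 4})
        out = rarefaction_regression({"fam": ("dikaryon", table)})
        assert out.loc[0, "slope"] == pytest.approx(0.0)

    def test_decreasing_table_negative_fit(self):
        ks = np.arange(1, 9)
        table = pd.DataFrame({"k": ks, "mean_common_sites": 1000 * 0.9**ks})
        out = rarefaction_regression({"fam": ("dikaryon", table)})
        assert out.loc[0, "slope"] < 0
        assert out.loc[0, "adjusted_r_squared"] > 0.9
        assert out.loc[0, "p"] < 0.05

    def test_too_few_sizes_raises(self):
        table = pd.DataFrame({"k": [1, 2], "mean_common_sites": [5.0, 4.0]})
        with pytest.raises(ValueError):
            rarefaction_regression({"fam": ("homokaryon", table)})


class TestNucleotypeModel:
    def test_end_to_end_recovery(self, small_cohort, small_records):
        candidates, _ = c3_site_filter(
            small_records, None, small_cohort.genomes.scaffold_lengths
        )
        retained, _ = depth_iqr_filter(candidates)
        results = NucleotypeModel(retained, parent="P").fit()
        flag = small_cohort.genomes.sites.set_index(["scaffold", "pos"])["ref_is_nuc1"]
        for _, row in small_cohort.line_truth.iterrows():
            prof = results.profiles[row["line_id"]]
            oriented = np.array(
                [
                    f if flag.loc[(k[0], k[1])] else 1 - f
                    for k, f in zip(prof.site_keys, prof.f_ref)
                ]
            )
            assert np.median(oriented) == pytest.approx(row["p"], abs=0.03)
        assert "Nucleotype proportion analysis" in results.summary()

    def test_missing_parent_raises(self, small_cohort, small_records):
        candidates, _ = c3_site_filter(
            small_records, None, small_cohort.genomes.scaffold_lengths
        )
        retained, _ = depth_iqr_filter(candidates)
        with pytest.raises(ValueError, match="parent"):
            NucleotypeModel(retained, parent="nope").fit()
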