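"""GPA, ordination, and permutation machinery against analytic oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import special_ortho_group

import limbmorph.morphometrics as mm
from limbmorph.phylo import Phylogeny


def random_sample(rng, n=8, k=12, noise=0.01):
    base = rng.normal(size=(k, 3))
    configs = []
    for _ in range(n):
        R = special_ortho_group.rvs(3, random_state=rng)
        c = (base + rng.normal(size=(k, 3)) * noise) @ R.T
        configs.append(c * rng.uniform(0.5, 2.0) + rng.normal(size=3))
    return mm.LandmarkSample(np.array(configs),
                             [f"s{i}" for i in range(n)])


class TestReflection:
    def test_all_left_identity(self, rng):
        s = random_sample(rng)
        sides = {i: "left" for i in s.specimen_ids}
        out = mm.reflect_landmarks(s, sides)
        assert np.array_equal(out.coords, s.coords)

    def test_mirror_twice_is_identity(self, rng):
        s = random_sample(rng)
        sides = {i: "right" for i in s.specimen_ids}
        out = mm.reflect_landmarks(mm.reflect_landmarks(s, sides), sides)
        assert np.allclose(out.coords, s.coords, atol=1e-12)

    def test_mirroring_preserves_size_and_distances(self, rng):
        s = random_sample(rng, n=2)
        sides = {"s0": "left", "s1": "right"}
        out = mm.reflect_landmarks(s, sides)
        for i in range(2):
            assert mm.centroid_size(out.coords[i]) == pytest.approx(
                mm.centroid_size(s.coords[i]))
        d_in = np.linalg.norm(
            s.coords[1][:, None] - s.coords[1][None], axis=2)
        d_out = np.linalg.norm(
            out.coords[1][:, None] - out.coords[1][None], axis=2)
        assert np.allclose(d_in, d_out, atol=1e-12)

    def test_unknown_side_rejected(self, rng):
        s = random_sample(rng, n=2)
        with pytest.raises(ValueError, match="side"):
            mm.reflect_landmarks(s, {"s0": "left", "s1": "dorsal"})


class TestGPA:
    def test_identical_configs_have_zero_procrustes_distance(self, rng):
        base = rng.normal(size=(10, 3))
        R = special_ortho_group.rvs(3, random_state=rng)
        other = base @ R.T * 3.3 + np.array([1.0, -2.0, 0.5])
        s = mm.LandmarkSample(np.array([base, other]), ["a", "b"])
        al = mm.gpa(s)
        assert mm.procrustes_distance(al.coords[0], al.coords[1]) < 1e-8

    def test_unit_square_centroid_size(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert mm.centroid_size(sq) == pytest.approx(np.sqrt(2))

    def test_consensus_is_mean_of_aligned(self, rng):
        al = mm.gpa(random_sample(rng))
        assert np.abs(al.coords.mean(axis=0) - al.consensus).max() < 1e-10

    def test_invariance_to_input_transforms(self, rng):
        """GPA output is unchanged by per-specimen rigid+scale transforms."""
        s = random_sample(rng, n=20, noise=0.05)
        al_ref = mm.gpa(s)
        coords = s.coords.copy()
        for i in range(s.n):
            R = special_ortho_group.rvs(3, random_state=rng)
            coords[i] = coords[i] @ R.T * rng.uniform(0.2, 5.0) \
                + rng.normal(size=3) * 10
        al2 = mm.gpa(mm.LandmarkSample(coords, s.specimen_ids))
        # aligned shapes agree up to one global rotation of the whole set
        H = al2.coords.reshape(-1, 3).T @ al_ref.coords.reshape(-1, 3)
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))])
        R = U @ D @ Vt
        rot = al2.coords @ R
        assert np.abs(rot - al_ref.coords).max() < 1e-8

    def test_procrustes_distances_form_a_metric(self, rng):
        al = mm.gpa(random_sample(rng, n=6, noise=0.3))
        n = 6
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                D[i, j] = mm.procrustes_distance(al.coords[i], al.coords[j])
        assert np.allclose(D, D.T)
        for i, j, k in itertools.permutations(range(n), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_coincident_landmarks_rejected(self):
        bad = np.zeros((2, 5, 3))
        bad[1] = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="coincident"):
            mm.gpa(mm.LandmarkSample(bad, ["a", "b"]))


class TestShapePCA:
    def test_collinear_data_single_axis(self, rng):
        direction = rng.normal(size=9)
        t = rng.normal(size=15)
        Y = np.outer(t, direction)
        pca = mm.shape_pca(Y)
        assert pca.percent_variance[0] == pytest.approx(100.0)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        Y = rng.normal(size=(12, 9))
        pca = mm.shape_pca(Y)
        total = ((Y - Y.mean(0)) ** 2).sum() / 11
        assert pca.eigenvalues.sum() == pytest.approx(total, rel=1e-10)

    def test_scores_reproduce_centered_data(self, rng):
        Y = rng.normal(size=(10, 6))
        pca = mm.shape_pca(Y)
        back = pca.scores @ pca.components + pca.mean
        assert np.allclose(back, Y, atol=1e-10)

    def test_star_tree_root_reconstruction_is_tip_mean(self, rng):
        star = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:1.0" for i in range(8)) + ");")
        Y = rng.normal(size=(8, 5))
        pca = mm.shape_pca(Y, tree=star,
                           specimen_ids=[f"t{i}" for i in range(8)])
        # root (first internal node) projects to the origin = mean shape
        assert np.abs(pca.node_scores[0]).max() < 1e-8


class TestProcrustesLM:
    def test_univariate_equals_classical_anova(self, rng):
        g = np.repeat(["a", "b", "c"], 10)
        y = rng.normal(size=30) + (g == "b") * 1.0
        fit = mm.procrustes_lm(y, pd.DataFrame({"g": g}), "~ g",
                               n_perm=999, seed=1)
        f_classic = stats.f_oneway(y[g == "a"], y[g == "b"],
                                   y[g == "c"]).statistic
        assert fit.table["f"][0] == pytest.approx(f_classic, rel=1e-10)
        p_param = stats.f.sf(f_classic, 2, 27)
        assert fit.table["p"][0] == pytest.approx(p_param, abs=0.05)

    def test_ancova_sequential_terms(self, rng):
        n = 24
        x = rng.normal(size=n)
        g = np.repeat(["a", "b"], n // 2)
        Y = np.outer(x, rng.normal(size=4)) + rng.normal(size=(n, 4)) * 0.5
        fit = mm.procrustes_lm(Y, pd.DataFrame({"lnsize": x, "ecotype": g}),
                               "~ lnsize * ecotype", n_perm=199, seed=0)
        assert list(fit.table["term"]) == ["lnsize", "ecotype",
                                           "lnsize:ecotype"]
        assert fit.table["p"][0] <= 0.01  # strong size signal
        assert (fit.table["r2"] >= 0).all() and fit.table["r2"].sum() <= 1 + 1e-9

    def test_exhaustive_permutations_match_sampled(self, rng):
        """Brute-force enumeration oracle at n=6."""
        y = rng.normal(size=6)
        g = ["a", "a", "a", "b", "b", "b"]
        data = pd.DataFrame({"g": g})
        exact = mm.procrustes_lm(y, data, "~ g", all_perms=True, seed=0)
        sampled = mm.procrustes_lm(y, data, "~ g", n_perm=4999, seed=3)
        assert exact.n_perm == 720
        assert sampled.table["p"][0] == pytest.approx(exact.table["p"][0],
                                                      abs=0.05)

    def test_phylo_transform_runs_and_reduces_clade_signal(self, study_tree,
                                                          study_ecotypes,
                                                          rng):
        """A purely clade-structured response loses significance under BM."""
        n = study_tree.n_tips
        C = study_tree.brownian_covariance()
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
        Y = L @ rng.normal(size=(n, 3))  # Brownian data, no ecotype effect
        data = pd.DataFrame({"ecotype": study_ecotypes.loc[study_tree.tip_labels]},
                            index=study_tree.tip_labels)
        naive = mm.procrustes_lm(Y, data, "~ ecotype", n_perm=199, seed=0)
        bm = mm.procrustes_lm(Y, data, "~ ecotype", n_perm=199, seed=0,
                              phylo="bm", tree=study_tree)
        assert bm.table["p"][0] > naive.table["p"][0] - 1e-9

    def test_rank_deficient_design_rejected(self, rng):
        data = pd.DataFrame({"a": ["x", "x", "y", "y"],
                             "b": ["x", "x", "y", "y"]})
        with pytest.raises(ValueError, match="rank"):
            mm.procrustes_lm(rng.normal(size=4), data, "~ a + b",
                             n_perm=9, seed=0)


class TestPairwiseGroups:
    def test_saturated_shift_hits_minimum_p(self, rng):
        g = np.repeat(["a", "b"], 8)
        Y = rng.normal(size=(16, 3)) * 0.01
        Y[8:] += 10.0
        fit = mm.procrustes_lm(Y, pd.DataFrame({"g": g}), "~ g",
                               n_perm=99, seed=0)
        pw = mm.pairwise_groups(fit, "g", n_perm=99, seed=0)
        assert pw["p"].iloc[0] == pytest.approx(1 / 100)
        # shift of 10 in each of the 3 response columns
        assert pw["distance"].iloc[0] == pytest.approx(10 * np.sqrt(3),
                                                       rel=0.1)

    def test_identical_groups_distance_near_zero(self, rng):
        g = np.repeat(["a", "b"], 10)
        Y = np.tile(rng.normal(size=(10, 3)), (2, 1))
        fit = mm.procrustes_lm(Y + rng.normal(size=(20, 3)) * 1e-6,
                               pd.DataFrame({"g": g}), "~ g",
                               n_perm=99, seed=0)
        pw = mm.pairwise_groups(fit, "g", n_perm=99, seed=0)
        assert pw["distance"].iloc[0] < 1e-5

    def test_exhaustive_agreement_three_groups(self, rng):
        y = rng.normal(size=(6, 2))
        g = ["a", "a", "b", "b", "c", "c"]
        fit = mm.procrustes_lm(y, pd.DataFrame({"g": g}), "~ g",
                               n_perm=9, seed=0)
        exact = mm.pairwise_groups(fit, "g", all_perms=True, seed=0)
        sampled = mm.pairwise_groups(fit, "g", n_perm=2999, seed=5)
        for (_, re), (_, rs) in zip(exact.iterrows(), sampled.iterrows()):
            assert rs["p"] == pytest.approx(re["p"], abs=0.06)


class TestTwoBlockPLS:
    def test_identical_blocks_r_one(self, rng):
        X = rng.normal(size=(15, 4))
        res = mm.two_block_pls(X, X.copy(), n_perm=99, seed=0)
        assert res.r_pls == pytest.approx(1.0)

    def test_known_linear_map_high_r(self, rng):
        X = rng.normal(size=(30, 5))
        A = rng.normal(size=(5, 3))
        Y = X @ A + rng.normal(size=(30, 3)) * 0.05
        res = mm.two_block_pls(X, Y, n_perm=199, seed=0)
        assert res.r_pls > 0.95
        assert res.p <= 0.01

    def test_rotation_invariance_of_r(self, rng):
        X = rng.normal(size=(20, 4))
        Y = X @ rng.normal(size=(4, 4)) + rng.normal(size=(20, 4)) * 0.3
        r0 = mm.two_block_pls(X, Y, n_perm=9, seed=0).r_pls
        Qx = special_ortho_group.rvs(4, random_state=rng)
        Qy = special_ortho_group.rvs(4, random_state=rng)
        r1 = mm.two_block_pls(X @ Qx, Y @ Qy, n_perm=9, seed=0).r_pls
        assert r1 == pytest.approx(r0, rel=1e-8)

    def test_zero_variance_block_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            mm.two_block_pls(np.ones((10, 3)), rng.normal(size=(10, 2)),
                             n_perm=9, seed=0)


class TestCVA:
    def test_fully_separated_groups_perfect(self, rng):
        c1 = rng.normal(size=(10, 6)) * 0.1 + 5
        c2 = rng.normal(size=(10, 6)) * 0.1 - 5
        res = mm.cva_jackknife(np.vstack([c1, c2]), ["a"] * 10 + ["b"] * 10)
        assert res.overall_accuracy == 100.0
        assert (res.group_accuracy == 100.0).all()

    def test_two_groups_single_axis(self, rng):
        X = rng.normal(size=(16, 5))
        res = mm.cva_jackknife(X, ["a"] * 8 + ["b"] * 8)
        assert res.axes.shape[1] == 1

    def test_overall_is_specimen_weighted_mean(self, rng):
        X = rng.normal(size=(24, 6))
        X[:6] += 4
        g = ["a"] * 6 + ["b"] * 18
        res = mm.cva_jackknife(X, g)
        weighted = (res.group_accuracy["a"] * 6
                    + res.group_accuracy["b"] * 18) / 24
        assert res.overall_accuracy == pytest.approx(weighted)

    def test_monotone_with_separation(self, rng):
        accs = []
        base = rng.normal(size=(40, 6))
        g = np.repeat(["a", "b"], 20)
        for sep in (4.0, 1.0, 0.0):
            X = base.copy()
            X[20:] += sep
            accs.append(mm.cva_jackknife(X, g).overall_accuracy)
        assert accs[0] >= accs[1] >= accs[2] - 15  # noisy at zero separation

    def test_excess_dims_auto_reduced(self, rng):
        X = rng.normal(size=(12, 40))
        with pytest.warns(UserWarning, match="retained"):
            res = mm.cva_jackknife(X, ["a"] * 6 + ["b"] * 6,
                                   retained_dims=20)
        assert res.retained_dims <= 9


class TestPillaiMANOVA:
    def test_univariate_reduces_to_ss_ratio(self, rng):
        g = np.repeat(["a", "b", "c"], 8)
        y = rng.normal(size=24) + (g == "c") * 2
        tab = mm.pillai_manova(y, pd.DataFrame({"g": g}), "~ g",
                               n_perm=99, seed=0)
        gm = y.mean()
        ss_tot = ((y - gm) ** 2).sum()
        fitted = pd.Series(y).groupby(g).transform("mean").to_numpy()
        ss_eff = ((fitted - gm) ** 2).sum()
        ss_res = ((y - fitted) ** 2).sum()
        assert tab["pillai"][0] == pytest.approx(ss_eff / (ss_eff + ss_res),
                                                 rel=1e-10)

    def test_duplicated_column_matches_univariate_p(self, rng):
        g = np.repeat(["a", "b"], 10)
        y = rng.normal(size=20) + (g == "b") * 1.2
        # a tiny jitter keeps the error matrix nonsingular
        Y2 = np.column_stack([y, y + rng.normal(size=20) * 1e-4])
        p1 = mm.pillai_manova(y, pd.DataFrame({"g": g}), "~ g",
                              n_perm=999, seed=0)["p"][0]
        p2 = mm.pillai_manova(Y2, pd.DataFrame({"g": g}), "~ g",
                              n_perm=999, seed=0)["p"][0]
        assert p2 == pytest.approx(p1, abs=0.05)

    def test_p_at_least_n_rejected(self, rng):
        Y = rng.normal(size=(10, 12))
        g = ["a"] * 5 + ["b"] * 5
        with pytest.raises(ValueError, match="principal components"):
            mm.pillai_manova(Y, pd.DataFrame({"g": g}), "~ g", n_perm=9,
                             seed=0)


class TestLandmarkIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        s = random_sample(rng, n=3, k=5)
        p = tmp_path / "lm.csv"
        mm.write_landmarks(s, p)
        back = mm.read_landmarks(p)
        assert back.specimen_ids == s.specimen_ids
        assert np.allclose(back.coords, s.coords)
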