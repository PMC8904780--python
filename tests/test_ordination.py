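"""Tests of the ordination stack: normalization, Bray-Curtis (against a
naive double-loop oracle and scikit-bio), NMDS geometry, envfit and
sequential-SS PERMANOVA (against exhaustive enumeration, classical ANOVA
and scikit-bio)."""

import numpy as np
import pandas as pd
import pytest
from itertools import permutations

from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from rainwin.ordination import (
    bray_curtis,
    envfit,
    nmds,
    normalize_columns,
    permanova,
    procrustes_correlation,
)


class TestNormalize:
    def test_three_four_five(self):
        M = pd.DataFrame({"t": [3.0, 4.0]})
        out = normalize_columns(M)
        assert np.allclose(out["t"], [0.6, 0.8])

    def test_idempotent_on_unit_columns(self):
        M = pd.DataFrame({"t": [0.6, 0.8], "u": [1.0, 0.0]})
        out = normalize_columns(M)
        assert np.allclose(out.to_numpy(), M.to_numpy())

    def test_every_column_unit_sum_of_squares(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.gamma(1, 5, size=(12, 6)))
        out = normalize_columns(M)
        assert np.allclose((out**2).sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_names_taxon(self):
        M = pd.DataFrame({"good": [1.0, 2.0], "ghost": [0.0, 0.0]})
        with pytest.raises(ValueError, match="ghost"):
            normalize_columns(M)


class TestBrayCurtis:
    def test_identical_and_disjoint_rows(self):
        M = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [0.0, 3.0], [4.0, 0.0]])
        D = bray_curtis(M).to_numpy()
        assert D[0, 1] == 0.0
        assert D[2, 3] == 1.0

    def test_hand_example(self):
        # |6-2| + |2-2| = 4 over 6+2+2+2 = 12
        D = bray_curtis(pd.DataFrame([[6.0, 2.0], [2.0, 2.0]]))
        assert D.iloc[0, 1] == pytest.approx(4.0 / 12.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(42)
        X = rng.gamma(1.0, 2.0, size=(10, 5))
        D = bray_curtis(pd.DataFrame(X)).to_numpy()
        naive = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                naive[i, j] = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
        assert np.abs(D - naive).max() <= 1e-12

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        X = rng.gamma(1.0, 2.0, size=(8, 4))
        ours = bray_curtis(pd.DataFrame(X)).to_numpy()
        theirs = skbio.diversity.beta_diversity("braycurtis", X).data
        assert np.abs(ours - theirs).max() <= 1e-12

    def test_two_empty_sites_error(self):
        M = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(M)


class TestNMDS:
    def test_embeddable_configuration_zero_stress(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 2))
        D = pd.DataFrame(squareform(pdist(P)))
        res = nmds(D, n_restarts=10, seed=0)
        assert res.stress <= 1e-3
        assert res.converged

    def test_unit_square_recovered(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        D = pd.DataFrame(squareform(pdist(pts)))
        res = nmds(D, n_restarts=10, seed=0)
        assert res.stress <= 1e-3
        assert procrustes_correlation(res.scores.to_numpy(), pts) >= 0.999

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(12, 3))  # needs genuine 3-D structure
        D = squareform(pdist(P))
        s1 = nmds(pd.DataFrame(D), n_restarts=12, seed=0).stress
        s2 = nmds(pd.DataFrame(D**2), n_restarts=12, seed=0).stress
        assert abs(s1 - s2) <= 1e-3

    def test_final_stress_not_worse_than_pcoa_start(self, default_study):
        from rainwin.ordination import _pcoa_coords, _stress_and_disparities

        M = normalize_columns(default_study["matrix"])
        D = bray_curtis(M)
        Dm = D.to_numpy()
        dvec = squareform(Dm, checks=False)
        X0 = _pcoa_coords(Dm, 2)
        init_stress, _ = _stress_and_disparities(pdist(X0), np.argsort(dvec, kind="stable"))
        res = nmds(D, n_restarts=5, seed=0)
        assert res.stress <= init_stress + 1e-12

    def test_scores_centered(self, default_study):
        M = normalize_columns(default_study["matrix"])
        res = nmds(bray_curtis(M), n_restarts=5, seed=0)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            nmds(pd.DataFrame(np.zeros((3, 3))))


class TestEnvfit:
    @pytest.fixture()
    def scores(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        return pd.DataFrame(X - X.mean(axis=0), columns=["NMDS1", "NMDS2"])

    def test_perfect_alignment(self, scores):
        ev = envfit(scores, scores["NMDS1"], n_perm=99, seed=0)
        assert ev.r2 == pytest.approx(1.0)
        assert ev.p == pytest.approx(1.0 / 100.0)

    def test_diagonal_direction_closed_form(self, scores):
        # variable = axis1 + axis2 on orthogonalized scores
        Q, _ = np.linalg.qr(scores.to_numpy())
        v = Q[:, 0] + Q[:, 1]
        ev = envfit(pd.DataFrame(Q, columns=["a", "b"]), v, n_perm=49, seed=0)
        assert np.allclose(np.abs(ev.direction), np.sqrt(0.5), atol=1e-9)

    def test_r2_invariant_to_rotation(self, scores):
        rng = np.random.default_rng(6)
        v = rng.normal(size=len(scores)) + scores["NMDS1"].to_numpy()
        angle = 0.83
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        rotated = pd.DataFrame(scores.to_numpy() @ R, columns=scores.columns)
        r2a = envfit(scores, v, n_perm=9, seed=0).r2
        r2b = envfit(rotated, v, n_perm=9, seed=0).r2
        assert r2a == pytest.approx(r2b, abs=1e-12)

    def test_null_rejection_rate_calibrated(self):
        """Independent variables yield approximately uniform p-values:
        the alpha=0.05 rejection rate over 500 replicates lies in
        [0.03, 0.07]."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 500
        X = rng.normal(size=(50, 2))
        scores = pd.DataFrame(X - X.mean(axis=0))
        for rep in range(n_rep):
            v = rng.normal(size=50)
            p = envfit(scores, v, n_perm=199, seed=rep).p
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_constant_variable_rejected(self, scores):
        with pytest.raises(ValueError, match="constant"):
            envfit(scores, np.ones(len(scores)))


class TestPermanova:
    def test_identical_groups_zero_ss(self):
        # the two groups contain the same pair of sites, so the group
        # term explains nothing even though sites differ
        r1 = np.array([1.0, 2.0, 0.5])
        r2 = np.array([3.0, 0.5, 1.5])
        D = bray_curtis(pd.DataFrame(np.vstack([r1, r2, r1, r2])))
        data = pd.DataFrame({"g": ["a", "a", "b", "b"]})
        table = permanova(D, data, ["g"], n_perm=19, seed=0)
        assert table.loc["g", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        """n = 6 sites, one 2-level factor: the permutation p-value from
        999 draws agrees with full 720-permutation enumeration within two
        binomial standard errors."""
        rng = np.random.default_rng(2)
        X = rng.gamma(1.0, 2.0, size=(6, 4))
        X[:3] *= 2.0  # group signal
        D = bray_curtis(pd.DataFrame(X))
        data = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3})
        table = permanova(D, data, ["g"], n_perm=999, seed=4)
        F_obs = table.loc["g", "pseudo_F"]

        # exhaustive oracle: recompute F for every relabelling
        Dm = D.to_numpy()
        n = 6
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ (-0.5 * Dm**2) @ J

        def F_of(labels):
            Z = np.column_stack([np.ones(n), [1.0 if l == "a" else 0.0 for l in labels]])
            Q, _ = np.linalg.qr(Z)
            H = Q @ Q.T
            H0 = np.ones((n, n)) / n
            ss_g = np.sum((H - H0) * G)
            ss_r = np.sum((np.eye(n) - H) * G)
            return (ss_g / 1.0) / (ss_r / (n - 2))

        labels = ["a"] * 3 + ["b"] * 3
        exact = np.mean(
            [F_of([labels[i] for i in perm]) >= F_obs - 1e-12
             for perm in permutations(range(n))]
        )
        se = np.sqrt(exact * (1 - exact) / 999)
        assert abs(table.loc["g", "P"] - exact) <= 2 * se + 1e-3

    def test_univariate_euclidean_equals_classical_anova(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=15)
        groups = np.repeat(["a", "b", "c"], 5)
        D = pd.DataFrame(np.abs(y[:, None] - y[None, :]))
        table = permanova(D, pd.DataFrame({"g": groups}), ["g"], n_perm=9, seed=0)
        F_classic = f_oneway(*[y[groups == g] for g in "abc"]).statistic
        assert table.loc["g", "pseudo_F"] == pytest.approx(F_classic, abs=1e-9)

    def test_r2_decomposition_sums_to_one(self, default_study):
        records = default_study["records"]
        M = normalize_columns(default_study["matrix"])
        D = bray_curtis(M)
        env = records.set_index(
            records["plot"].astype(str) + ":" + records["year"].astype(str)
        ).loc[D.index]
        table = permanova(D, env, ["year", "seasonal_rainfall", "total_cover"],
                          n_perm=29, seed=0)
        assert table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_skbio_one_way_statistic(self):
        skbio = pytest.importorskip("skbio")
        import skbio.stats.distance as sd

        rng = np.random.default_rng(9)
        X = rng.gamma(1, 2, size=(12, 6))
        D = bray_curtis(pd.DataFrame(X))
        groups = list(np.repeat(["a", "b", "c"], 4))
        ours = permanova(D, pd.DataFrame({"g": groups}), ["g"], n_perm=9, seed=0)
        theirs = sd.permanova(skbio.DistanceMatrix(D.to_numpy()), grouping=groups,
                              permutations=9)
        assert ours.loc["g", "pseudo_F"] == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_aliased_term_rejected(self):
        rng = np.random.default_rng(10)
        X = rng.gamma(1, 2, size=(8, 3))
        D = bray_curtis(pd.DataFrame(X))
        data = pd.DataFrame({"x": np.arange(8.0), "x2": np.arange(8.0) * 2})
        with pytest.raises(ValueError, match="x2"):
            permanova(D, data, ["x", "x2"], n_perm=9, seed=0)
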