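"""Size factors, dispersion, NB Wald test, BH, PCA and clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy import stats

import uroev
from uroev.diffexpr import (adjust_bh, build_design, estimate_dispersion,
                            hierarchical_cluster, log_transform,
                            nb_wald_test, pca, size_factors)

from conftest import make_sheet


def design_for(n_case, n_control, seed=0):
    return build_design(make_sheet(n_case, n_control, seed=seed))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = np.tile([[10], [20], [30]], (1, 4))
        np.testing.assert_allclose(size_factors(c), np.ones(4))

    def test_doubling_one_sample_doubles_its_factor(self):
        rng = np.random.default_rng(0)
        c = rng.integers(1, 100, (50, 4))
        s = size_factors(c)
        c2 = c.copy()
        c2[:, 0] *= 2
        s2 = size_factors(c2)
        assert s2[0] / s[0] == pytest.approx(2 * (s2[1] / s[1]))

    def test_hand_computed_two_sample_case(self):
        c = np.array([[10, 20], [20, 40], [30, 60]])
        s = size_factors(c)
        np.testing.assert_allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_no_common_region_errors(self):
        c = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="filter"):
            size_factors(c)


class TestDispersion:
    N = 63

    def _design(self):
        return design_for(47, 16)

    def test_poisson_null_estimates_near_zero(self):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(3, 1.5, 1000))
        y = rng.poisson(mu[:, None] * np.ones(self.N)[None, :])
        a = estimate_dispersion(y.astype(float), np.ones(self.N),
                                self._design())
        assert np.median(a) <= 0.05

    def test_nb_dispersion_recovered_within_band(self):
        rng = np.random.default_rng(2)
        mu = np.exp(rng.normal(3, 1.5, 1000))[:, None] * np.ones(self.N)
        r = 1 / 0.4
        y = rng.negative_binomial(r, r / (r + mu))
        a = estimate_dispersion(y.astype(float), np.ones(self.N),
                                self._design())
        assert 0.2 <= np.median(a) <= 0.8

    def test_constant_counts_hit_floor(self):
        y = np.full((20, self.N), 7.0)
        a = estimate_dispersion(y, np.ones(self.N), self._design())
        assert (a <= 1e-4).all()

    def test_few_regions_refuse_trend(self, caplog):
        y = np.random.default_rng(3).poisson(20.0, (5, self.N)).astype(float)
        with caplog.at_level("WARNING"):
            estimate_dispersion(y, np.ones(self.N), self._design())
        assert any("trend" in r.message for r in caplog.records)


class TestNbWald:
    def test_poisson_limit_matches_poisson_glm(self):
        """alpha -> 0: coefficients agree with a Poisson GLM to 1e-4."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        design = design_for(30, 33)
        X = design.to_numpy()
        n = X.shape[0]
        s = np.exp(rng.normal(0, 0.3, n))
        mu = np.exp(rng.normal(3, 1, 20))[:, None] * s[None, :]
        y = rng.poisson(mu).astype(float)
        res = nb_wald_test(pd.DataFrame(y), s, np.full(20, 1e-8), design)
        for i in range(20):
            ref = sm.GLM(y[i], X, family=sm.families.Poisson(),
                         offset=np.log(s)).fit()
            assert res["log2fc"].iloc[i] == pytest.approx(
                ref.params[1] / np.log(2), abs=1e-4)

    def test_planted_effect_direction_and_recovery(self):
        """Lower expression in cases gives negative log2fc near truth."""
        rng = np.random.default_rng(5)
        design = design_for(47, 16)
        case = design["status"].to_numpy()
        n = len(case)
        R = 50
        lfc = -2.3
        q = 2.0 ** (6.0 + lfc * case)[None, :] * np.ones((R, 1))
        r = 1 / 0.4
        y = rng.negative_binomial(r, r / (r + q)).astype(float)
        res = nb_wald_test(pd.DataFrame(y), np.ones(n), np.full(R, 0.4),
                           design)
        est = res["log2fc"][res["converged"]]
        assert (est < 0).all()
        assert est.mean() == pytest.approx(lfc, abs=0.5)

    def test_sample_rescaling_absorbed_by_size_factor(self):
        """Scaling one sample's counts is absorbed by its size factor.

        The size factor tracks the scaling exactly, so fold-change
        estimates stay put; Wald z moves only through the sample's count
        -scale information content (weights are nonlinear in the mean), a
        small second-order effect for any count GLM.
        """
        rng = np.random.default_rng(6)
        design = design_for(10, 10)
        n = 20
        y = rng.poisson(50.0, (30, n)).astype(float)
        s1 = size_factors(y)
        res1 = nb_wald_test(pd.DataFrame(y), s1, np.full(30, 0.1), design,
                            tol=1e-14, max_iter=300)
        y2 = y.copy()
        y2[:, 3] *= 4
        s2 = size_factors(y2)
        res2 = nb_wald_test(pd.DataFrame(y2), s2, np.full(30, 0.1), design,
                            tol=1e-14, max_iter=300)
        # the size factor itself absorbs the scaling exactly
        assert s2[3] / s1[3] == pytest.approx(4 * s2[0] / s1[0], rel=1e-9)
        np.testing.assert_allclose(res1["log2fc"], res2["log2fc"], atol=0.05)
        np.testing.assert_allclose(res1["wald_z"], res2["wald_z"], atol=0.05)


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(adjust_bh([0.03]), [0.03])

    def test_step_up_by_hand(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.random(30)
            q = adjust_bh(p)
            perm = rng.permutation(30)
            np.testing.assert_allclose(adjust_bh(p[perm]), q[perm])
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
            assert (q >= p - 1e-12).all()

    def test_missing_p_excluded_from_m(self):
        q = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]],
                                   adjust_bh([0.01, 0.04])[[0, 1]])

    def test_matches_step_up_oracle(self):
        """Agrees with a literal step-up implementation on random input."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            order = np.argsort(p)
            expect = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                expect[i] = running
            np.testing.assert_allclose(adjust_bh(p), expect)


class TestTransforms:
    def test_log_transform_examples(self):
        out = log_transform(pd.DataFrame([[0.0, 1e6]]))
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(np.log2(1e6 + 1))

    def test_log_transform_rejects_negative(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame([[-1.0]]))

    def test_pca_identical_samples(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, 3.0]})
        scores, _, var_exp = pca(m)
        assert np.allclose(scores.to_numpy(), 0)

    def test_pca_planted_axis_dominates(self):
        rng = np.random.default_rng(9)
        axis = rng.normal(0, 1, 40)
        weights = rng.normal(0, 3, 12)
        data = np.outer(axis, weights) + rng.normal(0, 0.05, (40, 12))
        m = pd.DataFrame(data, columns=[f"s{j}" for j in range(12)])
        _, _, var_exp = pca(m)
        assert var_exp[0] > 0.9

    def test_pca_reconstruction_identity(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(0, 1, (6, 5)),
                         columns=[f"s{j}" for j in range(5)])
        scores, loadings, _ = pca(m)
        recon = scores.to_numpy() @ loadings.to_numpy().T \
            + m.T.to_numpy().mean(axis=0)[None, :]
        np.testing.assert_allclose(recon, m.T.to_numpy(), atol=1e-10)

    def test_pca_single_sample_errors(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestClustering:
    def test_three_points_on_line(self):
        m = pd.DataFrame([[0.0, 1.0, 10.0]], columns=["a", "b", "c"])
        Z, ids = hierarchical_cluster(m)
        assert sorted(Z[0, :2].astype(int)) == [0, 1]  # {0,1} merge first

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(0, 1, (5, 8)),
                         columns=[f"s{j}" for j in range(8)])
        Z, _ = hierarchical_cluster(m)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_matches_naive_complete_linkage(self):
        """Same merge heights as a brute-force agglomerative oracle."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            X = rng.normal(0, 1, (10, 5))
            m = pd.DataFrame(X.T, columns=[f"s{j}" for j in range(10)])
            Z, _ = hierarchical_cluster(m)
            # oracle: maintain clusters, merge the closest pair by
            # complete linkage, record heights
            clusters = [{i} for i in range(10)]
            d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
            heights = []
            while len(clusters) > 1:
                best, pair = np.inf, None
                for a in range(len(clusters)):
                    for b in range(a + 1, len(clusters)):
                        h = max(d[i, j] for i in clusters[a]
                                for j in clusters[b])
                        if h < best:
                            best, pair = h, (a, b)
                a, b = pair
                clusters[a] = clusters[a] | clusters[b]
                del clusters[b]
                heights.append(best)
            np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(heights),
                                       rtol=1e-10)


class TestFullStage:
    def test_planted_markers_found_with_annotation(self, discovery_sim):
        art = discovery_sim
        filt = uroev.filter_expressed(art["counts"])
        de = uroev.differential_expression(filt, art["sheet"],
                                           annotation=art["annotation"])
        sig = de.result[de.result["p_adjusted"] < 0.05]
        markers = set(art["truth"].marker_region_ids)
        assert len(set(sig.index) & markers) / len(markers) >= 0.8
        # significant marker regions are annotated as snoRNA
        for key in set(sig.index) & markers:
            assert any(b == "snoRNA" for _, b in sig.loc[key, "genes"])

    def test_gender_dominates_pca_not_status(self, discovery_sim):
        """Global structure reflects gender, not case/control status."""
        art = discovery_sim
        filt = uroev.filter_expressed(art["counts"])
        tpm = uroev.compute_tpm(filt)
        scores, _, _ = pca(log_transform(tpm), n_components=2)
        sheet = art["sheet"].rows.set_index("sample_id")
        male = (sheet["gender"] == "male").astype(float)[scores.index]
        case = (sheet["group"] == "case").astype(float)[scores.index]
        r_gender = stats.pearsonr(scores["PC1"], male)[0]
        r_case1 = stats.pearsonr(scores["PC1"], case)[0]
        r_case2 = stats.pearsonr(scores["PC2"], case)[0]
        assert abs(r_gender) > 0.8
        assert abs(r_case1) < 0.4 and abs(r_case2) < 0.4
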