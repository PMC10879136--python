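"""Uncentered PCA against a by-hand SVD, NMDS against an independent
optimizer oracle, and the ordination invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from sklearn.base import clone
from sklearn.isotonic import IsotonicRegression

from mmstrat.ordination import (NMDS, UncenteredPCA, centroid_axes,
                                configuration_stress, scree_knee)


class TestUncenteredPCA:
    def test_constant_column_single_component(self):
        X = np.ones((5, 1))
        pca = UncenteredPCA(n_components=1).fit(X)
        scores = pca.transform(X)
        assert np.allclose(scores, scores[0])
        assert pca.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_matches_direct_svd_of_raw_matrix(self):
        X = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [1, 1, 1.0]])
        pca = UncenteredPCA(n_components=3).fit(X)
        scores = pca.transform(X)
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        # compare projections up to component sign
        direct = X @ vt.T
        for k in range(3):
            assert (np.allclose(scores[:, k], direct[:, k])
                    or np.allclose(scores[:, k], -direct[:, k]))
        assert np.allclose(pca.explained_variance_ratio_,
                           s ** 2 / (s ** 2).sum())
        # no centering happened: projecting the raw rows reproduces scores
        assert np.allclose(X @ pca.components_.T, scores)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 4))
        a = UncenteredPCA(n_components=2).fit(X)
        b = UncenteredPCA(n_components=2).fit(X.copy())
        assert np.allclose(a.components_, b.components_)
        for row in a.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_k_beyond_rank_errors(self):
        X = np.ones((4, 3))  # rank 1
        with pytest.raises(ValueError, match="rank"):
            UncenteredPCA(n_components=2).fit(X)

    def test_scree_knee_at_two_dimensions(self):
        assert scree_knee(np.array([0.6, 0.2, 0.1, 0.05, 0.04])) == 2


def oracle_stress(D, X):
    """Independent stress-1 evaluation (sklearn isotonic, not the package's
    PAVA path)."""
    d = pdist(np.asarray(X, float))
    order = np.lexsort((d, D))
    iso = IsotonicRegression(increasing=True)
    disp = np.empty_like(d)
    disp[order] = iso.fit_transform(np.arange(len(d)), d[order])
    denom = (d ** 2).sum()
    if denom == 0:
        return 1.0
    disp *= np.sqrt(denom / max((disp ** 2).sum(), 1e-300))
    return np.sqrt(((d - disp) ** 2).sum() / denom)


class TestNMDS:
    def test_collinear_points_embed_perfectly_in_1d(self):
        X = np.array([[0.0], [1.0], [2.5], [4.0], [7.0]])
        nmds = NMDS(n_components=1, n_starts=4, random_state=0).fit(X)
        assert nmds.stress_ < 1e-6

    def test_six_point_optimizer_oracle(self):
        """Final stress is at least as good as an independent numerical
        optimizer (Nelder-Mead over configurations) up to 1e-3."""
        rng = np.random.default_rng(5)
        pts = rng.random((6, 3))
        D = pdist(pts, "cityblock")
        nmds = NMDS(n_components=2, n_starts=10, random_state=1,
                    metric="precomputed")
        from scipy.spatial.distance import squareform
        nmds.fit(squareform(D))
        best_oracle = np.inf
        for s in range(8):
            r = np.random.default_rng(s)
            x0 = r.normal(scale=D.mean(), size=12)
            res = minimize(lambda v: oracle_stress(D, v.reshape(6, 2)), x0,
                           method="Nelder-Mead",
                           options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8})
            best_oracle = min(best_oracle, res.fun)
        assert nmds.stress_ <= best_oracle + 1e-3

    def test_stress_monotonically_non_increasing(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(30, 12)).astype(float)
        nmds = NMDS(n_components=2, n_starts=3, random_state=2).fit(X)
        hist = np.array(nmds.stress_history_)
        assert (np.diff(hist) <= 1e-12).all()

    def test_stress_invariant_under_rotation_translation_scaling(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(20, 10)).astype(float)
        D = pdist(X, "cityblock")
        nmds = NMDS(n_components=2, n_starts=3, random_state=0).fit(X)
        conf = nmds.embedding_
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        for transformed in (conf @ rot, conf + 5.0, conf * 3.2):
            assert configuration_stress(D, transformed) == \
                pytest.approx(nmds.stress_, abs=1e-9)

    def test_more_starts_never_worse(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 2, size=(25, 8)).astype(float)
        few = NMDS(n_components=2, n_starts=1, random_state=7).fit(X).stress_
        many = NMDS(n_components=2, n_starts=6, random_state=7).fit(X).stress_
        assert many <= few + 1e-12

    def test_identical_rows_rejected_with_advice(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError, match="jitter"):
            NMDS(n_components=2).fit(X)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(20, 6)).astype(float)
        a = NMDS(n_components=2, n_starts=3, random_state=5).fit(X)
        b = NMDS(n_components=2, n_starts=3, random_state=5).fit(X)
        assert np.array_equal(a.embedding_, b.embedding_)
        assert a.stress_ == b.stress_

    def test_sklearn_estimator_api(self):
        est = NMDS(n_components=3, n_starts=2, random_state=1)
        params = est.get_params()
        assert params["n_components"] == 3
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_agrees_with_sklearn_nonmetric_mds(self):
        """Independent cross-check: sklearn's non-metric SMACOF reaches a
        comparable normalised stress on the same dissimilarities."""
        from sklearn.manifold import MDS
        rng = np.random.default_rng(21)
        X = rng.integers(0, 2, size=(25, 10)).astype(float)
        from scipy.spatial.distance import squareform
        D = squareform(pdist(X, "cityblock"))
        import warnings
        mine = NMDS(n_components=2, n_starts=8, random_state=0,
                    metric="precomputed").fit(D).stress_
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            sk = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                     n_init=8, normalized_stress=True, random_state=0,
                     max_iter=500, eps=1e-9).fit(D)
        # sklearn constrains tied dissimilarities to equal disparities
        # (secondary approach), so its stress upper-bounds ours on the
        # heavily tied binary distances; both must be in the same ballpark.
        assert mine <= sk.stress_ + 0.01
        assert abs(mine - sk.stress_) < 0.15


class TestCentroidAxes:
    def coords(self, points, ids):
        return pd.DataFrame(points, index=ids, columns=["x", "y"])

    def membership(self, idx, **groups):
        m = pd.DataFrame(False, index=idx,
                         columns=["HD", "t-IgH", "1q&13+", "1q&13-"])
        for g, members in groups.items():
            m.loc[members, g] = True
        return m

    def test_orthogonal_layout_gives_zero_cosine(self):
        ids = list("abcd")
        coords = self.coords([[-1, 0], [1, 0], [0, -1], [0, 1]], ids)
        m = self.membership(ids, HD=["a"], **{"t-IgH": ["b"],
                                              "1q&13+": ["c"], "1q&13-": ["d"]})
        axes = centroid_axes(coords, m)
        assert axes.abs_cosine == pytest.approx(0.0, abs=1e-12)

    def test_identical_axes_give_cosine_one(self):
        ids = list("ab")
        coords = self.coords([[0, 0], [2, 1]], ids)
        m = self.membership(ids, HD=["a"], **{"t-IgH": ["b"],
                                              "1q&13+": ["a"], "1q&13-": ["b"]})
        assert centroid_axes(coords, m).abs_cosine == pytest.approx(1.0)

    def test_missing_group_listed_in_error(self):
        ids = list("ab")
        coords = self.coords([[0, 0], [1, 1]], ids)
        m = self.membership(ids, HD=["a"], **{"t-IgH": ["b"], "1q&13+": ["a"]})
        with pytest.raises(ValueError, match=r"1q&13-"):
            centroid_axes(coords, m)

    def test_separated_groups_are_transversal(self):
        """Constructed configuration: HD/t-IgH split along x, 1q&13 classes
        along y -> axes clearly transversal (|cos| < 0.5)."""
        rng = np.random.default_rng(4)
        n = 40
        ids = [f"p{i}" for i in range(n)]
        hd = np.arange(n) < 20
        pos = np.arange(n) % 2 == 0
        coords = self.coords(
            np.column_stack([np.where(hd, -2, 2) + rng.normal(0, .3, n),
                             np.where(pos, -2, 2) + rng.normal(0, .3, n)]), ids)
        m = self.membership(ids)
        m["HD"] = hd
        m["t-IgH"] = ~hd
        m["1q&13+"] = pos
        m["1q&13-"] = ~pos
        assert centroid_axes(coords, m).abs_cosine < 0.5
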