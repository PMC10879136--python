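"""Ordination of the binary alteration matrix.

Two estimators in the scikit-learn idiom:

* :class:`UncenteredPCA` - principal components of the raw matrix without
  centering or scaling (projection onto the top right singular vectors of
  the data matrix itself), as appropriate when the 0/1 coding is meaningful
  relative to the origin.
* :class:`NMDS` - non-metric multidimensional scaling minimising Kruskal
  stress-1 by iterative majorization (Guttman transform) alternated with
  monotone regression of configuration distances on the rank order of the
  observed dissimilarities (Kruskal's primary approach to ties). Manhattan
  distance is the default: on binary rows it equals twice the number of
  discordant variables.

Plus :func:`centroid_axes`, the transversality diagnostic comparing the
1q&13 axis with the HD / t-IgH axis through group centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array


class UncenteredPCA(TransformerMixin, BaseEstimator):
    """PCA without centering nor scaling.

    Components are the right singular vectors of the raw data matrix;
    ``explained_variance_ratio_`` is the fraction of the total uncentered
    sum of squares carried by each component. The sign of each component is
    fixed so its largest-magnitude loading is positive.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if len(s) else 0
        if self.n_components > rank:
            raise ValueError(f"n_components={self.n_components} exceeds the "
                             f"matrix rank ({rank})")
        k = self.n_components
        flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
        flip[flip == 0] = 1.0
        vt = vt * flip[:, None]
        u = u * flip[None, :]
        self.components_ = vt[:k]
        self.singular_values_ = s[:k]
        total = float((s ** 2).sum())
        self.explained_variance_ratio_ = (s[:k] ** 2) / total
        self._full_ratio = (s ** 2) / total
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X, dtype=float)
        return X @ self.components_.T

    def full_variance_ratio(self) -> np.ndarray:
        """Uncentered variance fractions of every component (for scree plots)."""
        return self._full_ratio.copy()


def scree_knee(variance_ratio: np.ndarray) -> int:
    """Dimensionality at the scree-plot knee: the component index (1-based)
    with the largest second difference of the explained-variance curve."""
    vr = np.asarray(variance_ratio, dtype=float)
    if len(vr) < 3:
        return len(vr)
    second = vr[:-2] - 2 * vr[1:-1] + vr[2:]
    return int(np.argmax(second)) + 2


def configuration_stress(D, X) -> float:
    """Kruskal stress-1 of an arbitrary configuration ``X`` against observed
    dissimilarities ``D`` (condensed or square), with primary-tie monotone
    disparities."""
    D = np.asarray(D, dtype=float)
    if D.ndim == 2:
        D = squareform(D, checks=False)
    d = pdist(np.asarray(X, dtype=float))
    disp = _monotone_disparities(d, D)
    denom = float((d ** 2).sum())
    if denom > 0:
        disp = disp * np.sqrt(denom / max((disp ** 2).sum(), 1e-300))
    return kruskal_stress(d, disp)


def kruskal_stress(d: np.ndarray, disparities: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(sum (d - dhat)^2 / sum d^2)."""
    denom = float((d ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - disparities) ** 2).sum() / denom))


def _monotone_disparities(d: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Monotone (isotonic) regression of configuration distances on the rank
    order of the observed dissimilarities. Kruskal's primary approach to
    ties: within a block of tied dissimilarities the distances are taken in
    ascending order, so ties impose no order constraint among themselves."""
    order = np.lexsort((d, D))
    fitted = isotonic_regression(d[order], increasing=True).x
    disp = np.empty_like(fitted)
    disp[order] = fitted
    return disp


class NMDS(BaseEstimator):
    """Non-metric MDS minimising Kruskal stress-1.

    Parameters
    ----------
    n_components : embedding dimensionality.
    metric : any scipy pdist metric, or "precomputed" to pass a square
        dissimilarity matrix to :meth:`fit`.
    n_starts : random initialisations tried in addition to one
        classical-scaling (Torgerson) start; the best final stress wins.
    max_iter, tol : per-start iteration cap and relative stress-change
        convergence tolerance.
    random_state : seed for the random starts.

    Attributes (after fit): ``embedding_``, ``stress_``, ``n_iter_``,
    ``converged_``.
    """

    def __init__(self, n_components: int = 2, metric: str = "cityblock",
                 n_starts: int = 20, max_iter: int = 300, tol: float = 1e-7,
                 random_state: int | None = None):
        self.n_components = n_components
        self.metric = metric
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internals ----------------------------------------------------
    def _dissimilarities(self, X) -> np.ndarray:
        if self.metric == "precomputed":
            D = check_array(X, dtype=float)
            if D.shape[0] != D.shape[1]:
                raise ValueError("precomputed dissimilarities must be square")
            return squareform(D, checks=False)
        X = check_array(X, dtype=float)
        if self.metric == "manhattan":
            return pdist(X, "cityblock")
        return pdist(X, self.metric)

    @staticmethod
    def _classical_start(D: np.ndarray, k: int) -> np.ndarray:
        """Torgerson classical scaling of the (squared) dissimilarities."""
        sq = squareform(D) ** 2
        n = sq.shape[0]
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ sq @ J
        w, v = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:k]
        lam = np.clip(w[idx], 0.0, None)
        return v[:, idx] * np.sqrt(lam)[None, :]

    def _run(self, D: np.ndarray, X0: np.ndarray):
        n = X0.shape[0]
        X = X0.copy()
        d = pdist(X)
        disp = _monotone_disparities(d, D)
        denom = float((d ** 2).sum())
        if denom > 0:
            disp *= np.sqrt(denom / max((disp ** 2).sum(), 1e-300))
        stress = kruskal_stress(d, disp)
        history = [stress]
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            # Guttman transform toward the current disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, disp / d, 0.0)
            Rm = squareform(ratio)
            Bm = -Rm
            np.fill_diagonal(Bm, Rm.sum(axis=1))
            X_new = (Bm @ X) / n
            d_new = pdist(X_new)
            disp_new = _monotone_disparities(d_new, D)
            denom = float((d_new ** 2).sum())
            if denom > 0:
                disp_new *= np.sqrt(denom / max((disp_new ** 2).sum(), 1e-300))
            stress_new = kruskal_stress(d_new, disp_new)
            if stress_new > stress + 1e-12:
                converged = True  # majorization stalled; keep the better config
                break
            X, d, disp = X_new, d_new, disp_new
            history.append(stress_new)
            if stress - stress_new < self.tol * max(stress, 1e-12):
                stress = stress_new
                converged = True
                break
            stress = stress_new
        return X, stress, n_iter, converged, history

    # -- API ----------------------------------------------------------
    def fit(self, X, y=None):
        D = self._dissimilarities(X)
        if np.all(D == 0):
            raise ValueError("all pairwise dissimilarities are zero (identical "
                             "rows); jitter the input or drop duplicates")
        n = int((1 + np.sqrt(1 + 8 * len(D))) / 2)
        rng = np.random.default_rng(self.random_state)
        scale = float(np.mean(D))
        starts = [self._classical_start(D, self.n_components)]
        starts += [rng.normal(scale=scale, size=(n, self.n_components))
                   for _ in range(self.n_starts)]
        best = None
        for X0 in starts:
            conf, stress, n_iter, conv, hist = self._run(D, X0)
            if best is None or stress < best[1]:
                best = (conf, stress, n_iter, conv, hist)
        (self.embedding_, self.stress_, self.n_iter_, self.converged_,
         self.stress_history_) = best
        self.dissimilarities_ = D
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


@dataclass
class CentroidAxes:
    centroids: pd.DataFrame        # one row per group label
    hd_tihg_axis: np.ndarray       # HD -> t-IgH vector
    q13_axis: np.ndarray           # 1q&13+ -> 1q&13- vector
    abs_cosine: float              # |cos| between the two axes


def centroid_axes(coords: pd.DataFrame, membership: pd.DataFrame) -> CentroidAxes:
    """Group centroids and the angle between the HD/t-IgH axis and the
    1q&13 axis.

    ``membership`` is a boolean frame indexed like ``coords`` with columns
    "HD", "t-IgH", "1q&13+", "1q&13-" (groups may overlap).
    """
    required = ["HD", "t-IgH", "1q&13+", "1q&13-"]
    missing_cols = [g for g in required if g not in membership.columns]
    if missing_cols:
        raise ValueError(f"membership lacks group columns {missing_cols}")
    empty = [g for g in required if not bool(membership[g].any())]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    membership = membership.loc[coords.index]
    cents = pd.DataFrame(
        {g: coords[membership[g].astype(bool)].mean(axis=0) for g in required}).T
    axis1 = (cents.loc["t-IgH"] - cents.loc["HD"]).to_numpy()
    axis2 = (cents.loc["1q&13-"] - cents.loc["1q&13+"]).to_numpy()
    n1, n2 = np.linalg.norm(axis1), np.linalg.norm(axis2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate axis: coincident group centroids")
    cosine = abs(float(axis1 @ axis2) / (n1 * n2))
    return CentroidAxes(cents, axis1, axis2, min(cosine, 1.0))
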