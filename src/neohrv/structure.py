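"""Feature-structure analysis: standardized PCA and feature clustering.

PCA is run on the standardized feature matrix (observations are recordings,
or recording × length-class rows); variable coordinates are loadings scaled
by the square root of the eigenvalue (equivalently the correlation between
variable and component score), cos² the squared coordinates, and the
contribution of a variable to a component its cos² × 100 / the component's
total cos².  Gestational and post-menstrual age can be projected as
supplementary continuous variables (correlated with the scores, not used in
the fit).  Features are then clustered as points in the space of their
leading PCA coordinates by k-means (with a Ward hierarchical view), the
number of clusters chosen by maximal average silhouette width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import InsufficientDataError, ValidationError

__all__ = ["PCAResult", "ClusterResult", "pca_features", "cluster_features"]


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray
    var_explained_pct: np.ndarray
    variable_coords: pd.DataFrame  # feature x component
    cos2: pd.DataFrame
    contrib_pct: pd.DataFrame
    supplementary_coords: pd.DataFrame | None
    n_obs: int


@dataclass(frozen=True)
class ClusterResult:
    assignments: pd.Series  # feature -> cluster id
    k: int
    mean_silhouette: float
    per_k_silhouette: dict[int, float]
    linkage: np.ndarray  # scipy linkage matrix (Ward)

    def to_newick(self) -> str:
        """Nested-parenthesis text rendering of the Ward merge tree."""
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.assignments.index)

        def _fmt(node) -> str:
            if node.is_leaf():
                return names[node.id]
            return f"({_fmt(node.left)},{_fmt(node.right)}):{node.dist:.4g}"

        return _fmt(tree) + ";"


def _clean_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    m = matrix.copy()
    n0 = len(m)
    m = m.dropna(axis=0)
    if len(m) < n0:
        warnings.warn(f"dropped {n0 - len(m)} observation rows with missing values",
                      stacklevel=3)
    const = [c for c in m.columns if np.std(m[c].to_numpy(dtype=float)) == 0]
    if const:
        warnings.warn(f"dropped constant feature columns: {const}", stacklevel=3)
        m = m.drop(columns=const)
    return m


def pca_features(
    matrix: pd.DataFrame,
    supplementary: pd.DataFrame | None = None,
) -> PCAResult:
    """Standardized PCA of an observations × features matrix.

    ``supplementary`` (same rows; e.g. GA and PMA) is projected after the
    fit: its coordinate on a component is its Pearson correlation with the
    component scores.
    """
    m = _clean_matrix(matrix)
    if len(m) < 3 or m.shape[1] < 2:
        raise InsufficientDataError("PCA requires >= 3 observations and >= 2 features")
    X = m.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    R = (Z.T @ Z) / len(Z)
    eig, vec = np.linalg.eigh(R)
    order = np.argsort(eig)[::-1]
    eig, vec = np.clip(eig[order], 0.0, None), vec[:, order]
    comps = [f"PC{k + 1}" for k in range(eig.size)]
    coords = vec * np.sqrt(eig)
    cos2 = coords**2
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = 100.0 * cos2 / cos2.sum(axis=0)
    features = list(m.columns)
    supp = None
    if supplementary is not None:
        s = supplementary.loc[m.index]
        scores = Z @ vec
        supp_rows = {}
        for name in s.columns:
            v = s[name].to_numpy(dtype=float)
            sd = v.std()
            if sd == 0:
                warnings.warn(f"supplementary variable {name!r} is constant; skipped",
                              stacklevel=2)
                continue
            vc = (v - v.mean()) / sd
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (vc @ scores) / (len(Z) * np.sqrt(eig))
            supp_rows[name] = np.where(eig > 0, corr, 0.0)
        supp = pd.DataFrame(supp_rows, index=comps).T
    return PCAResult(
        eigenvalues=eig,
        var_explained_pct=100.0 * eig / eig.sum(),
        variable_coords=pd.DataFrame(coords, index=features, columns=comps),
        cos2=pd.DataFrame(cos2, index=features, columns=comps),
        contrib_pct=pd.DataFrame(contrib, index=features, columns=comps),
        supplementary_coords=supp,
        n_obs=len(m),
    )


def cluster_features(
    matrix: pd.DataFrame,
    k_range: Sequence[int] = tuple(range(2, 11)),
    n_components: int | None = None,
    min_var_pct: float = 80.0,
    seed: int = 0,
) -> ClusterResult:
    """Cluster features as points in their leading PCA coordinates.

    ``n_components`` defaults to the smallest number of components whose
    cumulative explained variance reaches ``min_var_pct``.  k-means (20
    restarts, fixed seed) is run for every k in ``k_range``; the assignment
    at the silhouette-optimal k is returned together with the Ward linkage
    of the same points.  Ties in silhouette go to the smaller k.
    """
    pca = pca_features(matrix)
    if n_components is None:
        cum = np.cumsum(pca.var_explained_pct)
        n_components = int(np.searchsorted(cum, min_var_pct) + 1)
    n_components = min(n_components, pca.variable_coords.shape[1])
    pts = pca.variable_coords.iloc[:, :n_components].to_numpy()
    p = pts.shape[0]
    if np.allclose(pts, pts[0]):
        raise ValidationError("degenerate embedding: all feature points identical")
    ks = sorted({int(k) for k in k_range})
    if not ks or ks[0] < 2 or ks[-1] > p - 1:
        raise ValidationError(f"k_range must lie within [2, {p - 1}]")
    per_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(pts)
        labels_by_k[k] = km.labels_
        per_k[k] = (
            float(silhouette_score(pts, km.labels_))
            if len(set(km.labels_)) > 1
            else float("nan")
        )
    best_k = max(ks, key=lambda k: (per_k[k], -k))
    link = hierarchy.linkage(pts, method="ward")
    return ClusterResult(
        assignments=pd.Series(
            labels_by_k[best_k], index=pca.variable_coords.index, name="cluster"
        ),
        k=best_k,
        mean_silhouette=per_k[best_k],
        per_k_silhouette=per_k,
        linkage=link,
    )
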