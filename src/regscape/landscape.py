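"""Dihedral featurization, tICA, free-energy surfaces, and cluster-model
selection for conformational landscapes.

tICA (time-lagged independent component analysis) finds the linear
combinations of input features whose autocorrelation at a chosen lag tau
is maximal: the slowest collective coordinates. With mean-free features
X, the instantaneous covariance C(0) and the symmetrised time-lagged
covariance C(tau) define the generalized eigenproblem

    C(tau) v = lambda C(0) v,

whose eigenvalues are lag-tau autocorrelations of the projections and
whose implied timescales are t_i = -tau / ln lambda_i. The symmetrised
(reversible) estimator keeps eigenvalues real; a small ridge on C(0)
regularises near-singular feature sets. Projecting onto the top two
components and applying a Gaussian KDE gives a 2-D free-energy surface
F = -kT ln(rho / rho_max). Conformational states are extracted by Ward
agglomerative clustering over a range of cluster counts k, scored by
silhouette (higher better) and Davies-Bouldin (lower better); k is
selected by the silhouette, sparsely populated clusters are dropped from
reporting, and each retained state is represented by its medoid frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "TicaModel",
    "FreeEnergySurface",
    "ClusterModel",
    "featurize",
    "fit_tica",
    "free_energy_surface",
    "silhouette_score",
    "davies_bouldin_index",
    "cluster_scan",
    "representatives",
    "state_path",
]


def featurize(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Periodic embedding of backbone dihedrals.

    (cos, sin) of every defined angle, so features are continuous across
    the -180/180 seam; columns with undefined (NaN) terminal angles are
    dropped. Input shapes (frames, residues); output (frames, n_features)
    bounded in [-1, 1].
    """
    phi = np.radians(np.asarray(phi, float))
    psi = np.radians(np.asarray(psi, float))
    cols = []
    for ang in (phi, psi):
        defined = ~np.isnan(ang).any(axis=0)
        a = ang[:, defined]
        cols.extend([np.cos(a), np.sin(a)])
    return np.hstack(cols)


@dataclass
class TicaModel:
    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ct: np.ndarray
    eigenvalues: np.ndarray  # sorted descending
    components: np.ndarray  # (n_features, n_components), C0-orthonormal
    projection: np.ndarray  # (n_frames, n_components)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components

    def timescales(self) -> np.ndarray:
        """Implied timescales -tau / ln(lambda), frames; non-positive or
        >=1 eigenvalues give inf/nan-free positive values only."""
        lam = self.eigenvalues
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = -self.lag / np.log(np.clip(lam, 1e-12, 1 - 1e-12))
        return ts

    def as_dict(self) -> dict:
        return {
            "lag": self.lag,
            "eigenvalues": self.eigenvalues.tolist(),
            "timescales": self.timescales().tolist(),
        }


def fit_tica(
    features: np.ndarray,
    lag: int = 100,
    n_components: int = 2,
    regularization: float = 1e-8,
) -> TicaModel:
    """Fit tICA by symmetrised covariance estimation.

    Raises if the instantaneous covariance is singular and no ridge is
    applied, or if there are not enough frames for the lag.
    """
    X = np.asarray(features, float)
    n = X.shape[0]
    if n <= lag + 2:
        raise ValueError(f"need more than lag+2={lag + 2} frames, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    X0, Xt = Xc[:-lag], Xc[lag:]
    m = X0.shape[0]
    c0 = 0.5 * (X0.T @ X0 + Xt.T @ Xt) / (m - 1)
    ct = 0.5 * (X0.T @ Xt + Xt.T @ X0) / (m - 1)
    if regularization:
        c0 = c0 + regularization * np.eye(c0.shape[0])
    else:
        if np.linalg.matrix_rank(c0) < c0.shape[0]:
            raise np.linalg.LinAlgError(
                "singular instantaneous covariance: add regularization"
            )
    vals, vecs = sla.eigh(ct, c0)  # ascending; vecs are C0-orthonormal
    order = np.argsort(vals)[::-1][:n_components]
    eigenvalues = vals[order]
    components = vecs[:, order]
    return TicaModel(
        lag=lag,
        mean=mean,
        c0=c0,
        ct=ct,
        eigenvalues=eigenvalues,
        components=components,
        projection=Xc @ components,
    )


@dataclass
class FreeEnergySurface:
    """2-D free-energy grid in kT units, minimum shifted to zero."""

    x: np.ndarray  # grid centers, first component
    y: np.ndarray  # grid centers, second component
    F: np.ndarray  # (len(y), len(x)), kT
    kT: float = 1.0

    def minimum(self) -> float:
        return float(np.nanmin(self.F))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.F, index=self.y, columns=self.x).to_csv(path)


def free_energy_surface(
    projected: np.ndarray,
    grid_size: int = 100,
    kT: float = 1.0,
    bw_method="scott",
    pad: float = 0.05,
) -> FreeEnergySurface:
    """Free-energy surface from the first two projected coordinates via
    2-D Gaussian KDE: F = -kT ln(rho / rho_max), so min F = 0 exactly."""
    Y = np.asarray(projected, float)[:, :2]
    kde = stats.gaussian_kde(Y.T, bw_method=bw_method)
    lo = Y.min(axis=0)
    hi = Y.max(axis=0)
    span = hi - lo
    x = np.linspace(lo[0] - pad * span[0], hi[0] + pad * span[0], grid_size)
    y = np.linspace(lo[1] - pad * span[1], hi[1] + pad * span[1], grid_size)
    XX, YY = np.meshgrid(x, y)
    rho = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    with np.errstate(divide="ignore"):
        F = -kT * np.log(rho / rho.max())
    return FreeEnergySurface(x=x, y=y, F=F, kT=kT)


def silhouette_score(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b) with a the mean
    in-cluster distance and b the smallest mean distance to another
    cluster; singleton clusters contribute s = 0."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    D = squareform(pdist(X))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            continue
        a = D[i, own].sum() / (len(own) - 1)
        b = min(
            D[i, members[c]].mean() for c in uniq if c != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def davies_bouldin_index(X: np.ndarray, labels: np.ndarray) -> float:
    """DB = mean over clusters of max_j (S_i + S_j) / M_ij, with S the
    mean distance to the cluster centroid and M the centroid distance."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    cents = np.array([X[labels == c].mean(axis=0) for c in uniq])
    S = np.array(
        [np.linalg.norm(X[labels == c] - cents[k], axis=1).mean()
         for k, c in enumerate(uniq)]
    )
    M = cdist(cents, cents)
    k = len(uniq)
    ratios = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                ratios[i, j] = (S[i] + S[j]) / M[i, j]
    return float(ratios.max(axis=1).mean())


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray  # per-frame, 0-based
    silhouette: float
    davies_bouldin: float
    retained: list[int] = field(default_factory=list)
    medoids: dict[int, int] = field(default_factory=dict)

    def populations(self) -> dict[int, float]:
        n = len(self.labels)
        return {c: float(np.sum(self.labels == c)) / n for c in np.unique(self.labels)}


def cluster_scan(
    projected: np.ndarray,
    k_range=range(2, 11),
    linkage: str = "ward",
    min_population: int = 10,
) -> tuple[dict[int, ClusterModel], int]:
    """Agglomerative clustering over a k range with quality metrics.

    Returns (models by k, selected k). Selection maximises the silhouette
    score; Davies-Bouldin is reported alongside. Clusters with fewer than
    ``min_population`` frames are excluded from the retained list (they
    remain in the labelling).
    """
    Y = np.asarray(projected, float)
    n = len(Y)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k range empty after bounding by [2, n_frames-1]")
    Z = scipy_linkage(Y, method=linkage)
    models: dict[int, ClusterModel] = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        ss = silhouette_score(Y, labels)
        db = davies_bouldin_index(Y, labels)
        counts = np.bincount(labels)
        retained = [c for c in range(len(counts)) if counts[c] >= min_population]
        model = ClusterModel(
            k=k, labels=labels, silhouette=ss, davies_bouldin=db, retained=retained
        )
        model.medoids = representatives(model, Y)
        models[k] = model
    selected = max(ks, key=lambda k: models[k].silhouette)
    return models, selected


def representatives(model: ClusterModel, projected: np.ndarray) -> dict[int, int]:
    """Medoid frame index per retained cluster (minimum summed in-cluster
    distance in projected space; ties broken by lowest frame index)."""
    Y = np.asarray(projected, float)
    out = {}
    for c in model.retained:
        idx = np.flatnonzero(model.labels == c)
        D = cdist(Y[idx], Y[idx])
        out[c] = int(idx[np.argmin(D.sum(axis=1))])
    return out


def state_path(labels: np.ndarray, window: int = 1) -> dict[int, np.ndarray]:
    """Rolling occupancy of each cluster label over time.

    window=1 returns the raw indicator series; larger windows give the
    within-window fraction (valid mode, length n - window + 1).
    """
    labels = np.asarray(labels)
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.full(window, 1.0 / window)
    out = {}
    for c in np.unique(labels):
        ind = (labels == c).astype(float)
        out[int(c)] = np.convolve(ind, kernel, mode="valid")
    return out
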