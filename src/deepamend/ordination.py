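"""Non-metric multidimensional scaling with Kruskal stress-1.

The ordination embeds samples in a low-dimensional space so that Euclidean
distances between points reproduce, as well as possible, only the *rank
order* of the input dissimilarities.  Fit quality is Kruskal stress-1,

    stress = sqrt( Σ (d̂_ij − d_ij)² / Σ d_ij² ),

where d are configuration distances and d̂ are disparities obtained by
isotonic (monotone) regression of d on the rank order of the input
dissimilarities.  Stress below 0.2 is conventionally acceptable.

The optimisation is SMACOF-style majorization: each iteration alternates an
isotonic fit of the disparities with a Guttman transform of the
configuration, which never increases stress.  The best of several restarts
(one classical-scaling start plus random starts) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .otu import ValidationError


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    seed: int | None
    converged: bool
    sample_ids: list | None = None
    stress_history: list | None = None


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling start: eigendecomposition of −½ J D² J."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(vals)


def _smacof_single(
    d_flat: np.ndarray,
    order: np.ndarray,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool, list]:
    """One SMACOF run from configuration ``x0``; returns (X, stress, conv, hist)."""
    n = x0.shape[0]
    x = x0.copy()
    iso = IsotonicRegression(increasing=True)
    t = np.arange(d_flat.size, dtype=float)
    old_stress = np.inf
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        dist = pdist(x)
        # monotone regression of configuration distances on the input rank order
        disp_sorted = iso.fit_transform(t, dist[order])
        disparities = np.empty_like(dist)
        disparities[order] = disp_sorted
        # scale disparities to the size of the configuration distances
        ss_dist = (dist ** 2).sum()
        ss_disp = (disparities ** 2).sum()
        if ss_disp == 0:
            break
        disparities *= np.sqrt(ss_dist / ss_disp)
        stress = np.sqrt(((disparities - dist) ** 2).sum() / ss_dist)
        history.append(float(stress))
        if old_stress - stress < tol:
            converged = True
            old_stress = stress
            break
        old_stress = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disparities / dist, 0.0)
        b_flat = -squareform(ratio)
        np.fill_diagonal(b_flat, -b_flat.sum(axis=1))
        x = b_flat @ x / n
    stress = history[-1] if history else 0.0
    return x, float(stress), converged, history


class NMDS(BaseEstimator):
    """Non-metric MDS estimator over a precomputed dissimilarity matrix.

    Parameters
    ----------
    n_components : int, default 2
        Embedding dimension k.
    n_restarts : int, default 20
        Number of SMACOF runs; the first starts from classical (Torgerson)
        scaling of the input, the rest from random Gaussian configurations.
    max_iter, tol : SMACOF stopping rule per restart.
    seed : int or None
        Seeds the random starts; fixed seed gives a fixed result.

    Attributes
    ----------
    embedding_ : (n_samples, k) array of coordinates of the best restart.
    stress_ : Kruskal stress-1 of the best restart.
    converged_ : whether the best restart met the tolerance within max_iter.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 20,
        max_iter: int = 300,
        tol: float = 1e-6,
        seed: int | None = None,
    ) -> None:
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X, y=None) -> "NMDS":
        if isinstance(X, DistanceMatrix):
            d, ids = X.data, list(X.ids)
        else:
            d = np.asarray(X, dtype=float)
            ids = None
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        n = d.shape[0]
        k = self.n_components
        if k < 1:
            raise ValidationError("n_components must be ≥ 1")
        if n < k + 1:
            raise ValidationError(f"need at least {k + 1} samples for k={k}")

        d_flat = squareform(d, checks=False)
        order = np.argsort(d_flat, kind="stable")
        rng = np.random.default_rng(self.seed)

        best = None
        for r in range(self.n_restarts):
            if r == 0:
                x0 = _classical_scaling(d, k)
                if not np.isfinite(x0).all() or np.allclose(x0, 0):
                    x0 = rng.standard_normal((n, k))
            else:
                x0 = rng.standard_normal((n, k))
            x, stress, conv, hist = _smacof_single(
                d_flat, order, x0, self.max_iter, self.tol
            )
            if best is None or stress < best[1]:
                best = (x, stress, conv, hist)
        x, stress, conv, hist = best
        self.embedding_ = x
        self.stress_ = stress
        self.converged_ = conv
        self.stress_history_ = hist
        self.sample_ids_ = ids
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def nmds(
    D,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> OrdinationResult:
    """Functional wrapper around :class:`NMDS`."""
    est = NMDS(n_components=k, n_restarts=n_restarts, max_iter=max_iter,
               tol=tol, seed=seed).fit(D)
    return OrdinationResult(
        coordinates=est.embedding_,
        stress=est.stress_,
        n_restarts=n_restarts,
        seed=seed,
        converged=est.converged_,
        sample_ids=est.sample_ids_,
        stress_history=est.stress_history_,
    )
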