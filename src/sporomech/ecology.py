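"""Morphospace construction and the three-attribute fitness landscape.

The morphospace is a PCA of the seven per-specimen shape descriptors, with
k-means, PAM (partitioning around medoids) and UPGMA average-linkage
clustering used to delineate morphological groups, each scored by
silhouette widths.

The fitness landscape places every specimen in the unit cube of three
min–max-normalized dispersal attributes — spore yield (∝ cavity volume),
rupture pressure (∝ ejection force) and stress-assisted rupture (∝ release
success) — and scores fitness as the distance from the origin scaled so the
all-ones corner has fitness exactly 1:  f = sqrt((a1² + a2² + a3²)/3).
Niche regions: near the minimum corner (distance < 0.3 from (0,0,0)), near
the maximum corner (distance < 0.3 from (1,1,1)), the generalist centre
(distance < 0.2 from (0.5,0.5,0.5)), otherwise a specialist strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

NICHE_NEAR_MAX = "near-max"
NICHE_NEAR_MIN = "near-min"
NICHE_CENTER = "generalist-center"
NICHE_SPECIALIST = "specialist"


@dataclass
class Morphospace:
    attributes: pd.DataFrame
    scores: np.ndarray                      # PC scores (specimens × components)
    explained_variance_ratio: np.ndarray
    kmeans_labels: dict = field(default_factory=dict)    # k -> labels
    kmeans_silhouette: dict = field(default_factory=dict)  # k -> per-sample widths
    pam_labels: dict = field(default_factory=dict)
    pam_silhouette: dict = field(default_factory=dict)
    upgma_labels: np.ndarray | None = None
    linkage_matrix: np.ndarray | None = None
    cut_height: float = 3.0
    scaled_pca: bool = False


def build_morphospace(attributes: pd.DataFrame, ks=(4, 5),
                      cut_height: float = 3.0, scale_pca: bool = False,
                      random_state: int = 0) -> Morphospace:
    """PCA + clustering of a specimens × attributes table.

    The PCA is centered and, by default, unscaled (matching the reference
    statistical environment's defaults); set ``scale_pca=True`` to work on
    z-scored attributes instead.  Clustering (k-means with 100 seeded
    restarts, exact PAM, UPGMA cut at ``cut_height``) always uses z-scored
    attributes so that descriptors measured in μm³ and in degrees weigh
    comparably in the distances.
    """
    if len(attributes) < 3:
        raise ValueError("need at least 3 specimens")
    if attributes.isna().any().any():
        raise ValueError("missing attribute values")
    X = attributes.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        import warnings
        warnings.warn("constant attribute column (zero variance direction)")
    Xz = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    pca = PCA()
    scores = pca.fit_transform(Xz if scale_pca else X - X.mean(axis=0))

    ms = Morphospace(attributes=attributes, scores=scores,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     cut_height=cut_height, scaled_pca=scale_pca)
    for k in ks:
        if k >= len(attributes):
            continue
        km = KMeans(n_clusters=k, n_init=100, random_state=random_state)
        lab = km.fit_predict(Xz)
        ms.kmeans_labels[k] = lab
        ms.kmeans_silhouette[k] = silhouette_samples(Xz, lab)
        plab = pam(Xz, k)
        ms.pam_labels[k] = plab
        ms.pam_silhouette[k] = silhouette_samples(Xz, plab)
    Z = linkage(Xz, method="average", metric="euclidean")
    ms.linkage_matrix = Z
    ms.upgma_labels = fcluster(Z, t=cut_height, criterion="distance") - 1
    return ms


def pam(X: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Exact PAM (build + swap) k-medoids on Euclidean distances.

    Deterministic: the build phase adds, and the swap phase applies, the
    single best (cost-minimizing) change at each step, ties broken by the
    lowest index.  Suitable for the small cohorts used here.
    """
    n = len(X)
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n samples")
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    medoids: list[int] = []
    # build
    for _ in range(k):
        best, best_cost = None, np.inf
        for j in range(n):
            if j in medoids:
                continue
            cost = D[:, medoids + [j]].min(axis=1).sum()
            if cost < best_cost - 1e-15:
                best, best_cost = j, cost
        medoids.append(best)
    # swap
    for _ in range(max_iter):
        current = D[:, medoids].min(axis=1).sum()
        best_pair, best_cost = None, current
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                cost = D[:, trial].min(axis=1).sum()
                if cost < best_cost - 1e-12:
                    best_pair, best_cost = (mi, h), cost
        if best_pair is None:
            break
        medoids[best_pair[0]] = best_pair[1]
    return np.argmin(D[:, medoids], axis=1)


# ------------------------------------------------------------------- landscape
def normalize_attribute(values) -> np.ndarray:
    """Min–max map to [0, 1]; order-preserving affine transform."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant attribute")
    return (v - lo) / (hi - lo)


def spore_yield(cavity_volume):
    """Relative spore yield, proportional to sporangial cavity volume."""
    return np.asarray(cavity_volume, dtype=float)


def fitness_score(normalized) -> np.ndarray | float:
    """``sqrt((a1² + a2² + a3²)/3)``: 0 at the origin, 1 at the all-ones corner."""
    a = np.asarray(normalized, dtype=float)
    out = np.sqrt(np.sum(a * a, axis=-1) / a.shape[-1])
    return float(out) if out.ndim == 0 else out


def classify_niche(point) -> str:
    """Niche region of one point of the unit fitness cube.

    Precedence: near-max, then near-min, then generalist-center; everything
    else is a specialist strategy.  The three spheres are geometrically
    disjoint for the stated radii.
    """
    p = np.asarray(point, dtype=float)
    if np.linalg.norm(p - 1.0) < 0.3:
        return NICHE_NEAR_MAX
    if np.linalg.norm(p) < 0.3:
        return NICHE_NEAR_MIN
    if np.linalg.norm(p - 0.5) < 0.2:
        return NICHE_CENTER
    return NICHE_SPECIALIST


def fitness_landscape(table: pd.DataFrame,
                      yield_col: str = "cavity_volume",
                      pressure_col: str = "rupture_pressure",
                      assist_col: str = "stress_assisted_score") -> pd.DataFrame:
    """Normalize the three dispersal attributes and score every specimen.

    Returns a copy of ``table`` with columns ``f_yield``, ``f_pressure``,
    ``f_assist`` (each min–max normalized to [0, 1]), ``fitness`` and
    ``niche``.
    """
    out = table.copy()
    out["f_yield"] = normalize_attribute(spore_yield(table[yield_col]))
    out["f_pressure"] = normalize_attribute(table[pressure_col])
    out["f_assist"] = normalize_attribute(table[assist_col])
    pts = out[["f_yield", "f_pressure", "f_assist"]].to_numpy()
    out["fitness"] = fitness_score(pts)
    out["niche"] = [classify_niche(p) for p in pts]
    return out
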