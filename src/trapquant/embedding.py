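"""Unbiased heterogeneity exploration via 2-D embedding of radial profiles.

Per-object radial intensity profiles (DNA and protein channels concatenated)
are standardized per dimension and projected to 2-D. Pairwise controlled
manifold approximation (PaCMAP) is used when the ``pacmap`` package is
importable; otherwise the first two principal components are used and the
result is tagged ``method="pca"`` — the fallback is never silent. Clusters
are an external input (manual polygon selections, mirroring how apparent
clusters are picked out by eye), and their composition is quantified by
treatment condition and NET prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmbeddingSizeError, GeometryError


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n, 2)
    method: str  # "pacmap" or "pca"
    seed: int
    input_dim: int


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    out = x - mean
    nz = std > 0
    out[:, nz] /= std[nz]
    return out


def embed_profiles(profiles: np.ndarray, seed: int) -> EmbeddingResult:
    """Embed an (n_objects, n_dims) profile matrix into 2-D.

    Requires at least 10 objects. Deterministic for a fixed seed; under the
    PCA fallback the component signs are fixed by making the largest-loading
    coordinate positive, so runs agree across platforms.
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    n, dim = profiles.shape
    if n < 10:
        raise EmbeddingSizeError(f"need at least 10 objects to embed, got {n}")
    x = _standardize(profiles)
    try:
        import pacmap  # type: ignore[import-not-found]

        reducer = pacmap.PaCMAP(n_components=2, random_state=seed)
        coords = np.asarray(reducer.fit_transform(x), dtype=np.float64)
        method = "pacmap"
    except ImportError:
        warnings.warn(
            "pacmap is not installed; falling back to the first two principal components",
            stacklevel=2,
        )
        from sklearn.decomposition import PCA

        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(x)
        # deterministic sign convention: largest-|loading| entry positive
        for k in range(coords.shape[1]):
            comp = pca.components_[k]
            if comp[np.argmax(np.abs(comp))] < 0:
                coords[:, k] = -coords[:, k]
        method = "pca"
    if not np.all(np.isfinite(coords)):
        raise ValueError("embedding produced non-finite coordinates")
    return EmbeddingResult(coordinates=coords, method=method, seed=seed, input_dim=dim)


def cluster_composition(
    conditions: Sequence[str],
    is_net: Sequence[bool],
    cluster_labels: Sequence[int],
) -> pd.DataFrame:
    """Per-cluster counts and fractions by condition and NET prediction.

    Cluster id -1 means unassigned and is excluded. Returns one row per
    cluster with ``n_objects``, ``fraction_net`` and one
    ``fraction_<condition>`` column per condition; condition fractions sum
    to 1 within each cluster.
    """
    df = pd.DataFrame(
        {
            "condition": list(conditions),
            "is_net": np.asarray(is_net, dtype=bool),
            "cluster": np.asarray(cluster_labels, dtype=int),
        }
    )
    df = df[df["cluster"] >= 0]
    all_conditions = sorted(set(conditions))
    rows = []
    for cid, grp in df.groupby("cluster", sort=True):
        row: dict[str, object] = {
            "cluster": int(cid),
            "n_objects": len(grp),
            "fraction_net": float(grp["is_net"].mean()),
        }
        for cond in all_conditions:
            row[f"fraction_{cond}"] = float((grp["condition"] == cond).mean())
        rows.append(row)
    cols = ["cluster", "n_objects", "fraction_net"] + [f"fraction_{c}" for c in all_conditions]
    return pd.DataFrame(rows, columns=cols)


def assign_clusters_by_polygon(
    coordinates: np.ndarray, polygons: Sequence[Sequence[tuple[float, float]]]
) -> np.ndarray:
    """Assign each (x, y) point to the first polygon that contains it.

    Polygons must be simple (non-self-intersecting); boundary points count as
    inside. Points in no polygon get label -1.
    """
    from shapely.geometry import Point, Polygon
    from shapely.prepared import prep

    coordinates = np.asarray(coordinates, dtype=np.float64)
    polys = []
    for i, ring in enumerate(polygons):
        poly = Polygon(ring)
        if not poly.is_valid or poly.is_empty:
            raise GeometryError(f"polygon {i} is not a simple polygon")
        polys.append((poly, prep(poly)))
    labels = np.full(len(coordinates), -1, dtype=int)
    for j, (x, y) in enumerate(coordinates):
        pt = Point(float(x), float(y))
        for i, (poly, prepared) in enumerate(polys):
            # covers(): interior or boundary
            if prepared.intersects(pt) and poly.covers(pt):
                labels[j] = i
                break
    return labels
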