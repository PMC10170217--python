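"""Surface-graph machinery for flattened cortical patches.

Covers the spatial side of the mapping analysis: connected clusters of
above-threshold vertices, a max-cluster-size permutation test that
prunes clusters small enough to arise by chance, and the flat-map
normalized-distance construction that places every vertex at a fraction
between an ROI's low/short edge (A) and its high/long edge (B):

    normalized distance = |A*V*| / |A*B*|

where A*, B* are the vertex's nearest points on the two edge polylines
and V* its orthogonal projection onto the secant segment A*B* (clamped
into the segment, so the fraction stays in [0, 1]).  Distances are then
grouped into twenty 0.05-wide bins for the group analyses.

All geometry is straight-segment Euclidean in the flat 2-D embedding;
the embedding itself (e.g. FreeSurfer's mris_flatten output) is an
input, never computed here.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc

logger = logging.getLogger(__name__)

N_BINS = 20
BIN_WIDTH = 0.05


@dataclass(frozen=True)
class SurfacePatch:
    """Triangulated patch with flat 2-D coordinates per vertex."""

    faces: np.ndarray  # (F, 3) int
    flat_coords: np.ndarray  # (V, 2) float

    def __post_init__(self) -> None:
        faces = np.asarray(self.faces, int)
        coords = np.asarray(self.flat_coords, float)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("flat_coords must be (V, 2)")
        if faces.size and faces.max() >= len(coords):
            raise ValueError("face references a vertex beyond the coordinate table")
        object.__setattr__(self, "faces", faces)
        object.__setattr__(self, "flat_coords", coords)

    @property
    def n_vertices(self) -> int:
        return len(self.flat_coords)

    def adjacency(self) -> sparse.csr_matrix:
        """Vertex adjacency: two vertices are neighbours iff they share
        a triangle edge."""
        return adjacency_from_faces(self.faces, self.n_vertices)


@dataclass(frozen=True)
class ROIDefinition:
    """ROI vertex set plus its delimiting edge polylines.

    ``edge_a`` marks the low/short end of the preferred-magnitude
    gradient, ``edge_b`` the high/long end; lateral edges are carried
    for bookkeeping only.
    """

    vertices: np.ndarray  # vertex ids
    edge_a: np.ndarray  # (Pa, 2) polyline points
    edge_b: np.ndarray  # (Pb, 2)
    lateral_edges: tuple = ()
    name: str = "roi"

    def __post_init__(self) -> None:
        a = np.asarray(self.edge_a, float)
        b = np.asarray(self.edge_b, float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("edge polylines need at least two points")
        if a.shape == b.shape and np.allclose(a, b):
            raise ValueError("edge_a and edge_b must be distinct")
        object.__setattr__(self, "vertices", np.asarray(self.vertices, int))
        object.__setattr__(self, "edge_a", a)
        object.__setattr__(self, "edge_b", b)


def adjacency_from_faces(faces: np.ndarray, n_vertices: int) -> sparse.csr_matrix:
    faces = np.asarray(faces, int)
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    data = np.ones(len(i), dtype=np.int8)
    adj = sparse.coo_matrix((data, (i, j)), shape=(n_vertices, n_vertices))
    adj = adj + adj.T
    adj.data[:] = 1
    return adj.tocsr()


def connected_clusters(mask: np.ndarray, faces: np.ndarray,
                       adjacency: sparse.csr_matrix | None = None) -> list[np.ndarray]:
    """Maximal connected components of the masked vertex subgraph.

    Returns a list of vertex-id arrays partitioning the masked set,
    largest cluster first.
    """
    mask = np.asarray(mask, bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    adj = adjacency if adjacency is not None else adjacency_from_faces(faces, len(mask))
    sub = adj[idx][:, idx]
    n_comp, labels = _cc(sub, directed=False)
    clusters = [idx[labels == c] for c in range(n_comp)]
    clusters.sort(key=len, reverse=True)
    return clusters


def _max_cluster_sizes(n_true: int, adj: sparse.csr_matrix, n_vertices: int,
                       n_perm: int, rng: np.random.Generator) -> np.ndarray:
    sizes = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        idx = rng.choice(n_vertices, size=n_true, replace=False)
        idx.sort()
        sub = adj[idx][:, idx]
        n_comp, labels = _cc(sub, directed=False)
        sizes[p] = np.bincount(labels).max() if n_comp else 0
    return sizes


def cluster_permutation_prune(mask: np.ndarray, faces: np.ndarray,
                              n_perm: int = 1000, alpha: float = 0.01,
                              seed: int = 0,
                              adjacency: sparse.csr_matrix | None = None
                              ) -> tuple[np.ndarray, int]:
    """Remove clusters whose size could arise by chance.

    The null relocates the observed number of above-threshold vertices
    uniformly at random over the patch ``n_perm`` times and records the
    maximum cluster size of each relocation.  An observed cluster of
    size s is kept iff its empirical null probability
    P(max cluster size >= s) is at most ``alpha`` — equivalently, iff s
    is strictly larger than the empirical (1 - alpha) null quantile.
    Returns the pruned mask and the minimum surviving size (0 if
    nothing survives).
    """
    mask = np.asarray(mask, bool)
    if mask.all():
        raise ValueError("mask covers the whole patch; the relocation null is degenerate")
    if n_perm < 100:
        warnings.warn("n_perm < 100: the null quantile is unstable", stacklevel=2)
    adj = adjacency if adjacency is not None else adjacency_from_faces(faces, len(mask))
    clusters = connected_clusters(mask, faces, adjacency=adj)
    if not clusters:
        return mask.copy(), 0
    rng = np.random.default_rng(seed)
    null = _max_cluster_sizes(int(mask.sum()), adj, len(mask), n_perm, rng)
    pruned = np.zeros_like(mask)
    surviving = []
    for cl in clusters:
        p_emp = float(np.mean(null >= len(cl)))
        if p_emp <= alpha:
            pruned[cl] = True
            surviving.append(len(cl))
    return pruned, (min(surviving) if surviving else 0)


# ---------------------------------------------------------------------------
# Flat-map distance geometry


def project_to_polyline(point: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Euclidean-nearest point on a polyline (ties go to the earlier
    segment)."""
    p = np.asarray(point, float)
    poly = np.asarray(polyline, float)
    if len(poly) < 2:
        raise ValueError("polyline needs at least two points")
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    if np.all(seg_len2 < 1e-24):
        raise ValueError("degenerate zero-length polyline")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / seg_len2, 0.0, 1.0)
    t = np.where(seg_len2 < 1e-24, 0.0, t)
    cand = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", cand - p, cand - p)
    return cand[int(np.argmin(d2))]  # argmin returns the first (earlier segment)


def normalized_distance(point: np.ndarray, roi: ROIDefinition) -> float:
    """Fractional position of a flat-map point between the ROI edges.

    A* and B* are the point's projections on edge A and edge B; the
    point is then projected orthogonally onto the secant segment A*B*
    (clamped into it) and the returned value is |A*V*|/|A*B*|.
    """
    v = np.asarray(point, float)
    a_star = project_to_polyline(v, roi.edge_a)
    b_star = project_to_polyline(v, roi.edge_b)
    ab = b_star - a_star
    ab2 = float(ab @ ab)
    if ab2 < 1e-24:
        raise ValueError("edge projections coincide; normalized distance undefined")
    t = float((v - a_star) @ ab) / ab2
    return float(np.clip(t, 0.0, 1.0))


def normalized_distances(points: np.ndarray, roi: ROIDefinition) -> np.ndarray:
    """Vectorised helper over an (N, 2) array of flat coordinates."""
    return np.array([normalized_distance(p, roi) for p in np.atleast_2d(points)])


def bin_distance(d) -> np.ndarray | int:
    """Distance-bin label: twenty half-open 0.05 bins, the last closed
    so d = 1 falls in bin 19."""
    arr = np.asarray(d, float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("normalized distance must lie in [0, 1]")
    label = np.minimum(np.floor(arr / BIN_WIDTH).astype(int), N_BINS - 1)
    return int(label) if np.ndim(d) == 0 else label


def bin_centre(label) -> np.ndarray | float:
    return (np.asarray(label) + 0.5) * BIN_WIDTH


def orient_progression(distances: np.ndarray, preferences: np.ndarray,
                       tol: float = 1e-12) -> tuple[np.ndarray, bool]:
    """Flip the distance axis when preference decreases with distance.

    Fits preference ~ distance by least squares; if the slope is below
    ``-tol`` the distances are mapped d -> 1 - d so every progression
    enters the group model increasing.  Returns (distances, reversed).
    """
    d = np.asarray(distances, float)
    y = np.asarray(preferences, float)
    if len(np.unique(d[~np.isnan(y)])) < 3:
        raise ValueError("need at least 3 distinct distances to orient a progression")
    ok = ~np.isnan(y)
    slope = np.polyfit(d[ok], y[ok], 1)[0]
    if slope < -tol:
        return 1.0 - d, True
    return d, False


# ---------------------------------------------------------------------------
# I/O — JSON mesh exchange and GIFTI via nibabel


def patch_to_json(patch: SurfacePatch, roi: ROIDefinition | None = None) -> str:
    obj = {
        "faces": patch.faces.tolist(),
        "flat_coords": patch.flat_coords.tolist(),
    }
    if roi is not None:
        obj["roi"] = {
            "name": roi.name,
            "vertices": roi.vertices.tolist(),
            "edge_a": roi.edge_a.tolist(),
            "edge_b": roi.edge_b.tolist(),
            "lateral_edges": [np.asarray(e).tolist() for e in roi.lateral_edges],
        }
    return json.dumps(obj)


def patch_from_json(text: str) -> tuple[SurfacePatch, ROIDefinition | None]:
    obj = json.loads(text)
    patch = SurfacePatch(np.asarray(obj["faces"], int), np.asarray(obj["flat_coords"], float))
    roi = None
    if "roi" in obj:
        r = obj["roi"]
        roi = ROIDefinition(
            vertices=np.asarray(r["vertices"], int),
            edge_a=np.asarray(r["edge_a"], float),
            edge_b=np.asarray(r["edge_b"], float),
            lateral_edges=tuple(np.asarray(e, float) for e in r.get("lateral_edges", [])),
            name=r.get("name", "roi"),
        )
    return patch, roi


def patch_to_gifti(patch: SurfacePatch, path) -> None:
    """Write the patch as a GIFTI surface (flat coordinates, z = 0)."""
    import nibabel as nib

    coords = np.column_stack([patch.flat_coords,
                              np.zeros(patch.n_vertices)]).astype(np.float32)
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(coords, intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(patch.faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def patch_from_gifti(path) -> SurfacePatch:
    import nibabel as nib

    img = nib.load(str(path))
    coords = faces = None
    for da in img.darrays:
        if da.intent == 1008:  # pointset
            coords = np.asarray(da.data, float)[:, :2]
        elif da.intent == 1009:  # triangle
            faces = np.asarray(da.data, int)
    if coords is None or faces is None:
        raise ValueError("GIFTI file lacks a pointset/triangle pair")
    return SurfacePatch(faces, coords)
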