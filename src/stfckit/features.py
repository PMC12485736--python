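"""Streamline containers, per-parcel diffusion features, and neighborhood graphs.

The unit of analysis throughout the package is the *fiber cluster* (parcel): a
set of streamlines with similar geometry, summarized per subject by the mean of
a per-point microstructure scalar (FA or MD).  Clusters are related to each
other through a k-nearest-neighbor graph built from a geometric distance
between their representative polylines; that graph is what lets suprathreshold
clusters merge into larger connected components downstream.

Coordinates are RAS millimeters throughout; no re-orientation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import sparse

__all__ = [
    "Streamline",
    "FiberCluster",
    "ClusterFeatureTable",
    "NeighborhoodGraph",
    "mean_scalar_per_cluster",
    "separate_hemispheres",
    "assign_laterality",
    "cluster_distance",
    "pairwise_polyline_distances",
    "build_neighborhood_graph",
    "resample_polyline",
]

#: |mean x| below this (mm) is treated as midline / commissural.
MIDLINE_EPS_MM = 0.1


@dataclass
class Streamline:
    """One tractography streamline: an ordered 3D polyline with optional
    per-point scalars (``"FA"`` unitless in [0,1], ``"MD"`` in mm^2/s)."""

    points: np.ndarray
    scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("streamline points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least 2 points")
        for name, arr in list(self.scalars.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(self.points),):
                raise ValueError(
                    f"scalar array {name!r} has {arr.shape} values for "
                    f"{len(self.points)} points"
                )
            self.scalars[name] = arr
        fa = self.scalars.get("FA")
        if fa is not None and ((fa < 0).any() or (fa > 1).any()):
            raise ValueError("FA values must lie in [0, 1]")
        md = self.scalars.get("MD")
        if md is not None and (md < 0).any():
            raise ValueError("MD values must be non-negative")


@dataclass
class FiberCluster:
    """A fiber parcel: streamlines assigned to one atlas cluster (possibly
    none for a given subject), with a representative centroid polyline."""

    cluster_id: int | str
    laterality: str = "commissural"  # left | right | commissural
    streamlines: list[Streamline] = field(default_factory=list)
    centroid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right", "commissural"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


@dataclass
class ClusterFeatureTable:
    """Subjects x clusters matrix of per-parcel means for one measure.

    ``values`` is a DataFrame indexed by subject id with one column per
    cluster; entries under the missing mask are NaN (subject had no
    streamlines in that parcel) and are excluded from per-cluster model fits
    rather than imputed.  ``subject_meta`` carries ``sex`` (female=1, male=0)
    and ``age`` (years); ``cluster_meta`` carries id/laterality/label.
    """

    values: pd.DataFrame
    subject_meta: pd.DataFrame
    cluster_meta: pd.DataFrame | None = None
    measure: str = "FA"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.subject_meta.index):
            raise ValueError("values and subject_meta must share the subject index")
        for col in ("sex", "age"):
            if col not in self.subject_meta.columns:
                raise ValueError(f"subject_meta missing column {col!r}")
        if self.cluster_meta is not None and len(self.cluster_meta) != self.values.shape[1]:
            raise ValueError("cluster_meta length must match number of clusters")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values.isna().to_numpy()


class NeighborhoodGraph:
    """Undirected graph over cluster ids with geometric distance weights.

    Edges are the symmetric closure of the directed k-nearest-neighbor
    relation under :func:`cluster_distance`; ``k`` records the construction
    parameter.  Backed by a :class:`networkx.Graph`.
    """

    def __init__(self, graph: nx.Graph, k: int, metric: str = "mean_closest_point"):
        self.graph = graph
        self.k = int(k)
        self.metric = metric

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple]:
        return list(self.graph.edges)

    def adjacency_csr(self, node_order: Sequence | None = None) -> sparse.csr_matrix:
        """Binary adjacency as CSR in the given node order (default: sorted)."""
        order = list(node_order) if node_order is not None else sorted(self.graph.nodes)
        return nx.to_scipy_sparse_array(self.graph, nodelist=order, weight=None, format="csr")

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(a, b, float(d.get("weight", np.nan))) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "distance_mm"])

    @classmethod
    def from_edge_frame(
        cls, frame: pd.DataFrame, nodes: Iterable, k: int, metric: str = "mean_closest_point"
    ) -> "NeighborhoodGraph":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, d in frame.itertuples(index=False):
            g.add_edge(a, b, weight=float(d))
        return cls(g, k=k, metric=metric)


# ---------------------------------------------------------------------------
# per-parcel features


def mean_scalar_per_cluster(cluster: FiberCluster, measure: str) -> float:
    """Mean of ``measure`` over all points of all streamlines in the parcel.

    Pooling all points (rather than averaging per-streamline means) weights
    long streamlines proportionally to their sampled length.  An empty
    cluster returns NaN — a missing-mask entry, not an error; a cluster whose
    streamlines lack the requested scalar raises ``ValueError``.
    """
    if measure not in ("FA", "MD"):
        raise ValueError(f"measure must be 'FA' or 'MD', got {measure!r}")
    if not cluster.streamlines:
        return float("nan")
    chunks = []
    for sl in cluster.streamlines:
        if measure not in sl.scalars:
            raise ValueError(
                f"cluster {cluster.cluster_id}: streamline lacks scalar {measure!r}"
            )
        chunks.append(sl.scalars[measure])
    return float(np.mean(np.concatenate(chunks)))


def separate_hemispheres(n_bilateral: int, n_commissural: int) -> pd.DataFrame:
    """Expand an atlas parcellation into per-subject cluster slots.

    Each bilateral atlas cluster contributes a left and a right per-subject
    cluster; commissural clusters cross the midline and are never split.
    Returns a DataFrame with one row per per-subject slot (columns
    ``atlas_id``, ``laterality``, ``cluster_id``); its length is
    ``2 * n_bilateral + n_commissural``.
    """
    n_bilateral, n_commissural = int(n_bilateral), int(n_commissural)
    if n_bilateral < 0 or n_commissural < 0:
        raise ValueError("cluster counts must be non-negative")
    rows = []
    for i in range(n_bilateral):
        rows.append((i, "left", f"c{i:04d}_left"))
        rows.append((i, "right", f"c{i:04d}_right"))
    for j in range(n_commissural):
        atlas = n_bilateral + j
        rows.append((atlas, "commissural", f"c{atlas:04d}_comm"))
    return pd.DataFrame(rows, columns=["atlas_id", "laterality", "cluster_id"])


def assign_laterality(points: np.ndarray, eps: float = MIDLINE_EPS_MM) -> str:
    """Hemisphere of a point set by the sign of its mean x (RAS: +x = right).

    |mean x| below ``eps`` millimeters is treated as midline and handled as
    commissural.
    """
    mx = float(np.mean(np.asarray(points, dtype=float)[:, 0]))
    if abs(mx) < eps:
        return "commissural"
    return "right" if mx > 0 else "left"


# ---------------------------------------------------------------------------
# geometric distances and the neighborhood graph


def _as_point_array(obj) -> np.ndarray:
    if isinstance(obj, Streamline):
        return obj.points
    if isinstance(obj, FiberCluster):
        if obj.centroid is not None:
            return np.asarray(obj.centroid, dtype=float)
        if obj.streamlines:
            return np.vstack([s.points for s in obj.streamlines])
        raise ValueError("empty cluster has no geometry")
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return arr


def cluster_distance(a, b) -> float:
    """Symmetrized mean-closest-point distance (mm) between two point sets.

    For each point of ``a`` take the distance to its nearest point of ``b``
    and average; likewise b->a; return the mean of the two directed values.
    This is the standard fiber distance of the fiber-clustering literature.
    It satisfies d(a,a)=0, symmetry and non-negativity but is not a metric
    (no triangle inequality).  Single-point inputs degrade gracefully to
    point distances.
    """
    pa, pb = _as_point_array(a), _as_point_array(b)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def pairwise_polyline_distances(polylines: Sequence[np.ndarray]) -> np.ndarray:
    """Full symmetric matrix of :func:`cluster_distance` over polylines.

    Vectorized when all polylines share a point count (the synthetic
    generator's case); falls back to pairwise KD-tree queries otherwise.
    """
    n = len(polylines)
    arrs = [np.asarray(p, dtype=float) for p in polylines]
    counts = {a.shape[0] for a in arrs}
    if len(counts) == 1 and n > 1:
        p = counts.pop()
        stack = np.stack(arrs)  # (n, p, 3)
        out = np.zeros((n, n))
        # chunk rows to bound the (chunk*p, n*p) distance block
        flat = stack.reshape(n * p, 3)
        chunk = max(1, int(2_000_000 / max(1, n * p)))
        for s in range(0, n, chunk):
            e = min(n, s + chunk)
            block = stack[s:e].reshape(-1, 3)
            d = np.linalg.norm(block[:, None, :] - flat[None, :, :], axis=2)
            d = d.reshape(e - s, p, n, p)
            out[s:e] = d.min(axis=3).mean(axis=1)  # directed a->b
        return (out + out.T) / 2.0
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = cluster_distance(arrs[i], arrs[j])
    return out


def build_neighborhood_graph(
    centroids: Sequence[np.ndarray],
    k: int = 10,
    node_ids: Sequence | None = None,
    distances: np.ndarray | None = None,
) -> NeighborhoodGraph:
    """k-nearest-neighbor graph over cluster centroid polylines.

    Each node is linked to its ``k`` nearest clusters by
    :func:`cluster_distance`; the edge set is the symmetric closure of the
    directed k-NN relation (so degrees may exceed ``k``).  ``k=0`` yields an
    edgeless graph; ``k >= n_clusters`` is an error.  A precomputed distance
    matrix may be supplied to skip the geometry pass.
    """
    n = len(centroids)
    if n < 1:
        raise ValueError("need at least one centroid")
    k = int(k)
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= n and n > 1 or (n == 1 and k > 0):
        raise ValueError(f"k={k} must be smaller than n_clusters={n}")
    ids = list(node_ids) if node_ids is not None else list(range(n))
    if len(ids) != n:
        raise ValueError("node_ids length must match centroids")
    g = nx.Graph()
    g.add_nodes_from(ids)
    if k > 0 and n > 1:
        dmat = distances if distances is not None else pairwise_polyline_distances(centroids)
        for i in range(n):
            row = dmat[i].copy()
            row[i] = np.inf
            nearest = np.argpartition(row, k - 1)[:k]
            for j in nearest:
                g.add_edge(ids[i], ids[int(j)], weight=float(dmat[i, int(j)]))
    return NeighborhoodGraph(g, k=k)


def resample_polyline(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced along arc length."""
    pts = np.asarray(points, dtype=float)
    if n_points < 2:
        raise ValueError("need at least 2 output points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n_points, axis=0)
    t = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(t, s, pts[:, i]) for i in range(3)])
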