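"""Synthetic cohorts with known group effects for pipeline validation.

The generator works at the per-cluster feature level: it does not simulate
diffusion-weighted images or streamline tracking, but produces exactly the
objects the statistical pipeline consumes — a subjects x clusters table of
per-parcel means with sex/age covariates, cluster centroid geometry for the
neighborhood graph, and behavior matrices with a known population canonical
correlation to the affected clusters.

Generative model for subject s, cluster c::

    y_sc = mu_c + delta_c * group_s + gamma * (age_s - mean age) + eps_sc

with group coded female=1 / male=0, eps_sc ~ Normal(0, sigma^2), delta_c equal
to ``effect_size`` on the planted cluster region and 0 elsewhere.  The planted
region is required to be connected in the k-NN neighborhood graph of the
generated geometry, so a recovered suprathreshold component can be compared
to the truth cluster-for-cluster.

Defaults mirror a large young-adult cohort: 340 females and 367 males (707
subjects), ages truncated-normal 28.1 +/- 3.4 y within [22, 37], and 1516
per-subject clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    ClusterFeatureTable,
    NeighborhoodGraph,
    assign_laterality,
    build_neighborhood_graph,
    pairwise_polyline_distances,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "cluster_label",
    "generate_cluster_geometry",
    "generate_cohort",
    "generate_behavior",
    "select_connected_region",
]


def cluster_label(index: int) -> str:
    """Canonical column/node id for synthetic cluster ``index``."""
    return f"c{int(index):04d}"


@dataclass
class SimulationConfig:
    """Parameters of the cohort generative model.

    ``effect_size`` is the additive female-minus-male difference delta (in the
    measure's units) planted on ``effect_clusters``; ``age_slope`` is gamma in
    units per year applied to centered age; ``noise_sd`` is the residual sigma.
    Cluster baselines mu_c are drawn Normal(``baseline_mean``,
    ``baseline_sd``).  ``cluster_noise_sd`` optionally gives per-cluster
    sigmas (heteroscedastic option); default is homoscedastic.
    """

    n_female: int = 340
    n_male: int = 367
    n_clusters: int = 1516
    age_mean: float = 28.1
    age_sd: float = 3.4
    age_range: tuple[float, float] = (22.0, 37.0)
    effect_clusters: frozenset[int] = field(default_factory=frozenset)
    effect_size: float = 0.0
    age_slope: float = 0.0
    noise_sd: float = 0.02
    baseline_mean: float = 0.5
    baseline_sd: float = 0.05
    cluster_noise_sd: tuple[float, ...] | None = None
    knn_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("need at least one subject per group")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        self.effect_clusters = frozenset(int(c) for c in self.effect_clusters)
        bad = [c for c in self.effect_clusters if not 0 <= c < self.n_clusters]
        if bad:
            raise ValueError(f"effect clusters out of range: {sorted(bad)}")
        if self.cluster_noise_sd is not None and len(self.cluster_noise_sd) != self.n_clusters:
            raise ValueError("cluster_noise_sd must have one entry per cluster")

    def to_json(self) -> str:
        d = asdict(self)
        d["effect_clusters"] = sorted(self.effect_clusters)
        return json.dumps(d, indent=2)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth.

    ``truth_delta`` holds the per-cluster true effect (``effect_size`` on the
    planted region, 0 elsewhere); ``geometry`` the centroid polylines the
    neighborhood graph was built from.
    """

    feature_table: ClusterFeatureTable
    geometry: list[np.ndarray]
    graph: NeighborhoodGraph
    truth_delta: np.ndarray
    truth_region: frozenset[int]
    config: SimulationConfig
    behavior: pd.DataFrame | None = None

    @property
    def truth_ids(self) -> frozenset[str]:
        """Planted region as feature-table column / graph node ids."""
        return frozenset(cluster_label(c) for c in self.truth_region)


def generate_cluster_geometry(
    n_clusters: int,
    seed: int,
    layout: str = "grid",
    spacing: float = 10.0,
    n_points: int = 5,
    jitter: float = 0.5,
) -> list[np.ndarray]:
    """Centroid polylines on a jittered spatial lattice.

    Each cluster gets a short smooth arc (``n_points`` points, ~4 mm extent)
    centered on a lattice site, so nearest neighbors in the lattice are the
    geometric nearest neighbors of the polylines.  ``layout="grid"`` fills a
    near-cubic lattice centered on the origin (so mean-x laterality is
    meaningful); ``layout="line"`` places sites along the x axis.
    """
    n_clusters = int(n_clusters)
    if n_clusters < 1:
        raise ValueError("n_clusters must be positive")
    rng = np.random.default_rng(seed)
    if layout == "line":
        sites = np.zeros((n_clusters, 3))
        sites[:, 0] = np.arange(n_clusters) * spacing
        sites[:, 0] -= sites[:, 0].mean()
    elif layout == "grid":
        side = int(np.ceil(n_clusters ** (1 / 3)))
        idx = np.arange(n_clusters)
        ijk = np.column_stack([idx % side, (idx // side) % side, idx // side**2])
        sites = (ijk - (side - 1) / 2.0) * spacing
    else:
        raise ValueError(f"unknown layout {layout!r}")
    sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)

    polylines = []
    half_len = 0.2 * spacing
    for center in sites:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = rng.normal(size=3)
        v -= v @ u * u
        v /= np.linalg.norm(v)
        t = np.linspace(-1.0, 1.0, n_points)
        # gentle quadratic arc in the (u, v) plane
        pts = center + np.outer(t * half_len, u) + np.outer(0.15 * half_len * t**2, v)
        polylines.append(pts)
    return polylines


def select_connected_region(graph: NeighborhoodGraph, n: int, start: int | None = None) -> frozenset[int]:
    """A connected set of ``n`` clusters grown breadth-first from ``start``."""
    nodes = sorted(graph.graph.nodes)
    if n > len(nodes):
        raise ValueError("region larger than the graph")
    root = nodes[0] if start is None else start
    order = [root]
    seen = {root}
    for _, nxt in nx.bfs_edges(graph.graph, root):
        if nxt not in seen:
            seen.add(nxt)
            order.append(nxt)
        if len(order) >= n:
            break
    if len(order) < n:
        raise ValueError("graph component too small for requested region")
    return frozenset(order[:n])


def _region_connected(region: frozenset[int], graph: NeighborhoodGraph) -> bool:
    if len(region) <= 1:
        return True
    sub = graph.graph.subgraph(region)
    return nx.is_connected(sub)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model (bit-identical per seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_female + config.n_male

    geometry = generate_cluster_geometry(config.n_clusters, seed=config.seed)
    cluster_ids = [cluster_label(j) for j in range(config.n_clusters)]
    k = min(config.knn_k, config.n_clusters - 1) if config.n_clusters > 1 else 0
    graph = build_neighborhood_graph(geometry, k=k, node_ids=cluster_ids)
    region_ids = frozenset(cluster_label(c) for c in config.effect_clusters)
    if region_ids and not _region_connected(region_ids, graph):
        raise ValueError(
            "effect_clusters do not form a connected region in the "
            "neighborhood graph of the generated geometry"
        )

    sex = np.concatenate([np.ones(config.n_female), np.zeros(config.n_male)])
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_clusters)
    delta = np.zeros(config.n_clusters)
    if config.effect_clusters:
        delta[sorted(config.effect_clusters)] = config.effect_size

    sigma = (
        np.asarray(config.cluster_noise_sd, dtype=float)
        if config.cluster_noise_sd is not None
        else np.full(config.n_clusters, config.noise_sd)
    )
    eps = rng.standard_normal((n, config.n_clusters)) * sigma
    age_c = ages - ages.mean()
    # age enters every cluster with the same slope gamma
    values = mu + np.outer(sex, delta) + config.age_slope * age_c[:, None] + eps

    subjects = [f"sub-{i:04d}" for i in range(n)]
    laterality = [assign_laterality(p) for p in geometry]
    table = ClusterFeatureTable(
        values=pd.DataFrame(values, index=subjects, columns=cluster_ids),
        subject_meta=pd.DataFrame({"sex": sex.astype(int), "age": ages}, index=subjects),
        cluster_meta=pd.DataFrame(
            {"cluster_id": cluster_ids, "laterality": laterality, "label": ""}
        ),
    )
    return SyntheticCohort(
        feature_table=table,
        geometry=geometry,
        graph=graph,
        truth_delta=delta,
        truth_region=config.effect_clusters,
        config=config,
    )


def generate_behavior(
    cohort: SyntheticCohort,
    rho: float,
    n_measures: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Behavior matrix with population canonical correlation ``rho`` to the
    planted clusters' features.

    Construction: the latent z is the standardized mean of the planted
    clusters' standardized feature columns (an exact linear combination of
    the imaging side), and each behavior column is ``c * z`` plus independent
    unit-variance noise with ``c = rho / sqrt(m (1 - rho^2))`` for ``m``
    measures.  The best behavior combination (equal weights) then correlates
    ``rho`` with z, and no imaging combination can do better because all
    cross-covariance flows through z — so the population canonical
    correlation is exactly ``rho``.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if n_measures < 1:
        raise ValueError("need at least one behavioral measure")
    region = sorted(cohort.truth_region)
    if not region:
        raise ValueError("cohort has no planted region to correlate behavior with")
    rng = np.random.default_rng(seed)
    X = cohort.feature_table.values.to_numpy()[:, region]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    z = Xs.mean(axis=1)
    z = (z - z.mean()) / z.std(ddof=1)
    c = rho / np.sqrt(n_measures * (1.0 - rho**2))
    noise = rng.standard_normal((len(z), n_measures))
    beh = c * z[:, None] + noise
    cols = [f"beh_{j:02d}" for j in range(n_measures)]
    frame = pd.DataFrame(beh, index=cohort.feature_table.values.index, columns=cols)
    cohort.behavior = frame
    return frame
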