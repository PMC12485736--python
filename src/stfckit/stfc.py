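"""Suprathreshold fiber cluster (STFC) inference.

The group-difference statistic works in four steps, per diffusion measure:

1. every fiber cluster is tested with a GLM of its per-subject mean on
   [intercept, sex, centered age] — a two-sided t-test on the sex
   coefficient, with age as a nuisance covariate;
2. clusters with uncorrected p < alpha_unc (strict) are suprathreshold;
3. suprathreshold clusters that are neighbors in the geometric graph merge
   into connected components — the STFCs — whose *size* (number of member
   clusters) is the test statistic; by default components are formed
   separately within each effect direction;
4. a permutation test shuffles sex labels across subjects (ages travel with
   their subjects), reruns steps 1-3, and records the maximum STFC size per
   permutation.  An observed STFC's family-wise corrected p-value is the
   fraction of permutations whose maximum size reaches its size.

The max-size null distribution gives strong family-wise error control in the
classic suprathreshold-cluster sense.  Monte Carlo p-values use the
(1+b)/(1+N) estimator so p is never zero; when the requested permutation
count reaches the number of distinct label assignments C(n, n_female), the
test switches to exhaustive enumeration and returns the exact permutation
p-value b/N over all assignments (the identity included).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .features import ClusterFeatureTable, NeighborhoodGraph

__all__ = [
    "GLMResult",
    "STFC",
    "STFCRunConfig",
    "STFCResult",
    "fit_glm",
    "fit_glm_table",
    "threshold_clusters",
    "form_stfcs",
    "permutation_correct",
    "run_stfc",
    "stfc_report",
]

EXHAUSTIVE_CAP = 500_000  # refuse to enumerate beyond this many assignments


@dataclass
class GLMResult:
    """Per-cluster GLM table: sex-coefficient estimate, t, two-sided p."""

    table: pd.DataFrame  # columns: cluster, beta_group, t_stat, p_unc, n_used, direction, flag

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class STFC:
    member_clusters: frozenset
    size: int
    direction: int
    p_corrected: float | None = None
    anatomical_label: str | None = None

    def __post_init__(self) -> None:
        self.member_clusters = frozenset(self.member_clusters)
        if self.size != len(self.member_clusters) or self.size < 1:
            raise ValueError("size must equal the number of member clusters (>= 1)")


@dataclass
class STFCRunConfig:
    alpha_unc: float = 0.05
    alpha_corrected: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    sign_handling: str = "split_by_sign"  # or "ignore_sign"
    exhaustive: bool | None = None  # None = auto when n_permutations covers all assignments

    def __post_init__(self) -> None:
        if not 0 < self.alpha_unc < 1:
            raise ValueError("alpha_unc must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.sign_handling not in ("split_by_sign", "ignore_sign"):
            raise ValueError(f"unknown sign_handling {self.sign_handling!r}")


@dataclass
class STFCResult:
    stfcs: list[STFC]
    glm: GLMResult
    null_max_sizes: np.ndarray
    config: STFCRunConfig
    exhaustive: bool
    n_permutations_used: int
    report: pd.DataFrame = field(default=None)  # Table-style rows, filled by run_stfc


# ---------------------------------------------------------------------------
# GLM


def _design(sex: np.ndarray, age: np.ndarray) -> np.ndarray:
    """[intercept, sex, centered age]; a constant age column is dropped so
    the model degrades gracefully to the two-sample t-test."""
    age_c = age - age.mean()
    if np.ptp(age_c) == 0:
        return np.column_stack([np.ones(len(sex)), sex])
    return np.column_stack([np.ones(len(sex)), sex, age_c])


def fit_glm(values: np.ndarray, sex: np.ndarray, age: np.ndarray) -> dict:
    """OLS of one cluster's values on [1, sex, centered age]; t-test on sex.

    Missing values are dropped listwise for this cluster.  Untestable
    configurations (one group entirely missing, fewer than 4 usable
    subjects) and degenerate fits (zero residual variance) return p_unc=1
    with a flag rather than raising.
    """
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex, dtype=float)
    age = np.asarray(age, dtype=float)
    keep = ~np.isnan(values)
    v, s, a = values[keep], sex[keep], age[keep]
    n_used = int(keep.sum())
    base = dict(beta_group=0.0, t_stat=0.0, p_unc=1.0, n_used=n_used, direction=0)
    if n_used < 4 or len(np.unique(s)) < 2:
        return {**base, "flag": "untestable"}
    X = _design(s, a)
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return {**base, "flag": "singular"}
    beta = xtx_inv @ (X.T @ v)
    resid = v - X @ beta
    dof = n_used - X.shape[1]
    rss = float(resid @ resid)
    if dof <= 0 or rss <= max(1e-28, 1e-24 * float(v @ v)):
        return {**base, "beta_group": float(beta[1]), "flag": "degenerate"}
    se = np.sqrt(rss / dof * xtx_inv[1, 1])
    t = float(beta[1] / se)
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return dict(
        beta_group=float(beta[1]),
        t_stat=t,
        p_unc=min(p, 1.0),
        n_used=n_used,
        direction=int(np.sign(beta[1])),
        flag="ok",
    )


def fit_glm_table(table: ClusterFeatureTable) -> GLMResult:
    """GLM over every cluster; vectorized when no entries are missing."""
    Y = table.values.to_numpy(dtype=float)
    sex = table.subject_meta["sex"].to_numpy(dtype=float)
    age = table.subject_meta["age"].to_numpy(dtype=float)
    clusters = list(table.values.columns)
    if not np.isnan(Y).any():
        beta, t, p, flags = _glm_dense(Y, sex, age)
        frame = pd.DataFrame(
            {
                "cluster": clusters,
                "beta_group": beta,
                "t_stat": t,
                "p_unc": p,
                "n_used": len(sex),
                "direction": np.sign(beta).astype(int),
                "flag": flags,
            }
        )
        frame.loc[frame["flag"] != "ok", "direction"] = 0
        return GLMResult(frame)
    rows = [fit_glm(Y[:, j], sex, age) for j in range(Y.shape[1])]
    frame = pd.DataFrame(rows)
    frame.insert(0, "cluster", clusters)
    return GLMResult(frame)


def _glm_dense(Y: np.ndarray, sex: np.ndarray, age: np.ndarray):
    """All-cluster OLS via shared normal equations (no missing data)."""
    n, _ = Y.shape
    X = _design(sex, age)
    xtx_inv = np.linalg.inv(X.T @ X)
    A = xtx_inv @ X.T  # (3, n)
    beta = A @ Y  # (3, C)
    resid = Y - X @ beta
    dof = n - X.shape[1]
    rss = np.einsum("ij,ij->j", resid, resid)
    scale = np.maximum(1e-24 * np.einsum("ij,ij->j", Y, Y), 1e-28)
    degen = rss <= scale
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof * xtx_inv[1, 1])
        t = np.where(degen, 0.0, beta[1] / np.where(se > 0, se, np.inf))
    p = np.where(degen, 1.0, 2.0 * stats.t.sf(np.abs(t), dof))
    flags = np.where(degen, "degenerate", "ok")
    return beta[1], t, np.minimum(p, 1.0), flags


def _sex_t_stats(Y: np.ndarray, sex: np.ndarray, age_c: np.ndarray) -> np.ndarray:
    """t statistics of the sex coefficient for all clusters (dense fast path).

    Used inside the permutation loop: suprathreshold status p < alpha is
    decided by |t| > t_crit, avoiding per-permutation p-value evaluation.
    """
    n = Y.shape[0]
    if np.ptp(age_c) == 0:
        X = np.column_stack([np.ones(n), sex])
    else:
        X = np.column_stack([np.ones(n), sex, age_c])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = (xtx_inv @ X.T) @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    dof = n - X.shape[1]
    scale = np.maximum(1e-24 * np.einsum("ij,ij->j", Y, Y), 1e-28)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof * xtx_inv[1, 1])
        t = np.where(rss <= scale, 0.0, beta[1] / np.where(se > 0, se, np.inf))
    return t


# ---------------------------------------------------------------------------
# thresholding and component formation


def threshold_clusters(glm: GLMResult, alpha_unc: float = 0.05) -> pd.DataFrame:
    """Clusters with uncorrected p strictly below ``alpha_unc``."""
    t = glm.table
    return t.loc[t["p_unc"] < alpha_unc, ["cluster", "direction"]].reset_index(drop=True)


def form_stfcs(
    suprathreshold: pd.DataFrame,
    graph: NeighborhoodGraph,
    sign_handling: str = "split_by_sign",
) -> list[STFC]:
    """Connected components of the suprathreshold-induced subgraph.

    Under ``split_by_sign`` components are formed separately within each
    effect direction (an edge between opposite-sign clusters does not merge
    them); singleton components are valid size-1 STFCs.
    """
    if sign_handling not in ("split_by_sign", "ignore_sign"):
        raise ValueError(f"unknown sign_handling {sign_handling!r}")
    members = list(suprathreshold["cluster"])
    direction = dict(zip(suprathreshold["cluster"], suprathreshold["direction"]))
    sub = graph.graph.subgraph(members).copy()
    if sign_handling == "split_by_sign":
        drop = [(a, b) for a, b in sub.edges if direction[a] != direction[b]]
        sub.remove_edges_from(drop)
    out = []
    for comp in nx.connected_components(sub):
        comp = frozenset(comp)
        dirs = {direction[c] for c in comp}
        d = dirs.pop() if len(dirs) == 1 else 0
        out.append(STFC(member_clusters=comp, size=len(comp), direction=d))
    out.sort(key=lambda s: (-s.size, sorted(s.member_clusters)[0]))
    return out


def _max_stfc_size(
    t_stats: np.ndarray,
    t_crit: float,
    indptr: np.ndarray,
    indices: np.ndarray,
    split_by_sign: bool,
) -> int:
    """Largest same-sign connected suprathreshold component (0 if none)."""
    supra = np.abs(t_stats) > t_crit
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return 0
    sign = np.sign(t_stats)
    seen = np.zeros(len(t_stats), dtype=bool)
    best = 0
    for start in idx:
        if seen[start]:
            continue
        seen[start] = True
        stack = [start]
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for v in indices[indptr[u] : indptr[u + 1]]:
                if supra[v] and not seen[v] and (not split_by_sign or sign[v] == sign[u]):
                    seen[v] = True
                    stack.append(v)
        best = max(best, size)
    return best


# ---------------------------------------------------------------------------
# permutation correction


def _observed_chain(table: ClusterFeatureTable, graph: NeighborhoodGraph, config: STFCRunConfig):
    glm = fit_glm_table(table)
    supra = threshold_clusters(glm, config.alpha_unc)
    stfcs = form_stfcs(supra, graph, config.sign_handling)
    return glm, stfcs


def permutation_correct(
    table: ClusterFeatureTable,
    graph: NeighborhoodGraph,
    config: STFCRunConfig,
) -> STFCResult:
    """Family-wise corrected p-values for the observed STFCs.

    Each permutation shuffles the sex labels across subjects (each subject
    keeps its own age and features — the exchangeability-respecting scheme
    under the strong null of no group difference in any cluster), reruns the
    GLM -> threshold -> component chain, and records the maximum STFC size.
    """
    glm, stfcs = _observed_chain(table, graph, config)

    Y = table.values.to_numpy(dtype=float)
    has_missing = np.isnan(Y).any()
    sex = table.subject_meta["sex"].to_numpy(dtype=float)
    age = table.subject_meta["age"].to_numpy(dtype=float)
    age_c = age - age.mean()
    n = len(sex)
    n_f = int(sex.sum())
    dof = n - (2 if np.ptp(age_c) == 0 else 3)
    t_crit = stats.t.ppf(1.0 - config.alpha_unc / 2.0, dof) if dof > 0 else np.inf
    split = config.sign_handling == "split_by_sign"

    node_order = list(table.values.columns)
    adj = graph.adjacency_csr(node_order=node_order)
    indptr, indices = adj.indptr, adj.indices

    n_assign = comb(n, n_f)
    exhaustive = config.exhaustive
    if exhaustive is None:
        exhaustive = config.n_permutations >= n_assign and n_assign <= EXHAUSTIVE_CAP
    if exhaustive and n_assign > EXHAUSTIVE_CAP:
        raise ValueError(f"exhaustive mode infeasible: {n_assign} assignments")

    def max_size_for(sex_perm: np.ndarray) -> int:
        if has_missing:
            meta = table.subject_meta.copy()
            meta["sex"] = sex_perm.astype(int)
            perm_table = ClusterFeatureTable(
                values=table.values, subject_meta=meta, cluster_meta=table.cluster_meta,
                measure=table.measure,
            )
            g = fit_glm_table(perm_table)
            s = threshold_clusters(g, config.alpha_unc)
            comps = form_stfcs(s, graph, config.sign_handling)
            return max((c.size for c in comps), default=0)
        t = _sex_t_stats(Y, sex_perm, age_c)
        return _max_stfc_size(t, t_crit, indptr, indices, split)

    if exhaustive:
        max_sizes = np.empty(n_assign, dtype=np.int64)
        for i, fem in enumerate(itertools.combinations(range(n), n_f)):
            perm = np.zeros(n)
            perm[list(fem)] = 1.0
            max_sizes[i] = max_size_for(perm)
        n_used = n_assign
    else:
        rng = np.random.default_rng(config.seed)
        n_used = config.n_permutations
        max_sizes = np.empty(n_used, dtype=np.int64)
        for i in range(n_used):
            max_sizes[i] = max_size_for(rng.permutation(sex))

    corrected = []
    for s in stfcs:
        b = int((max_sizes >= s.size).sum())
        p = b / n_used if exhaustive else (1 + b) / (1 + n_used)
        corrected.append(
            STFC(member_clusters=s.member_clusters, size=s.size, direction=s.direction,
                 p_corrected=float(p), anatomical_label=s.anatomical_label)
        )
    return STFCResult(
        stfcs=corrected,
        glm=glm,
        null_max_sizes=max_sizes,
        config=config,
        exhaustive=bool(exhaustive),
        n_permutations_used=int(n_used),
    )


def stfc_report(result: STFCResult, table: ClusterFeatureTable) -> pd.DataFrame:
    """Published-table-style rows: index, size, label, p, per-group mean+/-SD.

    The group summary is the mean and SD, across an STFC's member clusters,
    of each cluster's within-group subject mean.
    """
    sex = table.subject_meta["sex"].to_numpy()
    rows = []
    for i, s in enumerate(sorted(result.stfcs, key=lambda x: (x.p_corrected, -x.size)), start=1):
        members = sorted(s.member_clusters)
        sub = table.values[members]
        f_means = sub[sex == 1].mean(axis=0)
        m_means = sub[sex == 0].mean(axis=0)
        rows.append(
            {
                "stfc_index": i,
                "stfc_size": s.size,
                "anatomical_structure": s.anatomical_label or "",
                "p_value": s.p_corrected,
                "direction": {1: "female>male", -1: "male>female", 0: "mixed"}[s.direction],
                "female_mean": f_means.mean(),
                "female_sd": f_means.std(ddof=1) if s.size > 1 else 0.0,
                "male_mean": m_means.mean(),
                "male_sd": m_means.std(ddof=1) if s.size > 1 else 0.0,
                "member_clusters": ";".join(str(m) for m in members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stfc_index", "stfc_size", "anatomical_structure", "p_value", "direction",
            "female_mean", "female_sd", "male_mean", "male_sd", "member_clusters",
        ],
    )


def run_stfc(
    table: ClusterFeatureTable,
    graph: NeighborhoodGraph,
    config: STFCRunConfig | None = None,
) -> STFCResult:
    """Full observed-plus-permutation STFC analysis with a report table."""
    config = config or STFCRunConfig()
    result = permutation_correct(table, graph, config)
    result.report = stfc_report(result, table)
    return result
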