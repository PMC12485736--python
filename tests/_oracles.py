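"""Independent reference computations used by the test suite.

Everything here is deliberately written against *different* code paths than
the package: statsmodels for the GLM, scipy's generalized eigenproblem for
CCA, explicit double loops for geometric distances, and itertools-based
enumeration for the exhaustive permutation test.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import statsmodels.api as sm
from scipy import linalg
from scipy.spatial.distance import cdist


def ols_sex_test(values, sex, age):
    """statsmodels OLS of values on [1, sex, centered age]; sex-coef test."""
    age = np.asarray(age, dtype=float)
    cols = [np.ones(len(sex)), np.asarray(sex, dtype=float)]
    age_c = age - age.mean()
    if np.ptp(age_c) > 0:
        cols.append(age_c)
    X = np.column_stack(cols)
    fit = sm.OLS(np.asarray(values, dtype=float), X).fit()
    return fit.params[1], fit.tvalues[1], fit.pvalues[1]


def mean_closest_point_distance(a, b):
    """Brute-force symmetrized mean-closest-point distance via cdist."""
    d = cdist(np.atleast_2d(a), np.atleast_2d(b))
    return (d.min(axis=1).mean() + d.min(axis=0).mean()) / 2.0


def stfc_components(supra_ids, directions, edges, split_by_sign=True):
    """Flood-fill connected components of the suprathreshold subgraph."""
    supra = set(supra_ids)
    adj = {u: set() for u in supra}
    for a, b in edges:
        if a in supra and b in supra:
            if not split_by_sign or directions[a] == directions[b]:
                adj[a].add(b)
                adj[b].add(a)
    comps, seen = [], set()
    for start in supra:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.add(u)
            stack.extend(adj[u] - seen)
        comps.append(frozenset(comp))
    return comps


def exhaustive_stfc_pvalues(values, sex, age, edges, alpha=0.05, split_by_sign=True):
    """Exact corrected p-values by full enumeration of label assignments.

    ``values`` is subjects x clusters; clusters are identified by column
    position.  Returns (observed components, {component: p}), where p is the
    fraction of all C(n, n_female) assignments whose maximum component size
    reaches the observed component's size.
    """
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n, n_clusters = values.shape
    n_f = int(sex.sum())

    def components_for(sex_vec):
        supra, direction = [], {}
        for j in range(n_clusters):
            beta, _, p = ols_sex_test(values[:, j], sex_vec, age)
            if p < alpha:
                supra.append(j)
                direction[j] = int(np.sign(beta))
        return stfc_components(supra, direction, edges, split_by_sign)

    observed = components_for(sex)
    max_sizes = []
    for fem in itertools.combinations(range(n), n_f):
        vec = np.zeros(n)
        vec[list(fem)] = 1.0
        comps = components_for(vec)
        max_sizes.append(max((len(c) for c in comps), default=0))
    max_sizes = np.array(max_sizes)
    pvals = {c: float((max_sizes >= len(c)).mean()) for c in observed}
    return observed, pvals


def cca_correlations_eig(X, Y):
    """Canonical correlations via the generalized eigenproblem on
    standardized data: Sxy Syy^-1 Syx a = r^2 Sxx a."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    n = len(Xs)
    Sxx = Xs.T @ Xs / (n - 1)
    Syy = Ys.T @ Ys / (n - 1)
    Sxy = Xs.T @ Ys / (n - 1)
    M = Sxy @ np.linalg.solve(Syy, Sxy.T)
    eigvals = linalg.eigh(M, Sxx, eigvals_only=True)[::-1]
    k = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(eigvals[:k], 0.0, 1.0))


def bh_qvalues(p):
    """Benjamini-Hochberg q-values by the textbook formula
    q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def path_graph_edges(ids):
    return [(a, b) for a, b in zip(ids, ids[1:])]


def networkx_knn_graph(distmat, k):
    """Reference k-NN symmetric-closure graph from a distance matrix."""
    n = len(distmat)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        order = np.argsort(distmat[i], kind="stable")
        picked = [j for j in order if j != i][:k]
        for j in picked:
            g.add_edge(i, j)
    return g
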