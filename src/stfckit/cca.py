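"""Canonical correlation of tract microstructure against behavior.

Given an imaging matrix X (subjects x STFC member-cluster means) and a
behavior matrix Y (subjects x measures), canonical correlation analysis
finds paired linear combinations — modes of co-variation — with maximal
correlation.  Modes are sorted by their correlation r; the first (major)
mode's significance is assessed by permuting the rows of Y relative to X and
recomputing r, and q-values across a family of analyses come from
Benjamini-Hochberg FDR.

Columns are standardized and each side is optionally reduced by PCA before
the canonical problem is solved via the SVD of the whitened cross-covariance
(QR factors of the centered sides).  The permutation loop refits the whole
standardize/PCA/CCA pipeline on the shuffled data so the null is exact;
because standardization and PCA are invariant to row order, this reduces to
re-orthogonalized row-permuted factors, which is what the fast path exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CCAConfig",
    "CCAResult",
    "fit_cca",
    "permutation_test_cca",
    "fdr_correct",
]


@dataclass
class CCAConfig:
    n_permutations: int = 100_000
    pca_variance_kept: float | None = 0.80  # None disables the reduction
    standardize: bool = True
    seed: int = 0
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.pca_variance_kept is not None and not 0 < self.pca_variance_kept <= 1:
            raise ValueError("pca_variance_kept must lie in (0, 1]")


@dataclass
class CCAResult:
    correlations: np.ndarray  # non-increasing, in [0, 1]
    x_weights: np.ndarray  # (p_reduced, n_modes) weights in the reduced space
    y_weights: np.ndarray
    n_subjects: int
    p_perm: float | None = None
    q_fdr: float | None = None

    @property
    def major_mode_r(self) -> float:
        return float(self.correlations[0])

    @property
    def n_modes(self) -> int:
        return len(self.correlations)


def _as_matrix(M) -> np.ndarray:
    arr = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D subjects x variables matrix")
    return arr


def _prepare_side(M: np.ndarray, config: CCAConfig, side: str) -> np.ndarray:
    """Center/standardize columns, then optional PCA keeping the configured
    variance fraction.  Raises if the result is rank deficient."""
    M = M - M.mean(axis=0)
    if config.standardize:
        sd = M.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"{side} side has constant columns; cannot standardize")
        M = M / sd
    if config.pca_variance_kept is not None and config.pca_variance_kept < 1:
        pca = PCA(n_components=config.pca_variance_kept, svd_solver="full")
        M = pca.fit_transform(M)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        raise ValueError(f"{side} side is rank deficient after reduction "
                         f"(rank {rank} < {M.shape[1]} columns)")
    return M


def _canonical_from_prepared(Xp: np.ndarray, Yp: np.ndarray):
    Qx, Rx = np.linalg.qr(Xp)
    Qy, Ry = np.linalg.qr(Yp)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    r = np.clip(s, 0.0, 1.0)
    k = min(Xp.shape[1], Yp.shape[1])
    wx = np.linalg.solve(Rx, U[:, :k])
    wy = np.linalg.solve(Ry, Vt.T[:, :k])
    return r[:k], wx, wy


def fit_cca(X, Y, config: CCAConfig | None = None) -> CCAResult:
    """Canonical correlations between two subject-aligned variable sets.

    Returns modes sorted non-increasing in r (the SVD order), with weight
    vectors expressed in the prepared (standardized / PCA-reduced) spaces.
    The number of modes equals the smaller side's retained dimension.
    """
    config = config or CCAConfig()
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same subject rows")
    n = Xm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    Xp = _prepare_side(Xm, config, "imaging (X)")
    Yp = _prepare_side(Ym, config, "behavior (Y)")
    if n <= Xp.shape[1] + Yp.shape[1]:
        raise ValueError(
            f"{n} subjects <= {Xp.shape[1]} + {Yp.shape[1]} retained dimensions; "
            "use a stronger reduction (lower pca_variance_kept)"
        )
    r, wx, wy = _canonical_from_prepared(Xp, Yp)
    return CCAResult(correlations=r, x_weights=wx, y_weights=wy, n_subjects=n)


def permutation_test_cca(X, Y, config: CCAConfig | None = None) -> CCAResult:
    """Permutation p-value for the major mode.

    Rows of Y are permuted relative to X; the full preparation pipeline is
    refit on each shuffle and the major-mode r recomputed.  One-sided test
    (r_perm >= r_obs): canonical correlations are non-negative by
    construction.  p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).
    """
    config = config or CCAConfig()
    result = fit_cca(X, Y, config)
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    Xp = _prepare_side(Xm, config, "imaging (X)")
    Qx, _ = np.linalg.qr(Xp)
    rng = np.random.default_rng(config.seed)
    n = Xm.shape[0]
    count = 0
    for _ in range(config.n_permutations):
        perm = rng.permutation(n)
        # preparation is row-order invariant, so refitting the pipeline on
        # Ym[perm] equals permuting the prepared side before whitening
        Yp = _prepare_side(Ym[perm], config, "behavior (Y)")
        Qy, _ = np.linalg.qr(Yp)
        r_perm = np.linalg.svd(Qx.T @ Qy, compute_uv=False)[0]
        if r_perm >= result.major_mode_r - 1e-12:
            count += 1
    result.p_perm = (1 + count) / (1 + config.n_permutations)
    return result


def fdr_correct(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values for one analysis family."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q
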