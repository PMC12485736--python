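"""Self-calibration experiments: error rates the pipeline should exhibit.

These routines run the full analysis on repeated synthetic cohorts and
measure its operating characteristics — type-I error of the family-wise
corrected STFC test under the null, power and localization (Jaccard overlap
with the planted region) under an additive group effect, and the canonical
correlation test's null rejection rate and recovery of a known population
correlation.  They exist so a user (or the test suite) can verify the
statistics are calibrated at simulation scales of their choosing.

All experiments are deterministic given their seed; per-repeat seeds are
simple offsets of it, kept below 2**31.
"""

from __future__ import annotations

import numpy as np

from .cca import CCAConfig, permutation_test_cca
from .simulate import SimulationConfig, generate_behavior, generate_cohort, select_connected_region
from .stfc import STFCRunConfig, permutation_correct

__all__ = [
    "stfc_type_i_error",
    "stfc_effect_recovery",
    "cca_recovery",
    "cca_null_rejection",
]

_SEED_MOD = 2**31 - 1


def _planted_config(n_clusters, region_size, n_female, n_male, effect_size, noise_sd, seed, k=10):
    """A cohort config whose effect region is connected by construction."""
    probe = generate_cohort(
        SimulationConfig(n_female=1, n_male=1, n_clusters=n_clusters, knn_k=k, seed=seed)
    )
    region = select_connected_region(probe.graph, region_size)
    ids = sorted(probe.feature_table.values.columns)
    return SimulationConfig(
        n_female=n_female,
        n_male=n_male,
        n_clusters=n_clusters,
        knn_k=k,
        effect_clusters=frozenset(ids.index(r) for r in region),
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
    )


def stfc_type_i_error(
    n_cohorts: int = 200,
    n_female: int = 20,
    n_male: int = 20,
    n_clusters: int = 200,
    k: int = 10,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null cohorts with any STFC at corrected p < alpha.

    Under exchangeable labels this family-wise rate should sit at or below
    the nominal alpha (the max-statistic construction is conservative when
    suprathreshold sets are sparse).
    """
    hits = 0
    for i in range(n_cohorts):
        cfg = SimulationConfig(
            n_female=n_female, n_male=n_male, n_clusters=n_clusters, knn_k=k,
            seed=(seed + 17 * i + 1) % _SEED_MOD,
        )
        cohort = generate_cohort(cfg)
        res = permutation_correct(
            cohort.feature_table, cohort.graph,
            STFCRunConfig(n_permutations=n_permutations, exhaustive=False,
                          seed=(seed + 31 * i + 2) % _SEED_MOD),
        )
        hits += any(s.p_corrected < alpha for s in res.stfcs)
    return hits / n_cohorts


def stfc_effect_recovery(
    n_seeds: int = 25,
    region_size: int = 10,
    n_female: int = 50,
    n_male: int = 50,
    n_clusters: int = 200,
    effect_size: float = 0.02,
    noise_sd: float = 0.02,
    n_permutations: int = 500,
    alpha: float = 0.05,
    min_jaccard: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """(recovery rate, mean best Jaccard) for a planted connected effect.

    A seed counts as recovered when some STFC significant at corrected
    p < alpha overlaps the planted region with Jaccard >= ``min_jaccard``.
    The default effect equals one residual SD per subject (delta = sigma).
    """
    recovered, jaccards = 0, []
    for i in range(n_seeds):
        cfg = _planted_config(
            n_clusters, region_size, n_female, n_male, effect_size, noise_sd,
            seed=(seed + 13 * i + 3) % _SEED_MOD,
        )
        cohort = generate_cohort(cfg)
        res = permutation_correct(
            cohort.feature_table, cohort.graph,
            STFCRunConfig(n_permutations=n_permutations, exhaustive=False,
                          seed=(seed + 41 * i + 4) % _SEED_MOD),
        )
        truth = cohort.truth_ids
        best = 0.0
        for s in res.stfcs:
            if s.p_corrected < alpha:
                jac = len(s.member_clusters & truth) / len(s.member_clusters | truth)
                best = max(best, jac)
        jaccards.append(best)
        recovered += best >= min_jaccard
    return recovered / n_seeds, float(np.mean(jaccards))


def cca_recovery(
    n_repeats: int = 50,
    rho: float = 0.6,
    n_female: int = 500,
    n_male: int = 500,
    region_size: int = 10,
    n_clusters: int = 30,
    n_measures: int = 5,
    n_permutations: int = 500,
    r_tol: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """(fraction of repeats with |r - rho| <= r_tol and p < alpha, mean r).

    The imaging side is the planted clusters' features; behavior is built
    with population canonical correlation ``rho`` to them.  No PCA reduction
    is applied: the experiment runs at the generative model's own dimension.
    """
    cfg0 = _planted_config(n_clusters, region_size, n_female, n_male,
                           effect_size=0.02, noise_sd=0.02, seed=seed % _SEED_MOD)
    good, rs = 0, []
    for i in range(n_repeats):
        cohort = generate_cohort(
            SimulationConfig(**{**cfg0.__dict__, "effect_clusters": cfg0.effect_clusters,
                                "seed": (seed + 7 * i + 5) % _SEED_MOD})
        )
        behavior = generate_behavior(cohort, rho=rho, n_measures=n_measures,
                                     seed=(seed + 11 * i + 6) % _SEED_MOD)
        X = cohort.feature_table.values[sorted(cohort.truth_ids)]
        res = permutation_test_cca(
            X, behavior,
            CCAConfig(pca_variance_kept=None, n_permutations=n_permutations,
                      seed=(seed + 19 * i + 7) % _SEED_MOD),
        )
        rs.append(res.major_mode_r)
        good += (abs(res.major_mode_r - rho) <= r_tol) and (res.p_perm < alpha)
    return good / n_repeats, float(np.mean(rs))


def cca_null_rejection(
    n_repeats: int = 100,
    n_subjects: int = 100,
    n_x: int = 5,
    n_y: int = 3,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the major-mode permutation test on independent data."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_repeats):
        X = rng.normal(size=(n_subjects, n_x))
        Y = rng.normal(size=(n_subjects, n_y))
        res = permutation_test_cca(
            X, Y,
            CCAConfig(pca_variance_kept=None, n_permutations=n_permutations,
                      seed=(seed + 23 * i + 8) % _SEED_MOD),
        )
        rejections += res.p_perm < alpha
    return rejections / n_repeats
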