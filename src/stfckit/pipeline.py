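"""End-to-end driver: simulate -> features -> STFC -> CCA -> reports.

All randomness flows from one manifest seed; each stage derives its own seed
as ``sha256(global_seed, stage_name) mod 2**31``, so stages are individually
reproducible and mutually independent.  Every run directory receives exactly
one ``manifest.json`` recording the config snapshot, derived seeds, output
file digests, package version and per-stage wall time; reruns with identical
config and seed reproduce byte-identical numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cca import CCAConfig, fit_cca, permutation_test_cca
from .io import write_covariates, write_feature_table, write_graph
from .simulate import SimulationConfig, generate_behavior, generate_cohort, select_connected_region
from .stfc import STFCRunConfig, run_stfc

__all__ = ["derive_seed", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def derive_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Run the full synthetic pipeline under ``out_dir``; returns the manifest.

    ``config`` keys (all optional): ``simulation`` (SimulationConfig fields,
    minus seed), ``effect_region_size`` (planted clusters grown from the
    neighborhood graph when ``effect_clusters`` is not given), ``stfc``
    (STFCRunConfig fields minus seed), ``cca`` (CCAConfig fields minus seed,
    plus ``rho`` and ``n_measures`` for the behavior generator).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "stfckit",
        "version": __version__,
        "seed": int(seed),
        "config": config,
        "stage_seeds": {},
        "stage_seconds": {},
        "outputs": [],
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        sim_kw = dict(config.get("simulation", {}))
        region_size = int(config.get("effect_region_size", 0))
        sim_seed = derive_seed(seed, "simulate")
        manifest["stage_seeds"]["simulate"] = sim_seed
        if region_size and "effect_clusters" not in sim_kw:
            probe = generate_cohort(SimulationConfig(**{**sim_kw, "n_female": 1, "n_male": 1,
                                                        "effect_size": 0.0, "seed": sim_seed}))
            region = select_connected_region(probe.graph, region_size)
            ids = sorted(probe.feature_table.values.columns)
            sim_kw["effect_clusters"] = frozenset(ids.index(r) for r in region)
        cohort = generate_cohort(SimulationConfig(**sim_kw, seed=sim_seed))
        write_feature_table(cohort.feature_table, out / "features.tsv")
        write_covariates(cohort.feature_table.subject_meta, out / "covariates.tsv")
        write_graph(cohort.graph, out / "graph.tsv")
        truth = {
            "effect_clusters": sorted(cohort.truth_region),
            "effect_size": cohort.config.effect_size,
            "config": json.loads(cohort.config.to_json()),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
        manifest["stage_seconds"]["simulate"] = round(time.perf_counter() - t0, 3)

        stage = "stfc"
        t0 = time.perf_counter()
        stfc_seed = derive_seed(seed, "stfc")
        manifest["stage_seeds"]["stfc"] = stfc_seed
        stfc_cfg = STFCRunConfig(**dict(config.get("stfc", {})), seed=stfc_seed)
        result = run_stfc(cohort.feature_table, cohort.graph, stfc_cfg)
        result.glm.table.to_csv(out / "glm.tsv", sep="\t", index=False, float_format="%.17g")
        result.report.to_csv(out / "stfc_report.tsv", sep="\t", index=False, float_format="%.17g")
        null = pd.Series(result.null_max_sizes).value_counts().sort_index()
        null.rename_axis("max_stfc_size").rename("count").to_csv(out / "null_max_sizes.tsv", sep="\t")
        manifest["stage_seconds"]["stfc"] = round(time.perf_counter() - t0, 3)

        stage = "cca"
        t0 = time.perf_counter()
        cca_kw = dict(config.get("cca", {}))
        rho = float(cca_kw.pop("rho", 0.0))
        n_measures = int(cca_kw.pop("n_measures", 5))
        cca_seed = derive_seed(seed, "cca")
        manifest["stage_seeds"]["cca"] = cca_seed
        cca_rows = []
        significant = [s for s in result.stfcs if s.p_corrected < stfc_cfg.alpha_corrected]
        if significant and cohort.truth_region:
            behavior = generate_behavior(cohort, rho=rho, n_measures=n_measures, seed=cca_seed)
            behavior.to_csv(out / "behavior.tsv", sep="\t", index_label="subject",
                            float_format="%.17g")
            members = sorted(set().union(*(s.member_clusters for s in significant)))
            X_all = cohort.feature_table.values[members]
            sex = cohort.feature_table.subject_meta["sex"]
            cca_cfg = CCAConfig(**cca_kw, seed=cca_seed)
            for grp, label in ((1, "female"), (0, "male")):
                rows = sex == grp
                res = permutation_test_cca(X_all[rows], behavior[rows], cca_cfg)
                cca_rows.append({"group": label, "major_mode_r": res.major_mode_r,
                                 "p_perm": res.p_perm, "n_subjects": res.n_subjects})
        pd.DataFrame(cca_rows, columns=["group", "major_mode_r", "p_perm", "n_subjects"]).to_csv(
            out / "cca_report.tsv", sep="\t", index=False, float_format="%.17g")
        manifest["stage_seconds"]["cca"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        raise PipelineError(stage, exc) from exc

    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest["outputs"] = [{"file": p.name, "sha256": _sha256(p)} for p in outputs]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
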