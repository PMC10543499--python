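"""End-to-end orchestration: simulate -> matrix -> cluster -> score -> associate -> meta.

A single YAML config drives the run; per-stage seeds are derived
deterministically from one master seed so a run is reproducible end to end
while individual stages stay independently re-runnable.  Every executed
stage records its parameters, seed, outputs and checksums in a JSON run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, bnmf, io, simulate, zmatrix

logger = logging.getLogger("insuclust")

STAGES = ["simulate_sumstats", "simulate_cohort", "build_matrix", "cluster", "score", "associate", "meta"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from a stable hash of the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Stage toggles plus all stage parameters for one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    sim_config: str | None = None  # path or fixture name for simulate stages
    sumstats: str | None = None  # existing input when simulate_sumstats is off
    genotypes: str | None = None
    phenotypes: str | None = None
    weights: str | None = None
    fi_trait: str = "FI"
    p_threshold: float = 5e-5
    r_threshold: float = 0.85
    k0: int = 20
    restarts: int = 100
    cutoff: float | str = 0.84  # numeric or "auto" (long-tail elbow)
    r2_min: float = 0.8
    freq_tol: float = 0.05
    exposure: str = "continuous_per10"
    pc_screen: bool = False
    outcomes: list | None = None
    n_tests: int = 56
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        enabled = set(self.stages)
        unknown = enabled - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "build_matrix" in enabled and "simulate_sumstats" not in enabled and not self.sumstats:
            raise ValueError("build_matrix enabled without simulate_sumstats or a sumstats path")
        if "score" in enabled and "cluster" not in enabled and not self.weights:
            raise ValueError("score enabled without cluster stage or a weights path")
        if "score" in enabled and "simulate_cohort" not in enabled and not self.genotypes:
            raise ValueError("score enabled without simulate_cohort or a genotypes path")
        if "associate" in enabled and "simulate_cohort" not in enabled and not self.phenotypes:
            raise ValueError("associate enabled without simulate_cohort or a phenotypes path")


@dataclass
class RunManifest:
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seed: int, params: dict, outputs: dict, warnings_seen=()):
        self.stages[stage] = {
            "seed": seed,
            "params": {k: str(v) for k, v in params.items()},
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in outputs.items()},
            "warnings": list(warnings_seen),
        }

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh, indent=2, sort_keys=True)
        return path


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order; halt on failure."""
    config.validate()
    out = Path(config.out_dir)
    manifest = RunManifest(seed=config.seed)
    manifest_path = out / "manifest.json"

    sim_cfg = None
    if config.sim_config:
        sim_cfg = simulate.load_sim_config(config.sim_config)

    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            seed = stage_seed(config.seed, stage)
            logger.info("stage=%s seed=%d starting", stage, seed)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                outputs = _run_stage(stage, config, sim_cfg, seed, out, state)
            msgs = [f"stage={stage} {w.message}" for w in caught]
            for msg in msgs:
                logger.warning(msg)
            manifest.record(stage, seed, _stage_params(stage, config), outputs, msgs)
    finally:
        manifest.write(manifest_path)
    return manifest


def _stage_params(stage: str, config: RunConfig) -> dict:
    relevant = {
        "simulate_sumstats": ["sim_config"],
        "simulate_cohort": ["sim_config"],
        "build_matrix": ["fi_trait", "p_threshold", "r_threshold"],
        "cluster": ["k0", "restarts", "cutoff"],
        "score": ["r2_min", "freq_tol"],
        "associate": ["exposure", "pc_screen", "outcomes"],
        "meta": ["n_tests", "alpha"],
    }[stage]
    return {k: getattr(config, k) for k in relevant}


def _run_stage(stage, config, sim_cfg, seed, out, state):
    if stage == "simulate_sumstats":
        cfg = sim_cfg or simulate.SUMSTATS_A()
        stats, truth = simulate.generate_summary_stats(cfg)
        state["stats"], state["truth"], state["sim_cfg_obj"] = stats, truth, cfg
        path = out / "sumstats" / "sumstats.tsv"
        io.write_summary_stats(stats, path)
        return {"sumstats": path}

    if stage == "simulate_cohort":
        cfg = state.get("sim_cfg_obj") or sim_cfg or simulate.COHORT_A()
        truth = state.get("truth")
        if truth is None:
            _, truth = simulate.generate_summary_stats(cfg)
        defs = simulate.planted_cluster_definitions(truth)
        ld = simulate.generate_ld_reference(cfg, variant_ids=defs.all_variant_ids())
        panel, cohort = simulate.generate_cohort(cfg, defs, ld=ld, seed=seed)
        state["panel"], state["cohort"], state["ld"] = panel, cohort, ld
        g_path = io.write_dosage_tsv(panel, out / "cohort" / "dosages.tsv")
        p_path = io.write_cohort(cohort, out / "cohort" / "phenotypes.tsv")
        ld_paths = io.write_ld_reference(ld, out / "cohort")
        return {"dosages": g_path, "phenotypes": p_path, **ld_paths}

    if stage == "build_matrix":
        stats = state.get("stats")
        if stats is None:
            stats = io.read_summary_stats(config.sumstats)
        variants = zmatrix.select_variants(stats, config.fi_trait, config.p_threshold)
        zmat = zmatrix.align_to_risk_allele(stats, variants, config.fi_trait)
        zmat = zmatrix.prune_traits(zmat, config.r_threshold)
        nn = zmatrix.build_nonnegative_matrix(zmat)
        state["zmat"], state["nn"] = zmat, nn
        paths = io.write_zmatrix(zmat, out / "matrix")
        paths["matrix"] = io.write_nonneg_matrix(nn, out / "matrix" / "nonneg.tsv")
        return paths

    if stage == "cluster":
        nn = state["nn"]
        model = bnmf.BayesianNMF(nn, k0=config.k0)
        fits = model.fit_restarts(n_restarts=config.restarts, seed=seed)
        solution = bnmf.select_solution(fits)
        cutoff = (
            bnmf.long_tail_cutoff(solution)
            if str(config.cutoff) == "auto"
            else float(config.cutoff)
        )
        zmat = state["zmat"]
        defs = bnmf.threshold_weights(
            solution,
            cutoff,
            fi_alleles=zmat.fi_increasing_allele.to_dict(),
            positions={
                v: (row["chromosome"], row["position"]) for v, row in zmat.variants.iterrows()
            },
        )
        state["defs"] = defs
        paths = io.write_cluster_definitions(defs, out / "clusters")
        report = out / "clusters" / "run_summary.json"
        with open(report, "w") as fh:
            json.dump(
                {
                    "k_per_restart": [f.effective_k for f in fits],
                    "objectives": [f.objective for f in fits],
                    "selected_k": solution.k,
                    "selected_seed": solution.fit.seed,
                    "cutoff": cutoff,
                },
                fh,
                indent=2,
            )
        paths["run_summary"] = report
        return paths

    if stage == "score":
        from . import scores as sc

        defs = state.get("defs")
        if defs is None:
            defs = io.read_cluster_definitions(config.weights)
        panel = state.get("panel")
        if panel is None:
            panel = io.read_genotypes(config.genotypes)
        ld = state.get("ld") or sc.LDReference(
            {v: float(panel.variants.loc[v, "frequency"]) for v in panel.variants.index}
        )
        resolved = sc.resolve_variants(defs, panel, ld, config.r2_min, config.freq_tol)
        pps = sc.compute_pps(panel, resolved)
        state["pps"] = pps
        paths = {"pps": io.write_pps(pps, out / "scores" / "pps.tsv")}
        rep = out / "scores" / "resolution.tsv"
        resolved.table.to_csv(rep, sep="\t", index=False)
        paths["resolution"] = rep
        cut = sc.reference_cutoffs(pps)
        paths["cutoffs"] = io.write_cutoffs(cut, out / "scores" / "cutoffs.tsv")
        return paths

    if stage == "associate":
        cohort = state.get("cohort")
        if cohort is None:
            cohort = io.read_cohort(config.phenotypes)
        pps = state["pps"]
        outcomes = config.outcomes or _detect_outcomes(cohort)
        results = []
        for cluster in pps.clusters:
            for outcome in outcomes:
                results.append(
                    assoc.fit_outcome_model(
                        cohort, pps, cluster, outcome,
                        exposure=config.exposure, pc_screen=config.pc_screen,
                    )
                )
        state["results"] = results
        path = io.write_association_results(results, out / "assoc" / "results.tsv")
        return {"results": path}

    if stage == "meta":
        results = state["results"]
        threshold = assoc.bonferroni_threshold(config.n_tests, config.alpha)
        groups: dict = {}
        for r in results:
            groups.setdefault((r.cluster, r.outcome, r.stratum, r.exposure), []).append(r)
        metas = []
        for group in groups.values():
            if not any(r.usable for r in group):
                continue
            metas.append(assoc.FixedEffectsMeta(group).fit(alpha_threshold=threshold))
        table = assoc.meta_table(metas, alpha_threshold=threshold)
        path = out / "meta" / "meta.tsv"
        path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(path, sep="\t", index=False)
        return {"meta": path}

    raise ValueError(f"unknown stage {stage!r}")


def _detect_outcomes(cohort: pd.DataFrame) -> list:
    reserved = {"individual_id", "age", "sex", "ancestry", "t2d_status"}
    reserved |= {f"PC{i}" for i in range(1, 11)}
    return [c for c in cohort.columns if c not in reserved]
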