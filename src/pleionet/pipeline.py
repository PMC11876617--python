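"""Pipeline orchestration: configuration, seeding, manifest, stage order.

run_pipeline drives the full synthetic-data demonstration: simulate ->
expression time -> co-expression modules -> GRN + motif census ->
partition heritability -> association -> SV calling.  Every stochastic
stage derives its RNG seed from (global seed, stage name) so stages are
reproducible independently, and a JSON manifest records input hashes,
parameters and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, coexpression, expression_time, genetics, grn
from . import io as pio
from . import motifs, simulate, sv_pav

logger = logging.getLogger("pleionet")

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Global pipeline parameters; unknown keys are rejected on load."""

    seed: int = 0
    out_dir: str = "pleionet_out"
    threads: int = 1
    # expression stage
    n_genes: int = 400
    n_dynamic: int = 80
    mutant_offset: float = 0.5
    # network stage
    soft_power: int = 6
    min_module_size: int = 10
    merge_cut_height: float = 0.25
    grn_trees: int = 50
    grn_weight_cutoff: float = 0.005
    motif_permutations: int = 100
    # genetics stage
    n_individuals: int = 200
    n_snps: int = 600
    h2_target: float = 0.5
    null_permutations: int = 50
    # sv stage
    sv_lines: int = 200
    sv_coverage: float = 100.0
    sv_residual_rate: float = 0.02

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    started: float = field(default_factory=time.time)
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "params": params,
            "outputs": {p.name: _hash_file(p) for p in outputs if p.exists()},
            "finished": time.time(),
        }

    def write(self, path: Path) -> None:
        payload = {"seed": self.seed, "version": self.version,
                   "started": self.started, "stages": self.stages}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on synthetic data; returns a result summary.

    Stages run in dependency order and halt with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    results: dict = {}
    stage = "init"
    try:
        # --- simulate + expression time -----------------------------------
        stage = "expression_time"
        logger.info("stage %s", stage)
        ecfg = simulate.ExpressionSimConfig(
            n_genes=config.n_genes,
            n_dynamic=config.n_dynamic,
            genotypes={"control": 0.0, "mutant": config.mutant_offset},
            module_spec=[(40, 0.8), (40, 0.7)],
            seed=stage_seed(config.seed, stage),
        )
        panel = simulate.gen_expression_panel(ecfg)
        meta = panel.metadata
        ref = meta[meta.genotype == "control"]["sample_id"].tolist()
        stage_rank = {
            s: float(r)
            for r, s in enumerate(dict.fromkeys(meta["stage"]), start=1)
        }
        sample_rank = pd.Series(
            [stage_rank[meta.set_index("sample_id").loc[s, "stage"]] for s in ref],
            index=ref,
        )
        dyn = expression_time.select_dynamic_genes(
            panel.tpm, meta, n=min(config.n_dynamic, config.n_genes)
        )
        model = expression_time.fit_trajectory(panel.tpm, dyn, ref, sample_rank)
        ets = expression_time.assign_expression_time(model, panel.tpm)
        ets.to_csv(out / "expression_time.tsv", sep="\t")
        pio.write_expression_tsv(panel.tpm, out / "expression_tpm.tsv")
        results["n_samples_staged"] = len(ets)
        manifest.record(stage, {"n_genes": config.n_genes},
                        [out / "expression_time.tsv", out / "expression_tpm.tsv"])

        # --- co-expression network ----------------------------------------
        stage = "coexpression"
        logger.info("stage %s", stage)
        module_genes = [g for g in panel.module_assignment] + panel.dynamic_genes[:40]
        sub = panel.tpm.loc[sorted(set(module_genes))]
        logx = np.log2(sub + 1)
        cor = coexpression.correlation_matrix(logx, method="bicor")
        adj = coexpression.signed_adjacency(cor, beta=config.soft_power)
        tom = coexpression.tom_similarity(adj)
        modules = coexpression.detect_modules(
            tom, logx, min_size=config.min_module_size,
            merge_cut=config.merge_cut_height,
        )
        modules.to_csv(out / "modules.tsv", sep="\t")
        results["n_modules"] = int((modules != "unassigned").sum() > 0) and modules[
            modules != "unassigned"
        ].nunique()
        manifest.record(stage, {"soft_power": config.soft_power},
                        [out / "modules.tsv"])

        # --- GRN + motifs ---------------------------------------------------
        stage = "grn_motifs"
        logger.info("stage %s", stage)
        rcfg = simulate.RegulatorySimConfig(
            n_tfs=20, n_targets=60, planted_motifs={"ffl": 6},
            seed=stage_seed(config.seed, stage),
        )
        truth, rexpr, tfs = simulate.gen_regulatory_truth(rcfg)
        net = grn.infer_grn(
            rexpr, tfs, n_trees=config.grn_trees,
            weight_cutoff=config.grn_weight_cutoff,
            seed=stage_seed(config.seed, stage + ".rf"),
        )
        census = motifs.triad_census(net)
        nulls = [
            motifs.triad_census(g)
            for g in motifs.randomize_network(
                net, n_perm=config.motif_permutations,
                seed=stage_seed(config.seed, stage + ".null"),
            )
        ]
        enr = motifs.motif_enrichment(census, nulls)
        pd.DataFrame([vars(e) for e in enr]).to_csv(
            out / "motif_enrichment.tsv", sep="\t", index=False
        )
        results["n_ffl"] = len(motifs.enumerate_ffls(net))
        manifest.record(stage, {"n_trees": config.grn_trees},
                        [out / "motif_enrichment.tsv"])

        # --- genetics: partition h2 ----------------------------------------
        stage = "genetics"
        logger.info("stage %s", stage)
        span = config.n_snps * 100
        gcfg = simulate.GenoPhenoSimConfig(
            n_individuals=config.n_individuals,
            n_snps=config.n_snps,
            ld_rho=0.3,
            causal_windows=[(span // 10, span // 4)],
            h2_targets=(config.h2_target, config.h2_target),
            seed=stage_seed(config.seed, stage),
        )
        geno = simulate.gen_genotypes(gcfg)
        pheno = simulate.gen_phenotypes(geno, gcfg)
        y = pheno.line_values["trait_1"].to_numpy()
        km = genetics.kinship(geno)
        est = genetics.reml_h2(y, km)
        results["genomewide_h2"] = round(est.h2, 4)
        pio.write_dosage_tsv(geno, out / "dosages.tsv")
        pio.write_phenotype_csv(pheno.records, out / "phenotypes.csv")
        manifest.record(stage, {"h2_target": config.h2_target},
                        [out / "dosages.tsv", out / "phenotypes.csv"])

        # --- association ----------------------------------------------------
        stage = "association"
        logger.info("stage %s", stage)
        dos = np.nan_to_num(geno.dosage, nan=0.0)
        scan = association.mlm_association(
            y, dos, covariates=None, K=km, snp_ids=list(geno.snps["id"])
        )
        scan.to_csv(out / "association.tsv", sep="\t", index=False)
        results["n_fdr_hits"] = int(scan["significant_fdr"].sum())
        manifest.record(stage, {"model": "MLM"}, [out / "association.tsv"])

        # --- SV / PAV --------------------------------------------------------
        stage = "sv_pav"
        logger.info("stage %s", stage)
        dcfg = simulate.ReadDepthSimConfig(
            n_lines=config.sv_lines,
            mean_coverage=config.sv_coverage,
            residual_rate=config.sv_residual_rate,
            seed=stage_seed(config.seed, stage),
        )
        depth, truth_calls = simulate.gen_read_depth(dcfg)
        calls = sv_pav.call_pav(depth, min_total=0.5 * config.sv_coverage)
        calls.to_csv(out / "pav_calls.tsv", sep="\t")
        results["pav_accuracy"] = float(
            (calls["call"].to_numpy() == truth_calls.to_numpy()).mean()
        )
        manifest.record(stage, {"coverage": config.sv_coverage},
                        [out / "pav_calls.tsv"])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest.write(out / "manifest.json")
    results["manifest"] = str(out / "manifest.json")
    return results
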