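"""End-to-end pipeline: load files, filter, fit models, scan, predict, report.

The pipeline is deterministic given a configuration (including its seed);
every tabular output carries the configuration hash on a leading comment
line, and a manifest JSON summarizes the run.  Stage failures abort with a
stage-labeled error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations as ann
from . import architecture as arch
from . import gwas as gwas_mod
from . import io as hio
from .genotypes import (
    additive_kinship,
    binned_kinships,
    dominance_kinship,
    filter_snps,
    fit_reference_pcs,
    genomic_inbreeding,
)
from .panel import HybridPanel
from .prediction import leave_one_population_out
from .reml import lrt
from .simulate import SimulationConfig, simulate_pips, simulate_study

logger = logging.getLogger("hybridgp")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, model choices and output location for one pipeline run."""

    vcf: str
    crosses: str
    phenotypes: str
    gff3: str
    bed: str
    gerp: str
    genetic_map: str
    imputation_r2: str
    outdir: str = "hybridgp_out"
    reference_panel: str | None = None  # sample ids file for pi/PCs; default: all parents
    features: tuple = ("gene",)
    min_r2: float = 0.8
    min_maf: float = 0.01
    run_gwas: bool = True
    run_prediction: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        """Hash of the scientific configuration (output location and logging
        verbosity excluded, so reruns into a different directory match)."""
        payload = {k: v for k, v in asdict(self).items() if k not in ("outdir", "log_level")}
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        for name in ("vcf", "crosses", "phenotypes", "gff3", "bed", "gerp", "genetic_map", "imputation_r2"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _setup_logging(level: str) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers = [handler]
    logger.setLevel(level)


def run_pipeline(config: RunConfig) -> dict:
    """Run load -> filter -> kernels -> fits -> GWAS -> enrichment -> prediction.

    Returns a manifest dict (also written to ``outdir/manifest.json``).
    """
    _setup_logging(config.log_level)
    chash = config.hash()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": chash, "stages": []}

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        config.validate_paths()
        markers, crosses = hio.markers_from_files(config.vcf, config.crosses)
        pheno = hio.read_tsv(config.phenotypes).set_index("hybrid_id")
        g = pheno.loc[crosses["hybrid_id"], "g"].to_numpy(dtype=float)
        scores = hio.read_tsv(config.imputation_r2)["r2"].to_numpy()
        snps_vcf, parent_counts_mat, samples = hio.read_vcf(config.vcf)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    try:
        stage("filter")
        ref_ids = samples
        if config.reference_panel:
            ref_ids = Path(config.reference_panel).read_text().split()
        ref_rows = [samples.index(s) for s in ref_ids]
        pi = parent_counts_mat[ref_rows].mean(axis=0) / 2.0
        markers.snps["ref_freq"] = pi
        sets = {
            f"{p}:{t}": np.flatnonzero((crosses["panel"] == p) & (crosses["tester_id"] == t))
            for p, t in crosses[["panel", "tester_id"]].drop_duplicates().itertuples(index=False)
        }
        markers, filter_report = filter_snps(
            markers, scores, sets, min_r2=config.min_r2, min_maf=config.min_maf
        )
        pi = markers.snps["ref_freq"].to_numpy()
        ok = (pi > 0) & (pi < 1)
        markers = markers.subset_snps(ok)
        hio.write_tsv(outdir / "filter_report.tsv", filter_report, chash)
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", exc) from exc

    try:
        stage("kernels")
        keep_cols = np.array([samples.index(s) for s in ref_ids])
        col_idx = pd.Index(snps_vcf["snp_id"]).get_indexer(markers.snps["snp_id"])
        ref_counts = parent_counts_mat[keep_cols][:, col_idx]
        pc_model = fit_reference_pcs(ref_counts.astype(float), k=3)
        pcs = pc_model.project(markers.X)
        F = genomic_inbreeding(markers.X, markers.snps["ref_freq"].to_numpy())
        panel_all = HybridPanel(table=crosses, g=g, pcs=pcs, F=F)
        G = additive_kinship(markers.X)
        D = dominance_kinship(markers.Z)
    except Exception as exc:  # noqa: BLE001
        raise StageError("kernels", exc) from exc

    try:
        stage("annotations")
        genes = ann.read_gff3_genes(config.gff3)
        peaks = ann.read_bed(config.bed)
        gmap = ann.read_genetic_map(config.genetic_map)
        gerp_tab = hio.read_tsv(config.gerp).set_index("snp_id")
        gerp = gerp_tab.loc[markers.snps["snp_id"], "gerp"].to_numpy()
        annoset = ann.annotate(
            markers.snps, genes, peaks, gmap, markers.snps["ref_freq"].to_numpy(), gerp
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotations", exc) from exc

    results: dict = {}
    try:
        stage("fits")
        panels = {name: np.flatnonzero(crosses["panel"] == name) for name in crosses["panel"].unique()}
        fits_summary = []
        for name, idx in panels.items():
            sub = panel_all.subset(idx)
            Gi = additive_kinship(markers.X[idx])
            fit_g = arch.fit_gblup(sub, Gi)
            row = {"panel": name, "model": "gblup", **fit_g.variances, "loglik": fit_g.loglik}
            fits_summary.append(row)
            results[f"gblup:{name}"] = fit_g
            if sub.n_testers >= 2:
                Di = dominance_kinship(markers.Z[idx])
                fit_d = arch.fit_dgblup(sub, Gi, Di)
                results[f"dgblup:{name}"] = fit_d
                shares = arch.proportion_variance(fit_d)
                fits_summary.append(
                    {
                        "panel": name,
                        "model": "dgblup",
                        **fit_d.variances,
                        "loglik": fit_d.loglik,
                        "degree_of_dominance": arch.degree_of_dominance(fit_d),
                        **{f"share_{k}": v for k, v in shares.items()},
                    }
                )
                fit_dir = arch.fit_directional(sub, Gi, Di)
                from .reml import wald_test

                idx_f = fit_dir.fixed_names.index("F")
                idx_f2 = fit_dir.fixed_names.index("F2")
                _, p_f = wald_test(fit_dir, [idx_f])
                _, p_f2 = wald_test(fit_dir, [idx_f2])
                fits_summary.append(
                    {
                        "panel": name,
                        "model": "directional",
                        "tau1": fit_dir.beta[idx_f],
                        "tau2": fit_dir.beta[idx_f2],
                        "p_tau1": p_f,
                        "p_tau2": p_f2,
                        "loglik": fit_dir.loglik,
                    }
                )
        hio.write_tsv(outdir / "fits.tsv", pd.DataFrame(fits_summary), chash)
    except Exception as exc:  # noqa: BLE001
        raise StageError("fits", exc) from exc

    try:
        stage("enrichment")
        rows = []
        for name, idx in panels.items():
            sub = panel_all.subset(idx)
            base = results[f"dgblup:{name}"] if f"dgblup:{name}" in results else results[f"gblup:{name}"]
            for feature in config.features:
                bins = annoset.bins[feature]
                add_k = binned_kinships(markers.X[idx], bins, tag="additive", prefix="G:")
                dom_k = (
                    binned_kinships(markers.Z[idx], bins, tag="dominance", prefix="D:")
                    if sub.n_testers >= 2
                    else []
                )
                fit_e = arch.fit_enrichment(sub, add_k, dom_k)
                stat, p = lrt(fit_e, base)
                enr = arch.snp_enrichment(fit_e)
                for comp, value in enr.items():
                    rows.append(
                        {"panel": name, "feature": feature, "component": comp,
                         "enrichment": value, "lrt_p": p}
                    )
        hio.write_tsv(outdir / "enrichment.tsv", pd.DataFrame(rows), chash)
        results["enrichment_table"] = pd.DataFrame(rows)
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrichment", exc) from exc

    if config.run_gwas:
        try:
            stage("gwas")
            name = list(panels)[0]
            idx = panels[name]
            sub = panel_all.subset(idx)
            sub_markers = markers.subset_hybrids(idx)
            Gi = additive_kinship(sub_markers.X)
            res = gwas_mod.emmax_scan(sub.g, sub.q_design(), sub_markers, [Gi])
            res.table["q"] = gwas_mod.bh_fdr(res.table["p_beta"].to_numpy())
            pips = simulate_pips(np.zeros(sub_markers.m), seed=config.seed)
            windows = gwas_mod.wpip(
                pips, sub_markers.snps["chrom"].to_numpy(), sub_markers.snps["pos"].to_numpy()
            )
            qtl = gwas_mod.select_high_confidence(res.table, windows)
            hio.write_tsv(outdir / "gwas.tsv", res.table, chash)
            hio.write_tsv(outdir / "gwas_windows.tsv", windows, chash)
            hio.write_tsv(outdir / "gwas_qtl.tsv", qtl, chash)
        except Exception as exc:  # noqa: BLE001
            raise StageError("gwas", exc) from exc

    if config.run_prediction:
        try:
            stage("prediction")
            # leave-one-population-out within the most structured panel
            name = max(panels, key=lambda k: crosses.loc[panels[k], "population"].nunique())
            idx = panels[name]
            sub = panel_all.subset(idx)
            sub_markers = markers.subset_hybrids(idx)
            if sub.table["population"].nunique() >= 3:
                report = leave_one_population_out(
                    sub,
                    sub_markers,
                    pc_model,
                    lambda p, m_: arch.fit_gblup(p, additive_kinship(m_.X)),
                )
                hio.write_tsv(outdir / "prediction_lopo.tsv", report.to_frame().reset_index(), chash)
                results["lopo"] = report
        except Exception as exc:  # noqa: BLE001
            raise StageError("prediction", exc) from exc

    stage("reports")
    hio.write_json(outdir / "manifest.json", manifest)
    results["manifest"] = manifest
    return results


def simulate_to_dir(sim_config: SimulationConfig, outdir) -> RunConfig:
    """Simulate a study, write its files, and return a matching RunConfig."""
    study = simulate_study(sim_config)
    paths = hio.write_study(study, outdir)
    return RunConfig(
        vcf=str(paths["vcf"]),
        crosses=str(paths["crosses"]),
        phenotypes=str(paths["phenotypes"]),
        gff3=str(paths["gff3"]),
        bed=str(paths["bed"]),
        gerp=str(paths["gerp"]),
        genetic_map=str(paths["map"]),
        imputation_r2=str(paths["scores"]),
        outdir=str(Path(outdir) / "results"),
        seed=sim_config.seed,
    )
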