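"""Readers and writers for the study's file formats.

Genotypes travel as uncompressed VCF (GT only), pedigree/phenotypes/maps as
tab-separated tables, gene models as GFF3, open-chromatin peaks as BED, and
ground truth / fitted models as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MarkerSet


def write_vcf(path, snps: pd.DataFrame, counts: np.ndarray, sample_ids) -> None:
    """Write homozygous allele counts ({0, 2}; 1 allowed for hybrids) as VCF.

    The counted (minor) allele is written as ALT, so allele counts round-trip
    as ALT dosages.
    """
    counts = np.asarray(counts)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j, row in enumerate(snps.itertuples(index=False)):
            gts = "\t".join(gt_map[int(c)] for c in counts[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a VCF into (snp table, ALT allele-count matrix, sample ids)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
    samples = list(vcf.samples)
    rows, counts = [], []
    for v in vcf:
        rows.append({"snp_id": v.ID, "chrom": v.CHROM, "pos": v.POS})
        gt = v.gt_types.astype(np.int8)
        if np.any(gt == 3):
            raise ValueError(f"missing genotype at {v.ID}; impute upstream")
        counts.append(gt)
    return pd.DataFrame(rows), np.array(counts, dtype=np.int8).T, samples


def write_gff3(path, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tsim\tgene\t{row.start}\t{row.end}\t.\t+\t.\tID={row.gene_id}\n"
            )


def write_bed(path, peaks: pd.DataFrame) -> None:
    """Write 1-based closed intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\n")


def write_tsv(path, df: pd.DataFrame, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_kernel_tsv(path, kernel, ids) -> None:
    """Write a relationship matrix as TSV with hybrid ids on both axes."""
    df = pd.DataFrame(kernel.K, index=ids, columns=ids)
    df.index.name = "hybrid_id"
    df.to_csv(path, sep="\t")


def read_kernel_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.columns)


def write_json(path, obj, config_hash: str | None = None) -> None:
    if config_hash is not None and isinstance(obj, dict):
        obj = {"config_hash": config_hash, **obj}

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def write_study(study, outdir) -> dict[str, Path]:
    """Write a simulated study to disk in its interchange formats.

    Returns a mapping of artifact name to path: parental VCF, cross table,
    phenotypes, gene GFF3, peak BED, GERP and genetic-map TSVs, imputation
    scores and truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    parent_ids = sorted({*study.panels["all"].table["female_id"], *study.panels["all"].table["tester_id"]})
    # rebuild the parent count matrix in a stable order
    lookup = {fid: study.founders.counts[i] for i, fid in enumerate(study.founders.ids)}
    counts = []
    table = study.panels["all"].table
    hyb_by_female = {r.female_id: i for i, r in enumerate(table.itertuples(index=False))}
    X = study.markers["all"].X
    for pid in parent_ids:
        if pid in lookup:
            counts.append(lookup[pid])
        else:
            # homozygous RIL: recover counts from any hybrid it parents
            i = hyb_by_female[pid]
            t = table.iloc[i]["tester_id"]
            counts.append((2 * X[i] - lookup[t]).astype(np.int8))
    counts = np.array(counts).T  # snps x parents

    paths["vcf"] = outdir / "parents.vcf"
    write_vcf(paths["vcf"], study.snps, counts.T, parent_ids)
    paths["crosses"] = outdir / "crosses.tsv"
    write_tsv(paths["crosses"], table)
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    write_tsv(
        paths["phenotypes"],
        pd.DataFrame({"hybrid_id": table["hybrid_id"], "g": study.panels["all"].g}),
    )
    paths["gff3"] = outdir / "genes.gff3"
    write_gff3(paths["gff3"], study.annotation_inputs.genes)
    paths["bed"] = outdir / "peaks.bed"
    write_bed(paths["bed"], study.annotation_inputs.peaks)
    paths["gerp"] = outdir / "gerp.tsv"
    write_tsv(
        paths["gerp"],
        pd.DataFrame({"snp_id": study.snps["snp_id"], "gerp": study.annotation_inputs.gerp}),
    )
    paths["map"] = outdir / "genetic_map.tsv"
    write_tsv(paths["map"], study.genetic_map)
    paths["scores"] = outdir / "imputation_r2.tsv"
    write_tsv(
        paths["scores"],
        pd.DataFrame({"snp_id": study.snps["snp_id"], "r2": study.imputation_r2}),
    )
    paths["truth"] = outdir / "truth.json"
    write_json(paths["truth"], study.truth.to_dict())
    return paths


def markers_from_files(vcf_path, cross_path) -> tuple[MarkerSet, pd.DataFrame]:
    """Reconstruct a hybrid MarkerSet from a parental VCF and a cross table."""
    from .genotypes import build_hybrid_markers
    from .panel import read_cross_table

    snps, counts, samples = read_vcf(vcf_path)
    snps = snps.assign(minor="C", major="A", ref_freq=np.nan)
    parent_counts = {sid: counts[i] for i, sid in enumerate(samples)}
    crosses = read_cross_table(cross_path)
    return build_hybrid_markers(parent_counts, crosses, snps), crosses
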