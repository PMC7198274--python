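"""Synthetic hybrid panels with known genetic architecture.

The generator emulates the two kinds of testcross panels the models target:

* a diverse inbred panel with subpopulation structure, crossed to two tester
  lines from different heterotic groups ("diversity panel"), and
* biparental RIL populations sharing one common parent, crossed to a single
  tester ("NAM-like panel"),

plus per-SNP functional features (gene proximity, recombination rate,
chromatin openness, MAF, GERP) and phenotypes composed of bin-enriched
additive effects, polygenic dominance, directional inbreeding effects,
panel-specific polygenic deviations and i.i.d. noise.  Every random draw
derives from one master seed, so identical configurations yield identical
output, and the full ground truth (effects, realized component variances)
is returned for recovery tests.

Effect scalings mirror the estimation models exactly: additive effects are
drawn per SNP with total variance sigma_u^2 relative to the noncentered
kernel G = XX'/m (i.e. a_j ~ N(0, sigma_u^2/m) under a uniform
architecture), and likewise for dominance and panel-specific terms, so a
REML fit of the matching model is estimating the very parameters used to
generate the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, annotate
from .genotypes import (
    MarkerSet,
    build_hybrid_markers,
    fit_reference_pcs,
    genomic_inbreeding,
    PcModel,
)
from .panel import HybridPanel

_STAGE_FOUNDERS = 1
_STAGE_RILS = 2
_STAGE_ANNOT = 3
_STAGE_PHENO = 4
_STAGE_PLOTS = 5
_STAGE_PIPS = 6
_STAGE_SCORES = 7


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage child generator from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic hybrid experiment.

    Default scale is a desk-size analogue of a hybrid testcross study:
    5,000 SNPs on 10 chromosomes, ~500 hybrids per panel, trait simulated in
    SD units (residual variance 1).
    """

    n_founders: int = 260
    n_subpops: int = 3
    divergence: float = 0.15  # Fst-like Balding-Nichols parameter
    family_size: int = 6  # founders per pedigree family within a subpopulation
    family_divergence: float = 0.4  # Balding-Nichols parameter of families within subpops
    m_snps: int = 5000
    n_chromosomes: int = 10
    chrom_length_bp: int = 50_000_000
    testers: int = 2
    n_ril_populations: int = 6
    rils_per_population: int = 80
    variance_spec: dict = field(
        default_factory=lambda: {
            "additive": 1.0,
            "dominance": 0.5,
            "panel": 0.0,
            "structure": 0.3,
            "residual": 1.0,
        }
    )
    inbreeding_effects: tuple = (0.0, 0.0)  # (tau1, tau2), trait SD per unit F
    enrichment_spec: dict = field(default_factory=dict)  # bin label -> fold
    enrichment_feature: str = "gene"
    recomb_rate_cm_per_mb: float = 1.5
    gene_proximal_fraction: float = 0.35
    mnase_open_fraction: float = 0.15
    mnase_gene_association: float = 0.7
    gerp_positive_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must lie in [0, 1)")
        if self.m_snps < 10 * self.n_chromosomes:
            raise ValueError("need at least 10 SNPs per chromosome")
        if self.testers not in (1, 2):
            raise ValueError("testers must be 1 or 2")
        for name, v in self.variance_spec.items():
            if v < 0:
                raise ValueError(f"variance {name!r} must be nonnegative")


@dataclass
class Founders:
    """Fully homozygous founder inbreds with subpopulation labels."""

    snps: pd.DataFrame  # snp_id, chrom, pos, ref_freq (minor-allele, reference subset)
    counts: np.ndarray  # n_founders x m, minor-allele counts in {0, 2}
    subpop: np.ndarray  # per-founder subpopulation index
    ids: list[str]
    reference_idx: np.ndarray  # rows forming the reference panel (PC/pi stand-in)

    @property
    def ref_freqs(self) -> np.ndarray:
        return self.snps["ref_freq"].to_numpy()


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside simulated phenotypes."""

    true_additive_effects: np.ndarray
    true_dominance_effects: np.ndarray
    true_variances: dict
    realized_variances: dict
    true_tau: tuple
    true_bin_enrichments: dict
    components: dict  # component name -> per-hybrid vector
    true_genetic_values: np.ndarray

    def to_dict(self) -> dict:
        return {
            "true_variances": self.true_variances,
            "realized_variances": self.realized_variances,
            "true_tau": list(self.true_tau),
            "true_bin_enrichments": self.true_bin_enrichments,
        }


def simulate_genetic_map(config: SimulationConfig, points_per_chrom: int = 41) -> pd.DataFrame:
    """Deterministic smooth genetic map (chrom, pos, cm).

    The local rate oscillates around the configured average so recombination
    tertiles are non-degenerate; the map is shared by RIL meiosis simulation
    and the recombination-rate annotation.
    """
    rows = []
    L = config.chrom_length_bp
    for c in range(config.n_chromosomes):
        bp = np.linspace(1, L, points_per_chrom)
        rate = config.recomb_rate_cm_per_mb * (
            1.0 + 0.8 * np.sin(2.0 * np.pi * 2.0 * bp / L + 0.7 * c)
        )
        gaps = np.diff(bp) / 1e6
        cm = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * gaps)])
        rows.append(pd.DataFrame({"chrom": str(c + 1), "pos": bp.astype(np.int64), "cm": cm}))
    return pd.concat(rows, ignore_index=True)


def simulate_founders(config: SimulationConfig) -> Founders:
    """Simulate homozygous founder inbreds under a Balding-Nichols model.

    Ancestral frequencies are Uniform(0.05, 0.95); each subpopulation draws
    its frequencies from a Beta distribution centred on the ancestral value
    with divergence ``F`` (the Fst-like parameter).  Within a subpopulation,
    founders come in pedigree families (``family_size`` lines per family)
    whose frequencies diverge further from the subpopulation by
    ``family_divergence`` — germplasm collections contain many closely
    related accessions, and this relatedness is what gives the panel its
    kinship contrast.  Each founder is homozygous at every locus.  Alleles
    are re-oriented so the counted allele is the minor allele in a
    designated reference subset of founders (the stand-in for an external
    reference panel), and SNPs monomorphic in that subset are dropped.
    """
    rng = _stage_rng(config.seed, _STAGE_FOUNDERS)
    m = config.m_snps
    n = config.n_founders
    k = config.n_subpops
    per_chrom = m // config.n_chromosomes
    chroms, positions = [], []
    for c in range(config.n_chromosomes):
        n_c = per_chrom + (1 if c < m % config.n_chromosomes else 0)
        pos = np.sort(rng.choice(np.arange(1, config.chrom_length_bp), size=n_c, replace=False))
        chroms.append(np.full(n_c, str(c + 1)))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)

    anc = rng.uniform(0.05, 0.95, size=m)
    subpop = np.arange(n) % k
    counts = np.empty((n, m), dtype=np.int8)
    Fst = config.divergence
    Ffam = config.family_divergence
    for s in range(k):
        if Fst > 0:
            a = anc * (1.0 - Fst) / Fst
            b = (1.0 - anc) * (1.0 - Fst) / Fst
            p_s = rng.beta(a, b)
        else:
            p_s = anc
        rows = np.flatnonzero(subpop == s)
        for start in range(0, len(rows), max(config.family_size, 1)):
            fam_rows = rows[start : start + max(config.family_size, 1)]
            if Ffam > 0:
                pc = np.clip(p_s, 1e-6, 1 - 1e-6)
                p_f = rng.beta(pc * (1 - Ffam) / Ffam, (1 - pc) * (1 - Ffam) / Ffam)
            else:
                p_f = p_s
            counts[fam_rows] = 2 * (rng.random((len(fam_rows), m)) < p_f).astype(np.int8)

    ids = [f"F{i:03d}" for i in range(n)]
    reference_idx = np.arange(n)[::3]  # designated reference subset, all subpops
    ref_freq = counts[reference_idx].mean(axis=0) / 2.0
    flip = ref_freq > 0.5
    counts[:, flip] = 2 - counts[:, flip]
    ref_freq = np.where(flip, 1.0 - ref_freq, ref_freq)
    keep = (ref_freq > 0.0) & (ref_freq < 1.0)

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp_{c}_{p}" for c, p in zip(chrom[keep], pos[keep])],
            "chrom": chrom[keep],
            "pos": pos[keep],
            "minor": "B",
            "major": "A",
            "ref_freq": ref_freq[keep],
        }
    )
    return Founders(
        snps=snps,
        counts=counts[:, keep],
        subpop=subpop,
        ids=ids,
        reference_idx=reference_idx,
    )


def simulate_ril_population(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    n_rils: int,
    genetic_map: pd.DataFrame,
    snps: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Homozygous RIL genotypes as doubled recombinant gametes.

    Each RIL is a mosaic of the two parental genomes from one simulated
    meiosis of their F1: crossover counts per chromosome are Poisson with
    mean the chromosome's map length in Morgans, crossover locations are
    uniform on the genetic scale, and the resulting gamete is doubled to
    homozygosity.  Every RIL locus therefore carries one of the two parental
    alleles.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    if np.any(parent_a == 1) or np.any(parent_b == 1):
        raise ValueError("RIL parents must be homozygous")
    m = len(snps)
    out = np.empty((n_rils, m), dtype=np.int8)
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy(dtype=float)
    for c, grp in genetic_map.groupby("chrom", sort=False):
        sel = np.flatnonzero(chrom_arr == c)
        if len(sel) == 0:
            continue
        bp = grp["pos"].to_numpy(dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        snp_cm = np.interp(pos_arr[sel], bp, cm)
        total_cm = cm[-1]
        for i in range(n_rils):
            n_cx = rng.poisson(total_cm / 100.0)
            start = rng.integers(0, 2)
            if n_cx == 0:
                origin = np.full(len(sel), start)
            else:
                cx = np.sort(rng.uniform(0.0, total_cm, size=n_cx))
                origin = (start + np.searchsorted(cx, snp_cm, side="right")) % 2
            out[i, sel] = np.where(origin == 0, parent_a[sel], parent_b[sel])
    return out


@dataclass
class AnnotationInputs:
    """Raw simulated annotation sources (writable to GFF3/BED/TSV)."""

    genes: pd.DataFrame  # chrom, start, end, gene_id (1-based closed)
    peaks: pd.DataFrame  # chrom, start, end (1-based closed)
    gerp: np.ndarray
    genetic_map: pd.DataFrame


def simulate_annotations(
    snps: pd.DataFrame, config: SimulationConfig
) -> tuple[AnnotationInputs, AnnotationSet]:
    """Simulate functional-feature inputs and compute their bin assignments.

    Gene intervals are placed uniformly with density targeting the configured
    proximal-SNP fraction; MNase peaks sit near genes with the configured
    association probability (association 0 means uniform placement); GERP
    scores are a two-sided exponential mixture with the configured positive
    fraction; MAF is the reference-panel frequency; the recombination map is
    the deterministic smooth map shared with RIL meiosis.
    """
    rng = _stage_rng(config.seed, _STAGE_ANNOT)
    L = config.chrom_length_bp
    gene_len_mean = 4000.0
    zone = gene_len_mean + 2000.0  # gene body plus 1-kb flanks
    genes_rows = []
    peaks_rows = []
    chrom_names = [str(c + 1) for c in range(config.n_chromosomes)]
    n_genes = int(round(-np.log(max(1.0 - config.gene_proximal_fraction, 1e-12)) * L / zone))
    peak_len_mean = 10_000.0
    n_peaks = int(round(config.mnase_open_fraction * L / peak_len_mean))
    for chrom in chrom_names:
        if config.gene_proximal_fraction > 0 and n_genes > 0:
            starts = rng.integers(1, L, size=n_genes)
            lengths = rng.lognormal(np.log(gene_len_mean), 0.4, size=n_genes).astype(np.int64)
            genes_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": np.minimum(starts + lengths, L),
                        "gene_id": [f"gene_{chrom}_{i}" for i in range(n_genes)],
                    }
                )
            )
        if n_peaks > 0:
            widths = rng.integers(5000, 15001, size=n_peaks)
            near_gene = rng.random(n_peaks) < config.mnase_gene_association
            centers = rng.integers(1, L, size=n_peaks)
            if genes_rows and near_gene.any():
                g = genes_rows[-1]
                anchor = rng.integers(0, len(g), size=int(near_gene.sum()))
                jitter = rng.integers(-2000, 2001, size=int(near_gene.sum()))
                centers[near_gene] = np.clip(
                    g["start"].to_numpy()[anchor] + jitter, 1, L
                )
            starts = np.clip(centers - widths // 2, 1, L)
            peaks_rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": np.minimum(starts + widths, L)}
                )
            )
    genes = (
        pd.concat(genes_rows, ignore_index=True)
        if genes_rows
        else pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
    )
    peaks = (
        pd.concat(peaks_rows, ignore_index=True)
        if peaks_rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    m = len(snps)
    positive = rng.random(m) < config.gerp_positive_fraction
    gerp = np.where(positive, rng.exponential(1.0, m), -rng.exponential(1.0, m))
    genetic_map = simulate_genetic_map(config)
    inputs = AnnotationInputs(genes=genes, peaks=peaks, gerp=gerp, genetic_map=genetic_map)
    annoset = annotate(
        snps,
        genes=genes,
        peaks=peaks,
        genetic_map=genetic_map,
        maf=snps["ref_freq"].to_numpy(),
        gerp=gerp,
    )
    return inputs, annoset


def simulate_phenotypes(
    panel: HybridPanel,
    markers: MarkerSet,
    config: SimulationConfig,
    bins: np.ndarray | None = None,
) -> tuple[np.ndarray, SimulationTruth]:
    """Simulate genotype means with the generative mirror of the fitted models.

    g = structure + sum_bins X_k a_k + Z d + tau1 F + tau2 F^2
        + panel-specific polygenic deviation + residual

    Variance targets are on the phenotypic scale: each genetic component is
    rescaled so that its realized sample variance — orthogonal to the fixed
    structure design [1 P], the part the genomic models can see — equals its
    target exactly.  Relative per-SNP effect variances (the enrichment
    folds from ``config.enrichment_spec`` applied to ``bins``) are preserved
    by the global rescaling; dominance effects are exchangeable across SNPs;
    panel deviations redraw a polygenic effect independently within each
    panel; the structure term acts on the panel's projected PCs.
    """
    rng = _stage_rng(config.seed, _STAGE_PHENO)
    spec = dict(config.variance_spec)
    for required in ("additive", "dominance", "residual"):
        if required not in spec:
            raise ValueError(f"variance_spec is missing the {required!r} component")
    s_add = spec["additive"]
    s_dom = spec["dominance"]
    s_panel = spec.get("panel", 0.0)
    s_struct = spec.get("structure", 0.0)
    s_res = spec["residual"]
    X = markers.X.astype(float)
    Z = markers.Z.astype(float)
    n, m = X.shape

    # projector removing the structure-aligned part: variance targets refer
    # to the component variance orthogonal to the panel indicators and PCs
    # (the fixed designs of the estimation models)
    panel_labels = panel.table["panel"].to_numpy()
    E = np.column_stack(
        [(panel_labels == lab).astype(float) for lab in pd.unique(panel_labels)]
    )
    Wq = E if panel.pcs is None else np.column_stack([E, panel.pcs])
    Hq = Wq @ np.linalg.solve(Wq.T @ Wq, Wq.T)

    def _adj_var(vec: np.ndarray) -> float:
        r = vec - Hq @ vec
        return float(r @ r) / n

    folds = np.ones(m)
    if bins is not None and config.enrichment_spec:
        bins = np.asarray(bins)
        for label, fold in config.enrichment_spec.items():
            folds[bins == label] = float(fold)
    v_snp = s_add * folds / folds.sum()
    a = rng.normal(0.0, 1.0, m) * np.sqrt(v_snp)
    d = rng.normal(0.0, 1.0, m) * np.sqrt(s_dom / m)

    u = X @ a
    if s_add > 0 and _adj_var(u) > 0:
        scale = np.sqrt(s_add / _adj_var(u))
        a, u = a * scale, u * scale
    w = Z @ d
    if s_dom > 0 and _adj_var(w) > 0:
        scale = np.sqrt(s_dom / _adj_var(w))
        d, w = d * scale, w * scale
    components = {"additive": u, "dominance": w}

    struct = np.zeros(n)
    if s_struct > 0 and panel.pcs is not None:
        pcs = np.asarray(panel.pcs, dtype=float)
        sd = pcs.std(axis=0)
        sd[sd == 0] = 1.0
        gamma = rng.normal(0.0, np.sqrt(s_struct / pcs.shape[1]), pcs.shape[1])
        struct = (pcs / sd) @ gamma
        if np.var(struct) > 0:
            struct = struct * np.sqrt(s_struct / np.var(struct))
    components["structure"] = struct

    tau1, tau2 = config.inbreeding_effects
    inb = np.zeros(n)
    if (tau1 != 0.0 or tau2 != 0.0) and panel.F is not None:
        inb = tau1 * panel.F + tau2 * panel.F**2
    components["inbreeding"] = inb

    dev = np.zeros(n)
    if s_panel > 0:
        labels = panel.table["panel"].to_numpy()
        for lab in pd.unique(labels):
            a1 = rng.normal(0.0, np.sqrt(s_panel / m), m)
            rows = labels == lab
            dev[rows] = X[rows] @ a1
        if _adj_var(dev) > 0:
            dev = dev * np.sqrt(s_panel / _adj_var(dev))
    components["panel"] = dev

    resid = rng.normal(0.0, np.sqrt(s_res), n) if s_res > 0 else np.zeros(n)
    components["residual"] = resid

    g = struct + u + w + inb + dev + resid
    realized = {name: _adj_var(vec) for name, vec in components.items()}
    # the structure term lives inside the span of [E P]; its raw variance is
    # the meaningful number
    realized["structure"] = float(np.var(struct))
    enrich = {}
    if bins is not None:
        bins = np.asarray(bins)
        overall = float(np.mean(a**2))
        for label in pd.unique(bins):
            enrich[str(label)] = float(np.mean(a[bins == label] ** 2) / overall)
    truth = SimulationTruth(
        true_additive_effects=a,
        true_dominance_effects=d,
        true_variances={
            "additive": s_add,
            "dominance": s_dom,
            "panel": s_panel,
            "structure": s_struct,
            "residual": s_res,
        },
        realized_variances=realized,
        true_tau=(tau1, tau2),
        true_bin_enrichments=enrich,
        components=components,
        true_genetic_values=u + w + dev,
    )
    return g, truth


def simulate_plot_data(
    genotype_values: np.ndarray,
    n_envs: int,
    env_variance: float,
    error_variance: float,
    seed: int,
    genotype_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Unreplicated-within-environment plot records: y = g_i + env_j + e_ij."""
    if n_envs < 2:
        raise ValueError("need at least two environments")
    rng = _stage_rng(seed, _STAGE_PLOTS)
    g = np.asarray(genotype_values, dtype=float)
    n = len(g)
    if genotype_ids is None:
        genotype_ids = [f"H{i:04d}" for i in range(n)]
    env_eff = rng.normal(0.0, np.sqrt(env_variance), n_envs) if env_variance > 0 else np.zeros(n_envs)
    rows = []
    for j in range(n_envs):
        e = rng.normal(0.0, np.sqrt(error_variance), n) if error_variance > 0 else np.zeros(n)
        rows.append(
            pd.DataFrame(
                {"genotype": list(genotype_ids), "env": f"env{j}", "y": g + env_eff[j] + e}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_pips(
    additive_effects: np.ndarray,
    seed: int,
    n_top: int = 10,
    top_range: tuple[float, float] = (0.6, 0.95),
    background: float = 0.02,
) -> np.ndarray:
    """Pseudo posterior inclusion probabilities concentrated at causal SNPs.

    Stands in for the output of a sparse Bayesian mixed model so the WPIP
    aggregation and QTL-selection path can be exercised with known truth:
    the ``n_top`` largest |effects| receive high PIPs, everything else noise
    below ``background``.
    """
    rng = _stage_rng(seed, _STAGE_PIPS)
    a = np.abs(np.asarray(additive_effects, dtype=float))
    pips = rng.uniform(0.0, background, len(a))
    top = np.argsort(a)[::-1][:n_top]
    pips[top] = rng.uniform(*top_range, size=len(top))
    return pips


# ------------------------------------------------------------ full study


@dataclass
class StudyData:
    """A complete simulated two-panel hybrid study."""

    config: SimulationConfig
    founders: Founders
    genetic_map: pd.DataFrame
    pc_model: PcModel
    markers: dict  # panel name -> MarkerSet ("ames", "nam", "all")
    panels: dict  # panel name -> HybridPanel, with g filled in
    annotation_inputs: AnnotationInputs
    annotations: AnnotationSet
    truth: SimulationTruth
    imputation_r2: np.ndarray
    tester_ids: list[str]

    @property
    def snps(self) -> pd.DataFrame:
        return self.founders.snps


def simulate_study(
    config: SimulationConfig, panels: Sequence[str] = ("ames", "nam")
) -> StudyData:
    """Simulate a full study: founders, panels, annotations, phenotypes.

    The diversity panel ("ames") crosses every non-tester founder to each
    tester; the NAM-like panel crosses RILs from biparental populations
    (common parent x diverse parents) to the tester shared between panels,
    plus the non-common parents themselves as check hybrids so the two
    panels share hybrids.  Phenotypes are simulated jointly on all panels so
    that main-effect architecture is shared and panel deviations are
    panel-specific.
    """
    founders = simulate_founders(config)
    genetic_map = simulate_genetic_map(config)
    snps = founders.snps
    parent_counts = {fid: founders.counts[i] for i, fid in enumerate(founders.ids)}

    # testers from different subpopulations; the last one is shared with NAM
    tester_ids = [founders.ids[0]]
    if config.testers == 2:
        tester_ids.append(founders.ids[np.flatnonzero(founders.subpop == 1 % config.n_subpops)[0]])
    shared_tester = tester_ids[-1]
    reserved = set(tester_ids)

    tables = []
    if "ames" in panels:
        females = [f for f in founders.ids if f not in reserved]
        rows = [
            {
                "hybrid_id": f"{f}x{t}",
                "female_id": f,
                "tester_id": t,
                "panel": "ames",
                "population": f"subpop{founders.subpop[founders.ids.index(f)]}",
            }
            for f in females
            for t in tester_ids
        ]
        tables.append(pd.DataFrame(rows))

    if "nam" in panels:
        rng_ril = _stage_rng(config.seed, _STAGE_RILS)
        candidates = [f for f in founders.ids if f not in reserved]
        common = candidates[0]
        pop_parents = candidates[1 : 1 + config.n_ril_populations]
        rows = []
        for p, parent in enumerate(pop_parents):
            rils = simulate_ril_population(
                parent_counts[common],
                parent_counts[parent],
                config.rils_per_population,
                genetic_map,
                snps,
                rng_ril,
            )
            for r in range(config.rils_per_population):
                rid = f"P{p:02d}R{r:03d}"
                parent_counts[rid] = rils[r]
                rows.append(
                    {
                        "hybrid_id": f"{rid}x{shared_tester}",
                        "female_id": rid,
                        "tester_id": shared_tester,
                        "panel": "nam",
                        "population": f"pop{p:02d}",
                    }
                )
            # the non-common parent crossed to the shared tester: a check
            # hybrid also present in the diversity panel
            rows.append(
                {
                    "hybrid_id": f"{parent}x{shared_tester}",
                    "female_id": parent,
                    "tester_id": shared_tester,
                    "panel": "nam",
                    "population": f"pop{p:02d}",
                }
            )
        tables.append(pd.DataFrame(rows))

    table_all = pd.concat(tables, ignore_index=True)
    markers_all = build_hybrid_markers(parent_counts, table_all, snps)

    ref_counts = founders.counts[founders.reference_idx].astype(float)
    pc_model = fit_reference_pcs(ref_counts, k=3)
    pcs = pc_model.project(markers_all.X)
    F = genomic_inbreeding(markers_all.X, founders.ref_freqs)
    panel_all = HybridPanel(table=table_all, pcs=pcs, F=F)

    annotation_inputs, annoset = simulate_annotations(snps, config)
    bins = annoset.bins.get(config.enrichment_feature) if config.enrichment_spec else None
    g, truth = simulate_phenotypes(panel_all, markers_all, config, bins=bins)
    panel_all.g = g

    rng_scores = _stage_rng(config.seed, _STAGE_SCORES)
    imputation_r2 = rng_scores.beta(40.0, 2.0, markers_all.m)

    markers = {"all": markers_all}
    out_panels = {"all": panel_all}
    labels = table_all["panel"].to_numpy()
    for name in panels:
        idx = np.flatnonzero(labels == name)
        markers[name] = markers_all.subset_hybrids(idx)
        out_panels[name] = panel_all.subset(idx)
    return StudyData(
        config=config,
        founders=founders,
        genetic_map=genetic_map,
        pc_model=pc_model,
        markers=markers,
        panels=out_panels,
        annotation_inputs=annotation_inputs,
        annotations=annoset,
        truth=truth,
        imputation_r2=imputation_r2,
        tester_ids=tester_ids,
    )
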