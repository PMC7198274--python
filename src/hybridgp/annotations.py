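"""Per-SNP functional features and their bin assignments.

Five features are used to partition SNPs into bins for functional-enrichment
variance models: proximity to annotated genes, local recombination rate,
chromatin openness (MNase hypersensitivity peaks), reference-panel minor
allele frequency, and evolutionary constraint (GERP score).  Each feature's
bins partition the SNP set exhaustively and exclusively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline


class DegenerateBinsError(ValueError):
    """Tertile cut-points collapsed because the values are all equal."""


@dataclass
class AnnotationSet:
    """Per-SNP feature values and bin labels.

    ``features`` has one row per SNP with columns ``gene_distance`` (bp, 0 if
    inside a gene), ``recomb_rate`` (cM/Mb), ``mnase_open`` (bool), ``maf``
    and ``gerp``.  ``bins`` maps a feature name to a per-SNP label vector.
    """

    features: pd.DataFrame
    bins: dict[str, np.ndarray] = field(default_factory=dict)

    def bin_labels(self, feature: str) -> np.ndarray:
        return self.bins[feature]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + 1:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def gene_distances(
    snp_chrom: np.ndarray, snp_pos: np.ndarray, genes: pd.DataFrame
) -> np.ndarray:
    """Distance (bp) from each SNP to the nearest gene interval; 0 if inside.

    ``genes`` needs columns ``chrom``, ``start``, ``end`` on 1-based closed
    coordinates.  Strand is irrelevant.  SNPs on chromosomes without any
    annotated gene get an infinite distance (with a warning).
    """
    snp_chrom = np.asarray(snp_chrom)
    snp_pos = np.asarray(snp_pos)
    dist = np.full(len(snp_pos), np.inf)
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    missing = []
    for chrom in pd.unique(snp_chrom):
        sel = snp_chrom == chrom
        if chrom not in by_chrom:
            missing.append(str(chrom))
            continue
        g = by_chrom[chrom]
        starts, ends = _merge_intervals(
            g["start"].to_numpy(dtype=np.int64), g["end"].to_numpy(dtype=np.int64)
        )
        pos = snp_pos[sel]
        # nearest merged interval via the insertion point among starts
        j = np.searchsorted(starts, pos, side="right") - 1
        d = np.full(pos.shape, np.inf)
        has_left = j >= 0
        jl = np.clip(j, 0, None)
        # distance to the interval at or left of the SNP (0 if inside)
        d_left = np.where(pos <= ends[jl], 0, pos - ends[jl])
        d[has_left] = d_left[has_left]
        has_right = j + 1 < len(starts)
        jr = np.clip(j + 1, None, len(starts) - 1)
        d_right = np.where(has_right, starts[jr] - pos, np.inf)
        dist[sel] = np.minimum(d, d_right)
    if missing:
        warnings.warn(
            f"no gene annotation on chromosome(s) {', '.join(missing)}; "
            "their SNPs are classified distal",
            stacklevel=2,
        )
    return dist


def assign_gene_proximity(
    snp_chrom: np.ndarray,
    snp_pos: np.ndarray,
    genes: pd.DataFrame,
    threshold_bp: int = 1000,
    inclusive: bool = False,
) -> np.ndarray:
    """Label each SNP ``proximal`` or ``distal`` to annotated genes.

    A SNP is proximal when it lies inside a gene or strictly less than
    ``threshold_bp`` away from a gene start or end (set ``inclusive=True``
    for a <= rule at the exact boundary).
    """
    d = gene_distances(snp_chrom, snp_pos, genes)
    close = d <= threshold_bp if inclusive else d < threshold_bp
    return np.where(close, "proximal", "distal")


def estimate_recombination_rate(
    snp_chrom: np.ndarray,
    snp_pos: np.ndarray,
    genetic_map: pd.DataFrame,
    window_bp: float = 1_000_000,
) -> np.ndarray:
    """Local recombination rate (cM/Mb) at each SNP.

    Per chromosome, the cumulative genetic position (cM) is smoothed against
    physical position with a GCV-penalized spline f, and the rate at SNP
    position s is the finite difference ``f(s + w/2) - f(s - w/2)`` over a
    1-Mb window, divided by the window span in Mb.  Evaluation points are
    clamped to the mapped range at chromosome ends.  Negative estimates
    (smoothing artifacts) are clamped to 0.

    ``genetic_map`` needs columns ``chrom``, ``pos`` (bp), ``cm``.
    """
    snp_chrom = np.asarray(snp_chrom)
    snp_pos = np.asarray(snp_pos, dtype=float)
    rates = np.full(len(snp_pos), np.nan)
    for chrom, grp in genetic_map.groupby("chrom"):
        sel = snp_chrom == chrom
        if not sel.any():
            continue
        grp = grp.sort_values("pos")
        bp = grp["pos"].to_numpy(dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        if len(bp) < 4:
            raise ValueError(f"need >= 4 genetic-map points on chromosome {chrom}")
        if np.ptp(cm) == 0:  # flat map: no recombination anywhere
            rates[sel] = 0.0
            continue
        try:
            f = make_smoothing_spline(bp, cm)
        except ValueError:
            # GCV can fail on noise-free (e.g. perfectly linear) maps; a
            # monotone interpolant is exact in that case
            f = lambda x, bp=bp, cm=cm: np.interp(x, bp, cm)  # noqa: E731
        lo = np.clip(snp_pos[sel] - window_bp / 2, bp[0], bp[-1])
        hi = np.clip(snp_pos[sel] + window_bp / 2, bp[0], bp[-1])
        span_mb = np.maximum(hi - lo, 1.0) / 1e6
        rates[sel] = np.maximum((f(hi) - f(lo)) / span_mb, 0.0)
    return rates


def tertile_bins(values: np.ndarray, labels: tuple[str, str, str] = ("low", "mid", "high")) -> np.ndarray:
    """Three bins split at the first two sample tertiles (type-7 quantiles).

    Intervals are lower-closed on the right boundary: ``v <= t1``,
    ``t1 < v <= t2``, ``t2 < v``.
    """
    values = np.asarray(values, dtype=float)
    t1, t2 = np.quantile(values, [1 / 3, 2 / 3])
    if t1 == t2:
        raise DegenerateBinsError("tertile cut-points coincide; values too concentrated")
    out = np.where(values <= t1, labels[0], np.where(values <= t2, labels[1], labels[2]))
    return out


def maf_bins(maf: np.ndarray) -> np.ndarray:
    """MAF bins at fixed edges: <= 0.01, (0.01, 0.05], > 0.05."""
    maf = np.asarray(maf, dtype=float)
    return np.where(maf <= 0.01, "rare", np.where(maf <= 0.05, "low", "common"))


def gerp_bins(gerp: np.ndarray) -> np.ndarray:
    """Two bins: unconstrained (GERP <= 0) and constrained (GERP > 0)."""
    gerp = np.asarray(gerp, dtype=float)
    return np.where(gerp > 0, "constrained", "unconstrained")


def mnase_bins(
    snp_chrom: np.ndarray, snp_pos: np.ndarray, peaks: pd.DataFrame
) -> np.ndarray:
    """Chromatin bins: ``open`` if the SNP falls in an MNase HS peak, else ``dense``.

    ``peaks`` uses 1-based closed coordinates (columns ``chrom``, ``start``,
    ``end``); see :func:`read_bed` for conversion from BED.
    """
    snp_chrom = np.asarray(snp_chrom)
    snp_pos = np.asarray(snp_pos)
    inside = np.zeros(len(snp_pos), dtype=bool)
    for chrom, grp in peaks.groupby("chrom"):
        sel = snp_chrom == chrom
        if not sel.any():
            continue
        starts, ends = _merge_intervals(
            grp["start"].to_numpy(dtype=np.int64), grp["end"].to_numpy(dtype=np.int64)
        )
        j = np.searchsorted(starts, snp_pos[sel], side="right") - 1
        ok = j >= 0
        hit = np.zeros(sel.sum(), dtype=bool)
        hit[ok] = snp_pos[sel][ok] <= ends[j[ok]]
        inside[sel] = hit
    return np.where(inside, "open", "dense")


def annotate(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    genetic_map: pd.DataFrame,
    maf: np.ndarray,
    gerp: np.ndarray,
    proximity_threshold_bp: int = 1000,
) -> AnnotationSet:
    """Compute all five features and their bin assignments for a SNP table."""
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    dist = gene_distances(chrom, pos, genes)
    rate = estimate_recombination_rate(chrom, pos, genetic_map)
    mnase = mnase_bins(chrom, pos, peaks)
    features = pd.DataFrame(
        {
            "gene_distance": dist,
            "recomb_rate": rate,
            "mnase_open": mnase == "open",
            "maf": np.asarray(maf, dtype=float),
            "gerp": np.asarray(gerp, dtype=float),
        }
    )
    bins = {
        "gene": np.where(dist < proximity_threshold_bp, "proximal", "distal"),
        "recomb": tertile_bins(rate),
        "mnase": mnase,
        "maf": maf_bins(maf),
        "gerp": gerp_bins(gerp),
    }
    return AnnotationSet(features=features, bins=bins)


# ---------------------------------------------------------------- file I/O


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Read gene intervals (feature type ``gene``) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    rows = [
        {"chrom": g.seqid, "start": g.start, "end": g.end, "gene_id": g.id}
        for g in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3 file, converting 0-based half-open to 1-based closed."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"] + 1
    return df


def read_genetic_map(path: str) -> pd.DataFrame:
    """Read a TSV genetic map with columns chrom, pos (bp), cm."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = {"chrom", "pos", "cm"}
    if not expected.issubset(df.columns):
        raise ValueError(f"genetic map must have columns {sorted(expected)}")
    return df
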