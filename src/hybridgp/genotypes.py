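"""Hybrid marker matrices, kernels, inbreeding coefficients and PC projection.

Testcross hybrids are crosses between fully homozygous parents, so a hybrid's
genotype at any SNP is determined by its two parents: the minor-allele count
``X`` is the mean of the parental counts and the heterozygosity indicator ``Z``
flags loci where the parents carry different alleles.  The additive genomic
relationship matrix is ``G = XX'/m`` and the dominance relationship matrix is
``D = ZZ'/m``, both built from *noncentered* matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class HeterozygousParentError(ValueError):
    """A parental genotype call was heterozygous (allele count 1)."""


class EmptyMarkerSetError(ValueError):
    """A SNP filter removed every SNP."""


@dataclass
class MarkerSet:
    """Per-SNP metadata plus hybrid allele-count and heterozygosity matrices.

    Attributes
    ----------
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id``, ``chrom``, ``pos`` (1-based),
        ``minor``, ``major`` (allele labels) and ``ref_freq`` (frequency of
        the designated minor allele in the reference panel).
    X : ndarray, shape (n_hybrids, m)
        Minor-allele counts in {0, 1, 2}.
    Z : ndarray, shape (n_hybrids, m)
        Heterozygosity indicators in {0, 1}.
    ids : list of str
        Hybrid identifiers, aligned with the rows of ``X`` and ``Z``.
    """

    snps: pd.DataFrame
    X: np.ndarray
    Z: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.shape != self.Z.shape:
            raise ValueError("X and Z must have identical shapes")
        if self.X.shape[1] != len(self.snps):
            raise ValueError("SNP table length does not match matrix columns")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "MarkerSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            snps=self.snps.iloc[idx].reset_index(drop=True),
            X=self.X[:, idx],
            Z=self.Z[:, idx],
        )

    def subset_hybrids(self, idx: np.ndarray) -> "MarkerSet":
        idx = np.asarray(idx)
        return replace(
            self,
            X=self.X[idx],
            Z=self.Z[idx],
            ids=[self.ids[i] for i in idx] if self.ids else [],
        )


@dataclass
class Kernel:
    """A named relationship matrix with provenance.

    ``cols`` records which SNP columns the kernel was built from (None means
    all of them), so that cross-relationship matrices for new individuals can
    be built from exactly the same SNP set and scaling.
    """

    name: str
    K: np.ndarray
    tag: str  # "additive" | "dominance"
    m: int  # number of SNPs it was built from
    bin_label: str = "genome"
    cols: np.ndarray | None = None

    def cross(self, M_new: np.ndarray, M_train: np.ndarray) -> np.ndarray:
        """Cross-kernel ``M_new M_train' / m`` restricted to this kernel's SNPs."""
        M_new = np.asarray(M_new, dtype=float)
        M_train = np.asarray(M_train, dtype=float)
        if self.cols is not None:
            M_new = M_new[:, self.cols]
            M_train = M_train[:, self.cols]
        if M_train.shape[1] != self.m:
            raise ValueError(
                f"kernel {self.name!r} was built from {self.m} SNPs, got {M_train.shape[1]}"
            )
        return (M_new @ M_train.T) / self.m


@dataclass
class PcModel:
    """Reference-panel principal-component model: ``P = (X - M) V``."""

    M: np.ndarray  # column means of the reference panel, length m
    V: np.ndarray  # SNP loadings, m x k
    explained: np.ndarray  # explained-variance shares, length k

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.M) @ self.V


def cross_genotypes(female: np.ndarray, tester: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Infer hybrid genotypes from two homozygous parents.

    Parameters are allele-count vectors (or matrices with parents in rows)
    with entries in {0, 2}.  Returns ``(x, z)``: the hybrid minor-allele count
    ``(female + tester) / 2`` and the heterozygosity indicator, 1 where the
    parental alleles differ.
    """
    female = np.asarray(female)
    tester = np.asarray(tester)
    if np.any(female == 1) or np.any(tester == 1):
        raise HeterozygousParentError("parental genotypes must be homozygous (0 or 2)")
    x = (female + tester) // 2
    z = (female != tester).astype(np.int8)
    return x.astype(np.int8), z


def build_hybrid_markers(
    parent_counts: pd.DataFrame | Mapping[str, np.ndarray],
    crosses: pd.DataFrame,
    snps: pd.DataFrame,
) -> MarkerSet:
    """Build a :class:`MarkerSet` for a panel of testcross hybrids.

    ``parent_counts`` maps parent id -> allele-count vector in {0, 2};
    ``crosses`` needs columns ``hybrid_id``, ``female_id``, ``tester_id``.
    """
    n = len(crosses)
    m = len(snps)
    X = np.empty((n, m), dtype=np.int8)
    Z = np.empty((n, m), dtype=np.int8)
    for i, row in enumerate(crosses.itertuples(index=False)):
        X[i], Z[i] = cross_genotypes(parent_counts[row.female_id], parent_counts[row.tester_id])
    return MarkerSet(snps=snps.reset_index(drop=True), X=X, Z=Z, ids=list(crosses["hybrid_id"]))


def filter_snps(
    markers: MarkerSet,
    imputation_r2: np.ndarray,
    set_assignments: Mapping[str, np.ndarray],
    min_r2: float = 0.8,
    min_maf: float = 0.01,
) -> tuple[MarkerSet, pd.DataFrame]:
    """Keep SNPs passing accuracy and MAF thresholds in *every* panel x tester set.

    ``set_assignments`` maps a set label (e.g. ``"ames:T1"``) to the hybrid row
    indices belonging to it.  A SNP is kept only if its imputation-accuracy
    score is >= ``min_r2`` and its within-set minor allele frequency is
    >= ``min_maf`` in every set, which removes SNPs private to any one set.

    Returns the filtered marker set and a per-criterion removal report.
    """
    imputation_r2 = np.asarray(imputation_r2, dtype=float)
    if imputation_r2.min() < 0 or imputation_r2.max() > 1:
        raise ValueError("imputation accuracy scores must lie in [0, 1]")
    keep = imputation_r2 >= min_r2
    n_fail_r2 = int((~keep).sum())
    n_fail_maf = 0
    for label, idx in set_assignments.items():
        freq = markers.X[np.asarray(idx)].mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        fail = maf < min_maf
        n_fail_maf += int((fail & keep).sum())
        keep &= ~fail
    if not keep.any():
        raise EmptyMarkerSetError("all SNPs removed by filters")
    report = pd.DataFrame(
        {
            "criterion": ["imputation_r2", "maf_in_some_set", "kept"],
            "n_snps": [n_fail_r2, n_fail_maf, int(keep.sum())],
        }
    )
    return markers.subset_snps(keep), report


def additive_kinship(
    X: np.ndarray, name: str = "G", bin_label: str = "genome", cols: np.ndarray | None = None
) -> Kernel:
    """``G = XX'/m`` from the noncentered minor-allele-count matrix."""
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    return Kernel(name=name, K=(X @ X.T) / m, tag="additive", m=m, bin_label=bin_label, cols=cols)


def dominance_kinship(
    Z: np.ndarray, name: str = "D", bin_label: str = "genome", cols: np.ndarray | None = None
) -> Kernel:
    """``D = ZZ'/m`` from the noncentered heterozygosity matrix."""
    Z = np.asarray(Z, dtype=float)
    m = Z.shape[1]
    return Kernel(name=name, K=(Z @ Z.T) / m, tag="dominance", m=m, bin_label=bin_label, cols=cols)


def binned_kinships(
    M: np.ndarray, bins: Sequence, tag: str = "additive", prefix: str = ""
) -> list[Kernel]:
    """Per-bin kernels ``K_k = M_k M_k' / m_k`` for a partition of the SNPs.

    ``bins`` is a per-SNP label vector; empty bins are impossible by
    construction, but a bin with a single label covering everything simply
    reproduces the genome-wide kernel.
    """
    M = np.asarray(M, dtype=float)
    bins = np.asarray(bins)
    if len(bins) != M.shape[1]:
        raise ValueError("bin labels must align with SNP columns")
    kernels = []
    for label in pd.unique(bins):
        cols = np.flatnonzero(bins == label)
        sub = M[:, cols]
        builder = additive_kinship if tag == "additive" else dominance_kinship
        kernels.append(builder(sub, name=f"{prefix}{label}", bin_label=str(label), cols=cols))
    return kernels


def genomic_inbreeding(X: np.ndarray, ref_freqs: np.ndarray) -> np.ndarray:
    """Genomic inbreeding relative to a reference panel.

    ``F_i = sum_j (x_ij - 2 pi_j)^2 / sum_j 2 pi_j (1 - pi_j)  -  1``

    where ``pi_j`` is the reference-panel frequency of the counted allele.
    F measures excess homozygosity: 0 on average under Hardy-Weinberg at the
    reference frequencies, -1 when every locus sits at its expected dosage.
    """
    X = np.asarray(X, dtype=float)
    pi = np.asarray(ref_freqs, dtype=float)
    if np.any((pi <= 0) | (pi >= 1)):
        raise ZeroDivisionError(
            "reference frequencies must lie strictly in (0, 1); filter fixed SNPs first"
        )
    denom = np.sum(2.0 * pi * (1.0 - pi))
    return np.sum((X - 2.0 * pi) ** 2, axis=1) / denom - 1.0


def fit_reference_pcs(ref_counts: np.ndarray, k: int = 3) -> PcModel:
    """Fit SNP loadings for the top-``k`` PCs of a reference inbred panel.

    The model keeps the reference column means ``M`` and the right singular
    vectors ``V`` of the centered matrix, so any panel can be projected onto
    the same axes with ``P = (X - M) V`` without refitting.
    """
    ref = np.asarray(ref_counts, dtype=float)
    if ref.shape[0] < k + 1:
        raise ValueError("reference panel too small for requested number of PCs")
    M = ref.mean(axis=0)
    centered = ref - M
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the centered reference matrix")
    V = Vt[:k].T
    # sign convention: force the largest-|loading| entry of each column positive
    for j in range(k):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    explained = (s[:k] ** 2) / np.sum(s**2)
    return PcModel(M=M, V=V, explained=explained)


def project_pcs(X: np.ndarray, model: PcModel) -> np.ndarray:
    """Project allele counts onto reference PCs: ``P = (X - M) V``."""
    return model.project(X)
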