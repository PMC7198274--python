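"""Cross-panel genomic prediction, validation schemes and accuracy tests.

Prediction for new hybrids combines the fixed part (projected reference
PCs, never refit on the validation panel) with BLUPs obtained through
cross-relationship matrices built from exactly the SNP sets and scalings of
the training kernels (e.g. ``X_new X_train' / m``).  Validation sets are
either whole biparental populations (leave-one-population-out) or random
subsets stratified by tester and population cluster; accuracies are Pearson
correlations tested by one-sample and paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genotypes import MarkerSet, PcModel
from .panel import HybridPanel
from .reml import VarianceComponentFit, blup

__all__ = [
    "PredictionReport",
    "predict_panel",
    "leave_one_population_out",
    "stratified_partition",
    "accuracy_tests",
]


@dataclass
class PredictionReport:
    """Per-validation-set accuracies and their significance tests."""

    accuracies: pd.Series  # indexed by validation-set label
    mean_accuracy: float
    t_statistic: float
    p_value: float  # one-sample t-test of nonzero mean accuracy
    paired_diff: pd.Series | None = None
    diff_t_statistic: float | None = None
    diff_p_value: float | None = None
    details: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.accuracies.rename("accuracy").to_frame()
        if self.paired_diff is not None:
            df["difference"] = self.paired_diff
        return df


def predict_panel(
    fit: VarianceComponentFit,
    train_markers: MarkerSet,
    new_markers: MarkerSet,
    pc_model: PcModel,
    W_new: np.ndarray | None = None,
) -> np.ndarray:
    """Predict genotype means for a new panel from a trained fit.

    The fixed part uses PCs of the new individuals projected with the
    reference :class:`PcModel`; the random part sums BLUPs through
    cross-kernels restricted to each training kernel's SNP columns.  The two
    marker sets must share SNP identity and minor-allele orientation.
    """
    if train_markers.m != new_markers.m or not np.array_equal(
        train_markers.snps["snp_id"].to_numpy(), new_markers.snps["snp_id"].to_numpy()
    ):
        raise ValueError("training and validation marker sets do not share SNPs")
    if W_new is None:
        pcs_new = pc_model.project(new_markers.X)
        W_new = np.column_stack([np.ones(new_markers.n), pcs_new])
    if W_new.shape[1] != fit.W.shape[1]:
        raise ValueError("new fixed design does not match the training design")
    pred = np.asarray(W_new, dtype=float) @ fit.beta
    cross = {}
    for k in fit.kernels:
        M_new = new_markers.X if k.tag == "additive" else new_markers.Z
        M_train = train_markers.X if k.tag == "additive" else train_markers.Z
        cross[k.name] = k.cross(M_new, M_train)
    for u in blup(fit, cross).values():
        pred = pred + u
    return pred


def leave_one_population_out(
    panel: HybridPanel,
    markers: MarkerSet,
    pc_model: PcModel,
    fit_fn,
    min_size: int = 5,
) -> PredictionReport:
    """Leave-one-population-out cross-validation within a structured panel.

    ``fit_fn(panel_train, markers_train)`` must return a
    :class:`VarianceComponentFit`; for each population the model is trained
    on all the others and the held-out hybrids are predicted, so no hybrid
    ever appears on both sides of a fold.
    """
    pops = panel.table["population"].to_numpy()
    labels = pd.unique(pops)
    if len(labels) < 3:
        raise ValueError("need at least 3 populations for leave-one-population-out")
    accs = {}
    for lab in labels:
        test_idx = np.flatnonzero(pops == lab)
        if len(test_idx) < min_size:
            import warnings

            warnings.warn(f"population {lab!r} has < {min_size} hybrids; skipped", stacklevel=2)
            continue
        train_idx = np.flatnonzero(pops != lab)
        fit = fit_fn(panel.subset(train_idx), markers.subset_hybrids(train_idx))
        pred = predict_panel(
            fit, markers.subset_hybrids(train_idx), markers.subset_hybrids(test_idx), pc_model
        )
        accs[str(lab)] = float(stats.pearsonr(panel.g[test_idx], pred)[0])
    return accuracy_tests(pd.Series(accs))


def stratified_partition(
    pcs: np.ndarray,
    testers: np.ndarray,
    k_clusters: int = 4,
    n_subsets: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Random validation subsets stratified by tester and PC cluster.

    Hybrids are clustered by k-means (k = 4, k-means++ with 10 restarts) on
    their PC coordinates, then dealt into ``n_subsets`` subsets separately
    within every tester x cluster cell, so subset sizes within a cell differ
    by at most one and every subset represents all cells that are large
    enough to spread.
    """
    pcs = np.asarray(pcs, dtype=float)
    testers = np.asarray(testers)
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed)
    clusters = km.fit_predict(pcs)
    rng = np.random.default_rng(seed)
    subsets = np.empty(len(testers), dtype=int)
    for t in pd.unique(testers):
        for c in range(k_clusters):
            cell = np.flatnonzero((testers == t) & (clusters == c))
            if len(cell) == 0:
                continue
            if len(cell) < n_subsets:
                import warnings

                warnings.warn(
                    f"cell tester={t!r}, cluster={c} smaller than {n_subsets}; members spread",
                    stacklevel=2,
                )
            perm = rng.permutation(cell)
            offset = int(rng.integers(n_subsets))
            subsets[perm] = (np.arange(len(perm)) + offset) % n_subsets
    return subsets


def accuracy_tests(
    accuracies: pd.Series, other: pd.Series | None = None
) -> PredictionReport:
    """One-sample t-test of nonzero mean accuracy; optional paired comparison.

    ``other`` must be indexed by the same validation-set labels; the paired
    two-sided t-test uses the per-set differences ``accuracies - other``.
    Identical pairings (zero-variance differences) report p = 1 by
    convention.
    """
    acc = accuracies.astype(float)
    if len(acc) < 3:
        raise ValueError("need at least 3 validation sets")
    t, p = stats.ttest_1samp(acc.to_numpy(), 0.0)
    report = PredictionReport(
        accuracies=acc,
        mean_accuracy=float(acc.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )
    if other is not None:
        other = other.astype(float).reindex(acc.index)
        if other.isna().any():
            raise ValueError("paired accuracies must cover the same validation sets")
        diff = acc - other
        if np.allclose(diff.to_numpy(), diff.to_numpy()[0]) and np.isclose(diff.std(ddof=1), 0.0):
            dt, dp = (0.0, 1.0) if np.isclose(diff.mean(), 0.0) else (np.inf, 1.0)
        else:
            dt, dp = stats.ttest_rel(acc.to_numpy(), other.to_numpy())
        report.paired_diff = diff
        report.diff_t_statistic = float(dt)
        report.diff_p_value = float(dp)
    return report
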