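"""Hybrid panel bookkeeping: pedigree, labels, genotype means, covariates."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class HybridPanel:
    """A panel of testcross hybrids with per-hybrid covariates.

    ``table`` has one row per hybrid with columns ``hybrid_id``,
    ``female_id``, ``tester_id``, ``panel`` and ``population``.  ``g`` holds
    genotype means (entry means of the trait), ``pcs`` the projected
    population principal components, and ``F`` the genomic inbreeding
    coefficients; all aligned with the rows of ``table``.
    """

    table: pd.DataFrame
    g: np.ndarray | None = None
    pcs: np.ndarray | None = None
    F: np.ndarray | None = None

    def __post_init__(self) -> None:
        required = {"hybrid_id", "female_id", "tester_id", "panel", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cross table is missing columns {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_testers(self) -> int:
        return self.table["tester_id"].nunique()

    @property
    def hybrid_ids(self) -> list[str]:
        return list(self.table["hybrid_id"])

    def q_design(self) -> np.ndarray:
        """Fixed design ``Q = [1 P]``: intercept plus the projected PCs."""
        if self.pcs is None:
            raise ValueError("panel has no PC coordinates")
        return np.column_stack([np.ones(self.n), self.pcs])

    def subset(self, idx: np.ndarray) -> "HybridPanel":
        idx = np.asarray(idx)
        return replace(
            self,
            table=self.table.iloc[idx].reset_index(drop=True),
            g=None if self.g is None else self.g[idx],
            pcs=None if self.pcs is None else self.pcs[idx],
            F=None if self.F is None else self.F[idx],
        )


def read_cross_table(path: str) -> pd.DataFrame:
    """Read a TSV cross table (hybrid_id, female_id, tester_id, panel, population)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def panel_design(panel_labels: np.ndarray) -> np.ndarray:
    """One-hot n x k design matrix attributing hybrids to panels."""
    labels = pd.unique(np.asarray(panel_labels))
    return np.column_stack([(panel_labels == lab).astype(float) for lab in labels])
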