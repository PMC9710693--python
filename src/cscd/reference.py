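"""Single-cell reference profile, observed proportions and pseudo-bulk.

The reference profile Z averages the CPM expression of each gene over all
cells of a type, pooled across subjects.  The pseudo-bulk Y = Z P mixes the
reference columns with the per-subject cell-type proportions observed in the
single-cell data; its sample moments define the target distribution the bulk
transformation maps onto.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CPM, SingleCellDataset

SIMPLEX_TOL = 1e-8


@dataclass
class ReferenceProfile:
    """G x C matrix of average relative abundance per cell type."""

    Z: np.ndarray
    cell_types: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.cell_types = tuple(map(str, self.cell_types))
        self.gene_ids = tuple(map(str, self.gene_ids))
        if self.Z.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError("Z shape does not match labels")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("duplicate cell-type labels")
        if not np.all(np.isfinite(self.Z)) or (self.Z.size and self.Z.min() < 0):
            raise ValueError("Z must be non-negative and finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=list(self.gene_ids), columns=list(self.cell_types))

    def subset_genes(self, genes) -> "ReferenceProfile":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from reference: {missing[:5]}")
        idx = [pos[g] for g in genes]
        return ReferenceProfile(self.Z[idx, :], self.cell_types, tuple(genes))


@dataclass
class ProportionMatrix:
    """C x K matrix whose columns live on the unit simplex."""

    P: np.ndarray
    cell_types: tuple[str, ...]
    column_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.cell_types = tuple(map(str, self.cell_types))
        self.column_ids = tuple(map(str, self.column_ids))
        if self.P.shape != (len(self.cell_types), len(self.column_ids)):
            raise ValueError("P shape does not match labels")
        if self.P.size:
            if self.P.min() < -SIMPLEX_TOL:
                raise ValueError("proportions must be non-negative")
            sums = self.P.sum(axis=0)
            if np.max(np.abs(sums - 1.0)) > SIMPLEX_TOL:
                raise ValueError("proportion columns must sum to one")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(self.cell_types), columns=list(self.column_ids))


@dataclass
class PseudoBulk:
    """G x J pseudo-bulk matrix Y = Z P."""

    Y: np.ndarray
    gene_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.gene_ids), len(self.subject_ids)):
            raise ValueError("Y shape does not match labels")
        if not np.all(np.isfinite(self.Y)) or (self.Y.size and self.Y.min() < 0):
            raise ValueError("Y must be non-negative and finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, index=list(self.gene_ids), columns=list(self.subject_ids))

    def subset_genes(self, genes) -> "PseudoBulk":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from pseudo-bulk: {missing[:5]}")
        idx = [pos[g] for g in genes]
        return PseudoBulk(self.Y[idx, :], tuple(genes), self.subject_ids)


def build_reference(sc: SingleCellDataset) -> ReferenceProfile:
    """Average CPM expression per cell type, cells pooled across subjects."""
    if sc.expr.scale != CPM:
        raise ValueError("build_reference expects CPM-scaled single-cell expression")
    types = sc.cell_types
    labels = sc.cell_type.to_numpy()
    cols = []
    for t in types:
        mask = labels == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has no cells")
        cols.append(sc.expr.values[:, mask].mean(axis=1))
    return ReferenceProfile(np.column_stack(cols), types, sc.expr.gene_ids)


def observed_proportions(sc: SingleCellDataset) -> ProportionMatrix:
    """Fraction of each cell type within each subject's cells."""
    types, subjects = sc.cell_types, sc.subjects
    tlab = sc.cell_type.to_numpy()
    slab = sc.subject.to_numpy()
    P = np.zeros((len(types), len(subjects)))
    for j, s in enumerate(subjects):
        in_subj = slab == s
        n = int(in_subj.sum())
        if n == 0:
            raise ValueError(f"subject {s!r} has no cells")
        for c, t in enumerate(types):
            P[c, j] = np.count_nonzero(in_subj & (tlab == t)) / n
    return ProportionMatrix(P, types, subjects)


def pseudo_bulk(Z: ReferenceProfile, P: ProportionMatrix) -> PseudoBulk:
    """Proportion-weighted mixture of reference columns, Y = Z P."""
    if Z.cell_types != P.cell_types:
        raise ValueError(
            f"cell-type labels differ between reference {Z.cell_types} "
            f"and proportions {P.cell_types}"
        )
    return PseudoBulk(Z.Z @ P.P, Z.gene_ids, P.column_ids)
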