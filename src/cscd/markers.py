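"""Marker-gene selection by detection-percentage difference.

A gene is a marker for a cluster when the fraction of that cluster's cells
detecting it (count > 0) exceeds the detection fraction among all other
cells by at least a threshold (default 0.5), and the gene survives for
exactly one cluster — markers shared between clusters are removed entirely,
so the final marker sets of any two cell types are disjoint.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, SingleCellDataset

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


class MarkerSelectionError(ValueError):
    """Raised when some cell type retains no marker genes."""

    def __init__(self, uncovered: Sequence[str]):
        self.uncovered = tuple(uncovered)
        super().__init__(
            "no marker genes survive for cell type(s): "
            + ", ".join(self.uncovered)
            + " — closely related cell types may share all their markers; "
            "consider lowering the detection threshold"
        )


def detection_fractions(sc: SingleCellDataset) -> pd.DataFrame:
    """Per (gene, cell type) detection fractions inside and outside the cluster.

    Returns a tidy table with columns gene_id, cell_type, pct_in, pct_out,
    one row per pair.  Detection means expression strictly above zero (CPM
    scaling preserves the zero pattern, so either scale may be passed).
    """
    if sc.n_types < 2:
        raise ValueError("detection fractions need at least two cell types")
    detected = sc.expr.values > 0  # G x N boolean
    labels = sc.cell_type.to_numpy()
    frames = []
    for t in sc.cell_types:
        mask = labels == t
        pct_in = detected[:, mask].mean(axis=1)
        pct_out = detected[:, ~mask].mean(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": sc.expr.gene_ids,
                    "cell_type": t,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def wilcoxon_prefilter(
    sc: SingleCellDataset, alpha: float = 0.05
) -> pd.DataFrame:
    """Optional per-gene cluster-vs-rest Wilcoxon rank-sum pre-filter.

    Returns the (gene, cell_type) pairs with Benjamini-Hochberg adjusted
    two-sided p-value <= ``alpha``, for use as a differential-expression
    screen ahead of the detection-percentage rule.
    """
    labels = sc.cell_type.to_numpy()
    rows = []
    for t in sc.cell_types:
        mask = labels == t
        res = stats.mannwhitneyu(
            sc.expr.values[:, mask], sc.expr.values[:, ~mask], axis=1
        )
        rows.append(
            pd.DataFrame(
                {"gene_id": sc.expr.gene_ids, "cell_type": t, "pvalue": res.pvalue}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["qvalue"] = stats.false_discovery_control(table["pvalue"], method="bh")
    return table[table["qvalue"] <= alpha].reset_index(drop=True)


def select_markers(
    table: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    allowed_pairs: pd.DataFrame | None = None,
) -> list[tuple[str, str]]:
    """Apply the two-step marker rule to a detection-fraction table.

    Step 1 retains pairs with ``|pct_in - pct_out| >= threshold`` and
    ``pct_in > pct_out`` (a marker must be enriched in its own cluster;
    ties at exactly the threshold are retained).  Step 2 removes genes
    retained for more than one cluster.  Raises
    :class:`MarkerSelectionError` if any cell type ends up uncovered.

    ``allowed_pairs`` optionally restricts step 1 to pre-screened
    (gene_id, cell_type) pairs, e.g. from :func:`wilcoxon_prefilter`.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    t = table
    if allowed_pairs is not None:
        key = ["gene_id", "cell_type"]
        t = t.merge(allowed_pairs[key].drop_duplicates(), on=key, how="inner")
    diff = t["pct_in"] - t["pct_out"]
    # ties at exactly the threshold are retained; tolerate fp rounding of the fractions
    step1 = t[(diff.abs() >= threshold - 1e-12) & (diff > 0)]
    counts = step1["gene_id"].value_counts()
    unique_genes = set(counts[counts == 1].index)
    final = step1[step1["gene_id"].isin(unique_genes)]
    all_types = tuple(dict.fromkeys(table["cell_type"]))
    covered = set(final["cell_type"])
    uncovered = [c for c in all_types if c not in covered]
    if uncovered:
        raise MarkerSelectionError(uncovered)
    logger.info(
        "select_markers: %d pairs pass step 1, %d markers after removing "
        "multi-cluster genes", len(step1), len(final),
    )
    return list(zip(final["gene_id"], final["cell_type"]))


def marker_table(table: pd.DataFrame, markers: list[tuple[str, str]]) -> pd.DataFrame:
    """Annotate a detection table with the retained flag for selected markers."""
    retained = set(markers)
    out = table.copy()
    out["retained"] = [
        (g, c) in retained for g, c in zip(out["gene_id"], out["cell_type"])
    ]
    return out


def restrict_to_markers(
    m: ExpressionMatrix, markers: Sequence[tuple[str, str]] | Sequence[str]
) -> ExpressionMatrix:
    """Row-restrict a matrix to the marker genes, preserving matrix order."""
    genes = {mk[0] if isinstance(mk, tuple) else mk for mk in markers}
    missing = genes - set(m.gene_ids)
    if missing:
        raise KeyError(f"marker genes absent from matrix: {sorted(missing)[:5]}")
    kept = [g for g in m.gene_ids if g in genes]
    return m.subset_genes(kept)
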