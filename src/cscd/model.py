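"""Covariance-based single-cell decomposition model.

``CSCD`` is constructed from an annotated single-cell dataset and a bulk
expression matrix, and ``fit()`` runs the full pipeline:

align genes -> pre-processing filters -> CPM -> reference profile Z and
observed proportions -> pseudo-bulk Y -> marker selection -> restriction of
Z, Y and the bulk to marker genes -> bulk transformation (multivariate,
univariate or none) -> simplex-constrained least squares per bulk sample.

The returned :class:`DeconvolutionResults` carries the estimated
proportions, per-sample residual norms, the marker table and a per-stage
gene-count log, with a ``summary()`` table in the spirit of statsmodels
results objects.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import covtransform, io_core, markers as markers_mod, reference
from .decompose import solve_proportions
from .io_core import BulkDataset, SingleCellDataset
from .reference import ProportionMatrix

logger = logging.getLogger(__name__)

MODES = ("cscd", "multivariate", "univariate", "none")


@contextmanager
def _stage(name: str):
    """Tag pipeline errors with the stage that raised them."""
    try:
        yield
    except markers_mod.MarkerSelectionError:
        raise  # already names the stage's failure precisely
    except (ValueError, KeyError) as exc:
        raise ValueError(f"[stage: {name}] {exc}") from exc


class CSCD:
    """Reference-based cell-type decomposition of bulk RNA-seq.

    Parameters
    ----------
    sc
        Annotated single-cell dataset (counts).
    bulk
        Bulk expression dataset (counts, or CPM to skip normalization).
    mode
        ``"multivariate"`` (the CSCD transform; ``"cscd"`` is an alias),
        ``"univariate"`` (the Bisque-style gene-wise baseline) or ``"none"``
        (no transformation; plain constrained least squares).
    marker_threshold
        Minimum detection-percentage difference for marker genes.
    de_prefilter
        Apply the optional Wilcoxon rank-sum / Benjamini-Hochberg screen
        before the detection-percentage rule.
    mito_prefixes
        Gene-symbol prefixes treated as mitochondrial.
    eig_floor
        Relative eigenvalue floor for the symmetric matrix roots.
    """

    def __init__(
        self,
        sc: SingleCellDataset,
        bulk: BulkDataset,
        *,
        mode: str = "multivariate",
        marker_threshold: float = markers_mod.DEFAULT_THRESHOLD,
        de_prefilter: bool = False,
        de_alpha: float = 0.05,
        mito_prefixes: Sequence[str] = io_core.DEFAULT_MITO_PREFIXES,
        eig_floor: float = covtransform.DEFAULT_EIG_FLOOR,
    ):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        self.sc = sc
        self.bulk = bulk
        self.mode = "multivariate" if mode == "cscd" else mode
        self.marker_threshold = marker_threshold
        self.de_prefilter = de_prefilter
        self.de_alpha = de_alpha
        self.mito_prefixes = tuple(mito_prefixes)
        self.eig_floor = eig_floor

    @classmethod
    def from_files(
        cls,
        sc_expr: str | Path,
        sc_annot: str | Path,
        bulk_expr: str | Path,
        **config,
    ) -> "CSCD":
        sc = io_core.single_cell_from_files(sc_expr, sc_annot)
        bulk = BulkDataset(io_core.read_expression(bulk_expr))
        return cls(sc, bulk, **config)

    # ------------------------------------------------------------------
    def fit(self) -> "DeconvolutionResults":
        stage_log: dict[str, int] = {}
        with _stage("align_genes"):
            sc, bulk = io_core.align_genes(self.sc, self.bulk)
        stage_log["common_genes"] = sc.expr.n_genes
        with _stage("filter_genes"):
            sc, bulk = io_core.filter_genes(sc, bulk, self.mito_prefixes)
        stage_log["after_filters"] = sc.expr.n_genes

        sc = sc.with_expr(io_core.cpm_normalize(sc.expr))
        if bulk.expr.scale == io_core.COUNTS:
            bulk = BulkDataset(io_core.cpm_normalize(bulk.expr))

        Z = reference.build_reference(sc)
        P_sc = reference.observed_proportions(sc)
        Y = reference.pseudo_bulk(Z, P_sc)

        det = markers_mod.detection_fractions(sc)
        allowed = (
            markers_mod.wilcoxon_prefilter(sc, self.de_alpha)
            if self.de_prefilter
            else None
        )
        with _stage("select_markers"):
            marker_pairs = markers_mod.select_markers(
                det, self.marker_threshold, allowed_pairs=allowed
            )
        stage_log["marker_genes"] = len(marker_pairs)

        marker_genes = [g for g in Z.gene_ids if g in {m[0] for m in marker_pairs}]
        Zm = Z.subset_genes(marker_genes)
        Ym = Y.subset_genes(marker_genes)
        Xm = BulkDataset(bulk.expr.subset_genes(marker_genes))

        with _stage(f"{self.mode}_transform"):
            if self.mode == "none":
                design = Xm.expr.values
            elif self.mode == "univariate":
                design = covtransform.univariate_transform(Xm, Ym).Xm
            else:
                design = covtransform.multivariate_transform(Xm, Ym, self.eig_floor).Xm

        C = len(Z.cell_types)
        I = Xm.n_samples
        P = np.empty((C, I))
        residuals = np.empty(I)
        for i in range(I):
            P[:, i], residuals[i] = solve_proportions(Zm.Z, design[:, i])

        proportions = ProportionMatrix(P, Z.cell_types, Xm.expr.column_ids)
        return DeconvolutionResults(
            model=self,
            proportions=proportions,
            residual_norms=pd.Series(
                residuals, index=list(Xm.expr.column_ids), name="residual_norm"
            ),
            mode=self.mode,
            markers=markers_mod.marker_table(det, marker_pairs),
            marker_pairs=marker_pairs,
            reference_profile=Zm,
            sc_proportions=P_sc,
            transformed=pd.DataFrame(
                design, index=marker_genes, columns=list(Xm.expr.column_ids)
            ),
            stage_log=stage_log,
        )


@dataclass
class DeconvolutionResults:
    """Fitted cell-type proportions and diagnostics."""

    model: CSCD
    proportions: ProportionMatrix
    residual_norms: pd.Series
    mode: str
    markers: pd.DataFrame
    marker_pairs: list[tuple[str, str]]
    reference_profile: reference.ReferenceProfile
    sc_proportions: ProportionMatrix
    transformed: pd.DataFrame
    stage_log: dict[str, int] = field(default_factory=dict)

    @property
    def proportions_frame(self) -> pd.DataFrame:
        return self.proportions.to_frame()

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "CSCD decomposition results",
            "=" * 60,
            f"mode:                 {self.mode}",
            f"cell types (C):       {len(self.proportions.cell_types)}",
            f"bulk samples (I):     {len(self.proportions.column_ids)}",
            f"sc subjects (J):      {len(self.sc_proportions.column_ids)}",
            f"common genes:         {self.stage_log.get('common_genes', 'n/a')}",
            f"genes after filters:  {self.stage_log.get('after_filters', 'n/a')}",
            f"marker genes used:    {self.stage_log.get('marker_genes', 'n/a')}",
            f"mean residual norm:   {self.residual_norms.mean():.4g}",
            "-" * 60,
            "estimated proportions (cell types x samples):",
            self.proportions_frame.round(4).to_string(),
            "=" * 60,
        ]
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        """Write proportions plus a residual-norm row."""
        out = self.proportions_frame.copy()
        out.loc["residual_norm"] = self.residual_norms.to_numpy()
        out.to_csv(path)

    def run_report(self) -> dict:
        return {
            "mode": self.mode,
            "stage_log": dict(self.stage_log),
            "n_markers": len(self.marker_pairs),
            "marker_threshold": self.model.marker_threshold,
            "eig_floor": self.model.eig_floor,
        }

    def save_run_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.run_report(), indent=2) + "\n")

    def plot_proportions(self, ax=None):
        """Jitter plot of estimated proportions per cell type (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.5 * len(self.proportions.cell_types), 4))
        rng = np.random.default_rng(0)
        for c, ct in enumerate(self.proportions.cell_types):
            y = self.proportions.P[c, :]
            x = c + rng.uniform(-0.15, 0.15, size=y.size)
            ax.scatter(x, y, s=12, alpha=0.7)
        ax.set_xticks(range(len(self.proportions.cell_types)))
        ax.set_xticklabels(self.proportions.cell_types, rotation=45, ha="right")
        ax.set_ylabel("estimated proportion")
        ax.set_ylim(-0.02, 1.02)
        return ax
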