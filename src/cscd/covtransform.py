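"""Sample moments, Ledoit-Wolf shrinkage and the bulk expression transforms.

The multivariate transform maps each bulk CPM column onto the distribution
of the single-cell pseudo-bulk:

    X^m = Ybar + sqrt(J/(J+1)) * S_Y,s^{1/2} S_X,s^{-1/2} (X - Xbar)

where S_Y,s and S_X,s are Ledoit-Wolf linear-shrinkage estimates of the
pseudo-bulk and bulk sample covariances (divisor n, matching the sample
moments), matrix powers are symmetric eigendecomposition roots, and
J/(J+1) deflates the single-cell-derived variance because the number of
single-cell subjects J is small.  The univariate variant applies the same
location-scale matching gene by gene and ignores gene-gene correlation.

With G marker genes typically far exceeding J and the number of bulk
samples I, the raw sample covariances are singular; shrinking towards the
scaled identity nu*I (nu = trace(S)/G) restores positive-definiteness with
a data-driven intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.covariance import ledoit_wolf_shrinkage

from .io_core import BulkDataset, ExpressionMatrix
from .reference import PseudoBulk

logger = logging.getLogger(__name__)

DEFAULT_EIG_FLOOR = 1e-8


@dataclass
class MomentSummary:
    """Row means and sample covariance (divisor n) of a genes x n matrix."""

    mean: np.ndarray
    cov: np.ndarray
    n: int


@dataclass
class ShrunkCovariance:
    """Linear-shrinkage covariance (1-intensity)*S + intensity*nu*I."""

    matrix: np.ndarray
    intensity: float
    target_scale: float


@dataclass
class TransformedBulk:
    """Transformed bulk expression (may contain negative entries)."""

    Xm: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.Xm = np.asarray(self.Xm, dtype=float)
        if not np.all(np.isfinite(self.Xm)):
            raise ValueError("transformed bulk contains non-finite entries")


def _data_matrix(m) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    if isinstance(m, ExpressionMatrix):
        return m.values, m.gene_ids, m.column_ids
    if isinstance(m, BulkDataset):
        return m.expr.values, m.expr.gene_ids, m.expr.column_ids
    if isinstance(m, PseudoBulk):
        return m.Y, m.gene_ids, m.subject_ids
    a = np.asarray(m, dtype=float)
    return a, tuple(map(str, range(a.shape[0]))), tuple(map(str, range(a.shape[1])))


def moments(m) -> MomentSummary:
    """Row means and covariance with divisor n (the population convention)."""
    values, _, _ = _data_matrix(m)
    n = values.shape[1]
    if n < 2:
        raise ValueError(f"moments need at least 2 columns, got {n}")
    mean = values.mean(axis=1)
    centered = values - mean[:, None]
    cov = (centered @ centered.T) / n
    return MomentSummary(mean, cov, n)


def lw_shrink(
    m,
    summary: MomentSummary | None = None,
    force_intensity: float | None = None,
) -> ShrunkCovariance:
    """Ledoit-Wolf linear shrinkage of the sample covariance of ``m``.

    The estimate is (1 - lambda) S + lambda nu I with nu = trace(S)/G and
    intensity lambda given by the plug-in formula that minimises the
    expected squared Frobenius loss, clipped to [0, 1].  The centered data
    columns are required to compute the intensity.  ``force_intensity``
    overrides the data-driven value (used for diagnostics and identities).
    """
    values, _, _ = _data_matrix(m)
    s = summary if summary is not None else moments(values)
    G = s.cov.shape[0]
    nu = float(np.trace(s.cov)) / G
    if nu <= 0:
        raise ValueError("all-zero covariance: no shrinkage target exists")
    if force_intensity is not None:
        lam = float(force_intensity)
        if not 0 <= lam <= 1:
            raise ValueError("shrinkage intensity must lie in [0, 1]")
    else:
        # observations x features orientation; same 1/n moment convention
        lam = float(ledoit_wolf_shrinkage(values.T, assume_centered=False))
    shrunk = (1.0 - lam) * s.cov + lam * nu * np.eye(G)
    return ShrunkCovariance(shrunk, lam, nu)


def _check_symmetric(c: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("matrix must be square")
    scale = max(np.abs(c).max(), 1.0)
    if np.abs(c - c.T).max() > tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    return (c + c.T) / 2.0


def _sym_power(c: np.ndarray, power: float, floor: float) -> np.ndarray:
    c = _check_symmetric(c)
    if floor <= 0:
        raise ValueError("eigenvalue floor must be positive")
    w, v = linalg.eigh(c)
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("matrix has no positive eigenvalues")
    w = np.clip(w, floor * wmax, None)
    out = (v * w**power) @ v.T
    return (out + out.T) / 2.0


def sym_root(c: np.ndarray, floor: float = DEFAULT_EIG_FLOOR) -> np.ndarray:
    """Symmetric square root via eigendecomposition, with a relative eigenvalue floor."""
    return _sym_power(c, 0.5, floor)


def sym_inv_root(c: np.ndarray, floor: float = DEFAULT_EIG_FLOOR) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition, with a relative floor."""
    return _sym_power(c, -0.5, floor)


def _check_aligned(bulk: BulkDataset, Y: PseudoBulk) -> None:
    if bulk.expr.gene_ids != Y.gene_ids:
        raise ValueError("bulk and pseudo-bulk must share the same genes in the same order")


def univariate_transform(bulk: BulkDataset, Y: PseudoBulk) -> TransformedBulk:
    """Gene-wise location-scale matching of bulk onto the pseudo-bulk.

    X^u_gi = Ybar_g + sqrt(J/(J+1)) sqrt(s^Y_gg / s^X_gg) (X_gi - Xbar_g),
    the baseline transform that ignores gene-gene correlation.
    """
    _check_aligned(bulk, Y)
    my = moments(Y)
    mx = moments(bulk)
    J = my.n
    sy = np.diag(my.cov)
    sx = np.diag(mx.cov)
    if np.any(sx <= 0):
        bad = bulk.expr.gene_ids[int(np.flatnonzero(sx <= 0)[0])]
        raise ValueError(
            f"gene {bad!r} has zero bulk variance; pre-processing should have removed it"
        )
    factor = np.sqrt(J / (J + 1.0)) * np.sqrt(sy / sx)
    Xu = my.mean[:, None] + factor[:, None] * (bulk.expr.values - mx.mean[:, None])
    return TransformedBulk(Xu, bulk.expr.gene_ids, bulk.expr.column_ids)


def multivariate_transform(
    bulk: BulkDataset,
    Y: PseudoBulk,
    floor: float = DEFAULT_EIG_FLOOR,
    force_intensity: float | None = None,
) -> TransformedBulk:
    """Covariance-based whitening/recoloring transform of the bulk matrix.

    Whitens the centered bulk columns with the inverse root of the shrunk
    bulk covariance and recolors with the root of the shrunk pseudo-bulk
    covariance; the product of roots is applied in that printed order and
    not symmetrized.
    """
    _check_aligned(bulk, Y)
    if Y.Y.shape[1] < 2 or bulk.n_samples < 2:
        raise ValueError("multivariate transform needs >= 2 subjects and >= 2 bulk samples")
    my = moments(Y)
    mx = moments(bulk)
    J = my.n
    centered = bulk.expr.values - mx.mean[:, None]
    if not centered.any():
        # constant-column bulk: nothing to whiten, every column maps to Ybar
        Xm = np.tile(my.mean[:, None], (1, bulk.n_samples))
        return TransformedBulk(Xm, bulk.expr.gene_ids, bulk.expr.column_ids)
    sy_s = lw_shrink(Y, my, force_intensity=force_intensity)
    sx_s = lw_shrink(bulk, mx, force_intensity=force_intensity)
    logger.info(
        "multivariate_transform: shrinkage intensity %.4f (pseudo-bulk), %.4f (bulk)",
        sy_s.intensity, sx_s.intensity,
    )
    A = sym_root(sy_s.matrix, floor)
    B = sym_inv_root(sx_s.matrix, floor)
    Xm = my.mean[:, None] + np.sqrt(J / (J + 1.0)) * (A @ (B @ centered))
    return TransformedBulk(Xm, bulk.expr.gene_ids, bulk.expr.column_ids)
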