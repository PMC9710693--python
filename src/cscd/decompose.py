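"""Simplex-constrained least squares for cell-type proportions.

Each bulk sample's proportions solve

    min_p || Z p - x ||^2   s.t.   p >= 0,  sum_c p_c = 1,

a convex quadratic program over the unit simplex.  For the small numbers of
cell types typical of deconvolution the program is solved exactly by
enumerating active sets: for every support F the equality-constrained
stationary point on the face {p_F : sum p_F = 1} is computed from the KKT
system, and the best feasible candidate is returned.  Ties from collinear
reference columns resolve to the minimum-Euclidean-norm solution.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
from scipy import optimize

from .reference import ReferenceProfile

logger = logging.getLogger(__name__)

_FEAS_TOL = 1e-9
_MAX_ENUM_TYPES = 12


def _kkt_face(ZtZ: np.ndarray, Ztx: np.ndarray, free: tuple[int, ...]) -> np.ndarray:
    """Stationary point of the equality-constrained LS on one simplex face."""
    k = len(free)
    idx = np.asarray(free)
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = 2.0 * ZtZ[np.ix_(idx, idx)]
    K[:k, k] = 1.0
    K[k, :k] = 1.0
    rhs = np.concatenate([2.0 * Ztx[idx], [1.0]])
    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    return sol[:k]


def solve_proportions(
    Z, x: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Minimise ||Z p - x|| over the unit simplex.

    Parameters
    ----------
    Z
        G x C reference matrix (ndarray or :class:`ReferenceProfile`).
    x
        Length-G bulk expression vector (possibly transformed, so negative
        entries are allowed and passed through untouched).

    Returns
    -------
    p : ndarray
        The optimal simplex vector.
    residual : float
        ``||Z p - x||`` at the optimum.
    """
    Zm = Z.Z if isinstance(Z, ReferenceProfile) else np.asarray(Z, dtype=float)
    x = np.asarray(x, dtype=float)
    if Zm.ndim != 2 or x.shape != (Zm.shape[0],):
        raise ValueError("Z must be G x C and x length G")
    G, C = Zm.shape
    if G < C:
        warnings.warn(
            f"fewer genes ({G}) than cell types ({C}); proportions may be non-unique",
            stacklevel=2,
        )
    if np.linalg.matrix_rank(Zm) < min(G, C):
        dup = _duplicate_columns(Zm)
        warnings.warn(
            "reference matrix is rank-deficient"
            + (f"; collinear cell-type columns: {dup}" if dup else "")
            + "; returning a minimum-norm solution",
            stacklevel=2,
        )

    # scale invariance of the argmin: work on a normalized copy for conditioning
    scale = max(np.abs(Zm).max(), np.abs(x).max(), 1.0)
    Zs, xs = Zm / scale, x / scale
    ZtZ = Zs.T @ Zs
    Ztx = Zs.T @ xs

    if C <= _MAX_ENUM_TYPES:
        best: tuple[float, float, np.ndarray] | None = None
        for size in range(1, C + 1):
            for free in itertools.combinations(range(C), size):
                pf = _kkt_face(ZtZ, Ztx, free)
                if pf.min() < -_FEAS_TOL:
                    continue
                p = np.zeros(C)
                p[list(free)] = np.clip(pf, 0.0, None)
                p /= p.sum()
                obj = float(np.sum((Zs @ p - xs) ** 2))
                key = (obj, float(p @ p), p)
                if best is None or key[:2] < best[:2]:
                    best = key
        if best is None:  # unreachable: singleton faces are always feasible
            raise RuntimeError("constrained solver found no feasible candidate")
        p = best[2]
    else:
        res = optimize.minimize(
            lambda p: float(np.sum((Zs @ p - xs) ** 2)),
            np.full(C, 1.0 / C),
            jac=lambda p: 2.0 * (ZtZ @ p - Ztx),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * C,
            constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
            options={"ftol": tol, "maxiter": 500},
        )
        if not res.success:
            raise RuntimeError(f"constrained solver failed to converge: {res.message}")
        p = np.clip(res.x, 0.0, None)
        p /= p.sum()
    residual = float(np.linalg.norm(Zm @ p - x))
    return p, residual


def _duplicate_columns(Z: np.ndarray) -> list[tuple[int, int]]:
    dup = []
    for a in range(Z.shape[1]):
        for b in range(a + 1, Z.shape[1]):
            if np.allclose(Z[:, a], Z[:, b]):
                dup.append((a, b))
    return dup


def decompose(sc, bulk, **config):
    """End-to-end decomposition; thin wrapper around :class:`cscd.model.CSCD`.

    Accepts the same keyword configuration as the model class (``mode``,
    ``marker_threshold``, ``eig_floor``, ``mito_prefixes``, ...) and returns
    a :class:`cscd.model.DeconvolutionResults`.
    """
    from .model import CSCD

    return CSCD(sc, bulk, **config).fit()
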