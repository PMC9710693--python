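import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cscd.io_core import BulkDataset, ExpressionMatrix, SingleCellDataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_sc(values, cell_types, subjects, gene_ids=None, scale="counts"):
    """Small single-cell dataset from raw arrays."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(g)]
    cells = [f"c{i + 1}" for i in range(n)]
    expr = ExpressionMatrix(values, tuple(gene_ids), tuple(cells), scale)
    return SingleCellDataset(
        expr,
        pd.Series(list(cell_types), index=cells),
        pd.Series(list(subjects), index=cells),
    )


def make_bulk(values, gene_ids=None, scale="counts"):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(g)]
    samples = [f"s{i + 1}" for i in range(n)]
    return BulkDataset(ExpressionMatrix(values, tuple(gene_ids), tuple(samples), scale))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sc():
    """4 genes x 6 cells, 2 types, 2 subjects, with clean marker structure."""
    # g1 marks A (detected only in A), g2 marks B, g3/g4 background
    values = np.array(
        [
            [5, 8, 6, 0, 0, 0],
            [0, 0, 0, 7, 9, 4],
            [1, 2, 1, 2, 1, 2],
            [3, 1, 2, 1, 3, 2],
        ],
        dtype=float,
    )
    return make_sc(values, "AAABBB", ["s1", "s1", "s2", "s1", "s2", "s2"])


@pytest.fixture
def separable_pipeline_data(rng):
    """Well-separated 3-type dataset plus a noiseless bulk built as Z @ P*."""
    from cscd.io_core import align_genes, cpm_normalize, filter_genes
    from cscd.reference import build_reference

    G, N, C, J = 60, 90, 3, 3
    base = rng.lognormal(1.0, 0.6, G)
    lam = np.tile(base[:, None], (1, C))
    for c in range(C):
        block = slice(15 * c, 15 * (c + 1))
        lam[block, c] *= 60.0  # strong exclusive markers per type
    types = np.repeat(np.arange(C), N // C)
    mean = lam[:, types] * 40.0 / lam[:, types].sum(0)
    counts = rng.poisson(mean * 50).astype(float)
    sc = make_sc(
        counts,
        [f"T{t + 1}" for t in types],
        [f"s{(i % J) + 1}" for i in range(N)],
    )
    # reference on the filtered, CPM-normalized data (the pipeline's own gene space)
    bulk_probe = make_bulk(np.ones((G, 1)), gene_ids=list(sc.expr.gene_ids))
    sc_f, _ = filter_genes(*align_genes(sc, bulk_probe))
    Z = build_reference(sc_f.with_expr(cpm_normalize(sc_f.expr)))
    P_star = np.column_stack([rng.dirichlet(np.ones(C)) for _ in range(8)])
    bulk = make_bulk(Z.Z @ P_star, gene_ids=list(Z.gene_ids))
    return sc, bulk, Z, P_star
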