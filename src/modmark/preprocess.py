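"""Row-wise z-score normalisation and network/matrix universe restriction.

Expression is standardised per gene across all retained samples (both
phenotype groups pooled), and the interaction network and matrix are
cut down to their common gene universe before any module search.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import ExpressionMatrix, PPINetwork

logger = logging.getLogger("modmark")


def zscore_rows(expr: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Standardise each gene row to mean 0 and sample SD 1.

    The sample standard deviation uses denominator ``n - ddof`` (default
    ``n - 1``).  A constant row has no defined z-score and is an error.

    Raises
    ------
    ValueError
        If any gene row has zero standard deviation.
    """
    means = expr.values.mean(axis=1, keepdims=True)
    sds = expr.values.std(axis=1, ddof=ddof, keepdims=True)
    flat = np.flatnonzero(sds[:, 0] == 0)
    if flat.size:
        raise ValueError(
            f"constant expression row(s), z-score undefined: "
            f"{[expr.gene_ids[i] for i in flat[:5]]}"
        )
    z = (expr.values - means) / sds
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), z)


def restrict_to_common_genes(
    net: PPINetwork, expr: ExpressionMatrix
) -> tuple[PPINetwork, ExpressionMatrix]:
    """Induce both inputs on the genes present in network AND matrix.

    Edges with either endpoint outside the intersection are dropped;
    expression rows for genes missing from the network are dropped.
    Row order of surviving genes is preserved.
    """
    common = net.nodes & set(expr.gene_ids)
    if not common:
        raise ValueError("no genes shared between network and expression matrix")
    kept_genes = [g for g in expr.gene_ids if g in common]
    out_net = net.induced(common)
    out_expr = expr.subset_genes(kept_genes)
    logger.info(
        "common-universe restriction: %d/%d network nodes, %d/%d edges, "
        "%d/%d expression rows kept",
        len(out_net.nodes), len(net.nodes), out_net.n_edges, net.n_edges,
        out_expr.n_genes, expr.n_genes,
    )
    return out_net, out_expr
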