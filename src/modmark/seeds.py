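"""Seed selection: per-gene differential-expression tests.

Each gene is tested for a mean shift between the control and case groups
with a two-sided two-sample t-test (Welch by default), p-values are
corrected by the Benjamini-Hochberg step-up procedure, and genes below
the adjusted-p threshold become seeds for greedy module growth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PhenotypeLabels

logger = logging.getLogger("modmark")


@dataclass
class GeneTestResult:
    gene_id: str
    t_stat: float
    p_value: float
    p_adjusted: float = float("nan")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_t_tests(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    equal_var: bool = False,
) -> list[GeneTestResult]:
    """Two-sided NORMAL-vs-CASE t-test for every gene row.

    Genes with zero variance in both groups are assigned t = 0, p = 1 with
    a warning rather than propagating a division by zero.  BH adjustment is
    computed across all tested genes.
    """
    normal_mask, case_mask = labels.group_masks(expr.sample_ids)
    if normal_mask.sum() < 2 or case_mask.sum() < 2:
        raise ValueError("need >= 2 samples per group for a t-test")
    a = expr.values[:, normal_mask]
    b = expr.values[:, case_mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t) | ~np.isfinite(p)
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero variance in both groups; p set to 1",
            int(degenerate.sum()),
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    padj = adjust_bh(p)
    return [
        GeneTestResult(g, float(t[i]), float(p[i]), float(padj[i]))
        for i, g in enumerate(expr.gene_ids)
    ]


def select_seeds(results: list[GeneTestResult], alpha: float = 0.01) -> list[str]:
    """Genes with BH-adjusted p < alpha, sorted by (p_adjusted, gene_id)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    hits = [r for r in results if r.p_adjusted < alpha]
    hits.sort(key=lambda r: (r.p_adjusted, r.gene_id))
    return [r.gene_id for r in hits]
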