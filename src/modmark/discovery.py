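"""Discriminative-module discovery on a protein-interaction network.

The module activity of a gene set M of size k is the per-sample sum of the
members' expression values divided by sqrt(k).  Fitting one Gaussian to the
activity of the control samples and one to the case samples, the
discriminative area ``disa(M)`` is the common area under the two density
curves: 1 when the groups are indistinguishable, approaching 0 when they
are perfectly separated.  Starting from each differentially expressed seed
gene, modules are grown greedily, at each step adding the network neighbour
that minimises ``disa``, until the area falls below a threshold delta or no
admissible step remains.  Grown modules with ``disa`` above a filter cut
are discarded.

The Gaussian overlap is computed in closed form.  For equal standard
deviations the two densities cross once, midway between the means, and the
overlap is ``2 * Phi(-|mu_1 - mu_2| / (2 * sigma))``.  Otherwise the
log-density equality is a quadratic with two real roots x1 < x2; between
the roots the narrower density is the higher one, so the overlap is the
wide density's mass on (x1, x2) plus the narrow density's mass outside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.special import ndtr  # standard normal CDF, vectorised
from scipy.stats import norm

from .io import ExpressionMatrix, Module, PhenotypeLabels, PPINetwork

logger = logging.getLogger("modmark")

#: relative sigma difference below which the equal-sigma branch is used
_EQUAL_SIGMA_RTOL = 1e-12
#: disa ties within this tolerance are broken lexicographically by gene ID
_TIE_TOL = 1e-12


@dataclass
class NormalFitPair:
    """Per-group Gaussian fits (mean, sample SD) of a module-activity vector."""

    mu_N: float
    sigma_N: float
    mu_C: float
    sigma_C: float

    def __post_init__(self) -> None:
        if not (self.sigma_N > 0 and self.sigma_C > 0):
            raise ValueError("group standard deviations must be positive")


@dataclass
class ActivityVector:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("activity length must equal sample count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")


@dataclass
class DiscoveryConfig:
    """Tunable knobs of the greedy search.

    delta : float
        Termination threshold on disa; growth stops once the module's
        overlap area drops below it (default 0.001).
    disa_filter : float
        Grown modules with disa above this are discarded (default 0.2).
    max_module_size : int
        Hard cap on module size; guards termination on dense networks.
    require_improvement : bool
        If true, a step must strictly lower disa or growth stops.
    """

    delta: float = 0.001
    disa_filter: float = 0.2
    max_module_size: int = 50
    require_improvement: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.delta < self.disa_filter <= 1):
            raise ValueError("require 0 < delta < disa_filter <= 1")
        if self.max_module_size < 1:
            raise ValueError("max_module_size must be positive")


# ---------------------------------------------------------------------------
# activity and Gaussian fits
# ---------------------------------------------------------------------------


def module_activity(expr: ExpressionMatrix, members) -> ActivityVector:
    """a(M): per-sample sum of member expression rows divided by sqrt(|M|)."""
    members = list(members)
    if not members:
        raise ValueError("module must have at least one member")
    idx = expr.gene_indices(members)
    vals = expr.values[idx].sum(axis=0) / math.sqrt(len(members))
    return ActivityVector(list(expr.sample_ids), vals)


def fit_group_normals(act: ActivityVector, labels: PhenotypeLabels) -> NormalFitPair:
    """Sample mean and SD (denominator n-1) of the activity in each group."""
    normal_mask, case_mask = labels.group_masks(act.sample_ids)
    if normal_mask.sum() < 2 or case_mask.sum() < 2:
        raise ValueError("need >= 2 samples per group to fit a Gaussian")
    a = act.values[normal_mask]
    b = act.values[case_mask]
    s_n = a.std(ddof=1)
    s_c = b.std(ddof=1)
    if s_n == 0 or s_c == 0:
        raise ValueError("degenerate fit: zero activity variance in a group")
    return NormalFitPair(float(a.mean()), float(s_n), float(b.mean()), float(s_c))


def _overlap_many(mu1, s1, mu2, s2) -> np.ndarray:
    """Vectorised closed-form overlap of N(mu1, s1^2) and N(mu2, s2^2)."""
    mu1, s1, mu2, s2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (mu1, s1, mu2, s2))
    )
    out = np.empty(mu1.shape, dtype=float)

    smax = np.maximum(s1, s2)
    equal = np.abs(s1 - s2) <= _EQUAL_SIGMA_RTOL * smax
    if equal.any():
        # single crossing at the midpoint of the means
        s = 0.5 * (s1[equal] + s2[equal])
        out[equal] = 2.0 * ndtr(-np.abs(mu1[equal] - mu2[equal]) / (2.0 * s))

    gen = ~equal
    if gen.any():
        # orient so index a = narrow, b = wide
        narrow_first = s1[gen] < s2[gen]
        ma = np.where(narrow_first, mu1[gen], mu2[gen])
        sa = np.where(narrow_first, s1[gen], s2[gen])
        mb = np.where(narrow_first, mu2[gen], mu1[gen])
        sb = np.where(narrow_first, s2[gen], s1[gen])
        # log phi_a(x) = log phi_b(x)  <=>  A x^2 + B x + C = 0
        va, vb = sa * sa, sb * sb
        A = 0.5 / vb - 0.5 / va          # < 0 since sa < sb
        B = ma / va - mb / vb
        C = 0.5 * (mb * mb / vb - ma * ma / va) + np.log(sb / sa)
        disc = B * B - 4.0 * A * C       # > 0 whenever sa != sb
        sq = np.sqrt(np.maximum(disc, 0.0))
        x1 = (-B + sq) / (2.0 * A)       # A < 0: this is the smaller root
        x2 = (-B - sq) / (2.0 * A)
        # narrow density exceeds wide on (x1, x2); min is wide there
        wide_inside = ndtr((x2 - mb) / sb) - ndtr((x1 - mb) / sb)
        narrow_outside = ndtr((x1 - ma) / sa) + ndtr(-(x2 - ma) / sa)
        out[gen] = wide_inside + narrow_outside

    return np.clip(out, 0.0, 1.0)


def overlap_area(fit: NormalFitPair) -> float:
    """disa: integral of min of the two fitted Gaussian densities.

    Closed form, with an adaptive-quadrature fallback if the intersection
    arithmetic ever produces a non-finite value.
    """
    val = float(_overlap_many(fit.mu_N, fit.sigma_N, fit.mu_C, fit.sigma_C))
    if not math.isfinite(val):  # pragma: no cover - defensive
        lo = min(fit.mu_N - 40 * fit.sigma_N, fit.mu_C - 40 * fit.sigma_C)
        hi = max(fit.mu_N + 40 * fit.sigma_N, fit.mu_C + 40 * fit.sigma_C)
        val, _ = quad(
            lambda x: min(
                norm.pdf(x, fit.mu_N, fit.sigma_N),
                norm.pdf(x, fit.mu_C, fit.sigma_C),
            ),
            lo, hi, limit=200,
        )
    return min(max(val, 0.0), 1.0)


def disa(expr: ExpressionMatrix, labels: PhenotypeLabels, members) -> float:
    """Discriminative area of a gene set: overlap of its group activity fits."""
    return overlap_area(fit_group_normals(module_activity(expr, members), labels))


# ---------------------------------------------------------------------------
# greedy growth
# ---------------------------------------------------------------------------


class _ActivityWorkspace:
    """Incremental group statistics for candidate evaluation.

    Keeps the running sum of member rows so that the activity of M + {g}
    for every candidate g is one vectorised operation.
    """

    def __init__(self, expr: ExpressionMatrix, labels: PhenotypeLabels):
        self.expr = expr
        self.normal_mask, self.case_mask = labels.group_masks(expr.sample_ids)
        if self.normal_mask.sum() < 2 or self.case_mask.sum() < 2:
            raise ValueError("need >= 2 samples per group")
        self.row_sum = np.zeros(expr.n_samples)
        self.k = 0

    def add(self, gene: str) -> None:
        self.row_sum = self.row_sum + self.expr.row(gene)
        self.k += 1

    def current_disa(self) -> float:
        act = self.row_sum / math.sqrt(self.k)
        return self._disa_from_activities(act[None, :])[0]

    def candidate_disas(self, genes: list[str]) -> np.ndarray:
        """disa of M + {g} for each candidate g; NaN marks degenerate fits."""
        idx = self.expr.gene_indices(genes)
        acts = (self.row_sum[None, :] + self.expr.values[idx]) / math.sqrt(self.k + 1)
        return self._disa_from_activities(acts)

    def _disa_from_activities(self, acts: np.ndarray) -> np.ndarray:
        a = acts[:, self.normal_mask]
        b = acts[:, self.case_mask]
        mu_n, mu_c = a.mean(axis=1), b.mean(axis=1)
        s_n, s_c = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
        ok = (s_n > 0) & (s_c > 0)
        out = np.full(acts.shape[0], np.nan)
        if ok.any():
            out[ok] = _overlap_many(mu_n[ok], s_n[ok], mu_c[ok], s_c[ok])
        return out


def grow_module(
    seed: str,
    net: PPINetwork,
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    cfg: DiscoveryConfig | None = None,
) -> Module:
    """Grow a module from a seed by greedy minimisation of disa.

    At each step every network neighbour of the current module is evaluated
    and the one giving the smallest disa of the enlarged module is added
    (ties within 1e-12 broken lexicographically by gene ID).  Growth stops
    when disa < delta, the neighbour set is exhausted, no candidate strictly
    improves disa (if ``require_improvement``), or the size cap is reached.
    Candidates without an expression row, or whose enlarged module has zero
    activity variance in a group, are skipped.
    """
    cfg = cfg or DiscoveryConfig()
    if seed not in net.nodes:
        raise KeyError(f"seed {seed!r} not in network")
    if seed not in expr.gene_ids:
        raise KeyError(f"seed {seed!r} not in expression matrix")

    ws = _ActivityWorkspace(expr, labels)
    ws.add(seed)
    members = [seed]
    member_set = {seed}
    current = ws.current_disa()
    trace: list[tuple[str, float]] = []
    have_expr = set(expr.gene_ids)

    while current >= cfg.delta and len(members) < cfg.max_module_size:
        candidates = sorted(
            g for g in net.neighborhood(member_set) if g in have_expr
        )
        if not candidates:
            break
        vals = ws.candidate_disas(candidates)
        finite = np.isfinite(vals)
        if not finite.any():
            break
        best = np.nanmin(vals)
        # lexicographically-first candidate within the tie tolerance
        pick = next(
            i for i, v in enumerate(vals) if finite[i] and v <= best + _TIE_TOL
        )
        if cfg.require_improvement and not vals[pick] < current:
            break
        ws.add(candidates[pick])
        members.append(candidates[pick])
        member_set.add(candidates[pick])
        current = float(vals[pick])
        trace.append((candidates[pick], current))

    return Module(seed=seed, members=members, disa=float(current), trace=trace)


def discover_modules(
    seeds,
    net: PPINetwork,
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    cfg: DiscoveryConfig | None = None,
) -> list[Module]:
    """Grow one module per (deduplicated) seed and apply the disa filter.

    Survivors are sorted ascending by disa, ties broken by seed ID.
    """
    cfg = cfg or DiscoveryConfig()
    seen: set[str] = set()
    unique_seeds = []
    for s in seeds:
        if s not in seen:
            seen.add(s)
            unique_seeds.append(s)
    if not unique_seeds:
        raise ValueError("seed list is empty")
    modules = [grow_module(s, net, expr, labels, cfg) for s in unique_seeds]
    survivors = [m for m in modules if m.disa <= cfg.disa_filter]
    survivors.sort(key=lambda m: (m.disa, m.seed))
    logger.info(
        "grew %d modules, %d survive disa <= %g",
        len(modules), len(survivors), cfg.disa_filter,
    )
    return survivors


def activity_correlations(
    modules: list[Module], expr: ExpressionMatrix
) -> np.ndarray:
    """Pearson correlation matrix between module activity vectors.

    A redundancy diagnostic: grown modules often share members and their
    activities correlate strongly.  Zero-variance activities yield NaN
    rows/columns (flagged with a warning) rather than an exception.
    """
    if not modules:
        raise ValueError("need at least one module")
    acts = np.vstack([module_activity(expr, m.members).values for m in modules])
    sds = acts.std(axis=1)
    if (sds == 0).any():
        logger.warning(
            "%d module activity vector(s) have zero variance; correlations NaN",
            int((sds == 0).sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.corrcoef(acts)
    cc = np.atleast_2d(cc)
    np.fill_diagonal(cc, 1.0)
    cc[sds == 0, :] = np.nan
    cc[:, sds == 0] = np.nan
    return cc
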