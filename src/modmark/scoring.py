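"""Biomarker selection by pathway-set functional similarity.

A grown module fits the discovery dataset by construction; to pick the one
most likely to generalise, each module is scored against prior disease
knowledge.  The module's enriched pathways (MF, hypergeometric
over-representation against a catalogue, BH-corrected) are compared with a
disease-background pathway set (DMF) by a bidirectional best-match average
of Jaccard indices, and the top-scoring module is the module biomarker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .io import Module, PathwayCollection
from .seeds import adjust_bh

logger = logging.getLogger("modmark")


@dataclass
class EnrichmentResult:
    pathway_name: str
    overlap_s: int
    p_value: float
    p_adjusted: float = float("nan")


@dataclass
class ModuleScore:
    module_id: str
    score: float
    enriched_pathways: list[str]


def enrichment_test(module_genes, pathway_genes, universe,
                    name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test.

    Population: the universe of size n (the analysis network's genes);
    successes: the pathway's genes within the universe (n2); draws: the
    module (n1); observed overlap s.  p = P(X >= s); s = 0 gives p = 1.
    """
    universe = set(universe)
    module = set(module_genes) & universe
    if len(module_genes) > len(universe):
        raise ValueError("module larger than the universe")
    pathway = set(pathway_genes) & universe
    s = len(module & pathway)
    if s == 0:
        p = 1.0
    else:
        p = float(hypergeom.sf(s - 1, len(universe), len(pathway), len(module)))
    return EnrichmentResult(name, s, min(max(p, 0.0), 1.0))


def enriched_pathways(
    module_genes,
    catalogue: PathwayCollection,
    universe,
    alpha_enrich: float = 0.05,
    adjust: bool = True,
) -> PathwayCollection:
    """MF: the catalogue subset over-represented in the module.

    P-values are BH-adjusted across the catalogue (set ``adjust=False`` for
    raw-p thresholding).
    """
    if len(catalogue) == 0:
        raise ValueError("empty pathway catalogue")
    if not 0 < alpha_enrich < 1:
        raise ValueError("alpha_enrich must lie in (0, 1)")
    names = catalogue.names()
    results = [
        enrichment_test(module_genes, catalogue.sets[n], universe, name=n)
        for n in names
    ]
    padj = adjust_bh([r.p_value for r in results])
    for r, q in zip(results, padj):
        r.p_adjusted = float(q)
    crit = (lambda r: r.p_adjusted) if adjust else (lambda r: r.p_value)
    hits = [r.pathway_name for r in results if crit(r) < alpha_enrich]
    return catalogue.subset(hits)


def set_jaccard(ps1, ps2) -> float:
    """Jaccard index |ps1 & ps2| / |ps1 | ps2| of two gene sets."""
    ps1, ps2 = set(ps1), set(ps2)
    if not ps1 and not ps2:
        raise ValueError("both gene sets are empty")
    return len(ps1 & ps2) / len(ps1 | ps2)


def pathway_set_similarity(ps1: PathwayCollection, ps2: PathwayCollection) -> float:
    """Bidirectional best-match average similarity of two pathway collections.

    sim(PS1, PS2) = [sum_i max_j J(ps1_i, ps2_j) + sum_j max_i J(ps2_j, ps1_i)]
    / (m + n).  An empty collection yields 0 with a warning so that modules
    without enriched pathways rank last rather than aborting the run.
    """
    if len(ps1) == 0 or len(ps2) == 0:
        logger.warning("empty pathway collection in similarity; score 0")
        return 0.0
    sets1 = list(ps1.sets.values())
    sets2 = list(ps2.sets.values())
    fwd = sum(max(set_jaccard(a, b) for b in sets2) for a in sets1)
    bwd = sum(max(set_jaccard(b, a) for a in sets1) for b in sets2)
    return (fwd + bwd) / (len(sets1) + len(sets2))


def score_modules(
    modules: list[Module],
    catalogue: PathwayCollection,
    background_dmf: PathwayCollection,
    universe,
    alpha_enrich: float = 0.05,
    restrict_background: bool = True,
) -> list[ModuleScore]:
    """Score every module as sim(MF, DMF) and rank descending.

    Ties are broken by smaller disa, then seed ID; the first entry is the
    selected module biomarker.  The background set is intersected with the
    universe by default.
    """
    if not modules:
        raise ValueError("no modules to score")
    universe = set(universe)
    dmf = (background_dmf.restrict_to(universe)
           if restrict_background else background_dmf)
    order = {m.module_id: (m.disa, m.seed) for m in modules}
    scored = []
    for m in modules:
        mf = enriched_pathways(m.members, catalogue, universe, alpha_enrich)
        score = pathway_set_similarity(mf, dmf) if len(mf) else 0.0
        scored.append(ModuleScore(m.module_id, score, mf.names()))
    scored.sort(key=lambda s: (-s.score, order[s.module_id]))
    return scored
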