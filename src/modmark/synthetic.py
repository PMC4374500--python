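"""Synthetic benchmark instances with a known planted module.

The generator emulates the statistical structure the discovery method
assumes: a background interaction network (Erdos-Renyi), i.i.d. standard
normal expression for null genes in both phenotype groups, and a planted
connected gene set whose members are mean-shifted by ``effect`` standard
deviations in the CASE group.  The module activity of the planted set is
then Gaussian in each group with a standardised mean gap of
``effect * sqrt(planted_size)``, so its expected overlap area is
``2 * Phi(-effect * sqrt(k) / 2)``.  A pathway catalogue and a
disease-background subset (DMF) are generated alongside, with a
configurable fraction of DMF pathways seeded with planted genes so the
scoring stage can recognise the planted module.

Everything is a deterministic function of ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (
    CASE,
    NORMAL,
    ExpressionMatrix,
    PathwayCollection,
    PhenotypeLabels,
    PPINetwork,
    write_expression,
    write_gene_sets,
    write_network,
    write_phenotypes,
)

#: fraction of catalogue pathways forming the disease-background (DMF) set
_DMF_FRACTION = 0.2


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults are the benchmark study conditions."""

    n_genes: int = 300
    n_per_group: int = 60
    planted_size: int = 10
    effect: float = 1.5
    background_edge_prob: float = 0.02
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (10, 40)
    dmf_overlap: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_size >= self.n_genes:
            raise ValueError("planted_size must be < n_genes")
        if self.n_per_group < 5:
            raise ValueError("need >= 5 samples per group")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 < self.background_edge_prob < 1:
            raise ValueError("background_edge_prob must lie in (0, 1)")
        if not 0 <= self.dmf_overlap <= 1:
            raise ValueError("dmf_overlap must lie in [0, 1]")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ValueError("pathway sizes exceed the gene universe")


@dataclass
class GroundTruth:
    planted_genes: frozenset[str]
    dmf_pathway_names: frozenset[str]


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{str(i).zfill(width)}" for i in range(1, n + 1)]


def generate_instance(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, PhenotypeLabels, PPINetwork, PathwayCollection,
           PathwayCollection, GroundTruth]:
    """One benchmark instance: expression, phenotypes, network, catalogue,
    disease-background catalogue and the ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = _gene_names(spec.n_genes)
    planted = sorted(
        rng.choice(spec.n_genes, size=spec.planted_size, replace=False)
    )
    planted_genes = [genes[i] for i in planted]

    # --- network: ER background + connected planted subgraph -------------
    g = nx.gnp_random_graph(
        spec.n_genes,
        spec.background_edge_prob,
        seed=int(rng.integers(2**31)),
    )
    graph = nx.relabel_nodes(g, dict(enumerate(genes)))
    # random spanning tree over the planted genes: attach each gene to a
    # uniformly chosen earlier one in a random order
    order = list(rng.permutation(planted_genes))
    for i in range(1, len(order)):
        j = int(rng.integers(i))
        graph.add_edge(order[i], order[j])
    # extra internal edges thicken the planted subgraph
    for i in range(len(planted_genes)):
        for j in range(i + 1, len(planted_genes)):
            if rng.random() < 0.3:
                graph.add_edge(planted_genes[i], planted_genes[j])
    net = PPINetwork(graph)

    # --- expression and phenotypes ---------------------------------------
    n_samples = 2 * spec.n_per_group
    sample_ids = [f"s{str(i).zfill(len(str(n_samples)))}"
                  for i in range(1, n_samples + 1)]
    values = rng.standard_normal((spec.n_genes, n_samples))
    case_cols = np.arange(spec.n_per_group, n_samples)
    values[np.ix_(planted, case_cols)] += spec.effect
    expr = ExpressionMatrix(genes, sample_ids, values)
    labels = PhenotypeLabels(
        {s: (NORMAL if i < spec.n_per_group else CASE)
         for i, s in enumerate(sample_ids)}
    )

    # --- pathway catalogue and DMF background ----------------------------
    lo, hi = spec.pathway_size_range
    n_dmf = max(2, round(_DMF_FRACTION * spec.n_pathways))
    n_forced = round(spec.dmf_overlap * n_dmf)
    sets: dict[str, frozenset[str]] = {}
    dmf_names: list[str] = []
    for p in range(spec.n_pathways):
        name = f"PW{p + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if p < n_forced:
            # DMF pathway seeded with >= 50% planted genes; its size is
            # capped at twice the planted set so the guarantee is feasible
            size = min(size, 2 * spec.planted_size)
            n_pl = max((size + 1) // 2, 1)
            pl = rng.choice(spec.planted_size, size=n_pl, replace=False)
            non_planted = [i for i in range(spec.n_genes) if i not in planted]
            rest = rng.choice(len(non_planted), size=size - n_pl, replace=False)
            members = ({planted_genes[i] for i in pl}
                       | {genes[non_planted[i]] for i in rest})
        else:
            members = {genes[i]
                       for i in rng.choice(spec.n_genes, size=size, replace=False)}
        sets[name] = frozenset(members)
        if p < n_dmf:
            dmf_names.append(name)
    catalogue = PathwayCollection(dict(sets))
    background = catalogue.subset(dmf_names)

    truth = GroundTruth(frozenset(planted_genes), frozenset(dmf_names))
    assert net.is_connected_subset(planted_genes)
    return expr, labels, net, catalogue, background, truth


def generate_null_instance(spec: SyntheticSpec):
    """Same construction with the planted effect forced to zero.

    The planted gene set is still recorded in the ground truth, so null
    runs can be compared gene-for-gene with signal runs.
    """
    null_spec = SyntheticSpec(
        n_genes=spec.n_genes,
        n_per_group=spec.n_per_group,
        planted_size=spec.planted_size,
        effect=0.0,
        background_edge_prob=spec.background_edge_prob,
        n_pathways=spec.n_pathways,
        pathway_size_range=spec.pathway_size_range,
        dmf_overlap=spec.dmf_overlap,
        rng_seed=spec.rng_seed,
    )
    return generate_instance(null_spec)


def write_instance(out_dir: str | Path, expr, labels, net, catalogue,
                   background) -> dict[str, Path]:
    """Write an instance to the same text formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "network": out / "network.tsv",
        "catalogue": out / "catalogue.gmt",
        "background": out / "background.gmt",
    }
    write_expression(expr, paths["expression"])
    write_phenotypes(labels, paths["phenotypes"])
    write_network(net, paths["network"])
    write_gene_sets(catalogue, paths["catalogue"])
    write_gene_sets(background, paths["background"])
    return paths
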