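"""Core domain types and plain-text readers/writers.

All pipeline inputs are tab-separated UTF-8 text: an expression matrix
(genes in rows, samples in columns), a two-column phenotype table, a
two-column interaction edge list, and GMT gene-set catalogues.  Lines
starting with ``#`` are ignored in every format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("modmark")

NORMAL = "NORMAL"
CASE = "CASE"

#: default phenotype-label aliases (case-insensitive match on the raw string)
DEFAULT_LABEL_ALIASES: dict[str, str] = {
    "ngt": NORMAL,
    "control": NORMAL,
    "normal": NORMAL,
    "dm": CASE,
    "t2dm": CASE,
    "case": CASE,
    "disease": CASE,
}


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix with unique row/column identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 4:
            raise ValueError("expression matrix needs >= 2 genes and >= 4 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing[:5]}")
        return np.fromiter((self._gene_index[g] for g in genes), dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(genes)
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PhenotypeLabels:
    """Mapping sample_id -> NORMAL/CASE binary phenotype."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {NORMAL, CASE}
        if bad:
            raise ValueError(f"labels must be NORMAL or CASE, got {sorted(bad)}")
        counts = self.counts()
        if counts[NORMAL] < 2 or counts[CASE] < 2:
            raise ValueError(
                "need >= 2 samples per phenotype group to fit a variance "
                f"(got NORMAL={counts[NORMAL]}, CASE={counts[CASE]})"
            )

    def counts(self) -> dict[str, int]:
        c = {NORMAL: 0, CASE: 0}
        for v in self.labels.values():
            c[v] = c.get(v, 0) + 1
        return c

    def samples(self, label: str) -> list[str]:
        return [s for s, v in self.labels.items() if v == label]

    def group_masks(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (normal, case) masks aligned with ``sample_ids``."""
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without phenotype label: {missing[:5]}")
        lab = np.array([self.labels[s] for s in sample_ids])
        return lab == NORMAL, lab == CASE

    def check_against(self, expr: ExpressionMatrix) -> None:
        extra = set(self.labels) - set(expr.sample_ids)
        if extra:
            raise ValueError(
                f"phenotype samples absent from expression matrix: {sorted(extra)[:5]}"
            )


@dataclass
class PPINetwork:
    """Undirected simple protein-interaction graph over gene identifiers."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str] = ()) -> "PPINetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        dropped = 0
        for u, v in edges:
            if u == v:
                dropped += 1
                continue
            g.add_edge(u, v)
        if dropped:
            logger.info("dropped %d self-loop edge record(s)", dropped)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def neighborhood(self, members: Iterable[str]) -> set[str]:
        """N(M): union of member neighbour sets, minus the members."""
        members = set(members)
        out: set[str] = set()
        for g in members:
            out.update(self.graph.neighbors(g))
        return out - members

    def induced(self, genes: Iterable[str]) -> "PPINetwork":
        return PPINetwork(self.graph.subgraph(set(genes)).copy())

    def is_connected_subset(self, genes: Sequence[str]) -> bool:
        sub = self.graph.subgraph(genes)
        return len(genes) > 0 and nx.is_connected(sub)


@dataclass
class PathwayCollection:
    """Named, non-empty gene sets (a pathway catalogue)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "PathwayCollection":
        names = list(names)
        return PathwayCollection(
            {n: self.sets[n] for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )

    def restrict_to(self, universe: set[str], drop_empty: bool = True
                    ) -> "PathwayCollection":
        sets, desc = {}, {}
        for n, g in self.sets.items():
            gg = g & universe
            if gg or not drop_empty:
                sets[n] = gg
                desc[n] = self.descriptions.get(n, "")
        return PathwayCollection(sets, desc)


@dataclass
class Module:
    """A connected gene set grown from a seed, with its overlap-area value.

    ``trace`` records each accepted addition as (gene, disa-after-addition);
    the seed itself is not in the trace.
    """

    seed: str
    members: list[str]
    disa: float
    trace: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members or self.members[0] != self.seed:
            raise ValueError("module members must start with the seed")
        if len(set(self.members)) != len(self.members):
            raise ValueError("module members must be unique")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def module_id(self) -> str:
        return f"M_{self.seed}"

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "seed": self.seed,
            "members": list(self.members),
            "disa": self.disa,
            "trace": [[g, d] for g, d in self.trace],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Module":
        return cls(
            seed=d["seed"],
            members=list(d["members"]),
            disa=float(d["disa"]),
            trace=[(g, float(x)) for g, x in d.get("trace", [])],
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            out.append((i, line))
    return out


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} ID: {x!r}")
        seen.add(x)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first row samples, first column genes)."""
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header = lines[0][1].split("\t")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                f"got {len(parts)}"
            )
        gene_ids.append(parts[0])
        vals = []
        for j, cell in enumerate(parts[1:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} for gene "
                    f"{parts[0]!r}, sample {sample_ids[j]!r}"
                ) from None
        rows.append(vals)
    _check_unique(gene_ids, "gene")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_phenotypes(path: str | Path,
                    aliases: Mapping[str, str] | None = None,
                    expr: ExpressionMatrix | None = None) -> PhenotypeLabels:
    """Read a two-column sample_id / label TSV, normalising labels via aliases."""
    alias_map = dict(DEFAULT_LABEL_ALIASES)
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})
    labels: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        sample, raw = parts[0], parts[1]
        if sample in labels:
            raise FormatError(f"{path}:{lineno}: duplicate sample ID {sample!r}")
        key = raw.lower()
        if key not in alias_map:
            raise FormatError(
                f"{path}:{lineno}: unknown phenotype label {raw!r}; accepted "
                f"aliases: {sorted(alias_map)}"
            )
        labels[sample] = alias_map[key]
    if not labels:
        raise FormatError(f"{path}: empty phenotype file")
    pheno = PhenotypeLabels(labels)
    if expr is not None:
        pheno.check_against(expr)
    return pheno


def write_phenotypes(pheno: PhenotypeLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, lab in pheno.labels.items():
            fh.write(f"{s}\t{lab}\n")


def read_network(path: str | Path) -> PPINetwork:
    """Read a two-column TSV edge list into an undirected simple graph."""
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
        edges.append((parts[0], parts[1]))
    net = PPINetwork.from_edges(edges)
    kept = net.n_edges
    logger.info("read %d edge records, kept %d unique edges", len(edges), kept)
    return net


def write_network(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_gene_sets(path: str | Path) -> PathwayCollection:
    """Read a GMT file (name, description, genes...; tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
            )
        name = parts[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        genes = frozenset(g for g in parts[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
        sets[name] = genes
        desc[name] = parts[1]
    return PathwayCollection(sets, desc)


def write_gene_sets(col: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in col:
            d = col.descriptions.get(name, "")
            fh.write(name + "\t" + d + "\t" + "\t".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# module result output (JSON authoritative, TSV summary alongside)
# ---------------------------------------------------------------------------


def write_modules(modules: Sequence[Module], json_path: str | Path,
                  tsv_path: str | Path | None = None,
                  scores: Mapping[str, float] | None = None,
                  metadata: Mapping | None = None) -> None:
    doc = {
        "metadata": dict(metadata or {}),
        "modules": [m.to_dict() for m in modules],
    }
    if scores is not None:
        for m in doc["modules"]:
            m["score"] = scores.get(m["module_id"])
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w", encoding="utf-8") as fh:
            fh.write("module_id\tseed\tsize\tdisa\tscore\n")
            for m in modules:
                sc = "" if scores is None else f"{scores.get(m.module_id, '')}"
                fh.write(f"{m.module_id}\t{m.seed}\t{m.size}\t{m.disa!r}\t{sc}\n")


def read_modules(json_path: str | Path) -> list[Module]:
    with open(json_path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return [Module.from_dict(d) for d in doc["modules"]]
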