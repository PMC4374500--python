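"""End-to-end orchestration: preprocess -> seeds -> discover -> score -> evaluate.

Each stage writes its outputs to the run directory as it completes, so a
failed run retains everything up to the failing stage and a re-run can
skip stages whose outputs already exist (unless forced).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .discovery import DiscoveryConfig, activity_correlations, discover_modules
from .evaluation import crossvalidate, noise_robustness
from .io import (
    ExpressionMatrix,
    Module,
    PathwayCollection,
    PhenotypeLabels,
    PPINetwork,
    read_expression,
    read_gene_sets,
    read_network,
    read_phenotypes,
    write_expression,
    write_modules,
)
from .preprocess import restrict_to_common_genes, zscore_rows
from .scoring import score_modules
from .seeds import gene_t_tests, select_seeds

logger = logging.getLogger("modmark")


class EmptyResultError(RuntimeError):
    """A stage produced no usable output (no seeds / no surviving modules)."""


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    expression: str | Path
    phenotypes: str | Path
    network: str | Path
    catalogue: str | Path
    background: str | Path
    out_dir: str | Path = "modmark_run"
    alpha_seed: float = 0.01
    delta: float = 0.001
    disa_filter: float = 0.2
    max_module_size: int = 50
    alpha_enrich: float = 0.05
    n_folds: int = 10
    noise_fractions: list[float] = field(
        default_factory=lambda: [round(0.01 * i, 2) for i in range(1, 11)]
    )
    noise_reps: int = 100
    rng_seed: int = 0
    zscore: bool = True
    equal_var: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha_seed <= 1:
            raise ValueError("alpha_seed must lie in (0, 1]")
        if not 0 < self.alpha_enrich < 1:
            raise ValueError("alpha_enrich must lie in (0, 1)")
        # validates delta/disa_filter/max_module_size ranges
        self.discovery_config()

    def discovery_config(self) -> DiscoveryConfig:
        return DiscoveryConfig(
            delta=self.delta,
            disa_filter=self.disa_filter,
            max_module_size=self.max_module_size,
        )


@dataclass
class PipelineResult:
    biomarker: Module
    modules: list[Module]
    scores: list  # list[ModuleScore]
    seeds: list[str]
    cv_report: object
    noise_report: object | None
    out_dir: Path


def run_pipeline(cfg: RunConfig, run_noise: bool = True) -> PipelineResult:
    """Execute the full discovery flow and return the top-scored module.

    Raises :class:`EmptyResultError` when no seed passes the threshold or
    no grown module survives the disa filter; partial outputs are on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}

    expr = read_expression(cfg.expression)
    pheno = read_phenotypes(cfg.phenotypes, expr=expr)
    net = read_network(cfg.network)
    catalogue = read_gene_sets(cfg.catalogue)
    background = read_gene_sets(cfg.background)
    timings["load"] = time.time() - t0

    return run_pipeline_objects(
        expr, pheno, net, catalogue, background, cfg,
        run_noise=run_noise, out=out, timings=timings,
    )


def run_pipeline_objects(
    expr: ExpressionMatrix,
    pheno: PhenotypeLabels,
    net: PPINetwork,
    catalogue: PathwayCollection,
    background: PathwayCollection,
    cfg: RunConfig,
    run_noise: bool = True,
    out: Path | None = None,
    timings: dict | None = None,
) -> PipelineResult:
    """In-memory variant of :func:`run_pipeline` (used by tests/simulations)."""
    timings = timings if timings is not None else {}
    t = time.time()

    # preprocess
    net, expr = restrict_to_common_genes(net, expr)
    if cfg.zscore:
        expr = zscore_rows(expr)
    if out:
        write_expression(expr, out / "expression.preprocessed.tsv")
    timings["preprocess"] = time.time() - t

    # seeds
    t = time.time()
    tests = gene_t_tests(expr, pheno, equal_var=cfg.equal_var)
    seeds = select_seeds(tests, cfg.alpha_seed)
    if out:
        with open(out / "seeds.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\tt_stat\tp_value\tp_adjusted\tis_seed\n")
            seedset = set(seeds)
            for r in tests:
                fh.write(
                    f"{r.gene_id}\t{r.t_stat!r}\t{r.p_value!r}\t"
                    f"{r.p_adjusted!r}\t{int(r.gene_id in seedset)}\n"
                )
    timings["seeds"] = time.time() - t
    logger.info("selected %d seeds at adjusted p < %g", len(seeds), cfg.alpha_seed)
    if not seeds:
        raise EmptyResultError(
            f"no gene passed the seed threshold (adjusted p < {cfg.alpha_seed})"
        )

    # discover
    t = time.time()
    modules = discover_modules(seeds, net, expr, pheno, cfg.discovery_config())
    if out:
        write_modules(modules, out / "modules.json", out / "modules.tsv",
                      metadata=_manifest_meta(cfg))
    timings["discover"] = time.time() - t
    if not modules:
        raise EmptyResultError(
            f"no module survived the disa <= {cfg.disa_filter} filter"
        )
    if len(modules) > 1:
        cc = activity_correlations(modules, expr)
        iu = np.triu_indices(len(modules), k=1)
        vals = cc[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            logger.info(
                "module-activity redundancy: median pairwise PCC %.3f, "
                "%.0f%% of pairs > 0.6",
                float(np.median(vals)), 100 * float(np.mean(vals > 0.6)),
            )

    # score
    t = time.time()
    scores = score_modules(
        modules, catalogue, background, universe=net.nodes,
        alpha_enrich=cfg.alpha_enrich,
    )
    by_id = {m.module_id: m for m in modules}
    biomarker = by_id[scores[0].module_id]
    if out:
        score_map = {s.module_id: s.score for s in scores}
        write_modules(modules, out / "modules.scored.json",
                      out / "modules.scored.tsv", scores=score_map,
                      metadata=_manifest_meta(cfg))
    timings["score"] = time.time() - t

    # evaluate
    t = time.time()
    cv = crossvalidate(expr, pheno, biomarker.members,
                       n_folds=cfg.n_folds, rng_seed=cfg.rng_seed)
    noise = None
    if run_noise and cfg.noise_fractions and cfg.noise_reps > 0:
        noise = noise_robustness(
            expr, pheno, biomarker.members, cfg.noise_fractions,
            n_reps=cfg.noise_reps, n_folds=cfg.n_folds, rng_seed=cfg.rng_seed,
        )
    timings["evaluate"] = time.time() - t

    if out:
        report = {
            "biomarker": biomarker.to_dict(),
            "score": scores[0].score,
            "cv": dataclasses.asdict(cv),
            "noise": _noise_dict(noise),
        }
        with open(out / "evaluation.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1)
            fh.write("\n")
        manifest = {
            **_manifest_meta(cfg),
            "n_seeds": len(seeds),
            "n_modules": len(modules),
            "top_score": scores[0].score,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
            fh.write("\n")

    return PipelineResult(
        biomarker=biomarker, modules=modules, scores=scores, seeds=seeds,
        cv_report=cv, noise_report=noise, out_dir=out or Path("."),
    )


def _manifest_meta(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for k in ("expression", "phenotypes", "network", "catalogue",
              "background", "out_dir"):
        d[k] = str(d[k])
    return {"modmark_version": __version__, "config": d,
            "rng_seed": cfg.rng_seed}


def _noise_dict(noise) -> dict | None:
    if noise is None:
        return None
    return {
        "fractions": noise.fractions,
        "mean_accuracy": {str(k): v for k, v in noise.mean_accuracy.items()},
        "sd_accuracy": {str(k): v for k, v in noise.sd_accuracy.items()},
        "ci95": {str(k): list(v) for k, v in noise.ci95.items()},
        "percentiles": {str(k): list(v) for k, v in noise.percentiles.items()},
        "n_repetitions": noise.n_repetitions,
    }
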