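"""End-to-end orchestration: preprocess -> instruments -> network -> effects.

A run is configured by a :class:`PipelineConfig` (loadable from YAML),
executes the four analysis stages in order and writes every
intermediate artifact into a run directory, together with a snapshot
of the configuration so every number in the outputs is traceable.
Artifacts contain no wall-clock information: identical configuration
and seed reproduce the run directory bit for bit.  Stage timings go to
the logger only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
import yaml

from . import io as cio
from .containers import GenotypeMatrix, MetaboliteMatrix, PhenotypeTable
from .effects import DirectEffectAnalyzer
from .instruments import GenomicInstrumentBuilder, LDProxyReducer
from .network import CausalNetworkLearner
from .preprocessing import (
    filter_missingness,
    harmonize_samples,
    prepare_outcome,
    transform_metabolites,
)

logger = logging.getLogger("causalome")

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    ``alpha`` is the single statistical tuning parameter; the remaining
    fields are operational defaults, echoed into the run snapshot so
    every choice is visible.
    """

    genotypes: str = ""
    metabolites: str = ""
    phenotypes: str = ""
    covariates: str | None = None
    alpha: float = 0.001
    r2_threshold: float = 0.80
    assoc_threshold: float = 5e-8
    max_members: int = 20
    max_order: int = 3
    stage2: bool = True
    f_min: float = 10.0
    n_boot: int = 200
    seed: int = 0
    winsor_lower: float = 0.01
    winsor_upper: float = 0.99
    metabolite_transform: str = "log_standardize"
    max_missing_frac: float = 0.2
    restrict_to_baseline: bool = True
    min_visit_n: int = 100
    adjust_covariates: bool = True
    adjust_selection: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "r2_threshold", "max_missing_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 <= self.winsor_lower < self.winsor_upper <= 1.0):
            raise ValueError("winsorisation quantiles must satisfy 0 <= lo < hi <= 1")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update(overrides)
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_inputs(config: PipelineConfig) -> None:
    for name in ("genotypes", "metabolites", "phenotypes"):
        path = getattr(config, name)
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"{name} file not found: {path!r}")
    if config.covariates and not os.path.exists(config.covariates):
        raise FileNotFoundError(f"covariates file not found: {config.covariates!r}")


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute the full analysis; returns a summary dict.

    Writes, under ``out_dir``: the config snapshot, preprocessing
    report, LD clusters and instruments, the network edge list and
    GraphML, the orientation log, the effect table and a JSON summary.
    On a stage failure the artifacts written so far are left in place
    and the failing stage is named.
    """
    _check_inputs(config)
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    stage = "load"
    try:
        t0 = time.time()
        if config.genotypes.endswith((".vcf", ".vcf.gz")):
            genotypes = cio.read_vcf(config.genotypes)
        else:
            genotypes = cio.read_dosage_tsv(config.genotypes)
        metabolites = MetaboliteMatrix(cio.read_table(config.metabolites), "raw")
        phenotypes = cio.load_phenotypes(config.phenotypes, config.covariates)
        logger.info("load: %.1fs", time.time() - t0)

        stage = "preprocessing"
        t0 = time.time()
        metabolites, report = filter_missingness(metabolites, config.max_missing_frac)
        genotypes, metabolites, phenotypes = harmonize_samples(
            genotypes, metabolites, phenotypes
        )
        metabolites = transform_metabolites(metabolites, config.metabolite_transform)
        phenotypes = prepare_outcome(phenotypes, config.winsor_lower, config.winsor_upper)
        with open(os.path.join(out_dir, "preprocess_report.json"), "w") as fh:
            json.dump(
                {
                    "dropped_metabolites": report.dropped,
                    "missingness_threshold": report.threshold,
                    "n_samples": len(metabolites.sample_ids),
                    "n_metabolites": len(metabolites.metabolite_ids),
                    "winsorisation": phenotypes.transform_log,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        logger.info("preprocessing: %.1fs", time.time() - t0)

        stage = "genome_instruments"
        t0 = time.time()
        reducer = LDProxyReducer(r2_threshold=config.r2_threshold).fit(genotypes)
        proxies = reducer.transform(genotypes)
        cluster_rows = [
            {"cluster": lab, "proxy": reducer.clustering_.proxies[lab],
             "members": ",".join(members), "size": len(members)}
            for lab, members in sorted(reducer.clustering_.clusters.items())
        ]
        cio.write_table(pd.DataFrame(cluster_rows).set_index("cluster"),
                        os.path.join(out_dir, "ld_clusters.tsv"))
        builder = GenomicInstrumentBuilder(
            assoc_threshold=config.assoc_threshold,
            max_members=config.max_members,
            f_min=config.f_min,
        ).fit(proxies, metabolites.values)
        inst = builder.instrument_set_
        cio.write_table(inst.to_frame(), os.path.join(out_dir, "instruments.tsv"))
        cio.write_table(builder.scores_, os.path.join(out_dir, "instrument_scores.tsv"))
        logger.info("genome_instruments: %.1fs", time.time() - t0)

        stage = "network_discovery"
        t0 = time.time()
        learner = CausalNetworkLearner(
            alpha=config.alpha,
            max_order=config.max_order,
            stage2=config.stage2,
            f_min=config.f_min,
        ).fit(metabolites.values, instruments=inst)
        graph = learner.graph_
        cio.write_table(graph.to_frame().set_index("source"),
                        os.path.join(out_dir, "network_edges.tsv"))
        nx.write_graphml(graph.to_networkx(), os.path.join(out_dir, "network.graphml"))
        with open(os.path.join(out_dir, "orientation_log.txt"), "w") as fh:
            fh.write("\n".join(graph.log) + "\n")
        logger.info("network_discovery: %.1fs", time.time() - t0)

        stage = "effect_analysis"
        t0 = time.time()
        covariates = (
            phenotypes.covariates
            if config.adjust_covariates and phenotypes.covariates.shape[1] > 0
            else None
        )
        analyzer = DirectEffectAnalyzer(
            alpha=config.alpha,
            n_boot=config.n_boot,
            seed=config.seed,
            restrict_to_baseline=config.restrict_to_baseline,
            min_visit_n=config.min_visit_n,
            adjust_selection=config.adjust_selection,
        ).fit(metabolites.values, phenotypes, graph=graph, covariates=covariates)
        cio.write_table(
            analyzer.effect_table_.set_index("metabolite"),
            os.path.join(out_dir, "effect_table.tsv"),
        )
        logger.info("effect_analysis: %.1fs", time.time() - t0)
    except Exception:
        logger.error("pipeline failed at stage %s", stage)
        raise

    summary = {
        "n_samples": len(metabolites.sample_ids),
        "n_metabolites": len(metabolites.metabolite_ids),
        "n_proxies": len(proxies.variant_ids),
        "n_instrumented": len(inst.usable(config.f_min)),
        "n_edges_directed": len(graph.directed) - len(graph.instrument_nodes),
        "n_edges_undirected": len(graph.undirected),
        "n_edges_conflict": len(graph.conflicts),
        "direct": analyzer.direct_,
        "indirect": analyzer.indirect_,
        "alpha": config.alpha,
        "seed": config.seed,
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def render_report(run_dir: str) -> str:
    """Human-readable markdown summary of a completed run (idempotent)."""
    path = os.path.join(run_dir, "report.md")
    lines = ["# Causal network analysis report", ""]
    missing = []

    def _load(name):
        p = os.path.join(run_dir, name)
        if not os.path.exists(p):
            missing.append(name)
            return None
        return p

    summary_path = _load("summary.json")
    if summary_path:
        with open(summary_path) as fh:
            summary = json.load(fh)
        lines += [
            "## Network summary",
            "",
            f"- samples: {summary['n_samples']}",
            f"- metabolites: {summary['n_metabolites']}",
            f"- LD proxies: {summary['n_proxies']} (instrumented metabolites: {summary['n_instrumented']})",
            f"- edges: {summary['n_edges_directed']} directed, "
            f"{summary['n_edges_undirected']} undirected (undecided), "
            f"{summary['n_edges_conflict']} in conflict",
            "",
        ]
        direct = summary["direct"]
        lines += ["## Metabolites with direct effects", ""]
        if direct:
            lines += [f"- {m}" for m in direct]
        else:
            lines.append(
                f"No metabolite shows a significant direct effect at alpha = {summary['alpha']}."
            )
        lines.append("")
        if summary["indirect"]:
            lines += ["## Metabolites with indirect effects", ""]
            lines += [f"- {m}" for m in summary["indirect"]] + [""]

    table_path = _load("effect_table.tsv")
    if table_path:
        table = pd.read_csv(table_path, sep="\t", na_values=["NA"])
        shown = table[table["status"].isin(["direct", "indirect"])]
        if len(shown):
            lines += ["## Effects in SD units (per visit)", ""]
            shown = shown.sort_values(["visit", "p_direct"], na_position="last")
            lines.append("| metabolite | visit | status | total effect | SE | p (direct test) |")
            lines.append("|---|---|---|---|---|---|")
            for _, row in shown.iterrows():
                lines.append(
                    f"| {row['metabolite']} | {row['visit']} | {row['status']} | "
                    f"{row['total_effect']:.3f} | {row['se']:.3f} | {row['p_direct']:.2e} |"
                )
            lines.append("")
    if missing:
        lines += ["## Incomplete run", ""]
        lines += [f"- missing artifact: {m}" for m in missing] + [""]
    text = "\n".join(lines)
    with open(path, "w") as fh:
        fh.write(text)
    return path
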