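"""End-to-end orchestration: filter → fish → dockfilter → network → enrich.

The pipeline consumes a compound SDF (or precomputed descriptor TSV), a
per-target known-ligand library, an interaction-score table and a GMT
pathway annotation; it writes every intermediate as TSV plus a structured
run report.  Thresholds default to the study settings: similarity 0.8,
score cutoff −8.0, enrichment alpha 0.01.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chem_io import read_sdf
from .ct_network import build_network, export_network, summarize_network
from .druglikeness import (
    compute_descriptors,
    read_descriptor_table,
    ro5_pass,
    write_descriptor_table,
)
from .enrichment import enrich, read_gmt, write_results_table
from .interaction_filter import apply_score_filter, read_score_table
from .target_fishing import (
    ReferenceLibrary,
    atom_pair_fingerprint,
    screen,
    write_candidate_pairs,
)

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "compounds_sdf": None,
    "descriptor_tsv": None,
    "library_tsv": None,
    "ligands_sdf": None,
    "scores_tsv": None,
    "gmt": None,
    "universe_file": None,
    "similarity_threshold": 0.8,
    "score_cutoff": -8.0,
    "alpha": 0.01,
    "typing_scheme": "element+degree",
    "counted_fingerprints": True,
    "exclude_amide": False,
    "missing_score_policy": "error",
    "sided": "two",
    "bh_correct": False,
    "split_fragments": False,
    "outdir": "phytonet_out",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    settings: dict = field(default_factory=lambda: dict(_DEFAULTS))

    def __getattr__(self, name):
        try:
            return self.settings[name]
        except KeyError:
            raise AttributeError(name) from None


def validate_config(path_or_dict) -> PipelineConfig:
    """Load a YAML config, apply defaults and reject bad values all at once."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a YAML mapping")
    problems = []
    unknown = set(raw) - set(_DEFAULTS)
    for key in sorted(unknown):
        problems.append(f"unknown config key: {key!r}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _DEFAULTS}}
    if not 0 <= merged["similarity_threshold"] <= 1:
        problems.append("similarity_threshold must be in [0, 1]")
    if not 0 < merged["alpha"] < 1:
        problems.append("alpha must be in (0, 1)")
    if merged["missing_score_policy"] not in ("error", "drop"):
        problems.append("missing_score_policy must be 'error' or 'drop'")
    if merged["sided"] not in ("two", "one"):
        problems.append("sided must be 'two' or 'one'")
    if problems:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(problems))
    logger.info("resolved config: %s", merged)
    return PipelineConfig(settings=merged)


@dataclass
class RunReport:
    """Per-stage counts and timings for one pipeline run."""

    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "timings_s": self.timings,
             "config": self.config, "version": self.version},
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"phytonet {self.version} run report", ""]
        for key, value in self.counts.items():
            lines.append(f"  {key}: {value}")
        return "\n".join(lines) + "\n"


def _load_library(config: PipelineConfig) -> ReferenceLibrary:
    df = pd.read_csv(config.library_tsv, sep="\t", dtype=str)
    required = {"target_id", "gene_symbol", "ligand_id"}
    if missing := required - set(df.columns):
        raise ValueError(f"library TSV missing columns: {sorted(missing)}")
    if config.ligands_sdf is None:
        raise ValueError("library requires a ligands SDF with the referenced structures")
    ligand_graphs = {
        rec.id: rec.graph
        for rec in read_sdf(Path(config.ligands_sdf).read_text(),
                            split_fragments=config.split_fragments)
    }
    entries = []
    for row in df.itertuples(index=False):
        if row.ligand_id not in ligand_graphs:
            raise ValueError(f"ligand {row.ligand_id!r} not found in ligands SDF")
        fp = atom_pair_fingerprint(ligand_graphs[row.ligand_id], config.typing_scheme)
        entries.append((row.target_id, row.gene_symbol, row.ligand_id, fp))
    return ReferenceLibrary(entries=entries)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all five stages, writing intermediates and the run report.

    Deterministic given inputs and config.  If the drug-likeness stage
    removes every compound the run exits cleanly with zeroed downstream
    counts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dict(config.settings))
    t0 = time.perf_counter()

    # stage 1: drug-likeness filter
    logger.info("=== stage filter: oral drug-likeness (Ro5) ===")
    graphs = {}
    if config.compounds_sdf:
        records = read_sdf(Path(config.compounds_sdf).read_text(),
                           split_fragments=config.split_fragments)
        graphs = {rec.id: rec.graph for rec in records}
        supplied = {}
        if config.descriptor_tsv:
            supplied = {d.compound_id: d.logP
                        for d in read_descriptor_table(config.descriptor_tsv)}
        descriptors = [
            compute_descriptors(cid, g, supplied.get(cid),
                                exclude_amide=config.exclude_amide)
            for cid, g in graphs.items()
        ]
    elif config.descriptor_tsv:
        descriptors = read_descriptor_table(config.descriptor_tsv)
    else:
        raise ValueError("stage filter: need compounds_sdf or descriptor_tsv")
    passing = [d for d in descriptors if ro5_pass(d)]
    write_descriptor_table(descriptors, outdir / "descriptors.tsv")
    write_descriptor_table(passing, outdir / "druglike.tsv")
    report.counts["compounds_in"] = len(descriptors)
    report.counts["compounds_druglike"] = len(passing)
    report.timings["filter"] = round(time.perf_counter() - t0, 4)

    if not passing:
        logger.warning("no compounds passed the drug-likeness filter; stopping")
        for key in ("candidate_pairs", "initial_targets", "retained_pairs",
                    "final_targets", "final_compounds", "enriched_pathways"):
            report.counts[key] = 0
        _write_report(report, outdir)
        return report

    # stage 2: target fishing
    t1 = time.perf_counter()
    logger.info("=== stage fish: ligand-similarity target fishing ===")
    if not graphs:
        raise ValueError("stage fish: target fishing requires compound structures (compounds_sdf)")
    library = _load_library(config)
    compounds = [
        (d.compound_id, atom_pair_fingerprint(graphs[d.compound_id], config.typing_scheme))
        for d in passing
    ]
    candidates = screen(compounds, library,
                        threshold=config.similarity_threshold,
                        counted=config.counted_fingerprints)
    write_candidate_pairs(candidates, outdir / "candidate_pairs.tsv")
    report.counts["candidate_pairs"] = len(candidates)
    report.counts["initial_targets"] = len({p.target_id for p in candidates})
    report.counts["initial_compounds"] = len({p.compound_id for p in candidates})
    report.timings["fish"] = round(time.perf_counter() - t1, 4)

    # stage 3: interaction-score filter
    t2 = time.perf_counter()
    logger.info("=== stage dockfilter: interaction-score cutoff ===")
    scores = read_score_table(config.scores_tsv)
    result = apply_score_filter(candidates, scores,
                                cutoff=config.score_cutoff,
                                missing=config.missing_score_policy)
    write_candidate_pairs(result.retained, outdir / "retained_pairs.tsv")
    report.counts["retained_pairs"] = len(result.retained)
    report.counts["final_targets"] = result.n_distinct_targets
    report.counts["final_compounds"] = result.n_distinct_compounds
    report.timings["dockfilter"] = round(time.perf_counter() - t2, 4)

    # stage 4: compound-target network
    t3 = time.perf_counter()
    logger.info("=== stage network: bipartite C-T network metrics ===")
    pairs = [(p.compound_id, p.target_id) for p in result.retained]
    net = build_network(pairs)
    sif, attrs = export_network(net)
    (outdir / "network.sif").write_text(sif)
    (outdir / "node_attributes.tsv").write_text(attrs)
    if net.n_nodes >= 3 and net.n_edges >= 1:
        summary = summarize_network(net)
        report.counts["network_nodes"] = summary.n_nodes
        report.counts["network_edges"] = summary.n_edges
        report.counts["network_centralization"] = round(summary.centralization, 4)
        report.counts["network_heterogeneity"] = round(summary.heterogeneity, 4)
    report.timings["network"] = round(time.perf_counter() - t3, 4)

    # stage 5: pathway enrichment
    t4 = time.perf_counter()
    logger.info("=== stage enrich: hypergeometric over-representation ===")
    query = sorted({p.gene_symbol for p in result.retained})
    (outdir / "final_target_genes.txt").write_text("\n".join(query) + "\n")
    if query and config.gmt:
        universe = None
        if config.universe_file:
            universe = {
                line.strip() for line in Path(config.universe_file).read_text().splitlines()
                if line.strip()
            }
        annotation = read_gmt(Path(config.gmt).read_text(), universe=universe)
        results = enrich(query, annotation, alpha=config.alpha,
                         sided=config.sided, bh_correct=config.bh_correct)
        write_results_table(results, outdir / "enrichment.tsv")
        report.counts["enriched_pathways"] = sum(r.passes for r in results)
        report.counts["tested_pathways"] = len(results)
        if results:
            report.counts["top_pathway"] = results[0].pathway_name
    else:
        report.counts["enriched_pathways"] = 0
    report.timings["enrich"] = round(time.perf_counter() - t4, 4)

    _write_report(report, outdir)
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.txt").write_text(report.to_text())
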