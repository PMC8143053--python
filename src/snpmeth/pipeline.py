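"""End-to-end orchestration: filter -> association -> DMS -> integration ->
enrichment -> network, driven by one declarative config.

Every stage reads its inputs from files (the original inputs or a prior
stage's TSV in the output directory) and writes its outputs there, so
stages are individually re-runnable; :func:`run` simply executes them in
order and assembles a JSON summary with the counts at every step.  The
whole run is deterministic given the config and inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (
    CohortDesign,
    read_edge_list,
    read_gene_list,
    read_gene_sets,
    read_intervals,
    read_manifest,
    read_matrix,
    read_meqtl,
    read_variants,
    write_edge_list,
)
from .association import (
    SELECTION_MODES,
    filter_rare_damaging,
    gene_burden_test,
    select_candidate_genes,
    variant_fisher_scan,
)
from .methylation import (
    call_dms,
    dms_direction_summary,
    probe_stats,
    region_distribution,
    sample_correlation,
)
from .integration import (
    case_frequent_genes,
    genes_with_dms_overlap,
    genes_with_island_variants,
    genes_with_meqtl_links,
    integrate,
)
from .enrichment import enrich
from .network import build_graph, prioritize

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    # input paths
    variants: str
    variant_dialect: str  # "vcf" | "tsv"
    design: str
    beta_matrix: str
    manifest: str
    meth_design: str
    islands: str
    meqtl: str
    gene_sets: str
    ppi_edges: str
    known_genes: str
    outdir: str
    # thresholds
    maf_max: float = 0.05
    require_sift_damaging: bool = True
    fisher_alpha: float = 0.05
    burden_alpha: float = 0.05
    candidate_mode: str = "union"
    delta_min: float = 0.1
    p_dms: float = 0.01
    require_dms_target: bool = True
    enrich_p: float = 0.05
    enrich_fdr: float = 0.05
    ppi_min_score: float = 0.4
    max_distance: float = 1
    correlation_flag_threshold: float = 0.9
    genome_build: str = "hg19"  # opaque label, carried through
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in (
            ("maf_max", 0, 0.5),
            ("fisher_alpha", 0, 1),
            ("burden_alpha", 0, 1),
            ("delta_min", 0, 1),
            ("p_dms", 0, 1),
            ("enrich_p", 0, 1),
            ("enrich_fdr", 0, 1),
            ("ppi_min_score", 0, 1),
            ("correlation_flag_threshold", -1, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside legal range [{lo}, {hi}]")
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.candidate_mode not in SELECTION_MODES:
            raise ValueError(f"unknown candidate_mode {self.candidate_mode!r}")
        if self.variant_dialect not in ("vcf", "tsv"):
            raise ValueError(f"unknown variant_dialect {self.variant_dialect!r}")
        for name in (
            "variants", "design", "beta_matrix", "manifest", "meth_design",
            "islands", "meqtl", "gene_sets", "ppi_edges", "known_genes",
        ):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config input {name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        return cfg

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, outdir: str | Path, **overrides) -> "PipelineConfig":
        """Convenience constructor pointing at a simulated fixture bundle."""
        b = Path(bundle_dir)
        return cls(
            variants=str(b / "variants.tsv"),
            variant_dialect="tsv",
            design=str(b / "design.tsv"),
            beta_matrix=str(b / "beta_matrix.tsv"),
            manifest=str(b / "manifest.tsv"),
            meth_design=str(b / "meth_design.tsv"),
            islands=str(b / "islands.bed"),
            meqtl=str(b / "meqtl.tsv"),
            gene_sets=str(b / "terms.gmt"),
            ppi_edges=str(b / "ppi.tsv"),
            known_genes=str(b / "known_genes.txt"),
            outdir=str(outdir),
            **overrides,
        )


def _read_design(path: str | Path) -> CohortDesign:
    return CohortDesign.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# stages (each reads files, writes files)
# ---------------------------------------------------------------------------


def stage_assoc(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    variants = read_variants(cfg.variants, cfg.variant_dialect)
    design = _read_design(cfg.design)
    filtered, class_summary = filter_rare_damaging(
        variants, maf_max=cfg.maf_max, require_sift_damaging=cfg.require_sift_damaging
    )
    class_summary.to_csv(out / "variant_class_summary.tsv", sep="\t", index=False)
    scan = variant_fisher_scan(filtered, design)
    scan.to_csv(out / "variant_scan.tsv", sep="\t", index=False)
    burden = gene_burden_test(filtered, design)
    burden.to_csv(out / "gene_association.tsv", sep="\t", index=False)
    candidates = select_candidate_genes(
        burden,
        fisher_alpha=cfg.fisher_alpha,
        burden_alpha=cfg.burden_alpha,
        mode=cfg.candidate_mode,
    )
    candidates.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    # the filtered variant subset is reused by the integration stage
    from .io import write_variants_tsv

    write_variants_tsv(filtered, out / "filtered_variants.tsv")
    return {
        "n_variants_input": len(variants),
        "n_variants_filtered": len(filtered),
        "n_genes_tested": len(burden),
        "n_genes_fisher": int((burden["fisher_min_p"] < cfg.fisher_alpha).sum()),
        "n_genes_burden": int((burden["burden_p"] < cfg.burden_alpha).sum()),
        "n_candidate_genes": len(candidates),
    }


def stage_dms(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_matrix(cfg.beta_matrix)
    manifest = read_manifest(cfg.manifest)
    design = _read_design(cfg.meth_design)
    corr, flagged = sample_correlation(matrix, design, cfg.correlation_flag_threshold)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t")
    stats_df = probe_stats(matrix, design)
    stats_df.to_csv(out / "probe_stats.tsv", sep="\t")
    dms = call_dms(stats_df, manifest, delta_min=cfg.delta_min, p_max=cfg.p_dms)
    dms.to_csv(out / "dms.tsv", sep="\t")
    region = region_distribution(dms, manifest)
    region.to_csv(out / "region_distribution.tsv", sep="\t", index=False)
    direction = dms_direction_summary(dms)
    direction.to_csv(out / "dms_direction_summary.tsv", sep="\t", index=False)
    n_hyper = int(direction.loc[direction["direction"] == "hyper", "n"].iloc[0])
    return {
        "n_probes": len(matrix),
        "qc_flagged_samples": flagged,
        "n_dms": len(dms),
        "n_dms_hyper": n_hyper,
        "n_dms_hypo": len(dms) - n_hyper,
    }


def stage_integrate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    candidates = pd.read_csv(out / "candidate_genes.tsv", sep="\t")["gene"].tolist()
    filtered = read_variants(out / "filtered_variants.tsv", "tsv")
    dms = pd.read_csv(out / "dms.tsv", sep="\t", index_col=0)
    islands = read_intervals(cfg.islands)
    meqtl = read_meqtl(cfg.meqtl)
    manifest = read_manifest(cfg.manifest)
    known = read_gene_list(cfg.known_genes)

    d_genes = genes_with_dms_overlap(candidates, dms)
    i_genes = genes_with_island_variants(candidates, filtered, islands)
    m_genes = genes_with_meqtl_links(
        candidates, filtered, meqtl, dms=dms, manifest=manifest,
        require_dms_target=cfg.require_dms_target,
    )
    table, venn = integrate(d_genes, i_genes, m_genes, known_genes=known)
    table.to_csv(out / "integrated_candidates.tsv", sep="\t", index=False)
    with open(out / "venn_counts.json", "w") as fh:
        json.dump(venn, fh, indent=2)
    burden = pd.read_csv(out / "gene_association.tsv", sep="\t")
    frequent = case_frequent_genes(table, burden)
    frequent.to_csv(out / "case_frequent_candidates.tsv", sep="\t", index=False)
    return {
        "n_genes_dms_overlap": len(d_genes),
        "n_genes_island_variant": len(i_genes),
        "n_genes_meqtl_link": len(m_genes),
        "n_integrated": len(table),
        "n_case_frequent": len(frequent),
        "venn": venn,
    }


def stage_enrich(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    table = pd.read_csv(out / "integrated_candidates.tsv", sep="\t")
    term_map = read_gene_sets(cfg.gene_sets)
    res = enrich(
        table["gene"], term_map, report_p=cfg.enrich_p, report_fdr=cfg.enrich_fdr
    )
    res.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return {
        "n_terms_tested": len(res),
        "n_terms_significant": int(res["significant"].sum()) if len(res) else 0,
    }


def stage_network(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    table = pd.read_csv(out / "integrated_candidates.tsv", sep="\t")
    edges = read_edge_list(cfg.ppi_edges)
    known = read_gene_list(cfg.known_genes)
    graph = build_graph(edges, min_score=cfg.ppi_min_score, extra_nodes=known)
    kept, sub_edges = prioritize(table, graph, known, max_distance=cfg.max_distance)
    kept.to_csv(out / "final_candidates.tsv", sep="\t", index=False)
    write_edge_list(sub_edges, out / "subnetwork.tsv")
    return {
        "n_graph_nodes": graph.number_of_nodes(),
        "n_graph_edges": graph.number_of_edges(),
        "n_final_candidates": len(kept),
        "final_candidates": kept["gene"].tolist(),
    }


def run(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the summary."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    summary: dict = {
        "snpmeth_version": __version__,
        "config": {k: v for k, v in asdict(cfg).items()},
    }
    for name, stage in (
        ("assoc", stage_assoc),
        ("dms", stage_dms),
        ("integrate", stage_integrate),
        ("enrich", stage_enrich),
        ("network", stage_network),
    ):
        try:
            summary[name] = stage(cfg)
        except Exception as exc:  # annotate the failing stage, then abort
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s done", name)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return summary
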