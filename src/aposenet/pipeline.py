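"""End-to-end orchestration: SE calling -> binding integration -> network.

``run_pipeline`` composes every stage on file inputs and writes the stage
tables plus a headline ``report.tsv``.  Runs are deterministic: identical
inputs and configuration produce byte-identical outputs.  Parameters and
input checksums are logged at run start; any stage failure aborts with the
stage name and the offending input.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .integration import (
    associate_genes,
    binding_bias_summary,
    biotype_breakdown,
    classify_de,
    crosstab_sirna_e2,
    round_pct_half_up,
    select_se_aerbs,
)
from .network import (
    annotate_nodes,
    build_network,
    build_promoter_footprints,
    extend_aerbs,
    write_graphml,
)
from .se_caller import SECallParameters, call_super_enhancers, se_table

logger = logging.getLogger(__name__)

# biotypes counted as lncRNA in breakdowns (everything annotated non-coding)
LNCRNA_BIOTYPES = {
    "antisense",
    "lincRNA",
    "processed_pseudogene",
    "processed_transcript",
    "transcribed_unprocessed_pseudogene",
    "snoRNA",
    "TEC",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and its input."""


@dataclass
class PipelineConfig:
    """Paths and parameters of a full pipeline run."""

    peaks: str
    chip: str
    input: str
    aerbs: str
    genes: str
    de_sirna: str
    de_e2: str
    pairs: list = field(default_factory=list)  # one BEDPE per experiment
    out_dir: str = "results"
    stitch_distance: int = 12_500
    tss_exclusion_window: int = 0
    window: int = 100_000
    alpha_sirna: float = 0.001
    alpha_timecourse: float = 0.05
    promoter_up: int = 2_000
    promoter_down: int = 500
    aerbs_pad: int = 1_000
    top_k: int = 50
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def input_paths(self) -> dict:
        paths = {
            "peaks": self.peaks,
            "chip": self.chip,
            "input": self.input,
            "aerbs": self.aerbs,
            "genes": self.genes,
            "de_sirna": self.de_sirna,
            "de_e2": self.de_e2,
        }
        for i, p in enumerate(self.pairs):
            paths[f"pairs_{i}"] = p
        return paths

    def validate(self) -> None:
        for name, p in self.input_paths().items():
            if not Path(p).is_file():
                raise FileNotFoundError(f"input '{name}' not found: {p}")
        for attr in (
            "window",
            "alpha_sirna",
            "alpha_timecourse",
            "promoter_up",
            "promoter_down",
            "top_k",
        ):
            if getattr(self, attr) <= 0:
                raise ValueError(f"parameter {attr} must be positive")
        if self.stitch_distance < 0 or self.aerbs_pad < 0 or self.tss_exclusion_window < 0:
            raise ValueError("distances must be >= 0")


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the headline report as a dict.

    Writes, under ``config.out_dir``: se_table.tsv, se_aerbs.tsv,
    associations.tsv, bias_summary.tsv, biotype_breakdown.tsv, crosstab.tsv,
    top_se.tsv, nodes.tsv, edges.tsv, network.graphml and report.tsv.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, p in sorted(config.input_paths().items()):
        logger.info("input %s: %s md5=%s", name, p, _md5(p))
    logger.info("parameters: %s", {k: v for k, v in asdict(config).items()})

    def stage(name: str, path, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage '{name}' failed on input {path}: {exc}") from exc

    peaks = stage("read_peaks", config.peaks, lambda: io.read_bed(config.peaks))
    chip = stage("read_chip", config.chip, lambda: io.read_bedgraph(config.chip))
    input_track = stage(
        "read_input", config.input, lambda: io.read_bedgraph(config.input)
    )
    genes = stage("read_genes", config.genes, lambda: io.read_gtf_genes(config.genes))
    sites = stage("read_aerbs", config.aerbs, lambda: io.read_aerbs(config.aerbs))

    params = SECallParameters(
        stitch_distance=config.stitch_distance,
        tss_exclusion_window=config.tss_exclusion_window,
    )
    regions = stage(
        "callse",
        config.peaks,
        lambda: call_super_enhancers(peaks, chip, input_track, params, genes),
    )
    io.write_tsv(out / "se_table.tsv", se_table(regions))
    ses = [r for r in regions if r.is_super]

    se_aerbs, site_map = stage(
        "select_se_aerbs", config.aerbs, lambda: select_se_aerbs(ses, sites)
    )
    se_aerbs_df = se_table(se_aerbs)
    se_aerbs_df["n_aerbs"] = [
        len(site_map[r.region_id]) for r in sorted(se_aerbs, key=lambda r: r.rank)
    ]
    io.write_tsv(out / "se_aerbs.tsv", se_aerbs_df)

    sirna_df = stage(
        "read_de_sirna", config.de_sirna, lambda: io.read_de_table(config.de_sirna)
    )
    e2_df = stage("read_de_e2", config.de_e2, lambda: io.read_de_table(config.de_e2))
    sirna_labels = classify_de(sirna_df, config.alpha_sirna)
    e2_labels = classify_de(e2_df, config.alpha_timecourse)

    bound_ids = {r.region_id for r in se_aerbs}
    assoc = stage(
        "associate_genes",
        config.genes,
        lambda: associate_genes(
            se_aerbs, genes, max_distance=config.window, bound_region_ids=bound_ids
        ),
    )
    assoc_df = pd.DataFrame(
        [
            {
                "se_id": a.se_id,
                "gene_id": a.gene_id,
                "distance": a.distance,
                "se_has_aerbs": a.se_has_aerbs,
                "nearest": assoc.nearest_gene.get(a.se_id) == a.gene_id,
            }
            for a in assoc.associations
        ],
        columns=["se_id", "gene_id", "distance", "se_has_aerbs", "nearest"],
    )
    io.write_tsv(out / "associations.tsv", assoc_df)

    bias = binding_bias_summary(sirna_labels, sites, genes, window=config.window)
    io.write_tsv(out / "bias_summary.tsv", bias)

    biotype_of = {g.gene_id: g.biotype for g in genes}
    assoc_gene_ids = {a.gene_id for a in assoc.associations}
    de_ids = {g for g, lab in sirna_labels.items() if lab in ("down", "up")}
    assoc_de_ids = assoc_gene_ids & de_ids
    assoc_lnc_ids = {
        g for g in assoc_gene_ids if biotype_of.get(g) in LNCRNA_BIOTYPES
    }
    assoc_de_lnc = [
        a for a in assoc.associations if a.gene_id in (assoc_de_ids & assoc_lnc_ids)
    ]
    breakdown = biotype_breakdown(assoc_de_lnc, genes)
    io.write_tsv(out / "biotype_breakdown.tsv", breakdown)

    crosstab = crosstab_sirna_e2(sirna_labels, e2_labels, assoc_lnc_ids)
    crosstab.reset_index().to_csv(out / "crosstab.tsv", sep="\t", index=False)

    top = se_table(sorted(regions, key=lambda r: r.rank)[: config.top_k]).copy()
    top["nearest_gene"] = [
        assoc.nearest_gene.get(f"{row.chrom}:{row.start}-{row.end}", "")
        for row in top.itertuples()
    ]
    io.write_tsv(out / "top_se.tsv", top)

    prom_nodes = build_promoter_footprints(
        genes, upstream=config.promoter_up, downstream=config.promoter_down
    )
    aerbs_nodes = extend_aerbs(sites, pad=config.aerbs_pad)
    all_pairs = []
    for i, p in enumerate(config.pairs):
        all_pairs.extend(
            stage(
                "read_pairs",
                p,
                lambda p=p, i=i: io.read_bedpe(p, experiment_id=f"experiment_{i}"),
            )
        )
    net = stage(
        "build_network",
        ";".join(config.pairs) if config.pairs else "(no pairs)",
        lambda: build_network(all_pairs, prom_nodes + aerbs_nodes),
    )
    log2fc_map = dict(
        zip(sirna_df["gene_id"].astype(str), sirna_df["log2fc"].astype(float))
    )
    annotate_nodes(net, de_log2fc=log2fc_map)
    io.write_tsv(out / "nodes.tsv", net.nodes_table())
    io.write_tsv(out / "edges.tsv", net.edges_table())
    write_graphml(net, out / "network.graphml")

    n_down = int((sirna_labels == "down").sum())
    n_up = int((sirna_labels == "up").sum())
    n_assoc_down = sum(1 for g in assoc_de_ids if sirna_labels.get(g) == "down")
    bias_by_class = bias.set_index("de_class")
    report = {
        "n_peaks": len(peaks),
        "n_stitched_regions": len(regions),
        "n_se": len(ses),
        "n_se_aerbs": len(se_aerbs),
        "n_genes": len(genes),
        "n_de_down_sirna": n_down,
        "n_de_up_sirna": n_up,
        "n_se_associated_genes": len(assoc_gene_ids),
        "n_se_associated_de_genes": len(assoc_de_ids),
        "n_se_associated_lncrna": len(assoc_lnc_ids),
        "n_se_associated_de_lncrna": len(assoc_de_ids & assoc_lnc_ids),
        "pct_down_of_se_associated_de": (
            round_pct_half_up(n_assoc_down, len(assoc_de_ids)) if assoc_de_ids else ""
        ),
        "pct_down_bound": bias_by_class.loc["down", "pct_bound"],
        "pct_up_bound": bias_by_class.loc["up", "pct_bound"],
        "n_network_nodes": net.graph.number_of_nodes(),
        "n_network_edges": net.graph.number_of_edges(),
    }
    report_df = pd.DataFrame(
        [{"metric": k, "value": v} for k, v in report.items()],
        columns=["metric", "value"],
    )
    io.write_tsv(out / "report.tsv", report_df)
    logger.info("pipeline complete: %d SEs, %d SE-aERBS", len(ses), len(se_aerbs))
    return report
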