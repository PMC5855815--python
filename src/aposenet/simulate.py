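"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator plants the features each downstream stage must recover:
clusters of high-signal H3K27ac peaks (planted super-enhancers) among
isolated background peaks; apoER-alpha binding sites inside a subset of the
planted SEs; differential-expression tables in which genes near a bound SE
are preferentially down-regulated; and ChIA-PET pairs looping each bound
SE's binding sites to its target gene promoter, plus uniform noise pairs.
Truth tables record every planted feature so downstream recovery can be
scored without external data.

A fixed master seed yields byte-identical output files.  Each generator
draws from its own pseudo-random stream derived from the master seed by a
fixed offset, so adding or re-running one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io
from .intervals import (
    BindingSite,
    GeneRecord,
    GenomicInterval,
    InteractionPair,
    SignalTrack,
)
from .network import promoter_footprint

BIOTYPES = (
    "protein_coding",
    "antisense",
    "lincRNA",
    "processed_pseudogene",
    "snoRNA",
    "TEC",
)
BIOTYPE_WEIGHTS = (0.55, 0.13, 0.13, 0.07, 0.06, 0.06)

# fixed per-generator stream offsets (see module docstring)
_STREAM_GENES = 1
_STREAM_LANDSCAPE = 2
_STREAM_AERBS_DE = 3
_STREAM_CHIAPET = 4


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic bundle.

    Defaults encode the conditions the recovery suites assume: 3 planted
    SEs of 5 peaks each at 5x the background peak enrichment, 50 isolated
    background peaks, 500 genes, 70% of planted SEs bound by 1-3 aERBSs,
    down-regulation probability 0.75 near bound SEs vs 0.4 background, and
    4 ChIA-PET pairs per planted loop with 6 uniform noise pairs.
    """

    seed: int = 0
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 6_000_000}
    )
    n_genes: int = 500
    n_background_peaks: int = 50
    n_planted_se: int = 3
    peaks_per_se: int = 5
    se_signal_ratio: float = 5.0
    aerbs_fraction_of_se: float = 0.7
    p_down_given_bound_se: float = 0.75
    p_down_background: float = 0.4
    n_noise_pairs: int = 6
    pairs_per_planted_loop: int = 4
    e2_responsive_fraction: float = 0.4
    e2_background_rate: float = 0.3
    gene_length_range: tuple = (1_000, 5_000)
    peak_width: int = 500
    baseline_cpm: float = 1.0
    background_enrichment_cpm: float = 2.0
    se_window: int = 10_000
    association_window: int = 100_000
    min_peak_separation: int = 13_000  # > default stitch distance of 12.5 kb
    anchor_width: int = 400

    def __post_init__(self) -> None:
        for p in (
            self.aerbs_fraction_of_se,
            self.p_down_given_bound_se,
            self.p_down_background,
            self.e2_responsive_fraction,
            self.e2_background_rate,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for n in (
            self.n_genes,
            self.n_background_peaks,
            self.n_planted_se,
            self.peaks_per_se,
            self.n_noise_pairs,
            self.pairs_per_planted_loop,
        ):
            if n < 0:
                raise ValueError("counts must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class PlantedSE:
    """Truth record for one planted super-enhancer."""

    interval: GenomicInterval
    target_gene_id: str
    is_bound: bool = False
    sites: list = field(default_factory=list)

    @property
    def center(self) -> int:
        return self.interval.center


@dataclass
class SimTruth:
    planted: list  # list[PlantedSE]
    bound_gene_ids: set = field(default_factory=set)
    gene_labels: dict = field(default_factory=dict)  # gene_id -> planted siRNA label


@dataclass
class SimBundle:
    config: SimulationConfig
    genes: list
    peaks: list
    chip: SignalTrack
    input_track: SignalTrack
    sites: list
    de_sirna: pd.DataFrame
    de_e2: pd.DataFrame
    pairs: list
    truth: SimTruth


def _pick_chrom(rng, chrom_sizes: dict) -> str:
    names = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in names], dtype=np.float64)
    return names[int(rng.choice(len(names), p=sizes / sizes.sum()))]


def generate_genes(config: SimulationConfig) -> list[GeneRecord]:
    """Place non-overlapping gene bodies with random strand and biotype."""
    rng = config.rng(_STREAM_GENES)
    lo, hi = config.gene_length_range
    occupied = {c: IntervalTree() for c in config.chrom_sizes}
    placed: list[tuple[str, int, int, str, str, int]] = []
    attempts_budget = max(2_000, 200 * config.n_genes)
    attempts = 0
    while len(placed) < config.n_genes:
        if attempts >= attempts_budget:
            raise RuntimeError(
                "genome too small to place the requested number of genes"
            )
        attempts += 1
        chrom = _pick_chrom(rng, config.chrom_sizes)
        length = int(rng.integers(lo, hi + 1))
        size = config.chrom_sizes[chrom]
        if size <= length:
            continue
        start = int(rng.integers(0, size - length))
        if occupied[chrom].overlap(start - 200, start + length + 200):
            continue
        occupied[chrom].addi(start, start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = BIOTYPES[int(rng.choice(len(BIOTYPES), p=BIOTYPE_WEIGHTS))]
        iso_len = int(rng.integers(max(200, length // 2), length + 1))
        placed.append((chrom, start, start + length, strand, biotype, iso_len))
    placed.sort()
    genes = []
    for i, (chrom, start, end, strand, biotype, iso_len) in enumerate(placed):
        iv = GenomicInterval(chrom, start, end, strand)
        tss = start if strand == "+" else end - 1
        genes.append(
            GeneRecord(
                gene_id=f"G{i:04d}",
                gene_name=f"GENE{i:04d}",
                interval=iv,
                tss=tss,
                biotype=biotype,
                longest_isoform_length=iso_len,
            )
        )
    return genes


def generate_enhancer_landscape(
    config: SimulationConfig, genes: list
) -> tuple[list, SignalTrack, SignalTrack, SimTruth]:
    """Peaks plus ChIP/input tracks with planted SEs near gene TSSs.

    Planted SEs are ``peaks_per_se`` peaks inside a ``se_window`` window
    (intra-cluster gaps well under the stitch distance) placed within the
    association window of a randomly chosen gene TSS; background peaks are
    isolated (pairwise separation above the stitch distance).  Peak
    enrichment density is homogeneous within each class — background peaks
    at ``background_enrichment_cpm`` over baseline, planted peaks at
    ``se_signal_ratio`` times that — so the null ranked-signal curve is
    exactly flat.  The input track is uniform at ``baseline_cpm``.
    """
    rng = config.rng(_STREAM_LANDSCAPE)
    if config.n_planted_se > 0 and not genes:
        raise ValueError("cannot plant SEs without genes to target")
    guard = {c: IntervalTree() for c in config.chrom_sizes}
    pad = config.min_peak_separation
    peaks: list[GenomicInterval] = []
    peak_class: list[str] = []  # parallel: "planted" | "background"
    planted: list[PlantedSE] = []
    w = config.se_window
    if config.n_planted_se > 0:
        target_idx = rng.choice(
            len(genes), size=min(config.n_planted_se, len(genes)), replace=False
        )
        for gi in target_idx:
            gene = genes[int(gi)]
            chrom = gene.interval.chrom
            size = config.chrom_sizes[chrom]
            window_start = None
            for _ in range(200):
                offset = int(rng.integers(-config.association_window + w, config.association_window - w))
                cand = gene.tss + offset - w // 2
                cand = min(max(cand, 0), size - w)
                if not guard[chrom].overlap(cand - pad, cand + w + pad):
                    window_start = cand
                    break
            if window_start is None:
                raise RuntimeError("could not place planted SE away from other peaks")
            guard[chrom].addi(window_start - pad, window_start + w + pad)
            spacing = w // config.peaks_per_se
            cluster = []
            for j in range(config.peaks_per_se):
                p_start = window_start + j * spacing + (spacing - config.peak_width) // 2
                cluster.append(
                    GenomicInterval(chrom, p_start, p_start + config.peak_width)
                )
            peaks.extend(cluster)
            peak_class.extend(["planted"] * len(cluster))
            planted.append(
                PlantedSE(
                    GenomicInterval(
                        chrom, cluster[0].start, cluster[-1].end
                    ),
                    gene.gene_id,
                )
            )
    n_bg = 0
    attempts = 0
    while n_bg < config.n_background_peaks:
        if attempts > 200 * max(config.n_background_peaks, 1):
            raise RuntimeError("genome too small to place isolated background peaks")
        attempts += 1
        chrom = _pick_chrom(rng, config.chrom_sizes)
        size = config.chrom_sizes[chrom]
        start = int(rng.integers(0, size - config.peak_width))
        if guard[chrom].overlap(start - pad, start + config.peak_width + pad):
            continue
        guard[chrom].addi(start - pad, start + config.peak_width + pad)
        peaks.append(GenomicInterval(chrom, start, start + config.peak_width))
        peak_class.append("background")
        n_bg += 1
    # signal tracks: input uniform; chip baseline with elevated peak steps
    input_track = SignalTrack.uniform(config.chrom_sizes, config.baseline_cpm)
    bg_value = config.baseline_cpm + config.background_enrichment_cpm
    se_value = config.baseline_cpm + config.se_signal_ratio * config.background_enrichment_cpm
    chip_records = []
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start))
    cursor: dict[str, int] = {}
    for i in order:
        p, cls = peaks[i], peak_class[i]
        pos = cursor.get(p.chrom, 0)
        if p.start > pos:
            chip_records.append((p.chrom, pos, p.start, config.baseline_cpm))
        chip_records.append(
            (p.chrom, p.start, p.end, se_value if cls == "planted" else bg_value)
        )
        cursor[p.chrom] = p.end
    for chrom, size in config.chrom_sizes.items():
        pos = cursor.get(chrom, 0)
        if pos < size:
            chip_records.append((chrom, pos, size, config.baseline_cpm))
    chip = SignalTrack.from_records(chip_records)
    return peaks, chip, input_track, SimTruth(planted)


def generate_aerbs_and_de(
    config: SimulationConfig, truth: SimTruth, genes: list
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Binding sites inside a fraction of planted SEs, plus DE tables.

    Genes whose TSS lies within the association window of a bound SE center
    are down-regulated with probability ``p_down_given_bound_se``; all other
    genes with ``p_down_background``.  The residual probability is split
    evenly between up and unchanged.  Labels are realised as (log2fc, adj_p)
    pairs matching the thresholds downstream classification applies.  The
    estradiol time-course table is drawn independently, with a configured
    fraction of SE-associated genes responsive.
    """
    rng = config.rng(_STREAM_AERBS_DE)
    n_planted = len(truth.planted)
    n_bound = int(round(config.aerbs_fraction_of_se * n_planted))
    bound_idx = set()
    if n_bound > 0:
        bound_idx = set(
            int(i) for i in rng.choice(n_planted, size=n_bound, replace=False)
        )
    sites: list[BindingSite] = []
    site_width = 300
    for i, pse in enumerate(truth.planted):
        if i not in bound_idx:
            continue
        pse.is_bound = True
        n_sites = int(rng.integers(1, 4))
        iv = pse.interval
        for _ in range(n_sites):
            s = int(rng.integers(iv.start, max(iv.end - site_width, iv.start + 1)))
            cls = "EnhT" if rng.random() < 0.6 else "EnhP"
            site = BindingSite(GenomicInterval(iv.chrom, s, s + site_width), cls)
            sites.append(site)
            pse.sites.append(site)
    bound_centers = [
        (p.interval.chrom, p.center) for p in truth.planted if p.is_bound
    ]
    truth.bound_gene_ids = {
        g.gene_id
        for g in genes
        if any(
            g.interval.chrom == c and abs(g.tss - ctr) <= config.association_window
            for c, ctr in bound_centers
        )
    }

    def realise(label: str) -> tuple[float, float]:
        if label == "down":
            return -abs(rng.normal(1.5, 0.5)), rng.uniform(0.0, 0.0005)
        if label == "up":
            return abs(rng.normal(1.5, 0.5)), rng.uniform(0.0, 0.0005)
        return rng.normal(0.0, 0.2), rng.uniform(0.1, 1.0)

    sirna_rows = []
    for g in genes:
        p_down = (
            config.p_down_given_bound_se
            if g.gene_id in truth.bound_gene_ids
            else config.p_down_background
        )
        u = rng.random()
        if u < p_down:
            label = "down"
        elif u < p_down + (1.0 - p_down) / 2.0:
            label = "up"
        else:
            label = "unchanged"
        truth.gene_labels[g.gene_id] = label
        log2fc, adj_p = realise(label)
        sirna_rows.append(
            {"gene_id": g.gene_id, "log2fc": log2fc, "adj_p": adj_p}
        )
    e2_rows = []
    for g in genes:
        p_resp = (
            config.e2_responsive_fraction
            if g.gene_id in truth.bound_gene_ids
            else config.e2_background_rate
        )
        if rng.random() < p_resp:
            sign = -1.0 if rng.random() < 0.5 else 1.0
            log2fc = sign * abs(rng.normal(1.0, 0.4))
            adj_p = rng.uniform(0.0, 0.04)
        else:
            log2fc = rng.normal(0.0, 0.2)
            adj_p = rng.uniform(0.1, 1.0)
        e2_rows.append({"gene_id": g.gene_id, "log2fc": log2fc, "adj_p": adj_p})
    cols = ["gene_id", "log2fc", "adj_p"]
    return (
        sites,
        pd.DataFrame(sirna_rows, columns=cols),
        pd.DataFrame(e2_rows, columns=cols),
    )


def generate_chiapet(
    config: SimulationConfig, truth: SimTruth, genes: list
) -> list[InteractionPair]:
    """ChIA-PET pairs looping bound SEs to target promoters, plus noise.

    Planted pairs put anchor1 inside (or just beside) one of the SE's
    binding sites and anchor2 inside the target gene's promoter footprint;
    noise pairs have uniformly random anchors.  Counts are 1 + Poisson(1).
    """
    rng = config.rng(_STREAM_CHIAPET)
    gene_by_id = {g.gene_id: g for g in genes}
    aw = config.anchor_width
    pairs: list[InteractionPair] = []
    for pse in truth.planted:
        if not pse.is_bound or not pse.sites:
            continue
        gene = gene_by_id[pse.target_gene_id]
        fp = promoter_footprint(gene.tss, gene.strand, gene.interval.chrom)
        for _ in range(config.pairs_per_planted_loop):
            site = pse.sites[int(rng.integers(0, len(pse.sites)))]
            siv = site.interval
            a1_start = int(rng.integers(max(siv.start - 200, 0), max(siv.end + 200 - aw, siv.start) + 1))
            anchor1 = GenomicInterval(siv.chrom, a1_start, a1_start + aw)
            a2_start = int(rng.integers(fp.start, max(fp.end - aw, fp.start) + 1))
            anchor2 = GenomicInterval(fp.chrom, a2_start, a2_start + aw)
            pairs.append(
                InteractionPair(anchor1, anchor2, "sim_1", 1 + int(rng.poisson(1.0)))
            )
    for _ in range(config.n_noise_pairs):
        anchors = []
        for _ in range(2):
            chrom = _pick_chrom(rng, config.chrom_sizes)
            start = int(rng.integers(0, config.chrom_sizes[chrom] - aw))
            anchors.append(GenomicInterval(chrom, start, start + aw))
        pairs.append(
            InteractionPair(anchors[0], anchors[1], "sim_1", 1 + int(rng.poisson(1.0)))
        )
    return pairs


def generate_bundle(config: SimulationConfig) -> SimBundle:
    """Run all generators with the configured seed; nothing touches disk."""
    genes = generate_genes(config)
    peaks, chip, input_track, truth = generate_enhancer_landscape(config, genes)
    sites, de_sirna, de_e2 = generate_aerbs_and_de(config, truth, genes)
    pairs = generate_chiapet(config, truth, genes)
    return SimBundle(
        config, genes, peaks, chip, input_track, sites, de_sirna, de_e2, pairs, truth
    )


BUNDLE_FILES = {
    "genes": "genes.gtf",
    "peaks": "peaks.bed",
    "chip": "chip.bedgraph",
    "input": "input.bedgraph",
    "aerbs": "aerbs.bed",
    "de_sirna": "de_sirna.tsv",
    "de_e2": "de_e2.tsv",
    "pairs": "pairs.bedpe",
    "truth_se": "truth/planted_se.tsv",
    "truth_genes": "truth/gene_truth.tsv",
}


def write_bundle(bundle: SimBundle, out_dir) -> dict:
    """Write every generated input plus the truth tables; returns the paths."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in BUNDLE_FILES.items()}
    io.write_gtf_genes(paths["genes"], bundle.genes)
    io.write_bed(paths["peaks"], bundle.peaks)
    io.write_bedgraph(paths["chip"], bundle.chip)
    io.write_bedgraph(paths["input"], bundle.input_track)
    io.write_bed(
        paths["aerbs"],
        [s.interval for s in bundle.sites],
        names=[s.epigenetic_class or "." for s in bundle.sites],
    )
    io.write_tsv(paths["de_sirna"], bundle.de_sirna)
    io.write_tsv(paths["de_e2"], bundle.de_e2)
    io.write_bedpe(paths["pairs"], bundle.pairs)
    truth_se = pd.DataFrame(
        [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "center": p.center,
                "target_gene": p.target_gene_id,
                "is_bound": p.is_bound,
            }
            for p in bundle.truth.planted
        ],
        columns=["chrom", "start", "end", "center", "target_gene", "is_bound"],
    )
    io.write_tsv(paths["truth_se"], truth_se)
    truth_genes = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "near_bound_se": g.gene_id in bundle.truth.bound_gene_ids,
                "planted_label": bundle.truth.gene_labels.get(g.gene_id, ""),
            }
            for g in bundle.genes
        ],
        columns=["gene_id", "near_bound_se", "planted_label"],
    )
    io.write_tsv(paths["truth_genes"], truth_genes)
    return paths
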