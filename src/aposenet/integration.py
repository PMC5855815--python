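"""Integration of super-enhancers with receptor binding and expression.

Covers: selecting SEs that overlap apoER-alpha binding sites (SE-aERBS),
associating SEs with gene TSSs by distance to the SE center, classifying
differential-expression tables at a significance threshold, the
binding-vs-regulation bias summary, the biotype breakdown of SE-associated
lncRNAs, the siER-alpha x estradiol-time-course cross-tabulation, and FPKM
conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .intervals import (
    BindingSite,
    GeneRecord,
    GenomicInterval,
    overlap,
    point_to_interval_distance,
)
from .se_caller import StitchedRegion

logger = logging.getLogger(__name__)

DE_LABELS = ("down", "up", "unchanged")


@dataclass(frozen=True)
class SEGeneAssociation:
    """A (super-enhancer, gene) pair within the association window."""

    se_id: str
    gene_id: str
    distance: int
    se_has_aerbs: bool = False


@dataclass
class AssociationResult:
    associations: list[SEGeneAssociation]
    # per-region nearest gene (ties -> lexicographically smaller gene_id);
    # the "first proximal gene TSS" of each region
    nearest_gene: dict


def _site_tree_by_chrom(sites: Iterable[BindingSite]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.interval.chrom, IntervalTree()).addi(
            s.interval.start, s.interval.end, s
        )
    return trees


def select_se_aerbs(
    ses: Sequence[StitchedRegion], sites: Sequence[BindingSite]
) -> tuple[list[StitchedRegion], dict]:
    """Subset of SEs whose stitched interval overlaps >= 1 binding site.

    Returns the selected SEs (input order preserved) and a mapping
    region_id -> list of overlapping sites.  Overlap is half-open: a site
    starting exactly at the SE end does not count.
    """
    trees = _site_tree_by_chrom(sites)
    selected: list[StitchedRegion] = []
    site_map: dict[str, list[BindingSite]] = {}
    for se in ses:
        iv = se.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = tree.overlap(iv.start, iv.end)
        if hits:
            selected.append(se)
            site_map[se.region_id] = sorted(
                (h.data for h in hits), key=lambda s: (s.interval.start, s.interval.end)
            )
    return selected, site_map


def classify_de(table: pd.DataFrame, alpha: float) -> pd.Series:
    """Per-gene label: down / up / unchanged.

    down iff adj_p < alpha and log2fc < 0; up iff adj_p < alpha and
    log2fc > 0; everything else (including log2fc exactly 0) is unchanged,
    so the three classes partition the genes cleanly.  Rows with missing
    adj_p are skipped; the skip count is logged and stored in
    ``result.attrs["n_skipped"]``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    missing = table["adj_p"].isna()
    n_skipped = int(missing.sum())
    if n_skipped:
        logger.warning("classify_de: skipped %d records with missing adj_p", n_skipped)
    t = table[~missing]
    sig = t["adj_p"] < alpha
    labels = np.where(
        sig & (t["log2fc"] < 0), "down", np.where(sig & (t["log2fc"] > 0), "up", "unchanged")
    )
    out = pd.Series(labels, index=t["gene_id"].to_numpy(), name="label")
    out.attrs["n_skipped"] = n_skipped
    return out


def associate_genes(
    regions: Sequence[StitchedRegion],
    genes: Sequence[GeneRecord],
    max_distance: int = 100_000,
    bound_region_ids: set | None = None,
    mode: str = "center",
) -> AssociationResult:
    """Associate regions with genes whose TSS lies within ``max_distance``.

    ``mode="center"`` (default) measures |TSS - SE center|, the rule applied
    throughout; ``mode="edge"`` measures the distance from the TSS to the
    stitched interval (0 inside).  The comparison is inclusive
    (distance == max_distance associates).  A gene may associate with several
    regions and vice versa; each region additionally reports its nearest gene.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    if mode not in ("center", "edge"):
        raise ValueError(f"unknown association mode {mode!r}")
    bound_region_ids = bound_region_ids or set()
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for lst in genes_by_chrom.values():
        lst.sort(key=lambda g: g.tss)
    associations: list[SEGeneAssociation] = []
    nearest: dict[str, str] = {}
    for r in regions:
        chrom_genes = genes_by_chrom.get(r.interval.chrom, [])
        tss_arr = np.array([g.tss for g in chrom_genes], dtype=np.int64)
        if mode == "center":
            center = r.center
            lo = int(np.searchsorted(tss_arr, center - max_distance, side="left"))
            hi = int(np.searchsorted(tss_arr, center + max_distance, side="right"))
            candidates = [
                (abs(chrom_genes[i].tss - center), chrom_genes[i]) for i in range(lo, hi)
            ]
        else:
            candidates = [
                (point_to_interval_distance(g.tss, r.interval), g)
                for g in chrom_genes
            ]
            candidates = [(d, g) for d, g in candidates if d <= max_distance]
        best: tuple[int, str] | None = None
        for dist, g in candidates:
            associations.append(
                SEGeneAssociation(
                    se_id=r.region_id,
                    gene_id=g.gene_id,
                    distance=int(dist),
                    se_has_aerbs=r.region_id in bound_region_ids,
                )
            )
            key = (int(dist), g.gene_id)
            if best is None or key < best:
                best = key
        if best is not None:
            nearest[r.region_id] = best[1]
    return AssociationResult(associations, nearest)


def round_pct_half_up(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (exact decimal arithmetic)."""
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def binding_bias_summary(
    labels: Mapping[str, str] | pd.Series,
    sites: Sequence[BindingSite],
    genes: Sequence[GeneRecord],
    window: int = 100_000,
    include_fisher: bool = True,
) -> pd.DataFrame:
    """Per DE class: how many genes carry a binding site near their TSS.

    A gene counts as bound when >= 1 site lies within ``window`` bp of its
    TSS (inclusive; distance 0 inside the site).  Percentages are rounded
    half-up to one decimal; an empty class reports NA.  When
    ``include_fisher`` is set, a two-sided Fisher exact test on the
    down/up x bound/unbound 2x2 table is attached as
    ``result.attrs["fisher_p"]`` (an annotation beyond the published
    analysis, which reports the bias without a named test).
    """
    labels = dict(labels.items() if isinstance(labels, pd.Series) else labels.items())
    trees = _site_tree_by_chrom(sites)
    bound: dict[str, bool] = {}
    for g in genes:
        tree = trees.get(g.interval.chrom)
        if tree is None:
            bound[g.gene_id] = False
            continue
        # site within `window` of the TSS <=> site overlaps this span
        bound[g.gene_id] = bool(tree.overlap(g.tss - window, g.tss + window + 1))
    rows = []
    counts = {}
    for cls in DE_LABELS:
        cls_genes = [g for g in genes if labels.get(g.gene_id) == cls]
        n = len(cls_genes)
        n_bound = sum(bound[g.gene_id] for g in cls_genes)
        pct = round_pct_half_up(n_bound, n) if n else float("nan")
        counts[cls] = (n, n_bound)
        rows.append({"de_class": cls, "n_genes": n, "n_bound": n_bound, "pct_bound": pct})
    df = pd.DataFrame(rows, columns=["de_class", "n_genes", "n_bound", "pct_bound"])
    if include_fisher:
        (n_dn, b_dn), (n_up, b_up) = counts["down"], counts["up"]
        if n_dn and n_up:
            _, p = fisher_exact(
                [[b_dn, n_dn - b_dn], [b_up, n_up - b_up]], alternative="two-sided"
            )
            df.attrs["fisher_p"] = float(p)
    return df


def biotype_breakdown(
    associations: Sequence[SEGeneAssociation], genes: Sequence[GeneRecord]
) -> pd.DataFrame:
    """Counts of distinct associated genes per biotype (plus a total row).

    The caller restricts ``associations`` to the gene set of interest
    (e.g. differentially expressed lncRNAs); per-biotype counts sum exactly
    to the number of distinct associated genes.
    """
    biotype_of = {g.gene_id: g.biotype for g in genes}
    distinct = sorted({a.gene_id for a in associations})
    counts: dict[str, int] = {}
    for gid in distinct:
        bt = biotype_of.get(gid, "unknown")
        counts[bt] = counts.get(bt, 0) + 1
    rows = [{"biotype": bt, "n_genes": n} for bt, n in sorted(counts.items())]
    rows.append({"biotype": "total", "n_genes": len(distinct)})
    return pd.DataFrame(rows, columns=["biotype", "n_genes"])


CROSSTAB_MARGIN = "unmeasured"


def crosstab_sirna_e2(
    sirna_labels: Mapping[str, str] | pd.Series,
    timecourse_labels: Mapping[str, str] | pd.Series,
    se_associated_gene_ids: Iterable[str],
) -> pd.DataFrame:
    """Cross-tabulate siER-alpha vs estradiol time-course DE labels.

    Restricted to SE-associated genes.  Rows are siER-alpha labels, columns
    time-course labels; a gene missing from one labelling falls in that
    axis's "unmeasured" margin rather than being dropped, so the full matrix
    always sums to the number of SE-associated genes.
    """
    sirna = dict(sirna_labels.items())
    e2 = dict(timecourse_labels.items())
    axes = list(DE_LABELS) + [CROSSTAB_MARGIN]
    mat = pd.DataFrame(0, index=pd.Index(axes, name="sirna"), columns=pd.Index(axes, name="e2"))
    for gid in set(se_associated_gene_ids):
        mat.loc[sirna.get(gid, CROSSTAB_MARGIN), e2.get(gid, CROSSTAB_MARGIN)] += 1
    return mat


def fpkm_from_counts(
    normalized_count: float, longest_isoform_length: int, counted_fragments_millions: float
) -> float:
    """Fragments per kilobase (longest isoform) per million counted fragments."""
    if longest_isoform_length < 1:
        raise ValueError("longest_isoform_length must be >= 1 bp")
    if counted_fragments_millions <= 0:
        raise ValueError("counted_fragments_millions must be > 0")
    return normalized_count / ((longest_isoform_length / 1000.0) * counted_fragments_millions)
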