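"""Long-range chromatin interaction network from ChIA-PET anchor pairs.

Nodes are gene promoters (-2 kb / +500 bp around the TSS, strand-oriented)
and apoER-alpha binding sites extended by 1 kb on each side.  Every ChIA-PET
pair connects the nodes overlapping its first anchor to the nodes overlapping
its second anchor; per experiment the pair counts linking a node pair are
summed, and the edge weight is the mean of those sums across the experiments
that contain at least one such pair.  Edges between two footprints on the
SAME anchor are never created — a ChIA-PET pair is evidence for the
anchor1<->anchor2 contact only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from intervaltree import IntervalTree

from .intervals import BindingSite, GeneRecord, GenomicInterval, InteractionPair

GENE_PROMOTER = "gene_promoter"
AERBS = "aerbs"

PROMOTER_UPSTREAM = 2_000
PROMOTER_DOWNSTREAM = 500
AERBS_PAD = 1_000


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    node_kind: str  # gene_promoter | aerbs
    footprint: GenomicInterval
    annotation: object = None  # log2FC for genes, epigenetic class for aERBS


def promoter_footprint(
    tss: int,
    strand: str,
    chrom: str,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Strand-oriented promoter window around the TSS, clipped at 0.

    "+": genomic [TSS - upstream, TSS + downstream); "-": the mirror image,
    upstream in the gene's transcriptional sense, i.e. genomic
    [TSS - downstream + 1, TSS + upstream + 1).
    """
    if strand == "-":
        start, end = tss - downstream + 1, tss + upstream + 1
    else:
        start, end = tss - upstream, tss + downstream
    return GenomicInterval(chrom, max(start, 0), end)


def build_promoter_footprints(
    genes: Sequence[GeneRecord],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[NetworkNode]:
    return [
        NetworkNode(
            node_id=g.gene_id,
            node_kind=GENE_PROMOTER,
            footprint=promoter_footprint(
                g.tss, g.strand, g.interval.chrom, upstream, downstream
            ),
        )
        for g in genes
    ]


def extend_aerbs(sites: Sequence[BindingSite], pad: int = AERBS_PAD) -> list[NetworkNode]:
    """aERBS nodes: each site extended by ``pad`` bp on each side, clipped at 0."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    out = []
    for s in sites:
        iv = s.interval
        footprint = GenomicInterval(iv.chrom, max(iv.start - pad, 0), iv.end + pad)
        out.append(
            NetworkNode(
                node_id=f"aerbs:{iv.chrom}:{iv.start}-{iv.end}",
                node_kind=AERBS,
                footprint=footprint,
                annotation=s.epigenetic_class,
            )
        )
    return out


def _pair_kind(kind_a: str, kind_b: str) -> str:
    kinds = sorted((kind_a, kind_b))
    if kinds == [AERBS, GENE_PROMOTER]:
        return "aerbs-gene"
    if kinds == [GENE_PROMOTER, GENE_PROMOTER]:
        return "gene-gene"
    return "aerbs-aerbs"


@dataclass
class ChiaPetNetwork:
    """Undirected interaction network plus assignment diagnostics.

    ``graph`` is a networkx Graph; node attributes: kind, chrom, start, end,
    annotation; edge attributes: weight (mean per-experiment pair count) and
    pair_kind.  ``unassigned`` tallies, per experiment, the pair count mass
    whose anchors matched no (or, in first-match mode, no two distinct)
    footprints; ``assigned`` is the complementary per-experiment mass.
    """

    graph: nx.Graph
    unassigned: dict
    assigned: dict

    def nodes_table(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": n,
                "kind": d["kind"],
                "chrom": d["chrom"],
                "start": d["start"],
                "end": d["end"],
                "annotation": "" if d["annotation"] is None else d["annotation"],
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["node_id", "kind", "chrom", "start", "end", "annotation"]
        )

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "pair_kind": d["pair_kind"],
                "weight": d["weight"],
            }
            for a, b, d in sorted(
                ((min(a, b), max(a, b), d) for a, b, d in self.graph.edges(data=True))
            )
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "pair_kind", "weight"])


def _node_tree(nodes: Sequence[NetworkNode]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for node in nodes:
        fp = node.footprint
        trees.setdefault(fp.chrom, IntervalTree()).addi(fp.start, fp.end, node)
    return trees


def _hits(trees, anchor: GenomicInterval) -> list[NetworkNode]:
    tree = trees.get(anchor.chrom)
    if tree is None:
        return []
    return sorted(
        (h.data for h in tree.overlap(anchor.start, anchor.end)),
        key=lambda n: n.node_id,
    )


def _best_hit(trees, anchor: GenomicInterval) -> "NetworkNode | None":
    """Maximal-overlap footprint for an anchor (ties -> smaller node_id)."""
    best = None
    for node in _hits(trees, anchor):
        fp = node.footprint
        ov = min(fp.end, anchor.end) - max(fp.start, anchor.start)
        if best is None or ov > best[0]:
            best = (ov, node)
    return best[1] if best else None


def build_network(
    pairs: Sequence[InteractionPair],
    nodes: Sequence[NetworkNode],
    first_match: bool = False,
) -> ChiaPetNetwork:
    """Connect footprints bridged by ChIA-PET pairs.

    Default mode: every node overlapping anchor1 is connected to every node
    overlapping anchor2 (combinatorial expansion); self-links are discarded.
    ``first_match=True`` assigns each anchor to at most its maximal-overlap
    footprint, under which pair-count mass is conserved exactly:
    assigned + unassigned = total input count, per experiment.

    Pair order and experiment order do not affect the result; reciprocal
    anchor orderings are symmetric because edges are undirected.
    """
    trees = _node_tree(nodes)
    # (experiment, node_a, node_b) -> summed count, node ids in sorted order
    per_exp: dict[str, dict[tuple[str, str], int]] = {}
    unassigned: dict[str, int] = {}
    assigned: dict[str, int] = {}
    kind_of = {n.node_id: n.node_kind for n in nodes}
    for p in pairs:
        unassigned.setdefault(p.experiment_id, 0)
        assigned.setdefault(p.experiment_id, 0)
        if first_match:
            a = _best_hit(trees, p.anchor1)
            b = _best_hit(trees, p.anchor2)
            hits1 = [a] if a else []
            hits2 = [b] if b else []
        else:
            hits1 = _hits(trees, p.anchor1)
            hits2 = _hits(trees, p.anchor2)
        linked = False
        for na in hits1:
            for nb in hits2:
                if na.node_id == nb.node_id:
                    continue
                key = tuple(sorted((na.node_id, nb.node_id)))
                bucket = per_exp.setdefault(p.experiment_id, {})
                bucket[key] = bucket.get(key, 0) + p.count
                linked = True
        if linked:
            assigned[p.experiment_id] += p.count
        else:
            unassigned[p.experiment_id] += p.count
    graph = nx.Graph()
    for node in nodes:
        fp = node.footprint
        graph.add_node(
            node.node_id,
            kind=node.node_kind,
            chrom=fp.chrom,
            start=fp.start,
            end=fp.end,
            annotation=node.annotation,
        )
    edge_sums: dict[tuple[str, str], list[int]] = {}
    for bucket in per_exp.values():
        for key, total in bucket.items():
            edge_sums.setdefault(key, []).append(total)
    for (a, b), sums in edge_sums.items():
        graph.add_edge(
            a,
            b,
            weight=float(sum(sums)) / len(sums),
            pair_kind=_pair_kind(kind_of[a], kind_of[b]),
        )
    return ChiaPetNetwork(graph, unassigned, assigned)


def annotate_nodes(
    network: ChiaPetNetwork,
    de_log2fc: Mapping[str, float] | None = None,
    site_classes: Mapping[str, str] | None = None,
) -> ChiaPetNetwork:
    """Attach siER-alpha log2FC to gene nodes (NA when absent) and the
    epigenetic class to aERBS nodes ("unclassified" when absent)."""
    de_log2fc = dict(de_log2fc or {})
    site_classes = dict(site_classes or {})
    for n, d in network.graph.nodes(data=True):
        if d["kind"] == GENE_PROMOTER:
            d["annotation"] = de_log2fc.get(n)
        else:
            existing = site_classes.get(n, d.get("annotation"))
            d["annotation"] = existing if existing else "unclassified"
    return network


def write_graphml(network: ChiaPetNetwork, path) -> None:
    """Plain-text GraphML export (None annotations written as empty string)."""
    g = network.graph.copy()
    for _, d in g.nodes(data=True):
        if d.get("annotation") is None:
            d["annotation"] = ""
    nx.write_graphml(g, path)
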