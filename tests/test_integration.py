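"""SE-binding overlap, gene association, DE classification and summaries."""

import numpy as np
import pandas as pd
import pytest

from aposenet.intervals import BindingSite, GeneRecord, GenomicInterval
from aposenet.integration import (
    associate_genes,
    binding_bias_summary,
    biotype_breakdown,
    classify_de,
    crosstab_sirna_e2,
    fpkm_from_counts,
    round_pct_half_up,
    select_se_aerbs,
    SEGeneAssociation,
)
from aposenet.se_caller import StitchedRegion
from _oracles import brute_associate


def _region(chrom, start, end, rank=1):
    return StitchedRegion(GenomicInterval(chrom, start, end), rank=rank, is_super=True)


def _gene(gid, chrom, tss, biotype="protein_coding", strand="+", length=1000):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + length, strand)
    else:
        iv = GenomicInterval(chrom, tss - length + 1, tss + 1, strand)
    return GeneRecord(gid, gid, iv, tss, biotype, length)


def _site(chrom, start, end, cls=None):
    return BindingSite(GenomicInterval(chrom, start, end), cls)


class TestSelectSeAerbs:
    def test_one_bp_overlap_selects(self):
        se = _region("chr1", 0, 10_000)
        selected, site_map = select_se_aerbs([se], [_site("chr1", 9_999, 10_200)])
        assert selected == [se]
        assert len(site_map[se.region_id]) == 1

    def test_half_open_adjacency_does_not_select(self):
        selected, _ = select_se_aerbs(
            [_region("chr1", 0, 10_000)], [_site("chr1", 10_000, 10_200)]
        )
        assert selected == []

    def test_exactly_the_overlapping_subset_returned(self):
        ses = [
            _region("chr1", 0, 1000),
            _region("chr1", 5000, 6000),
            _region("chr2", 0, 1000),
        ]
        sites = [_site("chr1", 500, 600), _site("chr2", 900, 1100)]
        selected, _ = select_se_aerbs(ses, sites)
        assert selected == [ses[0], ses[2]]

    def test_monotone_in_site_set(self):
        ses = [_region("chr1", i * 10_000, i * 10_000 + 2_000) for i in range(5)]
        rng = np.random.default_rng(7)
        sites = [
            _site("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 60_000, size=6)
        ]
        base, _ = select_se_aerbs(ses, sites)
        more, _ = select_se_aerbs(ses, sites + [_site("chr1", 41_000, 41_100)])
        assert set(r.region_id for r in base) <= set(r.region_id for r in more)
        assert set(r.region_id for r in base) <= {r.region_id for r in ses}


class TestClassifyDe:
    @pytest.mark.parametrize(
        "log2fc,adj_p,alpha,expected",
        [
            (-2.0, 1e-5, 0.001, "down"),
            (3.0, 0.01, 0.001, "unchanged"),  # fails the threshold
            (0.0, 1e-9, 0.001, "unchanged"),  # zero effect is never a class
            (1.5, 1e-4, 0.001, "up"),
            (-0.1, 0.04, 0.05, "down"),
        ],
    )
    def test_label_rules(self, log2fc, adj_p, alpha, expected):
        df = pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc], "adj_p": [adj_p]})
        assert classify_de(df, alpha)["g"] == expected

    def test_missing_adj_p_skipped_and_counted(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b"], "log2fc": [-2.0, -2.0], "adj_p": [np.nan, 1e-5]}
        )
        labels = classify_de(df, 0.001)
        assert "a" not in labels.index
        assert labels["b"] == "down"
        assert labels.attrs["n_skipped"] == 1

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            classify_de(pd.DataFrame(columns=["gene_id", "log2fc", "adj_p"]), 0.0)


class TestAssociateGenes:
    def test_tss_at_center(self):
        region = _region("chr1", 0, 20_000)  # center 10000
        res = associate_genes([region], [_gene("g", "chr1", 10_000)])
        (a,) = res.associations
        assert a.distance == 0

    def test_window_boundary_inclusive(self):
        region = _region("chr1", 0, 20_000)
        genes = [_gene("in", "chr1", 110_000), _gene("out", "chr1", 110_001)]
        res = associate_genes([region], genes, max_distance=100_000)
        assert [a.gene_id for a in res.associations] == ["in"]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(5)
        regions = [
            _region(rng.choice(["chr1", "chr2"]), int(s), int(s) + 10_000, rank=i + 1)
            for i, s in enumerate(rng.integers(0, 2_000_000, size=5))
        ]
        genes = [
            _gene(f"g{i}", rng.choice(["chr1", "chr2"]), int(t))
            for i, t in enumerate(rng.integers(0, 2_000_000, size=20))
        ]
        res = associate_genes(regions, genes, max_distance=100_000)
        got = {(a.se_id, a.gene_id, a.distance) for a in res.associations}
        expected = brute_associate(
            [(r.region_id, r.interval.chrom, r.center) for r in regions],
            [(g.gene_id, g.interval.chrom, g.tss) for g in genes],
            100_000,
        )
        assert got == expected

    def test_nearest_gene_ties_break_lexicographically(self):
        region = _region("chr1", 0, 20_000)
        genes = [_gene("b", "chr1", 9_000), _gene("a", "chr1", 11_000)]
        res = associate_genes([region], genes)
        assert res.nearest_gene[region.region_id] == "a"  # both at distance 1000

    def test_edge_mode_measures_to_interval(self):
        region = _region("chr1", 0, 20_000)
        gene = _gene("g", "chr1", 119_000)
        center = associate_genes([region], [gene], max_distance=100_000, mode="center")
        edge = associate_genes([region], [gene], max_distance=100_000, mode="edge")
        assert center.associations == []  # |119000 - 10000| > 100000
        assert len(edge.associations) == 1  # 119000 - 19999 <= 100000


class TestBindingBias:
    def _fixture(self, n_down, n_down_bound, n_up, n_up_bound):
        genes, labels, sites = [], {}, []
        pos = 1_000_000  # keep site footprints clear of coordinate zero
        for i in range(n_down + n_up):
            gid = f"g{i}"
            label = "down" if i < n_down else "up"
            bound = (i < n_down_bound) or (n_down <= i < n_down + n_up_bound)
            genes.append(_gene(gid, "chr1", pos))
            labels[gid] = label
            if bound:
                sites.append(_site("chr1", pos - 100, pos + 100))
            pos += 300_000  # farther than the window, no cross-talk
        return labels, sites, genes

    def test_published_counts_reproduce_published_percentages(self):
        labels, sites, genes = self._fixture(1376, 485, 1110, 300)
        df = binding_bias_summary(labels, sites, genes).set_index("de_class")
        assert df.loc["down", "pct_bound"] == 35.2
        assert df.loc["up", "pct_bound"] == 27.0
        assert df.loc["down", "n_bound"] == 485
        assert df.attrs["fisher_p"] < 0.001  # the bias is real at these counts

    def test_zero_bound_class(self):
        labels, sites, genes = self._fixture(10, 0, 5, 2)
        df = binding_bias_summary(labels, sites, genes).set_index("de_class")
        assert df.loc["down", "pct_bound"] == 0.0

    def test_empty_class_reports_na(self):
        labels, sites, genes = self._fixture(4, 1, 3, 1)
        df = binding_bias_summary(labels, sites, genes).set_index("de_class")
        assert np.isnan(df.loc["unchanged", "pct_bound"])

    def test_rounding_is_half_up(self):
        assert round_pct_half_up(1, 16) == 6.3  # 6.25 rounds up, not to even
        assert round_pct_half_up(485, 1376) == 35.2
        assert round_pct_half_up(300, 1110) == 27.0


class TestBiotypeBreakdown:
    def test_totals_conserved_on_synthetic_tally(self):
        genes = (
            [_gene(f"a{i}", "chr1", 1000 * (i + 1), "antisense") for i in range(3)]
            + [_gene(f"l{i}", "chr1", 50_000 * (i + 1), "lincRNA") for i in range(2)]
            + [_gene("t0", "chr1", 900_000, "TEC")]
        )
        assoc = [
            SEGeneAssociation("se1", g.gene_id, 0) for g in genes
        ] + [SEGeneAssociation("se2", "a0", 5)]  # duplicate association
        df = biotype_breakdown(assoc, genes).set_index("biotype")
        assert df.loc["antisense", "n_genes"] == 3
        assert df.loc["lincRNA", "n_genes"] == 2
        assert df.loc["TEC", "n_genes"] == 1
        assert df.loc["total", "n_genes"] == 6  # distinct genes, not associations

    def test_empty_input(self):
        df = biotype_breakdown([], [])
        assert df.set_index("biotype").loc["total", "n_genes"] == 0


class TestCrosstab:
    def test_hand_tallied_fixture(self):
        sirna = {"a": "down", "b": "down", "c": "up", "d": "unchanged"}
        e2 = {"a": "up", "b": "down", "c": "down", "e": "up"}
        mat = crosstab_sirna_e2(sirna, e2, {"a", "b", "c", "d", "e"})
        assert mat.loc["down", "up"] == 1
        assert mat.loc["down", "down"] == 1
        assert mat.loc["up", "down"] == 1
        assert mat.loc["unchanged", "unmeasured"] == 1
        assert mat.loc["unmeasured", "up"] == 1
        assert mat.to_numpy().sum() == 5

    def test_disjoint_universes_all_unmeasured(self):
        mat = crosstab_sirna_e2({"x": "down"}, {"y": "up"}, {"a", "b"})
        assert mat.loc["unmeasured", "unmeasured"] == 2
        assert mat.to_numpy().sum() == 2

    def test_all_unchanged_single_cell(self):
        ids = {"a", "b", "c"}
        lab = {g: "unchanged" for g in ids}
        mat = crosstab_sirna_e2(lab, lab, ids)
        assert mat.loc["unchanged", "unchanged"] == 3
        assert mat.to_numpy().sum() == 3


class TestFpkm:
    def test_direct_formula(self):
        assert fpkm_from_counts(1000, 2000, 10.0) == 50.0

    def test_zero_count(self):
        assert fpkm_from_counts(0, 1500, 3.0) == 0.0

    def test_doubling_length_halves_fpkm(self):
        assert fpkm_from_counts(300, 4000, 7.0) == pytest.approx(
            fpkm_from_counts(300, 2000, 7.0) / 2
        )

    @pytest.mark.parametrize("length,millions", [(0, 1.0), (1000, 0.0), (-5, 2.0)])
    def test_degenerate_inputs_rejected(self, length, millions):
        with pytest.raises(ValueError):
            fpkm_from_counts(10, length, millions)
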