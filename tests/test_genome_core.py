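"""Coordinate model, gene-model I/O, genome partitioning, TSS arithmetic."""

import numpy as np
import pytest

from agochip.genome_core import (
    FEATURE_LABELS,
    ChromSizes,
    GeneModel,
    Interval,
    locate_interval,
    partition_genome,
    read_gene_models,
    signed_tss_distance,
    write_gene_models,
)


def brute_force_labels(genes, sizes, flank):
    """Independent per-base labeler: at every base, collect all applicable
    classes over all genes and take the highest-precedence one."""
    precedence = {label: i for i, label in enumerate(FEATURE_LABELS)}
    out = {}
    for chrom, length in sizes.items():
        labels = ["intergenic"] * length
        for pos in range(length):
            applicable = []
            for g in genes:
                if g.chrom != chrom:
                    continue
                fwd = g.strand == "+"
                prom = (g.tx_start - flank, g.tx_start) if fwd else (g.tx_end, g.tx_end + flank)
                fl3 = (g.tx_end, g.tx_end + flank) if fwd else (g.tx_start - flank, g.tx_start)
                if prom[0] <= pos < prom[1]:
                    applicable.append("promoter")
                if fl3[0] <= pos < fl3[1]:
                    applicable.append("3flank")
                if g.tx_start <= pos < g.tx_end:
                    in_exon = any(s <= pos < e for s, e in g.exons)
                    if not in_exon:
                        applicable.append("intron")
                    elif not g.has_cds:
                        applicable.append("coding_exon")
                    elif g.cds_start <= pos < g.cds_end:
                        applicable.append("coding_exon")
                    elif pos < g.cds_start:
                        applicable.append("5utr" if fwd else "3utr")
                    else:
                        applicable.append("3utr" if fwd else "5utr")
            if applicable:
                labels[pos] = min(applicable, key=precedence.get)
        out[chrom] = labels
    return out


def make_sizes(**kwargs):
    s = ChromSizes()
    for k, v in kwargs.items():
        s[k] = v
    return s


class TestGeneModelIO:
    def test_bed12_field_mapping(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t999\t2000\tg1\t0\t+\t1099\t1900\t0\t2\t201,200\t0,801\n")
        (g,) = read_gene_models(p)
        assert (g.tx_start, g.tx_end) == (999, 2000)
        assert g.exons == [(999, 1200), (1800, 2000)]
        assert (g.cds_start, g.cds_end) == (1099, 1900)
        assert g.strand == "+" and g.gene_id == "g1"

    def test_gtf_coordinate_conversion(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\tsrc\texon\t1000\t2000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        (g,) = read_gene_models(p)
        assert (g.tx_start, g.tx_end) == (999, 2000)
        assert g.exons == [(999, 2000)]

    def test_exon_outside_transcript_rejected(self):
        with pytest.raises(ValueError, match="outside transcript"):
            GeneModel("g1", "chr1", "+", 100, 200, exons=[(100, 250)])

    def test_gene_without_exons_rejected(self):
        with pytest.raises(ValueError, match="no exons"):
            GeneModel("g1", "chr1", "+", 100, 200, exons=[])

    def test_round_trip_preserves_fields(self, tmp_path, sim):
        path = tmp_path / "rt.bed"
        write_gene_models(sim.genes, path)
        back = read_gene_models(path)
        assert back == sim.genes


class TestPartitionGenome:
    def test_empty_gene_list_all_intergenic(self):
        sizes = make_sizes(chr1=5000)
        fm = partition_genome([], sizes, flank_width=500)
        assert fm.genome_composition["intergenic"] == 5000
        assert sum(fm.genome_composition.values()) == 5000

    def test_single_gene_matches_brute_force(self):
        sizes = make_sizes(chr1=10_000)
        genes = [GeneModel("g1", "chr1", "+", 1000, 2000,
                           exons=[(1000, 1200), (1800, 2000)],
                           cds_start=1100, cds_end=1900)]
        fm = partition_genome(genes, sizes, flank_width=500)
        expected = brute_force_labels(genes, sizes, 500)
        got = [FEATURE_LABELS[c] for c in fm.labels["chr1"]]
        assert got == expected["chr1"]

    def test_promoter_wins_over_other_genes_intron(self):
        # gene 2's promoter overlaps gene 1's intron
        sizes = make_sizes(chr1=20_000)
        g1 = GeneModel("g1", "chr1", "+", 1000, 9000,
                       exons=[(1000, 1500), (8500, 9000)], cds_start=1200, cds_end=8800)
        g2 = GeneModel("g2", "chr1", "+", 6000, 7000, exons=[(6000, 7000)])
        fm = partition_genome([g1, g2], sizes, flank_width=1000)
        expected = brute_force_labels([g1, g2], sizes, 1000)
        got = [FEATURE_LABELS[c] for c in fm.labels["chr1"]]
        assert got == expected["chr1"]
        # the contested bases are labeled promoter
        assert set(got[5000:6000]) == {"promoter"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_toy_genomes_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        sizes = make_sizes(chrA=15_000, chrB=8_000)
        genes = []
        for i in range(6):
            chrom = "chrA" if i < 4 else "chrB"
            start = int(rng.integers(0, sizes[chrom] - 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            e1 = (start, start + int(rng.integers(200, 500)))
            e2_end = start + 2500
            e2 = (e2_end - int(rng.integers(200, 500)), e2_end)
            genes.append(GeneModel(f"g{i}", chrom, strand, start, e2_end,
                                   exons=[e1, e2],
                                   cds_start=e1[1] - 100, cds_end=e2[0] + 100))
        fm = partition_genome(genes, sizes, flank_width=800)
        expected = brute_force_labels(genes, sizes, 800)
        for chrom in sizes:
            got = [FEATURE_LABELS[c] for c in fm.labels[chrom]]
            assert got == expected[chrom], chrom

    def test_composition_conserves_genome_length(self, sim):
        fm = partition_genome(sim.genes, sim.sizes, 5000)
        assert sum(fm.genome_composition.values()) == sim.sizes.total

    def test_bad_flank_width(self, sim):
        with pytest.raises(ValueError):
            partition_genome(sim.genes, sim.sizes, 0)

    def test_unknown_chromosome_rejected(self):
        g = GeneModel("g1", "chrZ", "+", 0, 100, exons=[(0, 100)])
        with pytest.raises(KeyError):
            partition_genome([g], make_sizes(chr1=1000), 100)


class TestLocateInterval:
    @pytest.fixture()
    def fm(self):
        sizes = make_sizes(chr1=10_000)
        genes = [GeneModel("g1", "chr1", "+", 2000, 4000,
                           exons=[(2000, 2500), (3500, 4000)],
                           cds_start=2200, cds_end=3800)]
        return partition_genome(genes, sizes, flank_width=1000)

    def test_intergenic_interval(self, fm):
        assert locate_interval(fm, Interval("chr1", 6000, 6100)) == "intergenic"

    def test_midpoint_rule_at_boundary(self, fm):
        # straddles promoter / 5'UTR boundary at 2000 with midpoint in promoter
        iv = Interval("chr1", 1900, 2060)
        assert iv.midpoint == 1980
        assert locate_interval(fm, iv, "midpoint") == "promoter"

    def test_bp_composition_normalized(self, fm):
        fractions = locate_interval(fm, Interval("chr1", 1500, 4500), "bp_composition")
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert fractions["promoter"] == pytest.approx(500 / 3000)

    def test_off_chromosome_interval_rejected(self, fm):
        with pytest.raises(KeyError):
            locate_interval(fm, Interval("chr9", 0, 10))


class TestSignedTssDistance:
    def test_plus_strand(self):
        g = GeneModel("g", "chr1", "+", 1000, 2000, exons=[(1000, 2000)])
        assert signed_tss_distance(g, 1100) == 100
        assert signed_tss_distance(g, 1000) == 0

    def test_minus_strand_flip(self):
        g = GeneModel("g", "chr1", "-", 1000, 2000, exons=[(1000, 2000)])
        assert g.tss == 1999
        assert signed_tss_distance(g, 1899) == 100
        assert signed_tss_distance(g, 1999) == 0

    @pytest.mark.parametrize("pos", [0, 500, 1234, 2999])
    def test_strand_mirror_symmetry(self, pos):
        # mirroring a - strand gene and its query onto the + strand negates nothing:
        # the gene-oriented distances agree
        L = 3000
        g_minus = GeneModel("g", "chr1", "-", 1000, 2000, exons=[(1000, 2000)])
        g_plus = GeneModel("g", "chr1", "+", L - 2000, L - 1000,
                           exons=[(L - 2000, L - 1000)])
        mirrored = L - 1 - pos
        assert signed_tss_distance(g_minus, pos) == signed_tss_distance(g_plus, mirrored)
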