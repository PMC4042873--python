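"""Gene-model loading, 3' extension, and region-index geometry."""

import numpy as np
import pytest

from uarna import (
    GeneModel,
    build_region_index,
    build_ua_windows,
    extend_three_prime,
    load_gene_models,
)

LENGTHS = {"chr1": 100_000}


def bed(*lines):
    return list(lines)


class TestLoadGeneModels:
    def test_plus_strand_convention(self):
        genes = load_gene_models(bed("chr1\t1000\t5000\tgeneA\t0\t+"), LENGTHS)
        (g,) = genes
        assert (g.start, g.end, g.tss, g.strand) == (1000, 5000, 1000, "+")

    def test_minus_strand_tss_is_last_base(self):
        (g,) = load_gene_models(bed("chr1\t1000\t5000\tgeneB\t0\t-"), LENGTHS)
        assert g.tss == 4999

    def test_transcripts_merge_to_gene_span(self):
        genes = load_gene_models(
            bed("chr1\t2000\t6000\tgeneC\t0\t+", "chr1\t2500\t7000\tgeneC\t0\t+"),
            LENGTHS,
        )
        (g,) = genes
        assert (g.start, g.end) == (2000, 7000)

    def test_gtf_one_based_conversion(self):
        line = 'chr1\tsrc\texon\t1001\t5000\t.\t+\t.\tgene_id "gA";'
        (g,) = load_gene_models([line], LENGTHS, fmt="gtf")
        assert (g.start, g.end) == (1000, 5000)

    def test_unknown_chromosome_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            genes = load_gene_models(
                bed("chrUn\t0\t100\tgX\t0\t+", "chr1\t10\t20\tgY\t0\t+"), LENGTHS
            )
        assert [g.gene_id for g in genes] == ["gY"]
        assert "chrUn" in caplog.text

    @pytest.mark.parametrize(
        "line", ["chr1\t100\t200\tg\t0\t.", "chr1\t200\t100\tg\t0\t+"]
    )
    def test_malformed_records_raise(self, line):
        with pytest.raises(ValueError):
            load_gene_models(bed(line), LENGTHS)

    def test_deterministic_order(self):
        lines = bed(
            "chr1\t5000\t6000\tb\t0\t+",
            "chr1\t1000\t2000\ta\t0\t-",
            "chr1\t1000\t3000\taa\t0\t+",
        )
        genes = load_gene_models(lines, LENGTHS)
        assert [g.gene_id for g in genes] == ["a", "aa", "b"]


class TestExtendThreePrime:
    def test_unobstructed_gene_gains_full_extension(self):
        genes = [
            GeneModel("g1", "chr1", "+", 1000, 5000),
            GeneModel("g2", "chr1", "+", 20000, 25000),
        ]
        out = extend_three_prime(genes, LENGTHS)
        assert out[0].ext_end == 9000

    def test_same_strand_gene_in_window_blocks_entirely(self):
        genes = [
            GeneModel("g1", "chr1", "+", 1000, 5000),
            GeneModel("g2", "chr1", "+", 7000, 12000),
        ]
        out = extend_three_prime(genes, LENGTHS)
        assert out[0].ext_end == 5000  # all-or-nothing, no partial extension

    def test_opposite_strand_gene_does_not_block(self):
        genes = [
            GeneModel("g1", "chr1", "+", 1000, 5000),
            GeneModel("g2", "chr1", "-", 7000, 12000),
        ]
        out = extend_three_prime(genes, LENGTHS)
        assert out[0].ext_end == 9000

    def test_clipped_at_chromosome_end(self):
        genes = [GeneModel("g1", "chr1", "+", 90_000, 99_000)]
        out = extend_three_prime(genes, LENGTHS)
        assert out[0].ext_end == 100_000

    def test_minus_strand_extends_upstream_coordinates(self):
        genes = [GeneModel("g1", "chr1", "-", 10_000, 15_000)]
        out = extend_three_prime(genes, LENGTHS)
        assert (out[0].ext_start, out[0].ext_end) == (6000, 15_000)

    def test_idempotent(self):
        genes = [
            GeneModel("g1", "chr1", "+", 1000, 5000),
            GeneModel("g2", "chr1", "+", 20000, 25000),
        ]
        once = extend_three_prime(genes, LENGTHS)
        twice = extend_three_prime(once, LENGTHS)
        assert once == twice


class TestUaWindows:
    def test_plus_gene_window_on_minus_strand(self):
        (w,) = build_ua_windows([GeneModel("g", "chr1", "+", 10_000, 14_000)], LENGTHS)
        assert (w.start, w.end, w.strand, w.gene_id) == (8000, 10_000, "-", "g")

    def test_minus_gene_window_on_plus_strand(self):
        # TSS at 10_000 for a minus-strand gene ending there
        (w,) = build_ua_windows([GeneModel("g", "chr1", "-", 6000, 10_001)], LENGTHS)
        assert (w.start, w.end, w.strand) == (10_001, 12_001, "+")

    def test_window_clipped_at_chromosome_start(self):
        (w,) = build_ua_windows([GeneModel("g", "chr1", "+", 500, 4000)], LENGTHS)
        assert (w.start, w.end) == (0, 500)

    def test_window_never_intersects_own_sense_region(self):
        rng = np.random.default_rng(0)
        genes = []
        pos = 1000
        for i in range(40):
            length = int(rng.integers(500, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{i}", "chr1", strand, pos, pos + length))
            pos += length + int(rng.integers(7000, 9000))
        extended = extend_three_prime(genes, {"chr1": pos + 10_000})
        windows = {w.gene_id: w for w in build_ua_windows(extended, {"chr1": pos + 10_000})}
        for g in extended:
            w = windows[g.gene_id]
            s, e = g.sense_region
            assert w.end <= s or w.start >= e


class TestRegionIndexSymmetry:
    def test_strand_mirror_rebuilds_mirrored_regions(self):
        length = 50_000
        genes = [
            GeneModel("a", "chr1", "+", 1000, 5000),
            GeneModel("b", "chr1", "-", 15_000, 21_000),
        ]
        flip = {"+": "-", "-": "+"}
        mirrored = [
            GeneModel(g.gene_id, g.chrom, flip[g.strand], length - g.end, length - g.start)
            for g in genes
        ]
        idx = build_region_index(
            extend_three_prime(genes, {"chr1": length}), {"chr1": length}
        )
        idx_m = build_region_index(
            extend_three_prime(mirrored, {"chr1": length}), {"chr1": length}
        )
        fwd = {(c, length - e, length - s, n, flip[st]) for c, s, e, n, st in idx.sense_regions()}
        assert fwd == set(idx_m.sense_regions())
        fwd_ua = {(c, length - e, length - s, n, flip[st]) for c, s, e, n, st in idx.ua_regions()}
        assert fwd_ua == set(idx_m.ua_regions())

    def test_point_queries_are_strand_specific(self):
        genes = extend_three_prime(
            [GeneModel("a", "chr1", "+", 1000, 5000)], LENGTHS
        )
        idx = build_region_index(genes, LENGTHS)
        assert idx.sense_gene_ids("chr1", "+", 2000) == ["a"]
        assert idx.sense_gene_ids("chr1", "-", 2000) == []
        assert idx.ua_gene_ids("chr1", "-", 999) == ["a"]
        assert idx.ua_gene_ids("chr1", "+", 999) == []
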