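import pytest
from hypothesis import given, strategies as st

from ervkit.genome_model import (
    AnnotationParseError,
    FamilySpec,
    GenomicInterval,
    assemble_full_length_elements,
    flank_bins,
    nearest_ltr_distance,
    read_gene_models,
    read_repeat_annotation,
    write_gene_models_gtf,
    write_repeat_bed6,
)

from conftest import make_full_length, make_gene, make_repeat


class TestGenomicInterval:
    def test_rejects_inverted(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100)

    def test_overlap_half_open(self):
        a = GenomicInterval("chr1", 0, 100)
        assert not a.overlaps(GenomicInterval("chr1", 100, 200))
        assert a.overlaps(GenomicInterval("chr1", 99, 200))
        assert not a.overlaps(GenomicInterval("chr2", 0, 100))


class TestReadRepeatAnnotation:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_repeat_annotation(p, "bed6") == []

    def test_bed6_line(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chr1\t1000\t1500\tMT2_Mm\t0\t+\n")
        (el,) = read_repeat_annotation(p, "bed6")
        assert el.family == "MT2_Mm"
        assert el.part == "LTR"
        assert (el.interval.start, el.interval.end) == (1000, 1500)
        assert el.interval.strand == "+"

    def test_repeatmasker_coordinate_conversion(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            "  235 1.2 0.3 0.4 chr1 1001 1500 (100) + MT2_Mm LTR/ERVL 1 500 (0) 1\n"
        )
        (el,) = read_repeat_annotation(p, "repeatmasker")
        assert (el.interval.start, el.interval.end) == (1000, 1500)

    def test_repeatmasker_c_strand(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            "  235 1.2 0.3 0.4 chr1 1001 1500 (100) C MT2_Mm LTR/ERVL 1 500 (0) 1\n"
        )
        (el,) = read_repeat_annotation(p, "repeatmasker")
        assert el.interval.strand == "-"

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1000\t1500\tMT2_Mm\t0\t+\nchr1\tnotanumber\t2\tX\n")
        with pytest.raises(AnnotationParseError, match="line 2"):
            read_repeat_annotation(p, "bed6")

    def test_unknown_family_strict(self, tmp_path):
        p = tmp_path / "u.bed"
        p.write_text("chr1\t10\t20\tWEIRD99\t0\t+\n")
        with pytest.raises(ValueError, match="strict"):
            read_repeat_annotation(p, "bed6", strict=True)
        (el,) = read_repeat_annotation(p, "bed6", strict=False)
        assert el.part == "internal"

    def test_bed6_round_trip(self, tmp_path):
        els = [
            make_repeat("chr1", 0, 500, "MT2_Mm"),
            make_repeat("chr2", 100, 5100, "MERVL-int", "-", part="internal"),
        ]
        p = tmp_path / "rt.bed"
        write_repeat_bed6(els, p)
        back = read_repeat_annotation(p, "bed6")
        assert [(e.family, e.part, e.interval) for e in back] == [
            (e.family, e.part, e.interval) for e in els
        ]


class TestAssembly:
    def test_basic_triplet(self, mervl_spec):
        els = [
            make_repeat("chr1", 0, 500, "MT2_Mm"),
            make_repeat("chr1", 500, 5500, "MERVL-int", part="internal"),
            make_repeat("chr1", 5500, 6000, "MT2_Mm"),
        ]
        (fl,) = assemble_full_length_elements(els, [mervl_spec])
        assert (fl.interval.start, fl.interval.end) == (0, 6000)
        assert fl.family == "MERVL"
        assert fl.ltr5.family == fl.ltr3.family == "MT2_Mm"

    def test_solo_ltr_not_assembled(self, mervl_spec):
        els = [make_repeat("chr1", 0, 500, "MT2_Mm")]
        assert assemble_full_length_elements(els, [mervl_spec]) == []

    def test_mismatched_ltrs_not_assembled(self, mervl_spec):
        els = [
            make_repeat("chr1", 0, 500, "MT2_Mm"),
            make_repeat("chr1", 500, 5500, "MERVL-int", part="internal"),
            make_repeat("chr1", 5500, 6000, "RLTR10"),
        ]
        assert assemble_full_length_elements(els, [mervl_spec]) == []

    def test_length_window_enforced(self, mervl_spec):
        els = [
            make_repeat("chr1", 0, 500, "MT2_Mm"),
            make_repeat("chr1", 500, 900, "MERVL-int", part="internal"),
            make_repeat("chr1", 900, 1400, "MT2_Mm"),
        ]  # span 1400 < 5000
        assert assemble_full_length_elements(els, [mervl_spec]) == []

    def test_gap_tolerance(self, mervl_spec):
        els = [
            make_repeat("chr1", 0, 500, "MT2_Mm"),
            make_repeat("chr1", 650, 5500, "MERVL-int", part="internal"),
            make_repeat("chr1", 5500, 6000, "MT2_Mm"),
        ]  # 150 bp gap > 100 bp tolerance
        assert assemble_full_length_elements(els, [mervl_spec]) == []

    def test_strands_not_mixed(self, mervl_spec):
        els = [
            make_repeat("chr1", 0, 500, "MT2_Mm", "+"),
            make_repeat("chr1", 500, 5500, "MERVL-int", "-", part="internal"),
            make_repeat("chr1", 5500, 6000, "MT2_Mm", "+"),
        ]
        assert assemble_full_length_elements(els, [mervl_spec]) == []

    def test_components_not_reused_and_disjoint(self, mervl_spec):
        els = []
        for base in (0, 10_000, 20_000):
            els += [
                make_repeat("chr1", base, base + 500, "MT2_Mm"),
                make_repeat("chr1", base + 500, base + 5500, "MERVL-int",
                            part="internal"),
                make_repeat("chr1", base + 5500, base + 6000, "MT2_Mm"),
            ]
        out = assemble_full_length_elements(els, [mervl_spec])
        assert len(out) == 3
        for a, b in zip(out, out[1:]):
            assert a.interval.end <= b.interval.start
        for fl in out:
            assert fl.ltr5.part == fl.ltr3.part == "LTR"


class TestFlankBins:
    def test_plus_strand_geometry(self):
        el = make_full_length("chr1", 10_000, 16_000, "+")
        bins = flank_bins(el)
        assert len(bins) == 240
        five = [b for b in bins if b.side == "5prime"]
        three = [b for b in bins if b.side == "3prime"]
        assert (five[0].interval.start, five[0].interval.end) == (9_950, 10_000)
        assert (three[0].interval.start, three[0].interval.end) == (16_000, 16_050)
        assert five[119].interval.start == 10_000 - 6_000

    def test_minus_strand_mirrored(self):
        el = make_full_length("chr1", 10_000, 16_000, "-")
        bins = flank_bins(el)
        five0 = next(b for b in bins if b.side == "5prime" and b.bin_index == 0)
        assert (five0.interval.start, five0.interval.end) == (16_000, 16_050)

    def test_chromosome_edge_truncation(self):
        el = make_full_length("chr1", 30, 6_030, "+")
        bins = flank_bins(el)
        five0 = next(b for b in bins if b.side == "5prime" and b.bin_index == 0)
        assert five0.truncated
        assert (five0.interval.start, five0.interval.end) == (0, 30)
        five1 = next(b for b in bins if b.side == "5prime" and b.bin_index == 1)
        assert five1.interval is None and five1.truncated

    def test_widths_sum_to_span(self):
        el = make_full_length("chr1", 50_000, 56_000, "+")
        bins = flank_bins(el)
        for side in ("5prime", "3prime"):
            widths = sum(b.interval.length for b in bins
                         if b.side == side and b.interval is not None)
            assert widths == 6_000

    def test_bad_arguments(self):
        el = make_full_length("chr1", 50_000, 56_000, "+")
        with pytest.raises(ValueError):
            flank_bins(el, span=0)
        with pytest.raises(ValueError):
            flank_bins(el, bin_width=-1)
        with pytest.raises(ValueError):
            flank_bins(el, span=6_000, bin_width=33)

    def test_strand_mirror_reverses_order(self):
        plus = make_full_length("chr1", 50_000, 56_000, "+")
        minus = make_full_length("chr1", 50_000, 56_000, "-")
        plus_ivs = [(b.side, b.interval.start) for b in flank_bins(plus)]
        minus_ivs = {(b.side, b.bin_index): b.interval.start
                     for b in flank_bins(minus)}
        # 5' bin k of the plus element is the 3' bin k of the minus element
        for (side, start), b in zip(plus_ivs, flank_bins(plus)):
            other = "3prime" if b.side == "5prime" else "5prime"
            assert minus_ivs[(other, b.bin_index)] == b.interval.start


class TestNearestLtrDistance:
    FAMS = {"MT2_Mm", "MT2A", "MT2C"}

    def test_tss_inside_element(self):
        gene = make_gene("g", "chr1", [(1200, 1800), (2400, 3000)])
        els = [make_repeat("chr1", 1000, 1500, "MT2_Mm")]
        assert nearest_ltr_distance(gene, self.FAMS, els) == 0

    def test_gap_arithmetic(self):
        gene = make_gene("g", "chr1", [(10_000, 10_600)])
        els = [make_repeat("chr1", 4_500, 5_000, "MT2_Mm")]
        assert nearest_ltr_distance(gene, self.FAMS, els) == 5_000

    def test_absent_family(self):
        gene = make_gene("g", "chr1", [(10_000, 10_600)])
        els = [make_repeat("chr2", 4_500, 5_000, "MT2_Mm"),
               make_repeat("chr1", 0, 500, "IAPLTR1_Mm")]
        assert nearest_ltr_distance(gene, self.FAMS, els) is None

    def test_minus_strand_tss(self):
        gene = make_gene("g", "chr1", [(10_000, 10_600)], strand="-")
        els = [make_repeat("chr1", 11_000, 11_500, "MT2_Mm")]
        # TSS at 10_599 -> gap 11_000 - 10_599
        assert nearest_ltr_distance(gene, self.FAMS, els) == 401

    @given(shift=st.integers(min_value=0, max_value=10_000))
    def test_translation_invariance(self, shift):
        gene = make_gene("g", "chr1", [(10_000 + shift, 10_600 + shift)])
        els = [make_repeat("chr1", 2_000 + shift, 2_500 + shift, "MT2_Mm")]
        assert nearest_ltr_distance(gene, self.FAMS, els) == 7_500


class TestGeneModels:
    def test_gtf_round_trip(self, tmp_path):
        genes = [
            make_gene("gA", "chr1", [(100, 400), (900, 1200)]),
            make_gene("gB", "chr1", [(5_000, 5_300), (4_000, 4_300)],
                      strand="-", in_refseq=False),
        ]
        p = tmp_path / "genes.gtf"
        write_gene_models_gtf(genes, p)
        back = read_gene_models(p, "gtf")
        by_id = {g.gene_id: g for g in back}
        assert by_id["gA"].exons == genes[0].exons
        assert by_id["gA"].transcript_length == 600
        assert not by_id["gB"].in_refseq and by_id["gB"].in_ensembl
        assert by_id["gB"].tss == 5_299  # minus strand: highest coordinate

    def test_bed12(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t100\t1200\tgA\t0\t+\t100\t1200\t0\t2\t300,300\t0,800\n"
        )
        (g,) = read_gene_models(p, "bed12")
        assert [(e.start, e.end) for e in g.exons] == [(100, 400), (900, 1200)]
        assert g.transcript_length == 600

    def test_exon_order_validation(self):
        with pytest.raises(ValueError, match="transcript order"):
            make_gene("g", "chr1", [(900, 1200), (100, 400)])
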