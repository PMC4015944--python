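"""File readers/writers, the output table, UCSC links, promoters, sorting."""

import pytest

from regionannot import (
    BED_MAPPING,
    DISTANCE_MAPPING,
    ColumnMapping,
    GenomicRegion,
    OutputRow,
    RegionParseError,
    StrandRequiredError,
    make_promoters,
    read_annotation_file,
    read_query_file,
    sort_annotation_file,
    ucsc_link,
    write_output_table,
)


class TestColumnMapping:
    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            ColumnMapping(1, 1, 3, 4)

    def test_nonpositive_indices_rejected(self):
        with pytest.raises(ValueError):
            ColumnMapping(0, 2, 3, 4)


class TestReadAnnotationFile:
    def test_standard_bed_mapping(self, tmp_text):
        path = tmp_text("a.bed", "track name=x\n# comment\nchr1\t100\t200\tgeneA\n")
        (r,) = read_annotation_file(path, BED_MAPPING)
        assert r == GenomicRegion("chr1", 100, 200, name="geneA")

    def test_permuted_columns(self, tmp_text):
        path = tmp_text("a.txt", "geneA\tchr1\t100\t200\n")
        (r,) = read_annotation_file(path, ColumnMapping(2, 3, 4, 1))
        assert (r.chrom, r.start, r.end, r.name) == ("chr1", 100, 200, "geneA")

    def test_five_column_stranded_format(self, tmp_text):
        path = tmp_text("a.txt", "chr1 100 200 + geneA\n")
        (r,) = read_annotation_file(path, DISTANCE_MAPPING)
        assert (r.strand, r.name) == ("+", "geneA")

    def test_three_column_bed_yields_unnamed_regions(self, tmp_text):
        path = tmp_text("a.bed", "chr1\t100\t200\n")
        (r,) = read_annotation_file(path)
        assert r.name is None

    @pytest.mark.parametrize(
        "line,match",
        [
            ("chr1\t100", "columns"),
            ("chr1\tabc\t200", "non-integer"),
            ("chr1 100 200 ? geneA", "strand"),
            ("chr1\t100\t200\ta//b", "separator"),
        ],
    )
    def test_bad_lines_report_line_numbers(self, tmp_text, line, match):
        mapping = DISTANCE_MAPPING if "?" in line else BED_MAPPING
        path = tmp_text("bad.bed", "chr1\t0\t1\t+\tok\n" + line + "\n")
        with pytest.raises(RegionParseError, match="line 2"):
            read_annotation_file(path, mapping)
        with pytest.raises(RegionParseError, match=match):
            read_annotation_file(path, mapping)


class TestReadQueryFile:
    def test_mixed_dialects_with_auto_convention(self, tmp_text):
        path = tmp_text(
            "q.txt", "chr1:101-200\nchr1\t100\t200\nchr1:101-200\n"
        )
        regions, displays = read_query_file(path, "auto")
        # colon form is 1-based inclusive, tabular form BED: same region
        assert regions[0] == regions[1] == regions[2]
        assert len(displays) == 3

    def test_duplicates_preserved(self, tmp_text):
        path = tmp_text("q.txt", "chr1:1-10\nchr1:1-10\n")
        regions, _ = read_query_file(path)
        assert regions[0] == regions[1] and len(regions) == 2


class TestOutputTable:
    def test_cells_rows_and_separator(self, tmp_path):
        rows = [
            OutputRow("chr1:1-10", "http://x", ("TP53//WRAP53",)),
            OutputRow("chr1:1-10", "http://x", ("TP53//WRAP53",)),
            OutputRow("chr2:5-6", "http://y", ("",)),
        ]
        out = tmp_path / "out.tsv"
        write_output_table(rows, out, ["refseq"])
        lines = out.read_text().splitlines()
        assert lines[0] == "region\tlink\trefseq"
        assert len(lines) == 4
        assert lines[1] == lines[2]  # duplicate queries, identical annotations
        assert lines[1].split("\t")[2].split("//") == ["TP53", "WRAP53"]
        assert lines[3].split("\t")[2] == ""

    def test_header_suppression(self, tmp_path):
        out = tmp_path / "out.tsv"
        write_output_table([], out, ["c"], include_header=False)
        assert out.read_text() == ""


class TestUcscLink:
    def test_display_coordinates_and_assembly(self):
        url = ucsc_link(GenomicRegion("chr1", 7577505, 7577606), "hg19")
        assert "db=hg19" in url and "position=chr1:7577506-7577606" in url

    def test_other_assembly(self):
        assert "db=mm10" in ucsc_link(GenomicRegion("chr5", 0, 10), "mm10")

    def test_zero_length_uses_raw_bounds(self):
        url = ucsc_link(GenomicRegion("chr1", 55, 55), "hg19")
        assert "position=chr1:55-55" in url


class TestMakePromoters:
    def test_plus_strand_promoter_flanks_the_tss(self):
        (p,) = make_promoters(
            [GenomicRegion("chr1", 10_000, 15_000, name="nm_x", strand="+")]
        )
        assert (p.start, p.end, p.name) == (9_000, 11_000, "nm_x")
        assert p.length == 2_000

    def test_minus_strand_tss_is_the_transcript_end(self):
        (p,) = make_promoters(
            [GenomicRegion("chr1", 10_000, 15_000, name="nm_y", strand="-")]
        )
        assert (p.start, p.end) == (14_000, 16_000)

    def test_clamped_at_zero(self):
        (p,) = make_promoters(
            [GenomicRegion("chr1", 400, 5_000, name="nm_z", strand="+")]
        )
        assert (p.start, p.end) == (0, 1_400)

    def test_unstranded_transcript_rejected(self):
        with pytest.raises(StrandRequiredError):
            make_promoters([GenomicRegion("chr1", 0, 10, name="x")])


class TestSortAnnotationFile:
    CONTENT = "chr2\t5\t6\tc\nchr1\t30\t40\tb\nchr1\t0\t10\ta\n"

    def test_sorts_by_chrom_start_end(self, tmp_text, tmp_path):
        src = tmp_text("in.bed", self.CONTENT)
        dst = tmp_path / "out.bed"
        sort_annotation_file(src, dst)
        assert dst.read_text() == "chr1\t0\t10\ta\nchr1\t30\t40\tb\nchr2\t5\t6\tc\n"

    def test_idempotent_on_sorted_input(self, tmp_text, tmp_path):
        src = tmp_text("in.bed", self.CONTENT)
        once, twice = tmp_path / "once.bed", tmp_path / "twice.bed"
        sort_annotation_file(src, once)
        sort_annotation_file(once, twice)
        assert once.read_bytes() == twice.read_bytes()

    def test_large_file_matches_independent_sort(self, tmp_path):
        from regionannot.fixtures import FixtureSpec, generate_regions
        from regionannot import write_bed

        regions = generate_regions(FixtureSpec(10_000, seed=5, named=True))
        src, dst = tmp_path / "in.bed", tmp_path / "out.bed"
        write_bed(regions, src)
        sort_annotation_file(src, dst)
        lines = dst.read_text().splitlines()
        keys = [
            (f[0], int(f[1]), int(f[2])) for f in (l.split("\t") for l in lines)
        ]
        assert keys == sorted(keys)
        assert sorted(lines) == sorted(src.read_text().splitlines())
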