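"""Header/record parsing, file loading, validation and normalization."""

import gzip
import io

import pytest

from vcfsieve import Dataset, Zygosity, load_vcf, parse_header, \
    parse_record, split_multiallelic, validate_vcf
from vcfsieve.errors import VCFParseError
from vcfsieve.fixtures import generate_vcf
from vcfsieve.ingest import render_vcf

from conftest import HEADER, TOY_VCF, as_stream


def _meta():
    return parse_header(HEADER.splitlines())


class TestParseHeader:
    def test_declarations_captured_with_types(self):
        meta = _meta()
        assert meta.info_fields["AF"].type == "Float"
        assert meta.info_fields["AF"].number == "A"
        assert meta.format_fields["AD"].type == "Integer"
        assert meta.info_fields["SOMATIC"].type == "Flag"
        assert meta.filter_ids == {"PASS"}
        assert meta.sample_ids == ["S1", "S2"]

    def test_description_commas_do_not_break_parsing(self):
        meta = _meta()
        assert "e.g. HIGH" in meta.info_fields["IMPACT"].description

    def test_empty_info_section_single_sample(self):
        lines = ["##fileformat=VCFv4.2",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tX"]
        meta = parse_header(lines)
        assert meta.info_fields == {}
        assert meta.sample_ids == ["X"]

    def test_missing_chrom_line_is_an_error(self):
        with pytest.raises(VCFParseError):
            parse_header(["##fileformat=VCFv4.2"])

    def test_malformed_declaration_carries_line_number(self):
        lines = ["##fileformat=VCFv4.2",
                 "##INFO=<ID=DP,Number=1,Type=Bogus,Description=\"x\">",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        with pytest.raises(VCFParseError) as exc:
            parse_header(lines)
        assert exc.value.line_number == 2

    def test_duplicate_declaration_rejected(self):
        lines = ["##INFO=<ID=DP,Number=1,Type=Integer,Description=\"a\">",
                 "##INFO=<ID=DP,Number=1,Type=Integer,Description=\"b\">",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        with pytest.raises(VCFParseError):
            parse_header(lines)


class TestParseRecord:
    def test_typed_info_with_flag(self):
        doc = parse_record(
            "1\t100\t.\tA\tT\t50\tPASS\tDP=10;SOMATIC\t"
            "GT:AD:DP\t0/1:12,5:17\t0/0:20,0:20", _meta())
        assert doc.info == {"DP": 10, "SOMATIC": True}
        assert doc.qual == 50.0

    def test_per_alternate_array(self):
        doc = parse_record("1\t100\t.\tA\tT,G\t.\tPASS\tAF=0.5,0.2",
                           _meta())
        assert doc.info["AF"] == [0.5, 0.2]

    def test_missing_sample_values(self):
        doc = parse_record("1\t100\t.\tA\tT\t.\t.\t.\tGT:DP\t./.:.\t0/1:9",
                           _meta())
        call = doc.calls["S1"]
        assert call.zygosity is Zygosity.NO_CALL
        assert "DP" not in call.other_format
        assert doc.calls["S2"].other_format["DP"] == 9

    def test_dot_info_value_is_absent_not_zero(self):
        doc = parse_record("1\t100\t.\tA\tT\t.\t.\tDP=.", _meta())
        assert "DP" not in doc.info

    def test_too_few_columns_rejected(self):
        with pytest.raises(VCFParseError):
            parse_record("1\t100\t.\tA\tT\t50\tPASS", _meta())

    def test_undeclared_key_strict_vs_tolerant(self):
        line = "1\t100\t.\tA\tT\t.\t.\tFOO=3"
        with pytest.raises(VCFParseError):
            parse_record(line, _meta(), strict=True)
        doc = parse_record(line, _meta(), strict=False)
        assert doc.info["FOO"] == "3"  # retained as string

    def test_ill_typed_value_strict_vs_tolerant(self):
        line = "1\t100\t.\tA\tT\t.\t.\tDP=ten"
        with pytest.raises(VCFParseError):
            parse_record(line, _meta(), strict=True)
        assert parse_record(line, _meta()).info["DP"] == "ten"


class TestLoadVcf:
    def test_gzip_detected_by_magic_bytes(self, tmp_path):
        # deliberately misleading extension: plain name, gzipped content
        path = tmp_path / "data.vcf"
        path.write_bytes(gzip.compress(TOY_VCF.encode()))
        meta, records = load_vcf(path)
        docs = list(records)
        assert len(docs) == 3
        plain = list(load_vcf(as_stream(TOY_VCF))[1])
        assert [(d.chrom, d.pos, d.ref, d.alt) for d in docs] == \
            [(d.chrom, d.pos, d.ref, d.alt) for d in plain]

    def test_carrier_summaries(self):
        _, records = load_vcf(as_stream(TOY_VCF))
        doc = next(records)
        assert doc.derived["DERIVED.sample_count"] == 1
        assert doc.derived["DERIVED.sample_list"] == "S1"

    def test_streaming_record_count(self):
        text = generate_vcf(2000, 2, seed=3)
        _, records = load_vcf(as_stream(text))
        assert sum(1 for _ in records) == 2000

    def test_empty_source_is_an_error(self, tmp_path):
        empty = tmp_path / "empty.vcf"
        empty.write_text("")
        with pytest.raises(VCFParseError):
            load_vcf(empty)

    def test_sample_column_order_only_permutes_calls(self):
        swapped = TOY_VCF.replace("FORMAT\tS1\tS2", "FORMAT\tS2\tS1")
        lines = swapped.splitlines()
        out = []
        for line in lines:
            if line.startswith("#") or not line:
                out.append(line)
            else:
                cols = line.split("\t")
                cols[9], cols[10] = cols[10], cols[9]
                out.append("\t".join(cols))
        reordered = "\n".join(out) + "\n"
        a = list(load_vcf(as_stream(TOY_VCF))[1])
        b = list(load_vcf(as_stream(reordered))[1])
        for da, db in zip(a, b):
            assert da.calls.keys() == db.calls.keys()
            for sid in da.calls:
                assert da.calls[sid].gt_raw == db.calls[sid].gt_raw
            assert da.derived == db.derived


class TestValidateVcf:
    def test_clean_file_ok(self):
        report = validate_vcf(as_stream(generate_vcf(100, 3, seed=7)))
        assert report.ok
        assert report.issues == []

    def test_undeclared_info_key_reported_with_line(self):
        bad = TOY_VCF + "2\t99\t.\tC\tG\t.\t.\tFOO=1\tGT\t0/1\t0/0\n"
        report = validate_vcf(as_stream(bad))
        assert not report.ok
        (err,) = report.errors
        assert "FOO" in err.message
        assert err.line_number == len(TOY_VCF.splitlines()) + 1

    def test_single_planted_defect_located(self):
        lines = TOY_VCF.splitlines()
        lines.insert(-1, "1\t150\t.\tA")  # malformed: 4 columns
        report = validate_vcf(as_stream("\n".join(lines) + "\n"))
        assert len(report.errors) == 1
        assert report.errors[0].line_number == len(lines) - 1

    def test_non_monotone_positions_warn(self):
        shuffled = TOY_VCF + "1\t10\t.\tC\tG\t.\tPASS\tDP=1\tGT\t0/1\t0/0\n"
        report = validate_vcf(as_stream(shuffled))
        assert report.ok  # warning, not error
        assert any(i.severity == "warning" and "position" in i.message
                   for i in report.issues)


class TestSplitMultiallelic:
    def test_single_alt_identity(self):
        doc = parse_record("1\t100\t.\tA\tT\t.\t.\tDP=10", _meta())
        assert split_multiallelic(doc, _meta()) == [doc]

    def test_number_a_sliced_per_alternate(self):
        doc = parse_record("2\t50\t.\tT\tA,G\t.\t.\tAF=0.1,0.9", _meta())
        a, g = split_multiallelic(doc, _meta())
        assert (a.alt, a.info["AF"]) == ("A", [0.1])
        assert (g.alt, g.info["AF"]) == ("G", [0.9])

    def test_ad_and_gt_remapped_per_allele(self):
        meta = _meta()
        doc = parse_record(
            "2\t50\t.\tT\tA,G\t99\tPASS\tDP=40\tGT:AD\t1/2:4,6,8\t0/1:10,3,0",
            meta)
        rec_a, rec_g = split_multiallelic(doc, meta)
        s1a, s1g = rec_a.calls["S1"], rec_g.calls["S1"]
        assert (s1a.ref_depth, s1a.alt_depth) == (4, 6)
        assert (s1g.ref_depth, s1g.alt_depth) == (4, 8)
        assert s1a.is_carrier and s1g.is_carrier
        # S2 carried only allele 1 (A); depths slice accordingly
        s2a, s2g = rec_a.calls["S2"], rec_g.calls["S2"]
        assert (s2a.ref_depth, s2a.alt_depth) == (10, 3)
        assert (s2g.ref_depth, s2g.alt_depth) == (10, 0)

    def test_wrong_arity_per_alt_field_named_in_error(self):
        doc = parse_record("2\t50\t.\tT\tA,G\t.\t.\tAF=0.1", _meta())
        with pytest.raises(VCFParseError, match="AF"):
            split_multiallelic(doc, _meta())

    def test_key_multiset_conserved(self):
        text = generate_vcf(200, 2, seed=9, multiallelic_fraction=0.3)
        meta, records = load_vcf(as_stream(text))
        docs = list(records)
        expected = []
        for d in docs:
            expected += [(d.chrom, d.pos, d.ref, alt) for alt in d.alts]
        result = []
        for d in docs:
            for s in split_multiallelic(d, meta):
                result.append((s.chrom, s.pos, s.ref, s.alt))
                assert not s.is_multiallelic
        assert sorted(result) == sorted(expected)


def test_render_round_trip_preserves_keys():
    ds = Dataset.from_vcf(as_stream(generate_vcf(150, 3, seed=13)))
    text = render_vcf(ds.meta, ds.docs)
    ds2 = Dataset.from_vcf(io.BytesIO(text.encode()))
    keys = lambda d: [(x.chrom, x.pos, x.ref, x.alt) for x in d.docs]
    assert keys(ds) == keys(ds2)
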