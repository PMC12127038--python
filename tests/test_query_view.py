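"""Query layer tests: regions, include expressions, query/view rendering."""

import numpy as np
import pytest

from vczkit import (
    evaluate_include_expression,
    render_query,
    render_vcf,
    resolve_regions,
)
from vczkit.query_view import QueryError, Region, parse_region
from vczkit.testing import compare_vcf_files


class TestParseRegion:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("1", Region("1")),
            ("1:100", Region("1", 100, 100)),
            ("1:200-", Region("1", 200, None)),
            ("1:150-250", Region("1", 150, 250)),
            ("chr2:5-9", Region("chr2", 5, 9)),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_region(text) == expected

    def test_inverted_region_rejected(self):
        with pytest.raises(QueryError):
            Region("1", 10, 5)


class TestResolveRegions:
    def test_examples(self, toy_store):
        # toy positions: 100, 200, 300 on "1"; 7 on "X"
        assert resolve_regions(toy_store, ["1:150-250"]).tolist() == [1]
        assert resolve_regions(toy_store, ["1"]).tolist() == [0, 1, 2]
        assert resolve_regions(toy_store, ["1:200-"]).tolist() == [1, 2]
        assert resolve_regions(toy_store, ["X"]).tolist() == [3]

    def test_deletion_end_overlap(self, toy_store):
        # record at 300 has REF CTTT -> spans 300..303
        assert resolve_regions(toy_store, ["1:302-310"]).tolist() == [2]
        assert resolve_regions(toy_store, ["1:304-310"]).tolist() == []

    def test_unknown_contig(self, toy_store):
        with pytest.raises(QueryError, match="unknown contig"):
            resolve_regions(toy_store, ["7:1-10"])

    def test_matches_brute_force_scan(self, stats_fixture):
        store = stats_fixture["store"]
        pos = store.arr("variant_position")[:]
        contig = store.arr("variant_contig")[:]
        ends = pos + store.arr("variant_length")[:] - 1
        rng = np.random.default_rng(11)
        cids = store.contig_ids
        for _ in range(200):
            c = int(rng.integers(0, len(cids)))
            s = int(rng.integers(1, int(pos.max()) + 10))
            e = s + int(rng.integers(0, 3000))
            sel = resolve_regions(store, [f"{cids[c]}:{s}-{e}"])
            brute = np.nonzero((contig == c) & (pos <= e) & (ends >= s))[0]
            assert sel.tolist() == brute.tolist()


class TestIncludeExpressions:
    def test_format_conjunction_per_sample(self, toy_store):
        # GQ values: [[12, .], [99, .], [., .], [44, 7]]
        m = evaluate_include_expression("FORMAT/GQ>20", toy_store)
        assert m.tolist() == [False, True, False, True]

    def test_per_sample_conjunct_must_hold_in_one_sample(self, tmp_path):
        """site 1: sample 0 satisfies both comparisons -> passes.
        site 2: DP passes only in sample 0 and GQ only in sample 1, so no
        single sample satisfies the conjunct -> fails (even though both
        marginals pass at the site level)."""
        from vczkit import encode, explode

        text = "\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="D">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Q">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1",
            "1\t100\t.\tA\tT\t9\tPASS\t.\tGT:DP:GQ\t0/1:12:30\t0/0:5:50",
            "1\t200\t.\tC\tG\t9\tPASS\t.\tGT:DP:GQ\t0/1:12:15\t0/0:5:50",
        ]) + "\n"
        p = tmp_path / "conj.vcf"
        p.write_text(text)
        icf = explode([str(p)], tmp_path / "c.icf")
        store = encode(icf, tmp_path / "c.vcz")
        m = evaluate_include_expression("FORMAT/DP>10 & FORMAT/GQ>20", store)
        assert m.tolist() == [True, False]

    def test_matches_vector_oracle_on_fixture(self, stats_fixture):
        store = stats_fixture["store"]
        m = evaluate_include_expression("FORMAT/DP>32 & FORMAT/GQ>50", store)
        dp = store.arr("call_DP")[:]
        gq = store.arr("call_GQ")[:]
        brute = ((dp > 32) & (dp >= 0) & (gq > 50) & (gq >= 0)).any(axis=1)
        assert np.array_equal(m, brute)

    def test_pos_comparison(self, toy_store):
        m = evaluate_include_expression("POS<200", toy_store)
        assert m.tolist() == [True, False, False, True]

    def test_missing_comparisons_are_false(self, toy_store):
        # record 2 has no GQ at all -> always fails
        m = evaluate_include_expression("FORMAT/GQ<1000", toy_store)
        assert m.tolist()[2] == False  # noqa: E712

    def test_parentheses_and_disjunction(self, toy_store):
        m = evaluate_include_expression("(POS<150 | POS>250) & QUAL>=5", toy_store)
        assert m.tolist() == [True, False, True, True]

    def test_info_and_string_equality(self, toy_store):
        m = evaluate_include_expression('INFO/NS==2', toy_store)
        assert m.tolist() == [True, True, False, False]

    def test_unknown_field_rejected(self, toy_store):
        with pytest.raises(QueryError, match="unknown field"):
            evaluate_include_expression("FORMAT/XX>1", toy_store)

    def test_type_mismatch_rejected(self, toy_store):
        with pytest.raises(QueryError, match="type mismatch"):
            evaluate_include_expression('FORMAT/GQ=="x"', toy_store)

    def test_vector_field_rejected(self, toy_store):
        with pytest.raises(QueryError, match="scalar"):
            evaluate_include_expression("FORMAT/AD>1", toy_store)


class TestRenderQuery:
    def test_pos_lines(self, toy_store):
        out = "".join(render_query("%POS\\n", toy_store))
        assert out == "100\n200\n300\n7\n"

    def test_alt_join_and_tabs(self, toy_store):
        out = "".join(render_query("%CHROM\\t%POS\\t%REF\\t%ALT\\n", toy_store))
        lines = out.splitlines()
        assert lines[0] == "1\t100\tA\tT,G"
        assert lines[1] == "1\t200\tC\t."

    def test_info_placeholder(self, toy_store):
        out = "".join(render_query("%INFO/NS\\n", toy_store))
        assert out == "2\n2\n.\n.\n"

    def test_empty_selection(self, toy_store):
        assert "".join(render_query("%POS\\n", toy_store, regions=["1:999-9999"])) == ""

    def test_unknown_placeholder(self, toy_store):
        with pytest.raises(QueryError, match="placeholder"):
            list(render_query("%WAT\\n", toy_store))

    def test_only_named_arrays_read(self, toy_store):
        from vczkit import VczStore

        fresh = VczStore.open(toy_store.root.store.root)
        list(render_query("%POS\\n", fresh))
        assert "variant_position" in fresh.accessed
        for untouched in ("call_genotype", "variant_allele", "call_GQ"):
            assert untouched not in fresh.accessed


class TestRenderVcf:
    def test_full_round_trip(self, toy_vcf, toy_store, tmp_path):
        out = tmp_path / "out.vcf"
        out.write_text("\n".join(render_vcf(toy_store)) + "\n")
        assert compare_vcf_files(toy_vcf, str(out)) == []

    def test_fill_stripping_in_ad(self, toy_store):
        # record 3 is biallelic with AD rows of width 3 -> fill stripped
        lines = [l for l in render_vcf(toy_store, header=False)]
        fields = lines[2].split("\t")
        fmt = fields[8].split(":")
        s1 = dict(zip(fmt, fields[9].split(":")))
        assert s1["AD"] == "0,7"

    def test_haploid_call_restored(self, toy_store):
        lines = [l for l in render_vcf(toy_store, header=False)]
        s1 = lines[1].split("\t")[9]
        assert s1.split(":")[0] == "0"

    def test_sample_subset(self, toy_store, tmp_path):
        import pysam

        lines = list(render_vcf(toy_store, samples=["s2"]))
        out = tmp_path / "sub.vcf"
        out.write_text("\n".join(lines) + "\n")
        with pysam.VariantFile(str(out)) as vf:
            assert list(vf.header.samples) == ["s2"]
            recs = list(vf)
            assert len(recs) == 4
            assert recs[0].samples["s2"].allele_indices == (1, 2)

    def test_unknown_sample_rejected(self, toy_store):
        with pytest.raises(QueryError, match="not in store"):
            list(render_vcf(toy_store, samples=["nope"]))

    def test_region_and_include_combined(self, toy_store):
        lines = list(render_vcf(toy_store, regions=["1"], include="QUAL>=10",
                                header=False))
        assert [l.split("\t")[1] for l in lines] == ["100", "300"]

    def test_no_header_flag(self, toy_store):
        lines = list(render_vcf(toy_store, header=False))
        assert not lines[0].startswith("#")
        assert len(lines) == 4

    def test_site_mask(self, toy_store):
        mask = np.array([True, False, False, True])
        lines = list(render_vcf(toy_store, mask=mask, header=False))
        assert [l.split("\t")[1] for l in lines] == ["100", "7"]
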