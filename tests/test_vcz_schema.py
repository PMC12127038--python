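"""Schema/data-model tests: field mapping, widths, sentinels, genotype dims."""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vczkit import (
    FieldDefinition,
    FieldSummary,
    generate_schema,
    genotype_dimension_size,
    map_field_to_array_specs,
    merge_field_summaries,
    select_integer_width,
    sentinel_values,
)
from vczkit.vcz_schema import (
    FLOAT32_FILL,
    FLOAT32_MISSING,
    SchemaError,
    VczSchema,
)


def _n_unordered_genotypes(n_alleles, ploidy):
    """Brute-force oracle: enumerate unordered allele multisets."""
    return sum(1 for _ in itertools.combinations_with_replacement(range(n_alleles), ploidy))


class TestGenotypeDimensionSize:
    @pytest.mark.parametrize(
        "n_alleles,ploidy,expected",
        [(2, 2, 3), (4, 2, 10), (3, 2, 6), (1, 1, 1), (95, 2, 4560)],
    )
    def test_examples(self, n_alleles, ploidy, expected):
        assert genotype_dimension_size(n_alleles, ploidy) == expected

    def test_agrees_with_enumeration(self):
        for n in range(1, 9):
            for p in range(1, 5):
                assert genotype_dimension_size(n, p) == _n_unordered_genotypes(n, p)

    def test_diploid_closed_form(self):
        for n in range(1, 20):
            assert genotype_dimension_size(n, 2) == n * (n + 1) // 2

    def test_invalid(self):
        with pytest.raises(SchemaError):
            genotype_dimension_size(0, 2)


class TestSelectIntegerWidth:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0, 120, "int8"),
            (0, 200, "int16"),
            (0, 3_000_000_000, "int64"),
            (0, 3000, "int16"),
            (-100, 100, "int8"),
            (0, 2**31 - 1, "int32"),
        ],
    )
    def test_examples(self, lo, hi, expected):
        assert select_integer_width(lo, hi) == expected

    @pytest.mark.parametrize("bad", [-1, -2])
    def test_sentinel_collision(self, bad):
        with pytest.raises(SchemaError, match="sentinel"):
            select_integer_width(bad, 50)
        with pytest.raises(SchemaError, match="sentinel"):
            select_integer_width(-10, bad)

    @settings(max_examples=200, derandomize=True)
    @given(
        lo=st.integers(min_value=-(2**40), max_value=2**40),
        hi=st.integers(min_value=-(2**40), max_value=2**40),
        grow=st.integers(min_value=0, max_value=2**20),
    )
    def test_monotone(self, lo, hi, grow):
        """Enlarging the range never yields a narrower width."""
        if lo > hi or lo in (-1, -2) or hi in (-1, -2):
            return
        lo2, hi2 = lo - grow, hi + grow
        if lo2 in (-1, -2) or hi2 in (-1, -2):
            return
        order = ["int8", "int16", "int32", "int64"]
        assert order.index(select_integer_width(lo2, hi2)) >= order.index(
            select_integer_width(lo, hi)
        )


class TestSentinels:
    def test_integer_pair(self):
        pair = sentinel_values("int16")
        assert (pair.missing, pair.fill) == (-1, -2)

    def test_string_pair(self):
        pair = sentinel_values("string")
        assert (pair.missing, pair.fill) == (".", "")

    def test_float_pair_distinct_bitwise(self):
        pair = sentinel_values("float32")
        assert np.isnan(pair.missing) and np.isnan(pair.fill)
        assert np.float32(pair.missing).view(np.uint32) != np.float32(pair.fill).view(np.uint32)
        assert np.float32(pair.missing).view(np.uint32) == 0x7FC00001
        assert np.float32(pair.fill).view(np.uint32) == 0x7FC00002

    def test_bool_has_none(self):
        with pytest.raises(SchemaError):
            sentinel_values("bool")

    def test_float_sentinels_survive_array_assignment(self):
        a = np.empty(2, dtype="f4")
        a[0], a[1] = FLOAT32_MISSING, FLOAT32_FILL
        assert a.view(np.uint32).tolist() == [0x7FC00001, 0x7FC00002]


class TestFieldMapping:
    def test_ad_number_a(self):
        """Number=A integer FORMAT field with 3 alleles and values in
        [0, 120] maps to an int8 (variants, samples, alt_alleles=2) array."""
        fd = FieldDefinition("FORMAT", "AD", "A", "Integer")
        s = FieldSummary(max_number=2, min_value=0, max_value=120,
                         n_records=5, n_present=5, max_alleles=3, max_ploidy=2)
        (spec,) = map_field_to_array_specs(fd, s, n_variants=5, n_samples=3)
        assert spec.name == "call_AD"
        assert spec.dims == ("variants", "samples", "alt_alleles")
        assert spec.shape == (5, 3, 2)
        assert spec.dtype == "int8"

    def test_gt_three_arrays(self):
        fd = FieldDefinition("FORMAT", "GT", "1", "String")
        s = FieldSummary(max_number=2, min_value=0, max_value=2,
                         n_records=5, n_present=5, max_alleles=3, max_ploidy=2)
        specs = map_field_to_array_specs(fd, s, n_variants=5, n_samples=3)
        by_name = {x.name: x for x in specs}
        assert set(by_name) == {"call_genotype", "call_genotype_phased", "call_genotype_mask"}
        assert by_name["call_genotype"].dims == ("variants", "samples", "ploidy")
        assert by_name["call_genotype_phased"].dims == ("variants", "samples")
        assert by_name["call_genotype_mask"].dims == ("variants", "samples", "ploidy")

    def test_info_flag(self):
        fd = FieldDefinition("INFO", "DB", "0", "Flag")
        s = FieldSummary(n_records=5, n_present=2)
        (spec,) = map_field_to_array_specs(fd, s, n_variants=5, n_samples=3)
        assert spec.name == "variant_DB"
        assert spec.dims == ("variants",)
        assert spec.dtype == "bool"

    def test_info_ns_int16(self):
        """Values up to 3000 exceed int8 but fit int16."""
        fd = FieldDefinition("INFO", "NS", "1", "Integer")
        s = FieldSummary(max_number=1, min_value=0, max_value=3000,
                         n_records=5, n_present=5)
        (spec,) = map_field_to_array_specs(fd, s, n_variants=5, n_samples=3)
        assert spec.name == "variant_NS"
        assert spec.dims == ("variants",)
        assert spec.dtype == "int16"

    def test_number_g_requires_genotypes(self):
        fd = FieldDefinition("FORMAT", "PL", "G", "Integer")
        s = FieldSummary(max_number=3, min_value=0, max_value=99,
                         n_records=5, n_present=5, max_alleles=0, max_ploidy=0)
        with pytest.raises(SchemaError, match="no genotypes"):
            map_field_to_array_specs(fd, s, n_variants=5, n_samples=3)

    def test_flag_outside_info_rejected(self):
        with pytest.raises(SchemaError, match="Flag"):
            FieldDefinition("FORMAT", "X", "0", "Flag")


class TestMergeSummaries:
    def test_example(self):
        a = FieldSummary(max_number=1, max_value=5, min_value=0, n_records=10, n_present=10)
        b = FieldSummary(max_number=1, max_value=9, min_value=2, n_records=3, n_present=3)
        m = merge_field_summaries(a, b)
        assert (m.max_value, m.min_value, m.n_records, m.n_present) == (9, 0, 13, 13)

    def test_identity_and_commutativity(self):
        x = FieldSummary(max_number=4, max_value=7.5, min_value=-3.0, n_records=9, n_present=4)
        empty = FieldSummary()
        assert merge_field_summaries(x, empty) == x
        assert merge_field_summaries(empty, x) == x
        y = FieldSummary(max_number=1, max_value=11.0, min_value=0.0, n_records=2, n_present=2)
        assert merge_field_summaries(x, y) == merge_field_summaries(y, x)


class TestGenerateSchema:
    def test_fixed_arrays_and_defaults(self, toy_icf):
        schema = generate_schema(toy_icf)
        names = {a.name for a in schema.arrays}
        for required in (
            "variant_position", "variant_contig", "variant_allele", "variant_id",
            "variant_id_mask", "variant_quality", "variant_filter",
            "sample_id", "contig_id", "contig_length", "filter_id",
            "call_genotype", "call_genotype_phased", "call_genotype_mask",
        ):
            assert required in names
        gt = schema.array("call_genotype")
        assert gt.codecs[0]["shuffle"] == "bitshuffle"
        assert schema.array("call_GQ").codecs[0] == {
            "id": "blosc", "cname": "zstd", "clevel": 7, "shuffle": "noshuffle"
        }
        # dimensions are global and fixed: the toy file's max is 3 alleles
        assert schema.array("variant_allele").shape == (4, 3)
        assert schema.array("call_AD").shape == (4, 2, 3)
        assert schema.array("call_PL").shape == (4, 2, genotype_dimension_size(3, 2))

    def test_local_alleles_replaces_r_and_g(self, toy_icf):
        schema = generate_schema(toy_icf, local_alleles=True)
        names = {a.name for a in schema.arrays}
        assert {"call_LA", "call_LAD", "call_LPL"} <= names
        assert "call_AD" not in names and "call_PL" not in names
        assert schema.array("call_LA").dims == ("variants", "samples", "local_alleles")
        assert schema.array("call_LAD").shape[-1] == 2  # ploidy
        assert schema.array("call_LPL").shape[-1] == 3  # ploidy(ploidy+1)/2

    def test_json_round_trip(self, toy_icf):
        schema = generate_schema(toy_icf, variant_chunk=7, sample_chunk=2)
        text = schema.to_json()
        again = VczSchema.from_json(text)
        assert again == schema
        json.loads(text)  # valid JSON document

    def test_override_unknown_array_rejected(self, toy_icf):
        with pytest.raises(SchemaError, match="no array"):
            generate_schema(toy_icf, overrides={"call_nope": {"dtype": "int8"}})

    def test_chunk_defaults(self, toy_icf):
        schema = generate_schema(toy_icf)
        gt = schema.array("call_genotype")
        # defaults cap at the data extent for this small input
        assert gt.chunks[0] <= 10_000 and gt.chunks[1] <= 1_000
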