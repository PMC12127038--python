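"""Encoder tests: padding, array contents, region index, lossy filters."""

import math
import os

import numcodecs
import numpy as np
import pytest

from vczkit import (
    bitround_values,
    build_region_index,
    encode,
    explode,
    generate_schema,
    mean_absolute_error,
    pad_field_chunk,
    quantize_values,
    sentinel_values,
    to_zip,
    VczStore,
)
from vczkit.encoder import EncodeError
from vczkit.fixtures import FixtureConfig, write_vcf
from vczkit.icf import ABSENT


def _store_bytes(path):
    out = {}
    for root, _, files in os.walk(path):
        for f in files:
            fp = os.path.join(root, f)
            out[os.path.relpath(fp, path)] = open(fp, "rb").read()
    return out


class TestPadFieldChunk:
    def test_int_padding(self):
        block = pad_field_chunk([[10, 5]], 3, sentinel_values("int16"), "int16")
        assert block.tolist() == [[10, 5, -2]]

    def test_absent_row_collapses_to_missing(self):
        block = pad_field_chunk([ABSENT], 2, sentinel_values("int16"), "int16")
        assert block.tolist() == [[-1, -2]]

    def test_float_fill_distinguishable_bitwise(self):
        pair = sentinel_values("float32")
        block = pad_field_chunk([[0.5]], 2, pair, "float32")
        assert block[0, 0] == np.float32(0.5)
        bits = block.view(np.uint32)
        assert bits[0, 1] == 0x7FC00002  # fill
        missing = pad_field_chunk([[None]], 2, pair, "float32").view(np.uint32)
        assert missing[0, 0] == 0x7FC00001
        assert missing[0, 0] != bits[0, 1]

    def test_inner_missing_values(self):
        block = pad_field_chunk([(10, None, 5)], 4, sentinel_values("int32"), "int32")
        assert block.tolist() == [[10, -1, 5, -2]]

    def test_too_wide_row_rejected(self):
        with pytest.raises(EncodeError, match="exceeds"):
            pad_field_chunk([[1, 2, 3]], 2, sentinel_values("int16"), "int16")


class TestEncodeToy:
    def test_chunk_grid(self, toy_store):
        # 4 variants with variant_chunk=2 -> 2 chunks
        pos = toy_store.arr("variant_position")
        assert pos.shape == (4,)
        assert pos.chunks == (2,)
        assert pos[:].tolist() == [100, 200, 300, 7]

    def test_variant_contig_indexes_contig_id(self, toy_store):
        assert toy_store.contig_ids == ["1", "X"]
        assert toy_store.arr("variant_contig")[:].tolist() == [0, 0, 0, 1]

    def test_allele_matrix_padding(self, toy_store):
        alleles = toy_store.arr("variant_allele")[:]
        assert alleles[0].tolist() == ["A", "T", "G"]
        assert alleles[1].tolist() == ["C", "", ""]  # ALT "." -> fill only

    def test_id_and_mask(self, toy_store):
        assert toy_store.arr("variant_id")[:].tolist() == ["rs1", ".", ".", "."]
        assert toy_store.arr("variant_id_mask")[:].tolist() == [False, True, True, True]

    def test_qual_missing_nan(self, toy_store):
        q = toy_store.arr("variant_quality")[:]
        assert q[0] == np.float32(30.5)
        assert np.isnan(q[1])

    def test_filter_matrix(self, toy_store):
        filt = toy_store.arr("variant_filter")[:]
        ids = toy_store.filter_ids
        assert set(ids) >= {"PASS", "q10"}
        p, q10 = ids.index("PASS"), ids.index("q10")
        assert filt[0, p] and not filt[0, q10]
        assert not filt[1].any()  # FILTER "."
        assert filt[2, q10]

    def test_genotype_triple(self, toy_store):
        gt = toy_store.arr("call_genotype")[:]
        phased = toy_store.arr("call_genotype_phased")[:]
        mask = toy_store.arr("call_genotype_mask")[:]
        assert gt[0].tolist() == [[0, 1], [1, 2]]
        assert phased[0].tolist() == [True, False]
        assert gt[1].tolist() == [[0, -2], [-1, -1]]  # haploid fill, missing
        assert mask[1].tolist() == [[False, False], [True, True]]

    def test_absent_format_field_is_missing(self, toy_store):
        gq = toy_store.arr("call_GQ")[:]
        assert gq[2].tolist() == [-1, -1]  # record without GQ

    def test_vcf_header_attr(self, toy_store):
        assert "##fileformat" in toy_store.attrs["vcf_header"]


class TestDeterminism:
    def test_chunk_count_arithmetic(self, tmp_path):
        cfg = FixtureConfig(n_variants=25, n_samples=2, seed=9)
        p = write_vcf(cfg, tmp_path / "f.vcf")
        icf = explode([p], tmp_path / "f.icf")
        schema = generate_schema(icf, variant_chunk=10)
        store = encode(icf, tmp_path / "f.vcz", schema=schema)
        pos = store.arr("variant_position")
        assert math.ceil(25 / 10) == 3
        assert pos.nchunks == 3

    def test_partitioned_encode_identical(self, small_fixture, tmp_path):
        from vczkit import dencode_finalise, dencode_init, dencode_partition

        icf = small_fixture["icf"]
        schema = generate_schema(icf, variant_chunk=16, sample_chunk=3)
        out = tmp_path / "par.vcz"
        n = dencode_init(icf, schema, out)
        for i in reversed(range(n)):  # order must not matter
            dencode_partition(out, i)
        dencode_finalise(out)
        single = _store_bytes(small_fixture["store"].root.store_path.path
                              if hasattr(small_fixture["store"].root, "store_path")
                              else str(small_fixture["dir"] / "f.vcz"))
        single = _store_bytes(str(small_fixture["dir"] / "f.vcz"))
        partitioned = _store_bytes(str(out))
        assert single.keys() == partitioned.keys()
        assert all(single[k] == partitioned[k] for k in single)

    def test_zip_store_equivalent(self, small_fixture, tmp_path):
        src = str(small_fixture["dir"] / "f.vcz")
        zip_path = tmp_path / "store.vcz.zip"
        to_zip(src, zip_path)
        zstore = VczStore.open(zip_path)
        plain = small_fixture["store"]
        for name in ("variant_position", "call_genotype", "variant_allele"):
            a, b = plain.arr(name)[:], zstore.arr(name)[:]
            assert (np.asarray(a, dtype=object) == np.asarray(b, dtype=object)).all()


class TestRegionIndex:
    def test_hand_enumeration(self, tmp_path):
        text = "\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0",
            "1\t100\t.\tA\tT\t1\tPASS\t.\tGT\t0/1",
            "1\t200\t.\tC\tG\t1\tPASS\t.\tGT\t0/1",
            "1\t300\t.\tG\tA\t1\tPASS\t.\tGT\t0/1",
        ]) + "\n"
        p = tmp_path / "ri.vcf"
        p.write_text(text)
        icf = explode([str(p)], tmp_path / "ri.icf")
        store = encode(icf, tmp_path / "ri.vcz",
                       schema=generate_schema(icf, variant_chunk=2))
        index = store.region_index()
        assert index.tolist() == [[0, 0, 100, 200, 200, 2], [1, 0, 300, 300, 300, 1]]

    def test_contig_boundary_gives_two_rows(self, tmp_path):
        cfg = FixtureConfig(n_variants=10, n_samples=1, seed=3,
                            contigs=(("1", 10_000), ("2", 10_000)))
        p = write_vcf(cfg, tmp_path / "f.vcf")
        icf = explode([p], tmp_path / "f.icf")
        store = encode(icf, tmp_path / "f.vcz",
                       schema=generate_schema(icf, variant_chunk=10))
        index = store.region_index()
        # one 10-variant chunk spanning two contigs -> two rows
        assert index.shape[0] == 2
        assert index[:, 0].tolist() == [0, 0]
        assert index[:, 1].tolist() == [0, 1]
        assert index[:, 5].sum() == 10

    def test_unsorted_positions_rejected(self, tmp_path):
        text = "\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0",
            "1\t300\t.\tA\tT\t1\tPASS\t.\tGT\t0/1",
            "1\t100\t.\tC\tG\t1\tPASS\t.\tGT\t0/1",
        ]) + "\n"
        p = tmp_path / "bad.vcf"
        p.write_text(text)
        icf = explode([str(p)], tmp_path / "bad.icf")
        with pytest.raises(EncodeError, match="not sorted"):
            encode(icf, tmp_path / "bad.vcz")

    def test_completeness_bracketing(self, stats_fixture):
        """Chunks selected via the index contain every overlapping record
        and only chunks whose range intersects the query."""
        from vczkit.query_view import Region, candidate_chunks

        store = stats_fixture["store"]
        pos = store.arr("variant_position")[:]
        contig = store.arr("variant_contig")[:]
        length = store.arr("variant_length")[:]
        ends = pos + length - 1
        vc = store.variant_chunk_size
        rng = np.random.default_rng(7)
        for _ in range(100):
            c = int(rng.integers(0, len(store.contig_ids)))
            s = int(rng.integers(1, int(pos.max())))
            e = s + int(rng.integers(0, 5000))
            got = set(candidate_chunks(store, Region(store.contig_ids[c], s, e), c))
            overlapping = {
                int(i) // vc
                for i in np.nonzero((contig == c) & (pos <= e) & (ends >= s))[0]
            }
            assert overlapping <= got
            for ch in got:
                sl = slice(ch * vc, min((ch + 1) * vc, len(pos)))
                in_chunk = contig[sl] == c
                assert in_chunk.any()
                assert pos[sl][in_chunk].min() <= e and ends[sl][in_chunk].max() >= s


class TestQuantize:
    def test_examples(self):
        assert quantize_values(np.array([0.26]), 1)[0] == 0.25
        assert quantize_values(np.array([0.5]), 3)[0] == 0.5
        # 0.1234567 * 131072 = 16181.7168 -> rounds to 16182
        assert quantize_values(np.array([0.1234567]), 5)[0] == 16182 / 131072

    def test_matches_numcodecs_filter(self):
        x = np.random.default_rng(3).random(10_000, dtype="f4")
        for d in (1, 3, 5):
            ours = quantize_values(x, d)
            ref = numcodecs.Quantize(digits=d, dtype="f4").encode(x.copy())
            assert np.array_equal(ours, ref)

    def test_error_bound(self):
        x = np.random.default_rng(4).random(100_000)
        for d in range(1, 8):
            q = quantize_values(x, d)
            bound = 0.5 * 2.0 ** -math.ceil(d * math.log2(10))
            assert np.abs(q - x).max() <= bound

    def test_nan_payloads_preserved(self):
        pair = sentinel_values("float32")
        x = np.array([pair.missing, pair.fill, 0.25], dtype="f4")
        q = quantize_values(x, 2)
        assert q.view(np.uint32)[:2].tolist() == [0x7FC00001, 0x7FC00002]
        assert q[2] == 0.25


class TestBitRound:
    def test_examples(self):
        assert bitround_values(np.array([1.0], dtype="f4"), 5)[0] == 1.0
        assert bitround_values(np.array([0.123456], dtype="f4"), 5)[0] == np.float32(0.123046875)

    def test_identity_at_full_mantissa(self):
        x = np.random.default_rng(5).random(10_000, dtype="f4") * 100 - 50
        assert np.array_equal(bitround_values(x, 23), x)

    def test_matches_numcodecs_filter(self):
        x = np.random.default_rng(6).random(10_000, dtype="f4")
        for k in (3, 5, 10):
            codec = numcodecs.BitRound(keepbits=k)
            ref = codec.decode(codec.encode(x.copy()))
            assert np.array_equal(bitround_values(x, k), np.asarray(ref))

    def test_nan_payloads_preserved(self):
        pair = sentinel_values("float32")
        x = np.array([pair.missing, pair.fill], dtype="f4")
        out = bitround_values(x, 5)
        assert out.view(np.uint32).tolist() == [0x7FC00001, 0x7FC00002]


class TestMeanAbsoluteError:
    def test_examples(self):
        assert mean_absolute_error([1, 2], [1, 2]) == 0
        assert mean_absolute_error([0, 1], [0.5, 0.5]) == 0.5

    def test_excludes_nan_pairwise(self):
        a = np.array([1.0, np.nan, 3.0])
        b = np.array([2.0, 2.0, np.nan])
        assert mean_absolute_error(a, b) == 1.0

    def test_all_excluded_rejected(self):
        with pytest.raises(EncodeError, match="no finite"):
            mean_absolute_error([np.nan], [1.0])

    def test_quantize_bound_property(self):
        x = np.random.default_rng(8).random(50_000)
        for d in (1, 4, 7):
            bound = 0.5 * 2.0 ** -math.ceil(d * math.log2(10))
            assert mean_absolute_error(x, quantize_values(x, d)) <= bound


class TestLossyCodecChain:
    def test_quantize_filter_in_schema_override(self, tmp_path):
        cfg = FixtureConfig(n_variants=40, n_samples=3, seed=12)
        p = write_vcf(cfg, tmp_path / "f.vcf")
        icf = explode([p], tmp_path / "f.icf")
        schema = generate_schema(icf, overrides={
            "variant_AF": {"codecs": [
                {"id": "quantize", "digits": 3},
                {"id": "blosc", "cname": "zstd", "clevel": 7, "shuffle": "noshuffle"},
            ]},
        })
        store = encode(icf, tmp_path / "f.vcz", schema=schema)
        af = store.arr("variant_AF")[:]
        finite = af[np.isfinite(af)]
        # stored values are exactly their own quantization
        assert np.array_equal(finite, quantize_values(finite, 3))
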