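"""Stage 2 of conversion: materialize a chunked array store from ICF.

``encode`` walks the storage schema and fills each array one variant-chunk
at a time (memory is bounded by one chunk per field), padding ragged VCF
values into fixed shapes with missing/fill sentinels, applying the
configured codec chain, and deriving the structural arrays (contig indexes,
allele matrix, filter membership, genotype triple, local-allele fields) and
the per-chunk genomic region index.

The output is a Zarr v2 hierarchy (``.zarray``/``.zattrs`` JSON metadata,
chunk files keyed by grid coordinates) written either as a directory tree
or as an uncompressed-entry Zip archive of the identical layout. Encoding
is deterministic: the same ICF and schema produce byte-identical stores,
whether encoded in one process or partition by partition
(``dencode_init`` / ``dencode_partition`` / ``dencode_finalise``).
"""

from __future__ import annotations

import json
import math
import os
import shutil
import zipfile
from pathlib import Path

import numcodecs
import numpy as np
import zarr

from .icf import ABSENT, IcfStore
from .local_alleles import (
    compute_la_block,
    localize_g_field,
    localize_r_field,
)
from .vcz_schema import (
    FLOAT32_FILL,
    FLOAT32_MISSING,
    INT_FILL,
    INT_MISSING,
    STR_FILL,
    STR_MISSING,
    SentinelPair,
    VczSchema,
    sentinel_values,
)

VCZ_FORMAT_VERSION = "vczkit-vcz-0.1"


class EncodeError(ValueError):
    pass


class _FillMark:
    """Internal marker distinguishing fill from missing while rows are
    still Python objects (missing is represented by None at that stage)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance


FILL = _FillMark()


# ----------------------------------------------------------------------
# Lossy float filters and their error metric
# ----------------------------------------------------------------------

def quantize_values(x, digits: int):
    """Quantize floats to ~``digits`` decimal digits via power-of-two scaling.

    keep = ceil(log2(10^digits)), scale = 2^keep, result = round(x*scale)/scale
    with ties to even, so |result - x| <= 0.5/scale. Non-finite values
    (including the NaN sentinels) pass through with their bit patterns
    intact.
    """
    if digits < 1:
        raise EncodeError("digits must be >= 1")
    arr = np.array(x, copy=True)
    scale = 2.0 ** math.ceil(math.log2(10.0**digits))
    finite = np.isfinite(arr)
    out = np.around(arr * arr.dtype.type(scale)) / arr.dtype.type(scale)
    out = out.astype(arr.dtype)
    arr[finite] = out[finite]
    return arr


def bitround_values(x, keep_bits: int):
    """Round float32 mantissas to ``keep_bits`` fractional bits, ties to even.

    keep_bits = 23 (the full single-precision mantissa) is the identity on
    finite values; NaN payloads are preserved.
    """
    arr = np.array(x, dtype=np.float32, copy=True)
    if not 0 <= keep_bits <= 23:
        raise EncodeError("keep_bits must be in [0, 23] for float32")
    if keep_bits == 23:
        return arr
    drop = 23 - keep_bits
    u = arr.view(np.uint32)
    orig = u.copy()
    # Round-to-nearest-even on the integer representation: add the kept
    # LSB plus (half-ulp - 1), then truncate the dropped bits.
    u += ((u >> np.uint32(drop)) & np.uint32(1)) + np.uint32((1 << (drop - 1)) - 1)
    u &= np.uint32((0xFFFFFFFF << drop) & 0xFFFFFFFF)
    nonfinite = ~np.isfinite(orig.view(np.float32))
    u[nonfinite] = orig[nonfinite]
    return arr


def mean_absolute_error(a, b) -> float:
    """Mean |a - b| over positions where both values are finite.

    Missing/fill NaN sentinels are thereby excluded pairwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise EncodeError("inputs must have equal lengths")
    keep = np.isfinite(a) & np.isfinite(b)
    if not keep.any():
        raise EncodeError("no finite value pairs to compare")
    return float(np.mean(np.abs(a[keep] - b[keep])))


# ----------------------------------------------------------------------
# Padding
# ----------------------------------------------------------------------

def _np_dtype(dtype: str):
    return np.dtype(object) if dtype == "string" else np.dtype(dtype)


def pad_field_chunk(rows, width: int, sentinels: SentinelPair, dtype: str) -> np.ndarray:
    """Pad ragged per-record (or per-call) values into a fixed-width block.

    Rules: a ``.`` value (None) becomes the missing sentinel; slots beyond
    a row's length become the fill sentinel; a row that is absent entirely
    collapses to missing-then-fill (the documented corner case: the array
    form does not distinguish absent from missing).
    """
    out = np.empty((len(rows), width), dtype=_np_dtype(dtype))
    out[...] = sentinels.fill
    for i, row in enumerate(rows):
        if row is ABSENT or row is None:
            out[i, 0] = sentinels.missing
            continue
        if not isinstance(row, (tuple, list)):
            row = (row,)
        if len(row) > width:
            raise EncodeError(f"row of length {len(row)} exceeds target width {width}")
        for j, v in enumerate(row):
            if v is None:
                out[i, j] = sentinels.missing
            elif v is FILL:
                out[i, j] = sentinels.fill
            else:
                out[i, j] = v
    return out


def _scalar_block(values, sentinels: SentinelPair, dtype: str) -> np.ndarray:
    out = np.empty(len(values), dtype=_np_dtype(dtype))
    for i, v in enumerate(values):
        if v is ABSENT or v is None:
            out[i] = sentinels.missing
        elif isinstance(v, tuple):
            out[i] = sentinels.missing if v[0] is None else v[0]
        else:
            out[i] = v
    return out


# ----------------------------------------------------------------------
# Codec construction
# ----------------------------------------------------------------------

_SHUFFLE = {
    "noshuffle": numcodecs.Blosc.NOSHUFFLE,
    "shuffle": numcodecs.Blosc.SHUFFLE,
    "bitshuffle": numcodecs.Blosc.BITSHUFFLE,
}


def _build_codecs(codec_dicts, dtype: str):
    filters = []
    compressor = None
    for d in codec_dicts:
        cid = d.get("id")
        if cid == "blosc":
            compressor = numcodecs.Blosc(
                cname=d.get("cname", "zstd"),
                clevel=int(d.get("clevel", 7)),
                shuffle=_SHUFFLE[d.get("shuffle", "noshuffle")],
            )
        elif cid == "quantize":
            filters.append(numcodecs.Quantize(digits=int(d["digits"]), dtype="f4"))
        elif cid == "bitround":
            filters.append(numcodecs.BitRound(keepbits=int(d["keepbits"])))
        else:
            raise EncodeError(f"unknown codec id {cid!r}")
    return filters, compressor


# ----------------------------------------------------------------------
# Block builders (one schema variant-chunk at a time)
# ----------------------------------------------------------------------

class _EncodeContext:
    def __init__(self, icf: IcfStore, schema: VczSchema):
        self.icf = icf
        self.schema = schema
        self.contig_map = {c: i for i, (c, _) in enumerate(schema.contigs)}
        self.filter_map = {f: i for i, f in enumerate(schema.filters)}
        self._gt_cache: tuple[int, int, dict] | None = None

    def gt_blocks(self, lo, hi):
        if self._gt_cache is not None and self._gt_cache[:2] == (lo, hi):
            return self._gt_cache[2]
        spec = self.schema.array("call_genotype")
        n, s, p = hi - lo, spec.shape[1], spec.shape[2]
        gt = np.full((n, s, p), INT_FILL, dtype=_np_dtype(spec.dtype))
        gt[..., 0] = INT_MISSING
        phased = np.zeros((n, s), dtype=bool)
        values = self.icf.fetch_field_slice("FORMAT/GT", lo, hi)
        for i, v in enumerate(values):
            if v is ABSENT:
                continue
            for j, (alleles, ph) in enumerate(v):
                if len(alleles) > p:
                    raise EncodeError("call ploidy exceeds schema ploidy")
                row = [INT_MISSING if a is None else a for a in alleles]
                row += [INT_FILL] * (p - len(row))
                gt[i, j] = row
                phased[i, j] = ph
        blocks = {"genotype": gt, "phased": phased, "mask": gt == INT_MISSING}
        self._gt_cache = (lo, hi, blocks)
        return blocks


def _format_rows(values, n_samples, width):
    """Flatten per-record lists of per-sample values to per-call rows."""
    rows = []
    for v in values:
        if v is ABSENT:
            rows.extend([ABSENT] * n_samples)
        else:
            rows.extend(v)
    return rows


def _build_block(spec, ctx: _EncodeContext, lo: int, hi: int) -> np.ndarray:
    icf = ctx.icf
    kind = spec.source.get("kind")
    n = hi - lo

    if kind == "fixed:position":
        return _scalar_block(icf.fetch_field_slice("POS", lo, hi),
                             sentinel_values(spec.dtype), spec.dtype)
    if kind == "fixed:contig":
        chroms = icf.fetch_field_slice("CHROM", lo, hi)
        return np.array([ctx.contig_map[c] for c in chroms], dtype=_np_dtype(spec.dtype))
    if kind == "fixed:allele":
        refs = icf.fetch_field_slice("REF", lo, hi)
        alts = icf.fetch_field_slice("ALT", lo, hi)
        rows = [(r,) + a for r, a in zip(refs, alts)]
        return pad_field_chunk(rows, spec.shape[1], SentinelPair(STR_MISSING, STR_FILL), "string")
    if kind == "fixed:id":
        return _scalar_block(icf.fetch_field_slice("ID", lo, hi),
                             SentinelPair(STR_MISSING, STR_FILL), "string")
    if kind == "fixed:id_mask":
        ids = icf.fetch_field_slice("ID", lo, hi)
        return np.array([i is None for i in ids], dtype=bool)
    if kind == "fixed:quality":
        return _scalar_block(icf.fetch_field_slice("QUAL", lo, hi),
                             sentinel_values("float32"), "float32")
    if kind == "fixed:filter":
        filt = icf.fetch_field_slice("FILTER", lo, hi)
        out = np.zeros((n, spec.shape[1]), dtype=bool)
        for i, fs in enumerate(filt):
            for f in fs:
                if f not in ctx.filter_map:
                    raise EncodeError(f"FILTER {f!r} not declared in header")
                out[i, ctx.filter_map[f]] = True
        return out
    if kind == "fixed:length":
        pos = np.array(icf.fetch_field_slice("POS", lo, hi), dtype="int64")
        stop = np.array(icf.fetch_field_slice("STOP", lo, hi), dtype="int64")
        return (stop - pos + 1).astype(_np_dtype(spec.dtype))

    if kind == "genotype":
        return ctx.gt_blocks(lo, hi)["genotype"]
    if kind == "genotype_phased":
        return ctx.gt_blocks(lo, hi)["phased"]
    if kind == "genotype_mask":
        return ctx.gt_blocks(lo, hi)["mask"]
    if kind == "la":
        return compute_la_block(ctx.gt_blocks(lo, hi)["genotype"])

    if kind in ("lad", "lpl"):
        field = spec.source["field"]
        values = icf.fetch_field_slice(field, lo, hi)
        la = compute_la_block(ctx.gt_blocks(lo, hi)["genotype"])
        n_samples, width = spec.shape[1], spec.shape[2]
        localize = localize_r_field if kind == "lad" else localize_g_field
        rows = []
        for i, v in enumerate(values):
            for j in range(n_samples):
                sval = None if v is ABSENT else v[j]
                la_row = la[i, j]
                if sval is None:
                    row = [None if a >= 0 else FILL for a in la_row]
                    if kind == "lpl":
                        k = sum(1 for a in la_row if a >= 0)
                        m = k * (k + 1) // 2
                        row = [None] * m + [FILL] * (width - m)
                else:
                    row = localize(list(sval), list(la_row), missing=None, fill=FILL)
                rows.append(row)
        block = pad_field_chunk(rows, width, sentinel_values(spec.dtype), spec.dtype)
        return block.reshape(n, n_samples, width)

    if kind == "info":
        field = spec.source.get("field", "")
        values = icf.fetch_field_slice(field, lo, hi)
        if spec.dtype == "bool":  # Flag
            return np.array([v is True for v in values], dtype=bool)
        if len(spec.shape) == 1:
            return _scalar_block(values, sentinel_values(spec.dtype), spec.dtype)
        return pad_field_chunk(values, spec.shape[1], sentinel_values(spec.dtype), spec.dtype)

    if kind == "format":
        field = spec.source["field"]
        values = icf.fetch_field_slice(field, lo, hi)
        n_samples = spec.shape[1]
        rows = _format_rows(values, n_samples, None)
        if len(spec.shape) == 2:
            block = _scalar_block(rows, sentinel_values(spec.dtype), spec.dtype)
            return block.reshape(n, n_samples)
        block = pad_field_chunk(rows, spec.shape[2], sentinel_values(spec.dtype), spec.dtype)
        return block.reshape(n, n_samples, spec.shape[2])

    raise EncodeError(f"no builder for array source {spec.source!r}")


# ----------------------------------------------------------------------
# Store writing
# ----------------------------------------------------------------------

_STATE_FILE = ".vczkit_encode.json"


def _zarr_dtype(dtype: str):
    return str if dtype == "string" else np.dtype(dtype)


def _fill_value(dtype: str):
    if dtype == "string":
        return ""
    if dtype == "bool":
        return False
    if dtype == "float32":
        return float("nan")
    return INT_FILL


def dencode_init(icf_path, schema: VczSchema | None, out) -> int:
    """Create the store skeleton (metadata + fixed-size arrays); returns the
    number of variant-chunk encode partitions."""
    from .vcz_schema import generate_schema

    icf = icf_path if isinstance(icf_path, IcfStore) else IcfStore(icf_path)
    if schema is None:
        schema = generate_schema(icf)
    out = Path(out)
    if out.exists():
        raise EncodeError(f"output {out} already exists")
    root = zarr.open_group(str(out), mode="w", zarr_format=2)
    root.attrs.update(
        {
            "format_version": VCZ_FORMAT_VERSION,
            "vcf_header": schema.vcf_header,
            "info_order": schema.info_order,
            "format_order": schema.format_order,
        }
    )
    for spec in schema.arrays:
        filters, compressor = _build_codecs(spec.codecs, spec.dtype)
        if spec.dtype == "string":
            filters = [numcodecs.VLenUTF8()] + filters
        arr = root.create_array(
            spec.name,
            shape=spec.shape,
            chunks=spec.chunks,
            dtype=_zarr_dtype(spec.dtype),
            compressors=compressor,
            filters=filters or None,
            fill_value=_fill_value(spec.dtype),
        )
        arr.attrs["_ARRAY_DIMENSIONS"] = list(spec.dims)
        for k in ("field", "vcf_number", "vcf_type"):
            if k in spec.source:
                arr.attrs[k] = spec.source[k]
        if spec.description:
            arr.attrs["description"] = spec.description

    # Header-level arrays are tiny; write them during init.
    root["sample_id"][:] = np.array(schema.samples or [""], dtype=object)
    root["contig_id"][:] = np.array([c for c, _ in schema.contigs] or [""], dtype=object)
    root["contig_length"][:] = np.array(
        [l if l is not None else -1 for _, l in schema.contigs] or [-1], dtype="int64"
    )
    root["filter_id"][:] = np.array(schema.filters or [""], dtype=object)

    vc = schema.array("variant_position").chunks[0]
    n_chunks = max(1, math.ceil(icf.n_records / vc)) if icf.n_records else 0
    state = {
        "icf_path": str(icf.path),
        "schema": schema.to_json(),
        "n_partitions": n_chunks,
        "variant_chunk": vc,
    }
    (out / _STATE_FILE).write_text(json.dumps(state))
    return n_chunks


def _load_state(out):
    state = json.loads((Path(out) / _STATE_FILE).read_text())
    schema = VczSchema.from_json(state["schema"])
    return state, schema


def dencode_partition(out, index: int) -> None:
    """Encode variant-chunk ``index`` for every variant-dimension array."""
    state, schema = _load_state(out)
    if not 0 <= index < state["n_partitions"]:
        raise EncodeError(f"encode partition {index} out of range")
    icf = IcfStore(state["icf_path"])
    vc = state["variant_chunk"]
    lo = index * vc
    hi = min(lo + vc, icf.n_records)
    ctx = _EncodeContext(icf, schema)
    root = zarr.open_group(str(out), mode="r+")
    for spec in schema.arrays:
        if not spec.dims or spec.dims[0] != "variants":
            continue
        block = _build_block(spec, ctx, lo, hi)
        if spec.dtype == "string":
            block = block.astype(object)
        root[spec.name][lo:hi] = block


def dencode_finalise(out) -> "VczStore":
    """Validate ordering, build the region index, drop encode state."""
    state, schema = _load_state(out)
    root = zarr.open_group(str(out), mode="r+")
    _write_region_index(root, schema)
    os.remove(Path(out) / _STATE_FILE)
    return VczStore.open(out)


def encode(icf_path, out, *, schema: VczSchema | None = None) -> "VczStore":
    """Single-process encode: init, every variant chunk, finalise.

    If ``out`` ends with ``.zip`` the directory layout is written to a
    scratch directory and archived into an uncompressed-entry Zip.
    """
    out = str(out)
    if out.endswith(".zip"):
        tmp = out + ".dir"
        store = encode(icf_path, tmp, schema=schema)
        to_zip(tmp, out)
        shutil.rmtree(tmp)
        return VczStore.open(out)
    n = dencode_init(icf_path, schema, out)
    for i in range(n):
        dencode_partition(out, i)
    return dencode_finalise(out)


# ----------------------------------------------------------------------
# Region index
# ----------------------------------------------------------------------

def build_region_index(store: "VczStore") -> np.ndarray:
    """Per (variant-chunk, contig) rows of
    (chunk, contig, pos_min, pos_max, end_max, n_records).

    A record's end is INFO/END when carried, else POS + len(REF) - 1; both
    are folded into variant_length at encode time. Positions must be
    non-decreasing within each contig, otherwise the store cannot support
    region queries and an error is raised.
    """
    pos = store.arr("variant_position")[:]
    contig = store.arr("variant_contig")[:]
    length = store.arr("variant_length")[:]
    end = pos + length - 1
    n = pos.shape[0]
    vc = store.variant_chunk_size
    rows = []
    for i in range(1, n):
        if contig[i] == contig[i - 1] and pos[i] < pos[i - 1]:
            raise EncodeError(
                f"positions not sorted within contig at record {i}; "
                "store is invalid for region queries"
            )
    for chunk_start in range(0, n, vc):
        chunk = chunk_start // vc
        c_sl = slice(chunk_start, min(chunk_start + vc, n))
        c_contig, c_pos, c_end = contig[c_sl], pos[c_sl], end[c_sl]
        run_start = 0
        for i in range(1, len(c_contig) + 1):
            if i == len(c_contig) or c_contig[i] != c_contig[run_start]:
                rows.append(
                    (
                        chunk,
                        int(c_contig[run_start]),
                        int(c_pos[run_start:i].min()),
                        int(c_pos[run_start:i].max()),
                        int(c_end[run_start:i].max()),
                        i - run_start,
                    )
                )
                run_start = i
    if not rows:
        return np.zeros((0, 6), dtype="int32")
    arr = np.array(rows, dtype="int64")
    if arr.max() <= np.iinfo("int32").max:
        arr = arr.astype("int32")
    return arr


def _write_region_index(root, schema) -> None:
    store = VczStore(root)
    index = build_region_index(store)
    arr = root.create_array(
        "region_index",
        shape=index.shape,
        chunks=(max(index.shape[0], 1), 6),
        dtype=index.dtype,
        compressors=numcodecs.Blosc(cname="zstd", clevel=7,
                                    shuffle=numcodecs.Blosc.NOSHUFFLE),
        fill_value=0,
    )
    arr.attrs["_ARRAY_DIMENSIONS"] = ["region_index_rows", "region_index_cols"]
    arr.attrs["columns"] = [
        "chunk", "contig", "pos_min", "pos_max", "end_max", "n_records",
    ]
    if index.size:
        arr[:] = index


# ----------------------------------------------------------------------
# Zip archives
# ----------------------------------------------------------------------

def to_zip(directory, zip_path) -> None:
    """Archive a store directory into a deterministic uncompressed Zip."""
    directory = Path(directory)
    names = sorted(
        p.relative_to(directory).as_posix()
        for p in directory.rglob("*")
        if p.is_file()
    )
    with zipfile.ZipFile(zip_path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name in names:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.external_attr = 0o644 << 16
            zf.writestr(info, (directory / name).read_bytes())


# ----------------------------------------------------------------------
# Reading
# ----------------------------------------------------------------------

class VczStore:
    """Read handle over an encoded store (directory or Zip archive).

    Array reads are funnelled through :meth:`arr` so that callers (and
    tests) can observe which arrays a query actually touched.
    """

    def __init__(self, root: zarr.Group):
        self.root = root
        self.accessed: set[str] = set()

    @classmethod
    def open(cls, path) -> "VczStore":
        path = str(path)
        if os.path.isfile(path):
            store = zarr.storage.ZipStore(path, mode="r")
            return cls(zarr.open_group(store=store, mode="r"))
        return cls(zarr.open_group(path, mode="r"))

    def has(self, name: str) -> bool:
        return name in self.root

    def arr(self, name: str):
        if name not in self.root:
            raise KeyError(f"store has no array {name!r}")
        self.accessed.add(name)
        return self.root[name]

    @property
    def attrs(self):
        return self.root.attrs

    @property
    def n_variants(self) -> int:
        return self.arr("variant_position").shape[0]

    @property
    def n_samples(self) -> int:
        gt = "call_genotype"
        if self.has(gt):
            return self.root[gt].shape[1]
        sid = self.root["sample_id"]
        return sid.shape[0]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.arr("sample_id")[:]]

    @property
    def contig_ids(self) -> list[str]:
        return [str(c) for c in self.arr("contig_id")[:]]

    @property
    def filter_ids(self) -> list[str]:
        return [str(f) for f in self.arr("filter_id")[:]]

    @property
    def variant_chunk_size(self) -> int:
        return self.arr("variant_position").chunks[0]

    def region_index(self) -> np.ndarray | None:
        if not self.has("region_index"):
            return None
        return self.arr("region_index")[:]
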