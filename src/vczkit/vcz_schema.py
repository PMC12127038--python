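"""The VCF-Zarr data model: field-to-array mapping and schema generation.

Every VCF field becomes one named, typed, chunked array. FORMAT fields map
to ``call_<KEY>`` arrays with leading dimensions ``(variants, samples)``;
INFO and fixed fields map to ``variant_<KEY>`` arrays with leading dimension
``(variants,)``. The trailing dimension is determined by the field's VCF
``Number`` declaration and is *global and fixed*: its extent is the
dataset-wide maximum (e.g. the maximum allele count over all sites). Slots
that exist only because of this global padding hold a *fill* sentinel,
distinct from the *missing* sentinel used for values written as ``.`` in the
source VCF.

Sentinels are ``-1`` (missing) / ``-2`` (fill) for integers, ``"."`` / ``""``
for strings, and two distinct quiet-NaN bit patterns for floats
(``0x7FC00001`` missing, ``0x7FC00002`` fill) so that missingness survives a
round trip bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Any

import numpy as np

FORMAT_VERSION = "vczkit-schema-0.1"

#: Integer sentinels.
INT_MISSING = -1
INT_FILL = -2

#: Quiet-NaN float32 sentinels, distinguishable by payload bits.
FLOAT32_MISSING = np.frombuffer(np.uint32(0x7FC00001).tobytes(), dtype="<f4")[0]
FLOAT32_FILL = np.frombuffer(np.uint32(0x7FC00002).tobytes(), dtype="<f4")[0]

STR_MISSING = "."
STR_FILL = ""

_INT_DTYPES = ("int8", "int16", "int32", "int64")
_VALID_DTYPES = _INT_DTYPES + ("bool", "float32", "string")

DEFAULT_VARIANT_CHUNK = 10_000
DEFAULT_SAMPLE_CHUNK = 1_000
DEFAULT_COMPRESSOR = {"id": "blosc", "cname": "zstd", "clevel": 7, "shuffle": "noshuffle"}
BITSHUFFLE_COMPRESSOR = {"id": "blosc", "cname": "zstd", "clevel": 7, "shuffle": "bitshuffle"}


class SchemaError(ValueError):
    """Raised for invalid field definitions or schema inconsistencies."""


@dataclasses.dataclass(frozen=True)
class FieldDefinition:
    """A VCF header declaration for one field."""

    category: str  # "fixed" | "INFO" | "FORMAT"
    key: str
    vcf_number: str  # "0", "1", "A", "R", "G", "." or a fixed integer as text
    vcf_type: str  # Integer | Float | Flag | Character | String
    description: str = ""

    def __post_init__(self) -> None:
        if not self.key:
            raise SchemaError("field key must be non-empty")
        if self.category not in ("fixed", "INFO", "FORMAT"):
            raise SchemaError(f"unknown field category {self.category!r}")
        if self.vcf_type == "Flag" and self.category != "INFO":
            raise SchemaError(f"{self.key}: Flag is only valid for INFO fields")
        if self.vcf_type not in ("Integer", "Float", "Flag", "Character", "String"):
            raise SchemaError(f"{self.key}: unsupported VCF Type {self.vcf_type!r}")

    @property
    def full_name(self) -> str:
        if self.category == "fixed":
            return self.key
        return f"{self.category}/{self.key}"


@dataclasses.dataclass
class FieldSummary:
    """Statistics gathered over the whole dataset during explode.

    ``max_number`` is the maximum per-record value count; extrema are over
    all observed (non-missing) values and are ``None`` when nothing was
    observed. ``max_alleles``/``max_ploidy`` are the dataset-wide structural
    maxima, attached to every summary once partitions are merged.
    """

    max_number: int = 0
    min_value: float | None = None
    max_value: float | None = None
    n_records: int = 0
    n_present: int = 0
    max_alleles: int = 0
    max_ploidy: int = 0

    def update(self, n_values: int, values=()) -> None:
        self.max_number = max(self.max_number, n_values)
        self.n_present += 1
        for v in values:
            if v is None:
                continue
            if self.min_value is None or v < self.min_value:
                self.min_value = v
            if self.max_value is None or v > self.max_value:
                self.max_value = v

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def merge_field_summaries(a: FieldSummary, b: FieldSummary) -> FieldSummary:
    """Combine summaries of the same field from two partitions.

    Associative and commutative, with the empty summary as identity.
    """

    def _min(x, y):
        if x is None:
            return y
        if y is None:
            return x
        return min(x, y)

    def _max(x, y):
        if x is None:
            return y
        if y is None:
            return x
        return max(x, y)

    return FieldSummary(
        max_number=max(a.max_number, b.max_number),
        min_value=_min(a.min_value, b.min_value),
        max_value=_max(a.max_value, b.max_value),
        n_records=a.n_records + b.n_records,
        n_present=a.n_present + b.n_present,
        max_alleles=max(a.max_alleles, b.max_alleles),
        max_ploidy=max(a.max_ploidy, b.max_ploidy),
    )


@dataclasses.dataclass(frozen=True)
class SentinelPair:
    missing: Any
    fill: Any


def sentinel_values(dtype: str) -> SentinelPair:
    """Return the canonical (missing, fill) pair for a value-bearing dtype.

    Booleans carry no sentinels (missingness lives in companion mask
    arrays), so requesting them is an error.
    """
    if dtype in _INT_DTYPES:
        return SentinelPair(INT_MISSING, INT_FILL)
    if dtype == "float32":
        return SentinelPair(FLOAT32_MISSING, FLOAT32_FILL)
    if dtype == "string":
        return SentinelPair(STR_MISSING, STR_FILL)
    if dtype == "bool":
        raise SchemaError("bool arrays have no sentinel values")
    raise SchemaError(f"unknown dtype {dtype!r}")


def genotype_dimension_size(n_alleles: int, ploidy: int) -> int:
    """Number of unordered genotypes: C(n_alleles + ploidy - 1, ploidy).

    This is the extent of the ``genotypes`` dimension used by Number=G
    fields such as PL; for diploids it reduces to n(n+1)/2 and grows
    quadratically with the allele count.
    """
    if n_alleles < 1 or ploidy < 1:
        raise SchemaError("n_alleles and ploidy must be >= 1")
    return math.comb(n_alleles + ploidy - 1, ploidy)


def select_integer_width(min_value: int, max_value: int) -> str:
    """Narrowest signed integer dtype holding both extrema and the sentinels.

    Observed values equal to the sentinels -1/-2 cannot be stored losslessly
    in an integer array; such fields must be stored as floats instead.
    """
    if min_value > max_value:
        raise SchemaError("min_value must be <= max_value")
    for v in (min_value, max_value):
        if v in (INT_MISSING, INT_FILL):
            raise SchemaError(
                f"observed value {v} collides with the missing/fill sentinels; "
                "store this field as a float instead"
            )
    lo = min(min_value, INT_FILL)
    hi = max_value
    for dtype in _INT_DTYPES:
        info = np.iinfo(dtype)
        if info.min <= lo and hi <= info.max:
            return dtype
    raise SchemaError(f"range [{min_value}, {max_value}] exceeds int64")


@dataclasses.dataclass
class ArraySpec:
    """JSON-serializable description of one output array."""

    name: str
    dims: tuple[str, ...]
    shape: tuple[int, ...]
    dtype: str
    chunks: tuple[int, ...]
    codecs: list[dict]
    source: dict = dataclasses.field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        self.dims = tuple(self.dims)
        self.shape = tuple(int(s) for s in self.shape)
        self.chunks = tuple(int(c) for c in self.chunks)
        if not (len(self.dims) == len(self.shape) == len(self.chunks)):
            raise SchemaError(f"{self.name}: dims/shape/chunks lengths differ")
        if any(c < 1 for c in self.chunks):
            raise SchemaError(f"{self.name}: chunk lengths must be >= 1")
        if self.dtype not in _VALID_DTYPES:
            raise SchemaError(f"{self.name}: invalid dtype {self.dtype!r}")

    def asdict(self) -> dict:
        return {
            "name": self.name,
            "dims": list(self.dims),
            "shape": list(self.shape),
            "dtype": self.dtype,
            "chunks": list(self.chunks),
            "codecs": self.codecs,
            "source": self.source,
            "description": self.description,
        }

    @classmethod
    def fromdict(cls, d: dict) -> "ArraySpec":
        return cls(
            name=d["name"],
            dims=tuple(d["dims"]),
            shape=tuple(d["shape"]),
            dtype=d["dtype"],
            chunks=tuple(d["chunks"]),
            codecs=d["codecs"],
            source=d.get("source", {}),
            description=d.get("description", ""),
        )


@dataclasses.dataclass
class VczSchema:
    """Full storage schema: one ArraySpec per output array plus metadata.

    Serialized as stable-key-order JSON so it can be edited by hand between
    ``mkschema`` and ``encode``.
    """

    format_version: str
    samples: list[str]
    contigs: list[tuple[str, int | None]]
    filters: list[str]
    arrays: list[ArraySpec]
    vcf_header: str
    info_order: list[str] = dataclasses.field(default_factory=list)
    format_order: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.arrays]
        if len(names) != len(set(names)):
            raise SchemaError("array names must be unique")
        for a in self.arrays:
            src = a.source.get("kind", "")
            if src == "format" or a.name.startswith("call_"):
                if a.dims[:2] != ("variants", "samples"):
                    raise SchemaError(f"{a.name}: FORMAT arrays must lead with (variants, samples)")

    def array(self, name: str) -> ArraySpec:
        for a in self.arrays:
            if a.name == name:
                return a
        raise SchemaError(f"no array named {name!r} in schema")

    def to_json(self) -> str:
        d = {
            "format_version": self.format_version,
            "samples": self.samples,
            "contigs": [[c, l] for c, l in self.contigs],
            "filters": self.filters,
            "info_order": self.info_order,
            "format_order": self.format_order,
            "arrays": [a.asdict() for a in self.arrays],
            "vcf_header": self.vcf_header,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "VczSchema":
        d = json.loads(text)
        return cls(
            format_version=d["format_version"],
            samples=list(d["samples"]),
            contigs=[(c, l) for c, l in d["contigs"]],
            filters=list(d["filters"]),
            arrays=[ArraySpec.fromdict(a) for a in d["arrays"]],
            vcf_header=d["vcf_header"],
            info_order=list(d.get("info_order", [])),
            format_order=list(d.get("format_order", [])),
        )


def _value_dtype(field: FieldDefinition, summary: FieldSummary) -> str:
    if field.vcf_type == "Integer":
        if summary.min_value is None:  # never observed: narrowest width
            return "int8"
        return select_integer_width(int(summary.min_value), int(summary.max_value))
    if field.vcf_type == "Float":
        return "float32"
    if field.vcf_type == "Flag":
        return "bool"
    # Character is treated as a length-1 String.
    return "string"


def _trailing_dim(
    field: FieldDefinition, summary: FieldSummary, array_name: str
) -> tuple[str, int] | None:
    number = field.vcf_number
    if number in ("0", "1"):
        return None
    if number == "A":
        return ("alt_alleles", max(summary.max_alleles - 1, 1))
    if number == "R":
        return ("alleles", max(summary.max_alleles, 1))
    if number == "G":
        if summary.max_alleles < 1 or summary.max_ploidy < 1:
            raise SchemaError(
                f"{field.full_name}: Number=G field present but no genotypes observed"
            )
        return ("genotypes", genotype_dimension_size(summary.max_alleles, summary.max_ploidy))
    if number == ".":
        return (f"{array_name}_dim", max(summary.max_number, 1))
    # Fixed integer Number=N: the header arity is authoritative.
    return (f"{array_name}_dim", int(number))


def _chunks_for(shape, dims, variant_chunk, sample_chunk):
    chunks = []
    for dim, extent in zip(dims, shape):
        if dim == "variants":
            chunks.append(min(variant_chunk, max(extent, 1)))
        elif dim == "samples":
            chunks.append(min(sample_chunk, max(extent, 1)))
        else:
            chunks.append(max(extent, 1))
    return tuple(chunks)


def _default_codecs(name: str, dtype: str) -> list[dict]:
    # Bit-shuffle helps where the top bits are almost always zero:
    # genotype calls and booleans. Everything else gets plain zstd.
    if name == "call_genotype" or dtype == "bool":
        return [dict(BITSHUFFLE_COMPRESSOR)]
    return [dict(DEFAULT_COMPRESSOR)]


def map_field_to_array_specs(
    field: FieldDefinition,
    summary: FieldSummary,
    *,
    n_variants: int,
    n_samples: int,
    variant_chunk: int = DEFAULT_VARIANT_CHUNK,
    sample_chunk: int = DEFAULT_SAMPLE_CHUNK,
) -> list[ArraySpec]:
    """Map one VCF field declaration to its output array spec(s).

    GT is special-cased into three arrays: ``call_genotype`` (allele
    indexes, dims (variants, samples, ploidy)), ``call_genotype_phased``
    and ``call_genotype_mask``.
    """
    if field.category == "FORMAT" and field.key == "GT":
        ploidy = max(summary.max_ploidy, 1)
        max_allele = int(summary.max_value) if summary.max_value is not None else 0
        gt_dtype = select_integer_width(0, max(max_allele, 1))
        lead_dims = ("variants", "samples")
        lead_shape = (n_variants, n_samples)
        specs = [
            ArraySpec(
                name="call_genotype",
                dims=lead_dims + ("ploidy",),
                shape=lead_shape + (ploidy,),
                dtype=gt_dtype,
                chunks=_chunks_for(lead_shape + (ploidy,), lead_dims + ("ploidy",), variant_chunk, sample_chunk),
                codecs=_default_codecs("call_genotype", gt_dtype),
                source={"kind": "genotype"},
                description="Allele indexes; -1 missing, -2 ploidy padding",
            ),
            ArraySpec(
                name="call_genotype_phased",
                dims=lead_dims,
                shape=lead_shape,
                dtype="bool",
                chunks=_chunks_for(lead_shape, lead_dims, variant_chunk, sample_chunk),
                codecs=_default_codecs("call_genotype_phased", "bool"),
                source={"kind": "genotype_phased"},
                description="True where the call separator is |",
            ),
            ArraySpec(
                name="call_genotype_mask",
                dims=lead_dims + ("ploidy",),
                shape=lead_shape + (ploidy,),
                dtype="bool",
                chunks=_chunks_for(lead_shape + (ploidy,), lead_dims + ("ploidy",), variant_chunk, sample_chunk),
                codecs=_default_codecs("call_genotype_mask", "bool"),
                source={"kind": "genotype_mask"},
                description="True where the allele is missing",
            ),
        ]
        return specs

    if field.category == "FORMAT":
        name = f"call_{field.key}"
        dims: tuple[str, ...] = ("variants", "samples")
        shape: tuple[int, ...] = (n_variants, n_samples)
    else:
        name = f"variant_{field.key}"
        dims = ("variants",)
        shape = (n_variants,)

    dtype = _value_dtype(field, summary)
    trailing = None if field.vcf_type == "Flag" else _trailing_dim(field, summary, name)
    if trailing is not None:
        dims = dims + (trailing[0],)
        shape = shape + (trailing[1],)
    return [
        ArraySpec(
            name=name,
            dims=dims,
            shape=shape,
            dtype=dtype,
            chunks=_chunks_for(shape, dims, variant_chunk, sample_chunk),
            codecs=_default_codecs(name, dtype),
            source={
                "kind": field.category.lower() if field.category != "fixed" else "info",
                "field": field.full_name,
                "vcf_number": field.vcf_number,
                "vcf_type": field.vcf_type,
            },
            description=field.description,
        )
    ]


def _fixed_array_specs(icf, variant_chunk, sample_chunk) -> list[ArraySpec]:
    n = icf.n_records
    n_samples = len(icf.samples)
    n_contigs = max(len(icf.contigs), 1)
    n_filters = max(len(icf.filters), 1)
    max_alleles = max(icf.max_alleles, 1)
    pos_dtype = "int32" if icf.max_position <= np.iinfo("int32").max else "int64"
    contig_dtype = select_integer_width(0, max(n_contigs - 1, 1))

    def spec(name, dims, shape, dtype, kind, desc=""):
        return ArraySpec(
            name=name,
            dims=dims,
            shape=shape,
            dtype=dtype,
            chunks=_chunks_for(shape, dims, variant_chunk, sample_chunk),
            codecs=_default_codecs(name, dtype),
            source={"kind": kind},
            description=desc,
        )

    return [
        spec("variant_position", ("variants",), (n,), pos_dtype, "fixed:position", "POS"),
        spec("variant_contig", ("variants",), (n,), contig_dtype, "fixed:contig", "Index into contig_id"),
        spec("variant_allele", ("variants", "alleles"), (n, max_alleles), "string", "fixed:allele", "REF then ALT alleles"),
        spec("variant_id", ("variants",), (n,), "string", "fixed:id", "ID"),
        spec("variant_id_mask", ("variants",), (n,), "bool", "fixed:id_mask", "True where ID is missing"),
        spec("variant_quality", ("variants",), (n,), "float32", "fixed:quality", "QUAL"),
        spec("variant_filter", ("variants", "filters"), (n, n_filters), "bool", "fixed:filter", "FILTER membership over filter_id"),
        spec("variant_length", ("variants",), (n,), pos_dtype, "fixed:length", "end - POS + 1 (END-aware)"),
        spec("sample_id", ("samples",), (max(n_samples, 1),), "string", "fixed:sample_id"),
        spec("contig_id", ("contigs",), (n_contigs,), "string", "fixed:contig_id"),
        spec("contig_length", ("contigs",), (n_contigs,), "int64", "fixed:contig_length"),
        spec("filter_id", ("filters",), (n_filters,), "string", "fixed:filter_id"),
    ]


def _local_allele_specs(icf, specs, variant_chunk, sample_chunk) -> list[ArraySpec]:
    """Replace Number=R / Number=G FORMAT arrays by their localized forms."""
    gt = icf.fields.get("FORMAT/GT")
    if gt is None:
        raise SchemaError("local alleles requires a GT field")
    ploidy = gt[1].max_ploidy
    if ploidy > 2:
        # Number=G localization is defined for diploids only in this version.
        has_g = any(
            f.vcf_number == "G" for f, _ in icf.fields.values() if f.category == "FORMAT"
        )
        if has_g:
            raise SchemaError("local-allele localization of Number=G fields requires ploidy <= 2")
    n = icf.n_records
    n_samples = len(icf.samples)
    out = []
    max_allele = int(gt[1].max_value) if gt[1].max_value is not None else 0
    la_dtype = select_integer_width(0, max(max_allele, 1))
    lead = ("variants", "samples")
    lgd = genotype_dimension_size(ploidy, ploidy) if ploidy >= 1 else 1

    def spec(name, dims, shape, dtype, kind, src_field=None, desc="", number=None, vtype=None):
        source = {"kind": kind}
        if src_field:
            source["field"] = src_field
        if number is not None:
            source["vcf_number"] = number
        if vtype is not None:
            source["vcf_type"] = vtype
        return ArraySpec(
            name=name, dims=dims, shape=shape, dtype=dtype,
            chunks=_chunks_for(shape, dims, variant_chunk, sample_chunk),
            codecs=_default_codecs(name, dtype), source=source, description=desc,
        )

    out.append(
        spec("call_LA", lead + ("local_alleles",), (n, n_samples, max(ploidy, 1)), la_dtype,
             "la", desc="Sorted unique allele indexes observed in the call")
    )
    for s in specs:
        src = s.source
        if src.get("kind") != "format":
            out.append(s)
            continue
        number = src.get("vcf_number")
        key = src.get("field", "").split("/")[-1]
        if number == "R":
            out.append(
                spec(f"call_L{key}", lead + ("local_alleles",),
                     (n, n_samples, max(ploidy, 1)), s.dtype, "lad",
                     src_field=src["field"], desc=f"{key} restricted to local alleles",
                     number="R", vtype=src.get("vcf_type"))
            )
        elif number == "G":
            out.append(
                spec(f"call_L{key}", lead + ("local_genotypes",),
                     (n, n_samples, lgd), s.dtype, "lpl",
                     src_field=src["field"], desc=f"{key} restricted to local genotypes",
                     number="G", vtype=src.get("vcf_type"))
            )
        else:
            out.append(s)
    return out


def generate_schema(
    icf,
    *,
    variant_chunk: int = DEFAULT_VARIANT_CHUNK,
    sample_chunk: int = DEFAULT_SAMPLE_CHUNK,
    local_alleles: bool = False,
    overrides: dict[str, dict] | None = None,
) -> VczSchema:
    """Build the default storage schema from finalized ICF summaries.

    ``overrides`` maps array names to partial ArraySpec updates (for example
    ``{"call_BAF": {"codecs": [{"id": "bitround", "keepbits": 5}, ...]}}``),
    mirroring the edit-the-JSON mkschema workflow.
    """
    specs = _fixed_array_specs(icf, variant_chunk, sample_chunk)
    field_specs: list[ArraySpec] = []
    for name, (field, summary) in icf.fields.items():
        if field.category == "fixed":
            continue  # covered by the fixed arrays above
        field_specs.extend(
            map_field_to_array_specs(
                field, summary,
                n_variants=icf.n_records, n_samples=len(icf.samples),
                variant_chunk=variant_chunk, sample_chunk=sample_chunk,
            )
        )
    if local_alleles:
        field_specs = _local_allele_specs(icf, field_specs, variant_chunk, sample_chunk)
    specs.extend(field_specs)

    schema = VczSchema(
        format_version=FORMAT_VERSION,
        samples=list(icf.samples),
        contigs=[(c, l) for c, l in icf.contigs],
        filters=list(icf.filters),
        arrays=specs,
        vcf_header=icf.header_text,
        info_order=list(icf.info_keys),
        format_order=list(icf.format_keys),
    )
    for name, patch in (overrides or {}).items():
        a = schema.array(name)  # raises for unknown arrays
        for k, v in patch.items():
            if not hasattr(a, k):
                raise SchemaError(f"unknown ArraySpec attribute {k!r}")
            setattr(a, k, tuple(v) if k in ("dims", "shape", "chunks") else v)
    return schema
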