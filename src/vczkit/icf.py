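"""Intermediate columnar format (ICF): stage 1 of VCF conversion.

``explode`` parses VCF partitions into per-field, chunk-compressed columns
with random access by record index, accumulating the per-field summaries
(arity, extrema, presence) that later drive schema generation. The layout
is internal to this package and versioned as such; it exists so that the
array encoder can stream one field at a time without re-reading the VCF.

The distributed variants (``dexplode_init`` / ``explode_partition`` /
``dexplode_finalise``) are pure functions over a shared output directory:
partitions can run on different machines and a failed partition can simply
be re-run (its output is written to a temporary directory and renamed into
place on completion).

A deliberate difference from the final store: ICF *preserves* the
distinction between a field that is absent from a record and one that is
present but missing (``.``). The two collapse only at encode time, which is
one of the two documented lossy corner cases of the array representation.
"""

from __future__ import annotations

import dataclasses
import json
import os
import pickle
import shutil
from pathlib import Path

import pysam
import zstandard

from .vcz_schema import FieldDefinition, FieldSummary, merge_field_summaries

ICF_VERSION = "vczkit-icf-0.1"
_PICKLE_PROTOCOL = 4
DEFAULT_COLUMN_CHUNK_BYTES = 1 << 20  # ~1 MiB decompressed per column chunk


class IcfError(ValueError):
    pass


class Absent:
    """Marker for 'field does not appear in this record'."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __reduce__(self):
        return (Absent, ())

    def __repr__(self):
        return "ABSENT"


ABSENT = Absent()

FIXED_FIELDS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "STOP")


# ----------------------------------------------------------------------
# Genotype text parsing
# ----------------------------------------------------------------------

def parse_genotype_call(gt_text: str, max_ploidy: int):
    """Parse a VCF GT string into (allele indexes padded to max_ploidy, phased).

    ``.`` tokens become -1 (missing); positions beyond the call's ploidy
    become -2 (fill). The phased flag is True iff all separators are ``|``;
    a call with no separator (haploid) is unphased by convention.
    """
    has_pipe = "|" in gt_text
    has_slash = "/" in gt_text
    if has_pipe and has_slash:
        raise IcfError(f"mixed phasing separators in genotype {gt_text!r}")
    tokens = gt_text.split("|" if has_pipe else "/")
    if len(tokens) > max_ploidy:
        raise IcfError(f"genotype {gt_text!r} exceeds max ploidy {max_ploidy}")
    alleles = []
    for tok in tokens:
        if tok == ".":
            alleles.append(-1)
        else:
            try:
                alleles.append(int(tok))
            except ValueError:
                raise IcfError(f"non-numeric allele token {tok!r} in {gt_text!r}") from None
            if alleles[-1] < 0:
                raise IcfError(f"negative allele index in {gt_text!r}")
    alleles += [-2] * (max_ploidy - len(alleles))
    phased = has_pipe and len(tokens) > 1
    return alleles, phased


# ----------------------------------------------------------------------
# Header / record extraction (pysam-backed)
# ----------------------------------------------------------------------

def _header_field_defs(header: pysam.VariantHeader) -> dict[str, FieldDefinition]:
    """INFO/FORMAT field definitions in header declaration order."""
    defs: dict[str, FieldDefinition] = {}
    for rec in header.records:
        if rec.type not in ("INFO", "FORMAT"):
            continue
        key = rec.get("ID")
        number = str(rec.get("Number"))
        vtype = rec.get("Type")
        name = f"{rec.type}/{key}"
        if name in defs:
            continue
        defs[name] = FieldDefinition(
            category=rec.type,
            key=key,
            vcf_number=number,
            vcf_type=vtype,
            description=rec.get("Description", "") or "",
        )
    return defs


def _norm_scalar(v, vcf_type):
    if v is None:
        return None
    if vcf_type in ("String", "Character") and v == ".":
        return None
    return v


def _norm_value(v, vcf_type):
    """Normalize a pysam INFO/FORMAT value to scalar | tuple | None."""
    if v is None:
        return None
    if isinstance(v, tuple):
        out = tuple(_norm_scalar(x, vcf_type) for x in v)
        if all(x is None for x in out):
            return None
        return out
    return _norm_scalar(v, vcf_type)


def extract_record(rec, field_defs: dict[str, FieldDefinition]) -> dict:
    """Canonical per-record value dict keyed by ICF field name.

    The same extraction backs both explode and the semantic round-trip
    comparison, so "value equality" means equality of these dicts.
    """
    alts = tuple(rec.alts) if rec.alts else ()
    out = {
        "CHROM": rec.chrom,
        "POS": rec.pos,
        "ID": rec.id,
        "REF": rec.ref,
        "ALT": alts,
        "QUAL": rec.qual,
        "FILTER": tuple(rec.filter.keys()),
        # 1-based inclusive end; htslib folds INFO/END into rec.stop.
        "STOP": rec.stop,
    }
    info_present = set(rec.info.keys())
    for name, fd in field_defs.items():
        if fd.category == "INFO":
            if fd.key == "END":
                continue
            if fd.key not in info_present:
                out[name] = ABSENT
            elif fd.vcf_type == "Flag":
                out[name] = True
            else:
                out[name] = _norm_value(rec.info.get(fd.key), fd.vcf_type)
        elif fd.category == "FORMAT":
            if fd.key not in rec.format.keys():
                out[name] = ABSENT
                continue
            if fd.key == "GT":
                calls = []
                for s in rec.samples.values():
                    alleles = s.allele_indices or ()
                    phased = bool(s.phased) if len(alleles) > 1 else False
                    calls.append((tuple(alleles), phased))
                out[name] = calls
            else:
                out[name] = [
                    _norm_value(s.get(fd.key), fd.vcf_type) for s in rec.samples.values()
                ]
    return out


def read_vcf_records(path, field_defs=None):
    """Yield canonical record dicts from a VCF file."""
    with pysam.VariantFile(str(path)) as vf:
        defs = field_defs or _header_field_defs(vf.header)
        for rec in vf:
            yield extract_record(rec, defs)


# ----------------------------------------------------------------------
# Partitioning
# ----------------------------------------------------------------------

@dataclasses.dataclass
class Partition:
    """One unit of explode work: a whole file or an indexed genomic slice."""

    path: str
    regions: list[tuple[str, int, int]] | None = None  # 1-based inclusive slices
    ordinal: int = 0

    def asdict(self):
        return {
            "path": self.path,
            "regions": None if self.regions is None else [list(r) for r in self.regions],
            "ordinal": self.ordinal,
        }

    @classmethod
    def fromdict(cls, d):
        regions = d["regions"]
        return cls(
            path=d["path"],
            regions=None if regions is None else [tuple(r) for r in regions],
            ordinal=d["ordinal"],
        )


def _has_index(path: str) -> bool:
    return os.path.exists(path + ".tbi") or os.path.exists(path + ".csi")


def _split_file(path: str, k: int) -> list[Partition] | None:
    """Split one indexed file into <= k contiguous genomic slices."""
    with pysam.VariantFile(path) as vf:
        contigs = [(c, vf.header.contigs[c].length) for c in vf.header.contigs]
    if not contigs or any(l is None for _, l in contigs):
        return None
    total = sum(l for _, l in contigs)
    k = min(k, total)
    bounds = [total * i // k for i in range(k + 1)]
    parts = []
    for i in range(k):
        lo, hi = bounds[i], bounds[i + 1]  # concatenated coords, 0-based half-open
        regions = []
        offset = 0
        for contig, length in contigs:
            c_lo, c_hi = offset, offset + length
            s, e = max(lo, c_lo), min(hi, c_hi)
            if s < e:
                regions.append((contig, s - offset + 1, e - offset))
            offset = c_hi
        parts.append(Partition(path=path, regions=regions))
    return parts


def partition_vcf(paths, target_partitions: int) -> list[Partition]:
    """Split input files into ordered, disjoint partitions.

    Files with a Tabix/CSI index (and contig lengths in the header) can be
    split into multiple genomic slices; other files are single partitions.
    Concatenating partitions in order preserves the input record order.
    """
    paths = [str(p) for p in paths]
    for p in paths:
        if not os.path.exists(p):
            raise IcfError(f"cannot read {p}")
    n = len(paths)
    if target_partitions < 1:
        raise IcfError("target_partitions must be >= 1")
    per_file = [max(1, target_partitions // n + (1 if i < target_partitions % n else 0)) for i in range(n)]
    partitions: list[Partition] = []
    for path, k in zip(paths, per_file):
        parts = None
        if k > 1 and _has_index(path):
            parts = _split_file(path, k)
        if parts is None:
            parts = [Partition(path=path)]
        partitions.extend(parts)
    for i, p in enumerate(partitions):
        p.ordinal = i
    return partitions


def _iter_partition_records(partition: Partition):
    with pysam.VariantFile(partition.path) as vf:
        defs = _header_field_defs(vf.header)
        if partition.regions is None:
            for rec in vf:
                yield rec, defs
        else:
            for contig, start, stop in partition.regions:
                try:
                    it = vf.fetch(contig, start - 1, stop)
                except ValueError as e:
                    raise IcfError(f"{partition.path}: index fetch failed: {e}") from e
                for rec in it:
                    # Slice ownership is by POS so overlapping records
                    # (e.g. spanning deletions) land in exactly one slice.
                    if start <= rec.pos <= stop:
                        yield rec, defs


# ----------------------------------------------------------------------
# Column writing
# ----------------------------------------------------------------------

def _safe_name(field: str) -> str:
    return field.replace("/", "__")


class _ColumnWriter:
    def __init__(self, directory: Path, field: str, target_bytes: int):
        self.dir = directory / _safe_name(field)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.target = target_bytes
        self.values = []
        self.approx = 0
        self.chunk_counts: list[int] = []
        self._cctx = zstandard.ZstdCompressor(level=7)

    def append(self, value):
        self.values.append(value)
        self.approx += len(pickle.dumps(value, _PICKLE_PROTOCOL))
        if self.approx >= self.target:
            self.flush()

    def flush(self):
        if not self.values:
            return
        payload = self._cctx.compress(pickle.dumps(self.values, _PICKLE_PROTOCOL))
        idx = len(self.chunk_counts)
        (self.dir / f"c{idx:05d}").write_bytes(payload)
        self.chunk_counts.append(len(self.values))
        self.values = []
        self.approx = 0


# ----------------------------------------------------------------------
# Explode: init / partition / finalise
# ----------------------------------------------------------------------

def _header_union(paths):
    """Field defs, samples, contigs, filters from the input headers.

    Sample lists must be identical across files; contigs and filters are
    unioned in order of first appearance.
    """
    defs: dict[str, FieldDefinition] = {}
    samples = None
    contigs: list[tuple[str, int | None]] = []
    seen_contigs = set()
    filters: list[str] = []
    seen_filters = set()
    header_text = None
    for path in paths:
        with pysam.VariantFile(str(path)) as vf:
            h = vf.header
            if header_text is None:
                header_text = str(h)
            file_samples = list(h.samples)
            if samples is None:
                samples = file_samples
            elif samples != file_samples:
                raise IcfError(f"{path}: sample list differs from first input")
            for name, fd in _header_field_defs(h).items():
                defs.setdefault(name, fd)
            for c in h.contigs:
                if c not in seen_contigs:
                    seen_contigs.add(c)
                    contigs.append((c, h.contigs[c].length))
            for f in h.filters:
                if f not in seen_filters:
                    seen_filters.add(f)
                    filters.append(f)
    if "PASS" not in seen_filters:
        filters = ["PASS"] + filters
    return defs, samples or [], contigs, filters, header_text or ""


def dexplode_init(paths, out, *, target_partitions: int = 1,
                  column_chunk_bytes: int = DEFAULT_COLUMN_CHUNK_BYTES) -> int:
    """Plan a (possibly distributed) explode; returns the partition count."""
    out = Path(out)
    if out.exists():
        raise IcfError(f"output {out} already exists")
    partitions = partition_vcf(paths, target_partitions)
    defs, samples, contigs, filters, header_text = _header_union([str(p) for p in paths])
    out.mkdir(parents=True)
    (out / "partitions").mkdir()
    init = {
        "version": ICF_VERSION,
        "paths": [str(p) for p in paths],
        "partitions": [p.asdict() for p in partitions],
        "fields": {
            name: dataclasses.asdict(fd) for name, fd in defs.items()
        },
        "samples": samples,
        "contigs": [[c, l] for c, l in contigs],
        "filters": filters,
        "header_text": header_text,
        "column_chunk_bytes": column_chunk_bytes,
    }
    (out / "init.json").write_text(json.dumps(init, indent=2))
    return len(partitions)


def _check_int_sentinels(field_name, value, ctx):
    vals = value if isinstance(value, tuple) else (value,)
    for v in vals:
        if v in (-1, -2):
            raise IcfError(
                f"{ctx}: integer field {field_name} contains {v}, which collides "
                "with the missing/fill sentinels; redefine the field as Float to store it"
            )


def explode_partition(out, index: int) -> None:
    """Convert one partition to columnar chunks (idempotent, atomic)."""
    out = Path(out)
    init = json.loads((out / "init.json").read_text())
    partitions = [Partition.fromdict(d) for d in init["partitions"]]
    if not 0 <= index < len(partitions):
        raise IcfError(f"partition index {index} out of range")
    partition = partitions[index]
    defs = {name: FieldDefinition(**d) for name, d in init["fields"].items()}
    contig_index = {c: i for i, (c, _) in enumerate(init["contigs"])}
    target = init["column_chunk_bytes"]

    final_dir = out / "partitions" / f"p{index:05d}"
    tmp_dir = out / "partitions" / f".p{index:05d}.tmp"
    if tmp_dir.exists():
        shutil.rmtree(tmp_dir)
    tmp_dir.mkdir(parents=True)

    field_names = list(FIXED_FIELDS) + [n for n in defs if defs[n].key != "END"]
    writers = {name: _ColumnWriter(tmp_dir, name, target) for name in field_names}
    summaries = {name: FieldSummary() for name in field_names}
    n_records = 0
    first = last = None
    max_alleles = 0
    max_ploidy = 0

    for rec, _ in _iter_partition_records(partition):
        ctx = f"{partition.path}:{rec.chrom}:{rec.pos}"
        values = extract_record(rec, defs)
        if rec.chrom not in contig_index:
            raise IcfError(f"{ctx}: contig {rec.chrom!r} not declared in any header")
        key = (contig_index[rec.chrom], rec.pos)
        if first is None:
            first = key
        last = key
        n_alleles = 1 + len(values["ALT"])
        max_alleles = max(max_alleles, n_alleles)

        for name in field_names:
            v = values.get(name, ABSENT)
            writers[name].append(v)
            s = summaries[name]
            s.n_records += 1
            if name in FIXED_FIELDS:
                if name == "POS":
                    s.update(1, (v,))
                elif name == "QUAL" and v is not None:
                    s.update(1, (v,))
                elif name == "ALT":
                    s.update(len(v))
                continue
            if v is ABSENT:
                continue
            fd = defs[name]
            if name == "FORMAT/GT":
                rec_ploidy = 0
                obs = []
                for alleles, _phased in v:
                    rec_ploidy = max(rec_ploidy, len(alleles))
                    obs.extend(a for a in alleles if a is not None)
                max_ploidy = max(max_ploidy, rec_ploidy)
                s.update(rec_ploidy, obs)
            elif fd.category == "INFO":
                if fd.vcf_type == "Flag":
                    s.update(0)
                elif v is None:
                    s.update(1)
                elif isinstance(v, tuple):
                    if fd.vcf_type == "Integer":
                        _check_int_sentinels(name, v, ctx)
                    s.update(len(v), v if fd.vcf_type in ("Integer", "Float") else ())
                else:
                    if fd.vcf_type == "Integer":
                        _check_int_sentinels(name, v, ctx)
                    s.update(1, (v,) if fd.vcf_type in ("Integer", "Float") else ())
            else:  # FORMAT
                width = 1
                numeric = []
                for sval in v:
                    if sval is None:
                        continue
                    if isinstance(sval, tuple):
                        width = max(width, len(sval))
                        if fd.vcf_type == "Integer":
                            _check_int_sentinels(name, sval, ctx)
                        if fd.vcf_type in ("Integer", "Float"):
                            numeric.extend(x for x in sval if x is not None)
                    else:
                        if fd.vcf_type == "Integer":
                            _check_int_sentinels(name, sval, ctx)
                        if fd.vcf_type in ("Integer", "Float"):
                            numeric.append(sval)
                s.update(width, numeric)
        n_records += 1

    for w in writers.values():
        w.flush()

    summary = {
        "n_records": n_records,
        "first": first,
        "last": last,
        "max_alleles": max_alleles,
        "max_ploidy": max_ploidy,
        "fields": {
            name: {
                "summary": summaries[name].asdict(),
                "chunk_counts": writers[name].chunk_counts,
            }
            for name in field_names
        },
    }
    (tmp_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    if final_dir.exists():
        shutil.rmtree(final_dir)
    os.replace(tmp_dir, final_dir)


def dexplode_finalise(out) -> "IcfStore":
    """Merge partition summaries into the final ICF manifest."""
    out = Path(out)
    init = json.loads((out / "init.json").read_text())
    n_parts = len(init["partitions"])
    part_summaries = []
    missing = [
        i for i in range(n_parts)
        if not (out / "partitions" / f"p{i:05d}" / "summary.json").exists()
    ]
    if missing:
        raise IcfError(f"partitions not completed: {missing}")
    for i in range(n_parts):
        part_summaries.append(
            json.loads((out / "partitions" / f"p{i:05d}" / "summary.json").read_text())
        )

    # Ordered, non-overlapping inputs: partition boundaries must be monotone.
    prev_last = None
    for i, ps in enumerate(part_summaries):
        if ps["n_records"] == 0:
            continue
        first, last = tuple(ps["first"]), tuple(ps["last"])
        if prev_last is not None and first < prev_last:
            raise IcfError(
                f"inputs overlap or are out of order at partition {i} "
                f"(first record {first} precedes {prev_last})"
            )
        prev_last = last

    field_names = list(FIXED_FIELDS) + [
        n for n in init["fields"] if init["fields"][n]["key"] != "END"
    ]
    merged = {}
    max_alleles = max((ps["max_alleles"] for ps in part_summaries), default=0)
    max_ploidy = max((ps["max_ploidy"] for ps in part_summaries), default=0)
    for name in field_names:
        s = FieldSummary()
        for ps in part_summaries:
            s = merge_field_summaries(s, FieldSummary(**ps["fields"][name]["summary"]))
        s.max_alleles = max_alleles
        s.max_ploidy = max_ploidy
        merged[name] = s

    manifest = {
        "version": ICF_VERSION,
        "fields": init["fields"],
        "field_order": field_names,
        "samples": init["samples"],
        "contigs": init["contigs"],
        "filters": init["filters"],
        "header_text": init["header_text"],
        "summaries": {name: merged[name].asdict() for name in field_names},
        "partitions": [
            {
                "n_records": ps["n_records"],
                "chunk_counts": {n: ps["fields"][n]["chunk_counts"] for n in field_names},
            }
            for ps in part_summaries
        ],
        "max_alleles": max_alleles,
        "max_ploidy": max_ploidy,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return IcfStore(out)


def explode(paths, out, *, target_partitions: int = 1,
            column_chunk_bytes: int = DEFAULT_COLUMN_CHUNK_BYTES) -> "IcfStore":
    """Single-process explode: init, all partitions, finalise."""
    n = dexplode_init(paths, out, target_partitions=target_partitions,
                      column_chunk_bytes=column_chunk_bytes)
    for i in range(n):
        explode_partition(out, i)
    return dexplode_finalise(out)


# ----------------------------------------------------------------------
# Reading
# ----------------------------------------------------------------------

class IcfStore:
    """Random access reader over a finalized ICF directory."""

    def __init__(self, path):
        self.path = Path(path)
        manifest_path = self.path / "manifest.json"
        if not manifest_path.exists():
            raise IcfError(f"{path} is not a finalized ICF store (no manifest.json)")
        m = json.loads(manifest_path.read_text())
        self.manifest = m
        self.samples: list[str] = m["samples"]
        self.contigs: list[tuple[str, int | None]] = [(c, l) for c, l in m["contigs"]]
        self.filters: list[str] = m["filters"]
        self.header_text: str = m["header_text"]
        self.max_alleles: int = max(m["max_alleles"], 1)
        self.max_ploidy: int = m["max_ploidy"]
        self.field_order: list[str] = m["field_order"]
        self.fields: dict[str, tuple[FieldDefinition, FieldSummary]] = {}
        for name in self.field_order:
            if name in FIXED_FIELDS:
                fd = FieldDefinition(category="fixed", key=name, vcf_number="1",
                                     vcf_type="String")
            else:
                fd = FieldDefinition(**m["fields"][name])
            self.fields[name] = (fd, FieldSummary(**m["summaries"][name]))
        self._part_counts = [p["n_records"] for p in m["partitions"]]
        self._part_offsets = [0]
        for c in self._part_counts:
            self._part_offsets.append(self._part_offsets[-1] + c)
        self._dctx = zstandard.ZstdDecompressor()
        self._chunk_cache: dict[tuple, list] = {}

    @property
    def n_records(self) -> int:
        return self._part_offsets[-1]

    @property
    def info_keys(self) -> list[str]:
        """INFO keys in header order, including END (which is rendered from
        the derived variant_length array rather than stored directly)."""
        return [d["key"] for d in self.manifest["fields"].values() if d["category"] == "INFO"]

    @property
    def format_keys(self) -> list[str]:
        return [d["key"] for d in self.manifest["fields"].values() if d["category"] == "FORMAT"]

    @property
    def n_partitions(self) -> int:
        return len(self._part_counts)

    @property
    def max_position(self) -> int:
        pos = self.fields["POS"][1].max_value
        return int(pos) if pos is not None else 0

    def _read_chunk(self, field, part, chunk_idx):
        key = (field, part, chunk_idx)
        if key not in self._chunk_cache:
            if len(self._chunk_cache) > 64:
                self._chunk_cache.clear()
            payload = (
                self.path / "partitions" / f"p{part:05d}" / _safe_name(field) / f"c{chunk_idx:05d}"
            ).read_bytes()
            self._chunk_cache[key] = pickle.loads(self._dctx.decompress(payload))
        return self._chunk_cache[key]

    def fetch_field_slice(self, field: str, start: int, stop: int) -> list:
        """Values for records [start, stop), decompressing only the chunks
        that overlap the range. Records lacking the field yield ABSENT."""
        if field not in self.fields:
            raise IcfError(f"unknown field {field!r}")
        if not 0 <= start <= stop <= self.n_records:
            raise IcfError(f"slice [{start}, {stop}) out of bounds [0, {self.n_records})")
        out = []
        for part in range(self.n_partitions):
            p_lo, p_hi = self._part_offsets[part], self._part_offsets[part + 1]
            lo, hi = max(start, p_lo), min(stop, p_hi)
            if lo >= hi:
                continue
            counts = self.manifest["partitions"][part]["chunk_counts"][field]
            offset = p_lo
            for ci, cnt in enumerate(counts):
                c_lo, c_hi = offset, offset + cnt
                s, e = max(lo, c_lo), min(hi, c_hi)
                if s < e:
                    chunk = self._read_chunk(field, part, ci)
                    out.extend(chunk[s - c_lo : e - c_lo])
                offset = c_hi
        return out

    def iter_field(self, field: str, chunk_size: int = 10_000):
        for start in range(0, self.n_records, chunk_size):
            yield from self.fetch_field_slice(field, start, min(start + chunk_size, self.n_records))
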