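"""Query layer over encoded stores: regions, filters, and VCF regeneration.

This is the read-side counterpart of the converter: it resolves genomic
regions through the per-chunk region index (so only intersecting chunks are
read), evaluates bcftools-style include expressions into per-site masks,
renders tab-separated query output from format strings, and regenerates
VCF text whose parsed content is identical to the stored arrays.

Region semantics follow the 1-based inclusive, END-aware overlap convention
of the tabix/bcftools ecosystem: a record with POS p and end e (INFO/END if
given, else POS + len(REF) - 1) overlaps region [s, t] iff p <= t and
e >= s, so spanning deletions are picked up by regions that start inside
them.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np

from .encoder import VczStore
from .local_alleles import reconstruct_g_entries, reconstruct_r_entries
from .vcz_schema import INT_FILL, INT_MISSING, STR_FILL, STR_MISSING


class QueryError(ValueError):
    pass


# ----------------------------------------------------------------------
# Regions
# ----------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Region:
    contig: str
    start: int | None = None  # 1-based inclusive
    end: int | None = None  # 1-based inclusive

    def __post_init__(self):
        if self.start is not None and self.end is not None and self.start > self.end:
            raise QueryError(f"region start {self.start} > end {self.end}")


def parse_region(text: str) -> Region:
    """Parse ``chr``, ``chr:pos``, ``chr:start-``, ``chr:start-end``."""
    if ":" not in text:
        return Region(text)
    contig, _, coords = text.rpartition(":")
    if "-" not in coords:
        p = int(coords)
        return Region(contig, p, p)
    s, _, e = coords.partition("-")
    return Region(contig, int(s) if s else None, int(e) if e else None)


def parse_regions(text: str) -> list[Region]:
    return [parse_region(t) for t in text.split(",") if t]


def candidate_chunks(store: VczStore, region: Region, contig_index: int) -> list[int]:
    """Variant chunks whose coordinate range intersects the region,
    according to the region index (all chunks if no index is stored)."""
    index = store.region_index()
    n_chunks = -(-store.n_variants // store.variant_chunk_size) if store.n_variants else 0
    if index is None or index.size == 0:
        return list(range(n_chunks))
    start = region.start if region.start is not None else 1
    end = region.end if region.end is not None else np.iinfo("int64").max
    rows = index[
        (index[:, 1] == contig_index)
        & (index[:, 2] <= end)  # pos_min <= region end
        & (index[:, 4] >= start)  # end_max >= region start
    ]
    return sorted(set(int(r[0]) for r in rows))


def resolve_regions(store: VczStore, regions) -> np.ndarray:
    """Sorted variant indexes whose [POS, end] interval overlaps any region."""
    if isinstance(regions, (str, Region)):
        regions = [regions]
    regions = [parse_region(r) if isinstance(r, str) else r for r in regions]
    contig_ids = store.contig_ids
    vc = store.variant_chunk_size
    n = store.n_variants
    selected: set[int] = set()
    for region in regions:
        if region.contig not in contig_ids:
            raise QueryError(f"unknown contig {region.contig!r}")
        cidx = contig_ids.index(region.contig)
        start = region.start if region.start is not None else 1
        end = region.end if region.end is not None else np.iinfo("int64").max
        for chunk in candidate_chunks(store, region, cidx):
            lo, hi = chunk * vc, min((chunk + 1) * vc, n)
            pos = store.arr("variant_position")[lo:hi]
            length = store.arr("variant_length")[lo:hi]
            contig = store.arr("variant_contig")[lo:hi]
            rec_end = pos + length - 1
            hit = (contig == cidx) & (pos <= end) & (rec_end >= start)
            selected.update((lo + np.nonzero(hit)[0]).tolist())
    return np.array(sorted(selected), dtype="int64")


# ----------------------------------------------------------------------
# Include expressions
# ----------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<field>(?:FORMAT|FMT|INFO)/[A-Za-z_][A-Za-z0-9_.]*|POS|QUAL)"
    r"|(?P<num>-?\d+\.?\d*(?:[eE][+-]?\d+)?)"
    r"|(?P<str>\"[^\"]*\"|'[^']*')"
    r"|(?P<op>>=|<=|==|!=|>|<|&&|\|\||&|\||\(|\)))"
)


def _tokenize(expr: str):
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise QueryError(f"cannot parse filter expression at {expr[pos:]!r}")
        pos = m.end()
        if m.lastgroup == "field":
            tokens.append(("field", m.group("field")))
        elif m.lastgroup == "num":
            tokens.append(("num", float(m.group("num"))))
        elif m.lastgroup == "str":
            tokens.append(("str", m.group("str")[1:-1]))
        else:
            op = m.group("op")
            op = {"&&": "&", "||": "|"}.get(op, op)
            tokens.append(("op", op))
    return tokens


class _ExprEvaluator:
    """Recursive-descent evaluator producing per-site or per-sample masks.

    A per-sample (2-D) conjunction is reduced to a site mask only at the
    top level, so ``FORMAT/DP>10 & FORMAT/GQ>20`` passes a site iff some
    single sample satisfies both comparisons. Comparisons against missing
    values are false.
    """

    def __init__(self, store: VczStore, tokens):
        self.store = store
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse_or(self):
        left = self.parse_and()
        while self.peek() == ("op", "|"):
            self.take()
            left = self._combine(left, self.parse_and(), np.logical_or)
        return left

    def parse_and(self):
        left = self.parse_factor()
        while self.peek() == ("op", "&"):
            self.take()
            left = self._combine(left, self.parse_factor(), np.logical_and)
        return left

    @staticmethod
    def _combine(a, b, op):
        if a.ndim != b.ndim:
            if a.ndim == 1:
                a = a[:, None]
            else:
                b = b[:, None]
        return op(a, b)

    def parse_factor(self):
        kind, val = self.peek()
        if (kind, val) == ("op", "("):
            self.take()
            inner = self.parse_or()
            if self.take() != ("op", ")"):
                raise QueryError("unbalanced parentheses in filter expression")
            return inner
        return self.parse_comparison()

    def parse_comparison(self):
        kind, field = self.take()
        if kind != "field":
            raise QueryError(f"expected a field name, got {field!r}")
        opk, op = self.take()
        if opk != "op" or op not in (">", ">=", "<", "<=", "==", "!="):
            raise QueryError(f"expected a comparison operator after {field}")
        litk, lit = self.take()
        if litk not in ("num", "str"):
            raise QueryError(f"expected a literal after {field} {op}")
        values, valid, is_string = self._load(field)
        if is_string != (litk == "str"):
            raise QueryError(f"type mismatch comparing {field} with {lit!r}")
        if is_string and op not in ("==", "!="):
            raise QueryError(f"strings support only == and != ({field})")
        ops = {
            ">": np.greater, ">=": np.greater_equal,
            "<": np.less, "<=": np.less_equal,
            "==": np.equal, "!=": np.not_equal,
        }
        with np.errstate(invalid="ignore"):
            result = ops[op](values, lit)
        return result & valid

    def _load(self, field: str):
        store = self.store
        if field == "POS":
            vals = store.arr("variant_position")[:]
            return vals.astype("float64"), np.ones(len(vals), dtype=bool), False
        if field == "QUAL":
            vals = store.arr("variant_quality")[:]
            return vals.astype("float64"), np.isfinite(vals), False
        prefix, _, key = field.partition("/")
        name = ("call_" if prefix in ("FORMAT", "FMT") else "variant_") + key
        if not store.has(name):
            raise QueryError(f"unknown field {field!r}")
        arr = store.arr(name)
        expected_ndim = 2 if prefix in ("FORMAT", "FMT") else 1
        if arr.ndim != expected_ndim:
            raise QueryError(
                f"{field} has a per-allele/per-genotype dimension; only scalar "
                "fields are supported in filter expressions"
            )
        vals = arr[:]
        if vals.dtype.kind in ("U", "T", "O"):
            s = vals.astype(object)
            valid = (s != STR_MISSING) & (s != STR_FILL)
            return s, valid, True
        if vals.dtype.kind == "f":
            return vals.astype("float64"), np.isfinite(vals), False
        if vals.dtype.kind == "b":
            return vals.astype("float64"), np.ones(vals.shape, dtype=bool), False
        valid = (vals != INT_MISSING) & (vals != INT_FILL)
        return vals.astype("float64"), valid, False


def evaluate_include_expression(expr: str, store: VczStore,
                                variant_indexes=None) -> np.ndarray:
    """Evaluate a filter expression into a per-variant boolean site mask."""
    ev = _ExprEvaluator(store, _tokenize(expr))
    result = ev.parse_or()
    if ev.i != len(ev.tokens):
        raise QueryError("trailing tokens in filter expression")
    if result.ndim == 2:
        result = result.any(axis=1)
    if variant_indexes is not None:
        return result[np.asarray(variant_indexes, dtype="int64")]
    return result


# ----------------------------------------------------------------------
# Value formatting
# ----------------------------------------------------------------------

def format_float(v) -> str:
    """Shortest decimal string that round-trips at float32 precision."""
    v = np.float32(v)
    if np.isnan(v):
        return STR_MISSING
    if np.isinf(v):
        return "inf" if v > 0 else "-inf"
    return np.format_float_positional(v, unique=True, trim="0")


def _fmt_value(v, dtype_kind) -> str:
    if dtype_kind == "f":
        return format_float(v)
    return str(v)


def _strip_row(row, missing, fill, is_float):
    """Drop trailing fill slots; missing renders as '.'."""
    out = []
    for v in row:
        if is_float:
            bits = np.float32(v).view(np.uint32)
            if bits == np.float32(fill).view(np.uint32):
                break
            out.append(STR_MISSING if np.isnan(v) else format_float(v))
        else:
            if v == fill:
                break
            out.append(STR_MISSING if v == missing else str(v))
    return out


# ----------------------------------------------------------------------
# query -f
# ----------------------------------------------------------------------

_PLACEHOLDER_RE = re.compile(r"%(INFO/[A-Za-z_][A-Za-z0-9_.]*|CHROM|POS|ID|REF|ALT|QUAL|FILTER)")


def render_query(format_string: str, store: VczStore, regions=None, mask=None):
    """Yield one rendered string per selected variant.

    Only the arrays named in the format string are read from storage.
    """
    fmt = format_string.replace("\\n", "\n").replace("\\t", "\t")
    parts = []
    pos = 0
    for m in _PLACEHOLDER_RE.finditer(fmt):
        if m.start() > pos:
            parts.append(("lit", fmt[pos : m.start()]))
        parts.append(("ph", m.group(1)))
        pos = m.end()
    if pos < len(fmt):
        parts.append(("lit", fmt[pos:]))
    for kind, text in parts:
        if kind == "lit" and "%" in text:
            raise QueryError(f"unknown placeholder near {text!r}")

    sel = _selection(store, regions, None, mask)
    renderers = {ph: _placeholder_renderer(store, ph) for kind, ph in parts if kind == "ph"}
    for i in sel:
        yield "".join(
            text if kind == "lit" else renderers[text](int(i)) for kind, text in parts
        )


def _placeholder_renderer(store: VczStore, ph: str):
    if ph == "CHROM":
        contig = store.arr("variant_contig")[:]
        ids = store.contig_ids
        return lambda i: ids[contig[i]]
    if ph == "POS":
        pos = store.arr("variant_position")[:]
        return lambda i: str(int(pos[i]))
    if ph == "ID":
        vid = store.arr("variant_id")[:]
        return lambda i: str(vid[i])
    if ph == "REF":
        alleles = store.arr("variant_allele")[:]
        return lambda i: str(alleles[i, 0])
    if ph == "ALT":
        alleles = store.arr("variant_allele")[:]

        def render_alt(i):
            alts = [str(a) for a in alleles[i, 1:] if str(a) != STR_FILL]
            return ",".join(alts) if alts else STR_MISSING

        return render_alt
    if ph == "QUAL":
        qual = store.arr("variant_quality")[:]
        return lambda i: format_float(qual[i])
    if ph == "FILTER":
        filt = store.arr("variant_filter")[:]
        ids = store.filter_ids

        def render_filter(i):
            names = [ids[j] for j in np.nonzero(filt[i])[0]]
            return ";".join(names) if names else STR_MISSING

        return render_filter
    assert ph.startswith("INFO/")
    return _info_renderer(store, ph.split("/", 1)[1])


def _info_renderer(store: VczStore, key: str):
    name = f"variant_{key}"
    if not store.has(name):
        raise QueryError(f"unknown INFO field {key!r}")
    arr = store.arr(name)
    vals = arr[:]
    kind = vals.dtype.kind

    def render(i):
        v = vals[i]
        if kind == "b":
            return "1" if v else "0"
        if v.ndim if hasattr(v, "ndim") else False:
            pass
        if np.ndim(v) == 1:
            toks = _strip_row(
                v, *_sentinels_for_kind(kind), is_float=(kind == "f")
            )
            return ",".join(toks) if toks else STR_MISSING
        if kind == "f":
            return format_float(v)
        if kind in ("U", "T", "O"):
            return str(v) if str(v) != STR_FILL else STR_MISSING
        return STR_MISSING if v == INT_MISSING else str(v)

    return render


def _sentinels_for_kind(kind):
    if kind == "f":
        from .vcz_schema import FLOAT32_FILL, FLOAT32_MISSING

        return FLOAT32_MISSING, FLOAT32_FILL
    if kind in ("U", "T", "O"):
        return STR_MISSING, STR_FILL
    return INT_MISSING, INT_FILL


# ----------------------------------------------------------------------
# view (VCF text regeneration)
# ----------------------------------------------------------------------

def _selection(store, regions, include, mask):
    if regions is not None:
        sel = resolve_regions(store, regions)
    else:
        sel = np.arange(store.n_variants, dtype="int64")
    if include is not None:
        keep = evaluate_include_expression(include, store, sel)
        sel = sel[keep]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != store.n_variants:
            raise QueryError("site mask length must equal the variant count")
        sel = sel[mask[sel]]
    return sel


def _rewrite_header(header_text: str, samples: list[str]) -> str:
    lines = [l for l in header_text.rstrip("\n").split("\n") if l]
    out = []
    for line in lines:
        if line.startswith("#CHROM"):
            cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
            if samples:
                cols += ["FORMAT"] + samples
            out.append("\t".join(cols))
        else:
            out.append(line)
    return "\n".join(out)


class _RecordRenderer:
    def __init__(self, store: VczStore, sample_idx: np.ndarray):
        self.store = store
        self.sample_idx = sample_idx
        self.contig_ids = store.contig_ids
        self.filter_ids = store.filter_ids
        self.info_order = list(store.attrs.get("info_order", []))
        self.format_order = list(store.attrs.get("format_order", []))
        self.vc = store.variant_chunk_size
        self._chunk = -1
        self._data: dict[str, np.ndarray] = {}
        self.has_end = "END" in self.info_order

    def _load_chunk(self, chunk: int):
        if chunk == self._chunk:
            return
        store = self.store
        lo, hi = chunk * self.vc, min((chunk + 1) * self.vc, store.n_variants)
        d = {}
        for name in ("variant_position", "variant_contig", "variant_allele",
                     "variant_id", "variant_quality", "variant_filter",
                     "variant_length"):
            d[name] = store.arr(name)[lo:hi]
        for key in self.info_order:
            name = f"variant_{key}"
            if store.has(name):
                d[name] = store.arr(name)[lo:hi]
        for key in self.format_order:
            if key == "GT":
                if store.has("call_genotype"):
                    d["call_genotype"] = store.arr("call_genotype")[lo:hi][:, self.sample_idx]
                    d["call_genotype_phased"] = store.arr("call_genotype_phased")[lo:hi][:, self.sample_idx]
                continue
            for name in (f"call_{key}", f"call_L{key}"):
                if store.has(name):
                    d[name] = store.arr(name)[lo:hi][:, self.sample_idx]
                    break
        if store.has("call_LA"):
            d["call_LA"] = store.arr("call_LA")[lo:hi][:, self.sample_idx]
        self._data = d
        self._lo = lo
        self._chunk = chunk

    def line(self, i: int) -> str:
        self._load_chunk(i // self.vc)
        d = self._data
        k = i - self._lo
        pos = int(d["variant_position"][k])
        alleles = [str(a) for a in d["variant_allele"][k]]
        ref = alleles[0]
        alts = [a for a in alleles[1:] if a != STR_FILL]
        n_alleles = 1 + len(alts)
        vid = str(d["variant_id"][k])
        qual = format_float(d["variant_quality"][k])
        filt_names = [self.filter_ids[j] for j in np.nonzero(d["variant_filter"][k])[0]]
        cols = [
            self.contig_ids[int(d["variant_contig"][k])],
            str(pos),
            vid if vid else STR_MISSING,
            ref,
            ",".join(alts) if alts else STR_MISSING,
            qual,
            ";".join(filt_names) if filt_names else STR_MISSING,
            self._info_column(k, pos, ref),
        ]
        fmt_col, sample_cols = self._format_columns(k, n_alleles)
        if fmt_col is not None:
            cols.append(fmt_col)
            cols.extend(sample_cols)
        return "\t".join(cols)

    def _info_column(self, k, pos, ref) -> str:
        d = self._data
        items = []
        for key in self.info_order:
            if key == "END":
                end = pos + int(d["variant_length"][k]) - 1
                if end != pos + len(ref) - 1:
                    items.append(f"END={end}")
                continue
            name = f"variant_{key}"
            if name not in d:
                continue
            v = d[name][k]
            kind = d[name].dtype.kind
            if kind == "b":
                if bool(v):
                    items.append(key)
                continue
            if np.ndim(v) == 1:
                toks = _strip_row(v, *_sentinels_for_kind(kind), is_float=(kind == "f"))
                if toks and not all(t == STR_MISSING for t in toks):
                    items.append(f"{key}={','.join(toks)}")
                continue
            if kind == "f":
                if not np.isnan(v):
                    items.append(f"{key}={format_float(v)}")
            elif kind in ("U", "T", "O"):
                if str(v) not in (STR_MISSING, STR_FILL):
                    items.append(f"{key}={v}")
            else:
                if v != INT_MISSING and v != INT_FILL:
                    items.append(f"{key}={int(v)}")
        return ";".join(items) if items else STR_MISSING

    def _format_columns(self, k, n_alleles):
        d = self._data
        n_out = len(self.sample_idx)
        keys = []
        per_key_text: dict[str, list[str]] = {}

        for key in self.format_order:
            if key == "GT":
                if "call_genotype" not in d:
                    continue
                gt = d["call_genotype"][k]
                phased = d["call_genotype_phased"][k]
                texts = []
                for j in range(n_out):
                    row = [a for a in gt[j] if a != INT_FILL]
                    if not row:
                        texts.append(STR_MISSING)
                        continue
                    toks = [STR_MISSING if a == INT_MISSING else str(int(a)) for a in row]
                    sep = "|" if phased[j] and len(toks) > 1 else "/"
                    texts.append(sep.join(toks))
                keys.append("GT")
                per_key_text["GT"] = texts
                continue

            name = f"call_{key}"
            localized = name not in d and f"call_L{key}" in d
            if localized:
                texts = self._localized_texts(k, key, n_alleles)
            elif name in d:
                texts = self._plain_texts(d[name][k], d[name].dtype.kind)
            else:
                continue
            if any(t != STR_MISSING for t in texts):
                keys.append(key)
                per_key_text[key] = texts

        if not keys:
            if not self.format_order or n_out == 0:
                return None, []
            return STR_MISSING, [STR_MISSING] * n_out
        sample_cols = [
            ":".join(per_key_text[key][j] for key in keys) for j in range(n_out)
        ]
        return ":".join(keys), sample_cols

    def _plain_texts(self, block, kind):
        texts = []
        for row in np.atleast_1d(block):
            if np.ndim(row) == 0:
                row = [row]
            toks = _strip_row(row, *_sentinels_for_kind(kind), is_float=(kind == "f"))
            if not toks or all(t == STR_MISSING for t in toks):
                texts.append(STR_MISSING)
            else:
                texts.append(",".join(toks))
        return texts

    def _localized_texts(self, k, key, n_alleles):
        """Decode call_L<key> back to global-width text via call_LA."""
        d = self._data
        la = d["call_LA"][k]
        lv = d[f"call_L{key}"][k]
        kind = d[f"call_L{key}"].dtype.kind
        number = "G" if self._is_g_field(key) else "R"
        missing, fill = _sentinels_for_kind(kind)
        texts = []
        for j in range(la.shape[0]):
            if number == "R":
                row = reconstruct_r_entries(la[j], lv[j], n_alleles, missing=missing)
            else:
                row = reconstruct_g_entries(la[j], lv[j], n_alleles, la.shape[-1],
                                            missing=missing)
            toks = [
                STR_MISSING
                if (kind == "f" and np.isnan(v)) or (kind != "f" and v == missing)
                else (_fmt_value(v, kind) if not (kind != "f" and v == fill) else STR_MISSING)
                for v in row
            ]
            if all(t == STR_MISSING for t in toks):
                texts.append(STR_MISSING)
            else:
                texts.append(",".join(toks))
        return texts

    def _is_g_field(self, key) -> bool:
        arr = self._data.get(f"call_L{key}")
        if arr is None:
            return False
        attrs_number = None
        try:
            attrs_number = self.store.arr(f"call_L{key}").attrs.get("vcf_number")
        except KeyError:
            pass
        return attrs_number == "G"


def render_vcf(store: VczStore, regions=None, samples=None, include=None,
               mask=None, header: bool = True):
    """Yield VCF text lines (no trailing newline) for the selection.

    The header is reproduced from the stored original, with the #CHROM line
    rewritten when a sample subset is requested. Records re-parse to values
    identical to the stored arrays (semantic round trip); fill sentinels
    are stripped and missing values render as ``.``.
    """
    all_samples = store.samples if store.has("sample_id") else []
    if samples is None:
        sample_idx = np.arange(len(all_samples))
        out_samples = all_samples
    else:
        out_samples = list(samples)
        missing = [s for s in out_samples if s not in all_samples]
        if missing:
            raise QueryError(f"samples not in store: {missing}")
        sample_idx = np.array([all_samples.index(s) for s in out_samples], dtype=int)
    if not store.has("call_genotype") and not store.attrs.get("format_order"):
        # site-only store
        sample_idx = np.array([], dtype=int)
        out_samples = []

    if header:
        yield from _rewrite_header(store.attrs["vcf_header"], out_samples).split("\n")
    sel = _selection(store, regions, include, mask)
    renderer = _RecordRenderer(store, sample_idx)
    for i in sel:
        yield renderer.line(int(i))
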