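"""Round-trip verification helpers.

Semantic equality here means: parse both VCF documents with the same
extraction layer and compare the canonical per-record values, after the
normalizations implied by the array representation's two documented
corner cases (a present-but-missing field is indistinguishable from an
absent one) plus cosmetic ones (FILTER order, haploid phasing flags,
float32 text formatting).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .encoder import encode
from .icf import ABSENT, explode, read_vcf_records
from .query_view import render_vcf


class RoundTripError(AssertionError):
    pass


def _norm_float(v):
    return None if v is None else float(np.float32(v))


def _norm_numeric(v, is_float):
    if v is None:
        return None
    if isinstance(v, tuple):
        return tuple(_norm_numeric(x, is_float) for x in v)
    return _norm_float(v) if is_float else v


def normalize_record(rec: dict) -> dict:
    """Canonicalize a record dict for comparison."""
    out = {}
    for name, v in rec.items():
        if name == "FILTER":
            out[name] = frozenset(v)
            continue
        if name == "QUAL":
            out[name] = _norm_float(v)
            continue
        if name == "FORMAT/GT":
            if v is ABSENT or all(all(a is None for a in alleles) for alleles, _ in v):
                out[name] = ABSENT
            else:
                out[name] = [
                    (alleles, phased if len(alleles) > 1 else False)
                    for alleles, phased in v
                ]
            continue
        if name.startswith("FORMAT/"):
            if v is ABSENT or all(s is None for s in v):
                out[name] = ABSENT
            else:
                out[name] = [_norm_numeric(s, _looks_float(s)) for s in v]
            continue
        if name.startswith("INFO/"):
            out[name] = ABSENT if v is None or v is ABSENT else _norm_numeric(v, _looks_float(v))
            continue
        out[name] = v
    return out


def _looks_float(v):
    if isinstance(v, tuple):
        return any(isinstance(x, float) for x in v)
    return isinstance(v, float)


def compare_vcf_files(a_path, b_path) -> list[str]:
    """Field-by-field comparison; returns a list of human-readable
    discrepancies (empty when the files are semantically equal)."""
    problems = []
    a_records = [normalize_record(r) for r in read_vcf_records(a_path)]
    b_records = [normalize_record(r) for r in read_vcf_records(b_path)]
    if len(a_records) != len(b_records):
        return [f"record count differs: {len(a_records)} vs {len(b_records)}"]
    for i, (ra, rb) in enumerate(zip(a_records, b_records)):
        keys = set(ra) | set(rb)
        for key in sorted(keys):
            va, vb = ra.get(key, ABSENT), rb.get(key, ABSENT)
            if not _values_equal(va, vb):
                problems.append(
                    f"record {i} ({ra.get('CHROM')}:{ra.get('POS')}) field {key}: "
                    f"{va!r} != {vb!r}"
                )
    return problems


def _values_equal(a, b) -> bool:
    if a is ABSENT or b is ABSENT:
        return a is b
    if isinstance(a, float) and isinstance(b, float):
        return (math.isnan(a) and math.isnan(b)) or a == b
    if isinstance(a, (tuple, list)) and isinstance(b, (tuple, list)):
        return len(a) == len(b) and all(_values_equal(x, y) for x, y in zip(a, b))
    return a == b


def round_trip(vcf_path, workdir, *, local_alleles: bool = False,
               variant_chunk: int = 10_000, sample_chunk: int = 1_000) -> Path:
    """explode -> encode -> render back to VCF text; returns the output path."""
    from .vcz_schema import generate_schema

    workdir = Path(workdir)
    icf = explode([vcf_path], workdir / "staging.icf")
    schema = generate_schema(
        icf, variant_chunk=variant_chunk, sample_chunk=sample_chunk,
        local_alleles=local_alleles,
    )
    store = encode(icf, workdir / "store.vcz", schema=schema)
    out = workdir / "rendered.vcf"
    with open(out, "w") as f:
        for line in render_vcf(store):
            f.write(line + "\n")
    return out


def assert_round_trip(vcf_path, workdir, **kwargs) -> None:
    out = round_trip(vcf_path, workdir, **kwargs)
    problems = compare_vcf_files(vcf_path, out)
    if problems:
        raise RoundTripError(
            f"{vcf_path}: round trip not semantically equal:\n" + "\n".join(problems[:20])
        )
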