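"""Deterministic synthetic-VCF generation covering the full data model.

The generator emulates the structural variety of real cohort VCFs —
multiallelic sites, mixed ploidy, sparse FORMAT fields, INFO fields of
every Number/Type class — without population-genetic realism (no linkage,
no demography). Genotypes are drawn under Hardy–Weinberg equilibrium from
per-site allele frequencies with a U-shaped Beta(0.5, 0.5) distribution,
the shape typical of cohort site-frequency spectra. AD and PL are kept
consistent with the genotype call: reads are apportioned to called
alleles and PL is zero at the called genotype.

All randomness flows from a single counter-based Philox generator seeded
by ``FixtureConfig.seed``, so a given config is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np

_BASES = "ACGT"
_ALT_MENU = ["A", "C", "G", "T", "AA", "CC", "GG", "TT", "AC", "GT"]


@dataclasses.dataclass
class FixtureConfig:
    n_variants: int = 100
    n_samples: int = 10
    seed: int = 42
    contigs: tuple[tuple[str, int], ...] = (("1", 10_000_000), ("2", 8_000_000))
    multiallelic_fraction: float = 0.1
    max_alt: int = 3
    af_beta: tuple[float, float] = (0.5, 0.5)
    gt_missing_rate: float = 0.05
    field_missing_rate: float = 0.05
    info_absent_rate: float = 0.1
    haploid_rate: float = 0.0
    phased_rate: float = 0.3
    fields: tuple[str, ...] = ("GT", "GQ", "DP", "AD", "PL", "FT", "NS", "AF", "DB", "STR")

    def __post_init__(self):
        for rate in (self.multiallelic_fraction, self.gt_missing_rate,
                     self.field_missing_rate, self.info_absent_rate,
                     self.haploid_rate, self.phased_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.n_variants < 0 or self.n_samples < 0:
            raise ValueError("n_variants and n_samples must be >= 0")

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contigs"] = [list(c) for c in self.contigs]
        return d

    @classmethod
    def fromdict(cls, d: dict) -> "FixtureConfig":
        d = dict(d)
        if "contigs" in d:
            d["contigs"] = tuple((c, int(l)) for c, l in d["contigs"])
        for k in ("fields", "af_beta"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


_HEADER_DEFS = {
    "NS": '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">',
    "AF": '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
    "DB": '##INFO=<ID=DB,Number=0,Type=Flag,Description="Membership in a reference database">',
    "STR": '##INFO=<ID=STR,Number=.,Type=String,Description="Free-form annotations">',
    "END": '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    "GT": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "GQ": '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    "DP": '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    "AD": '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">',
    "PL": '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
    "FT": '##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-sample filter">',
}

_INFO_KEYS = ("NS", "AF", "DB", "STR", "END")
_FORMAT_KEYS = ("GT", "GQ", "DP", "AD", "PL", "FT")


def _header(config: FixtureConfig, extra_defs=()) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=vczkit-fixtures"]
    for contig, length in config.contigs:
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append('##FILTER=<ID=q10,Description="Quality below 10">')
    for key in _INFO_KEYS:
        if key in config.fields:
            lines.append(_HEADER_DEFS[key])
    for key in _FORMAT_KEYS:
        if key in config.fields:
            lines.append(_HEADER_DEFS[key])
    lines.extend(extra_defs)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if config.n_samples and "GT" in config.fields:
        cols += ["FORMAT"] + [f"s{i}" for i in range(config.n_samples)]
    elif config.n_samples and any(k in config.fields for k in _FORMAT_KEYS):
        cols += ["FORMAT"] + [f"s{i}" for i in range(config.n_samples)]
    lines.append("\t".join(cols))
    return lines


def _g_index(j: int, k: int) -> int:
    return k * (k + 1) // 2 + j


def _site_alleles(rng, config):
    ref = _BASES[rng.integers(0, 4)]
    if rng.random() < config.multiallelic_fraction and config.max_alt > 1:
        n_alt = int(rng.integers(2, config.max_alt + 1))
    else:
        n_alt = 1
    alts = []
    for cand in rng.permutation(len(_ALT_MENU)):
        a = _ALT_MENU[cand]
        if a != ref and a not in alts:
            alts.append(a)
        if len(alts) == n_alt:
            break
    return ref, alts


def _sample_call(rng, config, freqs):
    """Draw one call: (allele index list or None, phased)."""
    if rng.random() < config.gt_missing_rate:
        return None, False
    ploidy = 1 if rng.random() < config.haploid_rate else 2
    alleles = [int(rng.choice(len(freqs), p=freqs)) for _ in range(ploidy)]
    phased = ploidy > 1 and rng.random() < config.phased_rate
    return alleles, phased


def _format_record(rng, config, contig, pos, freqs, ref, alts):
    n_alleles = 1 + len(alts)
    calls = [_sample_call(rng, config, freqs) for _ in range(config.n_samples)]

    def missing():
        return rng.random() < config.field_missing_rate

    fmt_values: dict[str, list[str]] = {}
    if "GT" in config.fields:
        toks = []
        for alleles, phased in calls:
            if alleles is None:
                toks.append("./.")
            else:
                sep = "|" if phased else "/"
                toks.append(sep.join(str(a) for a in alleles))
        fmt_values["GT"] = toks
    depths = []
    for alleles, _ in calls:
        depths.append(int(rng.poisson(30)) + 2)
    if "DP" in config.fields:
        fmt_values["DP"] = [
            "." if missing() or c[0] is None else str(d)
            for c, d in zip(calls, depths)
        ]
    if "GQ" in config.fields:
        fmt_values["GQ"] = [
            "." if missing() or c[0] is None else str(int(rng.integers(0, 100)))
            for c in calls
        ]
    if "AD" in config.fields:
        toks = []
        for (alleles, _), depth in zip(calls, depths):
            if alleles is None or missing():
                toks.append(".")
                continue
            ad = [0] * n_alleles
            for a in alleles:
                ad[a] += depth // len(alleles)
            toks.append(",".join(str(x) for x in ad))
        fmt_values["AD"] = toks
    if "PL" in config.fields:
        toks = []
        for alleles, _ in calls:
            if alleles is None or len(alleles) != 2 or missing():
                toks.append(".")
                continue
            width = n_alleles * (n_alleles + 1) // 2
            pl = [int(rng.integers(20, 255)) for _ in range(width)]
            j, k = sorted(alleles)
            pl[_g_index(j, k)] = 0
            toks.append(",".join(str(x) for x in pl))
        fmt_values["PL"] = toks
    if "FT" in config.fields:
        fmt_values["FT"] = [
            "." if missing() or c[0] is None
            else ("PASS" if rng.random() < 0.8 else "q10")
            for c in calls
        ]

    info_items = []
    absent = lambda: rng.random() < config.info_absent_rate  # noqa: E731
    if "NS" in config.fields and not absent():
        ns = sum(1 for c in calls if c[0] is not None)
        info_items.append(f"NS={ns}")
    if "AF" in config.fields and not absent():
        info_items.append("AF=" + ",".join(f"{f:.4g}" for f in freqs[1:]))
    if "DB" in config.fields and rng.random() < 0.2:
        info_items.append("DB")
    if "STR" in config.fields and not absent():
        k = int(rng.integers(1, 4))
        words = ["alpha", "beta", "gamma", "delta"]
        info_items.append("STR=" + ",".join(words[int(w)] for w in rng.integers(0, 4, k)))

    vid = f"rs{pos}" if rng.random() < 0.3 else "."
    qual = "." if rng.random() < 0.1 else f"{rng.uniform(1, 100):.1f}"
    filt = "PASS" if rng.random() < 0.8 else "q10"
    cols = [contig, str(pos), vid, ref, ",".join(alts) if alts else ".",
            qual, filt, ";".join(info_items) if info_items else "."]
    if fmt_values:
        keys = [k for k in _FORMAT_KEYS if k in fmt_values]
        cols.append(":".join(keys))
        for j in range(config.n_samples):
            cols.append(":".join(fmt_values[k][j] for k in keys))
    return "\t".join(cols)


def generate_vcf(config: FixtureConfig) -> str:
    """Render a complete, parseable VCF document for the configuration."""
    rng = np.random.Generator(np.random.Philox(config.seed))
    lines = _header(config)
    n_contigs = len(config.contigs)
    per_contig = [
        config.n_variants // n_contigs + (1 if i < config.n_variants % n_contigs else 0)
        for i in range(n_contigs)
    ]
    a, b = config.af_beta
    for (contig, length), n_c in zip(config.contigs, per_contig):
        if n_c == 0:
            continue
        max_gap = max(1, min(100, length // (n_c + 1)))
        gaps = rng.integers(1, max_gap + 1, size=n_c)
        positions = np.cumsum(gaps)
        for pos in positions:
            ref, alts = _site_alleles(rng, config)
            p_alt = rng.beta(a, b)
            if len(alts) == 1:
                freqs = np.array([1 - p_alt, p_alt])
            else:
                split = rng.dirichlet([1.0] * len(alts)) * p_alt
                freqs = np.concatenate([[1 - p_alt], split])
            freqs = freqs / freqs.sum()
            lines.append(
                _format_record(rng, config, contig, int(pos), freqs, ref, alts)
            )
    return "\n".join(lines) + "\n"


def write_vcf(config: FixtureConfig, path, *, index: bool = False) -> str:
    """Write the fixture VCF; with ``index=True`` produce bgzipped + tabixed
    output (path should end in .vcf.gz)."""
    import pysam

    path = str(path)
    text = generate_vcf(config)
    if index or path.endswith(".gz"):
        plain = path[:-3] if path.endswith(".gz") else path
        Path(plain).write_text(text)
        pysam.tabix_compress(plain, path, force=True)
        Path(plain).unlink()
        if index:
            pysam.tabix_index(path, preset="vcf", force=True)
    else:
        Path(path).write_text(text)
    return path


# ----------------------------------------------------------------------
# Edge cases
# ----------------------------------------------------------------------

def edge_case_suite() -> dict[str, str]:
    """Small hand-built VCFs targeting the representation's corner cases.

    The ``negative_one_integer`` file must be *rejected* at explode (its
    value collides with the missing sentinel); every other file must
    survive the full round trip, with ``declared_unused`` encoding to an
    all-missing array.
    """
    base = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1,length=1000000>",
        '##FILTER=<ID=q10,Description="Quality below 10">',
        _HEADER_DEFS["GT"],
    ]
    chrom_line = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1"

    def doc(extra_header, records):
        return "\n".join(base + extra_header + [chrom_line] + records) + "\n"

    suite = {}
    suite["declared_unused"] = doc(
        [_HEADER_DEFS["GQ"], '##FORMAT=<ID=ZZ,Number=1,Type=Integer,Description="Declared but never used">'],
        [
            "1\t100\t.\tA\tT\t30\tPASS\t.\tGT:GQ\t0/1:12\t1/1:99",
            "1\t200\t.\tC\tG\t40\tPASS\t.\tGT:GQ\t0/0:7\t0/1:55",
        ],
    )
    suite["alt_dot"] = doc(
        [],
        [
            "1\t100\t.\tA\t.\t30\tPASS\t.\tGT\t0/0\t0/0",
            "1\t200\t.\tC\tG\t20\tPASS\t.\tGT\t0/1\t1/1",
        ],
    )
    suite["haploid_in_diploid"] = doc(
        [_HEADER_DEFS["GQ"]],
        [
            "1\t100\t.\tA\tT\t30\tPASS\t.\tGT:GQ\t0/1:12\t1:44",
            "1\t200\t.\tC\tG\t20\tPASS\t.\tGT:GQ\t1:9\t.:.",
        ],
    )
    suite["all_missing_format"] = doc(
        [_HEADER_DEFS["GQ"]],
        [
            "1\t100\t.\tA\tT\t30\tPASS\t.\tGT:GQ\t0/1:.\t1/1:.",
            "1\t200\t.\tC\tG\t20\tPASS\t.\tGT:GQ\t0/0:.\t0/1:.",
        ],
    )
    suite["negative_one_integer"] = doc(
        ['##INFO=<ID=NEG,Number=1,Type=Integer,Description="Contains a sentinel-colliding value">'],
        [
            "1\t100\t.\tA\tT\t30\tPASS\tNEG=-1\tGT\t0/1\t1/1",
        ],
    )
    pl_width = 7 * 8 // 2
    pl = ["37"] * pl_width
    pl[0] = "0"
    suite["max_alleles"] = doc(
        [_HEADER_DEFS["AD"], _HEADER_DEFS["PL"]],
        [
            "1\t100\t.\tA\tC,G,T,AA,CC,GG\t60\tPASS\t.\tGT:AD:PL\t"
            "0/0:10,0,0,0,0,0,0:" + ",".join(pl) + "\t2/5:0,0,5,0,0,7,0:" + ",".join(pl),
            "1\t200\t.\tC\tG\t20\tPASS\t.\tGT:AD:PL\t0/1:3,4:20,0,31\t1/1:0,9:44,25,0",
        ],
    )
    suite["spanning_deletion_end"] = doc(
        [_HEADER_DEFS["END"]],
        [
            "1\t95\t.\tACGTACGTAC\tA\t50\tPASS\t.\tGT\t0/1\t0/0",
            "1\t120\t.\tG\t<DEL>\t50\tPASS\tEND=180\tGT\t0/1\t0/0",
            "1\t300\t.\tT\tA\t50\tPASS\t.\tGT\t1/1\t0/1",
        ],
    )
    suite["info_missing_dot"] = doc(
        [_HEADER_DEFS["NS"]],
        [
            "1\t100\t.\tA\tT\t30\tPASS\tNS=.\tGT\t0/1\t1/1",
            "1\t200\t.\tC\tG\t20\tPASS\tNS=2\tGT\t0/0\t0/1",
        ],
    )
    return suite


def write_edge_case_suite(outdir) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, text in edge_case_suite().items():
        p = outdir / f"{name}.vcf"
        p.write_text(text)
        paths.append(str(p))
    return paths


# ----------------------------------------------------------------------
# Parameter grid
# ----------------------------------------------------------------------

def fixture_grid(n: int = 200, base_seed: int = 20_000) -> list[FixtureConfig]:
    """Deterministic list of configs spanning the generator's parameters."""
    combos = list(
        itertools.product(
            (1, 2, 5),  # n_samples
            (0.0, 0.2, 0.5),  # multiallelic fraction
            (0.0, 0.1, 0.3),  # missingness
            (0.0, 0.15),  # haploid rate
            (0.0, 0.5, 1.0),  # phased rate
            (
                ("GT", "GQ", "DP", "AD", "PL", "FT", "NS", "AF", "DB", "STR"),
                ("GT", "GQ", "AF"),
                ("GT", "AD", "PL", "STR"),
            ),
        )
    )
    # deterministic shuffle so any prefix of the grid spans every axis
    order = np.random.Generator(np.random.Philox(base_seed)).permutation(len(combos))
    axes = itertools.cycle(combos[i] for i in order)
    configs = []
    for i, (ns, multi, miss, haploid, phased, fields) in zip(range(n), axes):
        configs.append(
            FixtureConfig(
                n_variants=8 + (i % 4) * 8,
                n_samples=ns,
                seed=base_seed + i,
                multiallelic_fraction=multi,
                gt_missing_rate=miss,
                field_missing_rate=miss,
                haploid_rate=haploid,
                phased_rate=phased,
                fields=fields,
            )
        )
    return configs


def load_config(path) -> FixtureConfig:
    return FixtureConfig.fromdict(json.loads(Path(path).read_text()))
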