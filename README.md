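# vczkit

Lossless conversion of VCF into a chunked, columnar Zarr store — plus the
read side: a genomic region index, bcftools-style `query`/`view` over the
arrays, local-alleles data reduction for multiallelic cohorts, and
chunkwise genotype statistics.

## Why

VCF stores a cohort row by row: every record interleaves positions,
alleles, QC fields and one column per sample. Reading a single field (say,
every variant's position, or one sample's genotypes) means decompressing
the entire file. vczkit decouples the VCF **data model** from that
row-wise encoding: every field becomes its own typed n-dimensional array —
`variant_position (variants,)`, `call_genotype (variants, samples,
ploidy)`, `call_AD (variants, samples, alleles)` — split into a uniform
grid of independently compressed chunks (Zstandard, with a bit-shuffle
pre-filter for genotypes and booleans). Analyses then read only the
arrays and chunks they touch, and the chunk is a natural unit of
parallelism.

Two sentinel values keep the mapping lossless. Array dimensions are global
maxima over the dataset, so a biallelic row inside a triallelic dataset is
padded with a *fill* sentinel (−2 for integers, a dedicated quiet NaN for
floats, `""` for strings), distinct from the *missing* sentinel for values
written as `.` in the source (−1 / another quiet NaN / `.`). The only
information the representation drops is the distinction between an absent
field and a present-but-missing one, and integer fields that literally
contain −1/−2 are rejected at conversion with advice to store them as
floats.

For heavily multiallelic data, Number=R and Number=G FORMAT fields (AD,
PL) blow up with the site-wide allele count — quadratically for PL, whose
inner dimension is C(A+1, 2) for A alleles and ploidy 2. The
**local-alleles** encoding stores per call the sorted allele indexes the
genotype actually observes (`call_LA`) and rewrites AD/PL in those terms
(`call_LAD`, `call_LPL`), shrinking the inner dimension to the ploidy
(resp. ploidy·(ploidy+1)/2) while keeping every genotype-referenced value
exactly.

## Worked example

Conversion is two-stage (mirroring the `explode`/`encode` CLI): stage 1
parses the VCF into per-field compressed columns and gathers the value
extrema and arities that decide integer widths and array shapes; stage 2
fills the typed arrays chunk by chunk.

```python
from vczkit import explode, generate_schema, encode
from vczkit.fixtures import FixtureConfig, write_vcf

vcf = write_vcf(FixtureConfig(n_variants=2000, n_samples=20, seed=42,
                              multiallelic_fraction=0.2), "cohort.vcf")
icf = explode([vcf], "cohort.icf")
store = encode(icf, "cohort.vcz",
               schema=generate_schema(icf, variant_chunk=500, sample_chunk=10))
```

`python examples/convert_and_inspect.py` runs exactly this and prints (excerpt):

```
input: 2000 variants x 20 samples (1381 KiB of VCF text)

array                        dtype            shape         stored  ratio
call_AD                      int8             (2000, 20, 4)  46.5Ki    3.4
call_PL                      int16            (2000, 20, 10) 175.5Ki   4.5
call_genotype                int8             (2000, 20, 2)  14.2Ki    5.5
call_genotype_mask           bool             (2000, 20, 2)   2.9Ki   26.9
variant_position             int32            (2000,)         3.6Ki    2.2
...
total store: 355 KiB (vs 1381 KiB VCF text)
```

Each field got the narrowest integer width its observed values allow
(`call_AD` fits int8 here; `call_PL` needs int16), the `ratio` column is
uncompressed array bytes over stored bytes, and `call_PL`'s inner
dimension is 10 because one site reached 4 alleles: C(5,2) = 10 unordered
diploid genotypes. Re-rendering the store with `render_vcf` reproduces a
VCF that parses field-for-field equal to the input.

The read side works from the store alone:

```python
from vczkit import VczStore, resolve_regions, evaluate_include_expression
from vczkit.stats import af_dist

store = VczStore.open("cohort.vcz")
idx = resolve_regions(store, ["1:1000-5000"])            # region-index lookup
mask = evaluate_include_expression("FORMAT/DP>10 & FORMAT/GQ>20", store)
table = af_dist(store)                                    # HWE probability bins
```

`af_dist` bins every called genotype by its Hardy–Weinberg probability
given the site's observed allele frequency — ten equal bins whose counts
expose departures from HWE — streaming the genotype matrix one chunk at a
time.

Equivalent shell commands: `vczkit explode cohort.vcf cohort.icf`,
`vczkit mkschema cohort.icf > schema.json`, `vczkit encode cohort.icf
cohort.vcz --schema schema.json`, `vczkit query -f '%POS\n' cohort.vcz`,
`vczkit view cohort.vcz -r 1:1000-5000 -i 'FORMAT/GQ>20'`, `vczkit stats
af-dist cohort.vcz`. The distributed trios (`dexplode-init/partition/
finalise`, `dencode-*`) run the same stages as independent, retryable
jobs over a shared directory. The other `examples/*.py` scripts cover
local alleles, queries, af-dist and the lossy float filters.

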