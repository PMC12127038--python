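# Methods

## Data model

The converter maps each VCF field to one named, typed array. FORMAT fields
become `call_<KEY>` with leading dimensions `(variants, samples)`; INFO and
fixed fields become `variant_<KEY>` with leading dimension `(variants,)`.
The trailing dimension follows the header's Number declaration: absent for
Number 0/1, `alt_alleles` (max alleles − 1) for A, `alleles` for R,
`genotypes` (C(A+p−1, p) for A alleles, ploidy p) for G, the observed
maximum count for `.`, and the declared arity for fixed integers. GT
expands into `call_genotype` (allele indexes), `call_genotype_phased` and
`call_genotype_mask`. Structural arrays (`variant_position`,
`variant_contig` indexing `contig_id`, the `variant_allele` matrix,
`variant_filter` over `filter_id`, `variant_id` + mask, `variant_quality`,
`sample_id`, `contig_length`) complete the store, and the original header
text is kept as a store attribute so `view` can reproduce it.

All dimensions are global and fixed: extents are dataset-wide maxima, so
rows below the maximum are padded. Two sentinels make padding reversible:

| dtype   | missing (`.` in source) | fill (padding only)    |
|---------|-------------------------|------------------------|
| integer | −1                      | −2                     |
| float32 | NaN, payload 0x7FC00001 | NaN, payload 0x7FC00002 |
| string  | `"."`                   | `""`                   |

The float sentinels are quiet NaNs chosen by this package; they are
compared bitwise, survive blosc/zstd round trips, and pass through the
lossy filters untouched. Booleans carry no sentinels — missingness lives in
companion mask arrays. Integer fields take the narrowest signed width
covering both observed extrema and the sentinels; `variant_position` is
int32 unless a position exceeds 2³¹−1.

Two corner cases are inherent and documented rather than worked around: a
field that is absent from a record is indistinguishable from one present
with all values missing, and integer fields containing literal −1/−2 are
rejected at explode (store them as Float if they must be kept). One
further collapse is specific to this implementation: the htslib-based
parser folds INFO/END into the record's end coordinate, so END is stored
via the derived `variant_length` array (end − POS + 1) and re-emitted on
output only when it differs from POS + len(REF) − 1 — exactly the cases
where END carries information.

## Conversion pipeline

Stage 1 (**explode**) parses VCF through pysam into the intermediate
columnar format: one directory per field holding zstd-compressed pickled
value chunks of roughly 1 MiB decompressed (configurable), plus per-field
summaries (max per-record count, min/max value, presence counts, maximum
allele count and ploidy). The ICF layout is internal and versioned as
such. Indexed files can be split into genomic slices for parallel explode:
the header-declared contig coordinate space is divided evenly and each
slice fetches through the index, owning a record iff its POS falls inside
the slice — partitions are exact and disjoint, balanced only
approximately. Multi-file inputs must be ordered and non-overlapping
(checked at finalise from partition boundary coordinates); identical
sample lists are required, contigs and filters are unioned in order of
first appearance.

Stage 2 (**encode**) materializes the arrays per a JSON storage schema
generated from the ICF summaries (and hand-editable between `mkschema`
and `encode`). Memory is bounded by one variant-chunk per field. Default
chunks are 10,000 variants × 1,000 samples; the default codec is
Zstandard level 7 through blosc, with the bit-shuffle pre-filter only on
`call_genotype` and boolean arrays (their values occupy the low bits, so
grouping bit positions compresses far better) and no byte shuffle
anywhere. Output is Zarr v2 metadata (`.zarray`/`.zattrs`), written as a
directory tree or as an uncompressed-entry Zip archive of the identical
layout (deterministic entry order and timestamps). Both stages expose
init/partition/finalise trios that communicate only through the output
directory; partition outputs are written to a temporary name and renamed,
so a failed partition is simply re-run. Encoding is deterministic: a given
ICF + schema yields byte-identical stores regardless of how explode or
encode work was partitioned.

## Local alleles

`call_LA` lists, per call, the sorted unique non-negative allele indexes
in the genotype, fill-padded to the ploidy; it is derived from GT only, so
hom-ref and fully-missing calls stay distinguishable without consulting
genotypes. Number=R fields localize by index selection
(`out[j] = values[la[j]]`), Number=G fields (diploid only in this version;
higher ploidy is an error) by enumerating unordered pairs of local alleles
in canonical G order (pair (j, k), j ≤ k, at ordinal k(k+1)/2 + j).
Reconstruction inverts both exactly for every entry the genotype
references; entries for non-local alleles are the information deliberately
discarded. Note this means a homozygous call at a multiallelic site keeps
only its own allele's AD — full AD/PL round trips are exact precisely when
each call's genotype references every site allele. `call_genotype` keeps
global allele indexes; LA exists to decode LAD/LPL. Localization covers
Number=R and Number=G fields; Number=A fields stay global, since indexing
them by allele (REF included) is not well defined.

## Region index and queries

`region_index` holds one row per (variant chunk, contig present in it):
chunk ordinal, contig index, minimum and maximum POS, maximum end, record
count, where a record's end is INFO/END when carried, else
POS + len(REF) − 1. Interval resolution follows the 1-based inclusive,
END-aware overlap convention of the tabix/bcftools ecosystem (a spanning
deletion is selected by a region starting inside it); the index brackets
the chunks to read, and positions within each candidate chunk decide
membership. Building the index validates that positions are non-decreasing
within contigs. Filter expressions support numeric and string comparisons
on FORMAT/INFO scalars, POS and QUAL, combined with `&`, `|` and
parentheses; FORMAT comparisons are per sample, a conjunction over FORMAT
terms passes a site iff a single sample satisfies all of it, and any
comparison against a missing value is false. `view` regenerates VCF whose
*parsed* content equals the arrays — float text uses the shortest string
that round-trips at float32 precision, FILTER order follows `filter_id`,
INFO keys follow header order, and FORMAT keys are emitted only where some
sample carries data. Sample subsetting rewrites the `#CHROM` line; AC/AN/AF
recomputation on subset is out of scope.

## Statistics

`classify_genotypes` tallies hom-ref / het / hom-alt / missing (any −1
allele) / non-reference-ploidy (any −2) per variant; tallies sum to the
sample count. `allele_counts` counts called allele slots (AN) and per-
alternate occurrences (AC). `af_dist` restricts to sites with at most one
alternate allele (others counted as skipped, not collapsed), takes
p = AC/AN from the data (sites with AN = 0 skipped), and bins each
complete call's HWE probability — (1−p)² / 2p(1−p) / p² — into ten
half-open bins over [0, 1], the last closed. The per-call binning
definition is fixed by this package and conformance is against a
whole-matrix single-pass oracle, not any external tool's output text.
All three kernels stream variant chunks, so results are invariant to
chunking and memory stays bounded.

## Lossy float filters

`quantize_values(x, d)` rounds to the grid `2^-ceil(d·log2 10)` with ties
to even, so |error| ≤ 0.5·2^−ceil(d·log₂10); `bitround_values(x, k)`
rounds the float32 mantissa to k bits (k = 23 is the identity). Both match
the corresponding numcodecs filters bit for bit (cross-checked in tests)
and can be inserted into any float array's codec chain via a schema
override; both preserve non-finite values, including the sentinel
payloads. Mean absolute error is computed over pairs where both values are
finite, which excludes missing/fill slots pairwise.

## Synthetic data

The fixture generator emulates the structural variety the converter must
survive: multiallelic sites (fraction and maximum ALT count configurable),
mixed ploidy, per-call and per-field missingness, phased/unphased calls,
and INFO/FORMAT fields in every Number/Type class (integer, float, flag,
variable-length string). Genotypes are drawn under Hardy–Weinberg
equilibrium from per-site allele frequencies with a Beta(0.5, 0.5)
marginal — the U shape typical of cohort site-frequency spectra — split
across alternates by a flat Dirichlet at multiallelic sites. AD apportions
a Poisson(30) depth to called alleles and PL is zero at the called
genotype, so derived-field consistency can be asserted. All randomness
flows from one counter-based Philox generator per config seed; output is
byte-reproducible. What it does **not** emulate: linkage disequilibrium,
demography, realistic indel structure, or field correlations beyond
AD/PL-vs-GT — so green round-trip and kernel tests certify the *data
model and conversion machinery*, not population-genetic realism or
compression ratios on real cohorts. A hand-built edge-case suite covers
the corner cases: declared-but-unused fields (encode to all-missing
arrays), `.` ALT, haploid calls in diploid columns, all-missing FORMAT
fields, sentinel-colliding integers (must be rejected), a 6-ALT site
stressing the quadratic Number=G width, and an END-bearing symbolic
deletion.

## Numerical and scale choices

Verification sizes were chosen to exercise every code path on one CPU in
minutes: round-trip fidelity over a 200-config generator grid (8–32
variants, 1–5 samples each), oracle checks on a 1,000 × 100 store with
deliberately misaligned chunk sizes, determinism on a 10,000-variant
indexed fixture split four ways, and filter error bounds on 10⁶ uniform
values. Ties round to even throughout; bin membership uses half-open
intervals with the last bin closed; equality for floats is at float32
precision after parsing. Known limitations: BCF input is not parsed
directly (convert to VCF text first), Number=G localization is
diploid-only, per-sample loop placeholders (`[%GT ]`) and the full
bcftools expression language are not implemented, and stores are append-
only at the whole-array level.
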