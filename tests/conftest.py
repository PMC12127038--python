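import pytest

from vczkit import IcfStore, VczStore, encode, explode, generate_schema
from vczkit.fixtures import FixtureConfig, write_vcf

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##contig=<ID=X,length=500000>
##FILTER=<ID=q10,Description="low qual">
##INFO=<ID=NS,Number=1,Type=Integer,Description="Samples with data">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">
##INFO=<ID=STR,Number=.,Type=String,Description="Annotations">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Likelihoods">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\trs1\tA\tT,G\t30.5\tPASS\tNS=2;AF=0.5,0.1;DB;STR=foo,bar\tGT:GQ:AD:PL\t0|1:12:10,5,0:10,0,20,30,40,50\t1/2:.:.:.
1\t200\t.\tC\t.\t.\t.\tNS=2\tGT:GQ\t0:99\t./.
1\t300\t.\tCTTT\tC\t10\tq10\t.\tGT:AD\t1/1:0,7\t0/1:4,4
X\t7\t.\tG\tA\t5\tq10\tAF=0.25\tGT:GQ\t0/1:44\t0/0:7
"""


@pytest.fixture(scope="session")
def toy_vcf(tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture(scope="session")
def toy_icf(toy_vcf, tmp_path_factory):
    out = tmp_path_factory.mktemp("toy_icf") / "toy.icf"
    return explode([toy_vcf], out)


@pytest.fixture(scope="session")
def toy_store(toy_icf, tmp_path_factory):
    out = tmp_path_factory.mktemp("toy_vcz") / "toy.vcz"
    schema = generate_schema(toy_icf, variant_chunk=2, sample_chunk=2)
    return encode(toy_icf, out, schema=schema)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A 60-variant, 5-sample synthetic VCF with multiallelics and
    missingness; encoded with small chunks so chunk logic is exercised."""
    d = tmp_path_factory.mktemp("small")
    cfg = FixtureConfig(
        n_variants=60, n_samples=5, seed=101, multiallelic_fraction=0.3,
        gt_missing_rate=0.1, field_missing_rate=0.1, haploid_rate=0.05,
    )
    vcf = write_vcf(cfg, d / "f.vcf")
    icf = explode([vcf], d / "f.icf")
    schema = generate_schema(icf, variant_chunk=16, sample_chunk=3)
    store = encode(icf, d / "f.vcz", schema=schema)
    return {"config": cfg, "vcf": vcf, "icf": icf, "store": store, "dir": d}


@pytest.fixture(scope="session")
def stats_fixture(tmp_path_factory):
    """1,000 variants x 100 samples for chunkwise-vs-whole-matrix checks."""
    d = tmp_path_factory.mktemp("stats")
    cfg = FixtureConfig(
        n_variants=1000, n_samples=100, seed=202, multiallelic_fraction=0.15,
        gt_missing_rate=0.05, haploid_rate=0.02,
        fields=("GT", "GQ", "DP", "AF", "NS"),
    )
    vcf = write_vcf(cfg, d / "f.vcf")
    icf = explode([vcf], d / "f.icf")
    schema = generate_schema(icf, variant_chunk=128, sample_chunk=32)
    store = encode(icf, d / "f.vcz", schema=schema)
    return {"config": cfg, "vcf": vcf, "icf": icf, "store": store, "dir": d}
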