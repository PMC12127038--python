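"""Chunkwise Hardy–Weinberg genotype-probability distribution (af-dist).

Each called genotype at a biallelic site contributes its HWE probability —
(1-p)^2, 2p(1-p) or p^2 with p the site's observed alternate allele
frequency — to one of ten equal bins. Because the fixture draws genotypes
under HWE, mass should concentrate where HWE puts it: systematic excess
in unexpected bins would flag departures (e.g. genotyping error). The
table is accumulated one genotype chunk at a time, so the result is
independent of chunking and memory stays bounded.
"""

import tempfile
from pathlib import Path

from vczkit import encode, explode, generate_schema
from vczkit.stats import af_dist, allele_counts
from vczkit.fixtures import FixtureConfig, write_vcf

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cfg = FixtureConfig(n_variants=2000, n_samples=40, seed=17,
                        multiallelic_fraction=0.1)
    vcf = write_vcf(cfg, tmp / "f.vcf")
    icf = explode([vcf], tmp / "f.icf")
    store = encode(icf, tmp / "f.vcz",
                   schema=generate_schema(icf, variant_chunk=256, sample_chunk=16))

    an, ac = allele_counts(store)
    print(f"allele counts: {len(an)} sites, mean AN = {an.mean():.1f}")

    table = af_dist(store)
    print("\n" + table.to_tsv())
    print(f"\nskipped: {table.n_skipped_multiallelic} multiallelic sites, "
          f"{table.n_skipped_no_calls} sites without calls")
    print(f"total classified calls: {int(table.counts.sum())}")
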