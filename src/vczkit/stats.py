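"""Chunkwise analysis kernels over encoded stores.

All three operations — genotype classification, allele counts, and the
af-dist table — stream the genotype matrix one variant chunk at a time, so
memory stays bounded by a single chunk and the results are independent of
how the matrix is chunked.

af-dist bins every classified genotype call by its Hardy–Weinberg
probability given the site's observed alternate allele frequency
p = AC/AN: homozygous reference calls contribute (1-p)^2, heterozygotes
2p(1-p), homozygous alternate p^2. Ten equal-width half-open bins over
[0, 1] (the last closed) count the calls; systematic departures from HWE
show up as mass in unexpected bins.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .encoder import VczStore
from .vcz_schema import INT_FILL, INT_MISSING


@dataclasses.dataclass
class GenotypeClassCounts:
    """Per-variant genotype class tallies; columns sum to n_samples."""

    hom_ref: np.ndarray
    het: np.ndarray
    hom_alt: np.ndarray
    missing: np.ndarray
    other_ploidy: np.ndarray

    def __add__(self, other):
        return GenotypeClassCounts(
            *(np.concatenate([a, b]) for a, b in zip(
                dataclasses.astuple(self), dataclasses.astuple(other)))
        )


def classify_genotypes(chunk: np.ndarray) -> GenotypeClassCounts:
    """Classify a (variants, samples, ploidy) genotype block.

    A call with any missing allele (-1) is missing; otherwise a call with
    any fill allele (-2) has non-reference ploidy; complete calls are
    hom-ref (all alleles 0), hom-alt (all equal, non-zero) or het.
    """
    chunk = np.asarray(chunk)
    missing = (chunk == INT_MISSING).any(axis=-1)
    other = ~missing & (chunk == INT_FILL).any(axis=-1)
    complete = ~missing & ~other
    all_ref = (chunk == 0).all(axis=-1)
    all_same = (chunk == chunk[..., :1]).all(axis=-1)
    hom_ref = complete & all_ref
    hom_alt = complete & all_same & ~all_ref
    het = complete & ~hom_ref & ~hom_alt
    return GenotypeClassCounts(
        hom_ref=hom_ref.sum(axis=-1),
        het=het.sum(axis=-1),
        hom_alt=hom_alt.sum(axis=-1),
        missing=missing.sum(axis=-1),
        other_ploidy=other.sum(axis=-1),
    )


def _iter_gt_chunks(store: VczStore, variant_indexes=None):
    gt = store.arr("call_genotype")
    vc = gt.chunks[0]
    n = gt.shape[0]
    if variant_indexes is not None:
        variant_indexes = np.asarray(variant_indexes, dtype="int64")
    for lo in range(0, n, vc):
        hi = min(lo + vc, n)
        if variant_indexes is None:
            local = None
        else:
            local = variant_indexes[(variant_indexes >= lo) & (variant_indexes < hi)] - lo
            if local.size == 0:
                continue
        block = gt[lo:hi]
        if local is not None:
            block = block[local]
            yield lo, local, block
        else:
            yield lo, np.arange(hi - lo), block


def allele_counts(store: VczStore, variant_indexes=None):
    """Per-variant (AN, AC per alternate allele) from the genotype matrix.

    AN counts called allele slots (missing and fill excluded); AC[:, a-1]
    counts occurrences of allele index a.
    """
    max_alt = store.arr("variant_allele").shape[1] - 1
    an_parts, ac_parts = [], []
    for _, _, block in _iter_gt_chunks(store, variant_indexes):
        an_parts.append((block >= 0).sum(axis=(1, 2)))
        ac = np.stack(
            [(block == a).sum(axis=(1, 2)) for a in range(1, max_alt + 1)], axis=1
        ) if max_alt else np.zeros((block.shape[0], 0), dtype="int64")
        ac_parts.append(ac)
    if not an_parts:
        return np.zeros(0, dtype="int64"), np.zeros((0, max_alt), dtype="int64")
    return np.concatenate(an_parts), np.concatenate(ac_parts)


@dataclasses.dataclass
class AfDistTable:
    """Genotype-call counts binned by HWE probability."""

    bin_edges: np.ndarray  # n_bins + 1 edges over [0, 1]
    counts: np.ndarray  # per-bin call counts
    n_skipped_multiallelic: int = 0
    n_skipped_no_calls: int = 0

    def to_tsv(self) -> str:
        lines = ["prob_start\tprob_stop\tcount"]
        for i, c in enumerate(self.counts):
            lines.append(f"{self.bin_edges[i]:g}\t{self.bin_edges[i + 1]:g}\t{int(c)}")
        return "\n".join(lines)


def af_dist(store: VczStore, regions=None, mask=None, n_bins: int = 10) -> AfDistTable:
    """HWE genotype-probability distribution over biallelic diploid sites.

    Sites with more than one alternate allele are skipped (counted in
    ``n_skipped_multiallelic``), as are sites with no called alleles.
    Accumulation is chunkwise and order-independent.
    """
    from .query_view import _selection

    sel = _selection(store, regions, None, mask)
    alleles = store.arr("variant_allele")[:]
    n_alts = (np.asarray(alleles, dtype=object) != "").sum(axis=1) - 1
    counts = np.zeros(n_bins, dtype="int64")
    skipped_multi = 0
    skipped_empty = 0
    for lo, local, block in _iter_gt_chunks(store, sel):
        global_idx = lo + local
        site_alt = n_alts[global_idx]
        multi = site_alt > 1
        skipped_multi += int(multi.sum())
        keep = ~multi
        if not keep.any():
            continue
        block = block[keep]
        cls = classify_genotypes(block)
        an = (block >= 0).sum(axis=(1, 2))
        ac1 = (block == 1).sum(axis=(1, 2))
        empty = an == 0
        skipped_empty += int(empty.sum())
        ok = ~empty
        p = np.zeros(len(an))
        p[ok] = ac1[ok] / an[ok]
        for probs, tallies in (
            ((1 - p) ** 2, cls.hom_ref),
            (2 * p * (1 - p), cls.het),
            (p**2, cls.hom_alt),
        ):
            idx = np.minimum((probs * n_bins).astype(int), n_bins - 1)
            np.add.at(counts, idx[ok], tallies[ok])
    return AfDistTable(
        bin_edges=np.linspace(0, 1, n_bins + 1),
        counts=counts,
        n_skipped_multiallelic=skipped_multi,
        n_skipped_no_calls=skipped_empty,
    )
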