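"""Local-alleles reduction of per-allele and per-genotype fields.

At a multiallelic site, Number=R fields (one value per allele, e.g. AD) and
Number=G fields (one value per unordered genotype, e.g. PL) have global
dimensions set by the site-wide maximum allele count — quadratically so for
Number=G. A diploid call, however, can reference at most two alleles. The
local-alleles encoding stores, per call, the sorted list of allele indexes
actually observed in the genotype (LA), and rewrites AD/PL-class values in
terms of those local alleles (LAD/LPL), shrinking the inner dimension to
the ploidy (R) or ploidy·(ploidy+1)/2 (G, diploid).

The reduction keeps every value referenced by the genotype exactly; values
for alleles the call does not carry are the only information discarded.
LA is derived from GT alone, so homozygous-reference calls and fully
missing calls remain distinguishable without consulting the genotypes.
"""

from __future__ import annotations

import numpy as np

from .vcz_schema import INT_FILL, INT_MISSING


class LocalAlleleError(ValueError):
    pass


def compute_la(genotype) -> list[int]:
    """Sorted unique non-negative allele indexes, fill-padded to ploidy.

    ``genotype`` follows call_genotype conventions (-1 missing, -2 fill).
    A call with no observed alleles yields all fill.
    """
    ploidy = len(genotype)
    la = sorted({int(a) for a in genotype if a >= 0})
    la += [INT_FILL] * (ploidy - len(la))
    return la


def localize_r_field(values, la, *, missing, fill):
    """Select the per-allele (Number=R) entries named by the local alleles.

    ``values`` is the global-width row (length >= max referenced allele + 1,
    padded per Number=R conventions); output[j] = values[la[j]] for la[j]>=0,
    fill otherwise.
    """
    out = []
    for a in la:
        if a < 0:
            out.append(fill)
        else:
            if a >= len(values):
                raise LocalAlleleError(
                    f"local allele {a} has no Number=R entry (row length {len(values)})"
                )
            out.append(values[a])
    return out


def g_order_index(j: int, k: int) -> int:
    """Ordinal of the unordered diploid genotype (j, k), j <= k, in the
    canonical VCF Number=G ordering: k(k+1)/2 + j."""
    if j > k:
        raise LocalAlleleError(f"genotype pair must be ordered: ({j}, {k})")
    if j < 0:
        raise LocalAlleleError("allele indexes must be non-negative")
    return k * (k + 1) // 2 + j


def localize_g_field(values, la, *, missing, fill):
    """Rewrite a diploid Number=G vector in terms of the local alleles.

    Output enumerates unordered pairs of LA's non-fill entries in G order
    of the *local* indexes, each value pulled from the global vector via
    g_order_index on the *global* indexes; unused slots are fill.
    """
    ploidy = len(la)
    if ploidy > 2:
        raise LocalAlleleError("Number=G localization is defined for ploidy <= 2")
    local = [a for a in la if a >= 0]
    width = ploidy * (ploidy + 1) // 2
    out = [fill] * width
    for lk in range(len(local)):
        for lj in range(lk + 1):
            src = g_order_index(local[lj], local[lk])
            if src >= len(values):
                raise LocalAlleleError(
                    f"genotype ordinal {src} out of range for Number=G row of "
                    f"length {len(values)}"
                )
            out[g_order_index(lj, lk)] = values[src]
    return out


# ----------------------------------------------------------------------
# Block (chunk-level) forms used by the encoder
# ----------------------------------------------------------------------

def compute_la_block(genotypes: np.ndarray) -> np.ndarray:
    """compute_la applied over a (variants, samples, ploidy) block."""
    v, s, p = genotypes.shape
    out = np.full((v, s, p), INT_FILL, dtype=genotypes.dtype)
    for i in range(v):
        for j in range(s):
            out[i, j] = compute_la(genotypes[i, j])
    return out


def reconstruct_r_entries(la_row, lad_row, n_alleles, *, missing):
    """Invert localize_r_field: global-width row with missing for non-local
    alleles. Exact on every entry the genotype references."""
    out = [missing] * n_alleles
    for j, a in enumerate(la_row):
        if a >= 0:
            out[int(a)] = lad_row[j]
    return out


def reconstruct_g_entries(la_row, lpl_row, n_alleles, ploidy, *, missing):
    """Invert localize_g_field for diploids: global Number=G row with
    missing for genotypes involving non-local alleles."""
    if ploidy > 2:
        raise LocalAlleleError("Number=G reconstruction is defined for ploidy <= 2")
    from .vcz_schema import genotype_dimension_size

    width = genotype_dimension_size(max(n_alleles, 1), 2)
    out = [missing] * width
    local = [int(a) for a in la_row if a >= 0]
    for lk in range(len(local)):
        for lj in range(lk + 1):
            out[g_order_index(local[lj], local[lk])] = lpl_row[g_order_index(lj, lk)]
    return out
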