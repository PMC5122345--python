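"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's indexed code paths:
nearest-gene by exhaustive scan over all genes, classification by
containment testing against the flat list of every feature interval.
"""

from __future__ import annotations

import numpy as np
import pytest

from chipcoloc.annotation import (
    DEFAULT_PRIORITY,
    PROMOTER_DOWNSTREAM,
    PROMOTER_UPSTREAM,
    derive_features,
)
from chipcoloc.peak_io import GeneModel, GenomicInterval, Peak


def make_gene(
    gene_id="G1",
    chrom="chr1",
    start=10_000,
    end=20_000,
    strand="+",
    exons=None,
    cds=None,
):
    exons = exons or [(start, end)]
    cds_start, cds_end = cds if cds else (None, None)
    return GeneModel(
        gene_id=gene_id,
        name=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )


def make_peak(chrom="chr1", start=0, end=100, name="", summit=None):
    return Peak(GenomicInterval(chrom, start, end), name=name, summit_offset=summit)


def uniform_peaks(rng, n, chrom="chrS1", chrom_size=10_000_000, width=201):
    """Uniform random peaks of fixed odd width (odd: the center base is
    exactly self-mirroring, see the strand-symmetry test)."""
    starts = rng.integers(0, chrom_size - width, size=n)
    return [
        Peak(GenomicInterval(chrom, int(s), int(s) + width), name=f"p{i}")
        for i, s in enumerate(starts)
    ]


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def nearest_gene_oracle(center, chrom, genes):
    """Exhaustive linear scan: min |center - TSS| on the chromosome,
    ties to the lexicographically smallest gene_id."""
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(center - g.tss)
        if best is None or d < best[0] or (d == best[0] and g.gene_id < best[1]):
            best = (d, g.gene_id, g)
    if best is None:
        return None
    g = best[2]
    signed = center - g.tss if g.strand == "+" else g.tss - center
    return g.gene_id, signed


def flat_feature_list(
    genes,
    promoter_upstream=PROMOTER_UPSTREAM,
    promoter_downstream=PROMOTER_DOWNSTREAM,
    chrom_sizes=None,
):
    """Every feature interval of every gene as (chrom, start, end, category)."""
    flat = []
    for g in genes:
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        for cat, ivs in derive_features(
            g, promoter_upstream, promoter_downstream, size
        ).items():
            flat.extend((iv.chrom, iv.start, iv.end, cat) for iv in ivs)
    return flat


def classify_oracle(center, chrom, flat_features, priority=DEFAULT_PRIORITY):
    """Brute-force containment over the full feature list."""
    rank = {cat: i for i, cat in enumerate(priority)}
    best = None
    for fchrom, s, e, cat in flat_features:
        if fchrom == chrom and s <= center < e and cat in rank:
            if best is None or rank[cat] < rank[best]:
                best = cat
    return best if best is not None else "intergenic"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
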