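"""Nearest-gene peak annotation, regulatory-feature classification,
category distributions, and TSS/TES position profiles.

A peak is classified by the gene-regulatory feature containing its
*center* (promoter > enhancer > 5'UTR > 3'UTR > exon > intron, then
intergenic), which partitions the peak set into exactly one category
each. The nearest gene is the one minimizing |peak center - TSS| on the
same chromosome.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .peak_io import GeneModel, GenomicInterval, Peak, peak_center

__all__ = [
    "DEFAULT_PRIORITY",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "PeakAnnotation",
    "FeatureDistribution",
    "PositionProfile",
    "derive_features",
    "FeatureIndex",
    "classify_peak",
    "GeneIndex",
    "nearest_gene",
    "annotate_peaks",
    "feature_distribution",
    "position_profile",
]

#: classification priority when a peak center sits in several features
DEFAULT_PRIORITY: tuple[str, ...] = (
    "promoter",
    "enhancer",
    "5utr",
    "3utr",
    "exon",
    "intron",
)

#: default strand-aware promoter window around the TSS (bp)
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class PeakAnnotation:
    """One peak's nearest gene, signed TSS distance, and category.

    ``signed_tss_distance`` is positive when the peak center lies
    downstream of the TSS in the gene's transcription orientation;
    ``None`` (with ``gene_id=None``) when the chromosome has no gene.
    """

    peak: Peak
    gene_id: str | None
    signed_tss_distance: int | None
    category: str


@dataclass(frozen=True)
class FeatureDistribution:
    """Per-category peak counts and percentages (sums to 100)."""

    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class PositionProfile:
    """Peaks covering each strand-oriented offset around TSS or TES.

    ``percent_of_max`` rescales counts so the maximum position reads 100;
    an all-zero profile stays all-zero.
    """

    anchor: str
    offsets: np.ndarray
    counts: np.ndarray
    percent_of_max: np.ndarray


# ---------------------------------------------------------------------------
# feature derivation
# ---------------------------------------------------------------------------


def _subtract_window(
    intervals: Iterable[GenomicInterval], lo: int, hi: int
) -> list[GenomicInterval]:
    """Clip intervals to [lo, hi), dropping empties."""
    out = []
    for iv in intervals:
        s, e = max(iv.start, lo), min(iv.end, hi)
        if s < e:
            out.append(GenomicInterval(iv.chrom, s, e, iv.strand))
    return out


def derive_features(
    gene: GeneModel,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
    chrom_size: int | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Derive the regulatory feature intervals of one gene.

    The promoter is the strand-aware window covering ``promoter_upstream``
    bp upstream of the TSS and ``promoter_downstream`` bp downstream
    (including the TSS base) in transcription orientation. UTRs are the
    exonic sequence outside the coding bounds, strand-aware; ``exon`` is
    the remaining (coding) exonic sequence; ``intron`` the gaps between
    consecutive exons. Intervals are clipped to [0, chrom_size) when a
    chromosome size is given.
    """
    if promoter_upstream < 0 or promoter_downstream < 0:
        raise ValueError("promoter window sizes must be >= 0")
    chrom, strand = gene.chrom, gene.strand
    limit = chrom_size if chrom_size is not None else np.iinfo(np.int64).max

    if strand == "+":
        prom_lo = gene.tss - promoter_upstream
        prom_hi = gene.tss + promoter_downstream
    else:
        prom_lo = gene.tss - promoter_downstream + 1
        prom_hi = gene.tss + promoter_upstream + 1
    prom_lo, prom_hi = max(0, prom_lo), min(limit, prom_hi)

    features: dict[str, list[GenomicInterval]] = {
        "promoter": (
            [GenomicInterval(chrom, prom_lo, prom_hi, strand)] if prom_lo < prom_hi else []
        ),
        "5utr": [],
        "3utr": [],
        "exon": [],
        "intron": [],
    }

    if gene.is_coding:
        cs, ce = gene.cds_start, gene.cds_end
        left_utr = _subtract_window(gene.exons, gene.interval.start, cs)
        right_utr = _subtract_window(gene.exons, ce, gene.interval.end)
        features["5utr"] = left_utr if strand == "+" else right_utr
        features["3utr"] = right_utr if strand == "+" else left_utr
        features["exon"] = _subtract_window(gene.exons, cs, ce)
    else:
        features["exon"] = list(gene.exons)

    for prev, nxt in zip(gene.exons, gene.exons[1:]):
        if prev.end < nxt.start:
            features["intron"].append(GenomicInterval(chrom, prev.end, nxt.start, strand))

    if chrom_size is not None:
        features = {
            cat: _subtract_window(ivs, 0, chrom_size) for cat, ivs in features.items()
        }
    return features


class FeatureIndex:
    """Interval index of the regulatory features of a whole gene set.

    Optional enhancer intervals add an ``enhancer`` category; otherwise
    that category does not exist.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_upstream: int = PROMOTER_UPSTREAM,
        promoter_downstream: int = PROMOTER_DOWNSTREAM,
        enhancers: Sequence[GenomicInterval] | None = None,
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.categories = [
            c for c in DEFAULT_PRIORITY if c != "enhancer" or enhancers
        ]
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        for gene in genes:
            size = chrom_sizes.get(gene.chrom) if chrom_sizes else None
            feats = derive_features(gene, promoter_upstream, promoter_downstream, size)
            for cat, ivs in feats.items():
                for iv in ivs:
                    self._tree(cat, iv.chrom).addi(iv.start, iv.end)
        for iv in enhancers or ():
            self._tree("enhancer", iv.chrom).addi(iv.start, iv.end)

    def _tree(self, cat: str, chrom: str) -> IntervalTree:
        return self._trees.setdefault(cat, {}).setdefault(chrom, IntervalTree())

    def categories_at(self, chrom: str, pos: int) -> set[str]:
        """All feature categories whose intervals contain ``pos``."""
        hit = set()
        for cat, by_chrom in self._trees.items():
            tree = by_chrom.get(chrom)
            if tree is not None and tree.overlaps_point(pos):
                hit.add(cat)
        return hit

    def classify(
        self, chrom: str, pos: int, priority: Sequence[str] = DEFAULT_PRIORITY
    ) -> str:
        hits = self.categories_at(chrom, pos)
        for cat in priority:
            if cat in hits:
                return cat
        return "intergenic"


def classify_peak(
    peak: Peak,
    feature_index: FeatureIndex,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    center_mode: str = "midpoint",
) -> str:
    """Category of the highest-priority feature containing the peak center."""
    return feature_index.classify(peak.chrom, peak_center(peak, center_mode), priority)


# ---------------------------------------------------------------------------
# nearest gene
# ---------------------------------------------------------------------------


class GeneIndex:
    """Per-chromosome sorted-TSS index for nearest-gene queries.

    Genes sharing a TSS are collapsed to the lexicographically smallest
    gene_id, matching the deterministic tie rule.
    """

    def __init__(self, genes: Sequence[GeneModel]) -> None:
        by_chrom: dict[str, dict[int, GeneModel]] = {}
        for g in genes:
            best = by_chrom.setdefault(g.chrom, {}).get(g.tss)
            if best is None or g.gene_id < best.gene_id:
                by_chrom[g.chrom][g.tss] = g
        self._tss: dict[str, list[int]] = {
            c: sorted(d) for c, d in by_chrom.items()
        }
        self._genes: dict[str, dict[int, GeneModel]] = by_chrom

    def nearest(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """(gene_id, signed TSS distance) of the nearest gene, or None."""
        tss_list = self._tss.get(chrom)
        if not tss_list:
            return None
        i = bisect_left(tss_list, pos)
        candidates = [tss_list[j] for j in (i - 1, i) if 0 <= j < len(tss_list)]
        best_gene, best_dist = None, None
        for t in candidates:
            g = self._genes[chrom][t]
            d = abs(pos - t)
            if (
                best_dist is None
                or d < best_dist
                or (d == best_dist and g.gene_id < best_gene.gene_id)
            ):
                best_gene, best_dist = g, d
        signed = pos - best_gene.tss
        if best_gene.strand == "-":
            signed = -signed
        return best_gene.gene_id, signed


def nearest_gene(
    peak: Peak,
    genes: Sequence[GeneModel] | GeneIndex,
    center_mode: str = "midpoint",
) -> tuple[str, int] | None:
    """Nearest gene by |peak center - TSS| on the peak's chromosome.

    Ties break to the lexicographically smallest gene_id. Returns ``None``
    when the chromosome carries no gene. The distance is signed positive
    downstream of the TSS in the gene's orientation.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.nearest(peak.chrom, peak_center(peak, center_mode))


# ---------------------------------------------------------------------------
# whole-set annotation and summaries
# ---------------------------------------------------------------------------


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    enhancers: Sequence[GenomicInterval] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    center_mode: str = "midpoint",
) -> list[PeakAnnotation]:
    """Annotate every peak with its nearest gene and feature category."""
    findex = FeatureIndex(
        genes, promoter_upstream, promoter_downstream, enhancers, chrom_sizes
    )
    gindex = GeneIndex(genes)
    out = []
    for p in peaks:
        center = peak_center(p, center_mode)
        hit = gindex.nearest(p.chrom, center)
        gene_id, dist = hit if hit is not None else (None, None)
        out.append(
            PeakAnnotation(
                peak=p,
                gene_id=gene_id,
                signed_tss_distance=dist,
                category=findex.classify(p.chrom, center, priority),
            )
        )
    return out


def feature_distribution(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    enhancers: Sequence[GenomicInterval] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    center_mode: str = "midpoint",
) -> FeatureDistribution:
    """Count and percentage of peaks per regulatory category."""
    if not peaks:
        raise ValueError("feature_distribution requires at least one peak")
    findex = FeatureIndex(
        genes, promoter_upstream, promoter_downstream, enhancers, chrom_sizes
    )
    cats = list(findex.categories) + ["intergenic"]
    counts = {c: 0 for c in cats}
    for p in peaks:
        counts[findex.classify(p.chrom, peak_center(p, center_mode), priority)] += 1
    total = len(peaks)
    percentages = {c: 100.0 * n / total for c, n in counts.items()}
    return FeatureDistribution(counts=counts, percentages=percentages)


def position_profile(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    anchor: str = "tss",
    half_window: int = 5000,
    step: int = 50,
) -> PositionProfile:
    """Count peaks covering each offset around TSS or TES, pooled over genes.

    For every offset o in [-half_window, +half_window] at the given step,
    the count is the number of (gene, peak) pairs where the peak interval
    covers the genome position anchor + o taken in the gene's
    transcription orientation. Counts are rescaled to percent of the
    maximum position.
    """
    anchor = anchor.lower()
    if anchor not in ("tss", "tes"):
        raise ValueError("anchor must be 'tss' or 'tes'")
    if half_window <= 0 or step < 1:
        raise ValueError("require half_window > 0 and step >= 1")
    if not genes:
        raise ValueError("position_profile requires gene models")

    offsets = np.arange(-half_window, half_window + 1, step, dtype=np.int64)

    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in peaks}:
        on = [p for p in peaks if p.chrom == chrom]
        starts[chrom] = np.sort(np.array([p.start for p in on], dtype=np.int64))
        ends[chrom] = np.sort(np.array([p.end for p in on], dtype=np.int64))

    counts = np.zeros(len(offsets), dtype=np.int64)
    for g in genes:
        if g.chrom not in starts:
            continue
        base = g.tss if anchor == "tss" else g.tes
        positions = base + offsets if g.strand == "+" else base - offsets
        # coverage at p = #{starts <= p} - #{ends <= p}
        counts += np.searchsorted(starts[g.chrom], positions, side="right")
        counts -= np.searchsorted(ends[g.chrom], positions, side="right")

    peak_max = counts.max() if len(counts) else 0
    percent = (
        100.0 * counts / peak_max if peak_max > 0 else np.zeros(len(counts), dtype=float)
    )
    return PositionProfile(
        anchor=anchor, offsets=offsets, counts=counts, percent_of_max=percent
    )
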