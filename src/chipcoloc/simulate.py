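"""Synthetic data generators for every pipeline stage.

The generators emulate the statistical structure the analyses assume:

* a toy genome of non-overlapping gene models with exon/UTR structure
  (chromosome names ``chrS1`` ... to avoid conflation with real
  assemblies);
* a peak set placed by per-feature weights, so the feature-distribution
  stage has a known ground truth (defaults mirror a genome-wide binding
  profile with >half the peaks intergenic and ~6% in promoters);
* a query peak set whose centers decay away from anchor centers with a
  two-sided exponential (Laplace) kernel plus a uniform background
  fraction — a planted co-localization signal with an analytically known
  HMd curve;
* a patient cohort with log-normal expression, Ct values back-computed
  through a known qPCR standard curve, and a planted expression shift in
  a phenotype-positive subgroup.

Every generator is a pure function of its configuration, including the
seed; distinct generators draw from independently spawned RNG streams.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    PROMOTER_DOWNSTREAM,
    PROMOTER_UPSTREAM,
    derive_features,
)
from .cohort import StandardCurve
from .peak_io import GeneModel, GenomicInterval, Peak

__all__ = [
    "SimulationConfig",
    "DEFAULT_FEATURE_WEIGHTS",
    "DEFAULT_CURVE",
    "simulate_genome",
    "simulate_peaks_by_feature",
    "simulate_colocalized",
    "simulate_cohort",
]

#: default planted category weights: majority intergenic, ~6% promoter
DEFAULT_FEATURE_WEIGHTS: dict[str, float] = {
    "intergenic": 0.55,
    "promoter": 0.06,
    "5utr": 0.02,
    "3utr": 0.03,
    "exon": 0.09,
    "intron": 0.25,
}

#: 100%-efficiency qPCR calibration used to back-compute synthetic Ct values
DEFAULT_CURVE = StandardCurve(slope=-3.32, intercept=40.0, r_squared=1.0)

# RNG sub-stream keys so the four generators are independent under one seed
_STREAM_GENOME = 1
_STREAM_PEAKS = 2
_STREAM_COLOC = 3
_STREAM_COHORT = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    ``gene_min_gap`` keeps adjacent genes at least one promoter window
    apart so planted feature categories are recoverable without priority
    conflicts. ``effect_size`` is the planted group difference in SD
    units of log-expression.
    """

    seed: int = 0
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chrS1": 10_000_000}
    )
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    exons_per_gene_range: tuple[int, int] = (1, 8)
    coding_fraction: float = 0.8
    gene_min_gap: int = 3_000
    n_anchor_peaks: int = 200
    n_query_peaks: int = 5_000
    peak_width_range: tuple[int, int] = (150, 500)
    feature_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_WEIGHTS)
    )
    promoter_upstream: int = PROMOTER_UPSTREAM
    promoter_downstream: int = PROMOTER_DOWNSTREAM
    decay_scale: float = 300.0
    background_fraction: float = 0.2
    cohort_n: int = 60
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        w = sum(self.feature_weights.values())
        if self.feature_weights and abs(w - 1.0) > 1e-9:
            raise ValueError(f"feature_weights must sum to 1, got {w}")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValueError("background_fraction must lie in [0, 1]")
        for name in ("n_genes", "n_anchor_peaks", "n_query_peaks", "cohort_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _random_exon_chain(
    rng: np.random.Generator, chrom: str, start: int, end: int, n_exons: int, strand: str
) -> tuple[GenomicInterval, ...]:
    """Partition [start, end) into alternating exon/intron blocks; the
    first and last blocks are exons."""
    length = end - start
    n_blocks = 2 * n_exons - 1
    if n_blocks == 1:
        return (GenomicInterval(chrom, start, end, strand),)
    # n_blocks - 1 distinct internal cut points, each block >= 1 bp
    cuts = rng.choice(np.arange(1, length), size=n_blocks - 1, replace=False)
    bounds = np.concatenate(([0], np.sort(cuts), [length])) + start
    return tuple(
        GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1]), strand)
        for i in range(0, n_blocks, 2)
    )


def simulate_genome(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes uniformly on the toy chromosomes.

    Genes keep ``gene_min_gap`` bp of clearance so one gene's promoter
    window never overlaps a neighbour's body. Raises when placement
    repeatedly fails (chromosomes too crowded).
    """
    rng = config.rng(_STREAM_GENOME)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    lo_len, hi_len = config.gene_length_range
    lo_ex, hi_ex = config.exons_per_gene_range

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    max_attempts = 200

    for i in range(config.n_genes):
        for attempt in range(max_attempts):
            chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
            length = int(rng.integers(lo_len, hi_len + 1))
            limit = config.chrom_sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            lo, hi = start - config.gene_min_gap, end + config.gene_min_gap
            ivs = placed[chrom]
            j = bisect_left(ivs, (lo, lo))
            clash = (j > 0 and ivs[j - 1][1] > lo) or (j < len(ivs) and ivs[j][0] < hi)
            if clash:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(lo_ex, hi_ex + 1))
            exons = _random_exon_chain(rng, chrom, start, end, n_exons, strand)
            cds_start = cds_end = None
            if rng.random() < config.coding_fraction and length >= 4:
                a, b = np.sort(rng.choice(np.arange(start + 1, end), 2, replace=False))
                cds_start, cds_end = int(a), int(b)
            insort(ivs, (start, end))
            genes.append(
                GeneModel(
                    gene_id=f"G{i:04d}",
                    name=f"GENE{i}",
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
            break
        else:
            raise RuntimeError(
                f"could not place gene {i} after {max_attempts} attempts; "
                "chromosomes too small for the requested gene count"
            )
    return genes


# ---------------------------------------------------------------------------
# feature-weighted peaks
# ---------------------------------------------------------------------------


def _subtract(
    iv: GenomicInterval, holes: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pieces of ``iv`` not covered by any hole (holes assumed disjoint)."""
    pieces = [(iv.start, iv.end)]
    for h in holes:
        nxt = []
        for s, e in pieces:
            if h.end <= s or h.start >= e:
                nxt.append((s, e))
                continue
            if s < h.start:
                nxt.append((s, h.start))
            if h.end < e:
                nxt.append((h.end, e))
        pieces = nxt
    return [GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in pieces]


def _intergenic_pool(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> dict[str, list[GenomicInterval]]:
    """Per-chromosome complement of gene bodies and promoter windows."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_sizes}
    for g in genes:
        occupied[g.chrom].append((g.interval.start, g.interval.end))
        prom = derive_features(
            g,
            config.promoter_upstream,
            config.promoter_downstream,
            config.chrom_sizes[g.chrom],
        )["promoter"]
        for iv in prom:
            occupied[g.chrom].append((iv.start, iv.end))
    pool: dict[str, list[GenomicInterval]] = {c: [] for c in config.chrom_sizes}
    for chrom, size in config.chrom_sizes.items():
        pos = 0
        for s, e in sorted(occupied[chrom]):
            if s > pos:
                pool[chrom].append(GenomicInterval(chrom, pos, s))
            pos = max(pos, e)
        if pos < size:
            pool[chrom].append(GenomicInterval(chrom, pos, size))
    return pool


def simulate_peaks_by_feature(
    genome: Sequence[GeneModel], config: SimulationConfig
) -> list[Peak]:
    """Draw each peak's category from ``feature_weights`` and place its
    center uniformly inside a random interval of that category.

    Classifying the output recovers the planted category because genomes
    from :func:`simulate_genome` keep promoter windows clear of other
    genes' features.
    """
    rng = config.rng(_STREAM_PEAKS)
    pools: dict[str, list[GenomicInterval]] = {}
    for g in genome:
        feats = derive_features(
            g,
            config.promoter_upstream,
            config.promoter_downstream,
            config.chrom_sizes.get(g.chrom),
        )
        for cat, ivs in feats.items():
            if cat != "promoter":
                # the promoter window covers the first bases of the gene
                # body; keep lower-priority pools clear of it so the
                # planted category survives priority classification
                ivs = [
                    part
                    for iv in ivs
                    for part in _subtract(iv, feats["promoter"])
                ]
            pools.setdefault(cat, []).extend(ivs)
    pools["intergenic"] = [
        iv for ivs in _intergenic_pool(genome, config).values() for iv in ivs
    ]

    cats = [c for c, w in config.feature_weights.items() if w > 0]
    for cat in cats:
        if not pools.get(cat):
            raise ValueError(
                f"category {cat!r} has positive weight but no realizable interval"
            )
    weights = np.array([config.feature_weights[c] for c in cats], dtype=float)
    weights /= weights.sum()

    lo_w, hi_w = config.peak_width_range
    peaks: list[Peak] = []
    for i in range(config.n_query_peaks):
        cat = cats[rng.choice(len(cats), p=weights)]
        width = int(rng.integers(lo_w, hi_w + 1))
        for _ in range(100):
            iv = pools[cat][rng.integers(len(pools[cat]))]
            center = int(rng.integers(iv.start, iv.end))
            start = center - (width - 1) // 2
            end = start + width
            if start >= 0 and end <= config.chrom_sizes[iv.chrom]:
                break
        else:
            raise RuntimeError(f"could not place peak {i} in category {cat!r}")
        peaks.append(
            Peak(GenomicInterval(iv.chrom, start, end), name=f"{cat}_{i}")
        )
    return peaks


# ---------------------------------------------------------------------------
# co-localized queries
# ---------------------------------------------------------------------------


def simulate_colocalized(
    anchors: Sequence[Peak], config: SimulationConfig
) -> list[Peak]:
    """Generate query peaks co-localized with the anchors.

    Each query is uniform background with probability
    ``background_fraction``; otherwise its center is a uniformly chosen
    anchor center plus a Laplace offset of scale ``decay_scale`` bp,
    clipped to the chromosome.
    """
    if not anchors and config.background_fraction < 1.0:
        raise ValueError("signal queries require at least one anchor peak")
    rng = config.rng(_STREAM_COLOC)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    anchor_centers = [
        ((a.start + a.end - 1) // 2, a.chrom) for a in anchors
    ]
    lo_w, hi_w = config.peak_width_range

    peaks: list[Peak] = []
    for i in range(config.n_query_peaks):
        if rng.random() < config.background_fraction or not anchor_centers:
            chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
            center = int(rng.integers(0, config.chrom_sizes[chrom]))
        else:
            c0, chrom = anchor_centers[rng.integers(len(anchor_centers))]
            offset = int(round(rng.laplace(0.0, config.decay_scale)))
            center = int(np.clip(c0 + offset, 0, config.chrom_sizes[chrom] - 1))
        width = int(rng.integers(lo_w, hi_w + 1))
        start = max(0, center - (width - 1) // 2)
        end = min(config.chrom_sizes[chrom], start + width)
        start = max(0, min(start, end - width))
        peaks.append(Peak(GenomicInterval(chrom, start, end), name=f"q{i}"))
    return peaks


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

#: SD of log10 GOI expression across patients
_GOI_LOG_SD = 0.5
#: SD of log10 GAPDH expression (housekeeping; phenotype-independent)
_GAPDH_LOG_SD = 0.05


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Synthesize a patient cohort as raw qPCR inputs.

    GOI expression is log-normal with a planted mean shift of
    ``effect_size`` SD (of log10 GOI) in the phenotype-positive half of
    the cohort; GAPDH is phenotype-independent. Ct values are
    back-computed through :data:`DEFAULT_CURVE`, so quantification ->
    normalization -> dichotomization -> testing exercises the full
    pipeline end to end.

    Returns a DataFrame with patient_id, goi_ct, gapdh_ct, phenotype
    (binary covariate) and true_expression columns.
    """
    if config.cohort_n < 4:
        raise ValueError("cohort_n must be >= 4")
    rng = config.rng(_STREAM_COHORT)
    n = config.cohort_n
    phenotype = np.zeros(n, dtype=int)
    phenotype[: n // 2] = 1
    rng.shuffle(phenotype)

    log_goi = rng.normal(2.0, _GOI_LOG_SD, size=n)
    log_goi += config.effect_size * _GOI_LOG_SD * phenotype
    log_gapdh = rng.normal(3.0, _GAPDH_LOG_SD, size=n)

    curve = DEFAULT_CURVE
    goi_ct = curve.intercept + curve.slope * log_goi
    gapdh_ct = curve.intercept + curve.slope * log_gapdh
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "goi_ct": goi_ct,
            "gapdh_ct": gapdh_ct,
            "phenotype": phenotype,
            "true_expression": 10.0 ** (log_goi - log_gapdh),
        }
    )
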