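"""Feature derivation, classification, nearest-gene, distributions,
and TSS/TES position profiles."""

import numpy as np
import pytest

from chipcoloc.annotation import (
    DEFAULT_PRIORITY,
    FeatureIndex,
    GeneIndex,
    classify_peak,
    derive_features,
    feature_distribution,
    nearest_gene,
    position_profile,
)
from chipcoloc.peak_io import GeneModel, GenomicInterval, Peak
from chipcoloc.simulate import SimulationConfig, simulate_genome

from conftest import (
    classify_oracle,
    flat_feature_list,
    make_gene,
    make_peak,
    nearest_gene_oracle,
    uniform_peaks,
)


class TestDeriveFeatures:
    def test_plus_strand_promoter_window(self):
        g = make_gene(start=10_000, end=20_000, strand="+")
        (prom,) = derive_features(g, 2000, 500)["promoter"]
        assert (prom.start, prom.end) == (8000, 10_500)

    def test_minus_strand_promoter_window(self):
        # mirrored arithmetic: 500 downstream bases 19500..19999 plus
        # 2000 upstream bases 20000..21999
        g = make_gene(start=10_000, end=20_000, strand="-")
        (prom,) = derive_features(g, 2000, 500)["promoter"]
        assert (prom.start, prom.end) == (19_500, 22_000)
        assert prom.end - prom.start == 2500  # same width as plus strand

    def test_single_exon_noncoding_gene(self):
        g = make_gene(exons=[(10_000, 20_000)])
        feats = derive_features(g)
        assert feats["5utr"] == [] and feats["3utr"] == []
        assert len(feats["exon"]) == 1 and feats["intron"] == []

    def test_utrs_are_exonic_and_strand_aware(self):
        exons = [(10_000, 11_000), (14_000, 16_000), (18_000, 20_000)]
        plus = derive_features(make_gene(exons=exons, cds=(10_500, 19_000), strand="+"))
        minus = derive_features(make_gene(exons=exons, cds=(10_500, 19_000), strand="-"))
        # 5'UTR of the + gene is exonic sequence left of cds_start
        assert [(iv.start, iv.end) for iv in plus["5utr"]] == [(10_000, 10_500)]
        assert [(iv.start, iv.end) for iv in plus["3utr"]] == [(19_000, 20_000)]
        # the - gene swaps the two
        assert [(iv.start, iv.end) for iv in minus["3utr"]] == [(10_000, 10_500)]
        assert [(iv.start, iv.end) for iv in minus["5utr"]] == [(19_000, 20_000)]
        # coding exon portions and the two introns remain
        assert [(iv.start, iv.end) for iv in plus["exon"]] == [
            (10_500, 11_000), (14_000, 16_000), (18_000, 19_000)]
        assert [(iv.start, iv.end) for iv in plus["intron"]] == [
            (11_000, 14_000), (16_000, 18_000)]

    def test_clipping_to_chromosome(self):
        g = make_gene(start=500, end=5000, strand="+")
        feats = derive_features(g, 2000, 500, chrom_size=4000)
        (prom,) = feats["promoter"]
        assert prom.start == 0
        assert all(iv.end <= 4000 for ivs in feats.values() for iv in ivs)


class TestClassify:
    def test_promoter_beats_exon_of_other_gene(self):
        a = make_gene("A", start=10_000, end=20_000, strand="+")
        b = make_gene("B", start=21_000, end=30_000, strand="+")
        idx = FeatureIndex([a, b])
        # center 19_500: inside A's exon and inside B's promoter [19000,21500)
        assert classify_peak(make_peak(start=19_400, end=19_601), idx) == "promoter"

    def test_far_peak_is_intergenic(self):
        idx = FeatureIndex([make_gene()])
        assert classify_peak(make_peak(start=1_000_000, end=1_000_200), idx) == "intergenic"

    def test_intron_detected(self):
        g = make_gene(exons=[(10_000, 11_000), (15_000, 20_000)])
        idx = FeatureIndex([g])
        peak = make_peak(start=12_900, end=13_101)
        assert classify_peak(peak, idx) == "intron"
        flat = flat_feature_list([g])
        assert classify_oracle(13_000, "chr1", flat) == "intron"

    def test_enhancer_category_only_when_supplied(self):
        g = make_gene()
        enh = [GenomicInterval("chr1", 50_000, 51_000)]
        bare = FeatureIndex([g])
        with_enh = FeatureIndex([g], enhancers=enh)
        pk = make_peak(start=50_400, end=50_601)
        assert classify_peak(pk, bare) == "intergenic"
        assert classify_peak(pk, with_enh) == "enhancer"


class TestNearestGene:
    def test_nearest_by_tss(self):
        a = make_gene("A", start=5000, end=9000, strand="+")
        b = make_gene("B", start=20_000, end=25_000, strand="+")
        gid, dist = nearest_gene(make_peak(start=5900, end=6101), [a, b])
        assert (gid, dist) == ("A", 1000)

    def test_tie_breaks_to_smaller_gene_id(self):
        a = make_gene("A", start=5000, end=9000, strand="+")
        b = make_gene("B", start=20_000, end=25_000, strand="+")
        # center 12500 is 7500 from both TSSs
        gid, _ = nearest_gene(make_peak(start=12_500, end=12_501), [a, b])
        assert gid == "A"

    def test_no_gene_on_chromosome(self):
        assert nearest_gene(make_peak("chr9", 0, 100), [make_gene()]) is None

    def test_minus_strand_signed_distance(self):
        g = make_gene("A", start=5000, end=9000, strand="-")  # TSS 8999
        _, dist = nearest_gene(make_peak(start=8000, end=8001), [g])
        assert dist == 999  # downstream of the TSS in gene orientation

    def test_index_matches_linear_scan_oracle(self, rng):
        """Indexed nearest-gene equals exhaustive scan on random instances."""
        for trial in range(20):
            cfg = SimulationConfig(
                seed=int(rng.integers(2**31)),
                n_genes=int(rng.integers(1, 30)),
                chrom_sizes={"chrS1": 2_000_000, "chrS2": 1_000_000},
            )
            genes = simulate_genome(cfg)
            index = GeneIndex(genes)
            for pk in uniform_peaks(rng, 50, chrom_size=2_000_000):
                got = index.nearest(pk.chrom, (pk.start + pk.end - 1) // 2)
                exp = nearest_gene_oracle((pk.start + pk.end - 1) // 2, pk.chrom, genes)
                assert got == exp


class TestFeatureDistribution:
    def test_all_intergenic(self):
        genes = [make_gene()]
        peaks = [make_peak(start=s, end=s + 101) for s in range(500_000, 510_000, 1000)]
        d = feature_distribution(peaks, genes)
        assert d.counts["intergenic"] == 10
        assert d.percentages["intergenic"] == 100.0

    def test_percentage_arithmetic(self):
        g = make_gene(exons=[(10_000, 11_000), (15_000, 20_000)])
        prom = [make_peak(start=9_000, end=9_201) for _ in range(4)]
        intron = [make_peak(start=12_000, end=12_201) for _ in range(6)]
        d = feature_distribution(prom + intron, [g])
        assert d.percentages["promoter"] == 40.0
        assert d.percentages["intron"] == 60.0
        assert abs(sum(d.percentages.values()) - 100.0) < 1e-9

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            feature_distribution([], [make_gene()])

    def test_partition_sums_to_total(self, rng):
        """Category counts always partition the peak set."""
        for trial in range(10):
            cfg = SimulationConfig(seed=trial, n_genes=20,
                                   chrom_sizes={"chrS1": 3_000_000})
            genes = simulate_genome(cfg)
            peaks = uniform_peaks(rng, 100, chrom_size=3_000_000)
            d = feature_distribution(peaks, genes)
            assert sum(d.counts.values()) == 100

    def test_strand_mirror_symmetry(self, rng):
        """Mirroring the genome (reversing coordinates, flipping strands)
        leaves the feature distribution unchanged. Odd peak widths keep
        the center base self-mirroring."""
        L = 3_000_000
        cfg = SimulationConfig(seed=77, n_genes=25, chrom_sizes={"chrS1": L})
        genes = simulate_genome(cfg)
        peaks = uniform_peaks(rng, 300, chrom_size=L)

        def mirror_gene(g):
            s, e = L - g.interval.end, L - g.interval.start
            strand = "-" if g.strand == "+" else "+"
            exons = tuple(
                GenomicInterval(g.chrom, L - ex.end, L - ex.start, strand)
                for ex in reversed(g.exons)
            )
            cds = (
                (L - g.cds_end, L - g.cds_start) if g.is_coding else (None, None)
            )
            return GeneModel(g.gene_id, g.name,
                             GenomicInterval(g.chrom, s, e, strand),
                             exons, cds[0], cds[1])

        def mirror_peak(p):
            return Peak(GenomicInterval(p.chrom, L - p.end, L - p.start), p.name)

        d1 = feature_distribution(peaks, genes)
        d2 = feature_distribution([mirror_peak(p) for p in peaks],
                                  [mirror_gene(g) for g in genes])
        assert d1.counts == d2.counts


class TestPositionProfile:
    def test_single_peak_at_tss(self):
        g = make_gene(start=10_000, end=20_000, strand="+")  # TSS 10000
        pk = make_peak(start=9_900, end=10_100)  # covers [TSS-100, TSS+100)
        prof = position_profile([pk], [g], anchor="tss", half_window=500, step=50)
        inside = (prof.offsets >= -100) & (prof.offsets < 100)
        assert np.all(prof.counts[inside] == 1)
        assert np.all(prof.counts[~inside] == 0)
        assert np.all(prof.percent_of_max[inside] == 100.0)

    def test_empty_profile_stays_zero(self):
        g = make_gene()
        pk = make_peak("chr9", 0, 100)
        prof = position_profile([pk], [g], half_window=1000, step=100)
        assert np.all(prof.counts == 0) and np.all(prof.percent_of_max == 0.0)

    def test_percent_of_max_ratio(self):
        g = make_gene(start=10_000, end=20_000, strand="+")
        at_tss = [make_peak(start=9_950, end=10_051) for _ in range(2)]
        at_3kb = [make_peak(start=12_950, end=13_051)]
        prof = position_profile(at_tss + at_3kb, [g], half_window=4000, step=50)
        i0 = np.where(prof.offsets == 0)[0][0]
        i3k = np.where(prof.offsets == 3000)[0][0]
        assert prof.percent_of_max[i0] == 100.0
        assert prof.percent_of_max[i3k] == 50.0

    def test_minus_strand_orientation(self):
        g = make_gene(start=10_000, end=20_000, strand="-")  # TSS 19999
        pk = make_peak(start=19_000, end=19_201)  # upstream is > TSS here
        prof = position_profile([pk], [g], anchor="tss", half_window=2000, step=100)
        i = np.where(prof.offsets == 900)[0][0]  # downstream offset +900
        assert prof.counts[i] == 1

    def test_tes_anchor(self):
        g = make_gene(start=10_000, end=20_000, strand="+")  # TES 19999
        pk = make_peak(start=19_950, end=20_051)
        prof = position_profile([pk], [g], anchor="tes", half_window=500, step=50)
        i = np.where(prof.offsets == 0)[0][0]
        assert prof.counts[i] == 1

    def test_requires_genes(self):
        with pytest.raises(ValueError):
            position_profile([make_peak()], [], half_window=100, step=10)
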