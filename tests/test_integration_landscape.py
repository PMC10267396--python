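"""Density arithmetic, correlation test, feature precedence, windows, GC."""

import numpy as np
import pytest
from scipy import stats

from svarda.genomic_core import GeneModel, GenomicInterval, IntervalSet, make_windows
from svarda.insertion_calling import InsertionEvent
from svarda.integration_landscape import (
    DensityProfile,
    annotate_features,
    chromosomal_density,
    density_correlation,
    flank_gc_analysis,
    label_events,
    te_enrichment_fraction,
    te_rich_windows,
)
from svarda.genomic_core import ValidationError


def ev(chrom, start, end, support=1):
    return InsertionEvent(GenomicInterval(chrom, start, end), "R", "D1", support, 1)


SVA_ANN = IntervalSet(
    [GenomicInterval("chr1", i * 5_000, i * 5_000 + 1_000) for i in range(4)]
)  # mean length 1,000


class TestDensity:
    def test_formula(self):
        prof = chromosomal_density({"chr1": 2}, {"chr1": 1_000_000}, SVA_ANN)
        assert prof.mean_sva_length == 1_000
        assert prof.table.loc["chr1", "density"] == 2_000.0
        zero = chromosomal_density({"chr1": 0}, {"chr1": 1_000_000}, SVA_ANN)
        assert zero.table.loc["chr1", "density"] == 0.0

    def test_doubling_sizes_halves_density(self):
        counts = {"chr1": 4, "chr2": 6}
        a = chromosomal_density(counts, {"chr1": 1_000_000, "chr2": 500_000}, SVA_ANN)
        b = chromosomal_density(counts, {"chr1": 2_000_000, "chr2": 1_000_000}, SVA_ANN)
        assert np.allclose(
            a.table["density"].to_numpy(), 2 * b.table["density"].to_numpy()
        )

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            chromosomal_density({"chrZ": 1}, {"chr1": 1_000}, SVA_ANN)


class TestCorrelation:
    def _profile(self, values):
        sizes = {f"chr{i+1}": 1_000_000 for i in range(len(values))}
        return chromosomal_density(
            {c: v for c, v in zip(sorted(sizes), values)}, sizes, SVA_ANN
        )

    def test_proportional_profiles_r_one(self):
        a = self._profile([1, 2, 3, 4, 5])
        b = self._profile([2, 4, 6, 8, 10])
        ct = density_correlation(a, b)
        assert ct.r == pytest.approx(1.0) and ct.p == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.random(24)
            y = rng.random(24)
            a, b = self._profile(x * 100), self._profile(y * 100)
            ct = density_correlation(a, b)
            ref = stats.pearsonr(
                a.table["density"].to_numpy(), b.table["density"].to_numpy()
            )
            assert ct.r == pytest.approx(ref.statistic, abs=1e-12)
            assert ct.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValidationError):
            density_correlation(self._profile([2, 2, 2]), self._profile([1, 2, 3]))


# 5'UTR spans 10,000-10,200; note the promoter window (TSS-1kb..TSS+100)
# ends at 10,100, so 10,150 is UTR but not promoter
GENE_PLUS = GeneModel(
    "g+", "chr1", 10_000, 18_000, "+",
    exons=[(10_000, 10_400), (13_000, 13_400), (17_600, 18_000)],
    cds_start=10_200, cds_end=17_880,
)
GENE_NC = GeneModel(
    "nc", "chr1", 40_000, 44_000, "-",
    exons=[(40_000, 40_300), (43_700, 44_000)], cds_start=40_000, cds_end=40_000,
)
TE_ANN = IntervalSet(
    [
        GenomicInterval("chr1", 30_000, 30_200, "+", "SINE"),
        GenomicInterval("chr1", 30_100, 30_400, "+", "LINE"),
        GenomicInterval("chr1", 60_000, 60_300, "+", "LINE"),
    ]
)


class TestFeatureAnnotation:
    @pytest.mark.parametrize(
        "midpoint,label",
        [
            (9_500, "Promoter"),      # TSS-1kb .. TSS+100 on + strand
            (10_150, "5UTR"),
            (13_200, "Exon"),
            (11_000, "Intron"),
            (17_950, "3UTR"),
            (18_500, "TTS"),          # TTS-100 .. TTS+1kb
            (43_800, "ncRNA"),        # noncoding exon clear of the TTS window
            (30_050, "SINE"),         # SINE beats LINE at overlap
            (30_350, "LINE"),
            (80_000, "Intergenic"),
        ],
    )
    def test_midpoint_precedence(self, midpoint, label):
        events = [ev("chr1", midpoint - 5, midpoint + 5)]
        got = label_events(events, [GENE_PLUS, GENE_NC], TE_ANN)
        assert got == [label]

    def test_fractions_sum_to_one(self):
        events = {
            "R1": [ev("chr1", p - 5, p + 5) for p in (9_500, 13_200, 80_000, 30_050)],
            "R2": [ev("chr1", p - 5, p + 5) for p in (11_000, 60_100)],
        }
        ann = annotate_features(events, [GENE_PLUS, GENE_NC], TE_ANN)
        assert np.allclose(ann.fractions.sum(axis=1).to_numpy(), 1.0, atol=1e-9)
        assert ann.fractions.loc["R2", "LINE"] == 0.5


class TestTeWindows:
    def test_single_te_marks_overlapping_windows(self):
        te = IntervalSet([GenomicInterval("chr1", 150_000, 150_200, "+", "SINE")])
        enr = te_rich_windows(te, {"chr1": 400_000})
        nonzero = [w for w, c in zip(enr.windows, enr.counts) if c > 0]
        assert all(w.overlaps(list(te)[0]) for w in nonzero)
        assert all(c == 0 for w, c in zip(enr.windows, enr.counts) if not w.overlaps(list(te)[0]))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_counts_match_naive_scan(self, seed, small_genome):
        enr = te_rich_windows(small_genome.te, small_genome.chrom_sizes)
        sl = [iv for iv in small_genome.te if iv.label in ("SINE", "LINE")]
        rng = np.random.default_rng(seed)
        windows = list(enr.windows)
        for i in rng.choice(len(windows), size=30, replace=False):
            naive = sum(1 for t in sl if t.overlaps(windows[i]))
            assert enr.counts[i] == naive

    def test_enrichment_fraction_extremes(self):
        win = IntervalSet([GenomicInterval("chr1", 0, 100_000)])
        inside = [ev("chr1", 500, 600), ev("chr1", 5_000, 5_100)]
        labels = ["LINE", "SINE"]
        assert te_enrichment_fraction(inside, labels, win) == 100.0
        outside = [ev("chr1", 200_000, 200_100)]
        assert te_enrichment_fraction(outside, ["LINE"], win) == 0.0
        with pytest.raises(ValidationError):
            te_enrichment_fraction(inside, ["Exon", "Intron"], win)

    def test_uniform_te_placement_expectation(self):
        # with no gene models, uniformly placed events inside SINE/LINE bp
        # fall in above-mean windows at the covered-bp rate
        rng = np.random.default_rng(42)
        size = 2_000_000
        te = IntervalSet(
            [
                GenomicInterval("chr1", int(s), int(s) + 200, "+", "SINE")
                for s in rng.choice(size - 200, size=400, replace=False)
            ]
        )
        enr = te_rich_windows(te, {"chr1": size})
        te_positions = np.concatenate([np.arange(iv.start, iv.end) for iv in te])
        covered = np.zeros(size, dtype=bool)
        for w in enr.above_mean:
            covered[w.start : w.end] = True
        expected = covered[te_positions].mean()
        draws = rng.choice(te_positions, size=2_000)
        events = [ev("chr1", int(p), int(p) + 1) for p in draws]
        frac = te_enrichment_fraction(events, ["SINE"] * len(events), enr.above_mean) / 100
        se = np.sqrt(expected * (1 - expected) / len(draws))
        assert abs(frac - expected) < 4 * se + 1e-9


class TestFlankGc:
    def test_null_case_high_p(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300_000))
        genome = {"chr1": seq}
        events = [ev("chr1", i * 6_000 + 2_500, i * 6_000 + 2_600) for i in range(40)]
        res = flank_gc_analysis(events, genome, g0=50.0)
        assert res.p > 0.01
        assert res.mean == pytest.approx(50.0, abs=1.5)

    def test_t_matches_manual_formula(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=120_000))
        genome = {"chr1": seq}
        events = [ev("chr1", i * 6_000 + 2_500, i * 6_000 + 2_600) for i in range(15)]
        res = flank_gc_analysis(events, genome, g0=41.0)
        x = res.gc_percent
        t_manual = (x.mean() - 41.0) / (x.std(ddof=1) / np.sqrt(len(x)))
        p_manual = 2 * stats.t.sf(abs(t_manual), df=len(x) - 1)
        assert res.t == pytest.approx(t_manual, abs=1e-9)
        assert res.p == pytest.approx(p_manual, abs=1e-9)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        gc = 0.46
        codes = rng.choice(4, size=400_000, p=[(1-gc)/2, gc/2, gc/2, (1-gc)/2])
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
        events = [ev("chr1", i * 6_000 + 2_500, i * 6_000 + 2_600) for i in range(60)]
        res = flank_gc_analysis(events, {"chr1": seq}, g0=40.9)
        assert res.p < 0.05 and res.mean > 44.0

    def test_too_few_flanks_signalled(self):
        with pytest.raises(ValidationError):
            flank_gc_analysis([ev("chr1", 100, 200)], {"chr1": "ACGT" * 1000})
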