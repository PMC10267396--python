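"""Integration-target preference analyses.

Four views of where de novo SVA insertions land:

* chromosomal density — events per chromosome scaled by the mean annotated
  SVA length and chromosome size ("SVA bp per million chromosomal bp"),
  compared with the reference (annotated-SVA) profile by Pearson
  correlation with a Student-t p-value;
* genomic feature annotation — each event's midpoint assigned one label by
  a fixed precedence over gene features and TE classes;
* TE-rich windows — 100 kb windows with a 10 kb stagger scored by their
  SINE+LINE element count; enrichment is the fraction of LINE/SINE-labeled
  events falling in above-average (or top-quartile) windows;
* flank GC — GC% of event spans extended by 2.5 kb each side, tested
  against the genome-average constant with a one-sample two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ValidationError,
    gc_fraction,
    make_windows,
)
from .insertion_calling import InsertionEvent

__all__ = [
    "DensityProfile",
    "CorrelationTest",
    "FeatureAnnotation",
    "WindowEnrichment",
    "GcResult",
    "FEATURE_LABELS",
    "chromosomal_density",
    "density_correlation",
    "annotate_features",
    "te_rich_windows",
    "te_enrichment_fraction",
    "flank_gc_analysis",
]

FEATURE_LABELS = [
    "3UTR", "ncRNA", "TTS", "LINE", "SINE", "DNA", "Exon", "Intron",
    "Intergenic", "Promoter", "5UTR", "LTR", "Satellite",
]

PROMOTER_UP = 1_000   # promoter window: TSS -1 kb .. +100 bp (strand-aware)
PROMOTER_DOWN = 100
TTS_UP = 100          # termination window: TTS -100 bp .. +1 kb
TTS_DOWN = 1_000


@dataclass
class DensityProfile:
    """Per-chromosome density: n_c * mean SVA length / size * 1e6."""

    table: pd.DataFrame  # index chrom; columns: count, size, density
    mean_sva_length: float

    def densities(self, chroms: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(chroms), "density"].to_numpy()


@dataclass
class CorrelationTest:
    r: float
    n: int
    t: float
    p: float


def chromosomal_density(
    counts: Dict[str, int],
    chrom_sizes: Dict[str, int],
    sva_annotation: IntervalSet,
) -> DensityProfile:
    """Density of insertions per chromosome in SVA bp per Mb.

    The per-chromosome count is multiplied by the mean annotated SVA length
    (estimated from the reference annotation) and divided by the chromosome
    size, scaled to a million bp.
    """
    if len(sva_annotation) == 0:
        raise ValidationError("need a non-empty SVA annotation")
    mean_len = float(np.mean([len(iv) for iv in sva_annotation]))
    rows = []
    for chrom in counts:
        if chrom not in chrom_sizes:
            raise ValidationError(f"chromosome {chrom!r} absent from size table")
    for chrom in sorted(chrom_sizes):
        n = counts.get(chrom, 0)
        size = chrom_sizes[chrom]
        if size <= 0:
            raise ValidationError(f"non-positive size for {chrom}")
        rows.append((chrom, n, size, n * mean_len / size * 1e6))
    table = pd.DataFrame(
        rows, columns=["chrom", "count", "size", "density"]
    ).set_index("chrom")
    return DensityProfile(table, mean_len)


def reference_density(
    sva_annotation: IntervalSet, chrom_sizes: Dict[str, int]
) -> DensityProfile:
    """Density profile of the annotated (germline) SVAs themselves."""
    counts: Dict[str, int] = {}
    for iv in sva_annotation:
        counts[iv.chrom] = counts.get(iv.chrom, 0) + 1
    return chromosomal_density(counts, chrom_sizes, sva_annotation)


def mean_profile(profiles: Sequence[DensityProfile]) -> DensityProfile:
    """Arithmetic mean of density profiles across donors."""
    base = profiles[0].table.copy()
    base["density"] = np.mean([p.table["density"].to_numpy() for p in profiles], axis=0)
    base["count"] = np.mean([p.table["count"].to_numpy() for p in profiles], axis=0)
    return DensityProfile(base, profiles[0].mean_sva_length)


def density_correlation(
    profile_a: DensityProfile, profile_b: DensityProfile
) -> CorrelationTest:
    """Pearson r over paired chromosome densities with a t-distribution p.

    t = r * sqrt(n-2) / sqrt(1-r^2); p is the two-tailed tail probability
    of Student's t with n-2 degrees of freedom.
    """
    chroms = sorted(set(profile_a.table.index) & set(profile_b.table.index))
    n = len(chroms)
    if n < 3:
        raise ValidationError("need at least 3 shared chromosomes")
    a = profile_a.densities(chroms)
    b = profile_b.densities(chroms)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationTest(r=r, n=n, t=float("inf"), p=0.0)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationTest(r=r, n=n, t=float(t), p=p)


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------


@dataclass
class FeatureAnnotation:
    labels: Dict[int, str]          # event index -> label
    fractions: pd.DataFrame         # regions x FEATURE_LABELS, rows sum to 1


def _promoter_window(g: GeneModel) -> Tuple[int, int]:
    if g.strand == "+":
        return g.tss - PROMOTER_UP, g.tss + PROMOTER_DOWN + 1
    return g.tss - PROMOTER_DOWN, g.tss + PROMOTER_UP + 1


def _tts_window(g: GeneModel) -> Tuple[int, int]:
    if g.strand == "+":
        return g.tts - TTS_UP, g.tts + TTS_DOWN + 1
    return g.tts - TTS_DOWN, g.tts + TTS_UP + 1


def _classify_point(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    te: IntervalSet,
) -> str:
    """One label by fixed precedence: Promoter > 5UTR > 3UTR > Exon > TTS >
    ncRNA > SINE > LINE > LTR > DNA > Satellite > Intron > Intergenic."""
    in_promoter = in_5utr = in_3utr = in_exon = in_tts = in_nc = in_intron = False
    for g in genes:
        if g.chrom != chrom:
            continue
        lo, hi = _promoter_window(g)
        if lo <= pos < hi:
            in_promoter = True
        lo, hi = _tts_window(g)
        if lo <= pos < hi:
            in_tts = True
        if not (g.start <= pos < g.end):
            continue
        exonic = any(s <= pos < e for s, e in g.exons)
        if not g.coding:
            if exonic:
                in_nc = True
            else:
                in_intron = True
            continue
        if exonic:
            if g.strand == "+":
                if pos < g.cds_start:
                    in_5utr = True
                elif pos >= g.cds_end:
                    in_3utr = True
                else:
                    in_exon = True
            else:
                if pos >= g.cds_end:
                    in_5utr = True
                elif pos < g.cds_start:
                    in_3utr = True
                else:
                    in_exon = True
        else:
            in_intron = True
    if in_promoter:
        return "Promoter"
    if in_5utr:
        return "5UTR"
    if in_3utr:
        return "3UTR"
    if in_exon:
        return "Exon"
    if in_tts:
        return "TTS"
    if in_nc:
        return "ncRNA"
    point = GenomicInterval(chrom, pos, pos + 1)
    te_classes = {iv.label for iv in te.overlapping(point)}
    for cls in ("SINE", "LINE", "LTR", "DNA", "Satellite"):
        if cls in te_classes:
            return cls
    if in_intron:
        return "Intron"
    return "Intergenic"


def annotate_features(
    events_by_region: Dict[str, Sequence[InsertionEvent]],
    genes: Sequence[GeneModel],
    te_annotation: IntervalSet,
) -> FeatureAnnotation:
    """Assign one feature label per event (midpoint rule) and tabulate
    per-region fractions over all annotated events."""
    labels: Dict[int, str] = {}
    frac_rows = {}
    idx = 0
    for region in sorted(events_by_region):
        counts = {lab: 0 for lab in FEATURE_LABELS}
        for ev in events_by_region[region]:
            lab = _classify_point(
                ev.interval.chrom, ev.interval.midpoint, genes, te_annotation
            )
            labels[idx] = lab
            counts[lab] += 1
            idx += 1
        total = sum(counts.values())
        frac_rows[region] = (
            {lab: counts[lab] / total for lab in FEATURE_LABELS}
            if total
            else {lab: 0.0 for lab in FEATURE_LABELS}
        )
    fractions = pd.DataFrame.from_dict(frac_rows, orient="index")[FEATURE_LABELS]
    return FeatureAnnotation(labels, fractions)


def label_events(
    events: Sequence[InsertionEvent],
    genes: Sequence[GeneModel],
    te_annotation: IntervalSet,
) -> List[str]:
    """Feature label for each event in order (midpoint rule)."""
    return [
        _classify_point(ev.interval.chrom, ev.interval.midpoint, genes, te_annotation)
        for ev in events
    ]


# ---------------------------------------------------------------------------
# TE-rich windows
# ---------------------------------------------------------------------------


@dataclass
class WindowEnrichment:
    windows: IntervalSet
    counts: np.ndarray
    mean_count: float
    top25_threshold: float
    above_mean: IntervalSet
    top25: IntervalSet


def te_rich_windows(
    te_annotation: IntervalSet,
    chrom_sizes: Dict[str, int],
    width: int = 100_000,
    stagger: int = 10_000,
) -> WindowEnrichment:
    """Score staggered windows by their SINE+LINE element count.

    ``above_mean`` keeps windows whose count strictly exceeds the mean;
    ``top25`` keeps windows at or above the 75th percentile
    (linear-interpolation quantile). The two sets are computed
    independently.
    """
    windows = make_windows(chrom_sizes, width, stagger)
    sl = IntervalSet(iv for iv in te_annotation if iv.label in ("SINE", "LINE"))
    counts = np.array(
        [len(sl.overlapping(w)) for w in windows], dtype=float
    )
    mean = float(counts.mean()) if len(counts) else 0.0
    q75 = float(np.quantile(counts, 0.75)) if len(counts) else 0.0
    wlist = list(windows)
    above = IntervalSet(w for w, c in zip(wlist, counts) if c > mean)
    top = IntervalSet(w for w, c in zip(wlist, counts) if c >= q75)
    return WindowEnrichment(windows, counts, mean, q75, above, top)


def te_enrichment_fraction(
    events: Sequence[InsertionEvent],
    labels: Sequence[str],
    window_set: IntervalSet,
) -> float:
    """Percent of LINE/SINE-labeled events overlapping >=1 window."""
    pairs = [
        ev for ev, lab in zip(events, labels) if lab in ("LINE", "SINE")
    ]
    if not pairs:
        raise ValidationError("no LINE/SINE-labeled events")
    inside = sum(1 for ev in pairs if window_set.overlaps_any(ev.interval))
    return 100.0 * inside / len(pairs)


# ---------------------------------------------------------------------------
# Flank GC analysis
# ---------------------------------------------------------------------------


@dataclass
class GcResult:
    gc_percent: np.ndarray  # per-flank GC in %
    mean: float
    t: float
    p: float
    g0: float


def flank_gc_analysis(
    events: Sequence[InsertionEvent],
    genome: Dict[str, str],
    extension: int = 2_500,
    g0: float = 40.9,
) -> GcResult:
    """GC% of event spans extended +-``extension`` bp vs the genome constant.

    One-sample two-tailed t-test of the per-flank GC values against ``g0``
    (percent), df = m-1. Extension is clipped at chromosome ends.
    """
    if len(events) < 2:
        raise ValidationError("need at least 2 flanks for the t-test")
    values = []
    for ev in events:
        iv = ev.interval
        seq = genome[iv.chrom]
        lo = max(0, iv.start - extension)
        hi = min(len(seq), iv.end + extension)
        values.append(100.0 * gc_fraction(seq[lo:hi]))
    arr = np.array(values)
    t, p = stats.ttest_1samp(arr, g0)
    return GcResult(arr, float(arr.mean()), float(t), float(p), g0)
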