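"""Germline subtraction, unique genome mapping, and event collapsing.

The calling stages, in order:

1. align candidate flanks against every annotated SVA extended by 1 kb and
   drop any flank that hits (germline-transmitted / reference-derived);
2. map survivors to the genome and keep flanks with exactly one qualifying
   alignment genome-wide (both strands);
3. drop hits overlapping annotated SVA +- 3 kb (stringency re-check);
4. single-linkage merge the remaining hit intervals per region into
   insertion events carrying read support and distinct-flank counts.

The built-in aligner is an exact / near-exact seeded search (16-mer seeds,
ungapped verification) adequate for synthetic scale; external aligners can
be substituted by importing their hit tables as ``AlignmentHit`` lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genomic_core import (
    GenomicInterval,
    IntervalSet,
    ValidationError,
    merge_overlapping,
    revcomp,
)
from .read_processing import CandidateFlank

__all__ = [
    "AlignmentHit",
    "InsertionEvent",
    "SeedIndex",
    "align_flanks",
    "filter_sva_reference_hits",
    "unique_genome_mapping",
    "subtract_annotated_sva",
    "collapse_to_events",
    "singleton_fraction",
    "call_insertions",
    "CallingReport",
]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValidationError("identity/coverage must be in [0, 1]")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.target, self.start, self.end, self.strand)


@dataclass
class InsertionEvent:
    """A collapsed locus accepted as one de novo SVA integration."""

    interval: GenomicInterval
    region: str
    donor: str
    support: int
    distinct_flanks: int

    def __post_init__(self) -> None:
        if not (self.support >= self.distinct_flanks >= 1):
            raise ValidationError("require support >= distinct_flanks >= 1")


_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


class SeedIndex:
    """A k-mer seed index over a set of named target sequences.

    Exact mode reports every exact occurrence of the query (seeding at the
    query's first k-mer is lossless for exact matches). Near-exact mode
    seeds at k-spaced offsets and verifies candidates by ungapped Hamming
    identity; a hit can be missed only if every sampled seed carries a
    mismatch.
    """

    K = 16

    def __init__(self, targets: Dict[str, str]):
        if not targets:
            raise ValidationError("empty target set")
        self.targets = {name: seq.upper() for name, seq in targets.items()}
        self._names: List[str] = []
        self._kmers: List[np.ndarray] = []
        self._order: List[np.ndarray] = []
        k = self.K
        for name in sorted(self.targets):
            seq = self.targets[name]
            self._names.append(name)
            if len(seq) < k:
                self._kmers.append(np.empty(0, dtype=np.uint64))
                self._order.append(np.empty(0, dtype=np.int64))
                continue
            codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            valid = codes < 4
            codes = np.where(valid, codes, 0).astype(np.uint64)
            n = len(seq) - k + 1
            h = np.zeros(n, dtype=np.uint64)
            for j in range(k):
                h = h * np.uint64(4) + codes[j : j + n]
            # k-mers spanning an ambiguous base never match a query seed
            bad = np.zeros(n, dtype=bool)
            invalid_pos = np.flatnonzero(~valid)
            for p in invalid_pos:
                bad[max(0, p - k + 1) : p + 1] = True
            h[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
            order = np.argsort(h, kind="stable")
            self._kmers.append(h[order])
            self._order.append(order.astype(np.int64))

    @staticmethod
    def _encode_kmer(kmer: str) -> Optional[int]:
        v = 0
        for ch in kmer:
            c = _CODE[ord(ch)]
            if c >= 4:
                return None
            v = v * 4 + int(c)
        return v

    def _seed_positions(self, ti: int, kmer: str) -> np.ndarray:
        code = self._encode_kmer(kmer)
        if code is None:
            return np.empty(0, dtype=np.int64)
        hs = self._kmers[ti]
        lo = np.searchsorted(hs, np.uint64(code), side="left")
        hi = np.searchsorted(hs, np.uint64(code), side="right")
        return self._order[ti][lo:hi]

    def find_exact(self, query: str) -> List[Tuple[str, int]]:
        """All exact occurrences of ``query`` (forward orientation only)."""
        k = self.K
        out: List[Tuple[str, int]] = []
        if len(query) < k:
            raise ValidationError(f"query shorter than seed size {k}")
        for ti, name in enumerate(self._names):
            seq = self.targets[name]
            for pos in self._seed_positions(ti, query[:k]):
                p = int(pos)
                if seq[p : p + len(query)] == query:
                    out.append((name, p))
        out.sort()
        return out

    def find(
        self, query: str, min_identity: float, min_coverage: float
    ) -> List[Tuple[str, int, float, float]]:
        """Near-exact ungapped hits: (target, start, identity, coverage)."""
        k = self.K
        m = len(query)
        if m < k:
            raise ValidationError(f"query shorter than seed size {k}")
        offsets = list(range(0, m - k + 1, k))
        if offsets[-1] != m - k:
            offsets.append(m - k)
        out: List[Tuple[str, int, float, float]] = []
        for ti, name in enumerate(self._names):
            seq = self.targets[name]
            starts = set()
            for off in offsets:
                for pos in self._seed_positions(ti, query[off : off + k]):
                    starts.add(int(pos) - off)
            for s in sorted(starts):
                lo = max(s, 0)
                hi = min(s + m, len(seq))
                if hi <= lo:
                    continue
                aligned = hi - lo
                coverage = aligned / m
                if coverage < min_coverage:
                    continue
                qseg = query[lo - s : hi - s]
                tseg = seq[lo:hi]
                matches = sum(1 for a, b in zip(qseg, tseg) if a == b)
                identity = matches / aligned
                if identity >= min_identity:
                    out.append((name, lo, identity, coverage))
        return out


def align_flanks(
    flanks: Sequence[CandidateFlank],
    index: SeedIndex,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
    exact: bool = False,
) -> Dict[str, List[AlignmentHit]]:
    """All qualifying hits per flank sequence, both strands.

    Coordinates are reported on the forward strand of the target. Keys of
    the returned mapping are flank sequences (the collapse key).
    """
    hits: Dict[str, List[AlignmentHit]] = {}
    for f in flanks:
        found: List[AlignmentHit] = []
        for strand, q in (("+", f.seq), ("-", revcomp(f.seq))):
            if exact:
                for name, pos in index.find_exact(q):
                    found.append(
                        AlignmentHit(f.seq, name, pos, pos + len(q), strand, 1.0, 1.0)
                    )
            else:
                for name, pos, ident, cov in index.find(q, min_identity, min_coverage):
                    end = min(pos + len(q), len(index.targets[name]))
                    found.append(
                        AlignmentHit(f.seq, name, max(pos, 0), end, strand, ident, cov)
                    )
        hits[f.seq] = sorted(
            found, key=lambda h: (h.target, h.start, h.end, h.strand)
        )
    return hits


def _padded_reference_targets(
    sva_annotation: IntervalSet, genome: Dict[str, str], pad: int
) -> Dict[str, str]:
    targets = {}
    for i, iv in enumerate(sva_annotation):
        seq = genome[iv.chrom]
        lo = max(0, iv.start - pad)
        hi = min(len(seq), iv.end + pad)
        targets[f"{iv.label or 'SVA'}_{i}_{iv.chrom}:{lo}-{hi}"] = seq[lo:hi]
    return targets


def filter_sva_reference_hits(
    flanks: Sequence[CandidateFlank],
    sva_annotation: IntervalSet,
    genome: Dict[str, str],
    pad: int = 1_000,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
    exact: bool = False,
) -> Tuple[List[CandidateFlank], int]:
    """Drop flanks hitting any annotated SVA extended by ``pad`` bp.

    Returns (surviving flanks, number discarded).
    """
    if len(sva_annotation) == 0:
        return list(flanks), 0
    index = SeedIndex(_padded_reference_targets(sva_annotation, genome, pad))
    hits = align_flanks(flanks, index, min_identity, min_coverage, exact)
    survivors = [f for f in flanks if not hits[f.seq]]
    return survivors, len(flanks) - len(survivors)


def unique_genome_mapping(
    flanks: Sequence[CandidateFlank],
    genome_index: SeedIndex,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
    exact: bool = False,
) -> Tuple[List[Tuple[CandidateFlank, AlignmentHit]], int, int]:
    """Keep flanks with exactly one qualifying genome hit.

    Returns (kept pairs, n_unmapped, n_multimapped).
    """
    hits = align_flanks(flanks, genome_index, min_identity, min_coverage, exact)
    kept: List[Tuple[CandidateFlank, AlignmentHit]] = []
    unmapped = multi = 0
    for f in flanks:
        h = hits[f.seq]
        if len(h) == 0:
            unmapped += 1
        elif len(h) > 1:
            multi += 1
        else:
            kept.append((f, h[0]))
    return kept, unmapped, multi


def subtract_annotated_sva(
    pairs: Sequence[Tuple[CandidateFlank, AlignmentHit]],
    sva_annotation: IntervalSet,
    pad: int = 3_000,
) -> Tuple[List[Tuple[CandidateFlank, AlignmentHit]], int]:
    """Remove hits overlapping annotated SVA extended by ``pad`` bp."""
    padded = merge_overlapping(
        IntervalSet(iv.padded(pad) for iv in sva_annotation)
    )
    kept = [(f, h) for f, h in pairs if not padded.overlaps_any(h.interval)]
    return kept, len(pairs) - len(kept)


def collapse_to_events(
    pairs: Sequence[Tuple[CandidateFlank, AlignmentHit]],
    region: str,
    donor: str,
) -> List[InsertionEvent]:
    """Single-linkage merge of overlapping hit intervals into events.

    Event support is the summed read support of contributing flanks;
    ``distinct_flanks`` counts the collapsed flank sequences. Output order
    is genomic and independent of input order.
    """
    items = sorted(
        pairs, key=lambda p: (p[1].target, p[1].start, p[1].end, p[0].seq)
    )
    events: List[InsertionEvent] = []
    cur_iv: Optional[GenomicInterval] = None
    cur_support = 0
    cur_flanks = 0
    for f, h in items:
        iv = h.interval
        if cur_iv is not None and iv.chrom == cur_iv.chrom and iv.start < cur_iv.end:
            cur_iv = GenomicInterval(
                cur_iv.chrom, cur_iv.start, max(cur_iv.end, iv.end)
            )
            cur_support += f.support
            cur_flanks += 1
        else:
            if cur_iv is not None:
                events.append(
                    InsertionEvent(cur_iv, region, donor, cur_support, cur_flanks)
                )
            cur_iv = GenomicInterval(iv.chrom, iv.start, iv.end)
            cur_support = f.support
            cur_flanks = 1
    if cur_iv is not None:
        events.append(InsertionEvent(cur_iv, region, donor, cur_support, cur_flanks))
    return events


def singleton_fraction(events: Sequence[InsertionEvent]) -> float:
    """Fraction of events supported by exactly one read."""
    if not events:
        raise ValidationError("singleton fraction undefined for empty event list")
    return sum(1 for e in events if e.support == 1) / len(events)


@dataclass
class CallingReport:
    """Per-stage flank accounting for one region/donor."""

    flanks_in: int = 0
    sva_reference_discarded: int = 0
    unmapped: int = 0
    multimapped: int = 0
    sva_proximal_discarded: int = 0
    events: int = 0

    def as_dict(self) -> Dict[str, int]:
        return self.__dict__.copy()


def call_insertions(
    flanks: Sequence[CandidateFlank],
    genome: Dict[str, str],
    sva_annotation: IntervalSet,
    region: str,
    donor: str,
    genome_index: Optional[SeedIndex] = None,
    reference_pad: int = 1_000,
    subtraction_pad: int = 3_000,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
    exact: bool = False,
) -> Tuple[List[InsertionEvent], CallingReport]:
    """Run the full calling cascade for one region of one donor."""
    report = CallingReport(flanks_in=len(flanks))
    survivors, n_ref = filter_sva_reference_hits(
        flanks, sva_annotation, genome, reference_pad, min_identity, min_coverage, exact
    )
    report.sva_reference_discarded = n_ref
    if genome_index is None:
        genome_index = SeedIndex(genome)
    pairs, unmapped, multi = unique_genome_mapping(
        survivors, genome_index, min_identity, min_coverage, exact
    )
    report.unmapped, report.multimapped = unmapped, multi
    pairs, n_prox = subtract_annotated_sva(pairs, sva_annotation, subtraction_pad)
    report.sva_proximal_discarded = n_prox
    events = collapse_to_events(pairs, region, donor)
    report.events = len(events)
    return events, report
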