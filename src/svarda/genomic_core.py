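"""Coordinate conventions, interval algebra, and sequence/annotation I/O.

All genomic coordinates in this package are 0-based, half-open (BED
convention): an interval covers positions ``start .. end-1`` and two
intervals overlap iff they share at least one base; abutting intervals
(``a.end == b.start``) do not overlap.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "SequenceRecord",
    "ValidationError",
    "intersect",
    "subtract_overlapping",
    "merge_overlapping",
    "make_windows",
    "gc_fraction",
    "revcomp",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]


class ValidationError(ValueError):
    """Raised for malformed intervals or sequences."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded); ``label`` is
    free text such as a TE class or event name.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def padded(self, pad: int) -> "GenomicInterval":
        """Extend both ends by ``pad`` bp, clipping the start at 0."""
        return replace(self, start=max(0, self.start - pad), end=self.end + pad)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> Tuple:
        return (self.chrom, self.start, self.end, self.strand, self.label)


class IntervalSet:
    """An immutable, deterministically ordered collection of intervals.

    Iteration order is chrom-lexicographic, then start, then end — the
    canonical BED sort — regardless of construction order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._intervals: List[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        self._by_chrom: Optional[Dict[str, Tuple[List[int], List[int]]]] = None

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def _index(self) -> Dict[str, Tuple[List[int], List[int]]]:
        # per chrom: starts (sorted) and running max of ends in start order
        if self._by_chrom is None:
            idx: Dict[str, Tuple[List[int], List[int]]] = {}
            for iv in self._intervals:
                idx.setdefault(iv.chrom, ([], []))
            for iv in self._intervals:
                starts, maxends = idx[iv.chrom]
                starts.append(iv.start)
                prev = maxends[-1] if maxends else 0
                maxends.append(max(prev, iv.end))
            self._by_chrom = idx
        return self._by_chrom

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        """True iff ``iv`` overlaps at least one member (>=1 bp)."""
        entry = self._index().get(iv.chrom)
        if entry is None:
            return False
        starts, maxends = entry
        hi = bisect.bisect_left(starts, iv.end)
        return hi > 0 and maxends[hi - 1] > iv.start

    def overlapping(self, iv: GenomicInterval) -> List[GenomicInterval]:
        """All members overlapping ``iv`` (linear scan within the chrom)."""
        return [m for m in self._intervals if m.overlaps(iv)]


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Members of ``a`` overlapping >=1 bp with any member of ``b``."""
    return IntervalSet(iv for iv in a if b.overlaps_any(iv))


def subtract_overlapping(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Members of ``a`` with zero overlap against ``b`` (whole-interval removal)."""
    return IntervalSet(iv for iv in a if not b.overlaps_any(iv))


def merge_overlapping(a: IntervalSet) -> IntervalSet:
    """Single-linkage union: chains of pairwise-overlapping intervals collapse
    to one interval spanning min(start)..max(end). Strand/labels are dropped
    when more than one interval merges; a lone interval passes through."""
    merged: List[GenomicInterval] = []
    cur: Optional[GenomicInterval] = None
    n_in_cur = 0
    for iv in a:
        if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end))
            n_in_cur += 1
        else:
            if cur is not None:
                merged.append(cur)
            cur = iv
            n_in_cur = 1
    if cur is not None:
        merged.append(cur)
    return IntervalSet(merged)


def make_windows(
    chrom_sizes: Dict[str, int], width: int, stagger: int
) -> IntervalSet:
    """Staggered windows tiling each chromosome.

    Windows start at 0, stagger, 2*stagger, ...; a final truncated window is
    emitted so every position is covered. ``stagger`` must not exceed
    ``width``.
    """
    if width <= 0:
        raise ValidationError("window width must be > 0")
    if not (0 < stagger <= width):
        raise ValidationError("require 0 < stagger <= width")
    out: List[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        pos = 0
        while pos < size:
            out.append(GenomicInterval(chrom, pos, min(pos + width, size)))
            if pos + width >= size:
                break
            pos += stagger
    return IntervalSet(out)


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N bases are excluded from the denominator."""
    if not seq:
        raise ValidationError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise ValidationError("sequence has no unambiguous bases")
    return gc / denom


@dataclass
class GeneModel:
    """A transcript model with exon structure and optional CDS bounds.

    ``exons`` are genomic half-open intervals in ascending order. Coding
    transcripts carry ``cds_start``/``cds_end`` (genomic); non-coding
    transcripts (ncRNA) have ``cds_start == cds_end``.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]]
    cds_start: int
    cds_end: int

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def read_genes_bed12(path) -> List[GeneModel]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        cds_start, cds_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offs = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
        genes.append(GeneModel(name, chrom, start, end, strand, exons, cds_start, cds_end))
    return genes


def write_genes_bed12(genes: Sequence[GeneModel], path) -> None:
    lines = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        offs = ",".join(str(s - g.start) for s, e in g.exons)
        lines.append(
            f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}"
            f"\t{g.cds_start}\t{g.cds_end}\t0\t{len(g.exons)}\t{sizes}\t{offs}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Sequence records and file I/O
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValidationError(f"qual/seq length mismatch for {self.id}")

    def reverse_complement(self) -> "SequenceRecord":
        q = self.qual[::-1] if self.qual is not None else None
        return SequenceRecord(self.id, revcomp(self.seq), q)


def read_bed(path) -> IntervalSet:
    """Read a 3-6 column BED file (tab-separated)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        label = f[3] if len(f) > 3 else ""
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, label))
    return IntervalSet(out)


def write_bed(ivs: IntervalSet, path, scores: Optional[Sequence[int]] = None) -> None:
    """Write intervals as BED; 6 columns when any strand/label is set."""
    lines = []
    six = any(iv.label or iv.strand != "." for iv in ivs) or scores is not None
    for i, iv in enumerate(ivs):
        if six:
            score = scores[i] if scores is not None else 0
            lines.append(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{score}\t{iv.strand}"
            )
        else:
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path) -> None:
    recs = [_BioSeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> List[SequenceRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(SequenceRecord(rec.id, str(rec.seq), qual))
    return out


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
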