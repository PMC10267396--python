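"""Amplicon read filtering and flank extraction.

An accepted RDA amplicon read has the layout

    [24-mer RDA primer][GATC][genomic 5'-flank][(CCCTCT)_n hexamer][SVA body]

Processing (a) merges overlapping read pairs when input is paired, (b)
keeps reads that begin with the RDA primer (reverse-complemented reads are
flipped first), (c) locates the SVA hexamer run, (d) excises the genomic
flank between the reconstituted GATC ligation junction and the hexamer,
rejecting re-ligation artifacts (an internal GATC) and flanks of <= 30 bp,
and (e) collapses identical flanks, recording read support.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .genomic_core import SequenceRecord, revcomp
from .synthetic_data import HEXAMER, RDA_PRIMER

__all__ = [
    "CandidateFlank",
    "FlankRejection",
    "merge_pairs",
    "scan_rda_primer",
    "scan_hexamer",
    "extract_flank",
    "collapse_flanks",
    "process_reads",
    "FunnelCounts",
]

#: Length of the reconstituted MboI site at the adapter junction. Every true
#: RDA product carries GATC immediately after the primer; it is skipped, not
#: treated as an artifact.
LIGATION_SITE_LEN = 4

MIN_FLANK_LEN = 31  # ">30 bp" read strictly


class FlankRejection(enum.Enum):
    ARTIFACT_GATC = "artifact_gatc"
    TOO_SHORT = "too_short"
    BAD_LANDMARKS = "bad_landmarks"


@dataclass
class CandidateFlank:
    """A cleaned genomic 5'-flank, written 5'->3' toward the SVA."""

    seq: str
    region: str
    donor: str
    support: int = 1
    read_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "GATC" in self.seq:
            raise ValueError("candidate flank must be GATC-free")
        if len(self.seq) < MIN_FLANK_LEN:
            raise ValueError(f"flank shorter than {MIN_FLANK_LEN} bp")


def merge_pairs(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Optional[SequenceRecord]:
    """Merge an overlapping pair into one fragment, or return None.

    Finds the maximal suffix(r1)/prefix(revcomp(r2)) overlap of at least
    ``min_overlap`` bp whose mismatch fraction is within
    ``max_mismatch_frac``; disagreeing bases take the higher-quality call.
    """
    r2rc = r2.reverse_complement()
    a, b = r1.seq, r2rc.seq
    qa = r1.qual or "I" * len(a)
    qb = r2rc.qual or "I" * len(b)
    best = None
    for ov in range(min(len(a), len(b)), min_overlap - 1, -1):
        sa, sb = a[len(a) - ov :], b[:ov]
        mism = sum(1 for x, y in zip(sa, sb) if x != y)
        if mism / ov <= max_mismatch_frac:
            best = ov
            break
    if best is None:
        return None
    ov = best
    head = a[: len(a) - ov]
    tail = b[ov:]
    mid = []
    midq = []
    for i in range(ov):
        ia, ib = len(a) - ov + i, i
        if a[ia] == b[ib] or qa[ia] >= qb[ib]:
            mid.append(a[ia])
            midq.append(qa[ia])
        else:
            mid.append(b[ib])
            midq.append(qb[ib])
    seq = head + "".join(mid) + tail
    qual = qa[: len(a) - ov] + "".join(midq) + qb[ov:]
    rid = r1.id[:-2] if r1.id.endswith("/1") else r1.id
    return SequenceRecord(rid, seq, qual)


def _mismatches_prefix(seq: str, motif: str) -> int:
    return sum(1 for a, b in zip(seq, motif) if a != b)


def scan_rda_primer(
    read: SequenceRecord,
    primer: str = RDA_PRIMER,
    max_mismatch: int = 0,
) -> Optional[Tuple[SequenceRecord, int]]:
    """Orient a read primer-first and return (oriented read, primer end).

    Accepts reads whose first bases match the RDA primer within
    ``max_mismatch``; a read ending in revcomp(primer) is flipped and
    re-scanned. Returns None when the primer is absent.
    """
    if len(read.seq) >= len(primer):
        if _mismatches_prefix(read.seq, primer) <= max_mismatch:
            return read, len(primer)
        tail = read.seq[-len(primer):]
        if _mismatches_prefix(tail, revcomp(primer)) <= max_mismatch:
            flipped = read.reverse_complement()
            if _mismatches_prefix(flipped.seq, primer) <= max_mismatch:
                return flipped, len(primer)
    return None


def scan_hexamer(
    read: SequenceRecord, min_copies: int = 2, search_from: int = 0
) -> Optional[int]:
    """Start of the leftmost tandem run of >= min_copies exact hexamers."""
    pattern = re.compile(f"(?:{HEXAMER}){{{min_copies},}}")
    m = pattern.search(read.seq, search_from)
    return m.start() if m else None


def extract_flank(
    read: SequenceRecord,
    primer_end: int,
    hexamer_start: int,
    region: str = "",
    donor: str = "",
) -> Tuple[Optional[CandidateFlank], Optional[FlankRejection]]:
    """Excise the genomic flank between the ligation GATC and the hexamer.

    The 4 bp immediately after the primer are the reconstituted MboI site
    and are skipped; any GATC *inside* the remaining flank marks a
    re-ligation artifact and rejects the read. Flanks of <= 30 bp are
    length-rejected.
    """
    start = primer_end + LIGATION_SITE_LEN
    if hexamer_start <= start:
        return None, FlankRejection.BAD_LANDMARKS
    flank = read.seq[start:hexamer_start]
    if "GATC" in flank:
        return None, FlankRejection.ARTIFACT_GATC
    if len(flank) < MIN_FLANK_LEN:
        return None, FlankRejection.TOO_SHORT
    return (
        CandidateFlank(flank, region=region, donor=donor, read_ids=(read.id,)),
        None,
    )


def collapse_flanks(flanks: Iterable[CandidateFlank]) -> List[CandidateFlank]:
    """Exact-sequence deduplication; support is the collapsed multiplicity.

    Output order is deterministic (lexicographic by sequence) and
    independent of input order.
    """
    by_seq: Dict[str, List[CandidateFlank]] = {}
    for f in flanks:
        by_seq.setdefault(f.seq, []).append(f)
    out = []
    for seq in sorted(by_seq):
        group = by_seq[seq]
        rids = tuple(sorted(rid for f in group for rid in f.read_ids))
        out.append(
            CandidateFlank(
                seq,
                region=group[0].region,
                donor=group[0].donor,
                support=sum(f.support for f in group),
                read_ids=rids,
            )
        )
    return out


@dataclass
class FunnelCounts:
    """Per-stage read accounting, mirroring the processing funnel."""

    total: int = 0
    primer_matched: int = 0
    hexamer_matched: int = 0
    artifact_rejected: int = 0
    length_rejected: int = 0
    flanks_accepted: int = 0
    flanks_collapsed: int = 0

    def as_dict(self) -> Dict[str, int]:
        return self.__dict__.copy()


def process_reads(
    reads: Sequence[SequenceRecord],
    region: str,
    donor: str,
    primer: str = RDA_PRIMER,
    max_primer_mismatch: int = 0,
    hexamer_min_copies: int = 2,
) -> Tuple[List[CandidateFlank], FunnelCounts]:
    """Run primer scan -> hexamer scan -> flank extraction -> collapse."""
    counts = FunnelCounts(total=len(reads))
    accepted: List[CandidateFlank] = []
    for read in reads:
        hit = scan_rda_primer(read, primer, max_primer_mismatch)
        if hit is None:
            continue
        counts.primer_matched += 1
        oriented, primer_end = hit
        hstart = scan_hexamer(oriented, hexamer_min_copies, primer_end)
        if hstart is None:
            continue
        counts.hexamer_matched += 1
        flank, rejection = extract_flank(oriented, primer_end, hstart, region, donor)
        if rejection is FlankRejection.ARTIFACT_GATC:
            counts.artifact_rejected += 1
        elif rejection in (FlankRejection.TOO_SHORT, FlankRejection.BAD_LANDMARKS):
            counts.length_rejected += 1
        else:
            counts.flanks_accepted += 1
            accepted.append(flank)
    collapsed = collapse_flanks(accepted)
    counts.flanks_collapsed = len(collapsed)
    return collapsed, counts
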