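"""Alignment engine vs exhaustive scans; the germline-subtraction cascade."""

import numpy as np
import pytest

from svarda.genomic_core import GenomicInterval, IntervalSet, revcomp
from svarda.insertion_calling import (
    AlignmentHit,
    SeedIndex,
    align_flanks,
    collapse_to_events,
    filter_sva_reference_hits,
    singleton_fraction,
    subtract_annotated_sva,
    unique_genome_mapping,
)
from svarda.read_processing import CandidateFlank


def random_genome(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def sanitize(seq):
    """Make a random sequence a legal flank (no internal MboI site)."""
    while "GATC" in seq:
        seq = seq.replace("GATC", "GATG")
    return seq


def flank_of(seq, region="R", donor="D", support=1):
    return CandidateFlank(seq, region=region, donor=donor, support=support)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    genome = {"chr1": random_genome(rng, 100_000)}
    return rng, genome


def clean_slice(seq, start, length):
    """First GATC-free window of ``length`` at or after ``start``."""
    pos = start
    while "GATC" in seq[pos : pos + length]:
        pos += 1
    return seq[pos : pos + length]


def sliding_window_hits(genome, query, min_identity):
    """Brute-force ungapped scan on both strands (the oracle)."""
    out = []
    m = len(query)
    for strand, q in (("+", query), ("-", revcomp(query))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for name, seq in genome.items():
            sa = np.frombuffer(seq.encode(), dtype=np.uint8)
            if len(sa) < m:
                continue
            win = np.lib.stride_tricks.sliding_window_view(sa, m)
            matches = (win == qa).sum(axis=1)
            for pos in np.flatnonzero(matches / m >= min_identity):
                out.append((name, int(pos), strand))
    return sorted(out)


class TestAlignment:
    def test_verbatim_flank_single_exact_hit(self, toy):
        _, genome = toy
        q = clean_slice(genome["chr1"], 5_000, 60)
        start = genome["chr1"].index(q)
        hits = align_flanks([flank_of(q)], SeedIndex(genome), exact=True)[q]
        assert len(hits) == 1
        h = hits[0]
        assert (h.target, h.start, h.end, h.identity) == ("chr1", start, start + 60, 1.0)

    def test_duplicated_sequence_two_hits(self, toy):
        core = sanitize(random_genome(np.random.default_rng(7), 60))
        seq = random_genome(np.random.default_rng(8), 2_000) + core + \
            random_genome(np.random.default_rng(9), 2_000) + core + "ACGT"
        hits = align_flanks([flank_of(core)], SeedIndex({"c": seq}), exact=True)[core]
        assert len(hits) == 2

    @pytest.mark.parametrize("n_mut", [0, 1, 2])
    def test_hits_match_sliding_window_oracle(self, toy, n_mut):
        rng = np.random.default_rng(100 + n_mut)
        genome = {"chr1": random_genome(rng, 100_000)}
        index = SeedIndex(genome)
        for _ in range(15):
            start = int(rng.integers(0, 99_000))
            length = int(rng.integers(40, 120))
            q = list(genome["chr1"][start : start + length])
            for pos in rng.choice(length, size=n_mut, replace=False):
                q[pos] = "ACGT"[(("ACGT".index(q[pos])) + 1) % 4]
            q = sanitize("".join(q))
            if int(rng.integers(0, 2)):
                q = revcomp(q)
            q = sanitize(q)
            got = align_flanks(
                [flank_of(q)], index, min_identity=0.9, min_coverage=1.0
            )[q]
            got_pos = sorted((h.target, h.start, h.strand) for h in got)
            assert got_pos == sliding_window_hits(genome, q, 0.9)


class TestGermlineSubtraction:
    def test_leakthrough_flank_discarded_far_flank_survives(self, toy):
        _, genome = toy
        sva = IntervalSet([GenomicInterval("chr1", 50_000, 51_000, "+", "SVA_0")])
        near = clean_slice(genome["chr1"], 49_700, 40)  # upstream, inside 1 kb pad
        far = clean_slice(genome["chr1"], 10_000, 40)   # >> 1 kb from the SVA
        survivors, n = filter_sva_reference_hits(
            [flank_of(near), flank_of(far)], sva, genome, pad=1_000, exact=True
        )
        assert n == 1 and [f.seq for f in survivors] == [far]

    def test_unique_mapping_keeps_exactly_one_hit(self, toy):
        _, genome = toy
        unique = clean_slice(genome["chr1"], 30_000, 50)
        dup_core = sanitize(random_genome(np.random.default_rng(1), 50))
        g2 = {"chr1": genome["chr1"] + dup_core + random_genome(np.random.default_rng(2), 500) + dup_core}
        random_q = sanitize(random_genome(np.random.default_rng(3), 50))
        kept, unmapped, multi = unique_genome_mapping(
            [flank_of(unique), flank_of(dup_core), flank_of(random_q)],
            SeedIndex(g2),
            exact=True,
        )
        assert [f.seq for f, _ in kept] == [unique]
        assert unmapped == 1 and multi == 1

    @pytest.mark.parametrize("dist,kept", [(2_999, False), (3_001, True)])
    def test_subtraction_pad_boundary(self, dist, kept):
        sva = IntervalSet([GenomicInterval("chr1", 10_000, 11_000)])
        start = 11_000 + dist
        pair = (
            flank_of("A" * 40),
            AlignmentHit("A" * 40, "chr1", start, start + 40, "+", 1.0, 1.0),
        )
        out, removed = subtract_annotated_sva([pair], sva, pad=3_000)
        assert (len(out) == 1) is kept and removed == (0 if kept else 1)


class TestEventCollapse:
    def _pair(self, seq, start, end, support):
        return (
            flank_of(seq, support=support),
            AlignmentHit(seq, "chr1", start, end, "+", 1.0, 1.0),
        )

    def test_overlapping_hits_merge_supports_sum(self):
        pairs = [
            self._pair("A" * 80, 100, 180, 2),
            self._pair("C" * 80, 150, 230, 1),
        ]
        events = collapse_to_events(pairs, "R", "D")
        assert len(events) == 1
        e = events[0]
        assert (e.interval.start, e.interval.end) == (100, 230)
        assert e.support == 3 and e.distinct_flanks == 2

    def test_disjoint_hits_one_event_each(self):
        pairs = [self._pair("A" * 40, 100, 140, 1), self._pair("C" * 40, 500, 540, 1)]
        assert len(collapse_to_events(pairs, "R", "D")) == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_event_count_equals_connected_components(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        pairs = []
        for i in range(120):
            start = int(rng.integers(0, 5_000))
            end = start + int(rng.integers(20, 120))
            pairs.append(self._pair(sanitize(random_genome(rng, 40)), start, end, 1))
        events = collapse_to_events(pairs, "R", "D")
        g = nx.Graph()
        g.add_nodes_from(range(len(pairs)))
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                if pairs[i][1].interval.overlaps(pairs[j][1].interval):
                    g.add_edge(i, j)
        assert len(events) == nx.number_connected_components(g)

    def test_invariant_under_input_order(self):
        rng = np.random.default_rng(5)
        pairs = []
        for _ in range(40):
            start = int(rng.integers(0, 2_000))
            pairs.append(self._pair(sanitize(random_genome(rng, 40)), start, start + 50, 1))
        e1 = collapse_to_events(pairs, "R", "D")
        e2 = collapse_to_events(list(reversed(pairs)), "R", "D")
        assert [(e.interval.sort_key(), e.support, e.distinct_flanks) for e in e1] == [
            (e.interval.sort_key(), e.support, e.distinct_flanks) for e in e2
        ]

    def test_singleton_fraction(self):
        evs = collapse_to_events(
            [self._pair("A" * 40, i * 200, i * 200 + 40, s) for i, s in enumerate([1, 1, 1, 2])],
            "R", "D",
        )
        assert singleton_fraction(evs) == 0.75
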