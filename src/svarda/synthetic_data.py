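"""Synthetic genomes, lineage-structured somatic SVA insertions, and RDA reads.

The simulator emulates the data-generating process the pipeline assumes:

* a toy reference genome with a block-wise GC landscape, clustered TE
  annotation (SINE/LINE/LTR/DNA/Satellite), gene models, and planted
  germline SVA elements whose bodies begin with a (CCCTCT)_n hexamer;
* somatic SVA insertions assigned to branches of a brain-region lineage
  tree, so an insertion sits in exactly the regions descended from the
  cell division on whose branch it arose;
* RDA amplicon reads with the structure
  ``[24-mer RDA primer][GATC][genomic 5'-flank][(CCCTCT)_n][SVA body]``,
  a read-support distribution dominated by singletons, GATC re-ligation
  artifacts, and germline ("driver leak-through") flanks.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .genomic_core import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    SequenceRecord,
    merge_overlapping,
    revcomp,
    write_bed,
    write_fasta,
    write_genes_bed12,
)

__all__ = [
    "RDA_PRIMER",
    "HEXAMER",
    "SVA_BODY",
    "LineageTree",
    "SimulationConfig",
    "Genome",
    "TruthInsertion",
    "TruthSet",
    "generate_genome",
    "simulate_lineage_insertions",
    "synthesize_rda_reads",
    "split_into_pairs",
    "save_genome",
    "write_truth_tsv",
    "read_truth_tsv",
]

#: RDA 24-mer ligated to every tester fragment; amplicons begin with it.
RDA_PRIMER = "ACCGACGTCGACTATCCATGAACG"
#: RDA 12-mer completing the adapter (reconstitutes GATC at the junction).
RDA_12MER = "GATCCGTTCATG"
#: SVA-outward primer used in the enrichment PCR (simulator bookkeeping only).
SVA_OUTWARD_PRIMER = "AGAATCAGGCAGGGAGGTTG"
#: The SVA 5' hexamer unit.
HEXAMER = "CCCTCT"
#: Fixed SVA body sequence downstream of the hexamer run (Alu-like region
#: surrogate); free of GATC and of tandem hexamers.
SVA_BODY = (
    "AGGAGGGAGGTGGGGAGGAGCCAAGGGGAGGAGGCAGAGGAGGAGGGAGGTGGGGAGGAG"
    "CCAAGGAGGGAGGTGGAGAGGAGCCAAGGGGAGGAGGCAGAGGAGGAGGGAGGTGGGGAG"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


class LineageTree:
    """A rooted bifurcating lineage over brain-region labels.

    The default mirrors the ontogeny of the five sampled regions: the
    cerebellum (metencephalon) splits first, then olfactory bulb,
    hippocampus, and finally prefrontal cortex vs calcarine cortex.
    Branches are identified by the sorted tuple of leaves below them; the
    root branch (all leaves) models integrations that coalesce before any
    sampled split.
    """

    DEFAULT_TOPOLOGY = ("Cereb", ("Bulb", ("Hippo", ("Pfc", "Calca"))))

    def __init__(self, topology=DEFAULT_TOPOLOGY):
        self.topology = topology
        self._leaves: List[str] = []
        self._clades: List[Tuple[str, ...]] = []
        self._collect(topology)
        if len(set(self._leaves)) != len(self._leaves):
            raise ValueError("leaf labels must be unique")
        self._clades.append(tuple(sorted(self._leaves)))  # root branch

    def _collect(self, node) -> Tuple[str, ...]:
        if isinstance(node, str):
            self._leaves.append(node)
            clade = (node,)
        else:
            below: List[str] = []
            for child in node:
                below.extend(self._collect(child))
            clade = tuple(sorted(below))
        if clade not in self._clades:
            self._clades.append(clade)
        return clade

    @property
    def leaves(self) -> List[str]:
        return list(self._leaves)

    @property
    def clades(self) -> List[Tuple[str, ...]]:
        """All branches (leaf tuples), terminal branches first encountered."""
        return list(self._clades)

    def internal_clades(self) -> List[Tuple[str, ...]]:
        n = len(self._leaves)
        return [c for c in self._clades if 1 < len(c) < n]


def _default_branch_counts() -> Dict[Tuple[str, ...], int]:
    # 2,000 insertions/donor: mostly region-unique (singleton lineages), a
    # few hundred shared, ~50 deep coalescers present in all five regions.
    return {
        ("Cereb",): 340,
        ("Bulb",): 340,
        ("Hippo",): 340,
        ("Pfc",): 340,
        ("Calca",): 340,
        ("Calca", "Pfc"): 90,
        ("Calca", "Hippo", "Pfc"): 80,
        ("Bulb", "Calca", "Hippo", "Pfc"): 80,
        ("Bulb", "Calca", "Cereb", "Hippo", "Pfc"): 50,
    }


def _default_chrom_sizes() -> Dict[str, int]:
    return {
        "chr1": 800_000,
        "chr2": 700_000,
        "chr3": 600_000,
        "chr4": 500_000,
        "chr5": 400_000,
        "chr6": 300_000,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions the pipeline is evaluated under:
    5 regions x 2 donors, 2,000 somatic insertions per donor on the default
    lineage, a 0.77 singleton fraction, 1% artifact and 1% leak-through
    reads, and no sequencing error.
    """

    seed: int
    chrom_sizes: Dict[str, int] = field(default_factory=_default_chrom_sizes)
    # GC landscape: block-wise base composition
    gc_block: int = 50_000
    gc_mean: float = 0.41
    gc_sd: float = 0.06
    # TE annotation
    te_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "SINE": 650, "LINE": 350, "LTR": 120, "DNA": 90, "Satellite": 40
        }
    )
    te_cluster_block: int = 10_000
    te_cluster_shape: float = 0.5  # gamma shape; smaller => more clustered
    te_mutation_rate: float = 0.15
    # germline SVA + genes
    n_germline_sva: int = 40
    sva_body_len: int = 250
    sva_hexamer_copies: int = 6
    n_genes: int = 50
    # somatic insertions
    branch_counts: Dict[Tuple[str, ...], int] = field(
        default_factory=_default_branch_counts
    )
    placement: str = "uniform"  # uniform | te_biased | density_proportional
    te_bias: float = 0.6        # per-TE-count weight increment (te_biased)
    gc_bias: float = 4.0        # weight slope on (blockGC - gc_mean) (te_biased)
    flank_min: int = 31
    flank_max: int = 150
    hexamer_min_copies: int = 4
    hexamer_max_copies: int = 10
    min_locus_separation: int = 400
    germline_clearance: int = 3_500
    # read synthesis
    singleton_fraction: float = 0.77
    multi_support_extra_mean: float = 1.0  # support = 2 + Poisson(mean) for non-singletons
    artifact_rate: float = 0.01
    leak_rate: float = 0.01
    error_rate: float = 0.0
    n_donors: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("singleton_fraction", "artifact_rate", "leak_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.placement not in ("uniform", "te_biased", "density_proportional"):
            raise ValueError(f"unknown placement mode {self.placement!r}")


@dataclass
class Genome:
    seqs: Dict[str, str]
    te: IntervalSet
    sva: IntervalSet
    genes: List[GeneModel]

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


@dataclass
class TruthInsertion:
    ins_id: str
    chrom: str
    pos: int               # integration point (flank ends here)
    flank_len: int
    branch: Tuple[str, ...]
    flank_seq: str
    hexamer_copies: int
    supports: Dict[str, int] = field(default_factory=dict)

    @property
    def regions(self) -> Tuple[str, ...]:
        return self.branch

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.pos - self.flank_len, self.pos, label=self.ins_id
        )


@dataclass
class TruthSet:
    donor: str
    insertions: List[TruthInsertion]
    germline_sva: IntervalSet
    artifact_read_ids: Set[str] = field(default_factory=set)
    leak_read_ids: Set[str] = field(default_factory=set)

    def intervals(self, region: Optional[str] = None) -> IntervalSet:
        return IntervalSet(
            ins.interval
            for ins in self.insertions
            if region is None or region in ins.regions
        )


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def generate_genome(cfg: SimulationConfig) -> Genome:
    """Build the reference: sequence, TE track, germline SVAs, gene models.

    Deterministic for a given seed. Raises if the genome is too small to
    host the requested germline SVAs with their clearance.
    """
    rng = np.random.default_rng(cfg.seed)
    seq_arrays: Dict[str, np.ndarray] = {}
    block_gc: Dict[str, np.ndarray] = {}
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        n_blocks = -(-size // cfg.gc_block)
        gcs = np.clip(rng.normal(cfg.gc_mean, cfg.gc_sd, n_blocks), 0.25, 0.65)
        block_gc[chrom] = gcs
        parts = [
            _random_sequence(rng, min(cfg.gc_block, size - i * cfg.gc_block), gcs[i])
            for i in range(n_blocks)
        ]
        seq_arrays[chrom] = np.concatenate(parts)

    chroms = sorted(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)

    # --- TE track: clustered placement via per-block gamma weights -------
    te_class_len = {
        "SINE": (80, 300), "LINE": (100, 500), "LTR": (150, 400),
        "DNA": (80, 250), "Satellite": (100, 300),
    }
    consensus = {
        cls: _random_sequence(rng, hi, 0.45)
        for cls, (lo, hi) in te_class_len.items()
    }
    block_w = {
        c: rng.gamma(cfg.te_cluster_shape, 1.0, -(-cfg.chrom_sizes[c] // cfg.te_cluster_block))
        for c in chroms
    }
    te_ivs: List[GenomicInterval] = []
    chrom_p = sizes / sizes.sum()
    for cls, n in cfg.te_counts.items():
        lo, hi = te_class_len[cls]
        for _ in range(n):
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            w = block_w[chrom]
            blk = rng.choice(len(w), p=w / w.sum())
            length = int(rng.integers(lo, hi + 1))
            start = blk * cfg.te_cluster_block + int(
                rng.integers(0, cfg.te_cluster_block)
            )
            start = min(start, cfg.chrom_sizes[chrom] - length - 1)
            start = max(start, 0)
            copy = consensus[cls][:length].copy()
            n_mut = rng.binomial(length, cfg.te_mutation_rate)
            if n_mut:
                pos = rng.choice(length, size=n_mut, replace=False)
                copy[pos] = (copy[pos] + rng.integers(1, 4, n_mut)) % 4
            seq_arrays[chrom][start : start + length] = copy
            strand = "+" if rng.random() < 0.5 else "-"
            te_ivs.append(GenomicInterval(chrom, start, start + length, strand, cls))

    # --- germline SVA elements ------------------------------------------
    # Per-chromosome intensity varies (lognormal factor) so the reference
    # density profile is non-trivial for the density-correlation analysis.
    sva_factor = rng.lognormal(0.0, 0.6, len(chroms))
    sva_p = sizes * sva_factor
    sva_p = sva_p / sva_p.sum()
    hex_run = np.tile(
        np.frombuffer(HEXAMER.encode(), dtype=np.uint8), cfg.sva_hexamer_copies
    )
    hex_codes = np.searchsorted(_BASES, hex_run)  # ACGT are sorted bytes
    sva_ivs: List[GenomicInterval] = []
    placed: Dict[str, List[int]] = {c: [] for c in chroms}
    sva_total_len = len(hex_codes) + cfg.sva_body_len
    for i in range(cfg.n_germline_sva):
        for _attempt in range(5_000):
            chrom = chroms[rng.choice(len(chroms), p=sva_p)]
            size = cfg.chrom_sizes[chrom]
            margin = cfg.germline_clearance + 500
            if size <= 2 * margin + sva_total_len:
                continue
            start = int(rng.integers(margin, size - margin - sva_total_len))
            if any(abs(start - q) < 2 * cfg.germline_clearance + sva_total_len
                   for q in placed[chrom]):
                continue
            body = _random_sequence(rng, cfg.sva_body_len, 0.55)
            seq_arrays[chrom][start : start + len(hex_codes)] = hex_codes
            seq_arrays[chrom][
                start + len(hex_codes) : start + sva_total_len
            ] = body
            sva_ivs.append(
                GenomicInterval(chrom, start, start + sva_total_len, "+", f"SVA_{i}")
            )
            placed[chrom].append(start)
            break
        else:
            raise ValueError(
                "genome too small to place germline SVAs with clearance"
            )

    # --- gene models -----------------------------------------------------
    genes: List[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        size = cfg.chrom_sizes[chrom]
        n_ex = int(rng.integers(2, 7))
        ex_lens = rng.integers(100, 401, n_ex)
        in_lens = rng.integers(500, 3_001, n_ex - 1)
        glen = int(ex_lens.sum() + in_lens.sum())
        if glen + 200 >= size:
            continue
        start = int(rng.integers(100, size - glen - 100))
        exons: List[Tuple[int, int]] = []
        pos = start
        for j in range(n_ex):
            exons.append((pos, pos + int(ex_lens[j])))
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                pos += int(in_lens[j])
        end = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() < 0.8
        if coding:
            # CDS excludes a 5'UTR (60 bp) and 3'UTR (120 bp) in transcript
            # orientation, clipped to the terminal exons.
            if strand == "+":
                cds_start = min(exons[0][0] + 60, exons[0][1] - 1)
                cds_end = max(exons[-1][1] - 120, exons[-1][0] + 1)
            else:
                cds_start = min(exons[0][0] + 120, exons[0][1] - 1)
                cds_end = max(exons[-1][1] - 60, exons[-1][0] + 1)
            cds_end = max(cds_end, cds_start + 1)
        else:
            cds_start = cds_end = start
        genes.append(
            GeneModel(f"gene_{i}", chrom, start, end, strand, exons, cds_start, cds_end)
        )

    seqs = {c: _codes_to_str(a) for c, a in seq_arrays.items()}
    return Genome(seqs, IntervalSet(te_ivs), IntervalSet(sva_ivs), genes)


# ---------------------------------------------------------------------------
# Lineage-structured somatic insertions
# ---------------------------------------------------------------------------


def _placement_weights(
    genome: Genome, cfg: SimulationConfig
) -> Tuple[List[str], np.ndarray, Dict[str, np.ndarray]]:
    """Per-chromosome probabilities and per-10kb-block weights within them."""
    chroms = sorted(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    block = cfg.te_cluster_block
    block_w: Dict[str, np.ndarray] = {}
    for c in chroms:
        nb = -(-genome.chrom_sizes[c] // block)
        w = np.ones(nb)
        if cfg.placement == "te_biased":
            cnt = np.zeros(nb)
            for iv in genome.te:
                if iv.chrom == c and iv.label in ("SINE", "LINE"):
                    cnt[iv.midpoint // block] += 1
            gc_per_block = np.repeat(
                _block_gc_estimate(genome.seqs[c], cfg.gc_block),
                cfg.gc_block // block,
            )[:nb]
            w = (1.0 + cfg.te_bias * cnt) * np.clip(
                1.0 + cfg.gc_bias * (gc_per_block - cfg.gc_mean), 0.2, None
            )
        block_w[c] = w
    if cfg.placement == "density_proportional":
        sva_counts = np.array(
            [sum(1 for iv in genome.sva if iv.chrom == c) for c in chroms], float
        )
        chrom_p = sva_counts / sva_counts.sum()
    else:
        # blocks are equal-length, so total weight mass per chromosome is
        # proportional to the sum of its block weights
        chrom_totals = np.array([block_w[c].sum() for c in chroms])
        chrom_p = chrom_totals / chrom_totals.sum()
    return chroms, chrom_p, block_w


def _block_gc_estimate(seq: str, block: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    isgc = (arr == ord("G")) | (arr == ord("C"))
    nb = -(-len(seq) // block)
    out = np.empty(nb)
    for i in range(nb):
        chunk = isgc[i * block : (i + 1) * block]
        out[i] = chunk.mean() if len(chunk) else 0.0
    return out


def simulate_lineage_insertions(
    genome: Genome,
    tree: LineageTree,
    cfg: SimulationConfig,
    donor: str = "D1",
    rng: Optional[np.random.Generator] = None,
) -> TruthSet:
    """Place somatic insertions on lineage branches.

    Each insertion is a genomic position plus a fixed 5'-flank (the
    MboI-fragment side of the integration): the flank sequence is the
    reference upstream of the integration point, sampled so it is free of
    internal GATC sites and tandem hexamer runs, at least
    ``germline_clearance`` away from any germline SVA, and well separated
    from other somatic loci.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms, chrom_p, block_w = _placement_weights(genome, cfg)
    forbidden = merge_overlapping(
        IntervalSet(iv.padded(cfg.germline_clearance) for iv in genome.sva)
    )
    placed: Dict[str, List[int]] = {c: [] for c in chroms}
    insertions: List[TruthInsertion] = []
    counter = 0
    block = cfg.te_cluster_block
    for branch in sorted(cfg.branch_counts):
        missing = set(branch) - set(tree.leaves)
        if missing:
            raise ValueError(f"branch {branch} references unknown leaves {missing}")
        for _ in range(cfg.branch_counts[branch]):
            for _attempt in range(20_000):
                chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
                w = block_w[chrom]
                blk = rng.choice(len(w), p=w / w.sum())
                pos = blk * block + int(rng.integers(0, block))
                size = genome.chrom_sizes[chrom]
                flank_len = int(rng.integers(cfg.flank_min, cfg.flank_max + 1))
                if pos < flank_len + 10 or pos > size - 20:
                    continue
                iv = GenomicInterval(chrom, pos - flank_len, pos)
                if forbidden.overlaps_any(iv):
                    continue
                if any(abs(pos - q) < cfg.min_locus_separation for q in placed[chrom]):
                    continue
                flank = genome.seqs[chrom][pos - flank_len : pos]
                # flank must be GATC-free, carry no tandem hexamer run, and
                # not end in a hexamer copy (which would extend the SVA run
                # leftward and shift the detected flank boundary)
                if (
                    "GATC" in flank
                    or HEXAMER * 2 in flank
                    or flank.endswith(HEXAMER)
                    or "N" in flank
                ):
                    continue
                counter += 1
                insertions.append(
                    TruthInsertion(
                        ins_id=f"ins{counter:05d}",
                        chrom=chrom,
                        pos=pos,
                        flank_len=flank_len,
                        branch=branch,
                        flank_seq=flank,
                        hexamer_copies=int(
                            rng.integers(cfg.hexamer_min_copies, cfg.hexamer_max_copies + 1)
                        ),
                    )
                )
                placed[chrom].append(pos)
                break
            else:
                raise ValueError("genome too small to satisfy placement constraints")
    return TruthSet(donor=donor, insertions=insertions, germline_sva=genome.sva)


# ---------------------------------------------------------------------------
# RDA read synthesis
# ---------------------------------------------------------------------------


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        codes = np.searchsorted(_BASES, arr[hit])
        codes = (codes + rng.integers(1, 4, hit.sum())) % 4
        arr[hit] = _BASES[codes]
    return arr.tobytes().decode("ascii")


def _leak_flank(
    genome: Genome, sva: GenomicInterval, rng: np.random.Generator, cfg: SimulationConfig
) -> Optional[str]:
    """A germline-SVA 5'-flank: reference sequence immediately upstream."""
    seq = genome.seqs[sva.chrom]
    for _ in range(50):
        length = int(rng.integers(cfg.flank_min, cfg.flank_max + 1))
        if sva.start - length < 0:
            continue
        flank = seq[sva.start - length : sva.start]
        if (
            "GATC" not in flank
            and HEXAMER * 2 not in flank
            and not flank.endswith(HEXAMER)
        ):
            return flank
    return None


def synthesize_rda_reads(
    truth: TruthSet,
    genome: Genome,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, List[SequenceRecord]]:
    """Emit merged RDA amplicon reads per region for one donor.

    Read support per (insertion, region) is 1 with probability
    ``singleton_fraction``, else ``2 + Poisson(multi_support_extra_mean)``;
    supports are recorded back into the truth set. Artifact reads carry a
    GATC inside the flank; leak-through reads use germline SVA flanks.
    About half the reads are emitted reverse-complemented.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 101)
    regions = sorted({r for ins in truth.insertions for r in ins.regions})
    out: Dict[str, List[SequenceRecord]] = {}
    svas = list(genome.sva)
    for region in regions:
        reads: List[SequenceRecord] = []
        clean_templates: List[TruthInsertion] = []
        for ins in truth.insertions:
            if region not in ins.regions:
                continue
            clean_templates.append(ins)
            if rng.random() < cfg.singleton_fraction:
                support = 1
            else:
                support = 2 + int(rng.poisson(cfg.multi_support_extra_mean))
            ins.supports[region] = support
            amplicon = (
                RDA_PRIMER + "GATC" + ins.flank_seq
                + HEXAMER * ins.hexamer_copies + SVA_BODY
            )
            for j in range(support):
                seq = _mutate(amplicon, cfg.error_rate, rng)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                reads.append(
                    SequenceRecord(
                        f"{truth.donor}:{region}:{ins.ins_id}:r{j}", seq
                    )
                )
        n_clean = len(reads)
        # GATC re-ligation artifacts: a GATC written into the flank interior
        n_art = int(round(cfg.artifact_rate * n_clean))
        for j in range(n_art):
            ins = clean_templates[int(rng.integers(0, len(clean_templates)))]
            flank = ins.flank_seq
            off = int(rng.integers(1, len(flank) - 4))
            art_flank = flank[:off] + "GATC" + flank[off + 4 :]
            seq = (
                RDA_PRIMER + "GATC" + art_flank
                + HEXAMER * ins.hexamer_copies + SVA_BODY
            )
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"{truth.donor}:{region}:artifact{j}"
            truth.artifact_read_ids.add(rid)
            reads.append(SequenceRecord(rid, seq))
        # driver leak-through: flanks of annotated germline SVAs
        n_leak = int(round(cfg.leak_rate * n_clean))
        for j in range(n_leak):
            sva = svas[int(rng.integers(0, len(svas)))]
            flank = _leak_flank(genome, sva, rng, cfg)
            if flank is None:
                continue
            seq = (
                RDA_PRIMER + "GATC" + flank
                + HEXAMER * cfg.sva_hexamer_copies + SVA_BODY
            )
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"{truth.donor}:{region}:leak{j}"
            truth.leak_read_ids.add(rid)
            reads.append(SequenceRecord(rid, seq))
        order = rng.permutation(len(reads))
        out[region] = [reads[i] for i in order]
    return out


def split_into_pairs(
    record: SequenceRecord, read_len: int = 150
) -> Tuple[SequenceRecord, SequenceRecord]:
    """Fragment a merged amplicon into an overlapping R1/R2 pair."""
    seq = record.seq
    r1 = seq[:read_len]
    r2 = revcomp(seq[max(0, len(seq) - read_len):])
    return (
        SequenceRecord(record.id + "/1", r1),
        SequenceRecord(record.id + "/2", r2),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_genome(genome: Genome, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.seqs, outdir / "genome.fa")
    write_bed(genome.te, outdir / "te.bed")
    write_bed(genome.sva, outdir / "sva.bed")
    write_genes_bed12(genome.genes, outdir / "genes.bed")


def write_truth_tsv(truth: TruthSet, path) -> None:
    lines = ["donor\tins_id\tchrom\tstart\tend\tbranch\thexamer_copies\tsupports"]
    for ins in truth.insertions:
        supports = ",".join(
            f"{r}:{ins.supports[r]}" for r in sorted(ins.supports)
        )
        lines.append(
            f"{truth.donor}\t{ins.ins_id}\t{ins.chrom}\t{ins.pos - ins.flank_len}"
            f"\t{ins.pos}\t{';'.join(ins.branch)}\t{ins.hexamer_copies}\t{supports}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_tsv(path, germline_sva: Optional[IntervalSet] = None) -> TruthSet:
    lines = Path(path).read_text().splitlines()
    donor = ""
    insertions = []
    for line in lines[1:]:
        f = line.split("\t")
        donor = f[0]
        start, end = int(f[3]), int(f[4])
        supports = {}
        if f[7]:
            for part in f[7].split(","):
                r, c = part.split(":")
                supports[r] = int(c)
        insertions.append(
            TruthInsertion(
                ins_id=f[1], chrom=f[2], pos=end, flank_len=end - start,
                branch=tuple(f[5].split(";")), flank_seq="",
                hexamer_copies=int(f[6]), supports=supports,
            )
        )
    return TruthSet(
        donor=donor, insertions=insertions,
        germline_sva=germline_sva or IntervalSet(),
    )
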