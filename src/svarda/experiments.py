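"""Self-contained evaluation experiments on synthetic data.

Each function runs one study-scale experiment — spike-in recovery, lineage
topology recovery, singleton-fraction recovery, density-correlation
behaviour, GC-test calibration, TE-window enrichment — and returns plain
dictionaries of measured quantities. They are used by the acceptance
script and the analysis drivers; all randomness derives from the passed
seed.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .genomic_core import GenomicInterval, IntervalSet, merge_overlapping, revcomp
from .insertion_calling import InsertionEvent, SeedIndex, singleton_fraction
from .integration_landscape import (
    CorrelationTest,
    chromosomal_density,
    density_correlation,
    flank_gc_analysis,
    label_events,
    te_enrichment_fraction,
    te_rich_windows,
)
from .mosaic_phylogeny import internal_bipartitions
from .pipeline import PipelineResult, RunConfig, run_pipeline
from .synthetic_data import LineageTree, SimulationConfig, TruthSet

__all__ = [
    "spike_in_recovery",
    "topology_recovery",
    "density_experiment",
    "density_null_calibration",
    "gc_null_calibration",
    "gc_shift_power",
    "te_enrichment_experiment",
    "PLANTED_BIPARTITIONS",
]

#: Internal bipartitions of the default lineage (sides not containing the
#: cerebellar outgroup).
PLANTED_BIPARTITIONS: List[FrozenSet[str]] = [
    frozenset({"Pfc", "Calca"}),
    frozenset({"Hippo", "Pfc", "Calca"}),
]


def default_run_config(seed: int, **overrides) -> RunConfig:
    """The default synthetic study: exact-match alignment, default sim."""
    cfg = RunConfig(seed=seed, alignment_exact=True, **overrides)
    return cfg


def _uniquely_mappable(truth: TruthSet, index: SeedIndex) -> Dict[str, bool]:
    """Truth insertions whose flank occurs exactly once genome-wide."""
    out = {}
    for ins in truth.insertions:
        n = len(index.find_exact(ins.flank_seq)) + len(
            index.find_exact(revcomp(ins.flank_seq))
        )
        out[ins.ins_id] = n == 1
    return out


def spike_in_recovery(
    seed: int, result: Optional[PipelineResult] = None
) -> Dict[str, float]:
    """Run the default study and score event recovery against the truth.

    Recall is measured over uniquely mappable truth (insertion, region)
    pairs; precision over all emitted events. Also reports the number of
    events overlapping annotated SVA +- 3 kb (must be zero by
    construction) and the pooled singleton fraction.
    """
    if result is None:
        result = run_pipeline(default_run_config(seed))
    genome = result.genome
    index = SeedIndex(genome.seqs)
    padded_sva = merge_overlapping(
        IntervalSet(iv.padded(3_000) for iv in genome.sva)
    )
    n_truth = n_recovered = n_events = n_matched = in_pad = 0
    supports: List[int] = []
    singleton_by_donor = {}
    for donor, dres in result.donors.items():
        mappable = _uniquely_mappable(dres.truth, index)
        truth_by_region: Dict[str, IntervalSet] = {}
        for region in dres.events:
            ivs = [
                ins.interval
                for ins in dres.truth.insertions
                if region in ins.regions and mappable[ins.ins_id]
            ]
            truth_by_region[region] = IntervalSet(ivs)
        donor_events: List[InsertionEvent] = []
        for region, events in dres.events.items():
            tset = truth_by_region[region]
            eset = IntervalSet(e.interval for e in events)
            n_truth += len(tset)
            n_recovered += sum(1 for iv in tset if eset.overlaps_any(iv))
            n_events += len(events)
            n_matched += sum(
                1 for e in events if tset.overlaps_any(e.interval)
            )
            in_pad += sum(
                1 for e in events if padded_sva.overlaps_any(e.interval)
            )
            donor_events.extend(events)
            supports.extend(e.support for e in events)
        singleton_by_donor[donor] = singleton_fraction(donor_events)
    return {
        "recall": n_recovered / n_truth if n_truth else float("nan"),
        "precision": n_matched / n_events if n_events else float("nan"),
        "events_in_sva_pad": float(in_pad),
        "n_truth_pairs": float(n_truth),
        "n_events": float(n_events),
        "singleton_fraction": sum(1 for s in supports if s == 1) / len(supports),
        "singleton_fraction_by_donor": singleton_by_donor,
    }


def topology_recovery(
    seed: int, result: Optional[PipelineResult] = None
) -> Dict[str, object]:
    """Did the MP search uniquely recover the planted lineage topology?"""
    if result is None:
        result = run_pipeline(default_run_config(seed))
    out: Dict[str, object] = {}
    recovered = []
    min_supports = []
    for donor, dres in result.donors.items():
        res = dres.parsimony
        biparts = set(internal_bipartitions(res.topology))
        unique = len(res.co_optimal) == 1
        match = biparts == set(PLANTED_BIPARTITIONS)
        recovered.append(unique and match)
        supp = res.bootstrap or {}
        min_supports.append(
            min((supp.get(bp, 0.0) for bp in PLANTED_BIPARTITIONS), default=0.0)
        )
        out[f"tree_length_{donor}"] = res.tree_length
        out[f"informative_{donor}"] = res.informative_sites
    out["all_recovered"] = all(recovered)
    out["min_bootstrap"] = min(min_supports)
    return out


# ---------------------------------------------------------------------------
# Chromosomal density correlation
# ---------------------------------------------------------------------------


def _density_setup(rng: np.random.Generator, n_chroms: int, equal_sizes: bool):
    sizes = {
        f"chr{i + 1}": (200_000 if equal_sizes else int(rng.integers(100_000, 400_000)))
        for i in range(n_chroms)
    }
    # reference SVA annotation with chromosome-varying intensity
    intensity = rng.lognormal(0.0, 0.8, n_chroms)
    chroms = sorted(sizes)
    size_arr = np.array([sizes[c] for c in chroms], dtype=float)
    p = intensity * size_arr
    p = p / p.sum()
    counts = rng.multinomial(300, p)
    ivs = []
    for c, n in zip(chroms, counts):
        for j in range(n):
            start = int(rng.integers(0, sizes[c] - 1_500))
            ivs.append(GenomicInterval(c, start, start + 1_286, label=f"sva_{c}_{j}"))
    return sizes, IntervalSet(ivs)


def density_experiment(
    seed: int, n_insertions: int = 2_000, n_chroms: int = 20, mode: str = "proportional"
) -> CorrelationTest:
    """Correlate de novo density with the reference SVA density profile.

    ``proportional`` places insertions with per-chromosome probability
    proportional to reference SVA density x size (i.e. count); ``uniform``
    places them proportional to size alone on equal-size chromosomes (the
    null for calibration).
    """
    rng = np.random.default_rng(seed)
    sizes, sva = _density_setup(rng, n_chroms, equal_sizes=(mode == "uniform"))
    chroms = sorted(sizes)
    ref = chromosomal_density(
        {c: sum(1 for iv in sva if iv.chrom == c) for c in chroms}, sizes, sva
    )
    if mode == "proportional":
        dens = ref.table["density"].to_numpy()
        size_arr = ref.table["size"].to_numpy()
        p = dens * size_arr
    elif mode == "uniform":
        p = np.array([sizes[c] for c in chroms], dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = p / p.sum()
    counts = rng.multinomial(n_insertions, p)
    de_novo = chromosomal_density(dict(zip(chroms, counts.tolist())), sizes, sva)
    return density_correlation(ref, de_novo)


def density_null_calibration(
    seed: int, n_seeds: int = 300, alpha: float = 0.05
) -> Dict[str, float]:
    """Type-I behaviour of the correlation test under uniform placement."""
    rejections = 0
    abs_r = []
    for i in range(n_seeds):
        ct = density_experiment(seed + i, mode="uniform")
        rejections += ct.p < alpha
        abs_r.append(abs(ct.r))
    return {
        "rejection_rate": rejections / n_seeds,
        "mean_abs_r": float(np.mean(abs_r)),
        "n_seeds": float(n_seeds),
    }


# ---------------------------------------------------------------------------
# Flank GC test calibration and power
# ---------------------------------------------------------------------------


def _gc_flank_events(
    rng: np.random.Generator, m: int, gc: float, extension: int
) -> Tuple[List[InsertionEvent], Dict[str, str]]:
    """m disjoint flank events on a fresh homogeneous-GC chromosome."""
    span = 100  # nominal event span before extension
    slot = span + 2 * extension
    codes = rng.choice(4, size=m * slot, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
    genome = {"chr1": seq}
    events = [
        InsertionEvent(
            GenomicInterval("chr1", i * slot + extension, i * slot + extension + span),
            "sim", "D1", 1, 1,
        )
        for i in range(m)
    ]
    return events, genome


def gc_null_calibration(
    seed: int,
    n_reps: int = 1_000,
    m: int = 60,
    gc: float = 0.409,
    extension: int = 2_500,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Rejection rate of the flank-GC t-test when H0 is true.

    Flanks are disjoint windows of a homogeneous-GC sequence and the test
    constant equals the true GC, so the nominal rate is alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        events, genome = _gc_flank_events(rng, m, gc, extension)
        res = flank_gc_analysis(events, genome, extension=extension, g0=100 * gc)
        rejections += res.p < alpha
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": float(n_reps),
        "m_flanks": float(m),
    }


def gc_shift_power(
    seed: int,
    m: int = 500,
    g0: float = 40.9,
    shift: float = 2.0,
    extension: int = 2_500,
) -> Dict[str, float]:
    """p-value with a planted GC shift of ``shift`` percentage points."""
    rng = np.random.default_rng(seed)
    events, genome = _gc_flank_events(rng, m, (g0 + shift) / 100.0, extension)
    res = flank_gc_analysis(events, genome, extension=extension, g0=g0)
    return {"mean_gc": res.mean, "t": res.t, "p": res.p}


# ---------------------------------------------------------------------------
# TE-rich window enrichment
# ---------------------------------------------------------------------------


def te_enrichment_experiment(
    seed: int, result_biased: Optional[PipelineResult] = None
) -> Dict[str, float]:
    """TE-window enrichment of LINE/SINE-associated events.

    Runs the default study with TE/GC-biased insertion placement and, for
    contrast, with uniform placement, and reports the percentage of
    LINE/SINE-labeled events inside above-mean and top-quartile SINE+LINE
    windows.
    """
    out: Dict[str, float] = {}
    for mode in ("te_biased", "uniform"):
        if mode == "te_biased" and result_biased is not None:
            result = result_biased
        else:
            cfg = default_run_config(seed)
            cfg.simulation = {"placement": mode, "n_donors": 1}
            result = run_pipeline(cfg)
        genome = result.genome
        enr = te_rich_windows(genome.te, genome.chrom_sizes)
        fr_above = []
        fr_top = []
        for donor, dres in result.donors.items():
            for region, events in dres.events.items():
                labels = label_events(events, genome.genes, genome.te)
                if not any(l in ("LINE", "SINE") for l in labels):
                    continue
                fr_above.append(te_enrichment_fraction(events, labels, enr.above_mean))
                fr_top.append(te_enrichment_fraction(events, labels, enr.top25))
        out[f"{mode}_pct_above_mean"] = float(np.mean(fr_above))
        out[f"{mode}_pct_top25"] = float(np.mean(fr_top))
    return out
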