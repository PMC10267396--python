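"""End-to-end orchestration: simulate -> extract flanks -> call -> tree -> landscape.

A run is deterministic given the config seed and writes a self-describing
run directory: per-stage funnel counts, per-region event BEDs, newick
trees, report TSVs, and a manifest with every parameter used.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomic_core import GenomicInterval, IntervalSet, write_bed, write_fastq
from .insertion_calling import (
    CallingReport,
    InsertionEvent,
    SeedIndex,
    call_insertions,
    singleton_fraction,
)
from .integration_landscape import (
    annotate_features,
    chromosomal_density,
    density_correlation,
    flank_gc_analysis,
    label_events,
    mean_profile,
    reference_density,
    te_enrichment_fraction,
    te_rich_windows,
)
from .mosaic_phylogeny import (
    bootstrap_support,
    build_reference_positions,
    internal_bipartitions,
    mp_search,
    presence_absence_matrix,
    shared_set_counts,
    to_newick,
    write_character_fasta,
    write_phylip,
)
from .read_processing import FunnelCounts, process_reads
from .synthetic_data import (
    RDA_PRIMER,
    RDA_12MER,
    SVA_OUTWARD_PRIMER,
    Genome,
    LineageTree,
    SimulationConfig,
    TruthSet,
    generate_genome,
    save_genome,
    simulate_lineage_insertions,
    synthesize_rda_reads,
    write_truth_tsv,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "PipelineResult"]


class PipelineError(RuntimeError):
    """A stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All tunables of a pipeline run; serialized into the run manifest."""

    seed: int = 1
    # adapter / primer sequences
    rda_primer: str = RDA_PRIMER
    rda_12mer: str = RDA_12MER
    sva_outward_primer: str = SVA_OUTWARD_PRIMER
    # read processing
    hexamer_min_copies: int = 2
    max_primer_mismatch: int = 0
    # calling
    min_identity: float = 0.95
    min_coverage: float = 0.90
    alignment_exact: bool = False
    reference_pad: int = 1_000
    subtraction_pad: int = 3_000
    # phylogeny
    outgroup: str = "Cereb"
    bootstrap_replicates: int = 1_000
    # landscape
    window_width: int = 100_000
    window_stagger: int = 10_000
    gc_extension: int = 2_500
    gc_g0: float = 40.9
    # simulation sub-config (seed is filled from the run seed)
    simulation: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        known = {f.name for f in fields(SimulationConfig)}
        unknown = set(sim) - known
        if unknown:
            raise PipelineError("config", f"unknown simulation keys: {sorted(unknown)}")
        if "branch_counts" in sim:
            sim["branch_counts"] = {
                tuple(sorted(k.split(";"))) if isinstance(k, str) else tuple(k): v
                for k, v in sim["branch_counts"].items()
            }
        return SimulationConfig(**sim)

    def to_manifest(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        d["svarda_version"] = __version__
        d["python"] = sys.version.split()[0]
        return d


@dataclass
class DonorResult:
    truth: TruthSet
    events: Dict[str, List[InsertionEvent]]
    funnel: pd.DataFrame
    matrix: Any
    parsimony: Any
    shared: Any


@dataclass
class PipelineResult:
    genome: Genome
    donors: Dict[str, DonorResult]
    outdir: Optional[Path] = None


def _events_to_intervalset(events: List[InsertionEvent]) -> IntervalSet:
    return IntervalSet(e.interval for e in events)


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Run every stage; optionally write the full run directory."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage: simulate -------------------------------------------------
    try:
        sim_cfg = config.simulation_config()
        genome = generate_genome(sim_cfg)
        tree = LineageTree()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc
    if out is not None:
        save_genome(genome, out / "genome")

    genome_index = SeedIndex(genome.seqs)
    donors: Dict[str, DonorResult] = {}
    funnel_frames = []
    for d in range(sim_cfg.n_donors):
        donor = f"D{d + 1}"
        rng = np.random.default_rng(sim_cfg.seed + 1_000 * (d + 1))
        try:
            truth = simulate_lineage_insertions(genome, tree, sim_cfg, donor, rng)
            reads_by_region = synthesize_rda_reads(truth, genome, sim_cfg, rng)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", f"{donor}: {exc}") from exc
        if out is not None:
            write_truth_tsv(truth, out / f"truth_{donor}.tsv")
            (out / "reads").mkdir(exist_ok=True)
            for region, reads in reads_by_region.items():
                write_fastq(reads, out / "reads" / f"{donor}_{region}.fastq")

        # --- stage: extract-flanks ---------------------------------------
        events_by_region: Dict[str, List[InsertionEvent]] = {}
        rows = []
        for region, reads in reads_by_region.items():
            try:
                flanks, counts = process_reads(
                    reads,
                    region,
                    donor,
                    primer=config.rda_primer,
                    max_primer_mismatch=config.max_primer_mismatch,
                    hexamer_min_copies=config.hexamer_min_copies,
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("extract-flanks", f"{donor}/{region}: {exc}") from exc
            # --- stage: call ---------------------------------------------
            try:
                events, report = call_insertions(
                    flanks,
                    genome.seqs,
                    genome.sva,
                    region,
                    donor,
                    genome_index=genome_index,
                    reference_pad=config.reference_pad,
                    subtraction_pad=config.subtraction_pad,
                    min_identity=config.min_identity,
                    min_coverage=config.min_coverage,
                    exact=config.alignment_exact,
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("call", f"{donor}/{region}: {exc}") from exc
            events_by_region[region] = events
            rows.append(
                {"donor": donor, "region": region, **counts.as_dict(), **report.as_dict()}
            )
        funnel = pd.DataFrame(rows)
        funnel_frames.append(funnel)
        if out is not None:
            (out / "events").mkdir(exist_ok=True)
            for region, events in events_by_region.items():
                ivs = IntervalSet(
                    GenomicInterval(
                        e.interval.chrom, e.interval.start, e.interval.end,
                        label=f"{donor}_{region}_event{i}",
                    )
                    for i, e in enumerate(events)
                )
                supports = [e.support for e in sorted(events, key=lambda e: e.interval.sort_key())]
                write_bed(ivs, out / "events" / f"{donor}_{region}.bed", scores=supports)

        # --- stage: phylogeny --------------------------------------------
        try:
            event_sets = {
                r: _events_to_intervalset(evs) for r, evs in events_by_region.items()
            }
            reference = build_reference_positions(event_sets)
            matrix = presence_absence_matrix(reference, event_sets)
            shared = shared_set_counts(matrix)
            result = mp_search(matrix, config.outgroup)
            result.bootstrap = bootstrap_support(
                matrix,
                config.outgroup,
                replicates=config.bootstrap_replicates,
                seed=sim_cfg.seed + 7_000 + d,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("phylogeny", f"{donor}: {exc}") from exc
        if out is not None:
            (out / "phylogeny").mkdir(exist_ok=True)
            (out / "phylogeny" / f"{donor}.nwk").write_text(to_newick(result) + "\n")
            write_phylip(matrix, out / "phylogeny" / f"{donor}_matrix.phy")
            write_character_fasta(matrix, out / "phylogeny" / f"{donor}_matrix.fasta")
            venn = pd.DataFrame(
                [
                    {"regions": ";".join(sorted(k)), "n_loci": v}
                    for k, v in sorted(
                        shared.exact.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                    )
                ]
            )
            venn.to_csv(out / "phylogeny" / f"{donor}_venn.tsv", sep="\t", index=False)

        donors[donor] = DonorResult(truth, events_by_region, funnel, matrix, result, shared)

    # --- stage: landscape -----------------------------------------------
    try:
        landscape_tables = compute_landscape(genome, donors, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("landscape", str(exc)) from exc
    if out is not None:
        (out / "landscape").mkdir(exist_ok=True)
        for name, frame in landscape_tables.items():
            frame.to_csv(out / "landscape" / f"{name}.tsv", sep="\t")
        pd.concat(funnel_frames).to_csv(out / "funnel.tsv", sep="\t", index=False)
        (out / "manifest.yaml").write_text(yaml.safe_dump(config.to_manifest()))

    return PipelineResult(genome, donors, out)


def compute_landscape(
    genome: Genome, donors: Dict[str, DonorResult], config: RunConfig
) -> Dict[str, pd.DataFrame]:
    """Density, feature-fraction, TE-enrichment and GC tables for a run."""
    sizes = genome.chrom_sizes
    ref = reference_density(genome.sva, sizes)
    density_rows = {"reference": ref.table["density"]}
    corr_rows = []
    regions = sorted(next(iter(donors.values())).events)
    for region in regions:
        profiles = []
        for donor, dres in donors.items():
            counts: Dict[str, int] = {}
            for ev in dres.events[region]:
                counts[ev.interval.chrom] = counts.get(ev.interval.chrom, 0) + 1
            profiles.append(chromosomal_density(counts, sizes, genome.sva))
        mp = mean_profile(profiles)
        density_rows[region] = mp.table["density"]
        ct = density_correlation(ref, mp)
        corr_rows.append({"region": region, "r": ct.r, "n": ct.n, "t": ct.t, "p": ct.p})
    density = pd.DataFrame(density_rows)

    enr = te_rich_windows(
        genome.te, sizes, width=config.window_width, stagger=config.window_stagger
    )
    feature_frames = []
    table1_rows = []
    table2_rows = []
    for donor, dres in donors.items():
        ann = annotate_features(dres.events, genome.genes, genome.te)
        feature_frames.append(ann.fractions)
        for region in regions:
            events = dres.events[region]
            labels = label_events(events, genome.genes, genome.te)
            sample = f"{region}_{donor[1:]}"
            row: Dict[str, Any] = {"sample": sample}
            try:
                row["pct_above_mean_windows"] = te_enrichment_fraction(
                    events, labels, enr.above_mean
                )
                row["pct_top25_windows"] = te_enrichment_fraction(
                    events, labels, enr.top25
                )
            except Exception:
                row["pct_above_mean_windows"] = float("nan")
                row["pct_top25_windows"] = float("nan")
            table1_rows.append(row)
            gc = flank_gc_analysis(
                events, genome.seqs, extension=config.gc_extension, g0=config.gc_g0
            )
            table2_rows.append(
                {"sample": sample, "mean_gc_percent": gc.mean, "t": gc.t, "p": gc.p}
            )
    features = sum(feature_frames[1:], feature_frames[0].copy()) / len(feature_frames)
    return {
        "density": density,
        "density_correlation": pd.DataFrame(corr_rows).set_index("region"),
        "feature_fractions": features,
        "te_enrichment": pd.DataFrame(table1_rows).set_index("sample"),
        "flank_gc": pd.DataFrame(table2_rows).set_index("sample"),
    }
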